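"""Guide-only-controlled enrichment scoring.

The core statistic of the guide-only (GO) screen design. Counts from the
Cas9-positive arm are compared against the matched Cas9-negative
("guide only") arm, which experienced the same stochastic bottleneck
drift but no editing, so Cas9-independent abundance changes cancel:

1. counts are pseudocounted (+1) and scaled to reads-per-million;
2. per guide i, stage t in {T0, Tf} and replicate r,
   lambda[i,t,r] = log2(a_pos[i,t,r] / a_neg[i,t,r]);
3. within each (t, r), guides get average-rank percentiles
   rho in (0, 1] of lambda;
4. a gene's Enrichment Score at a stage is the mean rho of its guides
   (Initial ES at T0, adherent; Final ES at Tf, spheroid); the Library
   ES is the same construction on raw L0 abundance, reported for QC;
5. the Enrichment Ratio ER = mean_r Final ES / mean_r Initial ES; a
   two-sided paired t-test across replicates (Final vs Initial) gives p,
   Benjamini-Hochberg gives p_adj;
6. a gene is called depleted_in_suspension when ER < 1 and p_adj < 0.05
   (both strict; thresholds configurable).

A "naive" variant without the guide-only control is provided for
benchmarking: lambda at Tf is log2(a_pos[Tf]/a_pos[T0]) and lambda at T0
is identically zero, so the Initial ES collapses to the midpoint
percentile (N+1)/(2N) and the rest of the pipeline is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .counting import CountMatrix, SampleDescriptor
from .library import GuideLibrary

logger = logging.getLogger(__name__)

CALL_DEPLETED = "depleted_in_suspension"
CALL_NONE = "not_called"

#: canonical column order of the results table
RESULT_COLUMNS = [
    "gene",
    "n_guides",
    "library_es",
    "initial_es_mean",
    "final_es_mean",
    "er",
    "p_value",
    "p_adj",
    "call",
]


@dataclass(frozen=True)
class CallConfig:
    """Hit-calling thresholds: ER below ``er_threshold`` and BH-adjusted
    p below ``alpha``, both strict."""

    er_threshold: float = 1.0
    alpha: float = 0.05
    test: str = "paired_t"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.er_threshold <= 0:
            raise ConfigurationError("er_threshold must be positive")
        if self.test != "paired_t":
            raise ConfigurationError(f"unknown test {self.test!r}")


class AbundanceMatrix:
    """Pseudocounted reads-per-million; every entry positive, columns sum to 1e6."""

    def __init__(self, abundance: pd.DataFrame, design: Sequence[SampleDescriptor]):
        self.abundance = abundance
        self.design = list(design)

    def sample(self, arm: str, stage: str, replicate: int) -> pd.Series:
        for d in self.design:
            if d.key == (arm, stage, replicate):
                return self.abundance[d.sample_id]
        raise ValidationError(f"no sample with arm={arm}, stage={stage}, replicate={replicate}")

    def samples(self, arm: str, stage: str) -> list[SampleDescriptor]:
        return sorted(
            (d for d in self.design if d.arm == arm and d.stage == stage),
            key=lambda d: d.replicate,
        )


class GuideRatioTable:
    """Guide-level log2 ratios and their within-(stage, replicate) percentiles.

    ``lam`` and ``rho`` are DataFrames indexed by guide_id with MultiIndex
    columns (stage, replicate). ``library_rho`` holds the average-rank
    percentile of raw L0 abundance (mean over L0 samples if several).
    """

    def __init__(self, lam: pd.DataFrame, rho: pd.DataFrame, library_rho: pd.Series):
        self.lam = lam
        self.rho = rho
        self.library_rho = library_rho

    def replicates(self, stage: str) -> list[int]:
        return sorted({r for (t, r) in self.lam.columns if t == stage})


def _percentile_ranks(values: pd.Series) -> pd.Series:
    """Average-rank percentile in (0, 1]: rank/N, ties share the mean rank."""
    ranks = stats.rankdata(values.to_numpy(), method="average")
    return pd.Series(ranks / len(values), index=values.index)


def normalize(counts: CountMatrix) -> AbundanceMatrix:
    """Pseudocount (+1) and scale each sample to one million.

    a[i,s] = 1e6 * (c[i,s] + 1) / sum_j (c[j,s] + 1); the +1 guarantees
    positive abundances so every downstream log-ratio is finite.
    """
    if counts.counts.empty:
        raise ValidationError("empty count matrix")
    pseudo = counts.counts.astype(np.float64) + 1.0
    ab = 1e6 * pseudo / pseudo.sum(axis=0)
    return AbundanceMatrix(ab, counts.design)


def guide_log_ratios(
    ab: AbundanceMatrix,
    design: Sequence[SampleDescriptor] | None = None,
    method: str = "guide_only",
    cas9neg: str = "strict",
) -> GuideRatioTable:
    """Per-guide log2 ratios and percentile ranks for stages T0 and Tf.

    method="guide_only" (default): ratio of the Cas9+ over the matched
    Cas9- abundance at the same stage and replicate. With
    ``cas9neg="pooled"`` a missing Cas9- replicate falls back to the mean
    Cas9- abundance at that stage; the default is an error.

    method="naive": no Cas9- control; the Tf ratio is over the same
    replicate's Cas9+ T0 abundance, and the T0 ratio is identically 0.
    """
    if method not in ("guide_only", "naive"):
        raise ConfigurationError(f"unknown scoring method {method!r}")
    if cas9neg not in ("strict", "pooled"):
        raise ConfigurationError(f"cas9neg must be 'strict' or 'pooled', got {cas9neg!r}")
    design = list(design) if design is not None else ab.design

    lam_cols: dict[tuple[str, int], pd.Series] = {}
    pos_reps = {t: [d.replicate for d in ab.samples("cas9_pos", t)] for t in ("T0", "Tf")}
    if not pos_reps["T0"] or not pos_reps["Tf"]:
        raise ValidationError("Cas9-positive samples required at both T0 and Tf")

    if method == "guide_only":
        for stage in ("T0", "Tf"):
            neg_samples = ab.samples("cas9_neg", stage)
            neg_by_rep = {d.replicate: ab.abundance[d.sample_id] for d in neg_samples}
            for r in pos_reps[stage]:
                a_pos = ab.sample("cas9_pos", stage, r)
                if r in neg_by_rep:
                    a_neg = neg_by_rep[r]
                elif cas9neg == "pooled" and neg_by_rep:
                    a_neg = pd.concat(neg_by_rep.values(), axis=1).mean(axis=1)
                    logger.info("stage %s replicate %d: pooled Cas9- denominator", stage, r)
                else:
                    raise ValidationError(
                        f"no Cas9-negative sample for stage {stage} replicate {r} "
                        "(set cas9neg='pooled' to use the stage mean)"
                    )
                lam_cols[(stage, r)] = np.log2(a_pos / a_neg)
    else:
        common = sorted(set(pos_reps["T0"]) & set(pos_reps["Tf"]))
        if not common:
            raise ValidationError("naive scoring needs matched Cas9+ T0/Tf replicates")
        for r in common:
            a_t0 = ab.sample("cas9_pos", "T0", r)
            lam_cols[("T0", r)] = pd.Series(0.0, index=a_t0.index)
            lam_cols[("Tf", r)] = np.log2(ab.sample("cas9_pos", "Tf", r) / a_t0)

    lam = pd.DataFrame(lam_cols)
    lam.columns = pd.MultiIndex.from_tuples(lam.columns, names=["stage", "replicate"])
    rho = lam.apply(_percentile_ranks, axis=0)

    l0 = ab.samples("library", "L0")
    if l0:
        lib_rho = pd.concat(
            [_percentile_ranks(ab.abundance[d.sample_id]) for d in l0], axis=1
        ).mean(axis=1)
    else:
        lib_rho = pd.Series(np.nan, index=lam.index)
    return GuideRatioTable(lam, rho, lib_rho)


def gene_scores(
    ratios: GuideRatioTable, lib: GuideLibrary, ab: AbundanceMatrix | None = None
) -> pd.DataFrame:
    """Aggregate guide percentiles to per-gene Enrichment Scores.

    Returns a DataFrame indexed by gene with n_guides, is_control,
    library_es, and one column per (stage, replicate) ES, e.g.
    ``es_T0_r1``. A gene's stage/replicate ES is the mean rho of its
    guides; the Library ES is the mean L0 abundance percentile.
    """
    gene_of = pd.Series(lib.gene_of())
    present = gene_of.index.intersection(ratios.rho.index)
    skipped = set(lib.genes) - set(gene_of[present])
    if skipped:
        logger.warning("%d gene(s) have no scored guides and are excluded", len(skipped))
    grouper = gene_of[present]

    rho = ratios.rho.loc[present]
    by_gene = rho.groupby(grouper.values).mean()
    out = pd.DataFrame(index=by_gene.index)
    out.index.name = "gene"
    out["n_guides"] = grouper.value_counts().reindex(out.index)
    controls = lib.control_genes()
    out["is_control"] = [g in controls for g in out.index]
    out["library_es"] = ratios.library_rho.loc[present].groupby(grouper.values).mean()
    for (stage, r) in by_gene.columns:
        out[f"es_{stage}_r{r}"] = by_gene[(stage, r)]
    return out


def _es_matrix(table: pd.DataFrame, stage: str) -> np.ndarray:
    cols = sorted(
        (c for c in table.columns if c.startswith(f"es_{stage}_r")),
        key=lambda c: int(c.rsplit("r", 1)[1]),
    )
    if not cols:
        raise ValidationError(f"no ES columns for stage {stage}")
    return table[cols].to_numpy()


def enrichment_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Add Spheroid/Adherent Enrichment Ratio: mean Final ES / mean Initial ES.

    ER < 1 marks genes whose guides dropped out more strongly in
    suspension (spheroid) than adherent growth — candidate survival genes.
    """
    table = table.copy()
    table["initial_es_mean"] = _es_matrix(table, "T0").mean(axis=1)
    table["final_es_mean"] = _es_matrix(table, "Tf").mean(axis=1)
    table["er"] = table["final_es_mean"] / table["initial_es_mean"]
    return table


def paired_test(es_initial: Sequence[float], es_final: Sequence[float]) -> float:
    """Two-sided paired t-test (df = R - 1) on per-replicate ES pairs.

    Degenerate cases by convention: all differences zero -> p = 1;
    nonzero constant differences (zero variance) -> p = 0 (logged as a
    degenerate-variance case).
    """
    es_initial = np.asarray(es_initial, dtype=float)
    es_final = np.asarray(es_final, dtype=float)
    if es_initial.shape != es_final.shape:
        raise ValidationError("initial/final ES vectors must have equal length")
    if es_initial.size < 2:
        raise ValidationError("paired test requires at least 2 replicates")
    p, _ = _paired_test_arrays(es_initial[None, :], es_final[None, :])
    return float(p[0])


def _paired_test_arrays(es0: np.ndarray, esf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t over rows; returns (p, degenerate_flags)."""
    if es0.shape[1] < 2:
        raise ValidationError("paired test requires at least 2 replicates")
    d = esf - es0
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    n = d.shape[1]
    p = np.ones(d.shape[0])
    degenerate = (sd == 0) & (mean != 0)
    ok = sd > 0
    t = np.zeros(d.shape[0])
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    p[degenerate] = 0.0
    if degenerate.any():
        logger.warning(
            "%d gene(s) had zero variance with nonzero mean difference; p set to 0",
            int(degenerate.sum()),
        )
    return p, degenerate


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValidationError("NaN p-values passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_genes(table: pd.DataFrame, cfg: CallConfig = CallConfig()) -> pd.DataFrame:
    """Flag genes with ER strictly below threshold and p_adj strictly below alpha."""
    table = table.copy()
    hit = (table["er"] < cfg.er_threshold) & (table["p_adj"] < cfg.alpha)
    table["call"] = np.where(hit, CALL_DEPLETED, CALL_NONE)
    return table


def score_screen(
    counts: CountMatrix,
    lib: GuideLibrary,
    cfg: CallConfig = CallConfig(),
    method: str = "guide_only",
    cas9neg: str = "strict",
) -> pd.DataFrame:
    """Full pipeline: normalize -> ratios -> gene ES -> ER -> test -> BH -> calls.

    Returns the gene table indexed by gene, including per-replicate ES
    columns and the canonical result columns.
    """
    ab = normalize(counts)
    ratios = guide_log_ratios(ab, counts.design, method=method)
    table = gene_scores(ratios, lib, ab)
    table = enrichment_ratio(table)
    p, degenerate = _paired_test_arrays(_es_matrix(table, "T0"), _es_matrix(table, "Tf"))
    table["p_value"] = p
    table["degenerate_variance"] = degenerate
    table["p_adj"] = bh_adjust(p)
    return call_genes(table, cfg)


def naive_scores(
    counts: CountMatrix, lib: GuideLibrary, cfg: CallConfig = CallConfig()
) -> pd.DataFrame:
    """Benchmark baseline without the guide-only control (Cas9+ Tf vs T0)."""
    return score_screen(counts, lib, cfg, method="naive")


def results_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Project the gene table onto the canonical output columns (+ is_control)."""
    out = table.reset_index()
    cols = RESULT_COLUMNS + ["is_control"]
    return out[cols]


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    results_frame(table).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"scores file {path} lacks columns {sorted(missing)}")
    return df.set_index("gene")
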