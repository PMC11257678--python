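"""Generative model of a guide-only-controlled dropout screen.

Emulates the screen design end to end: a lognormally skewed plasmid
library (L0) is read at depth D; per replicate, each arm passes the
library through a cell bottleneck of size B (multinomial sampling — the
stochastic, Cas9-independent drift that dominates non-proliferative
cultures) to give the initial adherent population (T0), then through an
independent second bottleneck into suspension (Tf). Only the
Cas9-positive arm additionally reweights guide frequencies by each
gene's fitness multiplier (w < 1 = guides of that gene drop out) —
w_adherent acting at T0 and w_suspension at Tf. Sequencing is a second
multinomial at depth D, so read-level overdispersion emerges from the
two-stage sampling hierarchy.

The planted truth (per-gene class and multipliers) is returned alongside
the counts, which makes every downstream stage testable without real
sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .counting import CountMatrix, SampleDescriptor, assemble_counts
from .library import GuideLibrary, GuideRecord, group_controls
from . import qc, scoring

EFFECT_CLASSES = ("neutral", "adherent_essential", "suspension_essential", "both")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated screen.

    Defaults mirror a desk-scale genome-wide design: 2000 genes x 4
    guides plus 1000 non-targeting controls, triplicates, a 1e5-cell
    bottleneck per passage (the severity knob for drift), 1e6 reads per
    sample, lognormal library skew sigma=0.5, and a 4-fold per-passage
    dropout (w = 0.25) for affected guides.
    """

    n_genes: int = 2000
    guides_per_gene: int = 4
    n_controls: int = 1000
    replicates: int = 3
    library_logsd: float = 0.5
    bottleneck_size: int = 100_000
    depth: int = 1_000_000
    effect_classes: Mapping[str, float] = field(
        default_factory=lambda: {"neutral": 1.0}
    )
    effect_size: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name, val in (
            ("n_genes", self.n_genes),
            ("guides_per_gene", self.guides_per_gene),
            ("replicates", self.replicates),
            ("bottleneck_size", self.bottleneck_size),
            ("depth", self.depth),
        ):
            if int(val) < 1:
                raise ConfigurationError(f"{name} must be positive, got {val}")
        if self.n_controls < 0:
            raise ConfigurationError("n_controls must be >= 0")
        if not 0 < self.effect_size <= 1:
            raise ConfigurationError("effect_size must lie in (0, 1]")
        unknown = set(self.effect_classes) - set(EFFECT_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown effect classes: {sorted(unknown)}")
        total = sum(self.effect_classes.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"effect class fractions must sum to 1, got {total}")


def _synthetic_library(cfg: SimConfig, rng: np.random.Generator) -> GuideLibrary:
    n_guides = cfg.n_genes * cfg.guides_per_gene + cfg.n_controls
    spacers = set()
    seqs = []
    while len(seqs) < n_guides:
        batch = rng.integers(0, 4, size=(n_guides - len(seqs), 20))
        for row in batch:
            s = "".join(_BASES[row])
            if s not in spacers:
                spacers.add(s)
                seqs.append(s)
    records = []
    i = 0
    for g in range(cfg.n_genes):
        gene = f"GENE{g + 1:05d}"
        for j in range(cfg.guides_per_gene):
            records.append(GuideRecord(f"{gene}_g{j + 1}", gene, seqs[i]))
            i += 1
    for c in range(cfg.n_controls):
        records.append(
            GuideRecord(f"NonTargeting_{c + 1:05d}", "NonTargeting", seqs[i], is_control=True)
        )
        i += 1
    lib = GuideLibrary(records)
    if cfg.n_controls:
        lib = group_controls(lib, cfg.guides_per_gene)
    return lib


def _assign_classes(cfg: SimConfig, lib: GuideLibrary, rng: np.random.Generator) -> pd.DataFrame:
    genes = [g for g in lib.genes if not g.startswith("CTRL_")]
    ctrl_genes = [g for g in lib.genes if g.startswith("CTRL_")]
    counts = {k: int(round(frac * len(genes))) for k, frac in cfg.effect_classes.items()}
    # rounding drift absorbed by the largest class
    drift = len(genes) - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    labels = np.repeat(
        [k for k in EFFECT_CLASSES if k in counts],
        [counts[k] for k in EFFECT_CLASSES if k in counts],
    )
    rng.shuffle(labels)
    w = cfg.effect_size
    rows = []
    for gene, klass in zip(genes, labels):
        rows.append(
            {
                "gene": gene,
                "class": klass,
                "w_adherent": w if klass in ("adherent_essential", "both") else 1.0,
                "w_suspension": w if klass in ("suspension_essential", "both") else 1.0,
            }
        )
    for gene in ctrl_genes:
        rows.append({"gene": gene, "class": "neutral", "w_adherent": 1.0, "w_suspension": 1.0})
    return pd.DataFrame(rows).set_index("gene")


def _multinomial_freq(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    p = p / p.sum()
    return rng.multinomial(n, p) / n


def simulate_screen(cfg: SimConfig) -> tuple[CountMatrix, GuideLibrary, pd.DataFrame]:
    """Simulate a full screen; returns (counts, library, truth).

    All randomness flows from ``cfg.seed``: identical configs give
    identical matrices. Per-sample read counts sum exactly to
    ``cfg.depth``.
    """
    rng = np.random.default_rng(cfg.seed)
    lib = _synthetic_library(cfg, rng)
    truth = _assign_classes(cfg, lib, rng)

    gene_of = lib.gene_of()
    guide_genes = np.array([gene_of[g] for g in lib.guide_ids])
    w_adh = truth["w_adherent"].reindex(guide_genes).to_numpy()
    w_sus = truth["w_suspension"].reindex(guide_genes).to_numpy()

    n_guides = len(lib)
    f = np.exp(rng.normal(0.0, cfg.library_logsd, size=n_guides))
    f /= f.sum()

    columns: dict[str, pd.Series] = {}
    design: list[SampleDescriptor] = []
    guide_index = pd.Index(lib.guide_ids, name="guide_id")

    def add_sample(sid, arm, stage, rep, label, freq):
        reads = rng.multinomial(cfg.depth, freq / freq.sum())
        columns[sid] = pd.Series(reads, index=guide_index)
        design.append(SampleDescriptor(sid, arm, stage, rep, label))

    add_sample("L0", "library", "L0", 1, "library", f)

    for r in range(1, cfg.replicates + 1):
        for arm, w_t0, w_tf in (
            ("cas9_pos", w_adh, w_sus),
            ("cas9_neg", np.ones(n_guides), np.ones(n_guides)),
        ):
            # T0: bottleneck from the library, then Cas9-dependent selection
            freq_t0 = _multinomial_freq(rng, cfg.bottleneck_size, f) * w_t0
            s = freq_t0.sum()
            if s == 0:
                raise ValidationError("bottleneck extinguished every guide; increase B")
            freq_t0 /= s
            add_sample(f"T0_{arm}_r{r}", arm, "T0", r, "adherent", freq_t0)
            # Tf: independent second bottleneck from this arm's T0, then selection
            freq_tf = _multinomial_freq(rng, cfg.bottleneck_size, freq_t0) * w_tf
            s = freq_tf.sum()
            if s == 0:
                raise ValidationError("bottleneck extinguished every guide; increase B")
            freq_tf /= s
            add_sample(f"Tf_{arm}_r{r}", arm, "Tf", r, "spheroid", freq_tf)

    counts = assemble_counts(columns, design, lib)
    return counts, lib, truth


def benchmark_recovery(cfg: SimConfig, pipeline_variant: str = "guide_only") -> dict:
    """Simulate, score, and measure recovery of the planted truth.

    Returns a dict with the per-gene table joined to the truth plus:
    ``auc`` (ranking AUC of -ER for suspension-affected genes; NaN when
    no gene is planted), ``n_calls``, and ``false_positives`` (calls on
    genes with no suspension effect, control pseudo-genes included).
    """
    if pipeline_variant not in ("guide_only", "naive"):
        raise ConfigurationError(f"unknown pipeline variant {pipeline_variant!r}")
    counts, lib, truth = simulate_screen(cfg)
    table = scoring.score_screen(counts, lib, method=pipeline_variant)
    joined = table.join(truth)
    affected = (joined["w_suspension"] < 1).to_numpy()
    if affected.any() and (~affected).any():
        auc = qc.roc_controls(-joined["er"].to_numpy(), affected).auc
    else:
        auc = float("nan")
    calls = joined["call"] == scoring.CALL_DEPLETED
    return {
        "table": joined,
        "auc": auc,
        "n_calls": int(calls.sum()),
        "false_positives": int((calls & ~affected).sum()),
    }


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")
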