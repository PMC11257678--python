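"""Model/Results interface over the scoring pipeline.

``ScreenModel`` holds the data (count matrix, library, design) and the
variant to fit; ``fit()`` runs normalization, guide ratios, gene scores,
the paired test and BH correction, returning a ``ScreenResults`` that
carries the per-gene estimates, QC methods, a ``summary()`` table, and
writers/plotters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .counting import CountMatrix
from .library import GuideLibrary, group_controls
from . import qc, scoring
from .scoring import CallConfig


class ScreenModel:
    """A guide-only-controlled dropout screen to be scored.

    Parameters
    ----------
    counts
        Guide x sample read counts with design metadata.
    library
        The sgRNA reference. When ``control_group_size`` is given,
        non-targeting controls are grouped into pseudo-genes of that size
        so they enter the gene-level statistics (recommended for QC).
    method
        "guide_only" (Cas9+/Cas9- ratios; the default) or "naive"
        (Cas9+ Tf vs T0, no drift control; benchmarking only).
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: GuideLibrary,
        control_group_size: int | None = None,
        method: str = "guide_only",
    ):
        if control_group_size is not None:
            library = group_controls(library, control_group_size)
        self.counts = counts
        self.library = library
        self.method = method

    @classmethod
    def from_files(
        cls,
        counts_path,
        library_path,
        design_path,
        control_group_size: int | None = None,
        method: str = "guide_only",
    ) -> "ScreenModel":
        from .counting import read_counts, read_design
        from .library import read_library

        design, _ = read_design(design_path)
        lib = read_library(library_path)
        counts = read_counts(counts_path, design)
        return cls(counts, lib, control_group_size=control_group_size, method=method)

    def fit(self, cfg: CallConfig = CallConfig()) -> "ScreenResults":
        table = scoring.score_screen(self.counts, self.library, cfg, method=self.method)
        return ScreenResults(self, table, cfg)


class ScreenResults:
    """Fitted screen: per-gene ES/ER estimates, p-values, calls, and QC."""

    def __init__(self, model: ScreenModel, gene_table: pd.DataFrame, cfg: CallConfig):
        self.model = model
        self.gene_table = gene_table
        self.call_config = cfg

    @property
    def hits(self) -> pd.Index:
        """Genes called depleted in suspension (candidate survival genes)."""
        t = self.gene_table
        return t.index[t["call"] == scoring.CALL_DEPLETED]

    def control_nonessential_rate(self) -> float:
        return qc.control_nonessential_rate(self.gene_table)

    def roc_controls(self, score: str = "neg_er") -> qc.RocResult:
        """ROC of essentiality score vs control (known-nonessential) labels.

        Controls are the negatives; every targeting gene is treated as a
        putative positive. ``score`` is "neg_er" (default) or
        "neg_log10_p_adj".
        """
        t = self.gene_table
        if score == "neg_er":
            s = -t["er"].to_numpy()
        elif score == "neg_log10_p_adj":
            s = -np.log10(np.clip(t["p_adj"].to_numpy(), 1e-300, None))
        else:
            raise ValidationError(f"unknown ROC score {score!r}")
        labels = ~t["is_control"].to_numpy(dtype=bool)
        return qc.roc_controls(s, labels)

    def correlate_external(self, viability: pd.Series, method: str = "spearman"):
        return qc.correlate_external(self.gene_table["er"], viability, method=method)

    def summary(self) -> str:
        t = self.gene_table
        targeting = t[~t["is_control"].astype(bool)]
        lines = [
            "Guide-only CRISPR screen results" if self.model.method == "guide_only"
            else "Naive (uncontrolled) CRISPR screen results",
            "=" * 44,
            f"genes scored:            {len(targeting)}",
            f"control pseudo-genes:    {int(t['is_control'].sum())}",
            f"replicates:              {len([c for c in t.columns if c.startswith('es_T0_r')])}",
            f"ER threshold / alpha:    {self.call_config.er_threshold} / {self.call_config.alpha}",
            f"genes with ER < {self.call_config.er_threshold}:      "
            f"{int((targeting['er'] < self.call_config.er_threshold).sum())}",
            f"called depleted:         {int((targeting['call'] == scoring.CALL_DEPLETED).sum())}",
        ]
        if t["is_control"].any():
            lines.append(f"control non-essential:   {self.control_nonessential_rate():.3f}")
        return "\n".join(lines)

    def write(self, path) -> None:
        scoring.write_scores(self.gene_table, path)

    def plot_scores(self, path=None, ax=None):
        """Scatter of spheroid score (Final ES) vs adherent score (Initial ES).

        Hits are highlighted; the identity line marks ER = 1.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.gene_table
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        hit = t["call"] == scoring.CALL_DEPLETED
        ax.scatter(t.loc[~hit, "initial_es_mean"], t.loc[~hit, "final_es_mean"],
                   s=4, c="0.6", label="not called")
        ax.scatter(t.loc[hit, "initial_es_mean"], t.loc[hit, "final_es_mean"],
                   s=6, c="crimson", label="depleted in suspension")
        lim = (0, 1.02)
        ax.plot(lim, lim, lw=0.8, c="k", ls="--")
        ax.set(xlim=lim, ylim=lim, xlabel="adherent score (Initial ES)",
               ylabel="spheroid score (Final ES)")
        ax.legend(frameon=False, fontsize=8)
        if path is not None:
            ax.figure.savefig(Path(path), dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax
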