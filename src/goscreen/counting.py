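"""Guide quantitation from FASTQ and the count-matrix container.

Reads are trimmed with either a fixed 5' offset or a 5' anchor sequence
(the constant vector sequence immediately preceding the spacer), the
spacer is extracted, and counted only on an exact match against the
library. Reads whose spacer matches nothing — or whose anchor is absent —
are tallied as unassigned, so assigned + unassigned always equals the
number of reads processed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, ValidationError
from .library import GuideLibrary

logger = logging.getLogger(__name__)

ARMS = ("library", "cas9_pos", "cas9_neg")
STAGES = ("L0", "T0", "Tf")

_STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}
_ARM_ORDER = {a: i for i, a in enumerate(ARMS)}


@dataclass(frozen=True)
class SampleDescriptor:
    """Design metadata for one sequenced sample.

    arm is ``library`` (the plasmid pool, stage L0), ``cas9_pos`` or
    ``cas9_neg``; stage is ``L0`` (library), ``T0`` (initial, adherent)
    or ``Tf`` (final, spheroid/suspension); replicate is 1-based.
    """

    sample_id: str
    arm: str
    stage: str
    replicate: int = 1
    condition_label: str = ""

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r} (expected one of {ARMS})")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r} (expected one of {STAGES})")
        if (self.arm == "library") != (self.stage == "L0"):
            raise ValidationError(
                f"sample {self.sample_id!r}: arm 'library' if and only if stage 'L0' "
                f"(got arm={self.arm!r}, stage={self.stage!r})"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.arm, self.stage, self.replicate)

    def sort_key(self) -> tuple[int, int, int]:
        return (_STAGE_ORDER[self.stage], _ARM_ORDER[self.arm], self.replicate)


def _validate_design(design: Sequence[SampleDescriptor]) -> None:
    keys = [d.key for d in design]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (arm, stage, replicate) in design: {dupes}")
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in design")


class CountMatrix:
    """Non-negative integer read counts, guides x samples, plus design.

    Parameters
    ----------
    counts
        DataFrame indexed by guide_id with one integer column per
        sample_id.
    genes
        Series mapping guide_id -> gene, aligned with ``counts.index``.
    design
        One :class:`SampleDescriptor` per count column.
    unassigned
        Per-sample tally of reads matching no guide (0 when counts were
        not produced from FASTQ).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        genes: pd.Series,
        design: Sequence[SampleDescriptor],
        unassigned: Mapping[str, int] | None = None,
    ):
        _validate_design(design)
        design = list(design)
        ids = [d.sample_id for d in design]
        if set(ids) != set(counts.columns):
            raise ValidationError(
                "design sample_ids do not match count columns: "
                f"{sorted(set(ids) ^ set(counts.columns))}"
            )
        counts = counts[ids]
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("count matrix contains non-integer entries")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("count matrix contains negative entries")
        if not counts.index.is_unique:
            raise ValidationError("duplicate guide_id in count matrix index")
        genes = genes.reindex(counts.index)
        if genes.isna().any():
            missing = list(genes.index[genes.isna()])[:5]
            raise ValidationError(f"genes missing for guides: {missing}")
        self.counts = counts
        self.genes = genes
        self.design = design
        self.unassigned = dict(unassigned or {d.sample_id: 0 for d in design})

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return [d.sample_id for d in self.design]

    def samples(self, arm: str | None = None, stage: str | None = None) -> list[SampleDescriptor]:
        out = self.design
        if arm is not None:
            out = [d for d in out if d.arm == arm]
        if stage is not None:
            out = [d for d in out if d.stage == stage]
        return sorted(out, key=SampleDescriptor.sort_key)

    def replicates(self, stage: str, arm: str) -> list[int]:
        return sorted(d.replicate for d in self.samples(arm=arm, stage=stage))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.sort_index(axis=1).equals(other.counts.sort_index(axis=1))
            and self.genes.equals(other.genes)
            and sorted(d.key for d in self.design) == sorted(d.key for d in other.design)
        )


@dataclass(frozen=True)
class TrimSpec:
    """How to locate the spacer in a read.

    Exactly one of ``anchor`` (5' constant sequence immediately preceding
    the spacer) or ``offset`` (fixed 0-based start position) must be set.
    ``spacer_length`` defaults to the library's uniform spacer length;
    with anchor-based trimming, libraries with mixed spacer lengths are
    matched longest-first.
    """

    anchor: str | None = None
    offset: int | None = None
    spacer_length: int | None = None

    def __post_init__(self):
        if (self.anchor is None) == (self.offset is None):
            raise ConfigurationError("exactly one of anchor or offset must be given")
        if self.anchor is not None and (
            not self.anchor or not set(self.anchor.upper()) <= set("ACGTN")
        ):
            raise ConfigurationError(f"invalid anchor sequence {self.anchor!r}")
        if self.offset is not None and self.offset < 0:
            raise ConfigurationError("offset must be >= 0")


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_sample(
    fastq: str | Path,
    lib: GuideLibrary,
    trim: TrimSpec,
    ambiguous: str = "drop",
) -> tuple[pd.Series, int]:
    """Count exact spacer matches in one FASTQ (possibly gzipped).

    Returns (counts indexed by guide_id, unassigned read tally). Each read
    contributes to exactly one guide or to the unassigned tally, except
    under ``ambiguous="duplicate"`` where a spacer shared by several
    guides increments each of them; the default ``ambiguous="drop"`` sends
    such reads to unassigned to avoid double counting.
    """
    if ambiguous not in ("drop", "duplicate"):
        raise ConfigurationError(f"ambiguous must be 'drop' or 'duplicate', got {ambiguous!r}")
    lengths = sorted(lib.spacer_lengths(), reverse=True)
    if trim.spacer_length is not None:
        lengths = [trim.spacer_length]
    elif trim.offset is not None and len(lengths) > 1:
        raise ConfigurationError(
            "offset-based trimming requires a uniform spacer length; "
            f"library has lengths {sorted(lengths)}"
        )
    spacer_map: dict[str, list[str]] = {}
    for rec in lib.records:
        spacer_map.setdefault(rec.spacer, []).append(rec.guide_id)

    counts = dict.fromkeys(lib.guide_ids, 0)
    unassigned = 0
    n_reads = 0
    anchor = trim.anchor.upper() if trim.anchor is not None else None
    with _open_text(Path(fastq)) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            n_reads += 1
            seq = str(rec.seq).upper()
            if anchor is not None:
                pos = seq.find(anchor)
                start = pos + len(anchor) if pos >= 0 else -1
            else:
                start = trim.offset
            hit: list[str] | None = None
            if start is not None and start >= 0:
                for L in lengths:
                    candidate = seq[start : start + L]
                    if len(candidate) == L and candidate in spacer_map:
                        hit = spacer_map[candidate]
                        break
            if hit is None:
                unassigned += 1
            elif len(hit) == 1:
                counts[hit[0]] += 1
            elif ambiguous == "duplicate":
                for gid in hit:
                    counts[gid] += 1
            else:
                unassigned += 1
    if n_reads == 0:
        logger.warning("FASTQ %s contained no reads; returning an all-zero column", fastq)
    column = pd.Series(counts, name=None, dtype=np.int64)
    return column.reindex(lib.guide_ids), unassigned


def assemble_counts(
    columns: Mapping[str, pd.Series],
    design: Sequence[SampleDescriptor],
    lib: GuideLibrary,
    unassigned: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Combine per-sample count columns into a :class:`CountMatrix`.

    Columns are ordered deterministically: L0 first, then T0 by arm and
    replicate, then Tf. All columns must cover exactly the library's
    guide universe.
    """
    _validate_design(design)
    missing = [d.sample_id for d in design if d.sample_id not in columns]
    if missing:
        raise ValidationError(f"no count column for design samples: {missing}")
    universe = set(lib.guide_ids)
    for sid, col in columns.items():
        diff = universe ^ set(col.index)
        if diff:
            raise ValidationError(
                f"column {sid!r} guide set differs from library; symmetric "
                f"difference (first 10): {sorted(diff)[:10]}"
            )
    design = sorted(design, key=SampleDescriptor.sort_key)
    counts = pd.DataFrame(
        {d.sample_id: columns[d.sample_id].reindex(lib.guide_ids) for d in design},
        index=pd.Index(lib.guide_ids, name="guide_id"),
    )
    genes = pd.Series(lib.gene_of(), name="gene").reindex(lib.guide_ids)
    return CountMatrix(counts, genes, design, unassigned)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write counts as TSV: guide_id, gene, then one column per sample."""
    out = matrix.counts.copy()
    out.insert(0, "gene", matrix.genes)
    out.to_csv(path, sep="\t", index=True, index_label="guide_id")


def read_counts(path: str | Path, design: Sequence[SampleDescriptor]) -> CountMatrix:
    """Read a counts TSV; columns are aligned to the design regardless of file order."""
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    if "gene" not in df.columns:
        raise ValidationError(f"counts file {path} lacks a 'gene' column")
    genes = df["gene"]
    counts = df.drop(columns="gene")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(f"counts file {path} contains non-integer entries")
    return CountMatrix(counts, genes, design)


def read_design(path: str | Path) -> tuple[list[SampleDescriptor], dict[str, str]]:
    """Read a design TSV (sample_id, arm, stage, replicate[, condition_label][, fastq]).

    Returns the descriptors and a sample_id -> fastq path mapping (empty
    when the design carries no fastq column).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "arm", "stage", "replicate"}
    if not required <= set(df.columns):
        raise ConfigurationError(
            f"design file {path} must have columns {sorted(required)}; got {list(df.columns)}"
        )
    design = [
        SampleDescriptor(
            sample_id=row.sample_id,
            arm=row.arm,
            stage=row.stage,
            replicate=int(row.replicate),
            condition_label=getattr(row, "condition_label", ""),
        )
        for row in df.itertuples(index=False)
    ]
    _validate_design(design)
    fastqs = dict(zip(df["sample_id"], df["fastq"])) if "fastq" in df.columns else {}
    return design, fastqs


def write_design(design: Sequence[SampleDescriptor], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "arm": [d.arm for d in design],
            "stage": [d.stage for d in design],
            "replicate": [d.replicate for d in design],
            "condition_label": [d.condition_label for d in design],
        }
    ).to_csv(path, sep="\t", index=False)
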