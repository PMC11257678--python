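"""sgRNA library references.

A pooled CRISPR library is described by a CSV with one row per guide:
a unique guide id, the gene symbol it targets (or a control-group label),
and its spacer sequence (the programmable 20-nt targeting sequence).
Non-targeting controls — guides matching no genomic site — are flagged
either by an explicit boolean column or by a gene-label prefix; they are
the known negatives used for screen QC.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

SPACER_ALPHABET = frozenset("ACGT")

#: gene-label prefixes treated as non-targeting when no explicit flag column exists
DEFAULT_CONTROL_PREFIXES = ("NonTargeting", "CTRL", "NON-TARGETING", "CONTROL")

#: default CSV column names; a format_spec mapping may override any of them
DEFAULT_COLUMNS = {
    "guide_id": "guide_id",
    "gene": "gene",
    "spacer": "spacer",
    "is_control": "is_control",
}


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: id, targeted gene (or control-group label), spacer, control flag."""

    guide_id: str
    gene: str
    spacer: str
    is_control: bool = False


class GuideLibrary:
    """Ordered, validated collection of :class:`GuideRecord`.

    Parameters
    ----------
    records
        Guide records in library order. Guide ids must be unique and
        spacers must be non-empty uppercase strings over {A, C, G, T}.

    Attributes
    ----------
    records : tuple of GuideRecord
    gene_index : dict
        gene -> list of guide_ids, in library order.
    """

    def __init__(self, records: Iterable[GuideRecord]):
        records = tuple(records)
        seen: set[str] = set()
        gene_index: "OrderedDict[str, list[str]]" = OrderedDict()
        for row, rec in enumerate(records, start=1):
            if rec.guide_id in seen:
                raise ValidationError(f"duplicate guide_id {rec.guide_id!r}")
            seen.add(rec.guide_id)
            if not rec.spacer:
                raise ValidationError(f"empty spacer for guide {rec.guide_id!r} (row {row})")
            if rec.spacer != rec.spacer.upper() or not set(rec.spacer) <= SPACER_ALPHABET:
                raise ValidationError(
                    f"spacer for guide {rec.guide_id!r} (row {row}) is not an "
                    f"uppercase ACGT string: {rec.spacer!r}"
                )
            gene_index.setdefault(rec.gene, []).append(rec.guide_id)
        self.records = records
        self.gene_index: dict[str, list[str]] = dict(gene_index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, GuideLibrary) and self.records == other.records

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        return list(self.gene_index)

    @property
    def n_controls(self) -> int:
        return sum(r.is_control for r in self.records)

    def gene_of(self) -> dict[str, str]:
        """Mapping guide_id -> gene."""
        return {r.guide_id: r.gene for r in self.records}

    def control_genes(self) -> set[str]:
        """Genes (or pseudo-genes) whose guides are all non-targeting controls."""
        by_gene = {g: [r for r in self.records if r.gene == g] for g in self.gene_index}
        return {g for g, recs in by_gene.items() if recs and all(r.is_control for r in recs)}

    def spacer_lengths(self) -> set[int]:
        return {len(r.spacer) for r in self.records}

    def duplicate_spacers(self) -> dict[str, list[str]]:
        """Spacer -> guide_ids sharing it, for spacers used by >1 guide.

        Shared spacers are unresolvable at counting time; the counting
        module's ambiguity rule decides where their reads go.
        """
        by_spacer: dict[str, list[str]] = {}
        for rec in self.records:
            by_spacer.setdefault(rec.spacer, []).append(rec.guide_id)
        return {s: ids for s, ids in by_spacer.items() if len(ids) > 1}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "spacer": [r.spacer for r in self.records],
                "is_control": [r.is_control for r in self.records],
            }
        )


def read_library(
    path: str | Path,
    format_spec: Mapping[str, str] | None = None,
    control_prefixes: Sequence[str] = DEFAULT_CONTROL_PREFIXES,
) -> GuideLibrary:
    """Read and validate an sgRNA library CSV.

    The file must be comma-separated with a header. Required columns
    (names overridable through ``format_spec`` with keys ``guide_id``,
    ``gene``, ``spacer`` and optionally ``is_control``): guide id, gene,
    spacer. Controls are taken from the boolean column when present,
    otherwise from a case-insensitive gene-label prefix match against
    ``control_prefixes``.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if format_spec:
        cols.update(format_spec)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for role in ("guide_id", "gene", "spacer"):
        if cols[role] not in df.columns:
            raise ConfigurationError(
                f"library file {path} lacks required column {cols[role]!r} (role {role})"
            )
    if cols["is_control"] in df.columns:
        flags = df[cols["is_control"]].str.strip().str.lower().isin(
            {"true", "1", "yes", "t"}
        )
    else:
        prefixes = tuple(p.lower() for p in control_prefixes)
        flags = df[cols["gene"]].str.lower().str.startswith(prefixes)

    records = [
        GuideRecord(
            guide_id=gid.strip(),
            gene=gene.strip(),
            spacer=spacer.strip().upper(),
            is_control=bool(flag),
        )
        for gid, gene, spacer, flag in zip(
            df[cols["guide_id"]], df[cols["gene"]], df[cols["spacer"]], flags
        )
    ]
    lib = GuideLibrary(records)
    dups = lib.duplicate_spacers()
    if dups:
        logger.warning(
            "%d spacer sequence(s) are shared by multiple guides (e.g. %s); "
            "reads for them follow the counting ambiguity rule",
            len(dups),
            next(iter(dups.items())),
        )
    return lib


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    """Write the library back to CSV with the canonical column order."""
    lib.to_frame().to_csv(path, index=False)


def group_controls(lib: GuideLibrary, group_size: int) -> GuideLibrary:
    """Partition non-targeting controls into pseudo-genes of ``group_size``.

    Gene-level statistics need multi-guide units; controls are grouped
    deterministically in library order into pseudo-genes named
    ``CTRL_0001``, ``CTRL_0002``, ... (the last group may be smaller).
    Targeting guides are unchanged and order is preserved.
    """
    if group_size < 1:
        raise ConfigurationError(f"group_size must be >= 1, got {group_size}")
    n_controls = lib.n_controls
    if n_controls == 0:
        raise ValidationError("library contains no control guides to group")
    out: list[GuideRecord] = []
    ctrl_seen = 0
    for rec in lib.records:
        if rec.is_control:
            group = ctrl_seen // group_size + 1
            out.append(replace(rec, gene=f"CTRL_{group:04d}"))
            ctrl_seen += 1
        else:
            out.append(rec)
    return GuideLibrary(out)
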