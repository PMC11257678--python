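"""Multi-screen integration: hit-list intersections and over-representation.

Hit lists from several screens are intersected (with full Venn region
counts), and gene lists are tested for over-representation against
user-supplied gene-set collections (GMT format) with an upper-tail
hypergeometric test, a minimum-overlap filter applied before testing,
and Benjamini-Hochberg correction across the tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .scoring import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 45
DEFAULT_Q_CUTOFF = 0.01

ORA_COLUMNS = ["set_name", "k", "K", "n", "N", "p", "q", "significant"]


def _norm_symbol(g: str) -> str:
    return str(g).strip().upper()


def _norm_set(genes: Iterable[str]) -> set[str]:
    return {_norm_symbol(g) for g in genes if str(g).strip()}


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self):
        self.sets = {name: _norm_set(members) for name, members in self.sets.items()}
        if self.universe is not None:
            self.universe = _norm_set(self.universe)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT lines need name, description and >=1 gene"
                )
            name = parts[0].strip()
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = _norm_set(parts[2:])
    return GeneSetCollection(sets)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines ignored."""
    with open(path) as fh:
        return _norm_set(fh.read().splitlines())


def intersect_hits(lists: Mapping[str, Iterable[str]]) -> tuple[set[str], dict[frozenset, int]]:
    """Intersect >=2 named hit lists.

    Returns the common set and the full inclusion-exclusion region table:
    for every non-empty combination of list names, the number of genes in
    exactly those lists. Region counts sum to the union size.
    """
    if len(lists) < 2:
        raise ConfigurationError("need at least 2 hit lists to intersect")
    normed = {name: _norm_set(genes) for name, genes in lists.items()}
    for name, s in normed.items():
        if not s:
            logger.warning("hit list %r is empty", name)
    names = list(normed)
    regions: dict[frozenset, int] = {}
    union = set().union(*normed.values())
    membership = {g: frozenset(n for n in names if g in normed[n]) for g in union}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            key = frozenset(combo)
            regions[key] = sum(1 for m in membership.values() if m == key)
    common = set.intersection(*normed.values()) if normed else set()
    return common, regions


def ora(
    query: Iterable[str],
    gsc: GeneSetCollection,
    universe: Iterable[str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` against each gene set.

    With universe size N, set size K (members in the universe), query
    size n (in the universe) and overlap k, the p-value is the upper
    tail P(X >= k) of Hypergeometric(N, K, n). Sets with k below
    ``min_overlap`` are excluded before testing; BH runs across the
    tested sets only and rows with q < ``q_cutoff`` are flagged
    significant.
    """
    if universe is None:
        universe = gsc.universe
    if not universe:
        raise ValidationError("ORA requires a non-empty background universe")
    uni = _norm_set(universe)
    q_set = _norm_set(query)
    dropped = q_set - uni
    if dropped:
        logger.warning("%d query gene(s) outside the universe dropped", len(dropped))
    q_set &= uni
    n, N = len(q_set), len(uni)

    rows = []
    for name, members in gsc.sets.items():
        in_uni = members & uni
        k = len(q_set & in_uni)
        if k < min_overlap:
            continue
        K = len(in_uni)
        # upper tail P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < q_cutoff
        out = out.sort_values(["q", "p", "set_name"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out[ORA_COLUMNS]


def intersect_pathways(
    tables: Mapping[str, pd.DataFrame],
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> set[str]:
    """Pathway names significant in every enrichment table.

    Each table needs a ``set_name`` column and either a boolean
    ``significant`` column or a ``q`` column compared against
    ``q_cutoff``.
    """
    if len(tables) < 2:
        raise ConfigurationError("need at least 2 enrichment tables to intersect")
    sig_sets: list[set[str]] = []
    for name, tab in tables.items():
        if "set_name" not in tab.columns:
            raise ConfigurationError(f"table {name!r} lacks a 'set_name' column")
        if "significant" in tab.columns:
            sig = tab.loc[tab["significant"].astype(bool), "set_name"]
        elif "q" in tab.columns:
            sig = tab.loc[tab["q"] < q_cutoff, "set_name"]
        else:
            raise ConfigurationError(
                f"table {name!r} needs a 'significant' or 'q' column"
            )
        sig_sets.append({str(s) for s in sig})
    return set.intersection(*sig_sets)
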