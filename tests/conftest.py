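import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from goscreen import (
    CountMatrix,
    GuideLibrary,
    GuideRecord,
    SampleDescriptor,
)


@pytest.fixture
def toy_library() -> GuideLibrary:
    """Three 2-guide genes plus four non-targeting controls."""
    recs = []
    spacers = iter(
        ["ACGTACGTACGTACGTACGT", "TTTTACGTACGTACGTACGT", "GGGGACGTACGTACGTACGT",
         "CCCCACGTACGTACGTACGT", "ATATACGTACGTACGTACGT", "GCGCACGTACGTACGTACGT",
         "TACGTACGTACGTACGTACG", "CGTACGTACGTACGTACGTA", "GTACGTACGTACGTACGTAC",
         "AACCGGTTAACCGGTTAACC"]
    )
    for gene in ("GENEA", "GENEB", "GENEC"):
        for j in (1, 2):
            recs.append(GuideRecord(f"{gene}_g{j}", gene, next(spacers)))
    for c in range(1, 5):
        recs.append(GuideRecord(f"NT_{c}", "NonTargeting", next(spacers), is_control=True))
    return GuideLibrary(recs)


def make_design(replicates: int = 2, with_library: bool = True) -> list[SampleDescriptor]:
    design = []
    if with_library:
        design.append(SampleDescriptor("L0", "library", "L0", 1, "library"))
    for stage, label in (("T0", "adherent"), ("Tf", "spheroid")):
        for arm in ("cas9_pos", "cas9_neg"):
            for r in range(1, replicates + 1):
                design.append(SampleDescriptor(f"{stage}_{arm}_r{r}", arm, stage, r, label))
    return design


@pytest.fixture
def symmetric_counts(toy_library) -> CountMatrix:
    """Counts where the Cas9+ and Cas9- arms are identical per (stage, replicate)."""
    rng = np.random.default_rng(7)
    design = make_design(replicates=3)
    n = len(toy_library)
    idx = pd.Index(toy_library.guide_ids, name="guide_id")
    base = {}
    for d in design:
        if d.arm == "cas9_neg":
            continue
        base[d.key] = pd.Series(rng.integers(0, 500, size=n), index=idx)
    cols = {}
    for d in design:
        src = ("cas9_pos", d.stage, d.replicate) if d.arm == "cas9_neg" else d.key
        cols[d.sample_id] = base[src]
    counts = pd.DataFrame(cols)
    genes = pd.Series(toy_library.gene_of()).reindex(idx)
    return CountMatrix(counts, genes, design)
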