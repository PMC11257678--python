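import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goscreen import (
    CallConfig,
    ConfigurationError,
    ValidationError,
    bh_adjust,
    call_genes,
    enrichment_ratio,
    gene_scores,
    guide_log_ratios,
    normalize,
    paired_test,
    score_screen,
)
from goscreen.counting import CountMatrix, SampleDescriptor
from goscreen.scoring import CALL_DEPLETED, CALL_NONE, _percentile_ranks
from tests.conftest import make_design


# ---------------------------------------------------------------- oracles

def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def paired_t_p_df2(es0, esf):
    """Closed-form two-sided p for the paired t with 3 replicates (df = 2):
    p = 1 - |t| / sqrt(t^2 + 2)."""
    d = np.asarray(esf, float) - np.asarray(es0, float)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    return 1 - abs(t) / np.sqrt(t**2 + 2)


# ---------------------------------------------------------------- normalize

def test_normalize_hand_arithmetic(toy_library):
    design = [SampleDescriptor("L0", "library", "L0", 1)]
    idx = pd.Index(toy_library.guide_ids[:3], name="guide_id")
    counts = pd.DataFrame({"L0": pd.Series([0, 1, 3], index=idx)})
    genes = pd.Series(["GENEA", "GENEA", "GENEB"], index=idx)
    ab = normalize(CountMatrix(counts, genes, design))
    expected = 1e6 * np.array([1, 2, 4]) / 7
    np.testing.assert_allclose(ab.abundance["L0"].to_numpy(), expected, rtol=1e-12)


@pytest.mark.parametrize("column,expected", [
    ([0, 0, 0, 0], [250000.0] * 4),   # all-zero -> uniform
    ([41], [1e6]),                    # single guide takes the whole million
])
def test_normalize_degenerate_columns(column, expected):
    idx = pd.Index([f"g{i}" for i in range(len(column))], name="guide_id")
    counts = pd.DataFrame({"L0": pd.Series(column, index=idx)})
    genes = pd.Series("GENE", index=idx)
    ab = normalize(CountMatrix(counts, genes, [SampleDescriptor("L0", "library", "L0", 1)]))
    np.testing.assert_allclose(ab.abundance["L0"].to_numpy(), expected)


def test_normalized_columns_sum_to_a_million(symmetric_counts):
    ab = normalize(symmetric_counts)
    np.testing.assert_allclose(ab.abundance.sum(axis=0), 1e6, rtol=1e-9)
    assert (ab.abundance.to_numpy() > 0).all()


# ---------------------------------------------------------------- percentiles

@pytest.mark.parametrize("values,expected", [
    ([-2.0, 0.5, 3.1], [1 / 3, 2 / 3, 1.0]),
    ([1.0, 1.0, 2.0], [0.5, 0.5, 1.0]),
])
def test_percentile_rank_examples(values, expected):
    got = _percentile_ranks(pd.Series(values, index=list("abc")))
    np.testing.assert_allclose(got.to_numpy(), expected)


def test_percentile_mean_is_midpoint():
    rng = np.random.default_rng(0)
    values = pd.Series(rng.normal(size=101))
    rho = _percentile_ranks(values)
    n = len(values)
    assert rho.max() == 1.0
    np.testing.assert_allclose(rho.mean(), (n + 1) / (2 * n), rtol=1e-12)


# ---------------------------------------------------------------- ratios & ES

def test_identical_arms_give_zero_ratios_and_midpoint_percentiles(symmetric_counts):
    ab = normalize(symmetric_counts)
    ratios = guide_log_ratios(ab)
    assert np.allclose(ratios.lam.to_numpy(), 0.0)
    n = len(symmetric_counts.guide_ids)
    assert np.allclose(ratios.rho.to_numpy(), (n + 1) / (2 * n))


def test_doubled_guide_gets_top_percentile(toy_library):
    design = make_design(replicates=2)
    idx = pd.Index(toy_library.guide_ids, name="guide_id")
    base = pd.Series(100, index=idx)
    cols = {}
    for d in design:
        col = base.copy()
        if d.arm == "cas9_pos":
            col["GENEA_g1"] = 200
        cols[d.sample_id] = col
    genes = pd.Series(toy_library.gene_of()).reindex(idx)
    ab = normalize(CountMatrix(pd.DataFrame(cols), genes, design))
    ratios = guide_log_ratios(ab)
    lam = ratios.lam[("T0", 1)]
    # pseudocount and renormalization shift the exact value slightly off 1
    assert lam["GENEA_g1"] == lam.max() > 0.5
    assert ratios.rho[("T0", 1)]["GENEA_g1"] == 1.0


def test_missing_cas9_neg_strict_vs_pooled(toy_library):
    design = [d for d in make_design(replicates=2)
              if not (d.arm == "cas9_neg" and d.replicate == 2)]
    idx = pd.Index(toy_library.guide_ids, name="guide_id")
    cols = {d.sample_id: pd.Series(50, index=idx) for d in design}
    genes = pd.Series(toy_library.gene_of()).reindex(idx)
    counts = CountMatrix(pd.DataFrame(cols), genes, design)
    ab = normalize(counts)
    with pytest.raises(ValidationError, match="replicate 2"):
        guide_log_ratios(ab)
    ratios = guide_log_ratios(ab, cas9neg="pooled")
    assert ("T0", 2) in ratios.lam.columns


def test_gene_scores_are_guide_means(toy_library, symmetric_counts):
    ab = normalize(symmetric_counts)
    ratios = guide_log_ratios(ab)
    # plant known percentiles for one (stage, replicate)
    ratios.rho[("T0", 1)] = np.linspace(0.1, 1.0, len(ratios.rho))
    table = gene_scores(ratios, toy_library)
    gene_of = toy_library.gene_of()
    for gene in ("GENEA", "GENEB", "GENEC"):
        guides = [g for g, gg in gene_of.items() if gg == gene]
        expected = ratios.rho[("T0", 1)].loc[guides].mean()
        assert table.loc[gene, "es_T0_r1"] == pytest.approx(expected)
    assert (table.loc[["GENEA", "GENEB", "GENEC"], "n_guides"] == 2).all()


def test_enrichment_ratio_is_ratio_of_stage_means():
    table = pd.DataFrame(
        {"es_T0_r1": [0.4, 0.5], "es_T0_r2": [0.6, 0.5],
         "es_Tf_r1": [0.2, 0.5], "es_Tf_r2": [0.3, 0.5]},
        index=pd.Index(["G1", "G2"], name="gene"),
    )
    out = enrichment_ratio(table)
    assert out.loc["G1", "er"] == pytest.approx(0.25 / 0.5)
    assert out.loc["G2", "er"] == pytest.approx(1.0)


# ---------------------------------------------------------------- paired test

def test_paired_test_worked_example_matches_closed_form():
    es0, esf = [0.50, 0.60, 0.55], [0.30, 0.35, 0.40]
    p = paired_test(es0, esf)
    assert p == pytest.approx(paired_t_p_df2(es0, esf), rel=1e-10)
    assert p == pytest.approx(0.0202, abs=2e-4)


def test_paired_test_conventions():
    assert paired_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == 1.0  # no differences
    assert paired_test([0.4, 0.6], [0.3, 0.7]) == pytest.approx(1.0)  # t = 0
    assert paired_test([0.5, 0.5], [0.3, 0.3]) == 0.0  # degenerate nonzero shift
    with pytest.raises(ValidationError):
        paired_test([0.5], [0.3])


@given(st.lists(st.floats(-0.4, 0.4), min_size=3, max_size=3))
@settings(deadline=None, max_examples=50)
def test_paired_test_matches_df2_closed_form(diffs):
    es0 = np.full(3, 0.5)
    esf = es0 + np.asarray(diffs)
    if np.std(esf - es0, ddof=1) == 0:  # degenerate after float rounding
        return
    assert paired_test(es0, esf) == pytest.approx(paired_t_p_df2(es0, esf), rel=1e-10)


# ---------------------------------------------------------------- BH

def test_bh_worked_example():
    np.testing.assert_allclose(
        bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04], rtol=1e-12
    )


def test_bh_degenerate_inputs():
    np.testing.assert_allclose(bh_adjust([0.07]), [0.07])
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    with pytest.raises(ValidationError):
        bh_adjust([0.1, float("nan")])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
@settings(deadline=None, max_examples=100)
def test_bh_matches_stepup_oracle(p):
    got = bh_adjust(p)
    np.testing.assert_allclose(got, bh_oracle(p), rtol=1e-10, atol=1e-12)
    assert (got >= np.asarray(p) - 1e-12).all() and (got <= 1).all()


# ---------------------------------------------------------------- calls

@pytest.mark.parametrize("er,p_adj,expected", [
    (0.8, 0.03, CALL_DEPLETED),
    (1.0, 0.001, CALL_NONE),   # strict boundary on ER
    (0.5, 0.2, CALL_NONE),
    (0.99, 0.05, CALL_NONE),   # strict boundary on alpha
])
def test_call_rule(er, p_adj, expected):
    table = pd.DataFrame({"er": [er], "p_adj": [p_adj]}, index=["G"])
    assert call_genes(table, CallConfig())["call"].iloc[0] == expected


def test_call_config_validation():
    with pytest.raises(ConfigurationError):
        CallConfig(alpha=1.5)
    with pytest.raises(ConfigurationError):
        CallConfig(er_threshold=0)


# ---------------------------------------------------------------- pipeline

def test_identical_arms_full_pipeline_null(symmetric_counts, toy_library):
    table = score_screen(symmetric_counts, toy_library)
    np.testing.assert_allclose(table["er"], 1.0)
    np.testing.assert_allclose(table["p_value"], 1.0)
    assert (table["call"] == CALL_NONE).all()
    # initial and final ES agree replicate by replicate
    for r in (1, 2, 3):
        np.testing.assert_allclose(table[f"es_T0_r{r}"], table[f"es_Tf_r{r}"])


def test_guide_order_permutation_invariance(symmetric_counts, toy_library):
    rng = np.random.default_rng(11)
    table = score_screen(symmetric_counts, toy_library)
    perm = rng.permutation(len(symmetric_counts.guide_ids))
    shuffled = CountMatrix(
        symmetric_counts.counts.iloc[perm],
        symmetric_counts.genes.iloc[perm],
        symmetric_counts.design,
    )
    table2 = score_screen(shuffled, toy_library)
    pd.testing.assert_frame_equal(table.sort_index(), table2.sort_index())


def test_naive_identical_stages_give_er_one(toy_library):
    rng = np.random.default_rng(2)
    design = make_design(replicates=3)
    idx = pd.Index(toy_library.guide_ids, name="guide_id")
    base = pd.Series(rng.integers(1, 300, len(idx)), index=idx)
    cols = {d.sample_id: base for d in design}  # T0 == Tf for every arm
    genes = pd.Series(toy_library.gene_of()).reindex(idx)
    counts = CountMatrix(pd.DataFrame(cols), genes, design)
    table = score_screen(counts, toy_library, method="naive")
    np.testing.assert_allclose(table["er"], 1.0)
    assert (table["call"] == CALL_NONE).all()


def test_naive_single_replicate_errors(toy_library):
    design = make_design(replicates=1)
    idx = pd.Index(toy_library.guide_ids, name="guide_id")
    cols = {d.sample_id: pd.Series(10, index=idx) for d in design}
    genes = pd.Series(toy_library.gene_of()).reindex(idx)
    counts = CountMatrix(pd.DataFrame(cols), genes, design)
    with pytest.raises(ValidationError, match="2 replicates"):
        score_screen(counts, toy_library, method="naive")
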