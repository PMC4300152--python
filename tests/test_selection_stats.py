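import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from plastidsel.published import (published_summaries, published_table,
                                  DNDS_FALLBACK_GROUPS)
from plastidsel.selection_stats import (SelectionSummary, correlate_log_ratios,
                                        fisher_exact_2x2, mk_test,
                                        summarize_table)

from oracles import fisher_two_sided_oracle, pearson_oracle

counts = st.integers(min_value=0, max_value=40)


def test_fisher_balanced_table_is_one():
    assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)


@pytest.mark.parametrize("table", [(7, 17, 2, 42), (0, 10, 10, 0), (3, 0, 5, 9),
                                   (1, 2, 3, 4), (12, 5, 0, 19)])
def test_fisher_matches_enumeration_and_scipy(table):
    ours = fisher_exact_2x2(*table)
    assert ours == pytest.approx(fisher_two_sided_oracle(*table), abs=1e-12)
    a, b, c, d = table
    assert ours == pytest.approx(scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-6)


def test_fisher_zero_margin_convention():
    assert fisher_exact_2x2(0, 0, 5, 9) == 1.0
    assert fisher_exact_2x2(0, 3, 0, 9) == 1.0


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 2, 3, 4)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(a=counts, b=counts, c=counts, d=counts)
def test_fisher_transpose_symmetry(a, b, c, d):
    """Fisher's exact p is invariant to swapping the two rows."""
    assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
        fisher_exact_2x2(c, d, a, b), abs=1e-12)


def test_mk_neutrality_index_arithmetic():
    mk = mk_test("rps", "Tca", 7, 17, 2, 42)
    assert mk.ni == pytest.approx((2 / 42) / (7 / 17))
    assert mk.ni == pytest.approx(0.1157, abs=1e-4)
    assert mk.alpha == pytest.approx(1 - mk.ni)
    assert mk.p_bonferroni == pytest.approx(min(1.0, mk.p_value * 51))


def test_mk_equal_ratios_give_ni_one():
    mk = mk_test("g", "Tca", 10, 20, 5, 10)
    assert mk.ni == pytest.approx(1.0)
    assert mk.alpha == pytest.approx(0.0)


def test_mk_bonferroni_caps_at_one():
    mk = mk_test("g", "Tca", 5, 5, 5, 5, bonferroni_factor=51)
    assert mk.p_value == pytest.approx(1.0) and mk.p_bonferroni == 1.0


def test_mk_undefined_ni_is_nan():
    mk = mk_test("g", "Tca", 5, 5, 4, 0)
    assert math.isnan(mk.ni) and math.isnan(mk.alpha)


def test_mk_table_transpose_symmetry():
    p1 = mk_test("g", "o", 7, 17, 2, 42).p_value
    p2 = mk_test("g", "o", 2, 42, 7, 17).p_value
    assert p1 == pytest.approx(p2, abs=1e-12)


# ---------------------------------------------------------------------------
# correlation


def _rows(pairs, n_poly=5):
    return [SelectionSummary(f"g{i}", 300, n_poly, d, p)
            for i, (d, p) in enumerate(pairs)]


def test_correlation_exact_loglinear_relation():
    pairs = [(w, 0.7 * w) for w in (0.1, 0.2, 0.5, 1.0, 2.0)]
    out = correlate_log_ratios(_rows(pairs))
    assert out["r"] == pytest.approx(1.0)
    assert out["n_used"] == 5


def test_correlation_matches_covariance_oracle_and_row_order(rng):
    pairs = list(zip(np.exp(rng.normal(size=20)), np.exp(rng.normal(size=20))))
    out = correlate_log_ratios(_rows(pairs))
    r_oracle = pearson_oracle(np.log([p[0] for p in pairs]),
                              np.log([p[1] for p in pairs]))
    assert out["r"] == pytest.approx(r_oracle, abs=1e-12)
    out_rev = correlate_log_ratios(_rows(pairs)[::-1])
    assert out_rev["r"] == pytest.approx(out["r"], abs=1e-14)
    # r is invariant to log base, so base-10 transformed inputs give same r
    r10 = pearson_oracle(np.log10([p[0] for p in pairs]),
                         np.log10([p[1] for p in pairs]))
    assert r10 == pytest.approx(out["r"], abs=1e-12)


def test_correlation_filters_and_errors():
    rows = _rows([(0.5, 0.4), (0.6, 0.5), (0.7, 0.1)])
    rows += [SelectionSummary("few", 300, 1, 0.9, 0.9),     # < 3 SNPs
             SelectionSummary("zero", 300, 9, 0.9, 0.0),    # log(0)
             SelectionSummary("na", 300, 9, 0.9, math.nan)]  # inestimable
    out = correlate_log_ratios(rows, min_snps=3)
    assert out["n_used"] == 3
    assert set(out["included_labels"]) == {"g0", "g1", "g2"}
    with pytest.raises(ValueError, match="correlation undefined"):
        correlate_log_ratios(rows[:2])


def test_published_rows_pass_filter_with_eleven_groups():
    out = correlate_log_ratios(published_summaries(), min_snps=3)
    assert out["n_used"] == 11
    assert "psa" not in out["included_labels"]
    assert "clpP" not in out["included_labels"]


# ---------------------------------------------------------------------------
# summary table


def test_summarize_all_identical_inputs():
    rows = [SelectionSummary(f"g{i}", 300, 4, 0.25, 0.75) for i in range(4)]
    table = summarize_table(rows)
    mean_row = table[table["group"] == "All Genes"].iloc[0]
    assert mean_row["dN/dS"] == pytest.approx(0.25)
    assert mean_row["pN/pS"] == pytest.approx(0.75)


def test_summarize_published_table_means():
    """Unweighted means over the printed study values: dN/dS without the
    zero-dS fallback gene (clpP), pN/pS over estimable rows only."""
    table = summarize_table(published_summaries(),
                            mean_exclusions_dnds=DNDS_FALLBACK_GROUPS)
    mean_row = table[table["group"] == "All Genes"].iloc[0]
    assert mean_row["dN/dS"] == pytest.approx(0.430, abs=1e-3)
    assert mean_row["pN/pS"] == pytest.approx(0.518, abs=1e-3)


def test_published_table_totals():
    df = published_table()
    assert int(df["length"].sum()) == 62853
    assert int(df["n_polymorphisms"].sum()) == 174
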