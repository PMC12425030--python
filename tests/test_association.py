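"""Association scan: OLS core, covariate-adjusted scan, hit-list semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mwfomics as m
from mwfomics.association import fit_ols, run_scan, split_significant
from mwfomics.errors import (
    EmptyJoinError,
    InsufficientDataError,
    ParameterError,
    SingularDesignError,
)


def brute_force_ols(y, X):
    """Independent oracle: normal equations + closed-form t inference."""
    from scipy import stats

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtX)))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def test_exact_line_fit():
    X = np.column_stack([np.ones(3), [1.0, 2.0, 3.0]])
    fit = fit_ols([1.0, 2.0, 3.0], X)
    np.testing.assert_allclose(fit.params, [0.0, 1.0], atol=1e-12)
    assert fit.rss < 1e-24
    assert fit.p_values[1] == 0.0  # exact fit, nonzero slope


def test_matches_normal_equation_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(20, 120))
        k = int(rng.integers(2, 6))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = rng.normal(size=n)
        fit = fit_ols(y, X)
        beta, se, p = brute_force_ols(y, X)
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)
        np.testing.assert_allclose(fit.se, se, atol=1e-10)
        np.testing.assert_allclose(fit.p_values, p, atol=1e-10)


def test_matches_statsmodels(rng):
    import statsmodels.api as sm

    X = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
    y = rng.normal(size=60)
    fit = fit_ols(y, X)
    ref = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.params, ref.params, atol=1e-10)
    np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
    np.testing.assert_allclose(fit.p_values, ref.pvalues, atol=1e-10)


def test_orthogonal_covariate_leaves_slope_unchanged(rng):
    n = 40
    x = rng.normal(size=n)
    y = 2.0 * x + rng.normal(size=n)
    base = np.column_stack([np.ones(n), x])
    fit0 = fit_ols(y, base)
    # build a column exactly orthogonal to 1, x and y
    M = np.column_stack([np.ones(n), x, y])
    z = rng.normal(size=n)
    z -= M @ np.linalg.lstsq(M, z, rcond=None)[0]
    fit1 = fit_ols(y, np.column_stack([base, z]))
    np.testing.assert_allclose(fit1.params[1], fit0.params[1], atol=1e-10)


def test_singular_design_names_offending_column():
    n = 20
    x = np.linspace(0, 1, n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(SingularDesignError) as err:
        fit_ols(np.random.default_rng(0).normal(size=n), X, ["intercept", "a", "b"])
    assert set(err.value.columns) & {"a", "b"}


def test_too_few_rows_rejected():
    with pytest.raises(InsufficientDataError):
        fit_ols([1.0, 2.0], np.column_stack([np.ones(2), [1.0, 2.0]]))


# --- scan-level ----------------------------------------------------------


def test_zero_noise_scan_recovers_planted_directions(small_cfg):
    cfg = small_cfg.zero_noise()
    cohort, truth = m.simulate_cohort(cfg)
    prot = m.simulate_proteome(cfg, cohort, truth)
    rec = run_scan(cohort, prot).set_index("aptamer_id")
    planted_pos = truth.true_beta.index[truth.true_beta > 0]
    planted_neg = truth.true_beta.index[truth.true_beta < 0]
    assert (rec.loc[planted_pos, "direction"] == "positive").all()
    assert (rec.loc[planted_neg, "direction"] == "negative").all()
    nulls = truth.true_beta.index[truth.true_beta == 0]
    assert (rec.loc[nulls, "direction"] == "null").all()


def test_direction_threshold_semantics():
    # p just under the cutoff with positive beta is a positive hit
    rec = pd.DataFrame(
        {
            "aptamer_id": ["a", "b", "c"],
            "gene_symbol": ["GA", "GB", "GC"],
            "beta": [1.0, -1.0, 1.0],
            "p_value": [0.049, 0.049, 0.051],
        }
    )
    pos, neg = split_significant(rec, alpha=0.05)
    assert pos == ["GA"] and neg == ["GB"]


def test_gene_with_one_significant_aptamer_collapses_once():
    rec = pd.DataFrame(
        {
            "aptamer_id": ["a1", "a2"],
            "gene_symbol": ["G1", "G1"],
            "beta": [2.0, 0.1],
            "p_value": [0.001, 0.9],
        }
    )
    pos, neg = split_significant(rec)
    assert pos == ["G1"] and neg == []


def test_all_null_p_gives_empty_lists():
    rec = pd.DataFrame(
        {"aptamer_id": ["a"], "gene_symbol": ["G"], "beta": [1.0], "p_value": [1.0]}
    )
    assert split_significant(rec) == ([], [])


def test_hit_lists_match_brute_force_recount(bundle):
    rec = run_scan(bundle.cohort, bundle.proteins)
    pos, neg = split_significant(rec)
    sig = rec[rec["p_value"] < 0.05]
    by_gene = {}
    for _, row in sig.iterrows():
        g = row["gene_symbol"]
        if g not in by_gene or row["p_value"] < by_gene[g][0]:
            by_gene[g] = (row["p_value"], row["beta"])
    expect_pos = sorted([g for g, (_, b) in by_gene.items() if b > 0])
    expect_neg = sorted([g for g, (_, b) in by_gene.items() if b < 0])
    assert sorted(pos) == expect_pos and sorted(neg) == expect_neg
    assert not set(pos) & set(neg)
    assert len(pos) + len(neg) <= bundle.proteins["gene_symbol"].nunique()


def test_beta_halves_when_abundance_squared(bundle):
    rec = run_scan(bundle.cohort, bundle.proteins)
    squared = bundle.proteins.copy()
    subj = [c for c in squared.columns if c not in ("aptamer_id", "gene_symbol")]
    squared[subj] = squared[subj] ** 2
    rec2 = run_scan(bundle.cohort, squared)
    np.testing.assert_allclose(rec2["beta"], rec["beta"] / 2, rtol=1e-8)
    np.testing.assert_allclose(rec2["p_value"], rec["p_value"], rtol=1e-8)


def test_swap_direction_preserves_t_and_p(bundle):
    fwd = run_scan(bundle.cohort, bundle.proteins)
    swp = run_scan(bundle.cohort, bundle.proteins, swap_direction=True)
    np.testing.assert_allclose(fwd["p_value"], swp["p_value"], rtol=1e-9)
    np.testing.assert_allclose(
        np.sign(fwd["beta"]), np.sign(swp["beta"])
    )


def test_complete_case_per_protein(bundle):
    prot = bundle.proteins.copy()
    subj = [c for c in prot.columns if c not in ("aptamer_id", "gene_symbol")]
    prot.loc[0, subj[:5]] = np.nan
    rec = run_scan(bundle.cohort, prot)
    assert rec.loc[0, "n_used"] == len(subj) - 5
    assert (rec.loc[1:, "n_used"] == len(subj)).all()


def test_disjoint_subjects_raise_empty_join(bundle):
    cohort = bundle.cohort.copy()
    cohort["subject_id"] = "X" + cohort["subject_id"]
    with pytest.raises(EmptyJoinError):
        run_scan(cohort, bundle.proteins)


@given(alpha=st.floats(min_value=-1, max_value=2).filter(lambda a: not 0 < a < 1))
def test_invalid_alpha_rejected(alpha):
    rec = pd.DataFrame(
        {"aptamer_id": ["a"], "gene_symbol": ["G"], "beta": [1.0], "p_value": [0.5]}
    )
    with pytest.raises(ParameterError):
        split_significant(rec, alpha=alpha)


def test_null_pvalues_approximately_uniform():
    """Small global-null scan: p below 0.05 near nominal rate."""
    from scipy import stats

    cfg = m.SimConfig(seed=2, n_subjects=60, n_proteins=150, n_true_pos=0, n_true_neg=0)
    cohort, truth = m.simulate_cohort(cfg)
    prot = m.simulate_proteome(cfg, cohort, truth)
    p = run_scan(cohort, prot)["p_value"].to_numpy()
    assert stats.kstest(p, "uniform").pvalue > 0.01
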