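"""Normalization, dispersion, NB-LRT engine and responsive-gene rules."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from kappacascade.diffexpr import (CountMatrix, QpcrTriple, SampleMeta,
                                   _design_matrices, _fit_nb_batch,
                                   estimate_dispersion, fold_changes,
                                   lrt_interaction, normalize, qpcr_fold_change,
                                   select_responsive)


def design_metas(conditions=("WT:antiIgM", "WT:antiIgM_BAY"), times=(0, 1, 4, 18),
                 reps=2):
    metas = []
    for cond in conditions:
        geno, treat = cond.split(":")
        for t in times:
            for r in range(1, reps + 1):
                metas.append(SampleMeta(f"{geno}_{treat}_{t}_{r}", geno, treat, t, r))
    return metas


def nb_matrix(rng, mus, metas, alpha=0.05):
    """mus: genes x samples expected counts."""
    r = 1 / alpha
    counts = rng.negative_binomial(r, r / (r + np.maximum(mus, 1e-9)))
    return CountMatrix(
        pd.DataFrame(counts, columns=[m.sample_id for m in metas],
                     index=[f"g{i}" for i in range(len(counts))]),
        metas)


# --- normalization ----------------------------------------------------------

def test_normalize_identical_columns_unity():
    metas = design_metas(times=(0, 1), reps=1)
    col = np.array([10, 50, 200, 1000])
    cm = CountMatrix(pd.DataFrame({m.sample_id: col for m in metas},
                                  index=list("abcd")), metas)
    sf = normalize(cm).size_factors
    assert np.allclose(sf.values, 1.0)


def test_normalize_doubled_column_factor_two():
    metas = design_metas(times=(0, 1), reps=1)[:2]
    cm = CountMatrix(pd.DataFrame({
        metas[0].sample_id: [10, 50, 200],
        metas[1].sample_id: [20, 100, 400],
    }, index=list("abc")), metas)
    sf = normalize(cm).size_factors
    assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)
    assert np.exp(np.mean(np.log(sf.values))) == pytest.approx(1.0)


def test_normalize_recovers_depth_multipliers():
    rng = np.random.default_rng(0)
    metas = design_metas()
    true_sf = rng.uniform(0.5, 2.0, len(metas))
    true_sf /= np.exp(np.mean(np.log(true_sf)))
    base = rng.lognormal(5, 1, 2000)
    mus = base[:, None] * true_sf[None, :]
    cm = nb_matrix(rng, mus, metas)
    sf = normalize(cm).size_factors.values
    assert np.all(np.abs(sf / true_sf - 1) < 0.05)


# --- dispersion -------------------------------------------------------------

def test_dispersion_poisson_data_near_zero():
    rng = np.random.default_rng(1)
    metas = design_metas()
    base = rng.uniform(50, 500, 2000)
    mus = np.tile(base[:, None], (1, len(metas)))
    counts = rng.poisson(mus)
    cm = CountMatrix(pd.DataFrame(counts, columns=[m.sample_id for m in metas],
                                  index=[f"g{i}" for i in range(2000)]), metas)
    a = estimate_dispersion(normalize(cm))
    assert np.median(a.values) <= 0.01


def test_dispersion_constant_gene_floored():
    metas = design_metas(times=(0,), reps=4)
    cm = CountMatrix(pd.DataFrame(
        np.full((5, len(metas)), 100), columns=[m.sample_id for m in metas],
        index=[f"g{i}" for i in range(5)]), metas)
    a = estimate_dispersion(normalize(cm))
    assert (a.values <= 1e-6).all()


def test_dispersion_recovery_at_truth():
    rng = np.random.default_rng(2)
    metas = design_metas(conditions=("WT:antiIgM",), times=(0, 1, 4, 18), reps=2)
    base = rng.lognormal(5.5, 0.8, 2000)
    mus = np.tile(base[:, None], (1, len(metas)))
    cm = nb_matrix(rng, mus, metas, alpha=0.05)
    a = estimate_dispersion(normalize(cm))
    assert 0.03 <= np.median(a.values) <= 0.08


def test_dispersion_no_replicates_falls_back():
    metas = design_metas(conditions=("WT:antiIgM",), times=(0, 1), reps=1)
    cm = CountMatrix(pd.DataFrame(
        [[10, 20], [30, 40]], columns=[m.sample_id for m in metas],
        index=["a", "b"]), metas)
    with pytest.warns(UserWarning):
        a = estimate_dispersion(normalize(cm), fallback_alpha=0.07)
    assert (a.values == 0.07).all()


# --- NB GLM engine ----------------------------------------------------------

def test_irls_matches_statsmodels_glm():
    """Batched IRLS agrees with statsmodels NegativeBinomial GLM per gene."""
    rng = np.random.default_rng(3)
    metas = design_metas()
    X, _, _, _ = _design_matrices(metas)
    base = np.array([200.0, 800.0, 3000.0])
    mus = np.tile(base[:, None], (1, len(metas)))
    mus[0, [1, 2]] *= 4  # some structure
    cm = nb_matrix(rng, mus, metas, alpha=0.05)
    Y = cm.counts.values.astype(float)
    alpha = np.full(3, 0.05)
    offset = np.zeros(len(metas))
    beta, ll, conv = _fit_nb_batch(Y, X, alpha, offset)
    assert conv.all()
    for i in range(3):
        glm = sm.GLM(Y[i], X, family=sm.families.NegativeBinomial(alpha=0.05))
        fit = glm.fit(maxiter=200, tol=1e-10)
        assert np.allclose(beta[i], fit.params, atol=1e-5)
        assert ll[i] == pytest.approx(fit.llf, abs=1e-5)


def test_lrt_stat_nonnegative_and_allzero_excluded():
    rng = np.random.default_rng(4)
    metas = design_metas()
    base = rng.uniform(50, 500, 50)
    mus = np.tile(base[:, None], (1, len(metas)))
    cm = nb_matrix(rng, mus, metas)
    cm.counts.iloc[0] = 0  # all-zero gene
    res = lrt_interaction(normalize(cm))
    assert (res.table.lrt_stat.values >= 0).all()
    assert not res.table.tested.iloc[0]
    assert np.isnan(res.table.pvalue.iloc[0])
    assert res.df == 3


def test_lrt_degenerate_single_condition_tests_time():
    rng = np.random.default_rng(5)
    metas = design_metas(conditions=("WT:antiIgM",))
    base = np.full(20, 300.0)
    mus = np.tile(base[:, None], (1, len(metas)))
    times = np.array([m.time_h for m in metas])
    mus[:5, times == 1] *= 4  # time-responsive genes
    cm = nb_matrix(rng, mus, metas)
    res = lrt_interaction(normalize(cm))
    assert res.df == 3  # time vs intercept
    assert (res.table.qvalue.iloc[:5] <= 0.05).all()


def test_scale_invariance_of_lrt_and_fc():
    """Multiplying one library by a constant leaves results nearly unchanged.

    Exact invariance is impossible for a count-level NB model (a 4x-scaled
    library genuinely carries less shot noise, and the +1 pseudocount acts on
    the normalized scale), so the check is approximate.
    """
    rng = np.random.default_rng(6)
    metas = design_metas()
    base = rng.uniform(100, 1000, 300)
    mus = np.tile(base[:, None], (1, len(metas)))
    cm = nb_matrix(rng, mus, metas)
    res1 = lrt_interaction(normalize(cm))
    scaled = cm.counts.copy()
    scaled[metas[0].sample_id] *= 4
    res2 = lrt_interaction(normalize(CountMatrix(scaled, metas)))
    keep = (cm.counts > 0).all(axis=1).values
    assert np.allclose(res1.table.pvalue.values[keep],
                       res2.table.pvalue.values[keep], atol=0.05)
    assert np.allclose(res1.log2fc.values[keep], res2.log2fc.values[keep], atol=0.01)


# --- fold changes and selection ---------------------------------------------

def test_fold_change_pseudocount_arithmetic():
    metas = design_metas(conditions=("WT:antiIgM",), times=(0, 1), reps=1)
    cm = CountMatrix(pd.DataFrame(
        {metas[0].sample_id: [7, 5, 0], metas[1].sample_id: [31, 5, 0]},
        index=list("abc")), metas)
    cm = CountMatrix(cm.counts, metas, pd.Series(1.0, index=cm.counts.columns))
    fc = fold_changes(cm)
    assert fc.loc["a", ("WT:antiIgM", 1)] == pytest.approx(np.log2(32 / 8))
    assert fc.loc["b", ("WT:antiIgM", 1)] == 0.0
    assert fc.loc["c", ("WT:antiIgM", 1)] == 0.0


def test_fold_change_missing_baseline_raises():
    metas = design_metas(conditions=("WT:antiIgM",), times=(1, 4), reps=1)
    cm = CountMatrix(pd.DataFrame(
        {m.sample_id: [5] for m in metas}, index=["a"]), metas)
    cm = CountMatrix(cm.counts, metas, pd.Series(1.0, index=cm.counts.columns))
    with pytest.raises(ValueError, match="baseline"):
        fold_changes(cm)


def test_select_responsive_two_filter_rule():
    genes = ["up_strong", "not_sig", "weak_fc", "down_strong"]
    table = pd.DataFrame({
        "qvalue": [0.01, 0.2, 0.01, 0.001],
    }, index=genes)
    de = type("DE", (), {"table": table})()
    cols = pd.MultiIndex.from_product([["WT:antiIgM"], [1, 4, 18]],
                                      names=["condition", "time_h"])
    fc = pd.DataFrame([[1.5, 0.2, 0.0],     # 2.8x up
                       [2.0, 2.0, 2.0],     # 4x but q=0.2
                       [0.85, 0.2, 0.1],    # 1.8x only
                       [-0.2, -2.1, -0.5]], # 4.3x down
                      index=genes, columns=cols)
    sets = select_responsive(de, fc, "WT:antiIgM")
    assert sets["up"] == {"up_strong"}
    assert sets["down"] == {"down_strong"}


def test_select_responsive_monotone_in_thresholds():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(100)]
    de = type("DE", (), {"table": pd.DataFrame(
        {"qvalue": rng.uniform(0, 0.2, 100)}, index=genes)})()
    cols = pd.MultiIndex.from_product([["WT:antiIgM"], [1, 4, 18]])
    fc = pd.DataFrame(rng.normal(0, 1.5, (100, 3)), index=genes, columns=cols)
    loose = select_responsive(de, fc, "WT:antiIgM", fc_min=2, fdr_max=0.1)
    tight = select_responsive(de, fc, "WT:antiIgM", fc_min=3, fdr_max=0.05)
    assert tight["up"] <= loose["up"] and tight["down"] <= loose["down"]


@pytest.mark.parametrize("triple,expected", [
    ((20, 18, 22), 16.0),
    ((20, 20, 20), 1.0),
    ((30, 25, 25), 1.0),
])
def test_qpcr_fold_change(triple, expected):
    assert qpcr_fold_change(QpcrTriple(*triple)) == pytest.approx(expected)
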