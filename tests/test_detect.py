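"""Unit tests for batch detection: Wald tests, jackknife SEs, gPCA, PoV."""

import numpy as np
import pytest
from scipy import stats

import explobatch as eb

from conftest import make_expression


@pytest.mark.parametrize("coef,se,delta,lo,hi,sig", [
    (2.0, 0.5, 4.0, 1.02, 2.98, True),
    (0.0, 1.0, 0.0, -1.96, 1.96, False),
    (-0.5, 0.3, -5.0 / 3.0, -1.088, 0.088, False),
])
def test_wald_ci_examples(coef, se, delta, lo, hi, sig):
    d, l, h, s = eb.wald_ci(coef, se, 0.95)
    assert np.isclose(d, delta)
    # displayed bounds round to 2 d.p.; the exact z quantile is 1.959964...
    assert np.isclose(l, lo, atol=5e-3) and np.isclose(h, hi, atol=5e-3)
    assert s == sig


def test_wald_ci_rejects_bad_se():
    with pytest.raises(ValueError, match="positive"):
        eb.wald_ci(1.0, 0.0)
    with pytest.raises(ValueError, match="positive"):
        eb.wald_ci(1.0, -2.0)


def test_jackknife_se_positive_on_near_constant_data(rng):
    Y = np.ones((12, 5)) + 1e-3 * rng.standard_normal((12, 5))
    X = eb.build_design(["a"] * 6 + ["b"] * 6)
    se = eb.estimate_se(make_expression(Y), X, 2)
    assert np.all(np.isfinite(se)) and np.all(se > 0)


def test_jackknife_refuses_tiny_n(rng):
    Y = rng.standard_normal((8, 5))
    X = eb.build_design(["a"] * 4 + ["b"] * 4)
    with pytest.raises(ValueError, match="n >= 10"):
        eb.estimate_se(make_expression(Y), X, 2)


def test_jackknife_se_shrinks_with_sqrt_n():
    ds = eb.simulate(eb.SimulationConfig(n_per_batch=(30, 30), p=20, q_true=2,
                                         loading_scale=(1.2, 0.8), seed=3))
    X1 = ds.truth.design
    se1 = eb.estimate_se(ds.Y, X1, 2)
    Y2 = make_expression(np.vstack([ds.Y.values] * 2))
    X2 = eb.DesignMatrix(np.vstack([X1.values] * 2), X1.column_names,
                         X1.column_blocks)
    se2 = eb.estimate_se(Y2, X2, 2)
    col = X1.block_columns("batch")[0]
    ratios = se2[:, col] / se1[:, col]
    assert np.all(ratios > (1 - 0.15) / np.sqrt(2))
    assert np.all(ratios < (1 + 0.15) / np.sqrt(2))


def test_null_delta_magnitude_matches_standard_normal():
    """Under no batch effect, |Delta| should average sqrt(2/pi) ~ 0.798."""
    seeds = np.random.default_rng(42).integers(0, 2**31 - 1, 30)
    deltas = []
    for s in seeds:
        ds = eb.simulate(eb.SimulationConfig(n_per_batch=(25, 25), p=20,
                                             q_true=2, loading_scale=(1.2, 0.8),
                                             seed=int(s)))
        a = eb.find_batch(ds.Y, ds.batch, q=2)
        deltas.extend(np.abs(a.table["delta"]))
    assert abs(np.mean(deltas) - np.sqrt(2 / np.pi)) < 0.2


def test_find_batch_flags_injected_shift():
    ds = eb.simulate(eb.SimulationConfig(batch_beta=[[3.0], [0.0]],
                                         loading_scale=(1.2, 0.8), seed=5))
    a = eb.find_batch(ds.Y, ds.batch, q=2)
    assert a.batch_effect_present
    assert 1 in a.significant_components("batch")


def test_label_swap_flips_signs_only():
    ds = eb.simulate(eb.SimulationConfig(n_per_batch=(20, 20), p=15, q_true=2,
                                         batch_beta=[[2.5], [0.0]],
                                         loading_scale=(1.2, 0.8), seed=9))
    a = eb.find_batch(ds.Y, ds.batch, q=2)
    swapped = ["B2" if b == "B1" else "B1" for b in ds.batch]
    b = eb.find_batch(ds.Y, swapped, q=2)
    ta, tb = a.table, b.table
    np.testing.assert_allclose(tb["coefficient"], -ta["coefficient"], atol=1e-6)
    np.testing.assert_allclose(np.abs(tb["delta"]), np.abs(ta["delta"]),
                               rtol=1e-4)
    np.testing.assert_allclose(tb["ci_high"] - tb["ci_low"],
                               ta["ci_high"] - ta["ci_low"], rtol=1e-4)
    assert (tb["significant"] == ta["significant"]).all()


def test_find_batch_validations(rng):
    Y = make_expression(rng.standard_normal((12, 5)))
    with pytest.raises(ValueError, match=">= 3 samples"):
        eb.find_batch(Y, ["a"] * 10 + ["b"] * 2, q=1)
    with pytest.raises(ValueError, match="at least 2 batches"):
        eb.find_batch(Y, ["a"] * 12, q=1)
    batch = ["a"] * 6 + ["b"] * 6
    with pytest.raises(ValueError, match="rank-deficient|confounded"):
        eb.find_batch(Y, batch, covariates={"tissue": batch}, q=1)


# --- gPCA ------------------------------------------------------------------

def test_gpca_deterministic_under_seed(rng):
    Y = make_expression(rng.standard_normal((30, 10)))
    batch = ["a"] * 15 + ["b"] * 15
    r1 = eb.gpca_test(Y, batch, n_perm=99, seed=7)
    r2 = eb.gpca_test(Y, batch, n_perm=99, seed=7)
    assert r1.statistic == r2.statistic and r1.p_value == r2.p_value


def test_gpca_saturates_under_strong_global_shift(rng):
    Y = rng.standard_normal((40, 20))
    Y[20:] += 5.0                      # 5-sigma shift on every gene
    res = eb.gpca_test(make_expression(Y), ["a"] * 20 + ["b"] * 20,
                       n_perm=99, seed=0)
    assert res.p_value == pytest.approx(1.0 / 100.0)


def test_gpca_pvalue_monotone_in_shift(rng):
    ps = []
    for shift in (0.0, 1.0, 5.0):
        Y = rng.standard_normal((40, 20))
        Y[20:] += shift
        ps.append(eb.gpca_test(make_expression(Y), ["a"] * 20 + ["b"] * 20,
                               n_perm=199, seed=3).p_value)
    assert ps[0] >= ps[1] >= ps[2]


def test_gpca_rejects_single_batch(rng):
    Y = make_expression(rng.standard_normal((10, 5)))
    with pytest.raises(ValueError, match="2 batches"):
        eb.gpca_test(Y, ["a"] * 10, n_perm=99)
    with pytest.raises(ValueError, match="99"):
        eb.gpca_test(Y, ["a"] * 5 + ["b"] * 5, n_perm=10)


# --- proportion of variation ----------------------------------------------

def test_pov_rank_one_concentrates(rng):
    v = rng.standard_normal(8)
    coef = rng.standard_normal(15)
    Y = np.outer(coef, v)
    prof = eb.proportion_of_variation(make_expression(Y))
    assert prof.pov[0] == pytest.approx(1.0, abs=1e-10)
    assert np.all(prof.pov[1:] < 1e-10)


def test_pov_sums_to_one_and_monotone(rng):
    prof = eb.proportion_of_variation(make_expression(
        rng.standard_normal((25, 12))))
    assert prof.cumulative[-1] == pytest.approx(1.0, abs=1e-8)
    assert np.all(np.diff(prof.cumulative) >= -1e-12)
    assert np.all((prof.pov >= 0) & (prof.pov <= 1))


def test_pov_isotropic_limit(rng):
    Y = rng.standard_normal((2000, 10))
    prof = eb.proportion_of_variation(make_expression(Y))
    np.testing.assert_allclose(prof.pov, 1.0 / 10.0, rtol=0.15)


def test_pov_subset_sum(rng):
    prof = eb.proportion_of_variation(make_expression(
        rng.standard_normal((20, 6))))
    assert prof.subset_sum([1, 2]) == pytest.approx(prof.pov[:2].sum())
    with pytest.raises(ValueError):
        prof.subset_sum([0])


def test_pov_rejects_constant_matrix():
    with pytest.raises(ValueError, match="zero variance"):
        eb.proportion_of_variation(make_expression(np.ones((5, 4))))
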