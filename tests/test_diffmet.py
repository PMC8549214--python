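"""PLS/O-PLS discriminant models, VIP, Q2 and univariate DM calling."""

import itertools

import numpy as np
import pytest
from scipy import stats

from zhengomics.diffmet import (
    call_dms,
    cross_validate_q2,
    fit_oplsda,
    fit_plsda,
    univariate_mwu_fdr,
    vip,
)


def _signal_data(rng, n=60, j=30, n_info=6, effect=2.0):
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    X = rng.normal(0, 1, size=(n, j))
    X[:, :n_info] += np.outer(y - 0.5, np.full(n_info, effect))
    return X, y


# -- PLS-DA ------------------------------------------------------------------

def test_plsda_separates_constructed_clouds():
    rng = np.random.default_rng(0)
    X, y = _signal_data(rng, effect=4.0)
    model = fit_plsda(X, y, n_comp=2)
    t1 = model.scores[:, 0]
    assert t1[y == 1].min() > t1[y == 0].max() or t1[y == 0].min() > t1[y == 1].max()


def test_plsda_rejects_single_class():
    rng = np.random.default_rng(1)
    with pytest.raises(ValueError):
        fit_plsda(rng.normal(size=(10, 3)), np.zeros(10))


def test_one_feature_scores_proportional_to_scaled_feature():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, size=(20, 1))
    y = (x[:, 0] + rng.normal(0, 0.1, 20) > 0).astype(int)
    model = fit_plsda(x, y, n_comp=1)
    xs = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std(ddof=1)
    ratio = model.scores[:, 0] / xs
    assert np.allclose(ratio, ratio[0])


def test_successive_scores_orthogonal():
    rng = np.random.default_rng(3)
    X, y = _signal_data(rng)
    model = fit_plsda(X, y, n_comp=3)
    g = model.scores.T @ model.scores
    assert np.allclose(g - np.diag(np.diag(g)), 0, atol=1e-8)


# -- O-PLS-DA ----------------------------------------------------------------

def test_opls_zero_ortho_reduces_to_pls_component_one():
    rng = np.random.default_rng(4)
    X, y = _signal_data(rng)
    opls = fit_oplsda(X, y, n_ortho=0)
    pls = fit_plsda(X, y, n_comp=1)
    assert np.allclose(opls.t, pls.scores[:, 0], atol=1e-10)


def test_orthogonal_scores_uncorrelated_with_class():
    rng = np.random.default_rng(5)
    X, y = _signal_data(rng)
    # add a strong structured direction orthogonal to y
    confound = rng.normal(0, 1, size=len(y))
    confound -= confound.mean()
    yc = y - y.mean()
    confound -= (confound @ yc) / (yc @ yc) * yc
    X = X + np.outer(confound, rng.normal(0, 3, X.shape[1]))
    model = fit_oplsda(X, y, n_ortho=2)
    for k in range(model.n_ortho):
        r = np.corrcoef(model.t_ortho[:, k], yc)[0, 1]
        assert abs(r) < 1e-8


def test_orthogonal_filtering_improves_r2y_on_confounded_data():
    rng = np.random.default_rng(6)
    X, y = _signal_data(rng, effect=1.0)
    confound = rng.normal(0, 1, size=len(y))
    yc = y - y.mean()
    confound -= (confound @ yc) / (yc @ yc) * yc
    X = X + np.outer(confound, rng.normal(0, 5, X.shape[1]))
    r2_pls = fit_oplsda(X, y, n_ortho=0).r2y
    r2_opls = fit_oplsda(X, y, n_ortho=1).r2y
    assert r2_opls > r2_pls


def test_opls_rejects_nonbinary_y():
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError):
        fit_oplsda(rng.normal(size=(12, 4)), np.array([0, 1, 2] * 4))


# -- VIP ---------------------------------------------------------------------

def test_single_feature_vip_is_one():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(30, 1))
    y = (x[:, 0] > 0).astype(int)
    model = fit_oplsda(x, y, n_ortho=0)
    assert vip(model)[0] == pytest.approx(1.0)


def test_vip_mean_square_is_one():
    rng = np.random.default_rng(9)
    for _ in range(5):
        X, y = _signal_data(rng, n=40, j=17)
        v = vip(fit_oplsda(X, y, n_ortho=1))
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-6)


def test_informative_feature_outranks_noise():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 200
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = np.column_stack([y + rng.normal(0, 0.5, n), rng.normal(0, 1, n)])
        v = vip(fit_oplsda(X, y, n_ortho=0))
        if v[0] > 1 > v[1]:
            hits += 1
    assert hits == 10


# -- Q2 ----------------------------------------------------------------------

def test_q2_perfect_predictor():
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, size=40).astype(float)
    X = np.column_stack([y, rng.normal(0, 1, size=(40, 5))])
    q2 = cross_validate_q2(X, y, folds=10, seed=0)
    assert q2 > 0.95


def test_q2_deterministic_given_seed():
    rng = np.random.default_rng(11)
    X, y = _signal_data(rng)
    assert cross_validate_q2(X, y, seed=5) == cross_validate_q2(X, y, seed=5)


def test_q2_permutation_negative_in_expectation():
    rng = np.random.default_rng(12)
    X, y = _signal_data(rng, n=40, j=20)
    q2s = []
    for _ in range(20):
        yp = rng.permutation(y)
        if len(np.unique(yp)) < 2:
            continue
        q2s.append(cross_validate_q2(X, yp, folds=5, seed=1))
    assert np.mean(q2s) <= 0


def test_q2_below_r2y_on_training_data():
    rng = np.random.default_rng(13)
    X, y = _signal_data(rng, n=40, j=25, effect=1.0)
    model = fit_oplsda(X, y)
    q2 = cross_validate_q2(X, y, seed=2)
    assert q2 <= model.r2y


# -- univariate --------------------------------------------------------------

def test_mwu_identical_groups():
    X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
    p, q = univariate_mwu_fdr(X, [0, 0, 0, 1, 1, 1])
    assert p[0] == pytest.approx(1.0)


def test_mwu_exact_small_sample():
    """A=(1,2,3) vs B=(4,5,6): only 1 of C(6,3)=20 rank splits is as extreme,
    two-sided doubles it -> p = 0.1."""
    X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
    p, _ = univariate_mwu_fdr(X, [0, 0, 0, 1, 1, 1])
    assert p[0] == pytest.approx(0.1)
    # enumeration oracle: U_A = (sum of A's ranks) - 6 over all 20 splits;
    # observed U_A = 0, as extreme two-sided means U_A in {0, 9}
    u_values = [sum(comb) - 6 for comb in itertools.combinations(range(1, 7), 3)]
    count_extreme = sum(1 for u in u_values if u <= 0 or u >= 9)
    assert count_extreme / len(u_values) == pytest.approx(0.1)


def test_bh_step_up_by_hand():
    from statsmodels.stats.multitest import multipletests
    q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


# -- DM calling --------------------------------------------------------------

def test_vip_exactly_one_is_not_significant():
    out = call_dms(["m1"], np.array([1.0]), np.array([1e-6]), np.array([1e-6]),
                   mode="untargeted")
    assert not out["significant"].iloc[0]


def test_mode_specific_univariate_rule():
    # q above threshold, p below: targeted accepts, untargeted rejects
    out_t = call_dms(["m1"], np.array([2.0]), np.array([0.01]), np.array([0.2]),
                     mode="targeted")
    out_u = call_dms(["m1"], np.array([2.0]), np.array([0.01]), np.array([0.2]),
                     mode="untargeted")
    assert out_t["significant"].iloc[0]
    assert not out_u["significant"].iloc[0]


def test_misaligned_ids_error():
    with pytest.raises(ValueError):
        call_dms(["m1", "m2"], np.array([1.0]), np.array([0.5]), np.array([0.5]),
                 mode="targeted")


def test_results_invariant_to_feature_and_sample_order():
    rng = np.random.default_rng(14)
    X, y = _signal_data(rng, n=30, j=10)
    model = fit_oplsda(X, y)
    v1 = vip(model)
    perm_f = rng.permutation(10)
    perm_s = rng.permutation(30)
    v2 = vip(fit_oplsda(X[:, perm_f][perm_s], y[perm_s]))
    assert np.allclose(v1[perm_f], v2, atol=1e-8)
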