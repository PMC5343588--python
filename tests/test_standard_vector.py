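import numpy as np
import pandas as pd
import pytest

from cdnorm import estimate_statistical_error, standardize, sv_normalize, sv_step
from cdnorm.standard_vector import StandardVectorSet


def test_standardize_hand_example():
    x = np.tile([1.0, 2.0, 3.0], (20, 1))
    sv = standardize(x, trim_fraction=0.0)
    assert np.allclose(sv.vectors[0], [-1 / np.sqrt(2), 0, 1 / np.sqrt(2)])


def test_constant_gene_excluded():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(30, 3))
    x[7] = 5.0
    sv = standardize(pd.DataFrame(x, index=[f"g{i}" for i in range(30)]),
                     trim_fraction=0.0)
    assert "g7" in sv.trimmed_gene_ids
    assert sv.n_genes == 29


def test_two_sample_degenerate_sphere():
    x = np.array([[1.0, 2.0]] * 15)  # a < b
    sv = standardize(x, trim_fraction=0.0)
    assert np.allclose(sv.vectors, [-1 / np.sqrt(2), 1 / np.sqrt(2)])


def test_unit_norm_zero_sum_invariant():
    rng = np.random.default_rng(3)
    for s in (2, 3, 5, 8):
        x = rng.standard_t(df=3, size=(200, s))  # heavy-tailed on purpose
        sv = standardize(x, trim_fraction=0.02)
        norms = np.linalg.norm(sv.vectors, axis=1)
        sums = sv.vectors.sum(axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert np.allclose(sums, 0.0, atol=1e-9)


def test_trimming_removes_extreme_variances():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(1000, 4))
    x[:5] *= 50.0  # extreme-variance genes
    sv = standardize(x, trim_fraction=0.01)
    assert all(i in sv.trimmed_gene_ids for i in range(5))


def test_too_few_genes_errors():
    with pytest.raises(ValueError, match="at least"):
        standardize(np.random.default_rng(0).normal(size=(5, 3)), 0.0)


def test_symmetric_data_is_fixed_point():
    rng = np.random.default_rng(5)
    half = rng.normal(size=(100, 4))
    x = np.vstack([half, -half]) + 7.0  # exactly sign-symmetric residuals
    sv = standardize(x, trim_fraction=0.0)
    u, rec = sv_step(sv)
    assert np.allclose(u, 0.0, atol=1e-12)
    assert rec.numerical_error <= 1e-12


def test_offset_recovery_within_statistical_error():
    rng = np.random.default_rng(6)
    g, s = 10000, 3
    a = np.array([0.3, -0.1, -0.2])
    x = rng.normal(8.0, 1.0, size=(g, s)) + a
    offsets, trace = sv_normalize(x)
    assert trace[-1].status == "converged"
    err = offsets - (a - a.mean())
    rmse = float(np.sqrt((err**2).mean()))
    assert rmse <= 3 * trace[-1].statistical_error


@pytest.mark.parametrize("dist", ["gaussian", "uniform", "laplace"])
def test_distribution_free_recovery(dist):
    """Offsets are recovered whatever the gene noise distribution."""
    rng = np.random.default_rng(7)
    g, s = 6000, 4
    a = np.array([0.25, -0.05, -0.3, 0.1])
    noise = {
        "gaussian": lambda: rng.normal(size=(g, s)),
        "uniform": lambda: rng.uniform(-np.sqrt(3), np.sqrt(3), size=(g, s)),
        "laplace": lambda: rng.laplace(scale=1 / np.sqrt(2), size=(g, s)),
    }[dist]()
    x = 8.0 + noise + a
    offsets, trace = sv_normalize(x)
    err = offsets - (a - a.mean())
    rmse = float(np.sqrt((err**2).mean()))
    assert rmse <= 3 * trace[-1].statistical_error


def test_two_sample_reduces_to_mean_difference_correction():
    rng = np.random.default_rng(8)
    g = 5000
    a = np.array([0.2, -0.2])
    x = rng.normal(8.0, 1.0, size=(g, 2)) + a
    offsets, trace = sv_normalize(pd.DataFrame(x, columns=["s1", "s2"]))
    diff = x[:, 0] - x[:, 1]
    # the fixed point is the robust (median) half-difference ...
    assert abs(offsets["s1"] - np.median(diff) / 2) <= 3 * trace[-1].statistical_error
    # ... which agrees with the global mean log-difference for symmetric noise
    assert abs(offsets["s1"] - diff.mean() / 2) < 0.05


def test_scale_and_shift_equivariance():
    rng = np.random.default_rng(9)
    x = rng.normal(8.0, 1.0, size=(3000, 3)) + np.array([0.2, 0.0, -0.2])
    base, _ = sv_normalize(x)
    shifted, _ = sv_normalize(x + 5.0)
    scaled, _ = sv_normalize(x * 2.0)
    assert np.allclose(shifted, base, atol=1e-9)  # offsets are zero-sum
    assert np.allclose(scaled, 2.0 * base, atol=1e-9)


def test_permutation_equivariance():
    rng = np.random.default_rng(10)
    x = pd.DataFrame(rng.normal(8, 1, size=(3000, 4)) + np.array([0.3, -0.1, -0.1, -0.1]),
                     columns=["a", "b", "c", "d"])
    base, _ = sv_normalize(x)
    perm = ["c", "a", "d", "b"]
    permuted, _ = sv_normalize(x[perm])
    pd.testing.assert_series_equal(base.reindex(perm), permuted,
                                   check_names=False, atol=1e-12, rtol=0)


def test_statistical_error_zero_for_identical_vectors():
    v = np.array([-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)])
    sv = StandardVectorSet(vectors=np.tile(v, (50, 1)),
                           gene_ids=np.arange(50),
                           trimmed_gene_ids=frozenset(), scale=1.0)
    assert estimate_statistical_error(sv) <= 1e-15


def test_statistical_error_follows_sqrt_g_law():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(2000, 4))
    sv1 = standardize(x, 0.0)
    sv2 = standardize(np.vstack([x, x]), 0.0)  # doubled g, same distribution
    ratio = estimate_statistical_error(sv2) / estimate_statistical_error(sv1)
    assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.01)


def test_statistical_error_matches_monte_carlo_spread():
    rng = np.random.default_rng(12)
    g, s, reps = 2000, 3, 60
    recovered = []
    errs = []
    for _ in range(reps):
        x = rng.normal(0.0, 1.0, size=(g, s))
        offsets, trace = sv_normalize(x)
        recovered.extend(offsets)  # true offsets are zero
        errs.append(trace[-1].statistical_error)
    mc_rms = float(np.sqrt(np.mean(np.square(recovered))))
    est = np.mean(errs)
    assert est / 2 < mc_rms < est * 2


def test_nonconvergence_is_flagged():
    rng = np.random.default_rng(13)
    x = rng.normal(size=(500, 3)) + np.array([1.0, -0.5, -0.5])
    offsets, trace = sv_normalize(x, max_steps=1)
    assert trace[-1].status == "max_steps"
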