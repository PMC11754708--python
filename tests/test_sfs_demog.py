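"""Joint SFS construction, projection, folding, residuals, diversity and
the ILS bound."""

import numpy as np
import pytest

from transpoly import sfs_demog as sd
from transpoly.io_core import MISSING
from conftest import build_gm


def test_joint_sfs_increment_and_total():
    g = np.array([[0], [1], [2], [0], [0], [0]], dtype=np.int8)
    gm = build_gm(g, ["A"] * 3 + ["B"] * 3)
    sfs = sd.joint_sfs(gm, "A", "B")
    assert sfs.matrix[3, 0] == 1.0
    assert sfs.total == 1.0

    rng = np.random.default_rng(0)
    g2 = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
    gm2 = build_gm(g2, ["A"] * 3 + ["B"] * 3)
    assert sd.joint_sfs(gm2, "A", "B").total == 50


def test_joint_sfs_missing_handling():
    g = np.array([[0, MISSING], [1, 0], [2, 0], [0, 1], [0, 0], [0, 0]],
                 dtype=np.int8)
    gm = build_gm(g, ["A"] * 3 + ["B"] * 3)
    with pytest.raises(ValueError, match="missing"):
        sd.joint_sfs(gm, "A", "B")
    with pytest.warns(UserWarning, match="dropped"):
        sfs = sd.joint_sfs(gm, "A", "B", missing="drop")
    assert sfs.total == 1.0


def test_projection_hypergeometric_example():
    """One site with 2 alt of 4 haploids projected to 2 gives
    (1/6, 4/6, 1/6) — brute-force enumeration of draws of 2 without
    replacement."""
    m = np.zeros((5, 3))
    m[2, 0] = 1.0
    proj = sd.project_sfs(sd.JointSFS(m), 2, 2)
    np.testing.assert_allclose(proj.matrix[:, 0], [1 / 6, 4 / 6, 1 / 6],
                               atol=1e-12)


def test_projection_identity_mass_and_marginals():
    rng = np.random.default_rng(1)
    sfs = sd.JointSFS(rng.random((9, 7)))
    ident = sd.project_sfs(sfs, 8, 6)
    np.testing.assert_allclose(ident.matrix, sfs.matrix, atol=1e-12)
    proj = sd.project_sfs(sfs, 4, 4)
    assert proj.total == pytest.approx(sfs.total, abs=1e-9)
    # marginal of the joint projection equals the projected 1D marginal
    pa = sd._projection_matrix(8, 4)
    np.testing.assert_allclose(proj.matrix.sum(axis=1),
                               pa.T @ sfs.matrix.sum(axis=1), atol=1e-10)
    with pytest.raises(ValueError):
        sd.project_sfs(sfs, 1, 4)


def test_projection_matches_subsampling_monte_carlo():
    rng = np.random.default_rng(2)
    n_from, n_to = 10, 4
    counts = rng.integers(0, n_from + 1, size=2000)
    m = np.zeros((n_from + 1, 3))
    np.add.at(m, (counts, 0), 1.0)
    proj = sd.project_sfs(sd.JointSFS(m), n_to, 2)
    mc = np.zeros(n_to + 1)
    for c in counts:
        pool = np.array([1] * c + [0] * (n_from - c))
        mc[rng.choice(pool, n_to, replace=False).sum()] += 1
    np.testing.assert_allclose(proj.matrix[:, 0] / proj.total, mc / mc.sum(),
                               atol=0.03)


def test_folding_merge_conservation_and_commutation():
    rng = np.random.default_rng(3)
    m = rng.random((9, 9))
    sfs = sd.JointSFS(m)
    folded = sd.fold_sfs(sfs)
    assert folded.matrix[1, 1] == pytest.approx(m[1, 1] + m[7, 7])
    assert folded.matrix[7, 7] == 0.0
    assert folded.total == pytest.approx(sfs.total, abs=1e-9)
    with pytest.raises(ValueError, match="folded"):
        sd.fold_sfs(folded)
    # folding commutes with projection
    a = sd.fold_sfs(sd.project_sfs(sfs, 4, 4))
    b_unfolded = sd.project_sfs(sfs, 4, 4)
    np.testing.assert_allclose(a.matrix, sd.fold_sfs(b_unfolded).matrix,
                               atol=1e-12)


def test_shared_from_sfs_cells():
    m = np.zeros((21, 21))
    m[0, 5] = 3.0
    assert sd.shared_from_sfs(sd.JointSFS(m))[0] == 0.0
    m2 = np.zeros((21, 21))
    m2[2, 2] = 1.0
    count, prop = sd.shared_from_sfs(sd.JointSFS(m2))
    assert count == 1.0 and prop == 1.0
    # an allele fixed in one species is not a shared polymorphism
    m3 = np.zeros((21, 21))
    m3[20, 3] = 1.0
    assert sd.shared_from_sfs(sd.JointSFS(m3))[0] == 0.0


def test_shared_from_sfs_matches_classification_oracle():
    """Spectrum-based shared counting at the 1/20 threshold agrees with
    direct site classification of 10+10 diploid genotypes."""
    from transpoly import classify
    from transpoly.simulate import SplitSimConfig, sim_split_coalescent

    cfg = SplitSimConfig(n_A=10, n_B=10, theta=1.0, T_split=0.5, M=0.5,
                         n_loci=300, seed=12)
    gm, _ = sim_split_coalescent(cfg)
    sfs = sd.joint_sfs(gm, "A", "B")
    count, _ = sd.shared_from_sfs(sfs, min_count=2)
    # a MAF cutoff strictly between 1/20 and 2/20 selects minor count >= 2
    cls = classify.classify_sites(gm, "A", "B", maf_min=0.075, min_call_rate=0)
    assert count == (cls["label"] == "SHARED_POLY").sum()


def test_residuals_zero_arithmetic_and_modes():
    rng = np.random.default_rng(4)
    m = rng.random((5, 5)) + 0.5
    sfs = sd.JointSFS(m)
    res = sd.sfs_residuals(sfs, sfs)
    assert res.mean_standardized_residual == 0.0
    assert np.all(res.residuals == 0.0)

    o = sd.JointSFS(np.full((3, 3), 4.0))
    e = sd.JointSFS(np.ones((3, 3)))
    pear = sd.sfs_residuals(o, e)
    assert pear.residuals[1, 1] == pytest.approx(3.0)
    rel = sd.sfs_residuals(o, e, mode="relative")
    assert rel.residuals[1, 1] == pytest.approx(3.0)  # (4-1)/1
    with pytest.raises(ValueError, match="shapes"):
        sd.sfs_residuals(o, sd.JointSFS(np.ones((4, 4))))


def test_loglik_bic_maximal_at_truth_and_k_penalty():
    rng = np.random.default_rng(5)
    m = rng.integers(0, 20, size=(6, 6)).astype(float)
    emp = sd.JointSFS(m)
    ll_true, _ = sd.sfs_loglik_bic(emp, emp, k_params=0)
    for _ in range(5):
        pert = m + rng.normal(0, 1, m.shape)
        pert = np.clip(pert, 0.01, None)
        pert *= m.sum() / pert.sum()
        ll_p, _ = sd.sfs_loglik_bic(emp, sd.JointSFS(pert), k_params=0)
        assert ll_p <= ll_true
    _, bic0 = sd.sfs_loglik_bic(emp, emp, k_params=0, n_obs=100)
    _, bic2 = sd.sfs_loglik_bic(emp, emp, k_params=2, n_obs=100)
    assert bic2 - bic0 == pytest.approx(2 * np.log(100))


def test_diversity_stats_examples():
    # species fixed for different alleles at 1 site, 10 monitored sites
    g = np.vstack([np.zeros((3, 1)), np.full((3, 1), 2)]).astype(np.int8)
    gm = build_gm(g, ["A"] * 3 + ["B"] * 3)
    st = sd.diversity_stats(gm, "A", "B", n_monitored_sites=10)
    assert st["d_xy"] == pytest.approx(0.1)
    assert st["pi_a"] == 0.0

    # identical panels: D_xy == pi up to the n/(n-1) pairing correction
    rng = np.random.default_rng(6)
    half = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
    gm2 = build_gm(np.vstack([half, half]), ["A"] * 30 + ["B"] * 30)
    st2 = sd.diversity_stats(gm2, "A", "B", n_monitored_sites=50)
    assert st2["d_xy"] == pytest.approx(st2["pi_a"], rel=0.05)
    assert st2["d_xy"] == pytest.approx(st2["pi_a"] * 59 / 60, rel=1e-12)

    with pytest.warns(UserWarning, match="per-SNP"):
        sd.diversity_stats(gm2, "A", "B")


def test_ils_bound_arithmetic_and_monotonicity():
    res = sd.ils_bound(sd.ILSInputs(d_between=0.02, p_a=0.01, p_b=0.01,
                                    s_a=1000, s_b=900))
    assert res.tau_a == pytest.approx(1.0)
    assert res.retention_prob == pytest.approx(np.exp(-2), rel=1e-12)
    assert res.expected_shared_max == pytest.approx(1000 * np.exp(-2))

    zero_age = sd.ils_bound(sd.ILSInputs(d_between=0.01, p_a=0.01, p_b=0.008,
                                         s_a=500, s_b=400))
    assert zero_age.retention_prob == 1.0
    assert zero_age.expected_shared_max == 500

    bounds = [sd.ils_bound(sd.ILSInputs(d, 0.01, 0.01, 100, 100)
                           ).expected_shared_max
              for d in (0.01, 0.015, 0.02, 0.03)]
    assert all(x > y for x, y in zip(bounds, bounds[1:]))

    with pytest.raises(ValueError, match="undefined"):
        sd.ils_bound(sd.ILSInputs(d_between=0.02, p_a=0.0, p_b=0.01,
                                  s_a=10, s_b=10))
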