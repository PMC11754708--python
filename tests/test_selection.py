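"""alpha_b arithmetic and bootstrap, beta(1) calibration, LD r^2."""

import numpy as np
import pandas as pd
import pytest

from transpoly import selection as sel
from transpoly.io_core import MISSING
from conftest import build_gm


def test_count_polymorphisms_fixture():
    cls = pd.DataFrame({
        "chrom": ["c"] * 6, "pos": range(1, 7),
        "label": ["PRIVATE_A", "PRIVATE_A", "SHARED_POLY", "SHARED_POLY",
                  "PRIVATE_B", "INVARIANT"],
    })
    sites = pd.DataFrame({"chrom": ["c"] * 6, "pos": range(1, 7),
                          "annotation": ["SYN", "NS", "SYN", "NS", "SYN",
                                         "SYN"]})
    c = sel.count_polymorphisms(cls, sites, "a")
    assert (c.poly_syn, c.poly_ns, c.sp_syn, c.sp_ns) == (1, 1, 1, 1)
    c_b = sel.count_polymorphisms(cls, sites, "b")
    assert (c_b.poly_syn, c_b.poly_ns) == (1, 0)


def test_alpha_b_arithmetic_zero_and_errors():
    c = sel.PolymorphismCounts(10_000, 5_300, 1_000, 580)
    assert sel.alpha_b(c) == pytest.approx(1 - 0.53 / 0.58, abs=1e-12)
    assert sel.alpha_b(c) == pytest.approx(0.086206896551724, abs=1e-12)
    # equal NS/Syn ratios -> 0
    assert sel.alpha_b(sel.PolymorphismCounts(100, 50, 20, 10)) == 0.0
    with pytest.raises(ValueError, match="sp_ns"):
        sel.alpha_b(sel.PolymorphismCounts(10, 5, 2, 0))
    with pytest.raises(ValueError, match="poly_syn"):
        sel.alpha_b(sel.PolymorphismCounts(0, 5, 2, 1))


def test_alpha_b_scaling_invariance():
    c1 = sel.PolymorphismCounts(1000, 530, 100, 58)
    c2 = sel.PolymorphismCounts(7000, 3710, 700, 406)
    assert sel.alpha_b(c1) == pytest.approx(sel.alpha_b(c2), abs=1e-12)


def null_snp_table(rng, n_blocks=50,
                   lam=(40.0, 20.0, 8.0, 4.0)):
    cats = [("private", "SYN"), ("private", "NS"), ("shared", "SYN"),
            ("shared", "NS")]
    rows = []
    for b in range(n_blocks):
        for (lab, ann), l in zip(cats, lam):
            for _ in range(rng.poisson(l)):
                rows.append((b, lab, ann))
    return pd.DataFrame(rows, columns=["block_id", "label", "annotation"])


def test_alpha_b_bootstrap_deterministic_and_signal():
    rng = np.random.default_rng(0)
    tab = null_snp_table(rng)
    r1 = sel.alpha_b_bootstrap(tab, n_boot=200, seed=4)
    r2 = sel.alpha_b_bootstrap(tab, n_boot=200, seed=4)
    assert r1.ci_low == r2.ci_low and r1.p_value == r2.p_value

    # strong NS excess among shared SNPs: p at the floor
    strong = null_snp_table(rng, lam=(40.0, 20.0, 4.0, 30.0))
    res = sel.alpha_b_bootstrap(strong, n_boot=500, seed=1)
    assert res.alpha_b > 0.5
    assert res.p_value == pytest.approx(1 / 500)
    assert res.ci_low <= res.alpha_b <= res.ci_high


def test_alpha_b_bootstrap_needs_blocks():
    tab = pd.DataFrame({"block_id": [0] * 8,
                        "label": ["private"] * 4 + ["shared"] * 4,
                        "annotation": ["SYN", "NS"] * 4})
    with pytest.raises(ValueError, match="blocks"):
        sel.alpha_b_bootstrap(tab)


def test_beta1_similar_window_positive_and_empty():
    n = 40
    freqs = pd.DataFrame({"pos": [500, 520, 540, 560],
                          "folded_freq": [0.5, 0.5, 0.5, 0.5]})
    res = sel.beta1(freqs, core_pos=500, n=n, window=1000)
    assert res.beta1 > 0
    assert res.n_window_snps == 3

    lonely = pd.DataFrame({"pos": [500], "folded_freq": [0.5]})
    assert sel.beta1(lonely, core_pos=500, n=n) is None


def test_beta1_neutral_calibration():
    """Mean beta(1) across cores is ~0 for neutral-equilibrium frequencies
    in the free-recombination limit (site frequencies drawn independently
    from the 1/k spectrum): the normalizer makes the similarity-weighted
    sum an unbiased theta estimator, the same target as Watterson's."""
    rng = np.random.default_rng(9)
    n_hap = 40
    theta = 4.0
    a_n = np.sum(1.0 / np.arange(1, n_hap))
    k = np.arange(1, n_hap)
    pk = (1.0 / k) / a_n
    vals = []
    for _ in range(400):
        s = rng.poisson(theta * a_n)
        if s < 3:
            continue
        classes = rng.choice(k, size=s, p=pk)
        folded = np.minimum(classes, n_hap - classes) / n_hap
        pos = np.sort(rng.choice(1000, size=s, replace=False)) + 1
        freqs = pd.DataFrame({"pos": pos, "folded_freq": folded})
        core = freqs.iloc[s // 2]
        r = sel.beta1(freqs, core_pos=int(core["pos"]), n=n_hap, window=2000)
        if r is not None:
            vals.append(r.beta1)
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert len(vals) > 300
    assert abs(vals.mean()) < 3 * se


def test_beta1_elevated_at_balanced_locus():
    """Cores at a balanced trans-specific locus score above the neutral
    background: linked variants sit at the same intermediate frequency."""
    from transpoly.simulate import (BalancedLocusConfig, SplitSimConfig,
                                    sim_balanced_trans_locus)

    split = SplitSimConfig(T_split=2.0, theta=5.0, locus_len=500)
    aln, gm, info = sim_balanced_trans_locus(BalancedLocusConfig(seed=3),
                                             split)
    ia = gm.species_index("A")
    counts = gm.genotypes[ia].sum(axis=0)
    n_hap = 2 * ia.size
    folded = np.minimum(counts, n_hap - counts) / n_hap
    keep = folded > 0
    freqs = pd.DataFrame({"pos": gm.sites["pos"].to_numpy()[keep],
                          "folded_freq": folded[keep]})
    focal = info["trans_positions"][len(info["trans_positions"]) // 2]
    res = sel.beta1(freqs, core_pos=focal, n=n_hap, window=500)
    assert res.beta1 > 0


def test_ld_r2_trivial_pairs():
    g = np.array([[0, 0, 0, 2], [0, 2, 0, 2], [2, 0, 2, 0], [2, 2, 2, 0]],
                 dtype=np.int8)
    gm = build_gm(g, ["A"] * 4)
    res = sel.ld_r2(gm, pairs=[(0, 2), (0, 1), (0, 3)])
    r2 = res.set_index(["site_1", "site_2"])["r2"]
    assert r2[(0, 2)] == pytest.approx(1.0)       # identical dosages
    assert r2[(0, 1)] == pytest.approx(0.0)       # orthogonal
    assert r2[(0, 3)] == pytest.approx(1.0)       # anti-correlated


def test_ld_r2_full_coupling_haplotypes():
    rng = np.random.default_rng(8)
    hap = rng.integers(0, 2, size=24)
    g = (hap[:12] + hap[12:]).astype(np.int8)  # two loci in full coupling
    gm = build_gm(np.stack([g, g], axis=1), ["A"] * 12)
    res = sel.ld_r2(gm, pairs=[(0, 1)])
    assert res["r2"].iloc[0] == pytest.approx(1.0)


def test_ld_r2_monomorphic_flagged():
    g = np.array([[0, 0], [0, 1], [0, 2]], dtype=np.int8)
    gm = build_gm(g, ["A"] * 3)
    res = sel.ld_r2(gm, pairs=[(0, 1)])
    assert np.isnan(res["r2"].iloc[0])
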