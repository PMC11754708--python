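"""Generator correctness: coalescent expectations, sequence evolution,
read-depth calling, F1 crosses and the activity model."""

import numpy as np
import pytest

from transpoly.io_core import MISSING, tree_from_newick
from transpoly.simulate import (ActivitySimConfig, BalancedLocusConfig,
                                DepthModel, SplitSimConfig,
                                call_genotypes_from_reads, sim_activity,
                                sim_balanced_trans_locus, sim_f1_cross,
                                sim_quartet, sim_sequences_on_tree,
                                sim_split_coalescent)


def pairwise_pi_per_locus(gm):
    g = gm.genotypes
    n_hap = 2 * g.shape[0]
    ac = g.sum(axis=0)
    return (ac * (n_hap - ac) / (n_hap * (n_hap - 1) / 2)).sum()


def test_split_deterministic_under_seed():
    cfg = SplitSimConfig(n_A=4, n_B=4, n_loci=30, seed=5)
    gm1, t1 = sim_split_coalescent(cfg)
    gm2, t2 = sim_split_coalescent(SplitSimConfig(n_A=4, n_B=4, n_loci=30,
                                                  seed=5))
    assert gm1 == gm2
    assert t1.equals(t2)


def test_single_population_pi_matches_theta():
    """At T_split = 0 the model is panmictic: E[pi] = theta per locus."""
    cfg = SplitSimConfig(n_A=2, n_B=2, theta=1.0, T_split=0.0, n_loci=2500,
                         seed=1)
    gm, _ = sim_split_coalescent(cfg)
    pi = pairwise_pi_per_locus(gm) / cfg.n_loci
    assert pi == pytest.approx(1.0, abs=0.08)


def test_deep_split_no_shared_polymorphism():
    cfg = SplitSimConfig(n_A=5, n_B=5, theta=0.5, T_split=30.0, M=0.0,
                         n_loci=150, seed=2)
    gm, truth = sim_split_coalescent(cfg)
    ca = gm.genotypes[gm.species_index("A")].sum(axis=0)
    cb = gm.genotypes[gm.species_index("B")].sum(axis=0)
    shared = ((ca > 0) & (ca < 10) & (cb > 0) & (cb < 10)).sum()
    assert shared == 0


def test_shared_fraction_decreases_with_split_time():
    fracs = []
    for T in (0.1, 0.5, 1.0, 2.0):
        shared = total = 0
        for rep in range(3):
            cfg = SplitSimConfig(n_A=5, n_B=5, theta=1.0, T_split=T, M=0.0,
                                 n_loci=400, seed=100 * rep + int(T * 10))
            gm, _ = sim_split_coalescent(cfg)
            ca = gm.genotypes[gm.species_index("A")].sum(axis=0)
            cb = gm.genotypes[gm.species_index("B")].sum(axis=0)
            shared += ((ca % 10 != 0) & (cb % 10 != 0)).sum()
            total += gm.n_sites
        fracs.append(shared / total)
    assert all(x > y for x, y in zip(fracs, fracs[1:]))


def test_truth_table_ages_respect_split():
    cfg = SplitSimConfig(n_A=4, n_B=4, T_split=1.0, n_loci=100, seed=3)
    gm, truth = sim_split_coalescent(cfg)
    assert (truth.loc[truth["pre_split"], "age"] >= 1.0).all()
    assert set(truth.loc[~truth["pre_split"], "origin"]) <= {"A", "B"}
    assert (truth.loc[truth["pre_split"], "origin"] == "ancestral").all()
    # a post-split mutation is confined to its species of origin
    ca = gm.genotypes[gm.species_index("A")].sum(axis=0)
    cb = gm.genotypes[gm.species_index("B")].sum(axis=0)
    in_a = truth["origin"].to_numpy() == "A"
    assert (cb[in_a] == 0).all()


def test_split_matches_msprime_oracle():
    """Mean segregating sites per locus agrees with msprime under the same
    two-population split model."""
    msprime = pytest.importorskip("msprime")
    T, theta, n_loci = 1.0, 1.0, 800
    cfg = SplitSimConfig(n_A=3, n_B=3, theta=theta, T_split=T, M=0.0,
                         n_loci=n_loci, seed=4)
    gm, _ = sim_split_coalescent(cfg)
    s_ours = gm.n_sites / n_loci

    demog = msprime.Demography()
    demog.add_population(name="A", initial_size=0.5)  # units: 2N generations
    demog.add_population(name="B", initial_size=0.5)
    demog.add_population(name="anc", initial_size=0.5)
    demog.add_population_split(time=T, derived=["A", "B"], ancestral="anc")
    s_ms = 0
    reps = msprime.sim_ancestry(samples={"A": 3, "B": 3}, demography=demog,
                                ploidy=2, num_replicates=n_loci,
                                random_seed=7)
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(ts, rate=theta / 2, random_seed=i + 1,
                                    discrete_genome=False)
        s_ms += mts.num_sites
    s_ms /= n_loci
    assert s_ours == pytest.approx(s_ms, rel=0.08)


def test_quartet_admixture_shifts_allele_sharing():
    gm, _ = sim_quartet(n=(4, 4, 4, 4), t1=1.0, t2=2.0, t3=3.0,
                        admixture=(0.05, 0.5), n_loci=300, seed=6)
    assert set(gm.samples["species"]) == {"P1", "P2", "P3", "O"}


def test_sequences_on_tree_limits():
    tree = tree_from_newick("(a:0.0,b:0.0);")
    aln = sim_sequences_on_tree(tree, 200, 0.1, seed=0)
    assert aln.sequences[0] == aln.sequences[1]

    # JC correction recovers the simulated distance
    tree2 = tree_from_newick("(a:0.05,b:0.05);")
    aln2 = sim_sequences_on_tree(tree2, 100_000, 1.0, seed=1)
    from transpoly.genetrees import pairwise_distances
    d = pairwise_distances(aln2, model="jc69").matrix[0, 1]
    assert d == pytest.approx(0.1, rel=0.05)


def test_star_tree_equal_expected_distances():
    tree = tree_from_newick("(a:0.1,b:0.1,c:0.1);")
    aln = sim_sequences_on_tree(tree, 50_000, 1.0, seed=2)
    from transpoly.genetrees import pairwise_distances
    m = pairwise_distances(aln).matrix
    offdiag = m[np.triu_indices(3, 1)]
    assert offdiag.std() / offdiag.mean() < 0.1


def test_balanced_locus_focal_frequency_and_classes():
    split = SplitSimConfig(T_split=2.0, theta=5.0, locus_len=500)
    freqs = []
    for seed in range(6):
        aln, gm, info = sim_balanced_trans_locus(
            BalancedLocusConfig(n_per_species=10, seed=seed), split)
        freqs.extend([info["freq_A"], info["freq_B"]])
        assert len(info["trans_positions"]) == 13
        # trans-specific columns separate the classes perfectly
        arr = aln.to_array()
        col = arr[:, info["trans_positions"][0] - 1]
        classes = np.array([info["tip_class"][n] for n in aln.names])
        assert len(set(col[classes == "X"])) == 1
        assert len(set(col[classes == "Y"])) == 1
        assert set(col[classes == "X"]) != set(col[classes == "Y"])
    assert np.mean(freqs) == pytest.approx(0.5, abs=0.05)


def test_balanced_locus_species_mode():
    split = SplitSimConfig(T_split=2.0, theta=5.0, locus_len=500)
    aln, gm, info = sim_balanced_trans_locus(
        BalancedLocusConfig(n_linked_sites=0, n_per_species=6, seed=3), split)
    assert info["focal_pos"] is None
    assert set(info["tip_class"].values()) == {"X"}


def test_f1_cross_mendelian_limits():
    deep = DepthModel(depth_dist={200: 1.0}, error_rate=0.0)
    parents = np.ones(60, dtype=np.int8)
    gm, true = sim_f1_cross(parents, parents, deep, n_offspring=400, seed=0)
    freqs = np.array([(gm.genotypes == k).mean() for k in (0, 1, 2)])
    np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)
    assert np.array_equal(gm.genotypes, true)  # no calling error at depth 200

    shallow = DepthModel(depth_dist={1: 1.0}, error_rate=0.0)
    gm1, true1 = sim_f1_cross(parents, parents, shallow, n_offspring=100,
                              seed=1)
    assert (gm1.genotypes != 1).all()
    # true hets split evenly between the homozygote calls
    hets = true1 == 1
    calls = gm1.genotypes[hets]
    assert abs((calls == 0).mean() - 0.5) < 0.05


def test_het_miscall_rate_closed_form():
    """At fixed depth d without error, a true het is miscalled homozygous
    with probability 2^(1-d)."""
    dm = DepthModel(depth_dist={3: 1.0}, error_rate=0.0)
    rng = np.random.default_rng(2)
    true = np.ones(200_000, dtype=np.int8)
    called, _ = call_genotypes_from_reads(true, np.full(true.shape, 3), dm,
                                          rng)
    miscall = (called != 1).mean()
    assert miscall == pytest.approx(0.25, abs=0.01)


def test_activity_baseline_and_structure():
    cfg = ActivitySimConfig(baseline=0.0, clone_sd=0.0, block_sd=0.0, seed=0)
    tab = sim_activity(cfg)
    assert len(tab) == 216
    assert (tab.groupby(["genotype", "light"]).size() == 24).all()
    frac = (tab["n_active"] / tab["n_intervals"]).mean()
    assert frac == pytest.approx(0.5, abs=0.01)
    # clones nested in genotype
    assert (tab.groupby("clone_id")["genotype"].nunique() == 1).all()


def test_config_validation():
    with pytest.raises(ValueError):
        SplitSimConfig(n_A=1)
    with pytest.raises(NotImplementedError):
        SplitSimConfig(recomb=1e-8)
    with pytest.raises(ValueError):
        DepthModel(depth_dist={3: 0.5})
    with pytest.raises(ValueError):
        DepthModel(poisson_lambda=5.0, error_rate=0.7)
    with pytest.raises(ValueError):
        BalancedLocusConfig(s_het=-0.1)
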