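"""Synthetic data generators for two-species polymorphism analyses.

The central generator is a Hudson-style backward-in-time structured
coalescent: demes exchange lineages by migration, merge at scheduled split
times (viewed backward), and accumulate infinite-sites mutations as a
Poisson process on branch lengths. Time is measured in units of 2N
generations and the per-locus mutation parameter is theta = 4*N*mu*L, so a
panmictic sample obeys the textbook expectations E[pi] = theta per locus
and E[S] = theta * a_n.

On top of the neutral engine sit generators for the specific fixtures the
analysis pipeline needs:

* ``sim_split_coalescent`` — two species separated T_split coalescent units
  ago with optional symmetric migration, plus a per-site truth table
  (mutation age, pre/post-split origin).
* ``sim_quartet`` — four populations on an asymmetric species tree
  (((P1,P2),P3),O) with optional P2<->P3 migration or a pulse admixture
  event, for ABBA-BABA / f4-ratio testing.
* ``sim_balanced_trans_locus`` — a locus carrying two allelic haplotype
  classes older than the species split, held near frequency 0.5 by
  overdominance (forward Wright-Fisher at the focal site) with neutral
  mutations dropped on an explicit allele-class genealogy.
* ``sim_sequences_on_tree`` — Jukes-Cantor sequence evolution on a fixed
  genealogy.
* ``sim_f1_cross`` — Mendelian F1 genotypes pushed through a read-depth
  genotype-calling error model.
* ``sim_activity`` — binomial activity counts (active 5-second intervals)
  under a light x genotype model with clone and block effects.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_core import (MISSING, GenotypeMatrix, HaplotypeAlignment,
                      make_sample_table, make_site_table, tree_from_newick)

logger = logging.getLogger(__name__)

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


# ---------------------------------------------------------------------------
# configs


@dataclass
class SplitSimConfig:
    """Two-population split model: one ancestral population divides into
    species A and B at ``T_split`` (units of 2N generations), optionally
    connected by symmetric migration at rate ``M = 4Nm`` afterwards.

    ``theta`` is the per-locus population mutation parameter 4*N*mu*L.
    ``mu`` records the assumed per-site per-generation mutation rate and
    ``recomb`` the per-site recombination rate; loci are simulated without
    intra-locus recombination (single genealogy per locus), the regime all
    downstream consumers assume.
    """

    n_A: int = 20
    n_B: int = 20
    theta: float = 1.0
    T_split: float = 1.0
    M: float = 0.0
    n_loci: int = 100
    locus_len: int = 1000
    mu: float = 5.69e-9
    recomb: float = 0.0
    seed: int = 0
    species: tuple = ("A", "B")

    def __post_init__(self):
        if self.n_A < 2 or self.n_B < 2:
            raise ValueError("need >= 2 diploids per species")
        for name in ("theta", "T_split", "M", "mu", "recomb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.recomb > 0:
            raise NotImplementedError(
                "intra-locus recombination is not supported; loci are "
                "single-genealogy (set recomb=0 and use more, shorter loci)")


@dataclass
class BalancedLocusConfig:
    """A balanced trans-specific haplotype locus.

    Two allelic classes arose ``allele_age`` coalescent units ago
    (>= T_split, so the polymorphism predates the species split) and are
    held near frequency 0.5 by symmetric overdominance with heterozygote
    advantage ``s_het``. ``n_linked_sites`` trans-specific variants
    (including the focal SNP) distinguish the classes along a
    ``flank_len``-bp haplotype.
    """

    s_het: float = 1.0
    n_linked_sites: int = 13
    flank_len: int = 500
    allele_age: float = 6.0
    n_per_species: int = 30
    n_forward: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.s_het < 0:
            raise ValueError("s_het must be >= 0")
        if self.n_linked_sites < 0:
            raise ValueError("n_linked_sites must be >= 0")


@dataclass
class DepthModel:
    """Read-depth distribution plus a per-read error rate, defining the
    genotype-calling error process.

    Depth is drawn either from an empirical distribution
    ``depth_dist = {depth: probability}`` or from Poisson(``poisson_lambda``).
    Each read reports the wrong allele with probability ``error_rate``
    (symmetric ref<->alt). A heterozygote is called iff both alleles are
    seen at least ``het_call_rule`` times; otherwise the majority allele's
    homozygote is called; zero depth (or an unresolvable tie) yields a
    missing call.
    """

    depth_dist: dict | None = None
    poisson_lambda: float | None = None
    error_rate: float = 0.001
    het_call_rule: int = 1

    def __post_init__(self):
        if (self.depth_dist is None) == (self.poisson_lambda is None):
            raise ValueError("specify exactly one of depth_dist, poisson_lambda")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.het_call_rule < 1:
            raise ValueError("het_call_rule must be >= 1")
        if self.depth_dist is not None:
            tot = sum(self.depth_dist.values())
            if not math.isclose(tot, 1.0, rel_tol=1e-9):
                raise ValueError("depth_dist probabilities must sum to 1")
            if any(d < 0 for d in self.depth_dist):
                raise ValueError("depths must be non-negative")

    def draw_depths(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.poisson_lambda is not None:
            return rng.poisson(self.poisson_lambda, size=size)
        depths = np.fromiter(self.depth_dist.keys(), dtype=np.int64)
        probs = np.fromiter(self.depth_dist.values(), dtype=float)
        return rng.choice(depths, size=size, p=probs)

    def depth_support(self, quantile: float = 1 - 1e-9):
        """(depths, probabilities) covering all but ``1 - quantile`` mass."""
        if self.depth_dist is not None:
            d = np.fromiter(self.depth_dist.keys(), dtype=np.int64)
            p = np.fromiter(self.depth_dist.values(), dtype=float)
            order = np.argsort(d)
            return d[order], p[order]
        from scipy.stats import poisson
        dmax = int(poisson.ppf(quantile, self.poisson_lambda)) + 1
        d = np.arange(dmax + 1)
        p = poisson.pmf(d, self.poisson_lambda)
        return d, p / p.sum()


@dataclass
class ActivitySimConfig:
    """Beam-break activity experiment: three opsin genotypes x three light
    treatments, clones nested in genotype, experimental blocks, and a
    binomial count of active 5-second intervals per individual.

    Defaults mirror a 12-clone, 216-individual design measured over a 12-h
    window at 5-s sampling (~7,800 intervals after acclimation).
    """

    n_per_cell: int = 24
    n_intervals: int = 7800
    baseline: float = -1.0
    genotype_effects: dict = field(default_factory=lambda: {"AA": 0.0, "AB": 0.0, "BB": 0.0})
    light_effects: dict = field(default_factory=lambda: {"white": 0.0, "blue": 0.0, "dark": 0.0})
    interaction_effects: dict = field(default_factory=dict)
    clone_sd: float = 0.3
    block_sd: float = 0.2
    n_clones_per_genotype: int = 4
    n_blocks: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_intervals <= 0:
            raise ValueError("n_intervals must be > 0")
        if self.n_per_cell % self.n_clones_per_genotype:
            raise ValueError("n_per_cell must be divisible by n_clones_per_genotype")


# ---------------------------------------------------------------------------
# coalescent engine


class _RngBuf:
    """Block-buffered exponential/uniform draws (cuts per-call RNG overhead
    in the event loop)."""

    __slots__ = ("rng", "n", "_e", "_ei", "_u", "_ui")

    def __init__(self, rng, n=65536):
        self.rng = rng
        self.n = n
        self._e = rng.exponential(size=n)
        self._ei = 0
        self._u = rng.random(size=n)
        self._ui = 0

    def exp(self) -> float:
        i = self._ei
        if i == self.n:
            self._e = self.rng.exponential(size=self.n)
            i = 0
        self._ei = i + 1
        return self._e[i]

    def uni(self) -> float:
        i = self._ui
        if i == self.n:
            self._u = self.rng.random(size=self.n)
            i = 0
        self._ui = i + 1
        return self._u[i]

    def randint(self, k: int) -> int:
        return int(self.uni() * k)


def _sim_locus_branches(counts, events, migration, buf):
    """Simulate one genealogy; return per-branch (mask, length, t0, deme).

    counts: haploid lineage count per deme at time 0.
    events: time-sorted list of ("merge", t, src, dst) or
            ("pulse", t, src, dst, prob) tuples, applied backward in time.
    migration: {(i, j): per-lineage backward rate} while both demes exist.
    Lineages are integer bitmasks over sampled haploids; merging is bitwise
    OR, so descendant sets are exact. Each branch records the deme it was
    born in (exact origin labelling without migration; with migration a
    branch that moved mid-life keeps its birth deme).
    """
    demes = []
    h = 0
    for d, c in enumerate(counts):
        demes.append([(1 << (h + i), 0.0, d) for i in range(c)])
        h += c
    mig = dict(migration)
    b_mask, b_len, b_t0, b_deme = [], [], [], []
    t = 0.0
    ev_i = 0
    n_live = h
    n_events = len(events)
    while n_live > 1:
        R = 0.0
        coal = []
        for L in demes:
            k = len(L)
            r = k * (k - 1) * 0.5
            coal.append(r)
            R += r
        migs = []
        if mig:
            for (i, j), m in mig.items():
                r = len(demes[i]) * m
                if r > 0.0:
                    migs.append((r, i, j))
                    R += r
        t_sched = events[ev_i][1] if ev_i < n_events else math.inf
        t_new = t + buf.exp() / R if R > 0.0 else math.inf
        if t_new >= t_sched:
            if t_sched == math.inf:
                raise RuntimeError("isolated lineages cannot coalesce; "
                                   "check merge schedule")
            t = t_sched
            ev = events[ev_i]
            ev_i += 1
            if ev[0] == "merge":
                _, _, src, dst = ev
                demes[dst].extend(demes[src])
                demes[src] = []
                if mig:
                    mig = {k: v for k, v in mig.items() if src not in k}
            else:
                _, _, src, dst, prob = ev
                stay = []
                moved = demes[dst]
                for lin in demes[src]:
                    if buf.uni() < prob:
                        moved.append(lin)
                    else:
                        stay.append(lin)
                demes[src] = stay
            continue
        t = t_new
        x = buf.uni() * R
        done = False
        for d, r in enumerate(coal):
            if x < r:
                L = demes[d]
                k = len(L)
                a = buf.randint(k)
                b = buf.randint(k - 1)
                if b >= a:
                    b += 1
                if a < b:
                    a, b = b, a
                m1, t1, d1 = L.pop(a)
                m2, t2, d2 = L.pop(b)
                b_mask.append(m1); b_len.append(t - t1); b_t0.append(t1); b_deme.append(d1)
                b_mask.append(m2); b_len.append(t - t2); b_t0.append(t2); b_deme.append(d2)
                L.append((m1 | m2, t, d))
                n_live -= 1
                done = True
                break
            x -= r
        if not done:
            for r, i, j in migs:
                if x < r or (r, i, j) == migs[-1]:
                    L = demes[i]
                    lin = L.pop(buf.randint(len(L)))
                    demes[j].append(lin)
                    break
                x -= r
    return b_mask, np.array(b_len), np.array(b_t0), np.array(b_deme, dtype=np.int8)


def _masks_to_haplotypes(masks, n_hap) -> np.ndarray:
    """(n_sites, n_hap) 0/1 array from integer descendant bitmasks."""
    if not masks:
        return np.zeros((0, n_hap), dtype=np.uint8)
    nb = (n_hap + 7) // 8
    raw = b"".join(m.to_bytes(nb, "little") for m in masks)
    bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8).reshape(len(masks), nb),
                         axis=1, bitorder="little")
    return bits[:, :n_hap]


def _simulate_multi_pop(counts, theta, events, migration, n_loci, locus_len,
                        rng, labels, origin_label):
    """Run the engine over ``n_loci`` independent loci and assemble a
    GenotypeMatrix (diploids built from consecutive haploid pairs) plus a
    per-site truth table."""
    buf = _RngBuf(rng)
    n_hap = sum(counts)
    n_dip = n_hap // 2
    all_bits = []
    chroms, poss = [], []
    ages_all, origin_all = [], []
    for locus in range(n_loci):
        masks, blen, bt0, bdeme = _sim_locus_branches(counts, events, migration, buf)
        if len(masks) == 0:
            continue
        muts = rng.poisson(theta / 2.0 * blen)
        tot = int(muts.sum())
        if tot == 0:
            continue
        if tot > locus_len:
            raise ValueError(
                f"locus {locus}: {tot} mutations exceed locus_len={locus_len}; "
                "increase locus_len or reduce theta")
        idx = np.repeat(np.arange(len(masks)), muts)
        site_masks = [masks[i] for i in idx]
        ages = bt0[idx] + rng.random(tot) * blen[idx]
        bits = _masks_to_haplotypes(site_masks, n_hap)
        pos = np.sort(rng.choice(locus_len, size=tot, replace=False)) + 1
        all_bits.append(bits)
        chroms.extend([f"L{locus:05d}"] * tot)
        poss.extend(pos.tolist())
        ages_all.append(ages)
        origin_all.append(origin_label(ages, bdeme[idx]))
    if all_bits:
        bits = np.concatenate(all_bits, axis=0)
        ages = np.concatenate(ages_all)
        origins = np.concatenate(origin_all)
    else:
        bits = np.zeros((0, n_hap), dtype=np.uint8)
        ages = np.zeros(0)
        origins = np.zeros(0, dtype=object)
    genotypes = bits.reshape(-1, n_dip, 2).sum(axis=2).astype(np.int8).T

    sample_ids, species_lab = [], []
    for c, lab in zip(counts, labels):
        for i in range(c // 2):
            sample_ids.append(f"{lab}_{i:03d}")
            species_lab.append(lab)
    coverage = rng.uniform(10.0, 50.0, size=n_dip)
    samples = make_sample_table(sample_ids, species=species_lab,
                                mean_coverage=coverage)
    refs = _BASES[rng.integers(0, 4, size=len(poss))].astype("U1")
    alt_off = rng.integers(1, 4, size=len(poss))
    alts = _BASES[(np.searchsorted(_BASES, refs.astype("S1")) + alt_off) % 4].astype("U1")
    sites = make_site_table(chroms, poss, refs, alts)
    gm = GenotypeMatrix(samples, sites, genotypes)
    truth = pd.DataFrame({"chrom": chroms, "pos": poss, "age": ages,
                          "origin": origins})
    return gm, truth


def sim_split_coalescent(cfg: SplitSimConfig):
    """Two-species split coalescent.

    Returns (GenotypeMatrix, truth) where truth records, per site, the
    mutation age (units of 2N generations), whether it predates the split,
    and the lineage (species or 'ancestral') the mutation arose on.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = (2 * cfg.n_A, 2 * cfg.n_B)
    events = [("merge", cfg.T_split, 1, 0)]
    migration = {}
    if cfg.M > 0 and cfg.T_split > 0:
        migration = {(0, 1): cfg.M / 2.0, (1, 0): cfg.M / 2.0}

    def origin_label(ages, demes):
        pre = ages >= cfg.T_split
        lab = np.where(pre, "ancestral",
                       np.asarray(cfg.species, dtype=object)[demes])
        return lab.astype(object)

    gm, truth = _simulate_multi_pop(counts, cfg.theta, events, migration,
                                    cfg.n_loci, cfg.locus_len, rng,
                                    cfg.species, origin_label)
    truth["pre_split"] = truth["age"] >= cfg.T_split
    return gm, truth


def sim_quartet(n=(10, 10, 10, 10), theta=1.0, t1=1.0, t2=2.0, t3=3.0,
                m23=0.0, admixture=None, n_loci=200, locus_len=1000,
                labels=("P1", "P2", "P3", "O"), seed=0):
    """Four-population coalescent on the species tree (((P1,P2)t1,P3)t2,O)t3.

    ``m23`` adds symmetric P2<->P3 migration (rate 4Nm) until t1;
    ``admixture=(t_adm, frac)`` instead moves each P2 lineage to P3 with
    probability ``frac`` at time ``t_adm`` (a backward pulse: forward in
    time, a fraction ``frac`` of P2 ancestry derives from P3).
    """
    if not t1 < t2 < t3:
        raise ValueError("need t1 < t2 < t3")
    rng = np.random.default_rng(seed)
    counts = tuple(2 * x for x in n)
    events = []
    if admixture is not None:
        t_adm, frac = admixture
        if not 0 < t_adm < t1:
            raise ValueError("admixture time must lie in (0, t1)")
        events.append(("pulse", t_adm, 1, 2, frac))
    events += [("merge", t1, 1, 0), ("merge", t2, 2, 0), ("merge", t3, 3, 0)]
    migration = {}
    if m23 > 0:
        migration = {(1, 2): m23 / 2.0, (2, 1): m23 / 2.0}

    def origin_label(ages, demes):
        return np.asarray(labels, dtype=object)[demes].astype(object)

    return _simulate_multi_pop(counts, theta, events, migration, n_loci,
                               locus_len, rng, labels, origin_label)


def annotate_sites_random(gm: GenotypeMatrix, probs=None, seed=0) -> GenotypeMatrix:
    """Assign functional annotations to sites at random (in place).

    Default mix loosely follows a gene-dense genome: 25% synonymous, 25%
    non-synonymous, 50% other contexts.
    """
    if probs is None:
        probs = {"SYN": 0.25, "NS": 0.25, "INTRON": 0.2, "INTERGENIC": 0.3}
    rng = np.random.default_rng(seed)
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    gm.sites["annotation"] = rng.choice(cats, size=gm.n_sites, p=p)
    return gm


# ---------------------------------------------------------------------------
# sequence evolution on a fixed genealogy


def sim_sequences_on_tree(tree, length, mu_branch, seed=0) -> HaplotypeAlignment:
    """Jukes-Cantor sequences on a genealogy.

    ``mu_branch`` is the substitution rate per site per branch-length unit;
    on each edge a site keeps its state with probability
    1/4 + 3/4 exp(-4/3 mu d) (the exact JC transition), otherwise it takes
    one of the other three bases uniformly.
    """
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    states = {root: rng.integers(0, 4, size=length, dtype=np.int8)}
    names, seqs = [], []
    for node in tree.preorder_node_iter():
        if node is root:
            parent_state = states[root]
        else:
            parent_state = states[node.parent_node]
            d = node.edge.length or 0.0
            if d < 0:
                raise ValueError("negative branch length")
            p_same = 0.25 + 0.75 * math.exp(-4.0 / 3.0 * mu_branch * d)
            change = rng.random(length) >= p_same
            state = parent_state.copy()
            if change.any():
                shift = rng.integers(1, 4, size=int(change.sum()), dtype=np.int8)
                state[change] = (state[change] + shift) % 4
            states[node] = state
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"tip{len(names)}"
            names.append(label)
            seqs.append(_BASES[states[node]].tobytes().decode())
    return HaplotypeAlignment(names=names, sequences=seqs)


# ---------------------------------------------------------------------------
# balanced trans-specific locus


def _wf_overdominance(rng, n_dip, s_het, n_gens, p0):
    """Forward Wright-Fisher allele-frequency trajectory with symmetric
    overdominance (fitnesses 1 : 1+s : 1). Returns the final frequency or
    None if the allele fixed or was lost."""
    p = p0
    for _ in range(n_gens):
        q = 1.0 - p
        w_bar = p * p + 2 * p * q * (1.0 + s_het) + q * q
        p_star = (p * p + p * q * (1.0 + s_het)) / w_bar
        p = rng.binomial(2 * n_dip, p_star) / (2.0 * n_dip)
        if p <= 0.0 or p >= 1.0:
            return None
    return p


def sim_balanced_trans_locus(cfg: BalancedLocusConfig, split: SplitSimConfig):
    """Generate a locus whose haplotypes cluster by allelic class rather
    than by species.

    A symmetric-overdominance Wright-Fisher trajectory (conditioned on
    retention in both species) sets the class frequency in each species;
    haplotype classes predate the split by construction (classes join at
    ``allele_age`` >= T_split on the genealogy). Neutral mutations accrue
    by Jukes-Cantor on the genealogy; ``n_linked_sites`` trans-specific
    differences (the focal SNP at the window centre plus linked sites)
    separate the classes.

    With ``n_linked_sites == 0`` the locus is a plain species-tree window:
    haplotypes cluster by species and no focal polymorphism is injected.

    Returns (HaplotypeAlignment, GenotypeMatrix, info) where info carries
    the realized class frequencies, per-haplotype classes and the
    trans-specific site positions.
    """
    if cfg.allele_age < split.T_split:
        raise ValueError("allele_age must be >= T_split")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_per_species
    T = split.T_split
    A_age = cfg.allele_age
    balanced = cfg.n_linked_sites > 0

    freq = {"A": 0.5, "B": 0.5}
    if balanced:
        if cfg.s_het == 0 and A_age > 0.5:
            warnings.warn("s_het=0 with an old allele: polymorphism survival "
                          "is unlikely; conditioning on retention", stacklevel=2)
        N = cfg.n_forward
        g_anc = max(int(round((A_age - T) * 2 * N)), 1)
        g_split = max(int(round(T * 2 * N)), 1)
        for _ in range(1000):
            p_anc = _wf_overdominance(rng, N, cfg.s_het, g_anc, 0.5)
            if p_anc is None:
                continue
            p_a = _wf_overdominance(rng, N, cfg.s_het, g_split, p_anc)
            p_b = _wf_overdominance(rng, N, cfg.s_het, g_split, p_anc)
            if p_a is not None and p_b is not None:
                freq = {"A": p_a, "B": p_b}
                break
        else:
            raise RuntimeError("balanced polymorphism never survived; "
                               "increase s_het")

    # haplotype class labels per species (deterministic rounding of the
    # maintained frequency), randomly ordered so diploid pairing is random
    tip_class = {}
    tip_names = {"A": [], "B": []}
    for sp in ("A", "B"):
        if balanced:
            k = int(np.clip(round(2 * m * freq[sp]), 1, 2 * m - 1))
            classes = np.array(["X"] * k + ["Y"] * (2 * m - k))
            rng.shuffle(classes)
        else:
            classes = np.array(["X"] * 2 * m)
        for j in range(2 * m):
            name = f"{sp}|{sp}_{j // 2:03d}|h{j % 2}"
            tip_names[sp].append(name)
            tip_class[name] = classes[j]

    t_cell = 0.25 * T if T > 0 else 0.05
    def _clade(names, depth_from, depth_to):
        inner = ",".join(f"{n}:{depth_to}" for n in names)
        return f"({inner}):{depth_from - depth_to}"

    if balanced:
        # ((A-X, B-X):root, (A-Y, B-Y):root) — classes join at allele_age,
        # species within a class join at T_split
        parts = []
        for cls in ("X", "Y"):
            cells = []
            for sp in ("A", "B"):
                names = [n for n in tip_names[sp] if tip_class[n] == cls]
                if len(names) == 1:
                    cells.append(f"{names[0]}:{T}")
                else:
                    cells.append(_clade(names, T, t_cell))
            parts.append(f"({','.join(cells)}):{A_age - T}")
        newick = f"({parts[0]},{parts[1]});"
    else:
        cells = [_clade(tip_names[sp], T, t_cell) for sp in ("A", "B")]
        newick = f"({cells[0]},{cells[1]});"
    tree = tree_from_newick(newick)

    theta_site = split.theta / split.locus_len
    aln = sim_sequences_on_tree(tree, cfg.flank_len, theta_site / 2.0,
                                seed=int(rng.integers(2 ** 31)))
    # overlay trans-specific class-distinguishing sites
    focal_pos = cfg.flank_len // 2
    trans_positions = []
    if balanced:
        k_extra = cfg.n_linked_sites - 1
        other = rng.choice([p for p in range(cfg.flank_len) if p != focal_pos],
                           size=k_extra, replace=False) if k_extra else np.array([], int)
        trans_positions = sorted([focal_pos] + other.tolist())
        seq_arr = np.frombuffer("".join(aln.sequences).encode(), dtype="S1").reshape(
            len(aln.sequences), cfg.flank_len).copy()
        is_x = np.array([tip_class[n] == "X" for n in aln.names])
        for p in trans_positions:
            b1, b2 = rng.choice(4, size=2, replace=False)
            seq_arr[is_x, p] = _BASES[b1]
            seq_arr[~is_x, p] = _BASES[b2]
        aln = HaplotypeAlignment(names=aln.names,
                                 sequences=[s.tobytes().decode() for s in seq_arr])

    gm = genotype_matrix_from_alignment(aln, rng, chrom="BLOCK",
                                        ns_positions=set(trans_positions),
                                        gene_id="opsin_like")
    info = {"freq_A": freq["A"], "freq_B": freq["B"], "tip_class": tip_class,
            "trans_positions": [p + 1 for p in trans_positions],
            "focal_pos": focal_pos + 1 if balanced else None}
    return aln, gm, info


def genotype_matrix_from_alignment(aln: HaplotypeAlignment, rng=None,
                                   chrom="chr1", ns_positions=frozenset(),
                                   gene_id="") -> GenotypeMatrix:
    """Collapse a phased haplotype alignment into diploid genotypes.

    Tip names must follow ``species|sample|h{0,1}``; consecutive h0/h1 pairs
    form one diploid. Only biallelic columns become sites; trans-specific
    positions (0-based) are annotated NS, the rest OTHER.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    arr = aln.to_array()
    parsed = [n.split("|") for n in aln.names]
    sample_ids = []
    species = []
    hap_rows = {}
    for i, (sp, sid, h) in enumerate(parsed):
        hap_rows.setdefault(sid, {})[h] = i
        if sid not in sample_ids:
            sample_ids.append(sid)
            species.append(sp)
    chroms, poss, refs, alts, anns, genes = [], [], [], [], [], []
    cols = []
    for p in range(arr.shape[1]):
        col = arr[:, p]
        bases = sorted(set(col.tolist()) - {b"N"})
        if len(bases) != 2:
            continue
        ref, alt = bases[0], bases[1]
        chroms.append(chrom)
        poss.append(p + 1)
        refs.append(ref.decode())
        alts.append(alt.decode())
        anns.append("NS" if p in ns_positions else "OTHER")
        genes.append(gene_id)
        cols.append((col == alt).astype(np.int8))
    n_sites = len(poss)
    genotypes = np.zeros((len(sample_ids), n_sites), dtype=np.int8)
    if n_sites:
        hap = np.stack(cols, axis=1)  # (n_hap, n_sites)
        for si, sid in enumerate(sample_ids):
            rows = hap_rows[sid]
            genotypes[si] = hap[rows["h0"]] + hap[rows["h1"]]
    samples = make_sample_table(sample_ids, species=species,
                                mean_coverage=rng.uniform(10, 50, len(sample_ids)))
    sites = make_site_table(chroms, poss, refs, alts, annotation=anns,
                            gene_id=genes)
    return GenotypeMatrix(samples, sites, genotypes)


# ---------------------------------------------------------------------------
# read-depth genotype calling and F1 crosses


def call_genotypes_from_reads(true_gt: np.ndarray, depths: np.ndarray,
                              dm: DepthModel, rng: np.random.Generator):
    """Apply the read-sampling error model to true genotypes.

    Returns (called genotypes with MISSING where depth is 0 or the call is
    ambiguous, allele_depths array (..., 2))."""
    true_gt = np.asarray(true_gt)
    p_alt = np.choose(true_gt, [dm.error_rate, 0.5, 1.0 - dm.error_rate])
    alt = rng.binomial(depths, p_alt)
    ref = depths - alt
    called = np.full(true_gt.shape, MISSING, dtype=np.int8)
    het = (alt >= dm.het_call_rule) & (ref >= dm.het_call_rule)
    called[het] = 1
    hom_alt = ~het & (alt > ref)
    hom_ref = ~het & (ref > alt)
    called[hom_alt] = 2
    called[hom_ref] = 0
    # ties below the het rule, and zero depth, stay missing
    ad = np.stack([ref, alt], axis=-1).astype(np.int32)
    return called, ad


def sim_f1_cross(parent1, parent2, dm: DepthModel, n_offspring=50, seed=0):
    """Mendelian F1 offspring of two diploid parents, genotype-called
    through the read-depth error model.

    Returns (GenotypeMatrix of called offspring genotypes with allele
    depths, true genotype array (n_offspring, n_sites))."""
    rng = np.random.default_rng(seed)
    p1 = np.asarray(parent1, dtype=np.int8)
    p2 = np.asarray(parent2, dtype=np.int8)
    if p1.shape != p2.shape:
        raise ValueError("parents must cover the same sites")
    L = p1.size

    def gametes(parent):
        probs = parent / 2.0
        return rng.random((n_offspring, L)) < probs

    true = (gametes(p1).astype(np.int8) + gametes(p2).astype(np.int8))
    depths = dm.draw_depths(rng, (n_offspring, L))
    called, ad = call_genotypes_from_reads(true, depths, dm, rng)
    samples = make_sample_table([f"F1_{i:03d}" for i in range(n_offspring)],
                                species=["F1"] * n_offspring)
    sites = make_site_table(["cross"] * L, np.arange(1, L + 1),
                            ["A"] * L, ["T"] * L)
    gm = GenotypeMatrix(samples, sites, called, allele_depths=ad)
    return gm, true


# ---------------------------------------------------------------------------
# activity experiment


def sim_activity(cfg: ActivitySimConfig) -> pd.DataFrame:
    """Simulate per-individual active-interval counts.

    Each individual's count is Binomial(n_intervals, inv-logit(eta)) with
    eta = baseline + light + genotype + light:genotype + clone + block.
    Clones are nested in genotype; blocks are assigned cyclically.
    """
    rng = np.random.default_rng(cfg.seed)
    genotypes = list(cfg.genotype_effects)
    lights = list(cfg.light_effects)
    n_clone_ind = cfg.n_per_cell // cfg.n_clones_per_genotype
    clone_eff = {}
    rows = []
    block_effects = rng.normal(0.0, cfg.block_sd, size=cfg.n_blocks)
    ind = 0
    for g in genotypes:
        for ci in range(cfg.n_clones_per_genotype):
            clone = f"{g}_c{ci}"
            clone_eff[clone] = rng.normal(0.0, cfg.clone_sd)
        for light in lights:
            for ci in range(cfg.n_clones_per_genotype):
                clone = f"{g}_c{ci}"
                for _ in range(n_clone_ind):
                    block = ind % cfg.n_blocks
                    eta = (cfg.baseline + cfg.genotype_effects[g]
                           + cfg.light_effects[light]
                           + cfg.interaction_effects.get((g, light), 0.0)
                           + clone_eff[clone] + block_effects[block])
                    n_active = rng.binomial(cfg.n_intervals, expit(eta))
                    rows.append((f"ind_{ind:04d}", clone, g, light,
                                 f"block{block}", cfg.n_intervals, int(n_active)))
                    ind += 1
    return pd.DataFrame(rows, columns=["individual", "clone_id", "genotype",
                                       "light", "block", "n_intervals",
                                       "n_active"])
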