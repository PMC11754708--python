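"""Balancing-selection statistics: alpha_b, a folded beta(1)-style
frequency-correlation score, and linkage disequilibrium r^2.

alpha_b contrasts the non-synonymous/synonymous ratio among shared
(between-species) polymorphisms with the same ratio among within-species
(non-shared) polymorphisms, in the spirit of a McDonald-Kreitman
construction:

    alpha_b = 1 - (Poly_NS * SP_Syn) / (Poly_Syn * SP_NS)

A positive alpha_b means shared polymorphisms are enriched for
non-synonymous variants relative to the within-species background —
the expected footprint of balancing selection maintaining functional
variation across species. Significance comes from a block bootstrap over
genomic blocks (linked SNPs resample together).

beta(1) scores a core SNP by how tightly the folded frequencies of its
neighbours match its own: under long-term balancing selection linked
neutral variants accumulate at the balanced frequency. It is a
similarity-weighted theta estimate minus Watterson's theta, normalized so
its expectation is ~0 under neutral equilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PolymorphismCounts:
    poly_syn: float
    poly_ns: float
    sp_syn: float
    sp_ns: float

    def __post_init__(self):
        if min(self.poly_syn, self.poly_ns, self.sp_syn, self.sp_ns) < 0:
            raise ValueError("counts must be >= 0")


def count_polymorphisms(classification: pd.DataFrame, sites: pd.DataFrame,
                        species: str) -> PolymorphismCounts:
    """Tally synonymous/non-synonymous counts of shared vs within-species
    (private to ``species``) polymorphisms.

    ``classification`` is the output of classify_sites (species 'a' =
    PRIVATE_A etc.); ``sites`` supplies the annotation column, aligned by
    (chrom, pos).
    """
    if species not in ("a", "b"):
        raise ValueError("species must be 'a' or 'b' (classification axes)")
    merged = classification.merge(sites[["chrom", "pos", "annotation"]],
                                  on=["chrom", "pos"])
    ann = merged["annotation"]
    lab = merged["label"]
    private = f"PRIVATE_{species.upper()}"
    return PolymorphismCounts(
        poly_syn=int(((lab == private) & (ann == "SYN")).sum()),
        poly_ns=int(((lab == private) & (ann == "NS")).sum()),
        sp_syn=int(((lab == "SHARED_POLY") & (ann == "SYN")).sum()),
        sp_ns=int(((lab == "SHARED_POLY") & (ann == "NS")).sum()),
    )


def alpha_b(counts: PolymorphismCounts) -> float:
    """Point estimate of the fraction of shared non-synonymous
    polymorphisms attributable to balancing selection."""
    for name in ("poly_syn", "sp_ns"):
        if getattr(counts, name) == 0:
            raise ValueError(f"cannot compute alpha_b: {name} is zero")
    return 1.0 - (counts.poly_ns * counts.sp_syn) / (counts.poly_syn * counts.sp_ns)


@dataclass
class AlphaBResult:
    alpha_b: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    n_redrawn: int = 0


def alpha_b_bootstrap(snp_table: pd.DataFrame, n_boot: int = 1000,
                      seed: int = 0) -> AlphaBResult:
    """Block-bootstrap CI and one-sided p-value for alpha_b.

    ``snp_table`` needs columns ``label`` ('shared' or 'private'),
    ``annotation`` ('SYN'/'NS'), and ``block_id``. Blocks are resampled
    with replacement; replicates with a zero denominator are redrawn (count
    reported). p is the fraction of replicates <= 0, floored at 1/n_boot.
    """
    tab = snp_table[snp_table["annotation"].isin(("SYN", "NS"))]
    cats = (tab["label"].astype(str) + "_" + tab["annotation"].astype(str))
    per_block = pd.crosstab(tab["block_id"], cats)
    for col in ("private_SYN", "private_NS", "shared_SYN", "shared_NS"):
        if col not in per_block:
            per_block[col] = 0
    counts_mat = per_block[["private_SYN", "private_NS",
                            "shared_SYN", "shared_NS"]].to_numpy(float)
    n_blocks = counts_mat.shape[0]
    if n_blocks < 2:
        raise ValueError("block bootstrap needs >= 2 blocks")
    totals = counts_mat.sum(axis=0)
    point = alpha_b(PolymorphismCounts(*totals))

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n_redrawn = 0
    filled = 0
    while filled < n_boot:
        draw = rng.integers(0, n_blocks, size=(n_boot - filled, n_blocks))
        tot = counts_mat[draw].sum(axis=1)  # (reps, 4)
        ok = (tot[:, 0] > 0) & (tot[:, 3] > 0)
        n_redrawn += int((~ok).sum())
        good = tot[ok]
        vals = 1.0 - (good[:, 1] * good[:, 2]) / (good[:, 0] * good[:, 3])
        reps[filled:filled + len(vals)] = vals
        filled += len(vals)
    if n_redrawn:
        logger.info("alpha_b_bootstrap: redrew %d degenerate replicates",
                    n_redrawn)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    p = max(float((reps <= 0).mean()), 1.0 / n_boot)
    return AlphaBResult(alpha_b=point, ci_low=float(lo), ci_high=float(hi),
                        p_value=p, n_boot=n_boot, n_redrawn=n_redrawn)


# ---------------------------------------------------------------------------
# beta(1)


@dataclass
class BetaResult:
    beta1: float
    n_window_snps: int
    core_folded_freq: float


def _beta_normalizer(n: int, core_phi: float, p_exp: float) -> float:
    """Sum over frequency classes of similarity weight x expected folded
    class occupancy at theta = 1; dividing by this makes the weighted sum
    an unbiased theta estimator under neutral equilibrium."""
    k = np.arange(1, n)
    phi = np.minimum(k, n - k) / n
    w = (1.0 - np.abs(phi - core_phi) / 0.5) ** p_exp
    return float(np.sum(w / k))


def beta1(freqs: pd.DataFrame, core_pos: int, n: int, window: int = 1000,
          p_exp: float = 2.0) -> BetaResult | None:
    """Folded beta(1) score for one core SNP.

    ``freqs`` needs columns ``pos`` and ``folded_freq`` (minor-allele
    frequency in (0, 0.5]); ``n`` is the haploid sample size. Window SNPs
    are those within ``window``/2 bp either side of the core, excluding the
    core itself. Returns None (flagged undefined) for an empty window.

    beta1 = theta_beta - theta_W with
    theta_beta = sum_i w_i / C, w_i = (1 - |phi_i - phi_core|/0.5)^p_exp,
    C the neutral-expectation normalizer, and theta_W = S / a_n.
    """
    core = freqs.loc[freqs["pos"] == core_pos, "folded_freq"]
    if core.empty:
        raise ValueError(f"core position {core_pos} not in table")
    phi_core = float(core.iloc[0])
    if not 0 < phi_core <= 0.5:
        raise ValueError("core folded frequency must be in (0, 0.5]")
    half = window / 2.0
    sel = ((freqs["pos"] - core_pos).abs() <= half) & (freqs["pos"] != core_pos)
    win = freqs.loc[sel, "folded_freq"].to_numpy()
    if win.size == 0:
        return None
    w = (1.0 - np.abs(win - phi_core) / 0.5) ** p_exp
    c = _beta_normalizer(n, phi_core, p_exp)
    theta_beta = w.sum() / c
    a_n = np.sum(1.0 / np.arange(1, n))
    theta_w = win.size / a_n
    return BetaResult(beta1=float(theta_beta - theta_w),
                      n_window_snps=int(win.size),
                      core_folded_freq=phi_core)


def beta1_scan(freqs: pd.DataFrame, n: int, window: int = 1000,
               p_exp: float = 2.0) -> pd.DataFrame:
    """beta(1) for every SNP in the table as core (NaN where undefined)."""
    rows = []
    for pos in freqs["pos"]:
        phi = float(freqs.loc[freqs["pos"] == pos, "folded_freq"].iloc[0])
        if not 0 < phi <= 0.5:
            rows.append((pos, np.nan, 0, phi))
            continue
        res = beta1(freqs, pos, n, window=window, p_exp=p_exp)
        if res is None:
            rows.append((pos, np.nan, 0, phi))
        else:
            rows.append((pos, res.beta1, res.n_window_snps, phi))
    return pd.DataFrame(rows, columns=["pos", "beta1", "n_window_snps",
                                       "core_folded_freq"])


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(gm: GenotypeMatrix, pairs=None, max_dist: int | None = None
          ) -> pd.DataFrame:
    """Squared Pearson correlation of genotype dosages for site pairs.

    ``pairs`` is an iterable of (site_index_1, site_index_2); if omitted,
    all adjacent same-chromosome pairs are used, or all same-chromosome
    pairs within ``max_dist`` bp when given. Pairs with < 2 jointly
    non-missing samples or a monomorphic member are returned with r2 NaN.
    """
    if pairs is None:
        pairs = []
        chrom = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        if max_dist is None:
            for j in range(gm.n_sites - 1):
                if chrom[j] == chrom[j + 1]:
                    pairs.append((j, j + 1))
        else:
            for j in range(gm.n_sites):
                k = j + 1
                while (k < gm.n_sites and chrom[k] == chrom[j]
                       and pos[k] - pos[j] <= max_dist):
                    pairs.append((j, k))
                    k += 1
    rows = []
    g = gm.genotypes
    for j, k in pairs:
        x, y = g[:, j].astype(float), g[:, k].astype(float)
        ok = (x != MISSING) & (y != MISSING)
        r2 = np.nan
        if ok.sum() >= 2:
            xv, yv = x[ok], y[ok]
            if xv.std() > 0 and yv.std() > 0:
                r2 = float(np.corrcoef(xv, yv)[0, 1] ** 2)
        rows.append((j, k, int(ok.sum()), r2))
    return pd.DataFrame(rows, columns=["site_1", "site_2", "n_samples", "r2"])
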