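"""Patterson's D (ABBA-BABA) and the f4-ratio with block-jackknife
significance.

Both statistics work on per-site derived-allele frequencies of a four-taxon
arrangement (P1, P2, P3, Outgroup), polarized so the outgroup carries the
ancestral allele. With site frequencies p1, p2, p3, pO,

    ABBA = (1 - p1) p2 p3 (1 - pO),  BABA = p1 (1 - p2) p3 (1 - pO)
    D = sum(ABBA - BABA) / sum(ABBA + BABA)

D ~ 0 under a strict species tree ((P1,P2),P3); an excess of ABBA patterns
(D > 0) indicates gene flow between P2 and P3. The f4-ratio estimates the
admixed ancestry proportion by splitting P3 into halves P3a/P3b:

    alpha = f4(P1, P2; P3a, O) / f4(P1, P3b; P3a, O)

with f4(A, B; C, D) = mean over sites of (pA - pB)(pC - pD).
Standard errors come from a delete-one block jackknife over contiguous
SNP blocks, which is robust to linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_core import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QuartetFreqs:
    """Per-site derived-allele frequencies for (P1, P2, P3, O)."""

    freqs: pd.DataFrame  # columns p1, p2, p3, pO, block_id
    n_dropped: int = 0


def quartet_freqs(gm: GenotypeMatrix, taxa: dict,
                  polarize_by_outgroup: bool = True,
                  block_size: int = 1000) -> QuartetFreqs:
    """Compute per-site frequencies for a four-taxon test.

    ``taxa`` maps roles 'P1','P2','P3','O' to species labels in ``gm``.
    Sites where the outgroup is polymorphic or entirely missing are
    dropped (count logged). With polarization, sites where the outgroup is
    fixed for the alt allele have frequencies flipped so pO = 0 everywhere.
    Blocks are ``block_size`` consecutive retained SNPs.
    """
    freqs = {}
    for role in ("P1", "P2", "P3", "O"):
        if role not in taxa:
            raise ValueError(f"taxa must define {role}")
        idx = gm.species_index(taxa[role])
        freqs[role] = gm.alt_freqs(sample_idx=idx)
    po = freqs["O"]
    keep = ~np.isnan(po) & ((po == 0.0) | (po == 1.0))
    for role in ("P1", "P2", "P3"):
        keep &= ~np.isnan(freqs[role])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("quartet_freqs: dropped %d sites (outgroup polymorphic/"
                    "missing or frequencies undefined)", n_dropped)
    out = pd.DataFrame({k.lower() if k != "O" else "po": v[keep]
                        for k, v in freqs.items()})
    if polarize_by_outgroup:
        flip = out["po"] == 1.0
        for col in ("p1", "p2", "p3", "po"):
            out.loc[flip, col] = 1.0 - out.loc[flip, col]
    out["block_id"] = np.arange(len(out)) // block_size
    return QuartetFreqs(freqs=out.reset_index(drop=True), n_dropped=n_dropped)


def _abba_baba(f: pd.DataFrame):
    p1, p2, p3, po = (f[c].to_numpy() for c in ("p1", "p2", "p3", "po"))
    abba = (1 - p1) * p2 * p3 * (1 - po)
    baba = p1 * (1 - p2) * p3 * (1 - po)
    return abba, baba


def d_statistic(qf: QuartetFreqs) -> float:
    abba, baba = _abba_baba(qf.freqs)
    denom = (abba + baba).sum()
    if denom == 0:
        raise ValueError("no informative sites (ABBA + BABA sums to zero)")
    return float((abba - baba).sum() / denom)


@dataclass
class DStatResult:
    d: float
    z: float
    p_value: float
    n_blocks: int
    se: float


def jackknife_significance(qf: QuartetFreqs, statistic=d_statistic
                           ) -> DStatResult:
    """Delete-one block jackknife z-score and two-sided normal p-value for
    a statistic of QuartetFreqs. A zero jackknife SE (statistic constant
    across blocks) is reported as z = inf, p = 0."""
    blocks = qf.freqs["block_id"].unique()
    g = len(blocks)
    if g < 10:
        raise ValueError(f"need >= 10 blocks, got {g}")
    full = statistic(qf)
    loo = np.empty(g)
    for k, b in enumerate(blocks):
        sub = QuartetFreqs(freqs=qf.freqs[qf.freqs["block_id"] != b])
        loo[k] = statistic(sub)
    se = float(np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2)))
    if se == 0.0:
        return DStatResult(d=full, z=np.inf, p_value=0.0, n_blocks=g, se=0.0)
    z = full / se
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return DStatResult(d=full, z=float(z), p_value=float(p), n_blocks=g,
                       se=se)


def f4(f: pd.DataFrame, a: str, b: str, c: str, d: str) -> float:
    return float(((f[a] - f[b]) * (f[c] - f[d])).mean())


def f4_ratio(gm: GenotypeMatrix, taxa: dict, n_splits: int = 10, seed: int = 0,
             block_size: int = 1000):
    """Admixture-proportion estimate for P2 receiving ancestry from P3.

    P3 is split at random into halves P3a/P3b (repeated ``n_splits`` times,
    seeded, and averaged to damp split noise); the ratio is the classic
    P3-splitting estimator

        alpha = f4(P1, P2; P3a, O) / f4(P1, P3b; P3a, O)

    i.e., the allele-sharing excess of P2 with P3a, normalized by the same
    excess when P2 is replaced by more P3 (the full-admixture yardstick).

    Returns (mean ratio, per-split ratios).
    """
    rng = np.random.default_rng(seed)
    i3 = gm.species_index(taxa["P3"])
    if i3.size < 2:
        raise ValueError("P3 needs >= 2 samples to split")
    ratios = []
    for _ in range(n_splits):
        perm = rng.permutation(i3)
        half = i3.size // 2
        p3a_idx, p3b_idx = perm[:half], perm[half:]
        cols = {}
        for name, idx in (("p1", gm.species_index(taxa["P1"])),
                          ("p2", gm.species_index(taxa["P2"])),
                          ("po", gm.species_index(taxa["O"])),
                          ("p3a", p3a_idx), ("p3b", p3b_idx)):
            cols[name] = gm.alt_freqs(sample_idx=idx)
        f = pd.DataFrame(cols)
        f = f.dropna()
        f = f[(f["po"] == 0.0) | (f["po"] == 1.0)]
        flip = f["po"] == 1.0
        for col in f.columns:
            f.loc[flip, col] = 1.0 - f.loc[flip, col]
        denom = f4(f, "p1", "p3b", "p3a", "po")
        if denom == 0:
            raise ValueError("f4 denominator is zero")
        ratios.append(f4(f, "p1", "p2", "p3a", "po") / denom)
    ratios = np.asarray(ratios)
    return float(ratios.mean()), ratios


def f4_ratio_jackknife(gm: GenotypeMatrix, taxa: dict, seed: int = 0,
                       block_size: int = 1000, n_splits: int = 10):
    """Block-jackknife mean and SE of the f4-ratio (blocks over sites,
    one shared P3 split schedule across blocks)."""
    n_sites = gm.n_sites
    blocks = np.arange(n_sites) // block_size
    uniq = np.unique(blocks)
    if uniq.size < 10:
        raise ValueError(f"need >= 10 blocks, got {uniq.size}")
    full, _ = f4_ratio(gm, taxa, n_splits=n_splits, seed=seed)
    loo = np.empty(uniq.size)
    for k, b in enumerate(uniq):
        sub = gm.subset(site_idx=np.flatnonzero(blocks != b))
        loo[k], _ = f4_ratio(sub, taxa, n_splits=n_splits, seed=seed)
    g = uniq.size
    se = float(np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2)))
    return full, se
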