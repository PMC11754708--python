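"""Segregation and heterozygosity analyses under read-depth aware
genotype calling.

Low sequencing depth systematically *undercalls* heterozygotes: a true AB
individual sequenced to depth d shows only one allele with probability
2 x (1/2)^d and is miscalled homozygous. Testing Mendelian segregation or
Hardy-Weinberg heterozygote excess against naive expectations therefore
confounds biology with calling error. The functions here propagate an
explicit read-depth model (depth distribution + per-read error +
het-call rule) through the expectations:

* ``cross_expectation`` — true Mendelian genotype probabilities of a cross;
* ``depth_aware_expectation`` — called-genotype probabilities after pushing
  the true probabilities through the depth model (analytic mixture over
  depth, with a Monte-Carlo cross-check);
* ``het_excess_test`` — chi-square + exact binomial test of observed
  genotype counts against any expectation;
* ``fis`` / ``fis_null_distribution`` — per-gene inbreeding coefficient
  F_IS = 1 - H_obs/H_exp and its null distribution under HWE simulated
  through the same depth model (negative F_IS = heterozygote excess).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, binomtest, chisquare

from .io_core import MISSING
from .simulate import DepthModel, call_genotypes_from_reads


@dataclass
class CrossExpectation:
    """True-genotype probabilities (P_AA, P_AB, P_BB) of a diploid cross,
    counting the alt allele (AA = 0 alt copies)."""

    p_aa: float
    p_ab: float
    p_bb: float

    def __post_init__(self):
        total = self.p_aa + self.p_ab + self.p_bb
        if not np.isclose(total, 1.0):
            raise ValueError("probabilities must sum to 1")

    def as_array(self):
        return np.array([self.p_aa, self.p_ab, self.p_bb])


def cross_expectation(parent1: int, parent2: int) -> CrossExpectation:
    """Mendelian convolution of two parental genotype codes (0/1/2).
    AB x AB gives the classic 1:2:1."""
    probs = []
    for parent in (parent1, parent2):
        if parent not in (0, 1, 2):
            raise ValueError("parent genotypes must be diploid codes 0/1/2")
        probs.append(np.array([1 - parent / 2.0, parent / 2.0]))
    out = np.zeros(3)
    for a in (0, 1):
        for b in (0, 1):
            out[a + b] += probs[0][a] * probs[1][b]
    return CrossExpectation(*out)


def _call_matrix_at_depth(d: int, dm: DepthModel) -> np.ndarray:
    """P(called genotype | true genotype) at fixed depth d.

    Rows: true AA/AB/BB; columns: called AA, AB, BB, missing. Reads carry
    the wrong allele with probability ``error_rate``; het called iff both
    alleles seen >= het_call_rule reads, otherwise the majority homozygote
    (ties below the rule, and depth 0, are missing)."""
    out = np.zeros((3, 4))
    if d == 0:
        out[:, 3] = 1.0
        return out
    k = np.arange(d + 1)  # alt reads
    for g, p_alt in enumerate((dm.error_rate, 0.5, 1.0 - dm.error_rate)):
        pk = binom.pmf(k, d, p_alt)
        alt, ref = k, d - k
        het = (alt >= dm.het_call_rule) & (ref >= dm.het_call_rule)
        hom_bb = ~het & (alt > ref)
        hom_aa = ~het & (ref > alt)
        missing = ~het & (alt == ref)
        out[g, 0] = pk[hom_aa].sum()
        out[g, 1] = pk[het].sum()
        out[g, 2] = pk[hom_bb].sum()
        out[g, 3] = pk[missing].sum()
    return out


def depth_aware_expectation(ce: CrossExpectation, dm: DepthModel,
                            n_sim: int = 0, seed: int = 0):
    """Called-genotype probabilities for offspring of a cross observed
    through a read-depth model.

    Analytic: mixture over the depth distribution of the per-depth calling
    matrices. With ``n_sim > 0`` a Monte-Carlo estimate over ``n_sim``
    simulated offspring is returned alongside for cross-checking.

    Returns dict with 'called' (P_AA, P_AB, P_BB conditional on a call),
    'raw' (including the missing class), and optionally 'mc' (Monte-Carlo
    conditional probabilities).
    """
    depths, probs = dm.depth_support()
    mix = np.zeros((3, 4))
    for d, p in zip(depths, probs):
        mix += p * _call_matrix_at_depth(int(d), dm)
    true_p = ce.as_array()
    raw = true_p @ mix  # P(called AA, AB, BB, missing)
    called = raw[:3] / raw[:3].sum() if raw[:3].sum() > 0 else np.full(3, np.nan)
    out = {"called": called, "raw": raw}
    if n_sim > 0:
        rng = np.random.default_rng(seed)
        true = rng.choice(3, size=n_sim, p=true_p)
        d = dm.draw_depths(rng, n_sim)
        calls, _ = call_genotypes_from_reads(true, d, dm, rng)
        ok = calls != MISSING
        counts = np.bincount(calls[ok], minlength=3)
        out["mc"] = counts / counts.sum()
        out["mc_n_called"] = int(ok.sum())
    return out


@dataclass
class HetExcessResult:
    chi2: float
    df: int
    p_chi2: float
    het_fraction: float
    p_binomial: float


def het_excess_test(observed_counts, expected_probs) -> HetExcessResult:
    """Observed genotype counts (n_AA, n_AB, n_BB) against expected
    probabilities: Pearson chi-square over the three classes plus an exact
    two-sided binomial test of the heterozygote count."""
    obs = np.asarray(observed_counts, dtype=float)
    exp_p = np.asarray(expected_probs, dtype=float)
    if obs.shape != (3,) or exp_p.shape != (3,):
        raise ValueError("need 3 genotype classes")
    if obs.sum() <= 0:
        raise ValueError("no observations")
    if ((exp_p == 0) & (obs > 0)).any():
        raise ValueError("observed counts in a zero-probability class")
    n = obs.sum()
    keep = exp_p > 0
    chi2, p_chi2 = chisquare(obs[keep], f_exp=n * exp_p[keep] / exp_p[keep].sum())
    bt = binomtest(int(obs[1]), int(n), exp_p[1])
    return HetExcessResult(chi2=float(chi2), df=int(keep.sum() - 1),
                           p_chi2=float(p_chi2),
                           het_fraction=float(obs[1] / n),
                           p_binomial=float(bt.pvalue))


# ---------------------------------------------------------------------------
# F_IS


def fis_per_snp(counts: np.ndarray) -> np.ndarray:
    """F_IS = 1 - H_obs/H_exp per SNP from genotype count rows
    (n_AA, n_AB, n_BB); H_exp = 2 p (1 - p) from the sample allele
    frequency. NaN where H_exp = 0 (monomorphic)."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n = counts.sum(axis=1)
    p = (2 * counts[:, 2] + counts[:, 1]) / (2 * n)
    h_obs = counts[:, 1] / n
    h_exp = 2 * p * (1 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - h_obs / h_exp
    f[h_exp == 0] = np.nan
    return f


@dataclass
class FisResult:
    per_gene: pd.DataFrame  # gene_id, mean_fis, n_snps
    per_snp: pd.DataFrame


def fis(genotype_counts: pd.DataFrame) -> FisResult:
    """Per-gene mean F_IS.

    ``genotype_counts`` needs columns gene_id, n_aa, n_ab, n_bb (one row
    per SNP). Monomorphic SNPs are excluded; genes with no informative SNP
    are dropped (logged via the returned table's absence).
    """
    counts = genotype_counts[["n_aa", "n_ab", "n_bb"]].to_numpy(float)
    f = fis_per_snp(counts)
    per_snp = genotype_counts.copy()
    per_snp["fis"] = f
    ok = per_snp.dropna(subset=["fis"])
    per_gene = (ok.groupby("gene_id")["fis"]
                .agg(mean_fis="mean", n_snps="size").reset_index())
    return FisResult(per_gene=per_gene, per_snp=per_snp)


def gene_quantile(per_gene: pd.DataFrame, gene_id: str) -> float:
    """Quantile of a focal gene's mean F_IS within the genome-wide
    distribution (fraction of genes with mean F_IS <= the focal one)."""
    vals = per_gene["mean_fis"].to_numpy()
    focal = per_gene.loc[per_gene["gene_id"] == gene_id, "mean_fis"]
    if focal.empty:
        raise ValueError(f"gene {gene_id!r} not in table")
    return float((vals <= focal.iloc[0]).mean())


def fis_null_distribution(snp_freqs: pd.DataFrame, dm: DepthModel,
                          n_samples: int, n_sim: int = 200, seed: int = 0
                          ) -> pd.DataFrame:
    """Null distribution of per-gene mean F_IS under HWE observed through
    the read-depth model.

    ``snp_freqs`` needs columns gene_id and freq (alt-allele frequency per
    SNP). For each replicate, genotypes of ``n_samples`` individuals are
    drawn from HWE at each SNP, pushed through the depth model, and the
    per-gene mean F_IS recomputed from the *called* genotypes.

    Returns per-gene quantiles (2.5%, 50%, 97.5%) and mean of the null.
    """
    rng = np.random.default_rng(seed)
    genes = snp_freqs["gene_id"].to_numpy()
    freqs = snp_freqs["freq"].to_numpy(float)
    n_snps = freqs.size
    gene_ids = pd.unique(genes)
    sims = np.full((n_sim, len(gene_ids)), np.nan)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    hwe = np.stack([(1 - freqs) ** 2, 2 * freqs * (1 - freqs), freqs ** 2],
                   axis=1)
    for s in range(n_sim):
        u = rng.random((n_samples, n_snps))
        cum = hwe.cumsum(axis=1)
        true = (u[..., None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
        depths = dm.draw_depths(rng, (n_samples, n_snps))
        called, _ = call_genotypes_from_reads(true, depths, dm, rng)
        counts = np.stack([(called == g).sum(axis=0) for g in (0, 1, 2)],
                          axis=1)
        f = fis_per_snp(counts)
        df = pd.DataFrame({"gene": genes, "fis": f}).dropna()
        means = df.groupby("gene")["fis"].mean()
        for g, v in means.items():
            sims[s, gene_pos[g]] = v
    rows = []
    for g, i in gene_pos.items():
        col = sims[:, i]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        q = np.percentile(col, [2.5, 50, 97.5])
        rows.append((g, col.mean(), *q, col.size))
    return pd.DataFrame(rows, columns=["gene_id", "null_mean", "q025", "q50",
                                       "q975", "n_sim_ok"])
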