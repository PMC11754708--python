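"""Joint site-frequency spectra, model comparison, diversity and the
incomplete-lineage-sorting bound on shared polymorphism.

The joint (2D) SFS counts sites by their alt-allele count in species A
(rows, 0..2n_A) and species B (columns, 0..2n_B). Spectra can be projected
down to smaller sample sizes by the hypergeometric expectation (the
standard dadi/moments projection) and folded onto minor-allele counts.

Model spectra (e.g., from a diffusion or coalescent fit) are compared to
empirical ones through standardized residuals and a Poisson composite
log-likelihood / BIC.

The ILS bound asks how many of the polymorphisms segregating in the common
ancestor could still segregate in *both* descendant species today, absent
migration. With within-species synonymous diversities p_A, p_B and
between-species synonymous divergence d_between, the split age of lineage i
in units of its own 2N_i generations is

    tau_i = (d_between - theta_anc) / p_i,   theta_anc = max(p_A, p_B),

since divergence accrues at rate p_i per 2N_i generations on each lineage
and the ancestral contribution to d_between is theta_anc (ancestral
diversity taken as the larger of the two extant diversities). A neutral
polymorphism persists through tau coalescent units with probability
exp(-tau), independently in each species, so

    E[shared] <= max(S_A, S_B) * exp(-(tau_A + tau_B)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from scipy.special import gammaln
from scipy.stats import hypergeom

from .io_core import MISSING, GenotypeMatrix


@dataclass
class JointSFS:
    """2D allele-count spectrum. ``matrix[i, j]`` is the (possibly
    fractional, after projection) number of sites with alt count i in
    species A and j in species B."""

    matrix: np.ndarray
    folded: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("SFS matrix must be 2D")
        if (self.matrix < 0).any():
            raise ValueError("SFS entries must be >= 0")

    @property
    def n_a(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def n_b(self) -> int:
        return self.matrix.shape[1] - 1

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#joint-sfs\t{self.n_a}\t{self.n_b}\t"
                     f"{'folded' if self.folded else 'unfolded'}\n")
            np.savetxt(fh, self.matrix, delimiter="\t")

    @classmethod
    def from_tsv(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().split("\t")
            folded = header[3].strip() == "folded"
            matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
        return cls(matrix=matrix, folded=folded)


def joint_sfs(gm: GenotypeMatrix, species_a: str, species_b: str,
              site_idx=None, missing: str = "error") -> JointSFS:
    """Build the unfolded joint SFS from genotypes.

    ``missing='error'`` (default) refuses missing calls among the included
    samples; ``missing='drop'`` excludes affected sites (count logged on
    ``meta``-free return via warning).
    """
    ia = gm.species_index(species_a)
    ib = gm.species_index(species_b)
    g = gm.genotypes if site_idx is None else gm.genotypes[:, np.asarray(site_idx)]
    ga, gb = g[ia], g[ib]
    has_missing = (ga == MISSING).any(axis=0) | (gb == MISSING).any(axis=0)
    if has_missing.any():
        if missing == "error":
            raise ValueError(f"{int(has_missing.sum())} sites have missing "
                             "calls; use missing='drop' or project per site")
        ga, gb = ga[:, ~has_missing], gb[:, ~has_missing]
        warnings.warn(f"dropped {int(has_missing.sum())} sites with missing "
                      "calls", stacklevel=2)
    n_a, n_b = 2 * ia.size, 2 * ib.size
    ca = ga.sum(axis=0)
    cb = gb.sum(axis=0)
    matrix = np.zeros((n_a + 1, n_b + 1))
    np.add.at(matrix, (ca, cb), 1.0)
    return JointSFS(matrix=matrix)


def _projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """P[i, j] = E[fraction of draws with j alt | i alt among n_from]:
    hypergeometric pmf, rows i = 0..n_from, cols j = 0..n_to."""
    i = np.arange(n_from + 1)[:, None]
    j = np.arange(n_to + 1)[None, :]
    return hypergeom.pmf(j, n_from, i, n_to)


def project_sfs(sfs: JointSFS, m_a: int, m_b: int) -> JointSFS:
    """Project each axis down to haploid sizes (m_a, m_b) by the
    hypergeometric expectation; total mass is conserved."""
    if sfs.folded:
        raise ValueError("project before folding")
    if m_a < 2 or m_b < 2:
        raise ValueError("projected sizes must be >= 2")
    if m_a > sfs.n_a or m_b > sfs.n_b:
        raise ValueError("cannot project up")
    pa = _projection_matrix(sfs.n_a, m_a)
    pb = _projection_matrix(sfs.n_b, m_b)
    return JointSFS(matrix=pa.T @ sfs.matrix @ pb)


def fold_sfs(sfs: JointSFS) -> JointSFS:
    """Fold onto minor-allele joint counts: entry (i, j) merges with its
    complement (n_a - i, n_b - j); mass lands on the lexicographically
    smaller of the two index pairs."""
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    m = sfs.matrix
    na, nb = sfs.n_a, sfs.n_b
    out = np.zeros_like(m)
    for i in range(na + 1):
        for j in range(nb + 1):
            ci, cj = na - i, nb - j
            if (i, j) < (ci, cj):
                out[i, j] = m[i, j] + m[ci, cj]
            elif (i, j) == (ci, cj):
                out[i, j] = m[i, j]
    return JointSFS(matrix=out, folded=True)


def shared_from_sfs(sfs: JointSFS, min_count: int = 2):
    """Mass on cells polymorphic in both species with minor counts at or
    above ``min_count`` (for a 20x20 projection, min_count=2 is allele
    frequency strictly above 1/20 on both sides).

    Returns (count, proportion of total spectrum mass).
    """
    m = sfs.matrix
    na, nb = sfs.n_a, sfs.n_b
    i = np.arange(na + 1)[:, None]
    j = np.arange(nb + 1)[None, :]
    minor_a = np.minimum(i, na - i)
    minor_b = np.minimum(j, nb - j)
    mask = (minor_a >= min_count) & (minor_b >= min_count)
    count = float(m[mask].sum())
    total = sfs.total
    return count, count / total if total > 0 else 0.0


@dataclass
class SFSComparison:
    residuals: np.ndarray
    mean_standardized_residual: float
    n_excluded: int


def sfs_residuals(empirical: JointSFS, model: JointSFS,
                  mode: str = "pearson") -> SFSComparison:
    """Cell-wise standardized residuals of an empirical vs model spectrum.

    ``pearson`` (default) uses (O - E)/sqrt(E), appropriate for
    Poisson-distributed counts; ``relative`` uses (O - E)/E. Cells with
    E = 0 and O = 0 get residual 0; E = 0 with O > 0 cannot be
    standardized and are excluded from the mean (NaN in the matrix, with a
    warning). The absorbing corner cells (0,0) and (n_a, n_b), which carry
    no polymorphism information, are excluded from the mean.
    """
    o, e = empirical.matrix, model.matrix
    if o.shape != e.shape:
        raise ValueError("spectrum shapes differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(e) if mode == "pearson" else e
        res = (o - e) / denom
    res[(e == 0) & (o == 0)] = 0.0
    bad = (e == 0) & (o > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} cells observed where the model "
                      "predicts zero; excluded from mean", stacklevel=2)
        res[bad] = np.nan
    mask = np.ones_like(res, dtype=bool)
    mask[0, 0] = mask[-1, -1] = False
    vals = res[mask]
    return SFSComparison(residuals=res,
                         mean_standardized_residual=float(np.nanmean(vals)),
                         n_excluded=int(bad.sum()))


def sfs_loglik_bic(empirical: JointSFS, model: JointSFS, k_params: int,
                   n_obs: float | None = None):
    """Poisson composite log-likelihood of the empirical spectrum given the
    model spectrum, and BIC = -2 loglik + k ln(n_obs).

    The absorbing corners (0,0)/(n_a,n_b) are excluded; model cells equal
    to zero with observations get a 1e-12 pseudo-expectation (warned).
    """
    o, e = empirical.matrix.copy(), model.matrix.copy()
    if o.shape != e.shape:
        raise ValueError("spectrum shapes differ")
    mask = np.ones_like(o, dtype=bool)
    mask[0, 0] = mask[-1, -1] = False
    o, e = o[mask], e[mask]
    bad = (e == 0) & (o > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} observed cells with zero model "
                      "expectation; using pseudo-expectation 1e-12",
                      stacklevel=2)
        e[bad] = 1e-12
    keep = ~((e == 0) & (o == 0))
    o, e = o[keep], e[keep]
    loglik = float(np.sum(o * np.log(e) - e - gammaln(o + 1)))
    if n_obs is None:
        n_obs = empirical.total
    bic = -2.0 * loglik + k_params * np.log(n_obs)
    return loglik, bic


# ---------------------------------------------------------------------------
# diversity / divergence


def diversity_stats(gm: GenotypeMatrix, species_a: str, species_b: str,
                    site_idx=None, n_monitored_sites: float | None = None):
    """Nucleotide diversity within each species (pi) and divergence
    between them (D_xy), as mean pairwise differences over haploid allele
    counts.

    ``n_monitored_sites`` is the number of sites surveyed (including
    invariant ones); it is the denominator for per-site scaling. Without
    it the returned values are per-SNP averages over the polymorphic input
    (warned), which are not comparable across datasets.

    Returns dict with keys pi_a, pi_b, d_xy.
    """
    ia = gm.species_index(species_a)
    ib = gm.species_index(species_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("pi requires >= 2 samples per species")
    g = gm.genotypes if site_idx is None else gm.genotypes[:, np.asarray(site_idx)]

    def counts(idx):
        sub = g[idx]
        called = sub != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        return alt.astype(float), n.astype(float)

    aa, na = counts(ia)
    ab, nb = counts(ib)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_a_site = np.where(na > 1, aa * (na - aa) / (na * (na - 1) / 2.0), 0.0)
        pi_b_site = np.where(nb > 1, ab * (nb - ab) / (nb * (nb - 1) / 2.0), 0.0)
        dxy_site = np.where((na > 0) & (nb > 0),
                            (aa * (nb - ab) + (na - aa) * ab) / (na * nb), 0.0)
    denom = n_monitored_sites
    if denom is None:
        denom = g.shape[1]
        warnings.warn("no monitored-site count supplied; returning per-SNP "
                      "averages over the polymorphic input", stacklevel=2)
    return {"pi_a": float(pi_a_site.sum() / denom),
            "pi_b": float(pi_b_site.sum() / denom),
            "d_xy": float(dxy_site.sum() / denom)}


# ---------------------------------------------------------------------------
# ILS bound


@dataclass
class ILSInputs:
    """Synonymous summary statistics feeding the ILS bound: per-site
    divergence d_between (D_xy), per-site diversities p_A/p_B, and the
    synonymous polymorphism counts S_A/S_B per species."""

    d_between: float
    p_a: float
    p_b: float
    s_a: float
    s_b: float

    def __post_init__(self):
        for name in ("d_between", "p_a", "p_b", "s_a", "s_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ILSBound:
    tau_a: float
    tau_b: float
    retention_prob: float
    expected_shared_max: float


def ils_bound(inp: ILSInputs, exponent_scale: float = 1.0) -> ILSBound:
    """Upper bound on neutrally retained shared polymorphisms.

    tau_i = max(0, (d_between - theta_anc) / p_i) with
    theta_anc = max(p_A, p_B); retention = exp(-scale * (tau_A + tau_B));
    bound = max(S_A, S_B) * retention. ``exponent_scale`` exposes the
    persistence exponent for sensitivity analysis (1.0 = the lineage-pair
    coalescent rate used throughout).
    """
    theta_anc = max(inp.p_a, inp.p_b)
    excess = inp.d_between - theta_anc
    if excess > 0 and (inp.p_a == 0 or inp.p_b == 0):
        raise ValueError("zero within-species diversity with positive "
                         "divergence excess: split age undefined")
    tau_a = max(0.0, excess / inp.p_a) if inp.p_a > 0 else 0.0
    tau_b = max(0.0, excess / inp.p_b) if inp.p_b > 0 else 0.0
    retention = float(np.exp(-exponent_scale * (tau_a + tau_b)))
    return ILSBound(tau_a=tau_a, tau_b=tau_b, retention_prob=retention,
                    expected_shared_max=max(inp.s_a, inp.s_b) * retention)


def ils_inputs_from_data(gm: GenotypeMatrix, species_a: str, species_b: str,
                         site_idx=None, n_monitored_sites: float | None = None,
                         maf_min: float = 0.0) -> ILSInputs:
    """Convenience: compute the ILS-bound inputs (diversities, divergence,
    per-species polymorphism counts) from a genotype matrix."""
    stats = diversity_stats(gm, species_a, species_b, site_idx=site_idx,
                            n_monitored_sites=n_monitored_sites)
    ia = gm.species_index(species_a)
    ib = gm.species_index(species_b)
    g = gm.genotypes if site_idx is None else gm.genotypes[:, np.asarray(site_idx)]

    def n_poly(idx):
        sub = g[idx]
        called = sub != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, alt / n, 0.0)
        maf = np.minimum(f, 1 - f)
        return int((maf > maf_min).sum() if maf_min > 0
                   else ((alt > 0) & (alt < n)).sum())

    return ILSInputs(d_between=stats["d_xy"], p_a=stats["pi_a"],
                     p_b=stats["pi_b"], s_a=n_poly(ia), s_b=n_poly(ib))
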