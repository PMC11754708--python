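"""Cross-species site classification and sample-level diagnostics.

Sites segregating in a two-species panel fall into five classes computed
from within-species alt-allele frequencies over non-missing calls:

* ``SHARED_POLY`` — minor-allele frequency >= ``maf_min`` in both species;
* ``PRIVATE_A`` / ``PRIVATE_B`` — polymorphic (MAF >= ``maf_min``) in one
  species only;
* ``FIXED_DIFF`` — frequency exactly 0 in one species and 1 in the other;
* ``INVARIANT`` — same allele fixed in both;
* ``UNCLASSIFIED`` — call rate below ``min_call_rate`` in either species,
  or sub-threshold residual polymorphism.

Also provided: classification concordance between two assemblies/pipelines,
a bootstrap check of reference-allele dosage bias at heterozygous calls,
and the hybrid index (heterozygosity at fixed inter-species differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix

LABELS = ("PRIVATE_A", "PRIVATE_B", "SHARED_POLY", "FIXED_DIFF",
          "INVARIANT", "UNCLASSIFIED")


def classify_sites(gm: GenotypeMatrix, species_a: str, species_b: str,
                   maf_min: float = 0.01, min_call_rate: float = 0.5
                   ) -> pd.DataFrame:
    """Per-site classification table.

    Returns a DataFrame indexed like ``gm.sites`` with columns chrom, pos,
    freq_a, freq_b, call_rate_a, call_rate_b, label.
    """
    ia = gm.species_index(species_a)
    ib = gm.species_index(species_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("each species needs >= 2 samples")
    out = {"chrom": gm.sites["chrom"].to_numpy(),
           "pos": gm.sites["pos"].to_numpy()}
    freqs, rates = {}, {}
    for key, idx in (("a", ia), ("b", ib)):
        g = gm.genotypes[idx]
        called = g != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[key] = np.where(n > 0, alt / (2.0 * n), np.nan)
        rates[key] = n / idx.size
    fa, fb = freqs["a"], freqs["b"]
    maf_a = np.minimum(fa, 1 - fa)
    maf_b = np.minimum(fb, 1 - fb)
    poly_a = maf_a >= maf_min
    poly_b = maf_b >= maf_min
    ok_rate = (rates["a"] >= min_call_rate) & (rates["b"] >= min_call_rate)
    fixed = ((fa == 0) & (fb == 1)) | ((fa == 1) & (fb == 0))
    invariant = (fa == fb) & np.isin(fa, (0.0, 1.0))

    label = np.full(gm.n_sites, "UNCLASSIFIED", dtype=object)
    label[poly_a & poly_b] = "SHARED_POLY"
    label[poly_a & ~poly_b] = "PRIVATE_A"
    label[poly_b & ~poly_a] = "PRIVATE_B"
    label[~poly_a & ~poly_b & fixed] = "FIXED_DIFF"
    label[~poly_a & ~poly_b & invariant] = "INVARIANT"
    label[~ok_rate | np.isnan(fa) | np.isnan(fb)] = "UNCLASSIFIED"
    out.update(freq_a=fa, freq_b=fb, call_rate_a=rates["a"],
               call_rate_b=rates["b"], label=label)
    return pd.DataFrame(out)


@dataclass
class ConcordanceResult:
    n_common_sites: int
    fraction_unchanged: float
    confusion: pd.DataFrame


def classification_concordance(c1: pd.DataFrame, c2: pd.DataFrame
                               ) -> ConcordanceResult:
    """Compare two per-site classifications on their common (chrom, pos)
    keys; fraction_unchanged is the trace of the label confusion table over
    its total."""
    merged = c1.merge(c2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("no common sites between classifications")
    confusion = pd.crosstab(merged["label_1"], merged["label_2"])
    confusion = confusion.reindex(index=LABELS, columns=LABELS, fill_value=0)
    total = confusion.to_numpy().sum()
    trace = np.trace(confusion.to_numpy())
    return ConcordanceResult(n_common_sites=int(total),
                             fraction_unchanged=trace / total,
                             confusion=confusion)


@dataclass
class DosageBiasResult:
    mean_alt_fraction: float
    ci_low: float
    ci_high: float
    n_het_calls: int


def allele_dosage_bias(gm: GenotypeMatrix, sample_idx=None, n_snps: int = 1000,
                       n_boot: int = 100, seed: int = 0) -> DosageBiasResult:
    """Mean alt-read fraction at heterozygous calls with a bootstrap CI.

    Each bootstrap replicate draws ``n_snps`` heterozygous calls with
    replacement and averages their alt-read fraction; a mean far from 0.5
    indicates reference-allele mapping bias.
    """
    if gm.allele_depths is None:
        raise ValueError("allele depths (AD) required")
    g = gm.genotypes if sample_idx is None else gm.genotypes[sample_idx]
    ad = gm.allele_depths if sample_idx is None else gm.allele_depths[sample_idx]
    het = g == 1
    if not het.any():
        raise ValueError("no heterozygous calls")
    ref = ad[..., 0][het].astype(float)
    alt = ad[..., 1][het].astype(float)
    frac = alt / (ref + alt)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, frac.size, size=(n_boot, n_snps))
    boot_means = frac[draws].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return DosageBiasResult(mean_alt_fraction=float(frac.mean()),
                            ci_low=float(lo), ci_high=float(hi),
                            n_het_calls=int(frac.size))


def hybrid_index(classification: pd.DataFrame, gm_test: GenotypeMatrix
                 ) -> pd.DataFrame:
    """Per-sample fraction of fixed inter-species differences that are
    heterozygous (hybrid index: F1 hybrids ~1, pure parentals ~0).

    ``classification`` must come from :func:`classify_sites` on the
    reference species pair; fixed-difference sites are matched to
    ``gm_test`` by (chrom, pos). Samples with no non-missing call at any
    fixed site are flagged excluded (NaN index).
    """
    fixed = classification.loc[classification["label"] == "FIXED_DIFF",
                               ["chrom", "pos"]]
    if fixed.empty:
        raise ValueError("no fixed differences in classification")
    key = gm_test.sites.reset_index().merge(fixed, on=["chrom", "pos"])
    site_idx = key["index"].to_numpy()
    g = gm_test.genotypes[:, site_idx]
    called = g != MISSING
    n = called.sum(axis=1)
    n_het = ((g == 1) & called).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, n_het / n, np.nan)
    return pd.DataFrame({
        "sample_id": gm_test.samples["sample_id"],
        "n_fixed_sites": n,
        "fraction_heterozygous": frac,
        "excluded": n == 0,
    })
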