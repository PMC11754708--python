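"""Core data model and I/O for two-species diploid genotype data.

The central container is :class:`GenotypeMatrix`: a samples x sites table of
diploid genotype codes (alt-allele dosage 0/1/2, ``-1`` for missing) together
with sample metadata (species, population, mean sequencing coverage, clonal
lineage) and site metadata (position, alleles, functional annotation).
Optional per-call allele depths (ref reads, alt reads) support read-depth
aware analyses.

Readers/writers cover VCF 4.x (GT and AD fields; read via cyvcf2, written via
pysam), a self-contained tab-separated "table" format that round-trips all
metadata, FASTA haplotype alignments and Newick trees.

Clonal organisms are handled by collapsing samples into multi-locus
genotypes (MLGs): samples whose genotypes are identical up to a small
mismatch tolerance are treated as one genet, represented by the
highest-coverage sample.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MISSING = -1

ANNOTATIONS = ("SYN", "NS", "INTRON", "INTERGENIC", "UPDOWN", "UTR5", "UTR3", "OTHER")

SAMPLE_COLUMNS = ("sample_id", "species", "population", "mean_coverage", "clone_id")
SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "annotation", "gene_id")


def make_sample_table(sample_ids, species=None, population=None,
                      mean_coverage=None, clone_id=None) -> pd.DataFrame:
    """Build a validated sample-metadata table.

    Parameters default to a single species label ``"A"``, population
    ``"pop"``, coverage 0 and no clone assignment.
    """
    n = len(sample_ids)
    df = pd.DataFrame({
        "sample_id": list(sample_ids),
        "species": list(species) if species is not None else ["A"] * n,
        "population": list(population) if population is not None else ["pop"] * n,
        "mean_coverage": (np.asarray(mean_coverage, dtype=float)
                          if mean_coverage is not None else np.zeros(n)),
        "clone_id": list(clone_id) if clone_id is not None else [""] * n,
    })
    _validate_samples(df)
    return df


def make_site_table(chrom, pos, ref, alt, annotation=None, gene_id=None) -> pd.DataFrame:
    n = len(pos)
    df = pd.DataFrame({
        "chrom": list(chrom),
        "pos": np.asarray(pos, dtype=np.int64),
        "ref": list(ref),
        "alt": list(alt),
        "annotation": list(annotation) if annotation is not None else ["OTHER"] * n,
        "gene_id": list(gene_id) if gene_id is not None else [""] * n,
    })
    _validate_sites(df)
    return df


def _validate_samples(df: pd.DataFrame) -> None:
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    if (df["mean_coverage"].to_numpy() < 0).any():
        raise ValueError("mean_coverage must be non-negative")


def _validate_sites(df: pd.DataFrame) -> None:
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if df["pos"].to_numpy().min(initial=1) < 1:
        raise ValueError("positions are 1-based; pos >= 1 required")
    key = df[["chrom", "pos"]]
    if key.duplicated().any():
        raise ValueError("(chrom, pos) must be unique")
    # sorted within each chromosome, chromosomes in first-appearance order
    for _, sub in df.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise ValueError("sites must be sorted by position within chromosome")
    bad = df["annotation"].map(lambda a: a not in ANNOTATIONS)
    if bad.any():
        raise ValueError(f"unknown annotation: {df.loc[bad, 'annotation'].iloc[0]!r}")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for samples x sites plus metadata.

    genotypes[i, j] is the alt-allele dosage (0, 1, 2) of sample i at site j,
    or -1 for a missing call. ``allele_depths``, when present, has shape
    (n_samples, n_sites, 2) holding (ref reads, alt reads) per call.
    """

    samples: pd.DataFrame
    sites: pd.DataFrame
    genotypes: np.ndarray
    allele_depths: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        _validate_samples(self.samples)
        _validate_sites(self.sites)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites")
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if self.allele_depths is not None:
            ad = np.asarray(self.allele_depths, dtype=np.int32)
            if ad.shape != self.genotypes.shape + (2,):
                raise ValueError("allele_depths shape must be (n_samples, n_sites, 2)")
            if (ad < 0).any():
                raise ValueError("allele depths must be non-negative")
            called = self.genotypes != MISSING
            if (ad.sum(axis=2)[called] == 0).any():
                raise ValueError("called genotype with total read depth 0")
            self.allele_depths = ad

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def species_index(self, species: str) -> np.ndarray:
        """Row indices of samples belonging to ``species``."""
        idx = np.flatnonzero((self.samples["species"] == species).to_numpy())
        if idx.size == 0:
            raise ValueError(f"unknown or empty species label: {species!r}")
        return idx

    def subset(self, sample_idx=None, site_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        sj = np.arange(self.n_sites) if site_idx is None else np.asarray(site_idx)
        ad = None
        if self.allele_depths is not None:
            ad = self.allele_depths[np.ix_(si, sj)]
        return GenotypeMatrix(
            samples=self.samples.iloc[si].reset_index(drop=True),
            sites=self.sites.iloc[sj].reset_index(drop=True),
            genotypes=self.genotypes[np.ix_(si, sj)],
            allele_depths=ad,
            meta=dict(self.meta),
        )

    def alt_freqs(self, sample_idx=None) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing calls (NaN if none)."""
        g = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        called = g != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same = (self.samples[list(SAMPLE_COLUMNS)].equals(other.samples[list(SAMPLE_COLUMNS)])
                and self.sites[list(SITE_COLUMNS)].equals(other.sites[list(SITE_COLUMNS)])
                and np.array_equal(self.genotypes, other.genotypes))
        if not same:
            return False
        if (self.allele_depths is None) != (other.allele_depths is None):
            return False
        if self.allele_depths is not None:
            return np.array_equal(self.allele_depths, other.allele_depths)
        return True


@dataclass
class HaplotypeAlignment:
    """Equal-length haplotype sequences over {A, C, G, T, N}."""

    names: list
    sequences: list

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences length mismatch")
        if len(self.sequences) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("ragged alignment: sequences differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("sequence names must be unique")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def to_array(self) -> np.ndarray:
        """(n_seq, length) array of single-byte characters."""
        return np.frombuffer("".join(self.sequences).encode(), dtype="S1").reshape(
            len(self.sequences), self.length)


# ---------------------------------------------------------------------------
# VCF / table I/O


def read_genotypes(path, fmt: str = "vcf", sample_metadata: pd.DataFrame | None = None
                   ) -> GenotypeMatrix:
    """Read genotypes from a VCF (biallelic SNPs; multiallelic and non-SNP
    records are skipped and counted in ``meta['n_skipped']``) or from the
    package's self-contained table format.

    ``sample_metadata`` (sample_id-indexed or with a sample_id column) can
    supply species/population/coverage labels for VCF input, which does not
    carry them.
    """
    if fmt == "table":
        return _read_table(path)
    if fmt != "vcf":
        raise ValueError(f"unknown format: {fmt!r}")
    import cyvcf2

    vcf = cyvcf2.VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    gt_cols, ad_cols = [], []
    n_skipped = 0
    any_ad = False
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.ALT[0] not in "ACGT" or var.REF not in "ACGT":
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        # gts012: 0,1,2 = dosage, 3 = missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gt_cols.append(g)
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            ad = np.asarray(ad, dtype=np.int64)[:, :2]
            ad[ad < 0] = 0
            ad_cols.append(ad.astype(np.int32))
            any_ad = True
        else:
            ad_cols.append(None)
    vcf.close()
    if n_skipped:
        logger.info("read_genotypes: skipped %d multiallelic/non-SNP records", n_skipped)
    n_sites = len(poss)
    genotypes = (np.stack(gt_cols, axis=1) if n_sites
                 else np.zeros((len(sample_ids), 0), dtype=np.int8))
    allele_depths = None
    if any_ad:
        allele_depths = np.zeros((len(sample_ids), n_sites, 2), dtype=np.int32)
        for j, ad in enumerate(ad_cols):
            if ad is not None:
                allele_depths[:, j, :] = ad
    samples = make_sample_table(sample_ids)
    if sample_metadata is not None:
        md = sample_metadata.reset_index() if "sample_id" not in sample_metadata.columns \
            else sample_metadata
        samples = samples.drop(columns=[c for c in md.columns if c != "sample_id"
                                        and c in samples.columns])
        samples = samples.merge(md, on="sample_id", how="left")
        for col, default in (("species", "A"), ("population", "pop"),
                             ("mean_coverage", 0.0), ("clone_id", "")):
            if col not in samples.columns:
                samples[col] = default
            samples[col] = samples[col].fillna(default)
    sites = make_site_table(chroms, poss, refs, alts)
    return GenotypeMatrix(samples, sites, genotypes, allele_depths,
                          meta={"n_skipped": n_skipped})


def write_genotypes(gm: GenotypeMatrix, path, fmt: str = "vcf") -> None:
    """Write a GenotypeMatrix as VCF (GT + AD when depths are present) or as
    the self-contained table format (which also preserves metadata)."""
    if fmt == "table":
        _write_table(gm, path)
        return
    if fmt != "vcf":
        raise ValueError(f"unknown format: {fmt!r}")
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if gm.allele_depths is not None:
        header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                        'Description="Allelic depths">')
    for chrom in pd.unique(gm.sites["chrom"]):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in gm.samples["sample_id"]:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            rec = out.new_record(contig=row["chrom"], start=int(row["pos"]) - 1,
                                 alleles=(row["ref"], row["alt"]))
            for i, s in enumerate(gm.samples["sample_id"]):
                g = gm.genotypes[i, j]
                call = rec.samples[str(s)]
                if g == MISSING:
                    call["GT"] = (None, None)
                else:
                    call["GT"] = {(0): (0, 0), 1: (0, 1), 2: (1, 1)}[int(g)]
                if gm.allele_depths is not None:
                    call["AD"] = tuple(int(x) for x in gm.allele_depths[i, j])
            out.write(rec)


def _write_table(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##transpoly-table v1\n")
        fh.write("#SAMPLES\n")
        gm.samples[list(SAMPLE_COLUMNS)].to_csv(fh, sep="\t", index=False)
        fh.write("#SITES\n")
        gm.sites[list(SITE_COLUMNS)].to_csv(fh, sep="\t", index=False)
        fh.write("#GENOTYPES\n")
        np.savetxt(fh, gm.genotypes, fmt="%d", delimiter="\t")
        if gm.allele_depths is not None:
            fh.write("#ALLELE_DEPTHS\n")
            flat = gm.allele_depths.reshape(gm.n_samples, -1)
            np.savetxt(fh, flat, fmt="%d", delimiter="\t")


def _read_table(path) -> GenotypeMatrix:
    with open(path) as fh:
        text = fh.read()
    if not text.startswith("##transpoly-table"):
        raise ValueError(f"{path}: not a transpoly table file")
    sections = {}
    current = None
    for line in text.splitlines()[1:]:
        if line.startswith("#") and not line.startswith("##"):
            current = line[1:]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    def _df(name):
        return pd.read_csv(io.StringIO("\n".join(sections[name])), sep="\t",
                           dtype={"sample_id": str, "clone_id": str, "chrom": str,
                                  "gene_id": str, "population": str, "species": str},
                           keep_default_na=False)
    samples = _df("SAMPLES")
    sites = _df("SITES")
    n, s = len(samples), len(sites)
    if s > 0:
        genotypes = np.loadtxt(io.StringIO("\n".join(sections["GENOTYPES"])),
                               dtype=np.int8, delimiter="\t", ndmin=2)
    else:
        genotypes = np.zeros((n, 0), dtype=np.int8)
    ad = None
    if "ALLELE_DEPTHS" in sections and s > 0:
        ad = np.loadtxt(io.StringIO("\n".join(sections["ALLELE_DEPTHS"])),
                        dtype=np.int32, delimiter="\t", ndmin=2).reshape(n, s, 2)
    return GenotypeMatrix(samples, sites, genotypes, ad)


# ---------------------------------------------------------------------------
# FASTA / Newick I/O


def read_alignment(path) -> HaplotypeAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    return HaplotypeAlignment(names=[r.id for r in records],
                              sequences=[str(r.seq).upper() for r in records])


def write_alignment(aln: HaplotypeAlignment, path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="")
               for n, s in zip(aln.names, aln.sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# Multi-locus genotype (clone) assignment


def assign_mlg(gm: GenotypeMatrix, max_diff: float = 0.0):
    """Collapse clonal samples into multi-locus genotypes (MLGs).

    Samples are clustered by single linkage on the fraction of mismatching
    genotypes over jointly non-missing sites; clusters at distance
    <= ``max_diff`` share an MLG. Each MLG is represented by its
    highest-mean-coverage sample (ties broken by input sample order).

    Returns
    -------
    (assignments, representatives)
        ``assignments``: DataFrame with columns sample_id, mlg, is_representative.
        ``representatives``: list of representative sample_ids, one per MLG,
        in MLG-id order.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = gm.n_samples
    if n == 0:
        raise ValueError("need >= 1 sample")
    if n == 1:
        assignments = pd.DataFrame({"sample_id": gm.samples["sample_id"],
                                    "mlg": [0], "is_representative": [True]})
        return assignments, [gm.samples["sample_id"].iloc[0]]
    g = gm.genotypes
    called = g != MISSING
    # pairwise mismatch fraction over jointly called sites
    dist = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        mism = (g[i] != g[i + 1:]) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, mism.sum(axis=1) / denom, 1.0)
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    Z = linkage(squareform(dist, checks=False), method="single")
    labels = fcluster(Z, t=max_diff, criterion="distance")
    # renumber clusters by first appearance for permutation-stable output
    order = {}
    mlg = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        mlg[i] = order[lab]
    cov = gm.samples["mean_coverage"].to_numpy()
    representatives = []
    rep_idx = set()
    for m in range(len(order)):
        members = np.flatnonzero(mlg == m)
        best = members[np.argmax(cov[members])]  # argmax keeps first on ties
        representatives.append(gm.samples["sample_id"].iloc[best])
        rep_idx.add(best)
    assignments = pd.DataFrame({
        "sample_id": gm.samples["sample_id"],
        "mlg": mlg,
        "is_representative": [i in rep_idx for i in range(n)],
    })
    return assignments, representatives
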