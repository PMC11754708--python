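"""Gene trees around focal shared SNPs and the cophenetic-distance (CPD)
discordance test.

For a window of phased haplotypes centred on a high-frequency shared
non-synonymous SNP, a neighbor-joining tree is built from pairwise
sequence distances. The CPD statistic contrasts the median path-length
(cophenetic) distance among same-species tip pairs with the median among
cross-species pairs:

    delta = CPD_within - CPD_between

On a species-tree topology haplotypes cluster by species, so within-species
distances are the smaller ones and delta < 0. When haplotypes instead
cluster by allelic class that crosses the species boundary — the footprint
of a trans-specific balanced haplotype — enough within-species pairs span
the deep allele split that delta > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy

from .io_core import GenotypeMatrix, HaplotypeAlignment


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix/labels size mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.matrix) != 0).any():
            raise ValueError("diagonal must be zero")
        if (self.matrix < 0).any():
            raise ValueError("distances must be >= 0")


def pairwise_distances(aln: HaplotypeAlignment, model: str = "p"
                       ) -> DistanceMatrix:
    """p-distance (mismatch fraction over pairwise non-N sites) or its
    Jukes-Cantor correction -3/4 ln(1 - 4p/3)."""
    arr = aln.to_array()
    n = arr.shape[0]
    valid = arr != b"N"
    d = np.zeros((n, n))
    for i in range(n):
        comp = valid[i] & valid[i + 1:]
        mism = (arr[i] != arr[i + 1:]) & comp
        denom = comp.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, mism.sum(axis=1) / denom, 0.0)
        d[i, i + 1:] = p
        d[i + 1:, i] = p
    if model == "jc69":
        if (d >= 0.75).any():
            raise ValueError("p-distance >= 0.75: JC69 correction undefined")
        d = -0.75 * np.log1p(-4.0 * d / 3.0)
        np.fill_diagonal(d, 0.0)
    elif model != "p":
        raise ValueError(f"unknown model: {model!r}")
    return DistanceMatrix(labels=list(aln.names), matrix=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (Saitou & Nei) with deterministic tie-breaking
    (first minimal Q-pair in input-label order). Negative branch-length
    estimates are clamped to 0 with the deficit moved to the sister branch,
    so pairwise path lengths are preserved. Exact on additive matrices.

    The final two clusters are joined through a midpoint root, which leaves
    all tip-to-tip path lengths (and hence the CPD test) unchanged.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ requires >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    d = dm.matrix.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to the remaining clusters
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)
    a, b = active
    root = dendropy.Node()
    half = max(d[a, b], 0.0) / 2.0
    root.add_child(nodes[a])
    nodes[a].edge.length = half
    root.add_child(nodes[b])
    nodes[b].edge.length = half
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return tree


def cophenetic(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (patristic) distance between all tip pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = dist
    return DistanceMatrix(labels=labels, matrix=mat)


@dataclass
class CpdResult:
    cpd_within: float
    cpd_between: float
    delta: float
    call: str  # SPECIES_TREE | TRANS_SPECIFIC | TIE
    n_within_pairs: int
    n_between_pairs: int


def cpd_test(tree: dendropy.Tree, species_of_tip,
             include_same_individual: bool = True) -> CpdResult:
    """Median cophenetic distance within vs between species.

    ``species_of_tip`` maps tip label -> species label (dict or callable).
    With ``include_same_individual=False`` pairs of haplotypes from the
    same individual (labels ``species|sample|h0/h1``) are dropped from the
    within-species median.
    """
    getter = species_of_tip if callable(species_of_tip) else species_of_tip.get
    dm = cophenetic(tree)
    species = [getter(lab) for lab in dm.labels]
    counts = pd.Series(species).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("CPD test needs >= 2 tips per species for >= 2 species")

    def individual(lab):
        parts = lab.split("|")
        return parts[1] if len(parts) >= 2 else lab

    within, between = [], []
    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if species[i] == species[j]:
                if (not include_same_individual
                        and individual(dm.labels[i]) == individual(dm.labels[j])):
                    continue
                within.append(dm.matrix[i, j])
            else:
                between.append(dm.matrix[i, j])
    cpd_w = float(np.median(within))
    cpd_b = float(np.median(between))
    delta = cpd_w - cpd_b
    call = "TIE" if delta == 0 else ("TRANS_SPECIFIC" if delta > 0
                                     else "SPECIES_TREE")
    return CpdResult(cpd_within=cpd_w, cpd_between=cpd_b, delta=delta,
                     call=call, n_within_pairs=len(within),
                     n_between_pairs=len(between))


# ---------------------------------------------------------------------------
# window extraction


@dataclass
class Window:
    focal_chrom: str
    focal_pos: int
    alignment: HaplotypeAlignment
    truncated: bool


def extract_windows(aln: HaplotypeAlignment, gm: GenotypeMatrix,
                    classification: pd.DataFrame, flank: int = 500,
                    maf_min: float = 0.25, n_per_species: int = 30,
                    annotation: str = "NS") -> list:
    """Cut haplotype windows around focal shared SNPs.

    Focal SNPs are SHARED_POLY sites with the requested annotation and
    minor-allele frequency > ``maf_min`` in both species. ``aln`` holds
    full-length phased haplotypes named ``species|sample|h{0,1}`` whose
    columns correspond 1:1 to genomic positions (single contig); ``gm``
    supplies site metadata and per-sample coverage. Each window spans
    ``flank`` bp in total, centred on the focal SNP (truncated and flagged
    at contig edges), and keeps both haplotypes of the ``n_per_species``
    highest-coverage individuals per species (ties by sample order).
    """
    cls = classification.merge(gm.sites[["chrom", "pos", "annotation"]],
                               on=["chrom", "pos"])
    maf_a = np.minimum(cls["freq_a"], 1 - cls["freq_a"])
    maf_b = np.minimum(cls["freq_b"], 1 - cls["freq_b"])
    focal = cls[(cls["label"] == "SHARED_POLY")
                & (cls["annotation"] == annotation)
                & (maf_a > maf_min) & (maf_b > maf_min)]

    # rank individuals by coverage within species
    chosen = []
    for sp, group in gm.samples.groupby("species", sort=False):
        order = group.sort_values("mean_coverage", ascending=False,
                                  kind="stable")
        chosen.extend(order["sample_id"].head(n_per_species))
    chosen = set(chosen)
    keep = [i for i, name in enumerate(aln.names)
            if name.split("|")[1] in chosen]

    half = flank // 2
    length = aln.length
    windows = []
    for _, row in focal.iterrows():
        pos = int(row["pos"])
        lo = max(pos - half, 1)
        hi = min(pos + (flank - half), length)
        truncated = (lo != pos - half) or (hi != pos + (flank - half))
        seqs = [aln.sequences[i][lo - 1:hi] for i in keep]
        names = [aln.names[i] for i in keep]
        windows.append(Window(focal_chrom=row["chrom"], focal_pos=pos,
                              alignment=HaplotypeAlignment(names=names,
                                                           sequences=seqs),
                              truncated=truncated))
    return windows


def species_of_tip_label(label: str) -> str:
    """Species component of a ``species|sample|h`` tip label."""
    return label.split("|")[0]
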