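"""Concatenated-PCG supermatrix and distance-based tree inference.

The pipeline's in-house, fully testable tree stage is Saitou-Nei
neighbor joining over p/JC69/K2P distances, with nonparametric bootstrap
(column resampling, within partitions when labelled) for branch support.
Partitioned maximum-likelihood / Bayesian runs are export-only: the
supermatrix and partition files written by :mod:`mitochar.io_formats` feed
the external tools, and this module documents the recommended settings in
the export sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .annotation import MitoGenome, PCG_NAMES
from .codons import extract_cds
from .io_formats import AlignmentBlock

__all__ = [
    "DistanceMatrix",
    "build_gene_alignments",
    "concatenate_pcgs",
    "distance_matrix",
    "nj_tree",
    "bootstrap",
    "check_clades",
    "bipartitions",
    "robinson_foulds",
]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal
    flagged: np.ndarray  # True where the model correction saturated

    def __post_init__(self) -> None:
        assert self.d.shape == (len(self.taxa), len(self.taxa))


# ---------------------------------------------------------------------------
# supermatrix construction


def build_gene_alignments(genomes: list[MitoGenome], genes=PCG_NAMES) -> dict[str, AlignmentBlock]:
    """Per-gene blocks from annotated genomes with equal-length CDS (gap-free).

    Genomes whose copy of a gene differs in length need external alignment;
    that is an error here rather than a silent mis-stack.
    """
    out = {}
    taxa = [g.taxon for g in genomes]
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxon name collision among genomes")
    for gene in genes:
        rows = []
        for g in genomes:
            try:
                rows.append(extract_cds(g, gene))
            except KeyError:
                rows.append(None)
        lengths = {len(r) for r in rows if r is not None}
        if len(lengths) > 1:
            raise ValueError(f"{gene}: unequal CDS lengths {sorted(lengths)}; align first")
        width = lengths.pop() if lengths else 0
        rows = [r if r is not None else "-" * width for r in rows]
        out[gene] = AlignmentBlock(list(taxa), rows)
    return out


def concatenate_pcgs(
    gene_alignments: dict[str, AlignmentBlock],
    genomes: list[MitoGenome] | None = None,
) -> AlignmentBlock:
    """Concatenate per-gene blocks into a partition-labelled supermatrix.

    Taxa missing from a gene are padded with gaps.  With ``genomes`` given and
    ``gene_alignments`` empty/None, blocks are built from the annotations.
    """
    if not gene_alignments:
        if genomes is None:
            raise ValueError("need gene alignments or genomes")
        gene_alignments = build_gene_alignments(genomes)
    taxa: list[str] = []
    for block in gene_alignments.values():
        for t in block.taxa:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for gene, block in gene_alignments.items():
        w = block.nchar
        for t in taxa:
            rows[t].append(block.row(t) if t in block.taxa else "-" * w)
        partitions.append((gene, pos, pos + w - 1))
        pos += w
    return AlignmentBlock(taxa, ["".join(rows[t]) for t in taxa], partitions)


# ---------------------------------------------------------------------------
# distances

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_alignment(a: AlignmentBlock) -> np.ndarray:
    """(ntax, nchar) int8 matrix; 0-3 for ACGT, -1 for gap/N/ambiguity."""
    arr = np.full((len(a.taxa), a.nchar), -1, dtype=np.int8)
    for i, row in enumerate(a.rows):
        codes = np.frombuffer(row.upper().encode(), dtype=np.uint8)
        for b, v in _BASE_IDX.items():
            arr[i, codes == ord(b)] = v
    return arr


def _pair_stats(x: np.ndarray, weights: np.ndarray | None = None):
    """Per-pair comparable sites, mismatches and transitions (vectorized)."""
    n, L = x.shape
    w = np.ones(L) if weights is None else weights
    valid = x >= 0
    onehot = np.zeros((n, L, 4))
    for v in range(4):
        onehot[:, :, v] = (x == v)
    wh = onehot * w[None, :, None]
    # comparable columns per pair
    vw = valid * w[None, :]
    comp = vw @ valid.T.astype(float)
    match = np.einsum("ilk,jlk->ij", wh, onehot)
    # transitions: A<->G (0,2), C<->T (1,3)
    ts = np.einsum("il,jl->ij", wh[:, :, 0], onehot[:, :, 2])
    ts += np.einsum("il,jl->ij", wh[:, :, 2], onehot[:, :, 0])
    ts += np.einsum("il,jl->ij", wh[:, :, 1], onehot[:, :, 3])
    ts += np.einsum("il,jl->ij", wh[:, :, 3], onehot[:, :, 1])
    mismatch = comp - match
    return comp, mismatch, ts


def distance_matrix(a: AlignmentBlock, model: str = "JC69",
                    weights: np.ndarray | None = None) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/N columns.

    Models: ``p`` (raw proportion), ``JC69`` and ``K2P`` closed forms.
    Saturated corrections are flagged (and left as the raw bound is exceeded).
    """
    if len(a.taxa) < 2:
        raise ValueError("need at least two taxa")
    x = encode_alignment(a)
    comp, mismatch, ts = _pair_stats(x, weights)
    n = len(a.taxa)
    if np.any((comp == 0) & ~np.eye(n, dtype=bool)):
        i, j = np.argwhere((comp == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(f"no comparable sites between {a.taxa[i]} and {a.taxa[j]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = mismatch / comp
        if model == "p":
            d = p
            flagged = np.zeros_like(p, dtype=bool)
        elif model == "JC69":
            arg = 1.0 - 4.0 * p / 3.0
            flagged = arg <= 0
            d = np.where(flagged, np.nan, -0.75 * np.log(np.where(flagged, 1.0, arg)))
        elif model == "K2P":
            P = ts / comp
            Q = p - P
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            flagged = (a1 <= 0) | (a2 <= 0)
            safe1 = np.where(flagged, 1.0, a1)
            safe2 = np.where(flagged, 1.0, a2)
            d = np.where(flagged, np.nan, -0.5 * np.log(safe1) - 0.25 * np.log(safe2))
        else:
            raise ValueError(f"unknown model {model!r}")
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(flagged, False)
    return DistanceMatrix(list(a.taxa), d, flagged)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None,
            allow_flagged: bool = False) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break toward the lowest taxon-index pair.
    Negative branch lengths are clamped to zero with the deficit moved to the
    sibling edge.
    """
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("need at least three taxa")
    if dm.flagged.any() and not allow_flagged:
        raise ValueError("distance matrix contains saturated entries")
    tns = taxon_namespace or dendropy.TaxonNamespace(dm.taxa)
    nodes = []
    for t in dm.taxa:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(t)
        if nd.taxon is None:
            raise ValueError(f"taxon {t!r} missing from namespace")
        nodes.append(nd)
    D = dm.d.astype(float).copy()
    active = list(range(n0))  # indices into a growing node list
    allnodes = list(nodes)
    # D indexed by position in `allnodes`; grow it as new nodes appear
    size = n0

    def dist(i, j):
        return D[i, j]

    Dfull = np.zeros((2 * n0, 2 * n0))
    Dfull[:n0, :n0] = D

    while len(active) > 2:
        m = len(active)
        r = {i: sum(Dfull[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * Dfull[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = Dfull[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving mass to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        parent = dendropy.Node()
        ni, nj = allnodes[i], allnodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        u = size
        size += 1
        allnodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            Dfull[u, k] = Dfull[k, u] = 0.5 * (Dfull[i, k] + Dfull[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    root = dendropy.Node()
    root.add_child(allnodes[i])
    root.add_child(allnodes[j])
    half = max(Dfull[i, j], 0.0) / 2.0
    allnodes[i].edge.length = half
    allnodes[j].edge.length = half
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap and tree comparison


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted splits as frozensets of the smaller/canonical side."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        other = leaves - below
        if len(below) < 2 or len(other) < 2:
            continue
        canon = min((tuple(sorted(below)), tuple(sorted(other))))
        splits.add(frozenset(canon))
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def bootstrap(
    a: AlignmentBlock,
    replicates: int = 100,
    seed: int = 0,
    model: str = "JC69",
) -> dendropy.Tree:
    """NJ tree on the full data with majority-style bootstrap supports.

    Columns are resampled with replacement per replicate — within partitions
    when the block is labelled — and each replicate tree's bipartitions are
    tallied; supports (percent of replicates) annotate internal nodes of the
    full-data tree as ``node.label``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(a.taxa) < 4:
        raise ValueError("need at least four taxa")
    rng = np.random.default_rng(seed)
    full = nj_tree(distance_matrix(a, model))
    blocks = a.partitions or [("all", 1, a.nchar)]
    counts: dict[frozenset, int] = {}
    for _ in range(replicates):
        w = np.zeros(a.nchar)
        for _, s, e in blocks:
            width = e - s + 1
            idx = rng.integers(0, width, size=width)
            np.add.at(w, s - 1 + idx, 1.0)
        dm = distance_matrix(a, model, weights=w)
        rep = nj_tree(dm, allow_flagged=True) if dm.flagged.any() else nj_tree(dm)
        for split in bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    for nd in full.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        leaves = frozenset(l.taxon.label for l in full.leaf_node_iter())
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        other = leaves - below
        if len(below) < 2 or len(other) < 2:
            continue
        canon = frozenset(min((tuple(sorted(below)), tuple(sorted(other)))))
        nd.label = str(round(100.0 * counts.get(canon, 0) / replicates))
    return full


def check_clades(
    tree: dendropy.Tree,
    constraints: list[set[str]] | list[frozenset],
    outgroup: str,
) -> list[bool]:
    """Is each taxon set monophyletic on the tree rooted by ``outgroup``?"""
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if outgroup not in labels:
        raise KeyError(f"outgroup {outgroup!r} not in tree")
    t = tree.clone(depth=1)
    og = t.find_node_with_taxon_label(outgroup)
    t.to_outgroup_position(og, update_bipartitions=False)
    t.is_rooted = True
    results = []
    for cons in constraints:
        cons = set(cons)
        unknown = cons - labels
        if unknown:
            raise KeyError(f"unknown taxa in constraint: {sorted(unknown)}")
        if len(cons) == 1:
            results.append(True)
            continue
        mrca = t.mrca(taxon_labels=sorted(cons))
        below = {l.taxon.label for l in mrca.leaf_iter()}
        results.append(below == cons)
    return results
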