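"""Synthetic annotated mitogenomes and their evolution along a tree.

The generator emits genomes with the architecture the analyses assume: the
canonical 37-feature vertebrate layout (13 PCGs, 22 tRNAs, 2 rRNAs, OL,
control region) in the study species' gene order and strand assignments,
with the same 1-14 bp overlaps and intergenic spacers, a T-rich/C-rich
heavy-strand composition giving negative AT and GC skews, PCGs with valid
(possibly non-ATG) initiation codons, no internal stops, and complete or
polyadenylation-truncated terminators.

Evolution along a branch-length tree uses an HKY-flavoured proposal scheme
(transition:transversion weight ``kappa``) with per-gene acceptance:
synonymous proposals are always accepted, nonsynonymous ones with
probability min(1, omega_gene), and proposals creating stop codons (or
hitting initiation/termination codons) are rejected; tRNA/rRNA/control
sites evolve neutrally.  This accept/reject omega is a simulation
convenience — recovery checks on it are rank-based, not absolute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .annotation import (
    AnnotationError,
    FeatureType,
    MitoFeature,
    MitoGenome,
    Strand,
    published_annotation,
    published_spacer_column,
)
from .codons import VERTEBRATE_MITO, GeneticCode

__all__ = [
    "ArchFeature",
    "SimulationSpec",
    "DEFAULT_COMPOSITION",
    "DEFAULT_OMEGA",
    "default_architecture",
    "gene_panel_architecture",
    "megophryidae_taxa",
    "megophryidae_tree",
    "balanced_tree",
    "generate_root",
    "evolve",
]

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = np.array(list("ACGT"))


@dataclass(frozen=True)
class ArchFeature:
    """One slot of the architecture template."""

    name: str
    ftype: FeatureType
    strand: Strand
    length: int
    spacer_to_next: int  # signed; negative = overlap with the next feature
    start_codon: str | None = None
    stop_codon: str | None = None  # 3-mer or incomplete "T"/"TA"
    anticodon: str | None = None


#: Heavy-strand base frequencies matching the study genomes (T- and C-rich).
DEFAULT_COMPOSITION = {"A": 0.2745, "C": 0.2697, "G": 0.1481, "T": 0.3077}

#: Per-gene dN/dS used by default, anchored to the published per-gene pattern:
#: ATP8 fastest (0.246) and COI slowest (0.037), ATP6/ND2/ND4 relatively fast,
#: COIII/Cytb/COII slow, the remainder intermediate.
DEFAULT_OMEGA = {
    "ATP8": 0.246, "ATP6": 0.20, "ND2": 0.19, "ND4": 0.17, "ND3": 0.15,
    "ND4L": 0.14, "ND5": 0.12, "ND1": 0.11, "ND6": 0.10, "COII": 0.07,
    "Cytb": 0.06, "COIII": 0.055, "COI": 0.037,
}


def default_architecture(species: str = "sangzhiensis") -> list[ArchFeature]:
    """The study layout: gene order, strands, lengths and signed spacers."""
    genome = published_annotation(species)
    spacers = published_spacer_column(species)
    out = []
    for f, sp in zip(genome.features, spacers):
        out.append(
            ArchFeature(
                name=f.name,
                ftype=f.ftype,
                strand=f.strand,
                length=f.end - f.start + 1,
                spacer_to_next=sp,
                start_codon=f.start_codon,
                stop_codon=f.stop_codon,
                anticodon=f.anticodon,
            )
        )
    return out


def gene_panel_architecture(genes: dict[str, int]) -> list[ArchFeature]:
    """A minimal architecture of H-strand PCGs (codon counts incl. start,
    excl. stop) separated by 10 bp spacers, closed by a 200 bp control region.

    Useful for focused rate-recovery experiments where only coding sequence
    matters.
    """
    out = []
    for name, n_codons in genes.items():
        out.append(
            ArchFeature(name, FeatureType.PCG, Strand.H, 3 * n_codons + 3, 10,
                        start_codon="ATG", stop_codon="TAA")
        )
    out.append(ArchFeature("D-loop", FeatureType.control, Strand.H, 200, 0))
    return out


@dataclass
class SimulationSpec:
    architecture: list[ArchFeature] = field(default_factory=default_architecture)
    composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    tree: str | None = None  # newick with branch lengths (substitutions/site)
    kappa: float = 4.0
    omega: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("composition proportions must sum to 1")
        if any(w <= 0 for w in self.omega.values()):
            raise ValueError("omega values must be > 0")


# ---------------------------------------------------------------------------
# coordinate resolution


def resolve_coordinates(arch: list[ArchFeature]) -> tuple[list[MitoFeature], int]:
    """Turn lengths + signed spacers into 1-based features and genome length."""
    feats = []
    pos = 1
    for af in arch:
        start = pos
        end = start + af.length - 1
        feats.append(
            MitoFeature(af.name, af.ftype, start, end, af.strand,
                        af.start_codon, af.stop_codon, af.anticodon)
        )
        pos = end + af.spacer_to_next + 1
    genome_length = pos - 1  # closing spacer returns to position 1
    if genome_length < max(f.end for f in feats):
        raise AnnotationError("architecture spacers do not close the circle")
    return feats, genome_length


# ---------------------------------------------------------------------------
# codon machinery shared by generation and evolution


def _codon_h_positions(f: MitoFeature, codon_index: int) -> list[int]:
    """0-based heavy-strand positions of a codon, in coding-strand order."""
    if f.strand is Strand.H:
        base = f.start - 1 + 3 * codon_index
        return [base, base + 1, base + 2]
    base = f.end - 1 - 3 * codon_index
    return [base, base - 1, base - 2]


def _coding_base(h_base: int, strand: Strand) -> int:
    return h_base if strand is Strand.H else 3 - h_base


class _GenomeMap:
    """Site -> coding context lookup tables for one resolved architecture."""

    def __init__(self, feats: list[MitoFeature], genome_length: int):
        self.length = genome_length
        self.immutable = np.zeros(genome_length, dtype=bool)
        self.site_genes: dict[int, list[tuple[MitoFeature, int]]] = {}
        self.pcgs = [f for f in feats if f.ftype is FeatureType.PCG]
        for f in self.pcgs:
            L = f.end - f.start + 1
            n_full = L // 3
            rem = L % 3
            # codons counted in the coding frame; the terminal complete stop
            # and any trailing partial codon are locked, as is the initiator
            if rem == 0 and f.stop_codon and len(f.stop_codon) == 3:
                body = range(1, n_full - 1)
                locked = [0, n_full - 1]
            else:
                body = range(1, n_full)
                locked = [0]
            for ci in body:
                for h in _codon_h_positions(f, ci):
                    self.site_genes.setdefault(h, []).append((f, ci))
            for ci in locked:
                for h in _codon_h_positions(f, ci):
                    self.immutable[h] = True
            if rem:
                # trailing partial codon = the truncated stop descriptor
                tail = range(f.start - 1 + 3 * n_full, f.end) if f.strand is Strand.H \
                    else range(f.end - 1 - 3 * n_full, f.start - 2, -1)
                for h in tail:
                    self.immutable[h] = True


def _sense_codon_arrays(code: GeneticCode):
    codons = sorted(code.sense_codons())
    arr = np.array([[_IDX[b] for b in c] for c in codons], dtype=np.int8)
    return codons, arr


# ---------------------------------------------------------------------------
# root generation


def generate_root(spec: SimulationSpec, code: GeneticCode = VERTEBRATE_MITO) -> MitoGenome:
    """A genome realizing the architecture with the target composition."""
    rng = np.random.default_rng(spec.seed)
    feats, L = resolve_coordinates(spec.architecture)
    comp = np.array([spec.composition[b] for b in "ACGT"])
    seq = np.full(L, -1, dtype=np.int8)

    sense, sense_arr = _sense_codon_arrays(code)
    sense_w = np.prod(comp[sense_arr], axis=1)

    def write_coding(f: MitoFeature, ci: int, codon: str) -> None:
        for h, b in zip(_codon_h_positions(f, ci), codon):
            v = _coding_base(_IDX[b], f.strand)
            if seq[h] != -1 and seq[h] != v:
                raise AnnotationError(
                    f"infeasible template: conflicting bases at position {h + 1} ({f.name})"
                )
            seq[h] = v

    pcgs = [f for f in feats if f.ftype is FeatureType.PCG]
    # pin every initiation codon and terminator first, then fill bodies
    for f in pcgs:
        if not f.start_codon or not f.stop_codon:
            raise AnnotationError(f"{f.name}: PCG template needs start and stop codons")
        Lf = f.end - f.start + 1
        n_full = Lf // 3
        rem = Lf % 3
        if len(f.stop_codon) == 3 and rem != 0:
            raise AnnotationError(f"{f.name}: complete stop on a length not divisible by 3")
        if len(f.stop_codon) != 3 and rem != len(f.stop_codon):
            raise AnnotationError(f"{f.name}: stop descriptor inconsistent with length mod 3")
        write_coding(f, 0, f.start_codon)
        if rem == 0:
            if not code.is_stop(f.stop_codon):
                raise AnnotationError(f"{f.name}: {f.stop_codon} is not a stop codon")
            write_coding(f, n_full - 1, f.stop_codon)
        else:
            positions = _codon_h_positions(f, n_full)[:rem]
            for h, b in zip(positions, f.stop_codon):
                v = _coding_base(_IDX[b], f.strand)
                if seq[h] != -1 and seq[h] != v:
                    raise AnnotationError(f"infeasible template: stop of {f.name} conflicts")
                seq[h] = v
    for f in pcgs:
        Lf = f.end - f.start + 1
        n_full = Lf // 3
        rem = Lf % 3
        last_body = n_full - 1 if (rem == 0) else n_full
        for ci in range(1, last_body):
            hpos = _codon_h_positions(f, ci)
            fixed = [_coding_base(seq[h], f.strand) if seq[h] != -1 else -1 for h in hpos]
            mask = np.ones(len(sense), dtype=bool)
            for j, fb in enumerate(fixed):
                if fb != -1:
                    mask &= sense_arr[:, j] == fb
            if not mask.any():
                raise AnnotationError(
                    f"infeasible template: no sense codon fits constraints in {f.name}"
                )
            w = sense_w * mask
            codon = sense[rng.choice(len(sense), p=w / w.sum())]
            write_coding(f, ci, codon)
    free = seq == -1
    seq[free] = rng.choice(4, size=int(free.sum()), p=comp)
    sequence = "".join(_BASE[seq])
    return MitoGenome("synthetic", f"SYN{spec.seed:06d}", sequence, feats, circular=True)


# ---------------------------------------------------------------------------
# evolution along a tree


def balanced_tree(n_taxa: int, depth: float = 0.05, prefix: str = "t") -> str:
    """A balanced binary newick over n_taxa (power of two) with equal edges."""
    if n_taxa & (n_taxa - 1):
        raise ValueError("n_taxa must be a power of two")
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]

    def build(lo, hi):
        if hi - lo == 1:
            return f"{labels[lo]}:{depth}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{depth}"

    return build(0, n_taxa) + ";"


def megophryidae_taxa() -> list[str]:
    tree = dendropy.Tree.get(data=megophryidae_tree(), schema="newick", preserve_underscores=True)
    return [l.taxon.label for l in tree.leaf_node_iter()]


def megophryidae_tree() -> str:
    """A synthetic 29-taxon reference topology shaped like the study family:
    two subfamily clades, two species groups inside the focal genus, and a
    microhylid outgroup.  Branch lengths (substitutions/site) are invented.
    """
    boulenophrys = (
        "(((Boulenophrys_sangzhiensis:0.030,Boulenophrys_omeimontis:0.030):0.015,"
        "Boulenophrys_spinata:0.045):0.030,"
        "((Boulenophrys_tuberogranulata:0.025,Boulenophrys_jingganggensis:0.025):0.012,"
        "(Boulenophrys_boettgeri:0.022,(Boulenophrys_kuatunensis:0.020,"
        "Boulenophrys_baishanzuensis:0.020):0.010):0.012):0.030):0.040"
    )
    megophryinae = (
        f"({boulenophrys},(Brachytarsophrys_carinense:0.090,"
        "(Atympanophrys_shapingensis:0.045,Atympanophrys_gigantica:0.045):0.040):0.020):0.050"
    )
    oreolalax = (
        "(((Oreolalax_major:0.030,Oreolalax_xiangchengensis:0.030):0.012,"
        "(Oreolalax_jingdongensis:0.028,Oreolalax_omeimontis:0.028):0.012):0.015,"
        "((Oreolalax_multipunctatus:0.030,Oreolalax_lichuanensis:0.030):0.012,"
        "(Oreolalax_schmidti:0.028,Oreolalax_rhodostigmatus:0.028):0.012):0.015):0.035"
    )
    leptobrachium = (
        "((Leptobrachium_boringii:0.030,Leptobrachium_liui:0.030):0.015,"
        "(Leptobrachium_ailaonicum:0.028,Leptobrachium_leishanense:0.028):0.015):0.040"
    )
    scutiger = "(Scutiger_ningshanensis:0.035,Scutiger_liupanensis:0.035):0.045"
    leptobrachella = (
        "((Leptolalax_oshanensis:0.040,Leptobrachella_alpina:0.040):0.015,"
        "Leptolalax_pelodytoides:0.055):0.045"
    )
    leptobrachiinae = (
        f"((({oreolalax},{scutiger}):0.012,{leptobrachium}):0.012,{leptobrachella}):0.050"
    )
    return f"(({megophryinae},{leptobrachiinae}):0.080,Microhyla_fissipes:0.180);"


def evolve(
    root: MitoGenome,
    spec: SimulationSpec,
    code: GeneticCode = VERTEBRATE_MITO,
) -> tuple[dict[str, MitoGenome], dendropy.Tree]:
    """Evolve the root genome along ``spec.tree``; returns leaf genomes + tree.

    Substitution proposals per branch are Poisson(branch_length * genome
    length); acceptance depends on the coding context as described in the
    module docstring.  Deterministic given ``spec.seed``.
    """
    if spec.tree is None:
        raise ValueError("spec.tree is required for evolve()")
    rng = np.random.default_rng(spec.seed + 1)
    tree = dendropy.Tree.get(data=spec.tree, schema="newick", preserve_underscores=True)
    gmap = _GenomeMap(root.features, len(root))
    L = len(root)
    kappa = spec.kappa
    # proposal table: for each current base, alternatives and their probs
    ts_partner = {0: 2, 2: 0, 1: 3, 3: 1}
    alt_bases = {}
    alt_probs = {}
    for b in range(4):
        alts = [x for x in range(4) if x != b]
        w = np.array([kappa if x == ts_partner[b] else 1.0 for x in alts])
        alt_bases[b] = np.array(alts)
        alt_probs[b] = w / w.sum()

    root_arr = np.array([_IDX[b] for b in root.sequence], dtype=np.int8)
    tree.seed_node.value_seq = root_arr

    def mutate(arr: np.ndarray, edge_len: float) -> np.ndarray:
        out = arr.copy()
        n_prop = rng.poisson(edge_len * L)
        sites = rng.integers(0, L, size=n_prop)
        us = rng.random(n_prop)
        for site, u in zip(sites, us):
            if gmap.immutable[site]:
                continue
            cur = out[site]
            newb = rng.choice(alt_bases[cur], p=alt_probs[cur])
            ctx = gmap.site_genes.get(site)
            if ctx is None:
                out[site] = newb
                continue
            accept_p = 1.0
            ok = True
            for f, ci in ctx:
                hpos = _codon_h_positions(f, ci)
                codon_idx = [_coding_base(out[h], f.strand) for h in hpos]
                j = hpos.index(site)
                new_idx = list(codon_idx)
                new_idx[j] = _coding_base(newb, f.strand)
                old_codon = "".join("ACGT"[x] for x in codon_idx)
                new_codon = "".join("ACGT"[x] for x in new_idx)
                if code.is_stop(new_codon):
                    ok = False
                    break
                if code.aa(new_codon) != code.aa(old_codon):
                    accept_p *= min(1.0, spec.omega.get(f.name, 1.0))
            if ok and u < accept_p:
                out[site] = newb
        return out

    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        nd.value_seq = mutate(nd.parent_node.value_seq, nd.edge.length or 0.0)

    leaves: dict[str, MitoGenome] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        seq = "".join(_BASE[leaf.value_seq])
        leaves[name] = MitoGenome(
            name, f"{root.accession}:{name}", seq,
            [replace(f) for f in root.features], circular=True,
        )
        del leaf.value_seq
    return leaves, tree
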