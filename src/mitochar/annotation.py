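"""Typed model of an annotated mitochondrial genome and its interval accounting.

A vertebrate mitogenome is a circular molecule of ~16-17 kb carrying a fixed
complement of 37 features: 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs
and one noncoding control region (D-loop), plus the short origin of
light-strand replication (OL) between tRNA-Asn and tRNA-Cys.  Adjacent
features frequently overlap by a few bases or leave short intergenic spacers
(IGNs); this module provides the signed-spacer arithmetic that summarizes
those relationships.

Coordinates are 1-based inclusive throughout, matching GenBank convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

__all__ = [
    "FeatureType",
    "Strand",
    "MitoFeature",
    "MitoGenome",
    "SpacerReport",
    "AnnotationError",
    "feature_length",
    "spacer",
    "spacer_report",
    "validate",
    "rotate",
    "load_feature_table",
    "published_annotation",
    "PCG_NAMES",
]

#: Canonical names of the 13 mitochondrial protein-coding genes.
PCG_NAMES = (
    "ND1", "ND2", "COI", "COII", "ATP8", "ATP6", "COIII",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "Cytb",
)


class AnnotationError(ValueError):
    """Raised for incoherent coordinates or malformed feature tables."""


class FeatureType(str, enum.Enum):
    PCG = "PCG"
    tRNA = "tRNA"
    rRNA = "rRNA"
    control = "control"
    origin = "origin"


class Strand(str, enum.Enum):
    H = "H"  # heavy strand (the deposited sequence)
    L = "L"  # light strand


@dataclass(frozen=True)
class MitoFeature:
    """One annotated gene or region.

    ``stop_codon`` holds either a complete stop 3-mer ("TAA", "TAG", "AGA",
    "AGG") or the incomplete descriptor "T" / "TA" for genes whose stop is
    completed by polyadenylation of the transcript.
    """

    name: str
    ftype: FeatureType
    start: int
    end: int
    strand: Strand = Strand.H
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None
    wraps: bool = False  # spans the circular origin (end < start allowed)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"{self.name}: start must be >= 1, got {self.start}")
        if not self.wraps and self.end < self.start:
            raise AnnotationError(
                f"{self.name}: end {self.end} < start {self.start} on a non-wrapping feature"
            )


@dataclass
class MitoGenome:
    """Circular heavy-strand sequence plus its ordered feature annotation."""

    taxon: str
    accession: str
    sequence: str
    features: list[MitoFeature]
    circular: bool = True
    transl_table: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> MitoFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} in {self.accession}")

    def pcgs(self) -> list[MitoFeature]:
        return [f for f in self.features if f.ftype is FeatureType.PCG]


@dataclass
class SpacerReport:
    """Aggregated overlap / intergenic accounting over adjacent feature pairs."""

    overlap_bp_total: int
    overlap_pairs: int
    ign_bp_total: int
    ign_locations: int
    per_pair: list[tuple[str, str, int]] = field(default_factory=list)


def feature_length(f: MitoFeature, genome_length: int) -> int:
    """Length in bp of a feature, resolving wrap-around on a circular genome."""
    if f.start > genome_length or f.end > genome_length:
        raise AnnotationError(
            f"{f.name}: coordinates ({f.start}, {f.end}) outside [1, {genome_length}]"
        )
    if f.wraps:
        return (genome_length - f.start + 1) + f.end
    return f.end - f.start + 1


def spacer(fA: MitoFeature, fB: MitoFeature, genome_length: int | None = None) -> int:
    """Signed gap between two adjacent features: start(B) - end(A) - 1.

    Negative values are overlaps, 0 means abutting, positive values are
    intergenic nucleotides.  When ``genome_length`` is given the pair may
    straddle the circular origin; the nearest signed representative on the
    circle is returned (spacers are short relative to the genome).
    """
    raw = fB.start - fA.end - 1
    if genome_length is not None:
        half = genome_length // 2
        raw = (raw + half) % genome_length - half
    return raw


def _adjacent_pairs(g: MitoGenome) -> Iterable[tuple[MitoFeature, MitoFeature]]:
    feats = g.features
    for a, b in zip(feats, feats[1:]):
        yield a, b
    if g.circular and len(feats) > 1:
        yield feats[-1], feats[0]


def spacer_report(g: MitoGenome) -> SpacerReport:
    """Tally overlaps and intergenic nucleotides over all adjacent pairs."""
    names = [f.name for f in g.features]
    if len(set(names)) != len(names):
        raise AnnotationError("duplicate feature names; disambiguate (e.g. Ser1/Ser2)")
    L = len(g) if g.circular else None
    over_bp = over_n = ign_bp = ign_n = 0
    pairs: list[tuple[str, str, int]] = []
    for a, b in _adjacent_pairs(g):
        s = spacer(a, b, L)
        pairs.append((a.name, b.name, s))
        if s < 0:
            over_bp += -s
            over_n += 1
        elif s > 0:
            ign_bp += s
            ign_n += 1
    return SpacerReport(over_bp, over_n, ign_bp, ign_n, pairs)


_STRICT_COMPLEMENT = {
    FeatureType.PCG: 13,
    FeatureType.tRNA: 22,
    FeatureType.rRNA: 2,
    FeatureType.control: 1,
}


def validate(g: MitoGenome, mode: str = "strict") -> list[str]:
    """Check annotation coherence; returns a list of human-readable issues.

    ``lenient`` checks coordinates only; ``strict`` additionally requires the
    canonical 37-feature vertebrate complement, valid strands, and codon
    metadata on every PCG.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown validation mode {mode!r}")
    issues: list[str] = []
    L = len(g)
    for f in g.features:
        if f.start < 1 or f.start > L or f.end < 1 or f.end > L:
            issues.append(f"{f.name}: coordinates ({f.start}, {f.end}) outside [1, {L}]")
        if not f.wraps and f.end < f.start:
            issues.append(f"{f.name}: end < start on non-wrapping feature")
        if f.wraps and not g.circular:
            issues.append(f"{f.name}: wrapping feature on a linear genome")
    if mode == "lenient":
        return issues

    counts: dict[FeatureType, int] = {}
    for f in g.features:
        counts[f.ftype] = counts.get(f.ftype, 0) + 1
    for ftype, want in _STRICT_COMPLEMENT.items():
        have = counts.get(ftype, 0)
        if have != want:
            if ftype is FeatureType.PCG and have < want:
                present = {f.name for f in g.features if f.ftype is FeatureType.PCG}
                for missing in set(PCG_NAMES) - present:
                    issues.append(f"missing PCG {missing}")
            else:
                issues.append(f"expected {want} {ftype.value} features, found {have}")
    for f in g.features:
        if f.ftype is FeatureType.PCG:
            if not f.start_codon:
                issues.append(f"{f.name}: PCG without start codon")
            if not f.stop_codon:
                issues.append(f"{f.name}: PCG without stop codon")
        if f.ftype is FeatureType.tRNA and not f.anticodon:
            issues.append(f"{f.name}: tRNA without anticodon")
    starts = [f.start for f in g.features]
    if starts != sorted(starts) and not any(f.wraps for f in g.features):
        issues.append("features not sorted in genome order")
    return issues


def rotate(g: MitoGenome, offset: int) -> MitoGenome:
    """Shift the circular origin by ``offset`` bp (new position 1 = old offset+1)."""
    if not g.circular:
        raise AnnotationError("cannot rotate a linear genome")
    L = len(g)
    offset %= L
    seq = g.sequence[offset:] + g.sequence[:offset]
    feats = []
    for f in g.features:
        ns = (f.start - 1 - offset) % L + 1
        ne = (f.end - 1 - offset) % L + 1
        feats.append(replace(f, start=ns, end=ne, wraps=ne < ns))
    feats.sort(key=lambda f: f.start)
    # a wrapping feature belongs at the end of genome order
    feats.sort(key=lambda f: f.wraps)
    return MitoGenome(g.taxon, g.accession, seq, feats, circular=True)


# ---------------------------------------------------------------------------
# feature-table TSV dialect


def _parse_stop(cell: str) -> str | None:
    # printed incomplete stops look like "T(AA)" / "TA(A)"; strip the
    # polyadenylation completion to the bare descriptor
    if not cell:
        return None
    return cell.split("(")[0] if "(" in cell else cell


def load_feature_table(path_or_lines) -> list[MitoFeature]:
    """Read the 8-column feature TSV (extra columns ignored)."""
    if hasattr(path_or_lines, "read"):
        lines = path_or_lines.read().splitlines()
    elif isinstance(path_or_lines, str) and "\n" in path_or_lines:
        lines = path_or_lines.splitlines()
    else:
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    header = lines[0].rstrip("\n").split("\t")
    idx = {col: i for i, col in enumerate(header)}
    for col in ("name", "type", "start", "end", "strand"):
        if col not in idx:
            raise AnnotationError(f"feature table missing column {col!r}")
    feats = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")

        def get(col: str) -> str:
            i = idx.get(col)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        feats.append(
            MitoFeature(
                name=get("name"),
                ftype=FeatureType(get("type")),
                start=int(get("start")),
                end=int(get("end")),
                strand=Strand(get("strand")),
                start_codon=get("start_codon") or None,
                stop_codon=_parse_stop(get("stop_codon")),
                anticodon=get("anticodon") or None,
            )
        )
    return feats


_PUBLISHED = {
    "sangzhiensis": ("Boulenophrys sangzhiensis", "OQ830572", "sangzhiensis_features.tsv"),
    "tuberogranulata": ("Boulenophrys tuberogranulata", "OQ830573", "tuberogranulata_features.tsv"),
}


def published_annotation(species: str) -> MitoGenome:
    """The published annotation of one of the two study species.

    Returns a :class:`MitoGenome` whose sequence is empty (coordinates only);
    genome length is taken from the last feature's end, which coincides with
    the deposited sequence length for both species.
    """
    try:
        taxon, accession, fname = _PUBLISHED[species]
    except KeyError:
        raise KeyError(f"species must be one of {sorted(_PUBLISHED)}") from None
    text = resources.files("mitochar.data").joinpath(fname).read_text()
    feats = load_feature_table(text)
    length = max(f.end for f in feats)
    return MitoGenome(taxon, accession, "N" * length, feats, circular=True)


def published_spacer_column(species: str) -> list[int]:
    """The printed signed intergenic column for one study species (genome order)."""
    _, _, fname = _PUBLISHED[species]
    text = resources.files("mitochar.data").joinpath(fname).read_text()
    lines = text.splitlines()
    header = lines[0].split("\t")
    i = header.index("spacer_to_next")
    return [int(l.split("\t")[i]) for l in lines[1:] if l.strip()]


def published_length_column(species: str) -> list[int]:
    """The printed per-feature length column (genome order)."""
    _, _, fname = _PUBLISHED[species]
    text = resources.files("mitochar.data").joinpath(fname).read_text()
    lines = text.splitlines()
    header = lines[0].split("\t")
    i = header.index("length")
    return [int(l.split("\t")[i]) for l in lines[1:] if l.strip()]
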