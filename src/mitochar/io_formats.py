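"""Readers and writers for the formats the pipeline touches.

GenBank flat files and FASTA go through Biopython; alignments are exported
as relaxed PHYLIP or NEXUS with partition definitions (RAxML-style charsets
per gene and optionally per codon position) for downstream partitioned
ML/BI runs; trees go through Newick (dendropy).  Every writer has a matching
reader and the pair round-trips on model content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .annotation import FeatureType, MitoFeature, MitoGenome, Strand
from . import codons as _codons

__all__ = [
    "AlignmentBlock",
    "FormatError",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "write_supermatrix",
    "read_phylip",
    "read_nexus",
    "write_newick",
    "read_newick",
    "DEFAULT_RUN_SETTINGS",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alignments


@dataclass
class AlignmentBlock:
    """Equal-length gapped rows over an ordered taxon set.

    ``partitions`` is an ordered list of (label, start, end) charsets with
    1-based inclusive column ranges; when present they must tile the columns
    exactly once.
    """

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise FormatError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon names")
        if self.rows:
            w = len(self.rows[0])
            if any(len(r) != w for r in self.rows):
                raise FormatError("ragged alignment rows")
            if self.partitions:
                cols = []
                for _, s, e in self.partitions:
                    cols.extend(range(s, e + 1))
                if sorted(cols) != list(range(1, w + 1)):
                    raise FormatError("partitions do not tile the columns exactly once")

    @property
    def nchar(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


# ---------------------------------------------------------------------------
# GenBank

_FTYPE_TO_KEY = {
    FeatureType.PCG: "CDS",
    FeatureType.tRNA: "tRNA",
    FeatureType.rRNA: "rRNA",
    FeatureType.control: "D-loop",
    FeatureType.origin: "rep_origin",
}
_KEY_TO_FTYPE = {v: k for k, v in _FTYPE_TO_KEY.items()}


def write_genbank(g: MitoGenome, path) -> None:
    """Emit a minimal but standard flat file (LOCUS/FEATURES/ORIGIN)."""
    rec = SeqRecord(
        Seq(g.sequence),
        id=g.accession,
        name=g.accession[:16],
        description=f"{g.taxon} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if g.circular else "linear",
            "organism": g.taxon,
            "data_file_division": "VRT",
        },
    )
    L = len(g.sequence)
    rec.features.append(
        SeqFeature(SimpleLocation(0, L, strand=1), type="source",
                   qualifiers={"organism": [g.taxon]})
    )
    for f in g.features:
        strand = 1 if f.strand is Strand.H else -1
        if f.wraps:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, L, strand=strand),
                 SimpleLocation(0, f.end, strand=strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        quals = {"gene": [f.name]}
        if f.ftype is FeatureType.PCG:
            quals["codon_start"] = ["1"]
            quals["transl_table"] = [str(g.transl_table or 2)]
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        rec.features.append(SeqFeature(loc, type=_FTYPE_TO_KEY[f.ftype], qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "genbank")


def read_genbank(path) -> MitoGenome:
    """Parse a flat file into a :class:`MitoGenome`.

    complement(...) locations map to strand L; join(...) across the origin
    maps to a wrapping feature; PCG start/stop codons are re-derived from the
    sequence itself.
    """
    try:
        rec = SeqIO.read(path, "genbank")
    except ValueError as e:
        raise FormatError(str(e)) from e
    seq = str(rec.seq).upper()
    if not seq:
        raise FormatError("record has no sequence")
    L = len(seq)
    circular = rec.annotations.get("topology") == "circular"
    taxon = rec.annotations.get("organism", rec.description or rec.id)
    transl_table = None
    feats: list[MitoFeature] = []
    for sf in rec.features:
        if sf.type not in _KEY_TO_FTYPE:
            continue
        ftype = _KEY_TO_FTYPE[sf.type]
        name = (sf.qualifiers.get("gene") or sf.qualifiers.get("product") or [""])[0]
        if not name:
            name = "D-loop" if ftype is FeatureType.control else sf.type
        try:
            parts = sf.location.parts
            strand = Strand.L if sf.location.strand == -1 else Strand.H
            if len(parts) == 2 and int(parts[0].end) == L and int(parts[1].start) == 0:
                start, end, wraps = int(parts[0].start) + 1, int(parts[1].end), True
            else:
                start, end, wraps = int(sf.location.start) + 1, int(sf.location.end), False
        except Exception as e:  # pragma: no cover - malformed location
            raise FormatError(f"unparseable location for feature {name!r}: {e}") from e
        anticodon = None
        for note in sf.qualifiers.get("note", []):
            if note.startswith("anticodon:"):
                anticodon = note.split(":", 1)[1]
        if sf.type == "CDS" and "transl_table" in sf.qualifiers:
            transl_table = int(sf.qualifiers["transl_table"][0])
        feats.append(
            MitoFeature(name=name, ftype=ftype, start=start, end=end, strand=strand,
                        anticodon=anticodon, wraps=wraps)
        )
    g = MitoGenome(taxon, rec.id, seq, feats, circular=circular, transl_table=transl_table)
    # second pass: derive PCG codon metadata from the sequence
    from dataclasses import replace

    for i, f in enumerate(g.features):
        if f.ftype is FeatureType.PCG:
            cds = _codons.extract_cds(g, f.name)
            cls = _codons.classify_codons(cds)
            g.features[i] = replace(f, start_codon=cls.start_codon, stop_codon=cls.stop_codon)
    return g


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, uppercased sequence) pairs in file order."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate FASTA identifiers")
    return records


def write_fasta(records, path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------------------------
# supermatrix + partitions

#: Downstream tree-search settings recommended for the exported supermatrix.
DEFAULT_RUN_SETTINGS = (
    "ML: RAxML, partitioned, bootstrap 1000 replicates",
    "BI: MrBayes, 1.0e7 generations, sample every 1000, burn-in 25%",
)


def _codon_charsets(partitions):
    out = []
    for label, s, e in partitions:
        for p in (1, 2, 3):
            out.append((f"{label}_pos{p}", s + p - 1, e, 3))
    return out


def write_supermatrix(
    a: AlignmentBlock,
    path,
    fmt: str = "relaxed_phylip",
    partitions: bool = True,
    codon_positions: bool = False,
    settings_note: tuple[str, ...] = DEFAULT_RUN_SETTINGS,
) -> list[Path]:
    """Write the alignment plus (optionally) partition definitions.

    relaxed_phylip: alignment at ``path``, RAxML-style partition file at
    ``path`` + ".partitions.txt", run-settings note at ``path`` + ".settings.txt".
    nexus: single file with DATA and SETS blocks; settings in a [comment].
    """
    path = Path(path)
    written = [path]
    if fmt == "relaxed_phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(a.taxa)} {a.nchar}\n")
            for t, r in zip(a.taxa, a.rows):
                fh.write(f"{t.replace(' ', '_')}  {r}\n")
        if partitions and a.partitions:
            ppath = path.with_name(path.name + ".partitions.txt")
            with open(ppath, "w") as fh:
                if codon_positions:
                    for label, s, e, step in _codon_charsets(a.partitions):
                        fh.write(f"DNA, {label} = {s}-{e}\\{step}\n")
                else:
                    for label, s, e in a.partitions:
                        fh.write(f"DNA, {label} = {s}-{e}\n")
            written.append(ppath)
        if settings_note:
            spath = path.with_name(path.name + ".settings.txt")
            with open(spath, "w") as fh:
                fh.write("# recommended downstream run settings\n")
                for line in settings_note:
                    fh.write(line + "\n")
            written.append(spath)
    elif fmt == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n")
            if settings_note:
                fh.write("[ " + "; ".join(settings_note) + " ]\n")
            fh.write("BEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(a.taxa)} NCHAR={a.nchar};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
            for t, r in zip(a.taxa, a.rows):
                fh.write(f"    {t.replace(' ', '_')}  {r}\n")
            fh.write("  ;\nEND;\n")
            if partitions and a.partitions:
                fh.write("BEGIN SETS;\n")
                if codon_positions:
                    for label, s, e, step in _codon_charsets(a.partitions):
                        fh.write(f"  CHARSET {label} = {s}-{e}\\{step};\n")
                else:
                    for label, s, e in a.partitions:
                        fh.write(f"  CHARSET {label} = {s}-{e};\n")
                fh.write("END;\n")
    else:
        raise ValueError(f"unknown supermatrix format {fmt!r}")
    return written


def read_phylip(path) -> AlignmentBlock:
    with open(path) as fh:
        header = fh.readline().split()
        ntax, nchar = int(header[0]), int(header[1])
        taxa, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(seq.strip())
    if len(taxa) != ntax or any(len(r) != nchar for r in rows):
        raise FormatError("PHYLIP dimensions disagree with content")
    return AlignmentBlock(taxa, rows)


def read_nexus(path) -> AlignmentBlock:
    """Minimal NEXUS reader for this module's own dialect (DATA + SETS)."""
    text = Path(path).read_text()
    # strip [comments]
    out, depth = [], 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif depth == 0:
            out.append(ch)
    text = "".join(out)
    lines = [l.strip() for l in text.splitlines()]
    taxa, rows, partitions = [], [], []
    in_matrix = False
    for line in lines:
        upper = line.upper()
        if upper == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if line.startswith(";"):
                in_matrix = False
                continue
            if line:
                name, seq = line.split(None, 1)
                taxa.append(name)
                rows.append(seq.strip())
        elif upper.startswith("CHARSET"):
            body = line[len("CHARSET"):].strip().rstrip(";")
            label, rng = body.split("=")
            rng = rng.strip()
            if "\\" in rng:
                continue  # stride charsets are re-derivable; skip on read
            s, e = rng.split("-")
            partitions.append((label.strip(), int(s), int(e)))
    if not taxa:
        raise FormatError("no MATRIX block found")
    return AlignmentBlock(taxa, rows, partitions)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
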