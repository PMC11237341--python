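"""Vertebrate-mitochondrial-code codon analysis.

Covers CDS extraction on the coding strand, translation under NCBI table 2
(AGA/AGG are stops, TGA = Trp, ATA = Met), start/stop classification
including the incomplete stops ("T"/"TA", completed to TAA by
polyadenylation), raw codon usage, and relative synonymous codon usage
(RSCU): RSCU(c) = k * n_c / sum of counts over the k synonymous codons of
c's amino acid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .annotation import FeatureType, MitoGenome, Strand

__all__ = [
    "GeneticCode",
    "VERTEBRATE_MITO",
    "CodonUsageTable",
    "revcomp",
    "extract_cds",
    "classify_codons",
    "format_stop",
    "translate",
    "rscu",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon->amino-acid table with stop codons and permitted starts."""

    table_id: int
    codon_to_aa: dict  # 64 entries; stops map to "*"
    allowed_starts: frozenset

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    def aa(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def sense_codons(self) -> list[str]:
        return [c for c, a in self.codon_to_aa.items() if a != "*"]

    def family(self, codon: str) -> list[str]:
        """All synonymous codons encoding the same amino acid."""
        a = self.aa(codon)
        return [c for c, x in self.codon_to_aa.items() if x == a]


def _build_code(table_id: int, allowed_starts: frozenset) -> GeneticCode:
    bio = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = {}
    for codon in ("".join(p) for p in itertools.product(BASES, repeat=3)):
        mapping[codon] = "*" if codon in bio.stop_codons else bio.forward_table[codon]
    return GeneticCode(table_id, mapping, allowed_starts)


#: NCBI translation table 2 with the start codons seen in amphibian mitogenomes.
VERTEBRATE_MITO = _build_code(2, frozenset({"ATG", "ATA", "ATT", "ATC", "GTG", "TTG"}))


def extract_cds(g: MitoGenome, gene: str) -> str:
    """Coding-strand nucleotides of a PCG (reverse-complemented for L-strand genes)."""
    f = g.feature(gene)
    if f.ftype is not FeatureType.PCG:
        raise KeyError(f"{gene} is not a protein-coding gene")
    if f.wraps:
        raw = g.sequence[f.start - 1 :] + g.sequence[: f.end]
    else:
        raw = g.sequence[f.start - 1 : f.end]
    raw = raw.upper()
    return revcomp(raw) if f.strand is Strand.L else raw


@dataclass
class CodonClassification:
    start_codon: str
    stop_codon: str | None  # complete 3-mer or incomplete "T"/"TA"; None if absent
    warnings: list[str] = field(default_factory=list)


def classify_codons(cds: str, code: GeneticCode = VERTEBRATE_MITO) -> CodonClassification:
    """Identify the initiation codon and the (possibly incomplete) terminator."""
    if len(cds) < 6:
        raise ValueError("CDS shorter than two codons")
    cds = cds.upper()
    warnings: list[str] = []
    start = cds[:3]
    if start not in code.allowed_starts:
        warnings.append(f"non-canonical start codon {start}")
    rem = len(cds) % 3
    if rem == 0:
        last = cds[-3:]
        if code.is_stop(last):
            stop = last
        else:
            stop = None
            warnings.append(f"no terminal stop (last codon {last})")
    else:
        tail = cds[-rem:]
        if (rem == 1 and tail == "T") or (rem == 2 and tail == "TA"):
            stop = tail
        else:
            stop = None
            warnings.append(f"trailing {rem} nt {tail!r} not a truncated TAA stop")
    return CodonClassification(start, stop, warnings)


def format_stop(stop: str | None) -> str:
    """Render a stop descriptor the way annotation tables print it."""
    if stop is None:
        return ""
    if stop == "T":
        return "T(AA)"
    if stop == "TA":
        return "TA(A)"
    return stop


def translate(cds: str, code: GeneticCode = VERTEBRATE_MITO) -> str:
    """Translate complete codons; trailing partial codon ignored.

    Internal stops translate to "*" (callers treat them as QC issues); codons
    containing N translate to "X".
    """
    cds = cds.upper()
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if any(b not in "ACGTN" for b in codon):
            raise ValueError(f"non-nucleotide symbol in codon {codon!r}")
        out.append("X" if "N" in codon else code.aa(codon))
    return "".join(out)


@dataclass
class CodonUsageTable:
    counts: dict  # codon -> int, 64 entries
    rscu: dict  # codon -> float
    aa_totals: dict  # amino acid -> int (stops excluded)
    unobserved_families: list[str] = field(default_factory=list)

    def to_rows(self):
        """(codon, amino acid, count, RSCU) sorted by amino acid then codon."""
        rows = [
            (c, VERTEBRATE_MITO.aa(c), self.counts[c], self.rscu[c])
            for c in self.counts
            if VERTEBRATE_MITO.aa(c) != "*"
        ]
        rows.sort(key=lambda r: (r[1], r[0]))
        return rows


def rscu(cds_set, code: GeneticCode = VERTEBRATE_MITO) -> CodonUsageTable:
    """Codon usage and RSCU over one or more in-frame CDS.

    Terminal complete stop codons and trailing incomplete codons are excluded
    from the counts, as are codons containing N.
    """
    if isinstance(cds_set, str):
        cds_set = [cds_set]
    cds_set = list(cds_set)
    if not cds_set:
        raise ValueError("empty CDS set")
    counts = {c: 0 for c in code.codon_to_aa}
    for cds in cds_set:
        cds = cds.upper()
        n_full = len(cds) // 3
        for i in range(n_full):
            codon = cds[3 * i : 3 * i + 3]
            if "N" in codon or any(b not in BASES for b in codon):
                continue
            if i == n_full - 1 and code.is_stop(codon):
                continue  # terminal stop
            counts[codon] += 1
    aa_totals: dict[str, int] = {}
    for codon, n in counts.items():
        a = code.aa(codon)
        if a != "*":
            aa_totals[a] = aa_totals.get(a, 0) + n
    rscu_vals = {}
    unobserved = sorted(a for a, t in aa_totals.items() if t == 0)
    for codon in counts:
        a = code.aa(codon)
        if a == "*":
            rscu_vals[codon] = 0.0
            continue
        fam = [c for c in counts if code.aa(c) == a]
        total = aa_totals[a]
        rscu_vals[codon] = (counts[codon] * len(fam) / total) if total else 0.0
    return CodonUsageTable(counts, rscu_vals, aa_totals, unobserved)
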