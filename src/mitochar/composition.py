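"""Base composition and strand-skew statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on the
heavy strand.  Vertebrate mitogenomes in this family are T- and C-biased on
the heavy strand, so both skews come out negative for whole genomes and for
almost every protein-coding gene; the single L-strand PCG (ND6) shows a
strongly positive heavy-strand GC skew because its coding strand is the
complement.

Region tables follow the study layout: one row per PCG, pooled PCG rows
(all positions and codon positions 1/2/3), the two rRNAs singly and pooled,
all tRNAs pooled, and the control region.  Per-region rows are computed on
the heavy-strand slice of the region even for L-strand genes; codon-position
rows are computed per gene on the coding strand and pooled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .annotation import FeatureType, MitoGenome, Strand, feature_length
from .codons import extract_cds

__all__ = [
    "RegionCompositionRow",
    "base_composition",
    "skews",
    "skews_from_counts",
    "region_table",
]


@dataclass
class RegionCompositionRow:
    region: str
    length: int
    pctA: float
    pctT: float
    pctG: float
    pctC: float
    pctAT: float
    at_skew: float | None
    gc_skew: float | None


def _counts(seq: str) -> Counter:
    return Counter(seq.upper())


def base_composition(seq: str, region: str = "") -> RegionCompositionRow:
    """Percentages of A/T/G/C over counted (non-N) positions."""
    if not seq:
        raise ValueError("empty sequence")
    c = _counts(seq)
    n = sum(c[b] for b in "ACGT")
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    pct = {b: 100.0 * c[b] / n for b in "ACGT"}
    at, gc = skews_from_counts(c["A"], c["T"], c["G"], c["C"])
    return RegionCompositionRow(
        region=region,
        length=len(seq),
        pctA=pct["A"],
        pctT=pct["T"],
        pctG=pct["G"],
        pctC=pct["C"],
        pctAT=pct["A"] + pct["T"],
        at_skew=at,
        gc_skew=gc,
    )


def skews_from_counts(a: float, t: float, g: float, c: float):
    """(AT skew, GC skew) from base counts or percentages; undefined -> None."""
    at = (a - t) / (a + t) if a + t > 0 else None
    gc = (g - c) / (g + c) if g + c > 0 else None
    return at, gc


def skews(seq: str):
    """(AT skew, GC skew) of a sequence; a skew with zero denominator is None."""
    cnt = _counts(seq)
    return skews_from_counts(cnt["A"], cnt["T"], cnt["G"], cnt["C"])


def _region_seq(g: MitoGenome, f) -> str:
    """Heavy-strand slice of a feature (wrap resolved)."""
    if f.wraps:
        return g.sequence[f.start - 1 :] + g.sequence[: f.end]
    return g.sequence[f.start - 1 : f.end]


def region_table(g: MitoGenome) -> list[RegionCompositionRow]:
    """The per-region composition/skew table for one genome."""
    rows: list[RegionCompositionRow] = []
    pcgs = [f for f in g.features if f.ftype is FeatureType.PCG]
    rrnas = [f for f in g.features if f.ftype is FeatureType.rRNA]
    trnas = [f for f in g.features if f.ftype is FeatureType.tRNA]
    controls = [f for f in g.features if f.ftype is FeatureType.control]

    for f in pcgs:
        rows.append(base_composition(_region_seq(g, f), f.name))
    if pcgs:
        rows.append(base_composition("".join(_region_seq(g, f) for f in pcgs), "PCG-all"))
        # codon positions on the coding strand, pooled across genes; trailing
        # partial codons contribute their 1-2 nt to positions 1 (and 2)
        pos_seq = {1: [], 2: [], 3: []}
        for f in pcgs:
            cds = extract_cds(g, f.name)
            for i, b in enumerate(cds):
                pos_seq[i % 3 + 1].append(b)
        for p in (1, 2, 3):
            rows.append(base_composition("".join(pos_seq[p]), f"PCGs-{p}"))
    for f in rrnas:
        rows.append(base_composition(_region_seq(g, f), f.name))
    if rrnas:
        rows.append(base_composition("".join(_region_seq(g, f) for f in rrnas), "rRNAs"))
    if trnas:
        rows.append(base_composition("".join(_region_seq(g, f) for f in trnas), "tRNAs"))
    for f in controls:
        rows.append(base_composition(_region_seq(g, f), f.name))
    return rows


def round_row(row: RegionCompositionRow) -> dict:
    """Report-layer rounding: percentages to 2 decimals, skews to 3 (half-up)."""
    from decimal import ROUND_HALF_UP, Decimal

    def r(x, nd):
        if x is None:
            return None
        q = Decimal(1).scaleb(-nd)
        return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

    return {
        "region": row.region,
        "length": row.length,
        "pctT": r(row.pctT, 2),
        "pctC": r(row.pctC, 2),
        "pctA": r(row.pctA, 2),
        "pctG": r(row.pctG, 2),
        "pctAT": r(row.pctAT, 2),
        "at_skew": r(row.at_skew, 3),
        "gc_skew": r(row.gc_skew, 3),
    }
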