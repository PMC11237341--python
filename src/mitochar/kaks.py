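"""Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

The classic counting estimator: each sense codon contributes fractional
synonymous/nonsynonymous site counts (number of synonymous single-base
changes divided by 3 per position, mutations to stop codons dropped from the
numerators), observed codon differences are resolved by averaging over all
orderings of single steps with equal weights while skipping orderings that
pass through a stop codon, and the raw proportions pS = Sd/S, pN = Nd/N are
corrected for multiple hits with d = -(3/4) ln(1 - 4p/3).

Gene-level rates are aggregated over all taxon pairs; the default summary is
the ratio of mean Ka to mean Ks (robust when individual pairs saturate),
with mean-of-ratios available as an alternative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .codons import BASES, VERTEBRATE_MITO, GeneticCode

__all__ = [
    "PairwiseRates",
    "GeneRateEstimate",
    "codon_site_counts",
    "codon_path_diffs",
    "jukes_cantor",
    "pairwise_kaks",
    "gene_kaks",
]


@dataclass
class PairwiseRates:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    pS: float
    pN: float
    Ks: float | None  # None when the JC correction is saturated
    Ka: float | None
    ratio: float | None  # Ka/Ks, None when undefined


@dataclass
class GeneRateEstimate:
    gene: str
    Ka_mean: float
    Ks_mean: float
    ratio: float | None
    n_pairs: int
    n_excluded: int = 0


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, table_id: int):
    code = VERTEBRATE_MITO if table_id == 2 else None
    assert code is not None, "only table 2 is cached"
    syn = nonsyn = 0.0
    aa = code.aa(codon)
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue  # dropped: neither class
            if code.aa(mutant) == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


def codon_site_counts(codon: str, code: GeneticCode = VERTEBRATE_MITO):
    """(synonymous, nonsynonymous) fractional site counts of one sense codon."""
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValueError(f"{codon} is a stop codon")
    if code.table_id == 2:
        return _site_counts_cached(codon, 2)
    syn = nonsyn = 0.0
    aa = code.aa(codon)
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            if code.aa(mutant) == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


@lru_cache(maxsize=None)
def _path_diffs_cached(a: str, b: str):
    return _path_diffs(a, b, VERTEBRATE_MITO)


def _path_diffs(a: str, b: str, code: GeneticCode):
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    valid = []
    all_paths = []
    for order in itertools.permutations(positions):
        cur = a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                through_stop = True
            if code.aa(nxt) == code.aa(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not through_stop:
            valid.append((syn, nonsyn))
    pool = valid if valid else all_paths  # fall back if every path hits a stop
    s = sum(p[0] for p in pool) / len(pool)
    n = sum(p[1] for p in pool) / len(pool)
    return s, n


def codon_path_diffs(a: str, b: str, code: GeneticCode = VERTEBRATE_MITO):
    """Average (synonymous, nonsynonymous) differences between two sense codons."""
    a, b = a.upper(), b.upper()
    if code.table_id == 2:
        return _path_diffs_cached(a, b)
    return _path_diffs(a, b, code)


def jukes_cantor(p: float) -> float | None:
    """JC69 distance -(3/4) ln(1 - 4p/3); None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _usable_codon(c: str, code: GeneticCode) -> bool:
    return all(b in BASES for b in c) and not code.is_stop(c)


def pairwise_kaks(cdsA: str, cdsB: str, code: GeneticCode = VERTEBRATE_MITO) -> PairwiseRates:
    """NG86 rates for one aligned in-frame CDS pair.

    Codons containing gaps, N, or a stop in either sequence are removed
    pairwise (complete deletion per codon); trailing partial codons ignored.
    """
    if len(cdsA) != len(cdsB):
        raise ValueError("aligned CDS pair must have equal lengths")
    cdsA, cdsB = cdsA.upper(), cdsB.upper()
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cdsA) - len(cdsA) % 3, 3):
        ca, cb = cdsA[i : i + 3], cdsB[i : i + 3]
        if not (_usable_codon(ca, code) and _usable_codon(cb, code)):
            continue
        sa, na = codon_site_counts(ca, code)
        sb, nb = codon_site_counts(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        s, n = codon_path_diffs(ca, cb, code)
        Sd += s
        Nd += n
    if S == 0 or N == 0:
        raise ValueError("no comparable codons between the pair")
    pS, pN = Sd / S, Nd / N
    Ks, Ka = jukes_cantor(pS), jukes_cantor(pN)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return PairwiseRates(S, N, Sd, Nd, pS, pN, Ks, Ka, ratio)


def gene_kaks(
    alignment: dict[str, str] | list[tuple[str, str]],
    gene: str = "",
    code: GeneticCode = VERTEBRATE_MITO,
    summary: str = "ratio_of_means",
) -> GeneRateEstimate:
    """Per-gene Ka/Ks averaged over all taxon pairs of a codon alignment.

    ``alignment`` maps taxon -> aligned CDS.  Pairs whose JC correction
    saturates are excluded and counted in ``n_excluded``.
    """
    if isinstance(alignment, dict):
        items = list(alignment.items())
    else:
        items = list(alignment)
    if len(items) < 2:
        raise ValueError("need at least two taxa")
    kas, kss, ratios = [], [], []
    excluded = 0
    for (_, a), (_, b) in itertools.combinations(items, 2):
        r = pairwise_kaks(a, b, code)
        if r.Ka is None or r.Ks is None:
            excluded += 1
            continue
        kas.append(r.Ka)
        kss.append(r.Ks)
        if r.ratio is not None:
            ratios.append(r.ratio)
    if not kas:
        raise ValueError("all pairs saturated or unusable")
    ka_mean = sum(kas) / len(kas)
    ks_mean = sum(kss) / len(kss)
    if summary == "ratio_of_means":
        ratio = ka_mean / ks_mean if ks_mean > 0 else None
    elif summary == "mean_of_ratios":
        ratio = sum(ratios) / len(ratios) if ratios else None
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return GeneRateEstimate(gene, ka_mean, ks_mean, ratio, len(kas), excluded)
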