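"""Vertebrate mitochondrial code, start/stop classification, RSCU."""

import random

import pytest

from mitochar.annotation import published_annotation
from mitochar.codons import (
    VERTEBRATE_MITO,
    classify_codons,
    extract_cds,
    format_stop,
    revcomp,
    rscu,
    translate,
)
from mitochar.simulate import SimulationSpec, default_architecture, generate_root


def test_code_table_specifics():
    code = VERTEBRATE_MITO
    assert len(code.codon_to_aa) == 64
    assert code.is_stop("AGA") and code.is_stop("AGG")
    assert code.is_stop("TAA") and code.is_stop("TAG")
    assert code.aa("TGA") == "W"
    assert code.aa("ATA") == "M"
    assert len(code.sense_codons()) == 60


def test_translate_examples():
    assert translate("ATGTGATTT") == "MWF"
    assert translate("AGA") == "*"
    assert translate("ATGTT") == "M"  # trailing partial codon ignored
    assert translate("ATGNNN") == "MX"
    with pytest.raises(ValueError):
        translate("ATGXXA")


def test_classify_simple():
    cls = classify_codons("ATGAAATAA")
    assert (cls.start_codon, cls.stop_codon) == ("ATG", "TAA")
    assert cls.warnings == []
    cls = classify_codons("CCCAAATAA")
    assert any("non-canonical" in w for w in cls.warnings)
    cls = classify_codons("ATGAAAAAA")
    assert cls.stop_codon is None and any("no terminal stop" in w for w in cls.warnings)


def test_incomplete_stop_descriptors():
    assert classify_codons("ATGAAAT").stop_codon == "T"
    assert classify_codons("ATGAAATA").stop_codon == "TA"
    assert format_stop("T") == "T(AA)"
    assert format_stop("TA") == "TA(A)"
    assert format_stop("AGA") == "AGA"


@pytest.mark.parametrize("species", ["sangzhiensis", "tuberogranulata"])
def test_classification_reproduces_published_cells(species):
    """Every printed start/stop cell, via a genome realizing that annotation."""
    g = generate_root(SimulationSpec(architecture=default_architecture(species), seed=11))
    published = published_annotation(species)
    for f in published.pcgs():
        cds = extract_cds(g, f.name)
        cls = classify_codons(cds)
        assert cls.start_codon == f.start_codon, f.name
        assert cls.stop_codon == f.stop_codon, f.name


def test_extract_cds_strand_handling(synthetic_root):
    g = synthetic_root
    nd6 = g.feature("ND6")
    h_slice = g.sequence[nd6.start - 1 : nd6.end]
    assert extract_cds(g, "ND6") == revcomp(h_slice)
    assert len(extract_cds(g, "ND5")) == 1818
    assert extract_cds(g, "ND5").startswith("ATG")
    with pytest.raises(KeyError):
        extract_cds(g, "tRNA-Phe")


def test_no_internal_stops_in_synthetic_pcgs(synthetic_root):
    for f in synthetic_root.pcgs():
        cds = extract_cds(synthetic_root, f.name)
        aa = translate(cds)
        body = aa[:-1] if len(cds) % 3 == 0 else aa
        assert "*" not in body, f.name


def test_rscu_uniform_family_is_one():
    # equal use of Leu's six codons (two on each call keeps frames trivial)
    leu = ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"]
    table = rscu(["ATG" + "".join(leu)])
    for codon in leu:
        assert table.rscu[codon] == pytest.approx(1.0)


def test_rscu_hand_formula():
    # Ala counts {GCT:2, GCC:6}: RSCU(GCC) = 6 * 4 / 8
    cds = "ATG" + "GCT" * 2 + "GCC" * 6
    table = rscu([cds])
    assert table.rscu["GCC"] == pytest.approx(3.0)
    assert table.rscu["GCT"] == pytest.approx(1.0)
    assert table.rscu["GCA"] == 0.0


def test_rscu_excludes_terminal_stop_and_partial():
    table = rscu(["ATGAAATAA", "ATGAAAT"])
    assert table.counts["TAA"] == 0
    assert table.counts["ATG"] == 2 and table.counts["AAA"] == 2


def test_rscu_family_sums(synthetic_root):
    """Sum of RSCU over each observed family equals the family size."""
    cds_set = [extract_cds(synthetic_root, f.name) for f in synthetic_root.pcgs()]
    table = rscu(cds_set)
    code = VERTEBRATE_MITO
    seen = set()
    for codon in code.sense_codons():
        aa = code.aa(codon)
        if aa in seen:
            continue
        seen.add(aa)
        fam = code.family(codon)
        if table.aa_totals[aa]:
            assert sum(table.rscu[c] for c in fam) == pytest.approx(len(fam))


def test_rscu_empty_input_rejected():
    with pytest.raises(ValueError):
        rscu([])


def test_rscu_random_fuzz_family_sums():
    rng = random.Random(9)
    sense = VERTEBRATE_MITO.sense_codons()
    cds = "ATG" + "".join(rng.choice(sense) for _ in range(500))
    table = rscu([cds])
    for aa, total in table.aa_totals.items():
        fam = [c for c in sense if VERTEBRATE_MITO.aa(c) == aa]
        if total:
            assert sum(table.rscu[c] for c in fam) == pytest.approx(len(fam))
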