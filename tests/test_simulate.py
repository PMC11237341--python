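"""Generator structure, determinism, composition targets, evolution."""

import pytest

from mitochar.annotation import AnnotationError, FeatureType, spacer_report, validate
from mitochar.codons import classify_codons, extract_cds, translate
from mitochar.simulate import (
    ArchFeature,
    SimulationSpec,
    Strand,
    balanced_tree,
    default_architecture,
    evolve,
    gene_panel_architecture,
    generate_root,
    megophryidae_taxa,
    megophryidae_tree,
)


def test_default_root_structure(synthetic_root):
    g = synthetic_root
    counts = {}
    for f in g.features:
        counts[f.ftype] = counts.get(f.ftype, 0) + 1
    assert counts[FeatureType.PCG] == 13
    assert counts[FeatureType.tRNA] == 22
    assert counts[FeatureType.rRNA] == 2
    assert counts[FeatureType.control] == 1
    assert validate(g, "strict") == []
    assert len(g) == 16950


def test_default_root_spacer_totals(synthetic_root):
    rep = spacer_report(synthetic_root)
    assert rep.overlap_bp_total == 38 and rep.overlap_pairs == 13
    assert rep.ign_bp_total == 37 and rep.ign_locations == 11


def test_generation_deterministic():
    a = generate_root(SimulationSpec(seed=123))
    b = generate_root(SimulationSpec(seed=123))
    assert a.sequence == b.sequence
    c = generate_root(SimulationSpec(seed=124))
    assert c.sequence != a.sequence


def test_composition_recovered_within_two_points(synthetic_root):
    from mitochar.composition import base_composition
    from mitochar.simulate import DEFAULT_COMPOSITION

    row = base_composition(synthetic_root.sequence)
    for base, pct in (("A", row.pctA), ("C", row.pctC), ("G", row.pctG), ("T", row.pctT)):
        assert abs(pct - 100 * DEFAULT_COMPOSITION[base]) < 2.0, base
    assert row.at_skew < 0 and row.gc_skew < 0


def test_pcg_codon_metadata_realized(synthetic_root):
    for f in synthetic_root.pcgs():
        cds = extract_cds(synthetic_root, f.name)
        cls = classify_codons(cds)
        assert (cls.start_codon, cls.stop_codon) == (f.start_codon, f.stop_codon), f.name
        aa = translate(cds)
        body = aa[:-1] if len(cds) % 3 == 0 else aa
        assert "*" not in body


def test_infeasible_architecture_rejected():
    arch = [
        ArchFeature("big", FeatureType.PCG, Strand.H, 99, -50, "ATG", "TAA"),
        ArchFeature("D-loop", FeatureType.control, Strand.H, 30, 0),
    ]
    with pytest.raises(AnnotationError):
        generate_root(SimulationSpec(architecture=arch, seed=0))


def test_spec_validation():
    with pytest.raises(ValueError):
        SimulationSpec(composition={"A": 0.5, "C": 0.5, "G": 0.5, "T": 0.5})
    with pytest.raises(ValueError):
        SimulationSpec(omega={"ND1": -0.1})


def test_zero_length_branches_leave_root_unchanged():
    spec = SimulationSpec(seed=9, tree=balanced_tree(4, 0.0))
    root = generate_root(spec)
    leaves, _ = evolve(root, spec)
    assert all(g.sequence == root.sequence for g in leaves.values())


def test_evolution_deterministic_and_annotated():
    spec = SimulationSpec(seed=10, tree=balanced_tree(4, 0.03))
    root = generate_root(spec)
    l1, _ = evolve(root, spec)
    l2, _ = evolve(root, spec)
    assert {n: g.sequence for n, g in l1.items()} == {n: g.sequence for n, g in l2.items()}
    for g in l1.values():
        assert validate(g, "strict") == []
        assert g.sequence != root.sequence


def test_evolved_pcgs_stay_clean():
    spec = SimulationSpec(seed=11, tree=balanced_tree(4, 0.08))
    root = generate_root(spec)
    leaves, _ = evolve(root, spec)
    for g in leaves.values():
        for f in g.pcgs():
            cds = extract_cds(g, f.name)
            cls = classify_codons(cds)
            assert (cls.start_codon, cls.stop_codon) == (f.start_codon, f.stop_codon)
            aa = translate(cds)
            body = aa[:-1] if len(cds) % 3 == 0 else aa
            assert "*" not in body, (g.taxon, f.name)


def test_gene_panel_architecture():
    arch = gene_panel_architecture({"g1": 100, "g2": 50})
    root = generate_root(SimulationSpec(architecture=arch, omega={"g1": 0.5, "g2": 0.5},
                                        seed=3))
    assert len(extract_cds(root, "g1")) == 303
    assert len(extract_cds(root, "g2")) == 153


def test_family_tree_fixture_shape():
    taxa = megophryidae_taxa()
    assert len(taxa) == 29
    assert "Microhyla_fissipes" in taxa
    assert megophryidae_tree().count("Boulenophrys") == 8


def test_bt_architecture_matches_published_totals():
    g = generate_root(SimulationSpec(architecture=default_architecture("tuberogranulata"),
                                     seed=4))
    rep = spacer_report(g)
    assert len(g) == 16841
    assert rep.overlap_bp_total == 44 and rep.overlap_pairs == 14
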