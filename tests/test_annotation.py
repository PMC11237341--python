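"""Interval accounting against the published annotation tables."""

import pytest

from mitochar.annotation import (
    AnnotationError,
    FeatureType,
    MitoFeature,
    MitoGenome,
    Strand,
    feature_length,
    published_annotation,
    published_length_column,
    published_spacer_column,
    rotate,
    spacer,
    spacer_report,
    validate,
)


@pytest.mark.parametrize("species", ["sangzhiensis", "tuberogranulata"])
def test_lengths_match_published_table(species):
    g = published_annotation(species)
    computed = [feature_length(f, len(g)) for f in g.features]
    assert computed == published_length_column(species)


@pytest.mark.parametrize("species", ["sangzhiensis", "tuberogranulata"])
def test_spacers_match_published_table(species):
    g = published_annotation(species)
    rep = spacer_report(g)
    assert [p[2] for p in rep.per_pair] == published_spacer_column(species)


@pytest.mark.parametrize(
    "species,overlap_bp,overlap_pairs,ign_bp,ign_locations",
    [("sangzhiensis", 38, 13, 37, 11), ("tuberogranulata", 44, 14, 33, 10)],
)
def test_spacer_aggregates(species, overlap_bp, overlap_pairs, ign_bp, ign_locations):
    rep = spacer_report(published_annotation(species))
    assert rep.overlap_bp_total == overlap_bp
    assert rep.overlap_pairs == overlap_pairs
    assert rep.ign_bp_total == ign_bp
    assert rep.ign_locations == ign_locations


def test_feature_length_cases():
    nd5 = MitoFeature("ND5", FeatureType.PCG, 11770, 13587, Strand.H, "ATG", "TAA")
    assert feature_length(nd5, 16950) == 1818
    single = MitoFeature("x", FeatureType.tRNA, 5, 5, anticodon="AAA")
    assert feature_length(single, 100) == 1
    wrap = MitoFeature("w", FeatureType.control, 16940, 10, wraps=True)
    assert feature_length(wrap, 16950) == 21
    with pytest.raises(AnnotationError):
        feature_length(nd5, 12000)


def test_spacer_sign_convention():
    atp8 = MitoFeature("ATP8", FeatureType.PCG, 7781, 7945, Strand.H, "ATG", "TAA")
    atp6 = MitoFeature("ATP6", FeatureType.PCG, 7936, 8618, Strand.H, "ATG", "TA")
    assert spacer(atp8, atp6) == -10
    a = MitoFeature("a", FeatureType.tRNA, 1, 70, anticodon="AAA")
    b = MitoFeature("b", FeatureType.tRNA, 71, 100, anticodon="CCC")
    assert spacer(a, b) == 0
    val = MitoFeature("tRNA-Val", FeatureType.tRNA, 992, 1061, anticodon="TAC")
    r16s = MitoFeature("16S", FeatureType.rRNA, 1065, 2658)
    assert spacer(val, r16s) == 3


def test_abutting_genome_has_zero_aggregates():
    feats = [
        MitoFeature(f"f{i}", FeatureType.tRNA, 1 + 10 * i, 10 + 10 * i, anticodon="AAA")
        for i in range(5)
    ]
    g = MitoGenome("toy", "T1", "A" * 50, feats, circular=True)
    rep = spacer_report(g)
    assert (rep.overlap_bp_total, rep.overlap_pairs, rep.ign_bp_total, rep.ign_locations) \
        == (0, 0, 0, 0)


@pytest.mark.parametrize("species", ["sangzhiensis", "tuberogranulata"])
def test_strict_validation_clean(species):
    assert validate(published_annotation(species), "strict") == []


def test_validation_flags_missing_pcg(bs_genome):
    g = MitoGenome(
        bs_genome.taxon,
        bs_genome.accession,
        bs_genome.sequence,
        [f for f in bs_genome.features if f.name != "ND6"],
    )
    issues = validate(g, "strict")
    assert any("missing PCG ND6" in i for i in issues)
    assert sum("missing PCG" in i for i in issues) == 1


def test_validation_flags_bad_coordinates():
    with pytest.raises(AnnotationError):
        MitoFeature("bad", FeatureType.tRNA, 50, 10, anticodon="AAA")
    g = MitoGenome("t", "X", "A" * 100,
                   [MitoFeature("far", FeatureType.tRNA, 90, 150, anticodon="AAA")])
    issues = validate(g, "lenient")
    assert len(issues) == 1 and "outside" in issues[0]


def test_tiling_identity(synthetic_root):
    """Feature lengths + gaps - overlaps tile the circle exactly once."""
    g = synthetic_root
    rep = spacer_report(g)
    total = sum(feature_length(f, len(g)) for f in g.features)
    assert total + rep.ign_bp_total - rep.overlap_bp_total == len(g)


@pytest.mark.parametrize("offset", [1, 500, 7000, 16949])
def test_spacer_report_rotation_invariant(synthetic_root, offset):
    base = spacer_report(synthetic_root)
    rot = spacer_report(rotate(synthetic_root, offset))
    assert (rot.overlap_bp_total, rot.overlap_pairs, rot.ign_bp_total, rot.ign_locations) \
        == (base.overlap_bp_total, base.overlap_pairs, base.ign_bp_total, base.ign_locations)


def test_rotation_preserves_sequence_content(synthetic_root):
    rot = rotate(synthetic_root, 1234)
    assert sorted(rot.sequence) == sorted(synthetic_root.sequence)
    assert rotate(rot, len(rot) - 1234).sequence == synthetic_root.sequence
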