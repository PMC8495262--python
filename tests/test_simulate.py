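"""The synthetic allele-family generator and its truth table."""

import json

import pytest

from srnase.annotate import translate_dna
from srnase.fragments import summarize_detection
from srnase.model import AlleleRecord
from srnase.motifs import DEFAULT_MOTIFS
from srnase.simulate import (
    FamilyConfig,
    build_ancestor,
    emit_fixture_set,
    generate_family,
    plant_lof,
    simulate_observations,
)

QUICK = dict(n_base_alleles=4, n_mutant_derivatives=0, trans_specific_fraction=0.0,
             intron_length_range=(90, 180), n_samples=3)


def test_ancestor_translation_contains_each_motif_exactly_once(ancestor):
    protein = translate_dna(ancestor.cds)
    for motif in DEFAULT_MOTIFS.values():
        assert protein.count(motif) == 1


def test_ancestor_respects_a_degenerate_intron_length_range():
    config = FamilyConfig(seed=3, intron_length_range=(100, 100), **{k: v for k, v in QUICK.items() if k != "intron_length_range"})
    anc = build_ancestor(config)
    assert anc.structure.intron_length == 100


def test_same_seed_reproduces_identical_sequences():
    a = build_ancestor(FamilyConfig(seed=9, **QUICK))
    b = build_ancestor(FamilyConfig(seed=9, **QUICK))
    assert a.record.sequence == b.record.sequence


def test_fixture_set_is_byte_identical_across_runs(tmp_path):
    config = FamilyConfig(seed=4, **QUICK)
    p1 = emit_fixture_set(config, tmp_path / "one")
    p2 = emit_fixture_set(config, tmp_path / "two")
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes(), name


def test_family_sizes_and_protein_lengths_respect_the_config(family):
    lo, hi = family.config.intron_length_range
    plo, phi = family.config.protein_length_range
    lof = {e.allele_id for e in family.truth.lof_events}
    for record in family.records:
        structure = family.truth.structures[record.allele_id]
        if record.allele_id not in lof:
            assert lo <= structure.intron_length <= hi
            protein = translate_dna(structure.coding_sequence(record.sequence))
            assert plo <= len(protein) <= phi
            assert "*" not in protein


def test_allele_ids_are_numbered_by_ascending_amplicon_size(family):
    base = [r for r in family.records if r.allele_id in family.truth.substitution_counts]
    sizes = [len(r.sequence) for r in sorted(base, key=lambda r: int(r.allele_id[1:]))]
    assert sizes == sorted(sizes)


def test_zero_trans_fraction_yields_no_homologs():
    sim = generate_family(FamilyConfig(seed=6, **QUICK))
    assert sim.homologs == [] and sim.truth.trans_pairs == []


def test_concentrated_weights_place_every_replacement_in_that_segment():
    from srnase.simulate import ancestor_comparison_events

    weights = {k: 0.0 for k in ("C2-RHV", "RHV", "RHV-C3", "C3", "C3-RC4", "RC4")}
    weights["RC4-C5"] = 1.0
    config = FamilyConfig(seed=8, region_rate_weights=weights, **QUICK)
    sim = generate_family(config)
    events = ancestor_comparison_events(sim)
    subs = [e for e in events if e.event_type == "substitution"]
    assert subs
    assert {e.region for e in subs} == {"RC4-C5"}


# ---------------------------------------------------------------------------
# planted loss-of-function events
# ---------------------------------------------------------------------------

def test_splice_lof_turns_the_acceptor_into_gg(ancestor):
    mutant, event = plant_lof(
        ancestor.record, ancestor.structure, ancestor.region_map, "splice3-AG-to-GG"
    )
    a = ancestor.structure.intron2[1]
    assert mutant.sequence[a - 2:a] == "GG"
    assert len(mutant.sequence) == len(ancestor.record.sequence)
    assert event.position == a - 2


def test_post_c2_frameshift_truncates_below_forty_residues(ancestor):
    mutant, event = plant_lof(
        ancestor.record, ancestor.structure, ancestor.region_map, "frameshift-after-C2"
    )
    from srnase.simulate import _mutant_structure_after_deletion

    structure = _mutant_structure_after_deletion(ancestor.structure, event.position)
    protein = translate_dna(structure.coding_sequence(mutant.sequence))
    stop = protein.find("*")
    assert 0 <= stop < 40


def test_lof_positions_outside_their_segment_are_rejected(ancestor):
    with pytest.raises(ValueError, match="penultimate"):
        plant_lof(ancestor.record, ancestor.structure, ancestor.region_map,
                  "splice3-AG-to-GG", position=0)
    with pytest.raises(ValueError, match="window"):
        plant_lof(ancestor.record, ancestor.structure, ancestor.region_map,
                  "frameshift-upstream-C5", position=0)
    with pytest.raises(ValueError, match="unknown lof_type"):
        plant_lof(ancestor.record, ancestor.structure, ancestor.region_map, "nonsense-type")


def test_each_lof_event_appears_in_exactly_one_allele(family):
    ids = [e.allele_id for e in family.truth.lof_events]
    assert len(ids) == len(set(ids)) == family.config.n_mutant_derivatives


# ---------------------------------------------------------------------------
# samples and observations
# ---------------------------------------------------------------------------

def test_polyploid_samples_undercount_their_alleles(family):
    table = summarize_detection(
        family.truth.sample_alleles, family.truth.allele_sizes,
        resolution_bp=family.config.gel_resolution_bp,
    )
    assert (table.undercount >= 0).all()
    assert table.undercount.sum() > 0  # 22 slots over 23 alleles at 60 bp must collide


def test_monoploid_samples_show_one_band_per_allele():
    sim = generate_family(FamilyConfig(seed=10, ploidy=1, **QUICK))
    observations = simulate_observations(sim)
    gel = [o for o in observations if o.assay == "second-intron-gel"]
    for sample_id, alleles in sim.truth.sample_alleles.items():
        n_bands = sum(1 for o in gel if o.sample_id == sample_id)
        assert n_bands == len(set(alleles)) == 1


def test_truth_json_covers_every_emitted_allele(tmp_path):
    config = FamilyConfig(seed=12, **QUICK)
    paths = emit_fixture_set(config, tmp_path)
    truth = json.loads(paths["truth"].read_text())
    from srnase.io import read_fasta

    fasta_ids = {r.allele_id for r in read_fasta(paths["fasta"])}
    assert fasta_ids <= set(truth["structures"])
    assert set(truth["sample_alleles"]) == {str(i + 1) for i in range(config.n_samples)}


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(intron_length_range=(5, 10)),
        dict(protein_length_range=(10, 20)),
        dict(region_rate_weights={"RHV": 0.0}),
        dict(trans_specific_fraction=2.0),
        dict(n_base_alleles=2, n_mutant_derivatives=3),
    ],
)
def test_invalid_configs_are_rejected(kwargs):
    with pytest.raises(ValueError):
        FamilyConfig(**kwargs)


def test_records_respect_the_dna_alphabet(family):
    for record in family.records + family.homologs:
        assert set(record.sequence) <= set("ACGT")
        AlleleRecord(record.allele_id, record.sequence)  # invariants hold
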