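"""Gene-structure annotation, splice assessment, functional calling and
codon-level substitution counting."""

import pytest

from srnase.annotate import (
    annotate_family,
    assess_splice_sites,
    count_syn_nonsyn,
    detect_intron,
    project_structure,
    translate_cds,
    translate_dna,
)
from srnase.model import AlleleRecord, GeneStructure
from srnase.motifs import default_library, locate_conserved_regions_str
from srnase.validation import planted_lof_recall, recovered_lof_class, structure_recovery_fraction


# ---------------------------------------------------------------------------
# de novo structure detection
# ---------------------------------------------------------------------------

def test_planted_intron_recovered_exactly_on_all_non_lof_alleles(family, annotations):
    assert structure_recovery_fraction(family, annotations) == 1.0


def test_detect_intron_recovers_the_ancestor(ancestor):
    found = detect_intron(ancestor.record)
    assert found.intron2 == ancestor.structure.intron2
    assert found.frame_offset == ancestor.structure.frame_offset
    assert found.is_canonical


def test_sequence_without_donor_is_unannotatable():
    # C2 encoded without any GT dinucleotide, then donor-free filler
    c2_no_gt = "TTTACAATACACGGACTATGGCCATCAAAC"
    assert "GT" not in c2_no_gt
    record = AlleleRecord("no_donor", c2_no_gt + "AAA" * 60)
    with pytest.raises(ValueError, match="unannotatable"):
        detect_intron(record)


def test_random_sequence_without_c2_is_unannotatable():
    record = AlleleRecord("no_c2", "ACGT" * 120)
    with pytest.raises(ValueError, match="unannotatable"):
        detect_intron(record)


def test_splice_mutant_detected_with_flagged_gg_acceptor(family, annotations):
    (event,) = [e for e in family.truth.lof_events if e.lof_type == "splice3-AG-to-GG"]
    record = next(r for r in family.records if r.allele_id == event.allele_id)
    structure = detect_intron(record)
    assert structure.intron2 == family.truth.structures[event.allele_id].intron2
    assert structure.splice3_dinucleotide == "GG"
    splice = assess_splice_sites(record, structure)
    assert splice.donor_ok and not splice.acceptor_ok


# ---------------------------------------------------------------------------
# translation and conserved regions
# ---------------------------------------------------------------------------

def test_functional_proteins_lie_in_the_expected_length_band(family, annotations):
    lof = {e.allele_id for e in family.truth.lof_events}
    lo, hi = family.config.protein_length_range
    for aid, ann in annotations.items():
        if aid not in lof:
            assert lo <= len(ann.protein) <= hi
            assert ann.protein.stop_position is None


def test_translation_stops_at_first_stop_codon():
    record = AlleleRecord("t", "ATGAAATAAGGG" + "GT" + "A" * 58 + "AG" + "CCC")
    structure = GeneStructure(exon2=(0, 12), intron2=(12, 74), exon3=(74, 77), frame_offset=0)
    protein = translate_cds(record, structure)
    assert protein.residues == "MK"
    assert protein.stop_position == 2


def test_region_maps_tile_every_protein(annotations):
    for ann in annotations.values():
        tiles = ann.region_map.tiling()
        covered = []
        for _, (a, b) in tiles:
            covered.extend(range(a, b))
        assert covered == list(range(ann.region_map.protein_length))


def test_located_regions_match_planted_spans(family, annotations):
    lof = {e.allele_id for e in family.truth.lof_events}
    for aid, truth_map in family.truth.region_maps.items():
        if aid in lof or aid not in annotations:
            continue
        located = annotations[aid].region_map
        for name in ("C2", "RHV", "C3", "RC4", "C5"):
            assert getattr(located, name) == getattr(truth_map, name), (aid, name)


def test_truncated_protein_loses_downstream_regions(family, annotations):
    (event,) = [e for e in family.truth.lof_events if e.lof_type == "frameshift-after-C2"]
    region_map = annotations[event.allele_id].region_map
    assert {"C3", "RC4", "C5"} <= set(region_map.missing())


# ---------------------------------------------------------------------------
# splice assessment (intron retention)
# ---------------------------------------------------------------------------

def test_retained_intron_translation_of_toy_gene():
    # exon2 ATG CCC | intron GTTAAATAGG (non-canonical GG acceptor) | exon3
    record = AlleleRecord("toy", "ATGCCC" + "GTTAAATAGG" + "GGGCCC")
    structure = GeneStructure(
        exon2=(0, 6), intron2=(6, 16), exon3=(16, 22), frame_offset=0,
        splice5_dinucleotide="GT", splice3_dinucleotide="GG",
    )
    splice = assess_splice_sites(record, structure)
    assert not splice.acceptor_ok
    retained = splice.retained_intron_translation
    # hand-translation: ATG CCC GTT AAA TAG -> M P V K stop
    assert retained.residues == "MPVK"
    assert retained.stop_position == 4
    assert retained.novel_tail_length == 2  # V and K beyond the exon2-encoded MP


def test_canonical_sites_need_no_retention_analysis(ancestor):
    splice = assess_splice_sites(ancestor.record, ancestor.structure)
    assert splice.donor_ok and splice.acceptor_ok
    assert splice.retained_intron_translation is None


# ---------------------------------------------------------------------------
# functional status over the whole family
# ---------------------------------------------------------------------------

def test_planted_lof_alleles_are_recalled_with_correct_class(family, annotations):
    assert planted_lof_recall(family, annotations) == 1.0


def test_wildtype_alleles_are_called_functional(family, annotations):
    lof = {e.allele_id for e in family.truth.lof_events}
    for aid, ann in annotations.items():
        if aid not in lof:
            assert ann.call.status == "putative-functional", aid


def test_frameshift_call_names_its_wildtype_partner(family, annotations):
    for event in family.truth.lof_events:
        if event.lof_type.startswith("frameshift"):
            call = annotations[event.allele_id].call
            assert call.status == "frameshift-truncated"
            assert call.paired_wildtype == event.parent_id


def test_projection_transfers_structure_through_the_mutation(family, annotations):
    for event in family.truth.lof_events:
        parent = annotations[event.parent_id]
        mutant_record = next(r for r in family.records if r.allele_id == event.allele_id)
        projected = project_structure(parent.record, parent.structure, mutant_record)
        assert projected.intron2 == family.truth.structures[event.allele_id].intron2


def test_lof_class_mapping_is_none_for_functional_calls(annotations, family):
    lof = {e.allele_id for e in family.truth.lof_events}
    for aid, ann in annotations.items():
        if aid not in lof:
            assert recovered_lof_class(ann) is None


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous counting
# ---------------------------------------------------------------------------

def test_identical_sequences_have_no_substitutions():
    counts = count_syn_nonsyn("ATGGGAGAA", "ATGGGAGAA")
    assert (counts.synonymous, counts.nonsynonymous, counts.indels) == (0.0, 0.0, 0)


def test_single_synonymous_codon_change():
    counts = count_syn_nonsyn("GGA", "GGG")  # both glycine
    assert (counts.synonymous, counts.nonsynonymous) == (1.0, 0.0)
    assert not counts.fractional


def test_two_hit_codon_counts_average_over_orderings():
    # GAA->GTT: via GTA (nonsyn, syn) or via GAT (nonsyn, nonsyn)
    counts = count_syn_nonsyn("GAA", "GTT")
    assert counts.synonymous == pytest.approx(0.5)
    assert counts.nonsynonymous == pytest.approx(1.5)
    assert counts.fractional


def test_exonic_indel_reported_separately():
    counts = count_syn_nonsyn("ATGAAACCCGGG", "ATGAAACCC")
    assert counts.indels == 1


def test_translate_dna_handles_ambiguity_and_tail():
    assert translate_dna("ATGNNNAAA") == "MXK"
    assert translate_dna("ATGAA") == "M"  # trailing partial codon dropped


def test_locate_regions_requires_c2():
    with pytest.raises(ValueError, match="C2"):
        locate_conserved_regions_str("A" * 140, default_library())


def test_annotate_family_rejects_unpaired_unannotatable_input():
    records = [AlleleRecord("junk1", "ACGT" * 150), AlleleRecord("junk2", "TTTT" * 150)]
    with pytest.raises(ValueError, match="unannotatable"):
        annotate_family(records)


def test_cryptic_acceptor_candidates_flank_a_defective_splice_site(family, annotations):
    from srnase.annotate import cryptic_acceptor_candidates

    (event,) = [e for e in family.truth.lof_events if e.lof_type == "splice3-AG-to-GG"]
    ann = annotations[event.allele_id]
    candidates = cryptic_acceptor_candidates(ann.record, ann.structure, window=50)
    a = ann.structure.intron2[1]
    assert a not in candidates  # the annotated (defective) acceptor itself is excluded
    assert all(abs(c - a) <= 50 for c in candidates)
    for c in candidates:
        assert ann.record.sequence[c - 2:c] == "AG"
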