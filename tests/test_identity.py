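"""Pairwise identity computation and trans-specificity classification."""

import numpy as np
import pytest

from srnase.align import identity_percent, pairwise_align
from srnase.identity import classify_trans_specific, summarize_matrix
from srnase.validation import exhaustive_alignment, trans_classification_metrics


def test_identical_sequences_are_100_percent():
    assert identity_percent(pairwise_align("ACGT", "ACGT")) == 100.0


def test_single_mismatch_is_three_quarters():
    assert identity_percent(pairwise_align("ACGT", "ACGA")) == 75.0


def test_gap_counts_as_mismatch_under_default_convention():
    alignment = pairwise_align("ACGT", "AGT")
    assert alignment.length == 4
    assert identity_percent(alignment, "columns") == 75.0
    assert identity_percent(alignment, "no-gap-columns") == 100.0
    assert identity_percent(alignment, "shorter-sequence") == 100.0


def test_protein_mode_single_replacement():
    alignment = pairwise_align("MKVLWAAL", "MKVLWAAI", mode="protein")
    counts = alignment.counts()
    assert counts.identities == 7 and counts.mismatches == 1


def test_empty_sequences_rejected():
    with pytest.raises(ValueError, match="empty"):
        pairwise_align("", "ACGT")


def test_identity_is_symmetric_under_pair_swap():
    rng = np.random.default_rng(11)
    for _ in range(20):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
        ab = identity_percent(pairwise_align(a, b))
        ba = identity_percent(pairwise_align(b, a))
        assert ab == pytest.approx(ba)


def test_aligner_matches_exhaustive_enumeration_on_short_pairs():
    rng = np.random.default_rng(7)
    for _ in range(25):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 9))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 9))))
        oracle = exhaustive_alignment(a, b)
        alignment = pairwise_align(a, b)
        assert float(alignment.score) == pytest.approx(oracle.best_score)
        ident = identity_percent(alignment)
        assert any(ident == pytest.approx(x) for x in oracle.identities)


# ---------------------------------------------------------------------------
# matrices over the synthetic family
# ---------------------------------------------------------------------------

def test_matrices_are_symmetric_with_100_diagonal(matrices):
    for level in ("exon_nt", "protein", "intron_nt"):
        m = matrices.level(level)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        assert np.allclose(np.diag(m.to_numpy()), 100.0)
        assert ((m.to_numpy() >= 0) & (m.to_numpy() <= 100)).all()


def test_introns_diverge_faster_than_exons(matrices):
    # the family evolves its intron at an elevated rate with indels, so mean
    # intron identity must fall below mean exon identity
    assert summarize_matrix(matrices.intron_nt)["mean"] < summarize_matrix(matrices.exon_nt)["mean"]


def test_planted_trans_specific_pairs_sit_above_the_support_threshold(family, matrices):
    for a, b in family.truth.trans_pairs:
        assert float(matrices.protein.loc[a, b]) >= 96.0


def test_classifier_finds_exactly_the_planted_pairs(family, annotations, matrices):
    precision, recall = trans_classification_metrics(family, annotations, matrices, tree=None)
    assert (precision, recall) == (1.0, 1.0)


def test_classifier_excludes_same_species_pairs(annotations, matrices):
    calls = classify_trans_specific(matrices, annotations, tree=None)
    for call in calls:
        assert call.species[0] != call.species[1]


def test_wildtype_mutant_amplicons_are_near_identical(family):
    # the planted derivatives differ from their parents only by the LOF event
    # plus neutral intron noise, mirroring the >97% wild-type/mutant band
    for event in family.truth.lof_events:
        parent = next(r for r in family.records if r.allele_id == event.parent_id)
        mutant = next(r for r in family.records if r.allele_id == event.allele_id)
        ident = identity_percent(pairwise_align(parent.sequence, mutant.sequence))
        assert ident >= 97.0
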