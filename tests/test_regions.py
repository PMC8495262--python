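"""Mutation-event enumeration, conservativeness classing and region profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Align import substitution_matrices

from srnase.model import RegionMap
from srnase.regions import (
    classify_replacement,
    enumerate_substitutions,
    profile_pairs,
    region_frequency_table,
    select_pairs,
)
from srnase.simulate import DEFAULT_REGION_WEIGHTS, ancestor_comparison_events

AA = "ACDEFGHIKLMNPQRSTVWY"
_PAM250 = substitution_matrices.load("PAM250")


def test_known_conservative_and_nonconservative_pairs():
    # leucine/isoleucine score positively in PAM250, glycine/tryptophan negatively
    assert classify_replacement("L", "I") == "conservative"
    assert classify_replacement("G", "W") == "non-conservative"


def test_identical_residues_are_not_a_replacement():
    with pytest.raises(ValueError, match="not a replacement"):
        classify_replacement("A", "A")


def test_nonstandard_residues_are_not_classified():
    assert classify_replacement("X", "A") == "n/a"


@settings(max_examples=100, derandomize=True)
@given(st.sampled_from(AA), st.sampled_from(AA))
def test_classification_is_symmetric_and_tracks_matrix_sign(a, b):
    if a == b:
        return
    forward = classify_replacement(a, b)
    assert forward == classify_replacement(b, a)
    expected = "non-conservative" if float(_PAM250[a, b]) < 0 else "conservative"
    assert forward == expected


# ---------------------------------------------------------------------------
# event enumeration
# ---------------------------------------------------------------------------

def _toy_map(n: int = 30) -> RegionMap:
    return RegionMap(protein_length=n, C2=(0, 5), RHV=(8, 13), C3=(15, 18), RC4=(20, 23), C5=(26, n))


def test_identical_proteins_yield_no_events():
    p = "MKVLWAALCCDDEEFFGGHHIIKKLLNNPP"
    assert enumerate_substitutions(p, p, _toy_map()) == []


def test_single_substitution_is_labelled_by_reference_region():
    a = "MKVLWAALCCDDEEFFGGHHIIKKLLNNPP"
    b = a[:21] + "W" + a[22:]  # inside RC4 (20..23)
    (event,) = enumerate_substitutions(a, b, _toy_map())
    assert event.event_type == "substitution"
    assert event.region == "RC4"
    assert (event.residue_a, event.residue_b) == ("I", "W")


def test_gap_run_collapses_to_one_indel_event():
    a = "MKVLWAALCCDDEEFFGGHHIIKKLLNNPP"
    b = a[:10] + a[13:]  # 3-residue deletion
    events = enumerate_substitutions(a, b, _toy_map())
    indels = [e for e in events if e.event_type == "indel"]
    assert len(indels) == 1
    assert len(indels[0].residue_a) == 3
    # brute-force run-length check on the alignment's gap pattern
    from srnase.align import pairwise_align
    alignment = pairwise_align(a, b, mode="protein")
    gap_cols = [ca == "-" or cb == "-" for ca, cb in zip(alignment[0], alignment[1])]
    runs = sum(1 for i, g in enumerate(gap_cols) if g and (i == 0 or not gap_cols[i - 1]))
    assert len(indels) == runs


def test_event_totals_match_column_by_column_count(family, annotations):
    ids = [r.allele_id for r in family.records[:4]]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            events = enumerate_substitutions(
                annotations[a].protein, annotations[b].protein, annotations[a].region_map
            )
            subs = [e for e in events if e.event_type == "substitution"]
            from srnase.align import pairwise_align
            alignment = pairwise_align(
                annotations[a].protein.residues, annotations[b].protein.residues, mode="protein"
            )
            expected = sum(
                1 for ca, cb in zip(alignment[0], alignment[1])
                if ca != "-" and cb != "-" and ca != cb
            )
            assert len(subs) == expected


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_profile_shares_sum_to_100_and_counts_are_conserved(family):
    events = ancestor_comparison_events(family)
    table = region_frequency_table(events)
    assert table.share_pct.sum() == pytest.approx(100.0)
    assert table.substitutions.sum() == sum(1 for e in events if e.event_type == "substitution")
    assert (table.conservative + table.non_conservative <= table.substitutions).all()


def test_profile_invariant_to_pair_order(family, annotations):
    ids = [r.allele_id for r in family.records[:5]]
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    forward = region_frequency_table(profile_pairs(annotations, pairs))
    backward = region_frequency_table(profile_pairs(annotations, list(reversed(pairs))))
    assert forward.equals(backward)


def test_all_events_in_one_region_gives_full_share():
    a = "MKVLWAALCCDDEEFFGGHHIIKKLLNNPP"
    b = a[:21] + "W" + a[22:]
    table = region_frequency_table(enumerate_substitutions(a, b, _toy_map()))
    shares = table.set_index("region").share_pct
    assert shares["RC4"] == 100.0
    assert shares.drop("RC4").sum() == 0.0


def test_empty_event_list_is_an_error():
    with pytest.raises(ValueError, match="no events"):
        region_frequency_table([])


def test_generating_weights_recovered_within_binomial_error(family):
    events = ancestor_comparison_events(family)
    subs = [e for e in events if e.event_type == "substitution"]
    n = len(subs)
    assert n >= 500
    total_w = sum(DEFAULT_REGION_WEIGHTS.values())
    for label, weight in DEFAULT_REGION_WEIGHTS.items():
        p = weight / total_w
        k = sum(1 for e in subs if e.region == label)
        se = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 3 * se, (label, k, n * p, se)


# ---------------------------------------------------------------------------
# pair selection
# ---------------------------------------------------------------------------

def test_select_pairs_floor_zero_gives_all_pairs(matrices):
    n = len(matrices.protein)
    assert len(select_pairs(matrices.protein, aa_floor=0.0)) == n * (n - 1) // 2


def test_select_pairs_above_100_keeps_only_explicit_wildtype_pairs(matrices):
    pairs = select_pairs(matrices.protein, aa_floor=100.5, wildtype_mutant_pairs=[("S1", "S2")])
    assert pairs == [("S1", "S2")]


def test_explicit_roster_overrides_selection(matrices):
    assert select_pairs(matrices.protein, explicit_pairs=[("S3", "S1")]) == [("S1", "S3")]
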