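"""Region-partitioned mutation profile over closely related allele pairs.

For each aligned pair of deduced proteins, every differing column becomes a
MutationEvent carrying the structural region of the reference sequence
(conserved blocks C2/C3/RC4/C5, the hypervariable RHV, and the four
inter-region segments).  Amino-acid replacements are classed conservative or
non-conservative by the sign of their PAM score; runs of consecutive gap
columns collapse to single indel events, which are tallied separately
because gaps carry no PAM score.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional, Sequence

import pandas as pd
from Bio.Align import substitution_matrices

from . import align as _align
from .model import AlleleAnnotation, DeducedProtein, MutationEvent, RegionMap, REGION_ORDER


@lru_cache(maxsize=None)
def _matrix(name: str):
    return substitution_matrices.load(name)


def classify_replacement(residue_a: str, residue_b: str, matrix_name: str = "PAM250") -> str:
    """conservative (score >= 0) vs non-conservative (score < 0); symmetric."""
    if residue_a == residue_b:
        raise ValueError(f"{residue_a}->{residue_b} is not a replacement")
    try:
        score = float(_matrix(matrix_name)[residue_a, residue_b])
    except (KeyError, IndexError):
        return "n/a"
    if residue_a not in "ACDEFGHIKLMNPQRSTVWY" or residue_b not in "ACDEFGHIKLMNPQRSTVWY":
        return "n/a"
    return "non-conservative" if score < 0 else "conservative"


def enumerate_substitutions(
    protein_a: DeducedProtein | str,
    protein_b: DeducedProtein | str,
    region_map_a: RegionMap,
    pair_id: str = "",
    matrix_name: str = "PAM250",
) -> list[MutationEvent]:
    """All difference events between two proteins, labelled in A's coordinates.

    The first (reference) sequence provides region labels; an insertion into
    the reference inherits the label of the last reference residue before it.
    """
    if region_map_a is None:
        raise ValueError("a region map for the reference protein is required")
    seq_a = protein_a.residues if isinstance(protein_a, DeducedProtein) else protein_a
    seq_b = protein_b.residues if isinstance(protein_b, DeducedProtein) else protein_b
    alignment = _align.pairwise_align(seq_a, seq_b, mode="protein")
    col_a, col_b = alignment[0], alignment[1]

    events: list[MutationEvent] = []
    ref_pos = -1
    gap_run: Optional[dict] = None
    for col, (ca, cb) in enumerate(zip(col_a, col_b)):
        if ca != "-":
            ref_pos += 1
        if ca == "-" or cb == "-":
            if gap_run is None:
                gap_run = {"column": col, "a": "", "b": "", "ref": max(ref_pos, 0)}
            gap_run["a"] += ca
            gap_run["b"] += cb
            continue
        if gap_run is not None:
            events.append(_indel_event(pair_id, gap_run, region_map_a))
            gap_run = None
        if ca != cb:
            events.append(
                MutationEvent(
                    pair_id=pair_id,
                    column=col,
                    region=region_map_a.label(min(ref_pos, region_map_a.protein_length - 1)),
                    residue_a=ca,
                    residue_b=cb,
                    event_type="substitution",
                    conservativeness=classify_replacement(ca, cb, matrix_name),
                )
            )
    if gap_run is not None:
        events.append(_indel_event(pair_id, gap_run, region_map_a))
    return events


def _indel_event(pair_id: str, run: dict, region_map: RegionMap) -> MutationEvent:
    ref = min(run["ref"], region_map.protein_length - 1)
    return MutationEvent(
        pair_id=pair_id,
        column=run["column"],
        region=region_map.label(ref),
        residue_a=run["a"],
        residue_b=run["b"],
        event_type="indel",
        conservativeness="n/a",
    )


def region_frequency_table(events: Sequence[MutationEvent]) -> pd.DataFrame:
    """Per-region substitution/indel counts, substitution shares and
    non-conservative ratios.  Shares are over substitution events only;
    raw fractions are kept and rounding happens at report time."""
    if not events:
        raise ValueError("no events")
    labels = list(REGION_ORDER) + sorted(
        {e.region for e in events} - set(REGION_ORDER)
    )
    rows = []
    total_subs = sum(1 for e in events if e.event_type == "substitution")
    for label in labels:
        here = [e for e in events if e.region == label]
        subs = [e for e in here if e.event_type == "substitution"]
        indels = [e for e in here if e.event_type == "indel"]
        noncons = sum(1 for e in subs if e.conservativeness == "non-conservative")
        cons = sum(1 for e in subs if e.conservativeness == "conservative")
        rows.append(
            {
                "region": label,
                "substitutions": len(subs),
                "indels": len(indels),
                "share_pct": 100.0 * len(subs) / total_subs if total_subs else 0.0,
                "conservative": cons,
                "non_conservative": noncons,
                "non_conservative_pct": 100.0 * noncons / len(subs) if subs else 0.0,
            }
        )
    return pd.DataFrame(rows)


def select_pairs(
    aa_matrix: pd.DataFrame,
    aa_floor: float = 80.0,
    wildtype_mutant_pairs: Sequence[tuple[str, str]] = (),
    explicit_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> list[tuple[str, str]]:
    """Pairs entering the mutation profile.

    Default: every pair at or above ``aa_floor`` percent deduced-AA identity,
    plus all wild-type/mutant pairs.  An explicit roster overrides everything.
    """
    if explicit_pairs is not None:
        return sorted(tuple(sorted(p)) for p in explicit_pairs)
    ids = list(aa_matrix.index)
    pairs = {
        tuple(sorted((a, b)))
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
        if float(aa_matrix.loc[a, b]) >= aa_floor
    }
    pairs.update(tuple(sorted(p)) for p in wildtype_mutant_pairs)
    return sorted(pairs)


def profile_pairs(
    annotations: dict[str, AlleleAnnotation],
    pairs: Sequence[tuple[str, str]],
    matrix_name: str = "PAM250",
) -> list[MutationEvent]:
    """Enumerate events over a pair roster; the lexicographically first allele
    of each pair is the reference providing region labels."""
    events: list[MutationEvent] = []
    for a, b in pairs:
        ref, other = sorted((a, b))
        events.extend(
            enumerate_substitutions(
                annotations[ref].protein,
                annotations[other].protein,
                annotations[ref].region_map,
                pair_id=f"{ref}|{other}",
                matrix_name=matrix_name,
            )
        )
    return events
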