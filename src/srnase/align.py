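"""Pairwise global alignment and percent-identity computation.

Protein alignments are scored with PAM250 (the matrix family used throughout
the package for conservativeness classification as well); DNA alignments use
a simple match/mismatch scheme.  Both use affine gap penalties in the
ClustalW tradition.  Identity defaults to matches over alignment columns
carrying at least one residue, with gaps counting as mismatches; alternative
denominator conventions are selectable and recorded by callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: default alignment parameters, exposed for the run manifest
PROTEIN_PARAMS = {"matrix": "PAM250", "open": -10.0, "extend": -0.5}
DNA_PARAMS = {"match": 2.0, "mismatch": -1.0, "open": -10.0, "extend": -0.2}

IDENTITY_CONVENTIONS = ("columns", "no-gap-columns", "shorter-sequence")


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load(PROTEIN_PARAMS["matrix"])
        aligner.open_gap_score = PROTEIN_PARAMS["open"]
        aligner.extend_gap_score = PROTEIN_PARAMS["extend"]
    elif mode == "dna":
        aligner.match_score = DNA_PARAMS["match"]
        aligner.mismatch_score = DNA_PARAMS["mismatch"]
        aligner.open_gap_score = DNA_PARAMS["open"]
        aligner.extend_gap_score = DNA_PARAMS["extend"]
    else:
        raise ValueError(f"mode must be 'dna' or 'protein', got {mode!r}")
    return aligner


def pairwise_align(seq_a: str, seq_b: str, mode: str = "dna") -> Align.Alignment:
    """Global affine-gap alignment; deterministic (first optimal alignment)."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    if mode == "protein":
        seq_a, seq_b = seq_a.replace("*", "X"), seq_b.replace("*", "X")
    return _aligner(mode).align(seq_a, seq_b)[0]


def alignment_score(seq_a: str, seq_b: str, mode: str = "dna") -> float:
    if mode == "protein":
        seq_a, seq_b = seq_a.replace("*", "X"), seq_b.replace("*", "X")
    return float(_aligner(mode).score(seq_a, seq_b))


def identity_percent(alignment: Align.Alignment, denominator_convention: str = "columns") -> float:
    """Percent identity of a pairwise alignment under a stated convention.

    ``columns``            matches / columns with >= 1 residue (gaps mismatch)
    ``no-gap-columns``     matches / columns where both sequences have residues
    ``shorter-sequence``   matches / length of the shorter sequence
    """
    if alignment.length == 0:
        raise ValueError("zero-length alignment")
    counts = alignment.counts()
    matches = counts.identities
    if denominator_convention == "columns":
        denom = alignment.length  # pairwise global: every column holds a residue
    elif denominator_convention == "no-gap-columns":
        denom = counts.identities + counts.mismatches
    elif denominator_convention == "shorter-sequence":
        denom = min(len(alignment.sequences[0]), len(alignment.sequences[1]))
    else:
        raise ValueError(f"unknown denominator convention {denominator_convention!r}")
    if denom == 0:
        raise ValueError("identity denominator is zero")
    return 100.0 * matches / denom


@dataclass(frozen=True)
class AlignmentParameters:
    """Record of the parameters behind a set of identity matrices."""

    protein_matrix: str = PROTEIN_PARAMS["matrix"]
    protein_gap_open: float = PROTEIN_PARAMS["open"]
    protein_gap_extend: float = PROTEIN_PARAMS["extend"]
    dna_match: float = DNA_PARAMS["match"]
    dna_mismatch: float = DNA_PARAMS["mismatch"]
    dna_gap_open: float = DNA_PARAMS["open"]
    dna_gap_extend: float = DNA_PARAMS["extend"]
    identity_denominator: str = "columns"
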