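"""Conserved-region motif library and placement on deduced proteins.

Rosaceous S-RNases carry conserved amino-acid blocks (C2, C3, RC4, C5) with
the rosaceous hypervariable region (RHV) between C2 and C3.  The amplicons
analysed here start inside C2 and end at the C-terminal edge of C5.  Regions
are located by ungapped similarity against editable consensus motifs scored
with a PAM-family matrix; a region scoring below its threshold (a fraction of
the consensus self-score) is reported absent.

The default consensus motifs ship with the package and are synthetic: they
keep the universally conserved RNase T2 catalytic cores (HGLWP in C2, KHG in
C3) inside otherwise invented context, which is what the bundled family
simulator also uses.  For real data, load a library derived from a curated
alignment via :func:`load_motif_library`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from Bio.Align import substitution_matrices

from .model import RegionMap, Span

_PAM250 = substitution_matrices.load("PAM250")
_PAM_DICT: dict[tuple[str, str], float] = {
    (a, b): float(_PAM250[a, b]) for a in _PAM250.alphabet for b in _PAM250.alphabet
}


def pam_score(a: str, b: str, matrix=None) -> float:
    """Score one residue pair; unknown residues (X, gaps) score 0."""
    if matrix is None:
        return _PAM_DICT.get((a, b), 0.0)
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError):
        return 0.0


@dataclass
class MotifLibrary:
    """Consensus patterns, score thresholds and RHV placement offsets."""

    motifs: dict[str, str]
    #: minimum fraction of the consensus self-score for a region to be "present"
    threshold: float = 0.6
    #: residues between the end of C2 and the start of RHV
    rhv_offset: int = 4
    rhv_length: int = 13

    def __post_init__(self) -> None:
        for name in ("C2", "C3", "RC4", "C5"):
            if not self.motifs.get(name):
                raise ValueError(f"motif library must define {name}")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")

    def self_score(self, name: str) -> float:
        motif = self.motifs[name]
        return sum(pam_score(c, c) for c in motif)

    def window_score(self, name: str, window: str) -> float:
        motif = self.motifs[name]
        return sum(pam_score(a, b) for a, b in zip(motif, window))

    def best_placement(
        self, name: str, protein: str, start: int = 0, stop: Optional[int] = None
    ) -> tuple[Optional[Span], float]:
        """Best-scoring ungapped placement of ``name`` within protein[start:stop].

        Returns (span, score); span is ``None`` when no window reaches the
        threshold.  Ties resolve to the leftmost position.
        """
        motif = self.motifs[name]
        k = len(motif)
        stop = len(protein) if stop is None else stop
        best: tuple[float, int] = (float("-inf"), -1)
        for pos in range(start, stop - k + 1):
            s = self.window_score(name, protein[pos:pos + k])
            if s > best[0]:
                best = (s, pos)
        score, pos = best
        if pos < 0 or score < self.threshold * self.self_score(name):
            return None, score if pos >= 0 else float("-inf")
        return (pos, pos + k), score


#: Default synthetic consensus library (see module docstring).
DEFAULT_MOTIFS = {
    "C2": "FTIHGLWPSN",
    "C3": "WNKHGTCSEQ",
    "RC4": "PKQAIWKYSD",
    "C5": "DYNAGKEFWC",
}


def default_library(**overrides) -> MotifLibrary:
    return MotifLibrary(motifs=dict(DEFAULT_MOTIFS), **overrides)


def load_motif_library(path: str | Path) -> MotifLibrary:
    """Load a motif library from YAML (keys: motifs, threshold, rhv_offset, rhv_length)."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    unknown = set(data) - {"motifs", "threshold", "rhv_offset", "rhv_length"}
    if unknown:
        raise ValueError(f"unknown motif library keys: {sorted(unknown)}")
    return MotifLibrary(
        motifs=dict(data.get("motifs", DEFAULT_MOTIFS)),
        threshold=float(data.get("threshold", 0.6)),
        rhv_offset=int(data.get("rhv_offset", 4)),
        rhv_length=int(data.get("rhv_length", 13)),
    )


def dump_motif_library(library: MotifLibrary, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(
            {
                "motifs": library.motifs,
                "threshold": library.threshold,
                "rhv_offset": library.rhv_offset,
                "rhv_length": library.rhv_length,
            },
            handle,
            sort_keys=True,
        )


def total_motif_score(protein: str, library: MotifLibrary) -> float:
    """Summed best ordered placement score of C2, C3, RC4, C5 (for ranking splices)."""
    regions = locate_conserved_regions_str(protein, library, require_c2=False)
    total = 0.0
    for name in ("C2", "C3", "RC4", "C5"):
        span = getattr(regions, name)
        if span is not None:
            total += regions_score(protein, library, name, span)
    return total


def regions_score(protein: str, library: MotifLibrary, name: str, span: Span) -> float:
    return library.window_score(name, protein[span[0]:span[1]])


def locate_conserved_regions_str(
    protein: str, library: MotifLibrary, require_c2: bool = True
) -> RegionMap:
    """Place C2, C3, RC4, C5 (ordered, non-overlapping, jointly optimal) and RHV.

    C2 is anchored at the protein start (the amplicon begins inside C2; up to
    two leading residues of slack are allowed).  RHV is assigned positionally
    downstream of C2 using the library offsets and must end before C3 starts
    (or fit inside the protein when C3 is absent).  Raises ``ValueError`` when
    C2 cannot be found and ``require_c2`` is set.
    """
    n = len(protein)
    c2_motif = library.motifs["C2"]
    c2_span, _ = _best_anchored(protein, library, "C2", max_start=2)
    if c2_span is None:
        if require_c2:
            raise ValueError("C2 region not found at protein start (unannotatable)")
        return RegionMap(protein_length=n)

    # Joint ordered placement of C3, RC4, C5 after C2: enumerate above-threshold
    # candidates per motif (few in practice) and take the max-score ordered chain,
    # allowing any subset to be absent.
    candidates: dict[str, list[tuple[Span, float]]] = {}
    for name in ("C3", "RC4", "C5"):
        k = len(library.motifs[name])
        thr = library.threshold * library.self_score(name)
        cands = []
        for pos in range(c2_span[1], n - k + 1):
            s = library.window_score(name, protein[pos:pos + k])
            if s >= thr:
                cands.append(((pos, pos + k), s))
        candidates[name] = cands

    best_total = float("-inf")
    best_choice: dict[str, Optional[Span]] = {"C3": None, "RC4": None, "C5": None}
    names = ("C3", "RC4", "C5")

    def recurse(i: int, min_start: int, total: float, chosen: dict[str, Optional[Span]]):
        nonlocal best_total, best_choice
        if i == len(names):
            if total > best_total:
                best_total = total
                best_choice = dict(chosen)
            return
        name = names[i]
        chosen[name] = None
        recurse(i + 1, min_start, total, chosen)
        for span, score in candidates[name]:
            if span[0] >= min_start:
                chosen[name] = span
                recurse(i + 1, span[1], total + score, chosen)
        chosen[name] = None

    recurse(0, c2_span[1], 0.0, {})

    c3 = best_choice["C3"]
    rhv_start = c2_span[1] + library.rhv_offset
    rhv_end = rhv_start + library.rhv_length
    downstream = [s for s in (best_choice["C3"], best_choice["RC4"], best_choice["C5"]) if s]
    limit = min((s[0] for s in downstream), default=n)
    rhv: Optional[Span] = (rhv_start, rhv_end) if rhv_end <= limit else None

    return RegionMap(
        protein_length=n,
        C2=c2_span,
        RHV=rhv,
        C3=c3,
        RC4=best_choice["RC4"],
        C5=best_choice["C5"],
    )


def _best_anchored(
    protein: str, library: MotifLibrary, name: str, max_start: int
) -> tuple[Optional[Span], float]:
    k = len(library.motifs[name])
    thr = library.threshold * library.self_score(name)
    best: tuple[float, int] = (float("-inf"), -1)
    for pos in range(0, min(max_start, max(0, len(protein) - k)) + 1):
        if pos + k > len(protein):
            break
        s = library.window_score(name, protein[pos:pos + k])
        if s > best[0]:
            best = (s, pos)
    score, pos = best
    if pos < 0 or score < thr:
        return None, score
    return (pos, pos + k), score
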