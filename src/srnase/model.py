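"""Domain types shared by every stage of the S-RNase characterization pipeline.

Coordinates are 0-based half-open throughout; 1-based numbers appear only in
human-readable reports.  An "amplicon" is the genomic fragment spanning the
second conserved region (C2) through the fifth (C5) of a *Prunus*-type
S-RNase, containing the full, highly length-polymorphic second intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Span = tuple[int, int]

DNA_ALPHABET = set("ACGTN")

#: Canonical ordering of named protein regions and the segments between them.
REGION_ORDER = ("C2", "C2-RHV", "RHV", "RHV-C3", "C3", "C3-RC4", "RC4", "RC4-C5", "C5")
NAMED_REGIONS = ("C2", "RHV", "C3", "RC4", "C5")
SEGMENTS = ("C2-RHV", "RHV-C3", "C3-RC4", "RC4-C5")


@dataclass(frozen=True)
class AlleleRecord:
    """One cloned amplicon (e.g. the "S1" allele of one accession)."""

    allele_id: str
    sequence: str
    sample_id: str = ""
    accession: Optional[str] = None
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.allele_id:
            raise ValueError("allele_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.allele_id}: empty sequence")
        bad = [i for i, c in enumerate(self.sequence) if c not in DNA_ALPHABET]
        if bad:
            raise ValueError(
                f"{self.allele_id}: non-IUPAC character {self.sequence[bad[0]]!r} "
                f"at position {bad[0]}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneStructure:
    """Exon2 / intron2 / exon3 spans on the amplicon plus the reading frame.

    ``frame_offset`` is the number of bases preceding the first complete codon
    of exon 2 (the amplified fragment may start mid-codon).
    """

    exon2: Span
    intron2: Span
    exon3: Span
    frame_offset: int
    splice5_dinucleotide: str = "GT"
    splice3_dinucleotide: str = "AG"

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
        e2, i2, e3 = self.exon2, self.intron2, self.exon3
        if not (e2[0] < e2[1] == i2[0] < i2[1] == e3[0] < e3[1]):
            raise ValueError(f"spans must be contiguous and ordered: {e2}, {i2}, {e3}")

    @property
    def intron_length(self) -> int:
        return self.intron2[1] - self.intron2[0]

    @property
    def is_canonical(self) -> bool:
        return self.splice5_dinucleotide == "GT" and self.splice3_dinucleotide == "AG"

    def coding_sequence(self, sequence: str) -> str:
        """Spliced exon2+exon3 sequence (frame offset *not* removed)."""
        return sequence[self.exon2[0]:self.exon2[1]] + sequence[self.exon3[0]:self.exon3[1]]


@dataclass(frozen=True)
class DeducedProtein:
    """Conceptual translation of the spliced (or intron-retaining) transcript."""

    residues: str
    stop_position: Optional[int] = None
    novel_tail_length: int = 0

    def __post_init__(self) -> None:
        if "*" in self.residues:
            raise ValueError("residues must not contain internal stop characters")
        if self.novel_tail_length < 0:
            raise ValueError("novel_tail_length must be >= 0")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RegionMap:
    """Named spans of the conserved regions and RHV on a deduced protein.

    Absent regions (e.g. C5 lost to a frameshift) are ``None``.  The
    inter-region segments are derived by complementation so that every residue
    belongs to exactly one label of :data:`REGION_ORDER`.
    """

    protein_length: int
    C2: Optional[Span] = None
    RHV: Optional[Span] = None
    C3: Optional[Span] = None
    RC4: Optional[Span] = None
    C5: Optional[Span] = None

    def __post_init__(self) -> None:
        last = -1
        for name in NAMED_REGIONS:
            span = getattr(self, name)
            if span is None:
                continue
            if span[0] < 0 or span[1] > self.protein_length or span[0] >= span[1]:
                raise ValueError(f"{name}: invalid span {span}")
            if span[0] <= last:
                raise ValueError(f"{name}: spans must be ordered and non-overlapping")
            last = span[1] - 1

    def present(self) -> list[str]:
        return [n for n in NAMED_REGIONS if getattr(self, n) is not None]

    def missing(self) -> list[str]:
        return [n for n in NAMED_REGIONS if getattr(self, n) is None]

    def tiling(self) -> list[tuple[str, Span]]:
        """Ordered (label, span) tiles covering the whole protein.

        Gaps between consecutive present regions get the canonical segment
        label when the flanking regions are canonical neighbours, otherwise a
        descriptive ``"X-Y"`` label (this only arises on truncated proteins).
        """
        tiles: list[tuple[str, Span]] = []
        pos = 0
        present = [(n, getattr(self, n)) for n in NAMED_REGIONS if getattr(self, n) is not None]
        prev_name = None
        for name, span in present:
            if span[0] > pos:
                tiles.append((_segment_label(prev_name, name), (pos, span[0])))
            tiles.append((name, span))
            pos = span[1]
            prev_name = name
        if pos < self.protein_length:
            tiles.append((_segment_label(prev_name, None), (pos, self.protein_length)))
        return tiles

    def label(self, residue_index: int) -> str:
        if not 0 <= residue_index < self.protein_length:
            raise IndexError(f"residue index {residue_index} outside protein")
        for name, (a, b) in self.tiling():
            if a <= residue_index < b:
                return name
        raise AssertionError("tiling does not cover the protein")  # pragma: no cover


def _segment_label(prev: Optional[str], nxt: Optional[str]) -> str:
    """Canonical inter-region label for the gap between two named regions."""
    order = list(NAMED_REGIONS)
    if prev is None:
        prev = "C2"  # amplicons start in C2; a leading gap sits before it
        return f"start-{nxt}" if nxt not in (None, "C2") else "C2-RHV"
    i = order.index(prev)
    expected = order[i + 1] if i + 1 < len(order) else None
    if nxt == expected or nxt is None:
        nxt = expected
    if nxt is None:
        return f"{prev}-end"
    seg = f"{prev}-{nxt}"
    return seg


FUNCTIONAL_STATUSES = (
    "putative-functional",
    "frameshift-truncated",
    "premature-stop",
    "splice-defect",
)


@dataclass(frozen=True)
class FunctionalCall:
    """Per-allele loss-of-function verdict with its supporting evidence."""

    status: str
    missing_regions: tuple[str, ...] = ()
    evidence: str = ""
    paired_wildtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in FUNCTIONAL_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "putative-functional" and self.missing_regions:
            raise ValueError("putative-functional calls cannot have missing regions")
        for r in self.missing_regions:
            if r not in ("RHV", "C3", "RC4", "C5"):
                raise ValueError(f"invalid missing region {r!r}")


@dataclass(frozen=True)
class FragmentObservation:
    """One sized fragment of one sample, from either genotyping assay."""

    sample_id: str
    fragment_size: int
    assay: str  # "second-intron-gel" | "first-intron-capillary"
    intensity_note: str = ""

    def __post_init__(self) -> None:
        if self.fragment_size <= 0:
            raise ValueError(f"fragment_size must be positive, got {self.fragment_size}")
        if self.assay not in ("second-intron-gel", "first-intron-capillary"):
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass(frozen=True)
class MutationEvent:
    """One difference column between an aligned pair of deduced proteins."""

    pair_id: str
    column: int
    region: str
    residue_a: str
    residue_b: str
    event_type: str  # "substitution" | "indel"
    conservativeness: str  # "conservative" | "non-conservative" | "n/a"

    def __post_init__(self) -> None:
        if self.event_type not in ("substitution", "indel"):
            raise ValueError(f"bad event_type {self.event_type!r}")
        if self.event_type == "substitution":
            if self.conservativeness not in ("conservative", "non-conservative", "n/a"):
                raise ValueError(f"bad conservativeness {self.conservativeness!r}")
        elif self.conservativeness != "n/a":
            raise ValueError("indel events carry no conservativeness class")


@dataclass
class SpliceAssessment:
    """Donor/acceptor check plus the intron-retention translation, if relevant."""

    donor_ok: bool
    acceptor_ok: bool
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    retained_intron_translation: Optional[DeducedProtein] = None

    def __post_init__(self) -> None:
        if self.acceptor_ok != (self.acceptor_dinucleotide == "AG"):
            raise ValueError("acceptor_ok must mirror acceptor_dinucleotide == 'AG'")


@dataclass
class AlleleAnnotation:
    """Bundle of everything the pipeline derives for one allele."""

    record: AlleleRecord
    structure: GeneStructure
    protein: DeducedProtein
    region_map: RegionMap
    splice: SpliceAssessment
    call: Optional[FunctionalCall] = None
    structure_source: str = "de-novo"  # or "projected:<wildtype id>"
    notes: list[str] = field(default_factory=list)
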