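"""Gene-structure annotation and loss-of-function classification.

The amplicons span C2..C5 and contain one intron (the length-polymorphic
"second intron" of Prunus S-RNase genes).  De novo annotation searches for
the GT..AG interval whose removal yields a translation that starts in C2 and
maximizes the summed conserved-motif score; exact ties on that score are
resolved with a minimal splice-context model (donor GTAAGT consensus and the
3' polypyrimidine tract), which is what distinguishes the genuine acceptor
from phase-compatible AG dinucleotides in flanking exon sequence.

Mutant alleles whose own translation is disrupted are annotated by projecting
the gene structure of a near-identical wild-type partner through a DNA
alignment, mirroring how allelic frameshifts are characterized in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

from Bio.Data import CodonTable

from . import align as _align
from .model import (
    AlleleAnnotation,
    AlleleRecord,
    DeducedProtein,
    FunctionalCall,
    GeneStructure,
    RegionMap,
    SpliceAssessment,
)
from .motifs import MotifLibrary, default_library, locate_conserved_regions_str

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODONS[_stop] = "*"

DONOR_CONSENSUS = "GTAAGT"
ACCEPTOR_TRACT_WINDOW = 16  # nt upstream of the terminal dinucleotide


def translate_dna(seq: str) -> str:
    """Translate (standard code); ambiguous codons become X, stops are '*'.

    Trailing bases short of a full codon are ignored.
    """
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(_CODONS.get(seq[i:i + 3], "X"))
    return "".join(out)


def _translate_to_stop(seq: str) -> tuple[str, Optional[int]]:
    """Translate until the first stop codon; returns (residues, stop_index)."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = _CODONS.get(seq[i:i + 3], "X")
        if aa == "*":
            return "".join(out), len(out)
        out.append(aa)
    return "".join(out), None


# ---------------------------------------------------------------------------
# de novo intron detection
# ---------------------------------------------------------------------------

def _donor_context_score(seq: str, d: int) -> float:
    window = seq[d:d + len(DONOR_CONSENSUS)]
    return 0.5 * sum(1 for a, b in zip(window[2:], DONOR_CONSENSUS[2:]) if a == b)


def _acceptor_context_score(seq: str, a: int) -> float:
    window = seq[max(0, a - 2 - ACCEPTOR_TRACT_WINDOW):a - 2]
    if not window:
        return 0.0
    return 4.0 * sum(1 for c in window if c in "CT") / len(window)


@dataclass
class _Candidate:
    donor: int
    acceptor_end: int
    protein: str
    stop: Optional[int]
    motif_score: float
    context_score: float

    @property
    def score(self) -> float:
        return self.motif_score + self.context_score


def detect_intron(
    record: AlleleRecord,
    library: Optional[MotifLibrary] = None,
    min_intron_length: int = 60,
    min_exon3_length: int = 30,
    acceptor_relaxation: bool = True,
) -> GeneStructure:
    """Locate the intron of one amplicon de novo.

    Raises ``ValueError`` ("unannotatable") when no reading frame matches C2
    or no GT donor exists, and when several non-equivalent candidates score
    identically.
    """
    library = library or default_library()
    seq = record.sequence
    n = len(seq)
    c2 = library.motifs["C2"]

    # reading frame: translate each frame's prefix and anchor C2 at the start
    frame = None
    best_frame_score = float("-inf")
    for f in (0, 1, 2):
        prefix = translate_dna(seq[f:f + 3 * (len(c2) + 3)])
        span, score = library.best_placement("C2", prefix.replace("*", "X"), 0, min(len(prefix), len(c2) + 2))
        if span is not None and score > best_frame_score:
            best_frame_score = score
            frame = f
    if frame is None:
        raise ValueError(f"{record.allele_id}: unannotatable (no reading frame matches C2)")

    # donors: GT positions inside the stop-free part of exon 2, after C2
    donor_min = frame + 3 * len(c2)
    prefix_protein, first_stop = _translate_to_stop(seq[frame:])
    donor_max = n if first_stop is None else frame + 3 * first_stop + 2
    donors = [
        d for d in range(donor_min, min(donor_max, n - min_intron_length - min_exon3_length) + 1)
        if seq[d:d + 2] == "GT"
    ]
    if "GT" not in seq:
        raise ValueError(f"{record.allele_id}: unannotatable (no GT donor in sequence)")
    if not donors:
        raise ValueError(f"{record.allele_id}: unannotatable (no usable GT donor after C2)")

    def evaluate(d: int, a: int) -> _Candidate:
        spliced = seq[:d] + seq[a:]
        protein, stop = _translate_to_stop(spliced[frame:])
        from .motifs import total_motif_score
        return _Candidate(
            donor=d,
            acceptor_end=a,
            protein=protein,
            stop=stop,
            motif_score=total_motif_score(protein, library),
            context_score=_donor_context_score(seq, d) + _acceptor_context_score(seq, a),
        )

    def search(acceptor_ends: Sequence[int]) -> tuple[Optional[_Candidate], list[_Candidate]]:
        best: Optional[_Candidate] = None
        ties: list[_Candidate] = []
        for d in donors:
            for a in acceptor_ends:
                if a - d < min_intron_length or a > n - min_exon3_length:
                    continue
                cand = evaluate(d, a)
                if best is None or cand.score > best.score + 1e-9:
                    best, ties = cand, [cand]
                elif abs(cand.score - best.score) <= 1e-9:
                    ties.append(cand)
        return best, ties

    def resolve(best: Optional[_Candidate], ties: list[_Candidate]) -> Optional[_Candidate]:
        if best is None or len(ties) <= 1:
            return best
        spliced = {seq[:c.donor] + seq[c.acceptor_end:] for c in ties}
        if len(spliced) > 1:
            listing = ", ".join(f"({c.donor},{c.acceptor_end})" for c in ties)
            raise ValueError(
                f"{record.allele_id}: ambiguous intron placement, equally scoring "
                f"candidates: {listing}"
            )
        return min(ties, key=lambda c: c.donor)  # intron sliding: same spliced product

    ag_ends = [i + 2 for i in range(n - 1) if seq[i:i + 2] == "AG"]
    best, best_ties = search(ag_ends)

    def is_full(cand: Optional[_Candidate]) -> bool:
        if cand is None:
            return False
        regions = locate_conserved_regions_str(cand.protein, library, require_c2=False)
        return not regions.missing() and cand.stop is None

    def needs_relaxation(cand: Optional[_Candidate], ties: list[_Candidate]) -> bool:
        if not is_full(cand):
            return True
        if len({seq[:c.donor] + seq[c.acceptor_end:] for c in ties}) > 1:
            return True  # ambiguous canonical winners: look for a decisive acceptor
        return _acceptor_context_score(seq, cand.acceptor_end) < 3.5

    if acceptor_relaxation and needs_relaxation(best, best_ties):
        # non-canonical acceptor pass: any *G end, penalized, only adopted when
        # it restores a complete stop-free product
        g_ends = [i + 1 for i in range(1, n) if seq[i] == "G" and seq[i - 1] != "A"]
        relaxed, relaxed_ties = search(g_ends)
        if is_full(relaxed) and (best is None or relaxed.score - 2.0 > best.score):
            best, best_ties = relaxed, relaxed_ties
    best = resolve(best, best_ties)
    if best is None:
        raise ValueError(f"{record.allele_id}: unannotatable (no intron candidate)")

    d, a = best.donor, best.acceptor_end
    return GeneStructure(
        exon2=(0, d),
        intron2=(d, a),
        exon3=(a, n),
        frame_offset=frame,
        splice5_dinucleotide=seq[d:d + 2],
        splice3_dinucleotide=seq[a - 2:a],
    )


# ---------------------------------------------------------------------------
# translation / regions / splice assessment
# ---------------------------------------------------------------------------

def translate_cds(record: AlleleRecord, structure: GeneStructure) -> DeducedProtein:
    """Translate the spliced exons from the structure's frame offset."""
    cds = structure.coding_sequence(record.sequence)[structure.frame_offset:]
    residues, stop = _translate_to_stop(cds)
    return DeducedProtein(residues=residues, stop_position=stop)


def locate_conserved_regions(protein: DeducedProtein, library: Optional[MotifLibrary] = None) -> RegionMap:
    return locate_conserved_regions_str(protein.residues, library or default_library())


def assess_splice_sites(record: AlleleRecord, structure: GeneStructure) -> SpliceAssessment:
    seq = record.sequence
    d0, d1 = structure.intron2
    donor = seq[d0:d0 + 2]
    acceptor = seq[d1 - 2:d1]
    assessment = SpliceAssessment(
        donor_ok=donor == "GT",
        acceptor_ok=acceptor == "AG",
        donor_dinucleotide=donor,
        acceptor_dinucleotide=acceptor,
    )
    if not assessment.acceptor_ok:
        # intron retention: translate exon2 + intron + exon3 in frame
        retained = seq[structure.exon2[0] + structure.frame_offset:]
        residues, stop = _translate_to_stop(retained)
        exon2_codons = (structure.exon2[1] - structure.exon2[0] - structure.frame_offset) // 3
        tail = max(0, len(residues) - exon2_codons)
        assessment.retained_intron_translation = DeducedProtein(
            residues=residues, stop_position=stop, novel_tail_length=tail
        )
    return assessment


def cryptic_acceptor_candidates(
    record: AlleleRecord, structure: GeneStructure, window: int = 50
) -> list[int]:
    """AG dinucleotide end positions within ``window`` nt of the annotated
    acceptor — the candidate cryptic 3' splice sites a defective acceptor
    could activate.  Reported as supplementary output; choosing among them
    would require transcript evidence."""
    seq = record.sequence
    a = structure.intron2[1]
    lo = max(structure.intron2[0] + 2, a - window)
    hi = min(len(seq), a + window)
    return [
        i + 2
        for i in range(lo - 2, hi - 1)
        if seq[i:i + 2] == "AG" and i + 2 != a
    ]


def project_structure(
    wildtype: AlleleRecord, wildtype_structure: GeneStructure, mutant: AlleleRecord
) -> GeneStructure:
    """Transfer exon/intron boundaries to a near-identical allele via DNA alignment."""
    alignment = _align.pairwise_align(wildtype.sequence, mutant.sequence, mode="dna")
    mapping = _coordinate_map(alignment)
    d = mapping(wildtype_structure.intron2[0])
    a = mapping(wildtype_structure.intron2[1])
    seq = mutant.sequence
    if not (0 < d < a < len(seq)):
        raise ValueError(f"cannot project structure of {wildtype.allele_id} onto {mutant.allele_id}")
    return GeneStructure(
        exon2=(0, d),
        intron2=(d, a),
        exon3=(a, len(seq)),
        frame_offset=wildtype_structure.frame_offset,
        splice5_dinucleotide=seq[d:d + 2],
        splice3_dinucleotide=seq[a - 2:a],
    )


def _coordinate_map(alignment):
    """Return f(position in seq A) -> position in seq B under the alignment."""
    blocks_a, blocks_b = alignment.aligned

    def mapping(pos_a: int) -> int:
        for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
            if a0 <= pos_a < a1:
                return b0 + (pos_a - a0)
            if pos_a < a0:
                return b0  # position fell in a gap; snap to next aligned block
        return int(blocks_b[-1][1]) if len(blocks_b) else 0

    return mapping


def exonic_gap_runs(
    wildtype: AlleleRecord, wildtype_structure: GeneStructure, mutant: AlleleRecord
) -> list[int]:
    """Lengths of alignment gap runs falling inside the wild-type exons."""
    alignment = _align.pairwise_align(wildtype.sequence, mutant.sequence, mode="dna")
    blocks_a, blocks_b = alignment.aligned
    exon_spans = [wildtype_structure.exon2, wildtype_structure.exon3]
    runs: list[int] = []
    for i in range(len(blocks_a) - 1):
        a_gap = int(blocks_a[i + 1][0] - blocks_a[i][1])  # deletion in mutant
        b_gap = int(blocks_b[i + 1][0] - blocks_b[i][1])  # insertion in mutant
        gap_pos = int(blocks_a[i][1])
        if any(s <= gap_pos < e or s < blocks_a[i + 1][0] <= e for s, e in exon_spans):
            for g in (a_gap, b_gap):
                if g > 0:
                    runs.append(g)
    return runs


# ---------------------------------------------------------------------------
# functional status
# ---------------------------------------------------------------------------

def call_functional_status(
    record: AlleleRecord,
    structure: GeneStructure,
    protein: DeducedProtein,
    region_map: RegionMap,
    splice: SpliceAssessment,
    paired_wildtype: Optional[AlleleAnnotation] = None,
) -> FunctionalCall:
    """Classify one allele as functional or one of three loss-of-function modes.

    Evidence precedence: a non-canonical splice site outranks everything; a
    frameshift established by paired comparison (exonic indel of length not
    divisible by 3) outranks a bare premature stop, since the stop is then a
    downstream consequence of the frameshift.
    """
    missing = tuple(r for r in region_map.missing() if r != "C2")
    if not splice.acceptor_ok or not splice.donor_ok:
        tail = splice.retained_intron_translation
        evidence = (
            f"non-canonical splice sites {splice.donor_dinucleotide}..{splice.acceptor_dinucleotide}"
        )
        if tail is not None:
            evidence += (
                f"; intron retention adds {tail.novel_tail_length} novel residues before "
                + ("a stop" if tail.stop_position is not None else "the sequence end")
            )
        return FunctionalCall(
            status="splice-defect",
            missing_regions=missing,
            evidence=evidence,
            paired_wildtype=paired_wildtype.record.allele_id if paired_wildtype else None,
        )

    if paired_wildtype is not None:
        runs = exonic_gap_runs(paired_wildtype.record, paired_wildtype.structure, record)
        frameshifting = [g for g in runs if g % 3 != 0]
        if frameshifting:
            return FunctionalCall(
                status="frameshift-truncated",
                missing_regions=missing,
                evidence=(
                    f"exonic indel(s) of length {frameshifting} vs {paired_wildtype.record.allele_id} "
                    f"shift the reading frame"
                ),
                paired_wildtype=paired_wildtype.record.allele_id,
            )

    if protein.stop_position is not None and region_map.C5 is None:
        return FunctionalCall(
            status="premature-stop",
            missing_regions=missing,
            evidence=f"in-frame stop after {protein.stop_position} residues, before a detectable C5",
            paired_wildtype=paired_wildtype.record.allele_id if paired_wildtype else None,
        )

    evidence = "all conserved regions present, no premature stop, canonical splice sites"
    if missing:
        # divergence beyond motif thresholds without mechanistic evidence:
        # conservatively treat a missing C5 with a stop as handled above; here
        # report the uncertainty but keep the call functional.
        evidence = f"regions {missing} below motif threshold but no disruptive event found"
        return FunctionalCall(status="premature-stop" if protein.stop_position is not None else "putative-functional",
                              missing_regions=missing if protein.stop_position is not None else (),
                              evidence=evidence)
    return FunctionalCall(status="putative-functional", evidence=evidence)


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionCounts:
    synonymous: float
    nonsynonymous: float
    indels: int
    fractional: bool = False


def count_syn_nonsyn(wildtype_cds: str, mutant_cds: str) -> SubstitutionCounts:
    """Codon-by-codon synonymous/nonsynonymous counts between two coding sequences.

    Sequences must share a frame (pass the frame-offset-stripped CDS).  If
    their lengths differ the pair is aligned, indel runs are counted, and
    substitutions are scored on the indel-free prefix only.  Codons differing
    at several sites are counted by averaging over all substitution orderings
    (pathways through stop codons are excluded).
    """
    indels = 0
    a, b = wildtype_cds, mutant_cds
    if len(a) != len(b):
        alignment = _align.pairwise_align(a, b, mode="dna")
        blocks_a, blocks_b = alignment.aligned
        indels = sum(
            (int(blocks_a[i + 1][0] - blocks_a[i][1]) > 0)
            + (int(blocks_b[i + 1][0] - blocks_b[i][1]) > 0)
            for i in range(len(blocks_a) - 1)
        )
        indels += (int(blocks_a[0][0]) > 0) + (int(blocks_b[0][0]) > 0)
        indels += (int(blocks_a[-1][1]) < len(a)) + (int(blocks_b[-1][1]) < len(b))
        prefix = min(int(blocks_a[0][1]), int(blocks_b[0][1]))
        a, b = a[:prefix], b[:prefix]
    syn = nonsyn = 0.0
    fractional = False
    for i in range(0, min(len(a), len(b)) - 2, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca == cb:
            continue
        s, n, frac = _codon_pathway_counts(ca, cb)
        syn += s
        nonsyn += n
        fractional = fractional or frac
    return SubstitutionCounts(syn, nonsyn, indels, fractional)


def _codon_pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if len(diffs) == 1:
        aa_a, aa_b = _CODONS.get(codon_a, "X"), _CODONS.get(codon_b, "X")
        return (1.0, 0.0, False) if aa_a == aa_b else (0.0, 1.0, False)
    syn_total = nonsyn_total = 0.0
    valid = 0
    for order in permutations(diffs):
        syn = nonsyn = 0.0
        current = codon_a
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            aa_c, aa_n = _CODONS.get(current, "X"), _CODONS.get(nxt, "X")
            if aa_n == "*" and nxt != codon_b:
                through_stop = True
                break
            if aa_c == aa_n:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not through_stop:
            syn_total += syn
            nonsyn_total += nonsyn
            valid += 1
    if valid == 0:  # every pathway passes a stop; fall back to including them
        return float(len(diffs)) / 2, float(len(diffs)) / 2, True
    return syn_total / valid, nonsyn_total / valid, True


# ---------------------------------------------------------------------------
# family-level annotation (pairing + projection)
# ---------------------------------------------------------------------------

def annotate_family(
    records: Sequence[AlleleRecord],
    library: Optional[MotifLibrary] = None,
    pair_identity_threshold: float = 95.0,
) -> dict[str, AlleleAnnotation]:
    """Annotate a whole allele set, resolving mutant/wild-type pairs.

    Every allele is first annotated de novo.  Alleles whose full-amplicon DNA
    identity to another allele reaches ``pair_identity_threshold`` are treated
    as allelic variants of one gene: the member with a clean annotation (all
    regions present, no stop, canonical splice sites) anchors the pair and the
    partner's structure is projected from it, after which functional status is
    called with the paired evidence.
    """
    library = library or default_library()
    annotations: dict[str, AlleleAnnotation] = {}
    failures: dict[str, str] = {}
    for record in records:
        try:
            structure = detect_intron(record, library)
            annotations[record.allele_id] = _assemble(record, structure, library)
        except ValueError as exc:
            failures[record.allele_id] = str(exc)

    by_id = {r.allele_id: r for r in records}
    pairs = _near_identical_pairs(records, pair_identity_threshold)
    paired_with: dict[str, str] = {}
    for id_a, id_b in pairs:
        ann_a, ann_b = annotations.get(id_a), annotations.get(id_b)
        clean_a = ann_a is not None and _is_clean(ann_a)
        clean_b = ann_b is not None and _is_clean(ann_b)
        if clean_a and clean_b:
            if _projection_consistent(ann_a, by_id[id_b], ann_b):
                paired_with[id_a], paired_with[id_b] = id_b, id_a
                continue
            clean_b = _matches_family_consensus(ann_b, annotations, pairs)
            clean_a = not clean_b or _matches_family_consensus(ann_a, annotations, pairs)
        if clean_a ^ clean_b:
            wt_id, mut_id = (id_a, id_b) if clean_a else (id_b, id_a)
            wt = annotations[wt_id]
            mutant = by_id[mut_id]
            structure = project_structure(wt.record, wt.structure, mutant)
            ann = _assemble(mutant, structure, library)
            ann.structure_source = f"projected:{wt_id}"
            annotations[mut_id] = ann
            failures.pop(mut_id, None)
            paired_with[mut_id] = wt_id
            paired_with[wt_id] = mut_id

    if failures:
        unresolved = ", ".join(f"{k} ({v})" for k, v in sorted(failures.items()))
        raise ValueError(f"unannotatable alleles without a usable partner: {unresolved}")

    for allele_id, ann in annotations.items():
        partner_id = paired_with.get(allele_id)
        partner = annotations.get(partner_id) if partner_id else None
        wildtype = partner if partner is not None and _is_clean(partner) else None
        ann.call = call_functional_status(
            ann.record, ann.structure, ann.protein, ann.region_map, ann.splice,
            paired_wildtype=wildtype if wildtype is not ann else None,
        )
    return annotations


def _assemble(record: AlleleRecord, structure: GeneStructure, library: MotifLibrary) -> AlleleAnnotation:
    protein = translate_cds(record, structure)
    region_map = locate_conserved_regions_str(protein.residues, library, require_c2=False)
    splice = assess_splice_sites(record, structure)
    return AlleleAnnotation(
        record=record, structure=structure, protein=protein, region_map=region_map, splice=splice
    )


def _is_clean(ann: AlleleAnnotation) -> bool:
    return (
        not ann.region_map.missing()
        and ann.protein.stop_position is None
        and ann.splice.donor_ok
        and ann.splice.acceptor_ok
    )


def _near_identical_pairs(records: Sequence[AlleleRecord], threshold: float) -> list[tuple[str, str]]:
    """Each allele paired with its best partner above the identity threshold."""
    best: dict[str, tuple[float, str]] = {}
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            ident = _align.identity_percent(_align.pairwise_align(a.sequence, b.sequence, mode="dna"))
            if ident >= threshold:
                if ident > best.get(a.allele_id, (-1.0, ""))[0]:
                    best[a.allele_id] = (ident, b.allele_id)
                if ident > best.get(b.allele_id, (-1.0, ""))[0]:
                    best[b.allele_id] = (ident, a.allele_id)
    return sorted({tuple(sorted((a, p))) for a, (_, p) in best.items()})


def _projection_consistent(ann_a: AlleleAnnotation, rec_b: AlleleRecord, ann_b: AlleleAnnotation) -> bool:
    projected = project_structure(ann_a.record, ann_a.structure, rec_b)
    return projected.intron2 == ann_b.structure.intron2


def _matches_family_consensus(
    ann: AlleleAnnotation,
    annotations: dict[str, AlleleAnnotation],
    pairs: list[tuple[str, str]],
) -> bool:
    """Does this allele's exon3 start look like the family's acceptor context?

    Used only to break the rare both-clean-but-inconsistent pair tie: compare the
    12 nt following the acceptor with the majority consensus of unpaired
    clean alleles.
    """
    paired_ids = {x for p in pairs for x in p}
    prefixes = [
        a.record.sequence[a.structure.exon3[0]:a.structure.exon3[0] + 12]
        for aid, a in annotations.items()
        if aid not in paired_ids and _is_clean(a)
    ]
    if not prefixes:
        return True
    consensus = "".join(
        max("ACGT", key=lambda c: sum(p[i] == c for p in prefixes if len(p) > i))
        for i in range(12)
    )
    mine = ann.record.sequence[ann.structure.exon3[0]:ann.structure.exon3[0] + 12]
    matches = sum(1 for a, b in zip(mine, consensus) if a == b)
    return matches >= 8
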