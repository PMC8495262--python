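"""Synthetic S-RNase-like allele families with a known truth table.

The generator emulates the study conditions of a polyploid *Prunus* allele
survey: ~20 functional alleles plus mutant derivatives amplified between C2
and C5, amplicon sizes dominated by second-intron length variation
(81-1,116 bp on a ~423 bp coding core, i.e. amplicons of roughly 0.5-1.5 kb),
deduced proteins of 134-155 residues, three planted loss-of-function events
(a 1-nt deletion just upstream of C5, a 1-nt deletion after C2 creating a
premature stop, and an A-to-G at the intron's penultimate 3' position), a
configurable fraction of trans-specific allele pairs shared with a second
species label at <= 4% amino-acid divergence, and highly multiallelic samples
whose amplicons co-migrate on a gel below the resolution limit.

Every allele is checked against the package's own annotator before it is
emitted, so the planted gene structures are recoverable by construction;
alleles drawn with an unannotatable mutation pattern (e.g. intron sliding
ambiguity) are redrawn.  Exon substitutions are placed per-segment with the
configured relative rates; indels are confined to the intron except for the
planted frameshifts, reflecting that size polymorphism in this system is
carried by the intron.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as _io
from .annotate import _CODONS, detect_intron, translate_dna
from .fragments import group_bands
from .model import AlleleRecord, FragmentObservation, GeneStructure, RegionMap
from .motifs import DEFAULT_MOTIFS, MotifLibrary, default_library, locate_conserved_regions_str

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR = {}
for codon, aa in sorted(_CODONS.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)

#: protein layout of the ancestral allele: (label, length) in residues
BASE_LAYOUT = (
    ("C2", 10),
    ("C2-RHV", 4),
    ("RHV", 13),
    ("RHV-C3", 10),
    ("C3", 10),
    ("C3-RC4", 17),
    ("RC4", 10),
    ("RC4-C5", 57),
    ("C5", 10),
)
EXON2_NT = 100  # intron interrupts codon 33 after its first base (phase 1)

DEFAULT_REGION_WEIGHTS = {
    "C2-RHV": 8.0,
    "RHV": 16.0,
    "RHV-C3": 8.0,
    "C3": 3.0,
    "C3-RC4": 17.0,
    "RC4": 5.0,
    "RC4-C5": 43.0,
}

LOF_TYPES = ("frameshift-upstream-C5", "frameshift-after-C2", "splice3-AG-to-GG")


@dataclass
class FamilyConfig:
    n_base_alleles: int = 20
    n_mutant_derivatives: int = 3
    intron_length_range: tuple[int, int] = (81, 1116)
    protein_length_range: tuple[int, int] = (134, 155)
    region_rate_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    species_labels: tuple[str, ...] = ("A", "B")
    trans_specific_fraction: float = 0.2
    seed: int = 0
    ploidy: int = 22
    n_samples: int = 10
    exon_divergence: float = 0.10
    intron_divergence: float = 0.20
    intron_indel_mean_count: float = 3.0
    intron_indel_mean_length: float = 4.0
    dropout_probability: float = 0.0
    gel_resolution_bp: int = 60
    first_intron_size_range: tuple[int, int] = (150, 350)
    trans_max_aa_divergence: float = 0.04

    def __post_init__(self) -> None:
        if self.n_base_alleles < 1:
            raise ValueError("n_base_alleles must be >= 1")
        lo, hi = self.intron_length_range
        if not (21 <= lo <= hi):
            raise ValueError(f"infeasible intron_length_range {self.intron_length_range}")
        plo, phi = self.protein_length_range
        base_len = sum(l for _, l in BASE_LAYOUT)
        if not (plo <= base_len <= phi):
            raise ValueError(
                f"protein_length_range {self.protein_length_range} must contain the "
                f"base layout length {base_len}"
            )
        w = self.region_rate_weights
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("region_rate_weights must be non-negative and not all zero")
        if len(self.species_labels) < 2 and self.trans_specific_fraction > 0:
            raise ValueError("need two species labels for trans-specific pairs")
        if not 0 <= self.trans_specific_fraction <= 1:
            raise ValueError("trans_specific_fraction must be in [0, 1]")
        if self.n_mutant_derivatives > self.n_base_alleles:
            raise ValueError("cannot have more mutant derivatives than base alleles")


@dataclass
class LofEvent:
    allele_id: str
    parent_id: str
    lof_type: str
    position: int  # amplicon coordinate of the planted change


@dataclass
class TruthTable:
    structures: dict[str, GeneStructure]
    region_maps: dict[str, RegionMap]
    lof_events: list[LofEvent]
    trans_pairs: list[tuple[str, str]]
    sample_alleles: dict[str, list[str]]
    allele_sizes: dict[str, int]
    first_intron_sizes: dict[str, int]
    substitution_counts: dict[str, dict[str, int]]

    def to_json(self) -> str:
        payload = {
            "structures": {
                k: {
                    "exon2": list(v.exon2),
                    "intron2": list(v.intron2),
                    "exon3": list(v.exon3),
                    "frame_offset": v.frame_offset,
                    "splice5": v.splice5_dinucleotide,
                    "splice3": v.splice3_dinucleotide,
                }
                for k, v in self.structures.items()
            },
            "region_maps": {
                k: {
                    name: (list(getattr(v, name)) if getattr(v, name) else None)
                    for name in ("C2", "RHV", "C3", "RC4", "C5")
                }
                | {"protein_length": v.protein_length}
                for k, v in self.region_maps.items()
            },
            "lof_events": [asdict(e) for e in self.lof_events],
            "trans_pairs": [list(p) for p in self.trans_pairs],
            "sample_alleles": self.sample_alleles,
            "allele_sizes": self.allele_sizes,
            "first_intron_sizes": self.first_intron_sizes,
            "substitution_counts": self.substitution_counts,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class Ancestor:
    record: AlleleRecord
    structure: GeneStructure
    region_map: RegionMap
    cds: str
    intron: str
    layout: tuple[tuple[str, int], ...]


@dataclass
class FamilySimulation:
    config: FamilyConfig
    ancestor: Ancestor
    records: list[AlleleRecord]  # focal-species alleles (bases + mutants)
    homologs: list[AlleleRecord]  # second-species trans-specific partners
    truth: TruthTable


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))

def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


def _build_intron(rng: np.random.Generator, length: int) -> str:
    # canonical donor context, random interior, polypyrimidine tract, AG acceptor
    interior = length - 5 - 14 - 2
    if interior < 0:
        raise ValueError(f"intron length {length} below the minimal splice scaffold")
    body = "".join(rng.choice(list("ACGT"), size=interior))
    tract = "".join(rng.choice(list("CT"), size=14))
    return "GTAAG" + body + tract + "AG"


def _layout_spans(layout: Sequence[tuple[str, int]]) -> dict[str, tuple[int, int]]:
    spans = {}
    pos = 0
    for label, length in layout:
        spans[label] = (pos, pos + length)
        pos += length
    return spans


def _region_map_from_layout(layout: Sequence[tuple[str, int]]) -> RegionMap:
    spans = _layout_spans(layout)
    return RegionMap(
        protein_length=sum(l for _, l in layout),
        C2=spans["C2"],
        RHV=spans["RHV"],
        C3=spans["C3"],
        RC4=spans["RC4"],
        C5=spans["C5"],
    )


def _assemble(cds: str, intron: str) -> str:
    return cds[:EXON2_NT] + intron + cds[EXON2_NT:]


def _structure_for(cds: str, intron: str) -> GeneStructure:
    total = len(cds) + len(intron)
    return GeneStructure(
        exon2=(0, EXON2_NT),
        intron2=(EXON2_NT, EXON2_NT + len(intron)),
        exon3=(EXON2_NT + len(intron), total),
        frame_offset=0,
        splice5_dinucleotide=intron[:2],
        splice3_dinucleotide=intron[-2:],
    )


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------

def build_ancestor(config: FamilyConfig, library: Optional[MotifLibrary] = None) -> Ancestor:
    """Ancestral allele: consensus motifs at the conserved blocks, random
    filler elsewhere, one GT..AG intron of configured length."""
    library = library or default_library()
    rng = np.random.default_rng(config.seed)

    for _ in range(50):
        parts = []
        for label, length in BASE_LAYOUT:
            if label in library.motifs:
                motif = library.motifs[label]
                if len(motif) != length:
                    raise ValueError(f"motif {label} length {len(motif)} != layout {length}")
                parts.append(motif)
            else:
                parts.append(_random_residues(rng, length))
        protein = "".join(parts)
        cds = _reverse_translate(rng, protein)
        cds = _scrub_acceptor_neighbourhood(rng, cds)
        assert "*" not in translate_dna(cds)

        length = int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
        intron = _build_intron(rng, length)
        record = AlleleRecord(
            allele_id="ancestor",
            sequence=_assemble(cds, intron),
            species_tag=config.species_labels[0],
        )
        structure = _structure_for(cds, intron)
        if _annotation_matches(record, structure, BASE_LAYOUT, library):
            return Ancestor(
                record=record,
                structure=structure,
                region_map=_region_map_from_layout(BASE_LAYOUT),
                cds=cds,
                intron=intron,
                layout=BASE_LAYOUT,
            )
    raise ValueError("could not build an unambiguously annotatable ancestor")


def _scrub_acceptor_neighbourhood(rng: np.random.Generator, cds: str) -> str:
    """Redraw the filler codons at the exon-3 start until the 15 nt after the
    junction carry no AG dinucleotide.

    An AG a few phase-compatible codons into exon 3 would be an alternative
    canonical acceptor indistinguishable from the genuine one (it inherits the
    polypyrimidine context), which would make the planted splice-site defect
    unidentifiable; the emitted families mirror alleles whose defects were
    identifiable.
    """
    for _ in range(200):
        if "AG" not in cds[EXON2_NT - 1:EXON2_NT + 14]:
            return cds
        residues = _random_residues(rng, 4)  # junction codon + three filler codons
        cds = cds[:99] + _reverse_translate(rng, residues) + cds[111:]
    raise ValueError("could not scrub the acceptor neighbourhood")


def _annotation_matches(
    record: AlleleRecord,
    structure: GeneStructure,
    layout: Sequence[tuple[str, int]],
    library: MotifLibrary,
    expect_acceptor: str = "AG",
) -> bool:
    try:
        found = detect_intron(record, library)
    except ValueError:
        return False
    if found.intron2 != structure.intron2 or found.frame_offset != structure.frame_offset:
        return False
    if found.splice3_dinucleotide != expect_acceptor:
        return False
    protein = translate_dna(structure.coding_sequence(record.sequence))
    if "*" in protein:
        return False
    located = locate_conserved_regions_str(protein, library)
    truth = _region_map_from_layout(layout)
    return all(
        getattr(located, name) == getattr(truth, name) for name in ("C2", "RHV", "C3", "RC4", "C5")
    )


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------

def _place_exon_substitutions(
    rng: np.random.Generator,
    cds: str,
    layout: Sequence[tuple[str, int]],
    weights: dict[str, float],
    n_subs: int,
) -> tuple[str, dict[str, int]]:
    """Place nucleotide substitutions per-segment (C2 and C5 are untouched);
    substitutions creating a stop codon are redrawn."""
    spans = _layout_spans(layout)
    labels = [l for l, _ in layout if l in weights and weights[l] > 0]
    w = np.array([weights[l] for l in labels], dtype=float)
    w /= w.sum()
    seq = list(cds)
    counts = {l: 0 for l in labels}
    placed = 0
    guard = 0
    while placed < n_subs and guard < 50 * (n_subs + 1):
        guard += 1
        label = labels[int(rng.choice(len(labels), p=w))]
        lo, hi = spans[label]
        residue = int(rng.integers(lo, hi))
        pos = 3 * residue + int(rng.integers(3))
        old = seq[pos]
        alt = [b for b in "ACGT" if b != old]
        new = alt[int(rng.integers(3))]
        codon = seq[3 * residue:3 * residue + 3]
        codon[pos - 3 * residue] = new
        if _CODONS["".join(codon)] == "*":
            continue
        seq[pos] = new
        counts[label] += 1
        placed += 1
    return "".join(seq), counts


def _mutate_intron(
    rng: np.random.Generator,
    intron: str,
    sub_rate: float,
    indel_mean_count: float,
    indel_mean_length: float,
    target_length: Optional[int] = None,
    protect_head: int = 6,
    protect_tail: int = 18,
) -> str:
    seq = list(intron)

    def interior() -> tuple[int, int]:
        return protect_head, len(seq) - protect_tail

    n_subs = int(rng.poisson(sub_rate * len(seq)))
    for _ in range(n_subs):
        lo, hi = interior()
        if hi <= lo:
            break
        pos = int(rng.integers(lo, hi))
        alt = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alt[int(rng.integers(3))]

    n_indels = int(rng.poisson(indel_mean_count))
    for _ in range(n_indels):
        lo, hi = interior()
        if hi - lo < 4:
            break
        length = int(rng.geometric(1.0 / indel_mean_length))
        pos = int(rng.integers(lo, hi))
        if rng.random() < 0.5 and hi - lo > length + 2:
            del seq[pos:pos + min(length, hi - pos - 1)]
        else:
            seq[pos:pos] = list(rng.choice(list("ACGT"), size=length))

    if target_length is not None:
        diff = target_length - len(seq)
        lo, hi = interior()
        if diff > 0:
            pos = int(rng.integers(lo, hi)) if hi > lo else lo
            seq[pos:pos] = list(rng.choice(list("ACGT"), size=diff))
        elif diff < 0:
            need = -diff
            lo, hi = interior()
            if hi - lo <= need:
                raise ValueError("cannot shrink intron to target length")
            pos = int(rng.integers(lo, hi - need))
            del seq[pos:pos + need]
    return "".join(seq)


def _derive_allele(
    rng: np.random.Generator, ancestor: Ancestor, config: FamilyConfig
) -> tuple[str, str, tuple[tuple[str, int], ...], dict[str, int]]:
    """One divergent base allele: an in-frame RC4-C5 length change, weighted
    exon substitutions, and a resized/mutated intron."""
    layout = [list(t) for t in ancestor.layout]
    cds = ancestor.cds
    plo, phi = config.protein_length_range
    base_len = sum(l for _, l in ancestor.layout)
    delta = int(rng.integers(plo - base_len, phi - base_len + 1))
    spans = _layout_spans(ancestor.layout)
    s4lo, s4hi = spans["RC4-C5"]
    if delta > 0:
        at = int(rng.integers(s4lo + 1, s4hi))
        insert = _reverse_translate(rng, _random_residues(rng, delta))
        cds = cds[:3 * at] + insert + cds[3 * at:]
    elif delta < 0:
        at = int(rng.integers(s4lo + 1, s4hi + delta))
        cds = cds[:3 * at] + cds[3 * (at - delta):]
    for part in layout:
        if part[0] == "RC4-C5":
            part[1] += delta
    layout_t = tuple((l, n) for l, n in layout)

    n_subs = int(rng.poisson(config.exon_divergence * len(cds)))
    cds, counts = _place_exon_substitutions(rng, cds, layout_t, config.region_rate_weights, n_subs)

    target = int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
    intron = _mutate_intron(
        rng,
        ancestor.intron,
        config.intron_divergence,
        config.intron_indel_mean_count,
        config.intron_indel_mean_length,
        target_length=target,
    )
    return cds, intron, layout_t, counts


def plant_lof(
    record: AlleleRecord,
    structure: GeneStructure,
    region_map: RegionMap,
    lof_type: str,
    position: Optional[int] = None,
    mutant_id: Optional[str] = None,
) -> tuple[AlleleRecord, LofEvent]:
    """Plant exactly one loss-of-function event on a functional allele.

    Positions are amplicon coordinates.  When no position is given a
    deterministic, identifiable site is chosen: just upstream of C5 for the
    C5-removing frameshift; the earliest post-C2 site whose frameshift stops
    within 40 residues for the truncating frameshift; the intron's penultimate
    base for the splice-site defect.
    """
    if lof_type not in LOF_TYPES:
        raise ValueError(f"unknown lof_type {lof_type!r}")
    seq = record.sequence
    intron_len = structure.intron_length
    mutant_id = mutant_id or f"{record.allele_id}m"

    def cds_to_amplicon(cds_pos: int) -> int:
        return cds_pos if cds_pos < EXON2_NT else cds_pos + intron_len

    if lof_type == "splice3-AG-to-GG":
        default = structure.intron2[1] - 2
        position = default if position is None else position
        if position != default:
            raise ValueError("splice3-AG-to-GG targets the intron's penultimate base")
        if seq[position] != "A":
            raise ValueError("acceptor penultimate base is not A")
        mutated = seq[:position] + "G" + seq[position + 1:]
    elif lof_type == "frameshift-upstream-C5":
        c5 = region_map.C5
        if c5 is None:
            raise ValueError("allele has no C5 region to disrupt")
        window = (cds_to_amplicon(3 * (c5[0] - 8)), cds_to_amplicon(3 * c5[0]))
        position = cds_to_amplicon(3 * (c5[0] - 5)) if position is None else position
        if not window[0] <= position < window[1]:
            raise ValueError(f"position {position} outside the pre-C5 window {window}")
        mutated = seq[:position] + seq[position + 1:]
    else:  # frameshift-after-C2
        c2_end = region_map.C2[1] if region_map.C2 else 10
        candidates = (
            [position]
            if position is not None
            else [cds_to_amplicon(3 * p) for p in range(c2_end + 1, c2_end + 14)]
        )
        window = (cds_to_amplicon(3 * c2_end), cds_to_amplicon(3 * (c2_end + 15)))
        chosen = None
        for pos in candidates:
            if not window[0] <= pos < window[1]:
                raise ValueError(f"position {pos} outside the post-C2 window {window}")
            trial = seq[:pos] + seq[pos + 1:]
            shifted = _mutant_structure_after_deletion(structure, pos)
            spliced = trial[:shifted.intron2[0]] + trial[shifted.intron2[1]:]
            protein = translate_dna(spliced)
            stop = protein.find("*")
            if 0 <= stop < 40:
                chosen = pos
                break
        if chosen is None:
            chosen = candidates[0]
        position = chosen
        mutated = seq[:position] + seq[position + 1:]

    mutant = AlleleRecord(
        allele_id=mutant_id,
        sequence=mutated,
        sample_id=record.sample_id,
        species_tag=record.species_tag,
    )
    return mutant, LofEvent(
        allele_id=mutant_id, parent_id=record.allele_id, lof_type=lof_type, position=position
    )


def evolve_family(ancestor: Ancestor, config: FamilyConfig) -> FamilySimulation:
    """Evolve the full family: base alleles, mutant derivatives, trans-specific
    homologs, per-sample allele multisets and fragment truth."""
    library = default_library()
    rng = np.random.default_rng(config.seed + 1)

    drawn: list[tuple[str, str, tuple[tuple[str, int], ...], dict[str, int]]] = []
    for _ in range(config.n_base_alleles):
        for _attempt in range(40):
            cds, intron, layout, counts = _derive_allele(rng, ancestor, config)
            record = AlleleRecord(allele_id="tmp", sequence=_assemble(cds, intron))
            structure = _structure_for(cds, intron)
            if _annotation_matches(record, structure, layout, library):
                drawn.append((cds, intron, layout, counts))
                break
        else:
            raise ValueError("failed to draw an annotatable base allele")

    # name by ascending amplicon size, as allele series are numbered in practice
    order = sorted(range(len(drawn)), key=lambda i: (len(drawn[i][0]) + len(drawn[i][1]), i))
    species_a = config.species_labels[0]
    records: list[AlleleRecord] = []
    structures: dict[str, GeneStructure] = {}
    region_maps: dict[str, RegionMap] = {}
    sub_counts: dict[str, dict[str, int]] = {}
    base_parts: dict[str, tuple[str, str, tuple[tuple[str, int], ...]]] = {}
    for rank, idx in enumerate(order, start=1):
        cds, intron, layout, counts = drawn[idx]
        allele_id = f"S{rank}"
        records.append(
            AlleleRecord(allele_id=allele_id, sequence=_assemble(cds, intron), species_tag=species_a)
        )
        structures[allele_id] = _structure_for(cds, intron)
        region_maps[allele_id] = _region_map_from_layout(layout)
        sub_counts[allele_id] = counts
        base_parts[allele_id] = (cds, intron, layout)

    base_ids = [r.allele_id for r in records]

    # trans-specific homologs in a second species label
    n_trans = int(round(config.trans_specific_fraction * config.n_base_alleles))
    species_b = config.species_labels[1] if len(config.species_labels) > 1 else "B"
    trans_pairs: list[tuple[str, str]] = []
    homologs: list[AlleleRecord] = []
    if n_trans:
        parents = [base_ids[i] for i in rng.choice(len(base_ids), size=n_trans, replace=False)]
        for parent in sorted(parents):
            cds, intron, layout = base_parts[parent]
            max_changes = max(1, int(config.trans_max_aa_divergence * sum(l for _, l in layout)) - 1)
            for _attempt in range(40):
                m = int(rng.integers(1, max_changes + 1))
                h_cds, _ = _place_exon_substitutions(rng, cds, layout, config.region_rate_weights, m)
                h_intron = _mutate_intron(rng, intron, 0.01, 1.0, 3.0)
                hid = f"{parent}_{species_b}"
                record = AlleleRecord(allele_id=hid, sequence=_assemble(h_cds, h_intron), species_tag=species_b)
                structure = _structure_for(h_cds, h_intron)
                if _annotation_matches(record, structure, layout, library):
                    homologs.append(record)
                    structures[hid] = structure
                    region_maps[hid] = _region_map_from_layout(layout)
                    trans_pairs.append((parent, hid))
                    break
            else:
                raise ValueError(f"failed to draw a trans-specific homolog of {parent}")

    # mutant derivatives carrying the three LOF classes
    lof_events: list[LofEvent] = []
    mutant_records: list[AlleleRecord] = []
    if config.n_mutant_derivatives:
        parent_order = [base_ids[int(i)] for i in rng.permutation(len(base_ids))]
        used: set[str] = set()
        for j in range(config.n_mutant_derivatives):
            lof_type = LOF_TYPES[j % len(LOF_TYPES)]
            planted_ok = False
            for parent_id in parent_order:
                if parent_id in used:
                    continue
                if _try_plant(
                    rng, parent_id, lof_type, base_parts, region_maps, structures,
                    records, species_a, library, mutant_records, lof_events,
                ):
                    used.add(parent_id)
                    planted_ok = True
                    break
            if not planted_ok:
                raise ValueError(f"failed to plant {lof_type} on any parent")

    pool = records + mutant_records
    pool_ids = [r.allele_id for r in pool]
    allele_sizes = {r.allele_id: len(r.sequence) for r in pool + homologs}
    first_intron: dict[str, int] = {}
    lo, hi = config.first_intron_size_range
    for r in records:
        first_intron[r.allele_id] = int(rng.integers(lo, hi + 1))
    for e in lof_events:
        first_intron[e.allele_id] = first_intron[e.parent_id]

    sample_alleles: dict[str, list[str]] = {}
    for s in range(1, config.n_samples + 1):
        picks = rng.choice(len(pool_ids), size=config.ploidy, replace=True)
        sample_alleles[str(s)] = sorted(pool_ids[int(i)] for i in picks)

    truth = TruthTable(
        structures=structures,
        region_maps=region_maps,
        lof_events=lof_events,
        trans_pairs=trans_pairs,
        sample_alleles=sample_alleles,
        allele_sizes=allele_sizes,
        first_intron_sizes=first_intron,
        substitution_counts=sub_counts,
    )
    return FamilySimulation(
        config=config, ancestor=ancestor, records=pool, homologs=homologs, truth=truth
    )


def _try_plant(
    rng: np.random.Generator,
    parent_id: str,
    lof_type: str,
    base_parts: dict,
    region_maps: dict,
    structures: dict,
    records: list,
    species_tag: str,
    library: MotifLibrary,
    mutant_records: list,
    lof_events: list,
    attempts: int = 12,
) -> bool:
    """Plant one LOF event on a candidate parent (with fresh neutral intron
    noise per attempt); splice-site defects must be recoverable de novo by the
    annotator, otherwise the candidate is rejected."""
    cds, intron, layout = base_parts[parent_id]
    for _ in range(attempts):
        noisy_intron = _mutate_intron(rng, intron, 0.01, 1.0, 5.0)
        noisy = AlleleRecord(
            allele_id=parent_id,
            sequence=_assemble(cds, noisy_intron),
            species_tag=species_tag,
        )
        noisy_structure = _structure_for(cds, noisy_intron)
        mutant, event = plant_lof(noisy, noisy_structure, region_maps[parent_id], lof_type)
        if lof_type == "splice3-AG-to-GG":
            mutant_structure = _structure_for(cds, noisy_intron[:-2] + "GG")
            if not _annotation_matches(
                mutant, mutant_structure, layout, library, expect_acceptor="GG"
            ):
                continue
        else:
            mutant_structure = _mutant_structure_after_deletion(noisy_structure, event.position)
            if _denovo_looks_functional(mutant, library):
                # an alternative splice can absorb this frameshift, making the
                # defect unidentifiable; try another noise draw / parent
                continue
        mutant_records.append(mutant)
        structures[mutant.allele_id] = mutant_structure
        lof_events.append(event)
        return True
    return False


def _denovo_looks_functional(record: AlleleRecord, library: MotifLibrary) -> bool:
    """True when de novo annotation yields a clean, full-motif, stop-free
    product with canonical splice sites (i.e. the defect is invisible)."""
    try:
        structure = detect_intron(record, library)
    except ValueError:
        return False
    if not structure.is_canonical:
        return False
    protein = translate_dna(
        structure.coding_sequence(record.sequence)[structure.frame_offset:]
    )
    stop = protein.find("*")
    if stop >= 0:
        return False
    located = locate_conserved_regions_str(protein, library, require_c2=False)
    return not located.missing()


def _mutant_structure_after_deletion(structure: GeneStructure, position: int) -> GeneStructure:
    """Shift spans for a 1-nt exonic deletion at ``position``."""
    def shift(span: tuple[int, int]) -> tuple[int, int]:
        a, b = span
        return (a - (position < a), b - (position < b))

    return GeneStructure(
        exon2=shift(structure.exon2),
        intron2=shift(structure.intron2),
        exon3=shift(structure.exon3),
        frame_offset=structure.frame_offset,
        splice5_dinucleotide=structure.splice5_dinucleotide,
        splice3_dinucleotide=structure.splice3_dinucleotide,
    )


def generate_family(config: Optional[FamilyConfig] = None) -> FamilySimulation:
    config = config or FamilyConfig()
    return evolve_family(build_ancestor(config), config)


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def simulate_observations(sim: FamilySimulation) -> list[FragmentObservation]:
    """Per-sample fragment observations under the gel co-migration model and
    the 1-bp capillary assay, with optional per-allele dropout."""
    rng = np.random.default_rng(sim.config.seed + 2)
    out: list[FragmentObservation] = []
    for sample_id, alleles in sim.truth.sample_alleles.items():
        distinct = sorted(set(alleles))
        if sim.config.dropout_probability > 0:
            distinct = [
                a for a in distinct if rng.random() >= sim.config.dropout_probability
            ] or distinct[:1]
        sizes = [sim.truth.allele_sizes[a] for a in distinct]
        for band in group_bands(sizes, sim.config.gel_resolution_bp, labels=distinct):
            out.append(
                FragmentObservation(
                    sample_id=sample_id,
                    fragment_size=band.representative,
                    assay="second-intron-gel",
                    intensity_note="complex" if band.is_complex else "",
                )
            )
        for size in sorted({sim.truth.first_intron_sizes[a] for a in distinct}):
            out.append(
                FragmentObservation(
                    sample_id=sample_id, fragment_size=size, assay="first-intron-capillary"
                )
            )
    return out


def emit_fixture_set(config: FamilyConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + fragment TSV + JSON truth (+ homolog FASTA and config echo)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = generate_family(config)
    paths = {
        "fasta": out_dir / "family.fasta",
        "homologs": out_dir / "homologs.fasta",
        "fragments": out_dir / "fragments.tsv",
        "truth": out_dir / "truth.json",
        "config": out_dir / "config.yaml",
    }
    _io.write_fasta(sim.records, paths["fasta"])
    _io.write_fasta(sim.homologs, paths["homologs"])
    _io.write_fragment_table(simulate_observations(sim), paths["fragments"])
    paths["truth"].write_text(sim.truth.to_json() + "\n")
    cfg = asdict(config)
    cfg["intron_length_range"] = list(config.intron_length_range)
    cfg["protein_length_range"] = list(config.protein_length_range)
    cfg["first_intron_size_range"] = list(config.first_intron_size_range)
    cfg["species_labels"] = list(config.species_labels)
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def ancestor_comparison_events(sim: FamilySimulation):
    """Mutation events of every base allele against the ancestor (the
    measurement path for checking that the generator's per-segment rates are
    recovered by the region profile)."""
    from .annotate import translate_dna as _td
    from .regions import enumerate_substitutions

    anc_protein = _td(sim.ancestor.cds)
    events = []
    base_ids = [r.allele_id for r in sim.records if r.allele_id in sim.truth.substitution_counts]
    for allele_id in base_ids:
        record = next(r for r in sim.records if r.allele_id == allele_id)
        protein = _td(sim.truth.structures[allele_id].coding_sequence(record.sequence))
        events.extend(
            enumerate_substitutions(
                anc_protein, protein, sim.ancestor.region_map, pair_id=f"ancestor|{allele_id}"
            )
        )
    return events
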