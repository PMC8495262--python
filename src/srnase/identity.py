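"""Three-level pairwise identity matrices and trans-specificity classification.

Allelic lineages at the S-locus routinely survive speciation (trans-specific
evolution), so an allele can be more similar to an allele of another species
than to any allele of its own.  The classifier mirrors the multi-approach
logic of the field: deduced amino-acid identity carries the main signal
(supported above ~96%), second-intron identity and tree placement act as
corroboration, and amino-acid replacements inside the hypervariable region
(RHV) are attached as a caution because they may change allele specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import align as _align
from .model import AlleleAnnotation


@dataclass
class IdentityMatrices:
    """Symmetric percent-identity matrices over allele ids at three levels."""

    exon_nt: pd.DataFrame
    protein: pd.DataFrame
    intron_nt: pd.DataFrame
    parameters: _align.AlignmentParameters = field(default_factory=_align.AlignmentParameters)

    def level(self, name: str) -> pd.DataFrame:
        return {"exon_nt": self.exon_nt, "protein": self.protein, "intron_nt": self.intron_nt}[name]


def build_identity_matrices(
    annotations: dict[str, AlleleAnnotation],
    denominator_convention: str = "columns",
) -> IdentityMatrices:
    """All-vs-all identity at exon-nucleotide, deduced-protein and intron level."""
    ids = list(annotations)
    seqs = {}
    for allele_id, ann in annotations.items():
        if ann.structure is None:  # pragma: no cover - guarded upstream
            raise ValueError(f"allele {allele_id} is not annotated")
        s = ann.structure
        seqs[allele_id] = (
            s.coding_sequence(ann.record.sequence),
            ann.protein.residues,
            ann.record.sequence[s.intron2[0]:s.intron2[1]],
        )
    frames = []
    for level, mode in ((0, "dna"), (1, "protein"), (2, "dna")):
        m = pd.DataFrame(100.0, index=ids, columns=ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                alignment = _align.pairwise_align(seqs[a][level], seqs[b][level], mode=mode)
                ident = _align.identity_percent(alignment, denominator_convention)
                m.loc[a, b] = m.loc[b, a] = ident
        frames.append(m)
    params = _align.AlignmentParameters(identity_denominator=denominator_convention)
    return IdentityMatrices(exon_nt=frames[0], protein=frames[1], intron_nt=frames[2], parameters=params)


def summarize_matrix(matrix: pd.DataFrame) -> dict:
    """Mean/min/max over off-diagonal pairs, with the arg pairs."""
    ids = list(matrix.index)
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    if not pairs:
        raise ValueError("need at least two alleles")
    values = [(float(matrix.loc[a, b]), (a, b)) for a, b in pairs]
    mean = sum(v for v, _ in values) / len(values)
    vmin, pmin = min(values, key=lambda t: (t[0], t[1]))
    vmax, pmax = max(values, key=lambda t: (t[0], t[1]))
    return {
        "mean": mean,
        "min": vmin,
        "min_pair": pmin,
        "max": vmax,
        "max_pair": pmax,
        "n_pairs": len(values),
    }


@dataclass(frozen=True)
class TransSpecificCall:
    pair: tuple[str, str]
    species: tuple[str, str]
    aa_identity: float
    intron_identity: float
    rhv_replacements: int
    verdict: str  # supported | ambiguous | unsupported
    tree_support_note: str = ""


def classify_trans_specific(
    matrices: IdentityMatrices,
    annotations: dict[str, AlleleAnnotation],
    tree=None,
    aa_threshold: float = 96.0,
    ambiguous_floor: float = 92.0,
    intron_floor: float = 90.0,
) -> list[TransSpecificCall]:
    """Classify every cross-species allele pair.

    supported    AA identity >= ``aa_threshold`` and, when a tree is given,
                 the two alleles are mutually nearest cross-species leaves
    ambiguous    AA identity in [``ambiguous_floor``, threshold), or high AA
                 identity whose intron identity falls below ``intron_floor``
                 or whose tree placement fails the mutual-nearest check
    unsupported  everything else
    """
    from .regions import enumerate_substitutions  # local import avoids a cycle

    species = {aid: ann.record.species_tag or "unlabelled" for aid, ann in annotations.items()}
    ids = list(annotations)
    cross = [
        (a, b) for i, a in enumerate(ids) for b in ids[i + 1:] if species[a] != species[b]
    ]
    nearest = _mutual_nearest(tree, species) if tree is not None else None

    calls = []
    for a, b in cross:
        aa = float(matrices.protein.loc[a, b])
        intron = float(matrices.intron_nt.loc[a, b])
        ref, other = sorted((a, b))
        events = enumerate_substitutions(
            annotations[ref].protein,
            annotations[other].protein,
            annotations[ref].region_map,
            pair_id=f"{ref}|{other}",
        )
        rhv = sum(1 for e in events if e.region == "RHV" and e.event_type == "substitution")
        note = ""
        if aa >= aa_threshold:
            verdict = "supported"
            if intron < intron_floor:
                verdict = "ambiguous"
                note = f"intron identity {intron:.1f}% below support floor {intron_floor:.0f}%"
            if nearest is not None and not (nearest.get(a) == b and nearest.get(b) == a):
                verdict = "ambiguous"
                note = (note + "; " if note else "") + "pair not mutually nearest in tree"
            elif nearest is None:
                note = (note + "; " if note else "") + "no-tree"
        elif aa >= ambiguous_floor:
            verdict = "ambiguous"
            note = f"AA identity {aa:.1f}% in the uncertain band"
        else:
            verdict = "unsupported"
            note = f"AA identity {aa:.1f}% argues against trans-specific origin"
        if rhv > 0 and verdict == "supported":
            note = (note + "; " if note else "") + f"{rhv} RHV replacement(s): specificity caution"
        calls.append(
            TransSpecificCall(
                pair=(ref, other),
                species=(species[ref], species[other]),
                aa_identity=aa,
                intron_identity=intron,
                rhv_replacements=rhv,
                verdict=verdict,
                tree_support_note=note,
            )
        )
    return calls


def _mutual_nearest(tree, species: dict[str, str]) -> Optional[dict[str, str]]:
    """allele -> its nearest cross-species leaf, when mutual; else absent."""
    from .phylo import leaf_distances

    dists = leaf_distances(tree)
    nearest: dict[str, str] = {}
    for a in dists:
        candidates = [
            (d, b) for b, d in dists[a].items() if species.get(b) != species.get(a)
        ]
        if candidates:
            nearest[a] = min(candidates)[1]
    return nearest


def calls_table(calls: Sequence[TransSpecificCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "allele_a": c.pair[0],
                "allele_b": c.pair[1],
                "species_a": c.species[0],
                "species_b": c.species[1],
                "aa_identity": round(c.aa_identity, 1),
                "intron_identity": round(c.intron_identity, 1),
                "rhv_replacements": c.rhv_replacements,
                "verdict": c.verdict,
                "note": c.tree_support_note,
            }
            for c in calls
        ]
    )
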