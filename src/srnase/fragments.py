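"""Gel-band grouping and size-category binning for the two genotyping assays.

Second-intron amplicons are separated on agarose gels where size differences
below the resolution limit (about 60 bp here) co-migrate into one band, so a
highly multiallelic sample shows fewer bands than alleles.  Bands are grouped
by single-linkage chaining, matching how adjacent smears merge on a gel.
First-intron fragments are sized on a capillary sequencer at 1-bp precision
and are simply binned by exact integer size.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import AlleleRecord, FragmentObservation, GeneStructure


@dataclass(frozen=True)
class BandGroup:
    """One gel band: the fragment sizes (and allele labels) it contains."""

    sizes: tuple[int, ...]
    labels: tuple[str, ...]
    representative: int

    @property
    def is_complex(self) -> bool:
        return len(set(self.labels)) >= 2


def amplicon_length(record: AlleleRecord, structure: GeneStructure) -> int:
    """Total amplicon length from the annotated spans (must tile the sequence)."""
    e2, i2, e3 = structure.exon2, structure.intron2, structure.exon3
    if e2[0] != 0 or e3[1] != len(record.sequence):
        raise ValueError(
            f"{record.allele_id}: structure spans {e2}..{e3} do not cover the sequence"
        )
    return (e2[1] - e2[0]) + (i2[1] - i2[0]) + (e3[1] - e3[0])


def group_bands(
    sizes: Sequence[int],
    resolution_bp: int = 60,
    labels: Optional[Sequence[str]] = None,
) -> list[BandGroup]:
    """Single-linkage grouping: sizes share a band iff chained by gaps < resolution.

    ``labels`` (one per size, e.g. allele ids) feed the complex-band flag;
    without labels each fragment counts as a distinct allele.  Groups come
    back sorted by representative (median) size.
    """
    if resolution_bp < 0:
        raise ValueError("resolution_bp must be >= 0")
    items = list(zip(sizes, labels if labels is not None else map(str, range(len(sizes)))))
    if any(s <= 0 for s, _ in items):
        raise ValueError("fragment sizes must be positive")
    items.sort()
    groups: list[list[tuple[int, str]]] = []
    for item in items:
        if groups and item[0] - groups[-1][-1][0] < resolution_bp:
            groups[-1].append(item)
        elif groups and resolution_bp == 0 and item[0] == groups[-1][-1][0]:
            groups[-1].append(item)
        else:
            groups.append([item])
    return [
        BandGroup(
            sizes=tuple(s for s, _ in g),
            labels=tuple(l for _, l in g),
            representative=int(round(median(s for s, _ in g))),
        )
        for g in groups
    ]


def bin_size_categories(observations: Iterable[FragmentObservation]) -> dict[int, int]:
    """Counts per exact integer size for capillary (first-intron) fragments.

    Neighbouring 1-bp sizes stay distinct categories, as on a capillary trace.
    """
    counts: dict[int, int] = {}
    for obs in observations:
        if obs.assay != "first-intron-capillary":
            continue
        counts[obs.fragment_size] = counts.get(obs.fragment_size, 0) + 1
    return dict(sorted(counts.items()))


def summarize_detection(
    sample_alleles: dict[str, list[str]],
    allele_sizes: dict[str, int],
    observations: Optional[Iterable[FragmentObservation]] = None,
    resolution_bp: int = 60,
) -> pd.DataFrame:
    """Per-sample table of alleles carried vs gel bands resolved.

    ``undercount`` = distinct alleles carried - bands observed (>= 0 when
    bands are computed from the gel model; observed tables must not contain
    samples absent from the truth).
    """
    observed: dict[str, int] = {}
    if observations is not None:
        for obs in observations:
            if obs.assay != "second-intron-gel":
                continue
            if obs.sample_id not in sample_alleles:
                raise ValueError(f"observed sample {obs.sample_id!r} not in truth")
            observed[obs.sample_id] = observed.get(obs.sample_id, 0) + 1
    rows = []
    for sample_id, alleles in sorted(sample_alleles.items()):
        distinct = sorted(set(alleles))
        sizes = [allele_sizes[a] for a in distinct]
        bands = (
            observed.get(sample_id, 0)
            if observations is not None
            else len(group_bands(sizes, resolution_bp, labels=distinct))
        )
        rows.append(
            {
                "sample_id": sample_id,
                "alleles_carried": len(distinct),
                "bands_observed": bands,
                "undercount": len(distinct) - bands,
            }
        )
    return pd.DataFrame(rows)
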