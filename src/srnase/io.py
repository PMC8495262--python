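"""Readers and writers for the plain-text formats the pipeline touches.

FASTA headers carry the allele id plus optional space-separated
``key=value`` tokens (``sample=``, ``species=``, ``accession=``); unknown
keys are ignored so headers derived from GenBank deposits parse cleanly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlleleRecord, FragmentObservation

_KNOWN_KEYS = ("sample", "species", "accession")


def read_fasta(path: str | Path) -> list[AlleleRecord]:
    """Parse a FASTA file of amplicons into :class:`AlleleRecord` objects.

    Sequences are uppercased and U is mapped to T.  Duplicate allele ids and
    characters outside {A,C,G,T,N} raise ``ValueError``.
    """
    path = Path(path)
    records: list[AlleleRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        allele_id = entry.id
        if allele_id in seen:
            raise ValueError(f"duplicate allele_id {allele_id!r} in {path}")
        seen.add(allele_id)
        meta = _parse_header_tokens(entry.description)
        seq = str(entry.seq).upper().replace("U", "T")
        records.append(
            AlleleRecord(
                allele_id=allele_id,
                sequence=seq,
                sample_id=meta.get("sample", ""),
                accession=meta.get("accession"),
                species_tag=meta.get("species", ""),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _parse_header_tokens(description: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            if key in _KNOWN_KEYS:
                meta[key] = value
    return meta


def write_fasta(records: Iterable[AlleleRecord], path: str | Path) -> None:
    """Write records with their metadata as key=value header tokens."""
    out = []
    for r in records:
        desc = []
        if r.sample_id:
            desc.append(f"sample={r.sample_id}")
        if r.species_tag:
            desc.append(f"species={r.species_tag}")
        if r.accession:
            desc.append(f"accession={r.accession}")
        out.append(SeqRecord(Seq(r.sequence), id=r.allele_id, description=" ".join(desc)))
    SeqIO.write(out, str(path), "fasta")


def read_fragment_table(path: str | Path) -> list[FragmentObservation]:
    """Parse a TSV of per-sample fragment sizes (columns: sample_id, size_bp, assay)."""
    path = Path(path)
    observations: list[FragmentObservation] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"sample_id", "size_bp", "assay"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                size = int(row["size_bp"])
            except (TypeError, ValueError):
                raise ValueError(f"{path}:{lineno}: non-integer size {row['size_bp']!r}") from None
            try:
                observations.append(
                    FragmentObservation(
                        sample_id=row["sample_id"],
                        fragment_size=size,
                        assay=row["assay"],
                        intensity_note=row.get("intensity_note", "") or "",
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return observations


def write_fragment_table(observations: Iterable[FragmentObservation], path: str | Path) -> None:
    rows = [
        [o.sample_id, str(o.fragment_size), o.assay, o.intensity_note]
        for o in observations
    ]
    write_tsv_report(["sample_id", "size_bp", "assay", "intensity_note"], rows, path, sort=False)


def write_tsv_report(
    header: Sequence[str], rows: Iterable[Sequence], path: str | Path, sort: bool = True
) -> None:
    """Write a rectangular table as UTF-8 TSV, rows sorted by first column by default."""
    rows = [[str(c) for c in row] for row in rows]
    for row in rows:
        if len(row) != len(header):
            raise ValueError(f"row width {len(row)} != header width {len(header)}")
    if sort:
        rows.sort(key=lambda r: r[0])
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def read_tsv_report(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        table = list(reader)
    if not table:
        raise ValueError(f"{path}: empty table")
    return table[0], table[1:]
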