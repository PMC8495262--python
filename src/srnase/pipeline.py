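"""End-to-end orchestration: annotate -> identities -> trans-specificity ->
mutation profile -> tree, with a reproducible run manifest.

Every stage writes plain-text tables under the output directory; the manifest
records the package version, all parameters and SHA-256 checksums of inputs
and outputs, so a run can be re-executed and verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import io as _io
from .annotate import annotate_family
from .fragments import bin_size_categories, group_bands
from .identity import build_identity_matrices, calls_table, classify_trans_specific, summarize_matrix
from .model import AlleleAnnotation
from .motifs import default_library, load_motif_library
from .phylo import (
    DistanceModel,
    align_proteins,
    bootstrap_support,
    mask_low_coverage_columns,
    to_newick,
)
from .regions import profile_pairs, region_frequency_table, select_pairs


@dataclass
class PipelineConfig:
    input_fasta: Optional[str] = None
    homolog_fasta: Optional[str] = None
    fragment_table: Optional[str] = None
    motif_library: Optional[str] = None
    out_dir: str = "results/pipeline"
    resolution_bp: int = 60
    aa_threshold: float = 96.0
    ambiguous_floor: float = 92.0
    intron_floor: float = 90.0
    aa_floor: float = 80.0
    coverage: float = 0.95
    gamma_shape: float = 0.8
    distance_model: str = "jtt-gamma"
    bootstrap_replicates: int = 100
    pair_identity_threshold: float = 95.0
    matrix_name: str = "PAM250"
    identity_denominator: str = "columns"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.resolution_bp < 0:
            raise ValueError("resolution_bp must be >= 0")
        for name in ("aa_threshold", "ambiguous_floor", "intron_floor", "aa_floor"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected, absent keys defaulted."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    if not config.input_fasta:
        raise ValueError("config.input_fasta is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = (
        load_motif_library(config.motif_library) if config.motif_library else default_library()
    )

    records = _io.read_fasta(config.input_fasta)
    homologs = _io.read_fasta(config.homolog_fasta) if config.homolog_fasta else []

    # --- stage: annotation -------------------------------------------------
    annotations = annotate_family(
        records + homologs, library, pair_identity_threshold=config.pair_identity_threshold
    )
    _write_annotation_tables(annotations, out)

    # --- stage: identity matrices -----------------------------------------
    matrices = build_identity_matrices(annotations, config.identity_denominator)
    for level, frame in (
        ("exon_nt", matrices.exon_nt),
        ("protein", matrices.protein),
        ("intron_nt", matrices.intron_nt),
    ):
        frame.round(4).to_csv(out / f"identity_{level}.tsv", sep="\t")
    summary_rows = []
    for level in ("exon_nt", "protein", "intron_nt"):
        s = summarize_matrix(matrices.level(level))
        summary_rows.append(
            [level, f"{s['mean']:.4f}", f"{s['min']:.4f}", "|".join(s["min_pair"]),
             f"{s['max']:.4f}", "|".join(s["max_pair"]), str(s["n_pairs"])]
        )
    _io.write_tsv_report(
        ["level", "mean", "min", "min_pair", "max", "max_pair", "n_pairs"],
        summary_rows, out / "identity_summary.tsv",
    )

    # --- stage: tree -------------------------------------------------------
    proteins = {aid: ann.protein.residues for aid, ann in annotations.items() if len(ann.protein)}
    tree = None
    if len(proteins) >= 3:
        msa = align_proteins(proteins)
        masked = mask_low_coverage_columns(msa.ids, msa.rows, config.coverage)
        model = DistanceModel(model=config.distance_model, gamma_shape=config.gamma_shape)
        tree = bootstrap_support(
            masked, model, n_replicates=config.bootstrap_replicates, seed=config.seed
        )
        (out / "tree.nwk").write_text(to_newick(tree) + "\n")

    # --- stage: trans-specificity -----------------------------------------
    calls = classify_trans_specific(
        matrices,
        annotations,
        tree=tree,
        aa_threshold=config.aa_threshold,
        ambiguous_floor=config.ambiguous_floor,
        intron_floor=config.intron_floor,
    )
    table = calls_table(calls)
    if not table.empty:
        table = table.sort_values(["allele_a", "allele_b"])
    table.to_csv(out / "trans_specificity.tsv", sep="\t", index=False)

    # --- stage: mutation-region profile ------------------------------------
    wt_mut = [
        (aid, ann.call.paired_wildtype)
        for aid, ann in annotations.items()
        if ann.call and ann.call.paired_wildtype
    ]
    pairs = select_pairs(matrices.protein, config.aa_floor, wildtype_mutant_pairs=wt_mut)
    events = profile_pairs(annotations, pairs, matrix_name=config.matrix_name)
    _io.write_tsv_report(
        ["pair", "column", "region", "residue_a", "residue_b", "event_type", "class"],
        [
            [e.pair_id, e.column, e.region, e.residue_a, e.residue_b, e.event_type,
             e.conservativeness]
            for e in events
        ],
        out / "mutation_events.tsv",
    )
    if events:
        profile = region_frequency_table(events)
        profile.round(4).to_csv(out / "region_profile.tsv", sep="\t", index=False)

    # --- stage: fragment report (optional) ----------------------------------
    if config.fragment_table:
        observations = _io.read_fragment_table(config.fragment_table)
        by_sample: dict[str, list[int]] = {}
        for obs in observations:
            if obs.assay == "second-intron-gel":
                by_sample.setdefault(obs.sample_id, []).append(obs.fragment_size)
        band_rows = []
        for sample_id, sizes in sorted(by_sample.items()):
            for band in group_bands(sizes, config.resolution_bp):
                band_rows.append(
                    [sample_id, band.representative, len(band.sizes),
                     "complex" if band.is_complex else "simple"]
                )
        _io.write_tsv_report(
            ["sample_id", "representative_bp", "n_fragments", "band_class"],
            band_rows, out / "band_report.tsv",
        )
        categories = bin_size_categories(observations)
        _io.write_tsv_report(
            ["size_bp", "count"], [[k, v] for k, v in categories.items()],
            out / "first_intron_categories.tsv",
        )

    # --- manifest -----------------------------------------------------------
    inputs = {
        name: {"path": p, "sha256": _sha256(Path(p))}
        for name, p in (
            ("input_fasta", config.input_fasta),
            ("homolog_fasta", config.homolog_fasta),
            ("fragment_table", config.fragment_table),
            ("motif_library", config.motif_library),
        )
        if p
    }
    outputs = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "srnase",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": inputs,
        "outputs": outputs,
        "n_alleles": len(annotations),
        "n_trans_calls": len(calls),
        "n_mutation_events": len(events),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def _write_annotation_tables(annotations: dict[str, AlleleAnnotation], out: Path) -> None:
    rows = []
    gff: list[str] = ["##gff-version 3"]
    for aid in sorted(annotations):
        ann = annotations[aid]
        s = ann.structure
        call = ann.call
        rows.append(
            [
                aid,
                len(ann.record.sequence),
                s.exon2[1] - s.exon2[0],
                s.intron_length,
                s.exon3[1] - s.exon3[0],
                len(ann.protein),
                call.status if call else "",
                ",".join(call.missing_regions) if call else "",
                s.splice5_dinucleotide + ".." + s.splice3_dinucleotide,
                ann.structure_source,
                call.evidence if call else "",
            ]
        )
        for kind, (a, b) in (("exon", s.exon2), ("intron", s.intron2), ("exon", s.exon3)):
            gff.append(
                "\t".join(
                    [aid, "srnase", kind, str(a + 1), str(b), ".", "+", ".", f"ID={aid}.{kind}.{a}"]
                )
            )
    _io.write_tsv_report(
        [
            "allele_id", "amplicon_bp", "exon2_bp", "intron2_bp", "exon3_bp", "protein_aa",
            "status", "missing_regions", "splice_sites", "structure_source", "evidence",
        ],
        rows,
        out / "annotation.tsv",
    )
    (out / "annotation.gff3").write_text("\n".join(gff) + "\n")
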