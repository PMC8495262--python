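"""Annotate gene structure and functional status; check truth recovery.

De novo annotation recovers every planted exon/intron span on non-LOF
alleles; the three mutant derivatives are resolved through their wild-type
partners and called frameshift-truncated / splice-defect accordingly.
"""
import argparse
from srnase.annotate import annotate_family
from srnase.io import write_tsv_report
from srnase.simulate import FamilyConfig, generate_family
from srnase.validation import planted_lof_recall, structure_recovery_fraction

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", default="results/analysis/annotation.tsv")
args = parser.parse_args()

sim = generate_family(FamilyConfig(seed=args.seed))
annotations = annotate_family(sim.records + sim.homologs)
rows = [
    [aid, len(a.record.sequence), a.structure.intron_length, len(a.protein),
     a.call.status, ",".join(a.call.missing_regions), a.structure_source]
    for aid, a in annotations.items()
]
write_tsv_report(
    ["allele", "amplicon_bp", "intron_bp", "protein_aa", "status", "missing", "source"],
    rows, args.out,
)
print(f"structure recovery: {100*structure_recovery_fraction(sim, annotations):.1f}% "
      f"| planted LOF recall: {100*planted_lof_recall(sim, annotations):.1f}%")
for e in sim.truth.lof_events:
    call = annotations[e.allele_id].call
    print(f"  {e.allele_id} ({e.lof_type}) -> {call.status}, missing {list(call.missing_regions)}")
print(f"wrote {args.out}")
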