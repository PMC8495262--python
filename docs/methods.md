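# Methods

## System and scope

The package analyses partial S-RNase genes amplified between the second (C2)
and fifth (C5) conserved regions of rosaceous S-RNases.  Each amplicon
contains two partial exons separated by the second intron, whose extreme
length polymorphism (tens of bp to >1 kb) carries most of the size variation
used for gel-based S-genotyping.  The deduced protein runs from inside C2 to
the end of C5 and contains, in order: C2, the rosaceous hypervariable region
(RHV), C3, RC4 and C5, with four inter-region segments between them.  All
coordinates are 0-based half-open internally; reports print 1-based values.

## Synthetic allele families

`srnase.simulate` generates families with a fully known truth table.  The
ancestor is a 141-residue protein laid out as
C2(10) · 4 · RHV(13) · 10 · C3(10) · 17 · RC4(10) · RC4–C5(57) · C5(10),
with consensus motifs at the conserved blocks and uniform random filler
elsewhere, reverse-translated with uniformly drawn codons, and interrupted
after the first base of codon 34 (exon 2 = 100 nt) by an intron of
configurable length.  Default generator parameters and what they emulate:

| parameter | default | meaning |
|---|---|---|
| `n_base_alleles` | 20 | functional alleles in the focal species |
| `n_mutant_derivatives` | 3 | one per loss-of-function class |
| `intron_length_range` | 81–1,116 bp | the observed second-intron band |
| `protein_length_range` | 134–155 aa | deduced-protein band; varied via in-frame indels in RC4–C5 |
| `region_rate_weights` | 8/16/8/3/17/5/43 | relative exon substitution rates for C2–RHV, RHV, RHV–C3, C3, C3–RC4, RC4, RC4–C5 (C2 and C5 untouched) |
| `exon_divergence` | 0.10/site | per-allele exon substitutions (Poisson) |
| `intron_divergence` | 0.20/site | elevated intron substitution rate |
| `intron_indel_*` | ~3 indels, mean 4 bp | geometric-length intron indels; a block resize spreads lengths over the configured range |
| `trans_specific_fraction` | 0.2 | alleles duplicated into a second species label with ≤ 4% further AA divergence |
| `ploidy` / `n_samples` | 22 / 10 | allele draws per sample, with replacement (multiple genomic copies of one allele) |
| `gel_resolution_bp` | 60 | single-linkage co-migration threshold |

Substitutions are uniform over the three alternative bases and redrawn if
they would create a stop codon.  Indels are confined to the intron except the
planted frameshifts.  The three loss-of-function derivatives carry exactly
one planted event each plus mild neutral intron noise (≈1% substitutions plus
one short indel), keeping wild-type/mutant amplicon identity in the high-90s
band expected of recent derivatives: a 1-nt deletion a few codons upstream of
C5, a 1-nt deletion just downstream of C2 placed so the shifted frame stops
within 40 residues, and an A→G at the intron's penultimate position (AG→GG
acceptor).

Three constructional guarantees make the truth table recoverable, emulating
the fact that the real alleles *were* annotatable: introns carry a canonical
GTAAG donor context and a 14-nt polypyrimidine tract before the acceptor; the
15 nt after the splice junction are kept free of AG dinucleotides (an AG
there would be an alternative acceptor indistinguishable from the real one);
and every emitted allele must round-trip through the package's own annotator
(alleles drawn with ambiguous structures — e.g. intron sliding — are
redrawn, and frameshift plantings that an alternative splice could silently
absorb are rejected).  This rejection step conditions the realized
substitution patterns slightly, which is why rate-recovery acceptance is
binomial-error-based rather than exact.

What the generator does **not** emulate: coalescent genealogies under
balancing selection, recombination, per-site rate heterogeneity in exons
beyond the segment weights, preferential PCR amplification (available as a
dropout probability, default 0), and sequencing error.  Passing the synthetic
checks therefore shows the measurement chain is correct, not that real data
meet its assumptions.

## De novo gene-structure annotation

The reading frame is fixed by matching C2 against the translated prefix in
all three frames.  Donor candidates are GT dinucleotides after C2 inside the
stop-free part of the frame; acceptor candidates are AG ends.  Each (donor,
acceptor) pair is scored as the summed best ordered placement score of C2,
C3, RC4 and C5 on the spliced translation (PAM250, ungapped, threshold 0.6 of
the motif self-score) plus a small splice-context term (0.5 per match to the
GTAAGT donor consensus beyond GT, up to 4.0 for the pyrimidine fraction of
the 16 nt upstream of the acceptor dinucleotide).  The context term is what
separates the genuine acceptor from phase-compatible AGs nearby, which leave
the motif score unchanged.  Exact score ties between structurally different
candidates raise an explicit ambiguity error; ties from intron sliding
(identical spliced product) resolve to the leftmost donor.

A relaxed second pass allowing any `*G` acceptor (penalty 2.0) runs when the
canonical pass leaves motifs missing, is ambiguous, or lands on an acceptor
with a weak pyrimidine context; it is adopted only if it restores a complete,
stop-free product.  This is how the AG→GG splice mutant is found and flagged.

Alleles whose full-amplicon DNA identity to another allele reaches 95%
(analysis parameter `pair_identity_threshold`; recent wild-type/mutant pairs
sit well above it, unrelated alleles well below) are treated as variants of
one gene: the member with a clean annotation anchors the pair and the
partner's boundaries are projected through a DNA alignment.  This mirrors
practice — frameshifted alleles cannot be annotated by motif maximization,
which would "repair" the frameshift by shifting the splice site.  If both
members look clean but disagree under projection, the allele whose exon-3
start matches the family consensus wins.

## Functional status

Precedence: splice-defect (non-canonical donor or acceptor) outranks
everything; a frameshift established by paired comparison (any exonic gap run
with length ≢ 0 mod 3) outranks a bare premature stop, because the stop is
then a downstream consequence of the frameshift; premature-stop requires an
in-frame stop before a detectable C5; otherwise putative-functional.  A
missing motif without any mechanistic evidence (no indel, stop or splice
anomaly) is reported as a caution, not a loss-of-function call — motif decay
by ordinary divergence is not a mechanism.  For splice defects the
intron-retention translation is computed and the number of novel residues
between the exon-2-encoded prefix and the first stop reported.

Synonymous/nonsynonymous counts compare codons in the shared frame; codons
differing at 2–3 positions are averaged over all substitution orderings,
excluding pathways through stop codons (all-stop pathways fall back to an
even split, flagged).  Sequences of unequal length are aligned, indel runs
counted separately, and substitutions scored on the indel-free prefix.

## Identity and trans-specificity

Alignments are global with affine gaps: PAM250, open 10 / extend 0.5 for
proteins; match +2 / mismatch −1, open 10 / extend 0.2 for DNA — ClustalW-
family parameter territory, recorded in every matrix's parameter block.
Identity defaults to matches over alignment columns (gaps count as
mismatches); `no-gap-columns` and `shorter-sequence` conventions are
selectable.  For near-identical pairs the conventions agree to within a
fraction of a point; for divergent pairs the choice (and a pairwise rather
than multiple alignment) can move values by about a point, which is why the
deposited-data identity checks carry ±1 pp tolerances.

Trans-specificity thresholds: supported ≥ 96% AA identity (with
mutually-nearest placement in the tree when one is supplied, and intron
identity ≥ 90% as corroboration), ambiguous 92–96%, all configurable.  The
classifier is evaluated over functional alleles and homologs; mutant
derivatives inherit their parent's history and would otherwise duplicate
every supported pair.

## Region mutation profile

Events are enumerated per pair from the protein alignment, labelled with the
region of the reference sequence (lexicographically first allele) at that
column; insertions inherit the label of the preceding reference residue;
maximal gap runs collapse to one indel event.  Conservative vs
non-conservative is the sign of the PAM250 entry; indels have no PAM score
and are excluded from the percentages but reported.  Default pair selection
takes every pair at ≥ 80% AA identity plus all wild-type/mutant pairs; an
explicit roster file overrides selection, and both substitution-only and
with-indel totals are reported rather than guessing which convention a
published total used.

## Phylogeny

Multiple alignment is delegated to MAFFT (progressive, deterministic
settings); columns with residue coverage < 95% are masked (gaps, X and
ambiguity all count against coverage).  Distances: p-distance;
Poisson-gamma `d = α((1−p)^(−1/α) − 1)`; and the default `jtt-gamma`,
the equal-input-calibrated form `d = b·α·((1−p/b)^(−1/α) − 1)` with
`b = 1 − Σπᵢ²` over the JTT equilibrium frequencies and shape α = 0.8.
This tracks matrix-based gamma distances closely enough for topology work;
exact ML pairwise JTT distances are a non-goal, and branch-length totals are
therefore not comparable across programs.  Saturated pairs (p ≥ b) are set to
a ceiling (10 substitutions/site) rather than infinity.

Neighbor-joining uses the standard Q criterion with ties broken by the
lexicographically smallest label pair; negative branch lengths are clamped to
zero with the deficit moved to the sibling, and new inter-node distances are
floored at zero.  Bootstrap support resamples masked columns with replacement
(seeded NumPy generator) and counts replicate trees containing each original
bipartition.  A full minimum-evolution topology search is out of scope; NJ is
the initial tree of such searches and is consistent on additive inputs, which
the validation suite verifies by construction against random additive
matrices.

## Validation oracles and problem sizes

The alignment oracle enumerates every global alignment of short sequences
(≤ 8 nt; affine runs scored open + (L−1)·extend) and checks both the optimal
score and that the aligner's identity is achieved by a co-optimal alignment.
The NJ oracle builds random unrooted binary trees (uniform 0.1–1.0 branch
lengths), reads their additive matrices, and demands exact topology
recovery.  Test and acceptance problem sizes — a 23-allele family with four
homologs, 100 additive-matrix instances up to 6 taxa, 200 oracle alignment
pairs, 10–200 bootstrap replicates — were chosen so each validation carries
real statistical weight while a full run stays in the minutes range on one
core.

## Known limitations

* Motif-threshold region calling can mark genuinely divergent regions absent;
  such alleles are reported with a caution rather than forced into an LOF
  class.
* De novo annotation of an unpaired frameshifted allele is unreliable in
  principle (an alternative splice can absorb the defect); the pipeline
  depends on a near-identical partner for mechanism calls, as surveys do.
* The trans-specificity verdicts depend on alignment parameters within about
  a percentage point near the 96% threshold; thresholds are exposed rather
  than hidden.
* Cryptic-acceptor prediction reports candidate `AG`s near a defective splice
  site as supplementary output without choosing among them; confirming actual
  splice outcomes needs transcript data, which is outside this package.
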