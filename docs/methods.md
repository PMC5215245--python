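# Methods

`ampliscope` implements an evaluation protocol for targeted-metagenomics
(16S rDNA amplicon) analysis pipelines: simulate mock communities whose
composition is known exactly, score any pipeline's read-level taxonomic
assignments against that ground truth, and compare pipelines' abundance
profiles with each other.

## Taxonomy handling

All assignments are reconciled on a single rooted taxonomy (NCBI dump
dialect or a compact 4-column TSV). A read assigned at any depth is
projected to the evaluated rank (family or genus) by walking its lineage;
the walk is inclusive, so a call *at* the rank maps to itself. Calls
coarser than the rank (e.g. an order-level call evaluated at family) carry
no information at that rank and become unclassified-at-rank; this matches
scoring unclassified reads as false negatives. Name-based assignments
resolve by exact, case-insensitive match on scientific names; an ambiguous
name resolves to the shallowest matching node with a warning, or raises in
strict mode — lineage reconciliation across source databases is
fundamentally heuristic, so the choice is exposed rather than hidden.
Retired-taxid remapping (`merged.dmp`) is supported but optional.

## Community designs and read allocation

Three built-in community complexities mirror common mock-community
benchmarks: **LC** (one dominant genome at 30%, others equal), **MC**
(four dominant genomes at 20% each, others equal) and **HC** (all equal).
Read budgets (default grid: 25,000 / 50,000 / 100,000) are apportioned by
largest remainder with lexicographic tie-breaking, so the composition is
exact and deterministic — no multinomial sampling noise. Doubling the
budget under exact divisions exactly doubles every count.

## In-silico PCR

Primer sites must match exactly (IUPAC degeneracy expanded, zero
mismatches) on either strand; a genome without a perfect site simply does
not amplify and is dropped from the design with renormalized weights.
Products are primer-inclusive. Each forward site yields one product: the
nearest in-range reverse site, capped at 5,000 nt to guard against runaway
matches. Each simulated read draws uniformly among its genome's amplicon
copies; multiplicity is the only copy-number weighting.

## Sequencing error model

The per-read model emulates an Ion Torrent profile with four parameters
(defaults in parentheses):

| parameter | default | meaning |
|---|---|---|
| `deletion_rate` | 0.01 | per-base deletion probability |
| `insertion_rate` | 0.005 | per-base probability of a 1-base insertion after the position |
| `substitution_rate` | 0.005 | per-base probability of substitution to one of the 3 other bases |
| `length_sd` | 20 bp | SD of the read-length draw around the amplicon length |
| `end_bias` | 1.0 | slope of the linear 3' error ramp (0 = uniform) |

Read length is drawn from Normal(L, `length_sd`) and rounded, where L is
the amplicon length. Shorter targets truncate the read at its 3' end;
targets longer than the amplicon read through the template end into
uniform random bases, emulating adapter read-through, so the realized
length distribution is two-sided with SD ≈ `length_sd` whenever the lower
clamp at 1 base is inactive (`length_sd` ≪ L). A one-sided clamp at L was
rejected because it would shrink the realized SD to ≈ 0.58·`length_sd`,
breaking the stated spread. With all rates and `length_sd` at 0 the model
is the exact identity, which is how error-free datasets are produced.

Per-base events are mutually exclusive per position and drawn
independently with probability `rate · w(i)`, where the positional weight
`w(i) = (1 + b·i/(n−1)) / (1 + b/2)` is a linear 5'→3' ramp normalized to
mean 1 — realized mean rates match the nominal rates for any `end_bias`
b ≥ 0. The ramp reflects the empirical tendency of single-molecule
flow-based chemistry to degrade toward read ends; it is a declared
stand-in, not a flowgram model. Homopolymer-specific indel inflation,
chimeras, PCR bias and quality-score modeling are deliberately out of
scope; FASTQ qualities are a constant Q40 placeholder because the
protocol evaluates raw reads and never consumes qualities.

Determinism: each read uses an RNG stream keyed by (master seed, read
index), so datasets are byte-identical across runs and independent of
generation order.

## Synthetic fixture genomes

`generate_fixture_collection` emits one genome per species, each embedding
1–k copies of a marker gene (conserved primer sites flanking a 160 nt
variable region) separated by random spacers, plus a consistent toy
taxonomy. Divergence is hierarchical: family variable regions are
independent random draws, genera mutate the family sequence at 12% of
sites, species a further 3% — so within-genus identity exceeds
across-family identity, as for real 16S hypervariable regions. What the
fixtures do **not** emulate: real 16S length/composition, intragenomic
copy variation in sequence (copies are identical), conserved-region
homology across families, or database-mismatch effects. Passing tests
therefore demonstrate correctness of the protocol machinery, not the
field performance of any real pipeline.

## Scoring

At each rank, a read is **TP** if its predicted rank-level taxon equals
the rank-level taxon of its source genome, **FP** if it differs, **FN** if
the pipeline discarded it or left it unclassified (including
coarser-than-rank calls). Precision = TP/(TP+FP), recall = TP/(TP+FN),
F = 2PR/(P+R); all zero-denominator cases are defined as 0 and logged.
The optional singleton rule (on by default in the CLI) removes taxa
supported by exactly one read *after* projection to the evaluated rank,
per run, and recounts their reads as FN — mirroring the guideline of
discarding taxonomic singletons from final results.

Richness is estimated by Chao1, bias-corrected by default
(S_obs + f1(f1−1)/(2(f2+1)), the mothur/QIIME default), with the classic
f1²/(2f2) variant behind a flag. Chao1 error percent is the signed
relative deviation from the ground-truth richness × 100, where the ground
truth is the number of distinct rank-level taxa among the dataset's truth
reads (equal to the design richness whenever everything amplified).
Diversity uses Shannon entropy (natural log; base configurable) and
inverse Simpson 1/Σp². The unclassified pool is never a taxon for
richness/diversity purposes.

Partition agreement between prediction and truth uses NMI and AMI with
the max-entropy normalization, under which 1−NID = I/max(H_U,H_V) = NMI;
both are reported for interface compatibility, and AMI (chance-corrected
under the permutation model) is clamped at 0. Normalization by
max(H_U, H_V) was chosen so one contingency computation serves NMI and
NID consistently. Unclassified reads enter the predicted partition as one
dedicated cluster — so heavy unclassified rates genuinely depress
agreement — while discarded reads are excluded from both partitions;
inclusion of unclassified reads is an assumption, exposed in the API
rather than baked in silently. Degenerate conventions: both partitions a
single shared cluster → all metrics 1; a single cluster on one side
only → 0.

Taxonomic merging pools OTUs (or reads) assigned to the same rank-level
taxon into one abundance unit, making clustering-first (OTU-table) and
assignment-first (per-read) outputs comparable on the same profile-level
metrics.

## Cross-pipeline comparison

Profiles are compared as relative abundances with the unclassified pool
excluded and rows renormalized. Pipelines are clustered by average-linkage
(UPGMA) on Euclidean distances — operating on relative, not raw,
abundances, with a raw-count path available by passing counts directly —
with rows pre-sorted by label for a deterministic tie-break; the newick
output encodes merge heights as child-to-parent branch lengths.
Ordination is classical PCoA on Bray-Curtis dissimilarities; negative
eigenvalues are dropped (not corrected) and their summed magnitude
reported so non-Euclidean distortion is visible. Group differences in
richness/diversity use a two-sided Mann-Whitney-Wilcoxon test: exact null
enumeration when the combined n ≤ 12 and the data are tie-free (desk-scale
group comparisons), otherwise the tie- and continuity-corrected normal
approximation. Two-sided is the declared default; sidedness is an
analysis choice, not a property of the data.

## Problem sizes and numerical choices

Error-model recovery checks use 50,000 reads of 200 nt (rates) and 400 nt
(length SD) templates, accepting 3 binomial standard errors on rates and
5% relative on the SD; the suite's faster variants use 5,000–10,000 reads
at the same tolerances. Partition-metric equivalence against the
brute-force contingency/entropy oracle is exhaustive over all pairs of set
partitions of 3–5 items and a seeded 300-pair sample at 6 items; the AMI
permutation-model oracle enumerates all 720 relabelings of 6 items.
End-to-end identity checks run on a 12-genome fixture community at
1,200–25,000 reads. Community weights must sum to 1 within 1e-9;
largest-remainder floors use a 1e-9 guard against floating-point quota
error; PCoA eigenvalues within 1e-10 (relative) of zero are treated as
zero.

## Known limitations

- The error model is a parametric stand-in for flow-based chemistry: no
  homopolymer-length errors, no quality values, no chimeras or PCR bias.
- Scoring requires every truth read to project to the evaluated rank;
  taxonomies whose ground-truth lineages skip the rank are rejected
  rather than guessed at.
- The comparison module assumes profiles at a common rank; it does not
  reconcile profiles built against different taxonomies.
- No wrappers are provided to execute third-party pipelines; users bring
  assignment tables in the documented TSV schema.
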