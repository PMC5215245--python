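# ampliscope

Ground-truthed 16S amplicon simulation and pipeline benchmarking.

Targeted metagenomics (amplicon sequencing of a marker locus such as 16S
rDNA) profiles a microbial community's composition, but the profile a study
reports depends heavily on the analysis pipeline — clustering-first tools
that build OTUs and then classify them, or assignment-first tools that
classify every read by k-mers. `ampliscope` is for pipeline developers and
users who want to measure that dependence: it simulates mock communities
whose composition and per-read origin are known exactly, scores any
pipeline's read-level taxonomic assignments against that ground truth, and
compares multiple pipelines' abundance profiles with each other.

## What it computes

Given a truth table (read → source genome/taxon) and a pipeline's
assignment table (read → taxon, unclassified, or discarded), both
projected onto a fixed rank r (family or genus) via a shared taxonomy:

- **Confusion / F-measure.** TP: predicted taxon at r equals the source
  genome's taxon at r; FP: it differs; FN: the read was discarded or is
  unclassified at r. Then precision = TP/(TP+FP), recall = TP/(TP+FN),
  F = 2PR/(P+R). An optional singleton rule removes taxa supported by one
  read and recounts those reads as FN.
- **Richness.** Bias-corrected Chao1,
  Ŝ = S_obs + f₁(f₁−1)/(2(f₂+1)), and its signed error
  (Ŝ − S_true)/S_true × 100 against the designed richness.
- **Diversity.** Shannon entropy H = −Σ pᵢ ln pᵢ and inverse Simpson
  1/Σ pᵢ².
- **Partition agreement.** NMI = I(U;V)/max(H(U),H(V)), chance-corrected
  AMI, and 1−NID (identical to NMI under the max normalization), with
  unclassified reads forming one dedicated predicted cluster.
- **Cross-pipeline comparison.** UPGMA on Euclidean distances between
  relative-abundance profiles (unclassified excluded), PCoA on
  Bray-Curtis dissimilarities, and two-sided Mann-Whitney-Wilcoxon tests
  between pipeline groups.

The simulator performs exact-match in-silico PCR (IUPAC-degenerate
primers, no mismatches), allocates reads over LC/MC/HC community designs
(one dominant genome at 30% / four at 20% each / all equal) by
deterministic largest remainder, and corrupts reads with an Ion
Torrent-style model: per-base deletion/insertion/substitution rates
(defaults 0.01/0.005/0.005), a 3'-weighted error ramp, and read lengths
drawn with a 20 bp standard deviation around the amplicon size. See
`docs/methods.md` for the model details and assumptions.

## Worked example

Simulate a low-complexity community from the built-in synthetic fixture
genomes and score a truth-copying "pipeline" (the upper bound any real
pipeline is compared against):

```python
import pandas as pd
import ampliscope as amp

fc = amp.generate_fixture_collection(seed=1)        # 12 genomes, 3 families, 6 genera
ids = sorted(fc.genomes)
design = amp.lc_design(ids, ids[0])                 # 30% dominant, rest equal
ds = amp.simulate_dataset(fc.genomes, fc.species_taxids, design, fc.primers,
                          n_reads=2000, params=amp.ErrorModelParams(), seed=7,
                          out_fastq="reads.fastq")
oracle = pd.DataFrame({"read_id": ds.truth["read_id"],
                       "status": "classified", "taxid": ds.truth["taxid"]})
report = amp.evaluate_pipeline(ds.truth, oracle, fc.taxonomy,
                               dataset="LC_2000", pipeline="oracle")
print(report.pivot_table(index="rank", columns="metric", values="value").round(4))
```

```
metric  precision  recall  f_measure  chao1  chao1_error_percent  shannon  inverse_simpson  one_minus_nid
rank
family        1.0     1.0        1.0    3.0                  0.0   1.0451           2.6947            1.0
genus         1.0     1.0        1.0    6.0                  0.0   1.6793           4.6861            1.0
```

A perfect pipeline scores F-measure 1.0 and Chao1 error 0% at both ranks:
the estimated richness (3 families, 6 genera) equals the design exactly.
The diversity values reflect the skew of the LC design — inverse Simpson
2.69 means the community behaves like ~2.7 equally-abundant families
because one family dominates, well below the richness of 3. A real
pipeline's assignment TSV (`read_id  status  taxid`) drops into the same
call; lower F, inflated Chao1 or depressed 1−NID quantify its errors.

The same protocol is scriptable from the shell:

```sh
ampliscope fixtures --out fix --seed 1
ampliscope simulate --genomes fix/genomes.fasta --genome-taxids fix/genome_taxids.tsv \
    --out sim --seed 1 --throughputs 25000
ampliscope evaluate --truth sim/LC_25000_error-prone/truth.tsv \
    --taxonomy fix/taxonomy.tsv --assignments mypipeline.tsv --out report
ampliscope compare --profiles report/profile_mypipeline_family.tsv ... --out cmp
ampliscope run-all --out demo --seed 1   # self-contained demonstration loop
```

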