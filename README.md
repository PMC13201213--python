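# pirnakit

Analysis toolkit for **oxidized small-RNA sequencing libraries** aimed at
detecting PIWI-interacting RNA (piRNA) signatures in tissues where piRNAs
are rare — such as sorted intestinal stem cells and enteroblasts — together
with a **ground-truth library simulator** that makes every stage of the
analysis verifiable without real sequencing data.

## The scientific problem

piRNAs are 23–32 nt small RNAs, typically transposon (TE)-targeting, that
carry 2′-*O*-methylated 3′ ends. Sodium periodate oxidation destroys
unmethylated RNAs during library preparation, so an "oxidized" library is
enriched for piRNAs and endo-siRNAs over the miRNA and degradation
background that otherwise dominates somatic tissue. Whether a small-RNA
population is genuinely piRNA-like is then decided by its molecular
signatures:

* **1U / 10A ping-pong biases.** Reciprocal cleavage between sense and
  antisense piRNAs with a 10-nt 5′ overlap leaves a uridine at position 1
  of TE-antisense reads and an adenine at position 10 of TE-sense reads.
  For each anchor, base frequencies *f* are measured in an 11-position
  window centred on the anchor and summarized as

  ```
  z = (f[anchor] − mean(f over the 11 positions)) / population SD of those 11 values
  ```

* **Phased biogenesis.** Processive head-to-tail piRNA production leaves a
  uridine bias at the genomic base immediately 3′ of each read (≈50 % in
  phased populations vs. ≈25 % background).

* **TE-mapping fraction** of piRNA-sized (>22 nt) reads, sense/antisense
  **size distributions** (normalized per million hairpin-RNA endo-siRNA
  reads), and **piRNA-cluster tile abundances** from genome-unique mappers
  after masking tRNA/snRNA/snoRNA neighbourhoods (±100 nt) and the
  *aubergine* locus.

The pipeline re-specifies the standard external tooling (Bowtie-style
all-best-strata k-mismatch mapping, bedtools-style tile counting,
FASTX-style adapter trimming) as internal, exactly testable operations at
toy scale, and the simulator generates raw FASTQ libraries whose 1U bias,
ping-pong pairing geometry, phasing, methylation/oxidation survival and
background composition are all known and configurable.

## Worked example

```bash
pirnakit simulate-ref   --seed 2 --outdir ref/
pirnakit simulate-reads --seed 2 --refdir ref/ --n-reads 8000 \
    --out-fastq reads.fq --out-truth truth.tsv
pirnakit run-all --fastq reads.fq --refdir ref/ --outdir out/ --seed 2
cat out/summary.tsv
```

This prints (abridged; values to 4 significant digits):

```
statistic                       value
n_input_reads                   7453
n_clean_reads                   7453
hpRNA_total                     1162.0
z_1U_antisense                  3.1535
z_10A_sense                     3.1520
phasing_downstream_U_all        0.4902
te_mapping_fraction             0.9982
cluster_abundance:cluster1      2651463.0
cluster_abundance:cluster2      2723752.2
```

Reading the numbers: both ping-pong z-scores sit essentially at the
theoretical maximum for an 11-value window with one dominant anchor
(√10 ≈ 3.162), the downstream-uridine frequency recovers the simulated
phasing probability of 0.5, and >99 % of piRNA-sized reads map to the TE
consensus library because every simulated piRNA derives from cluster TE
fragments. Cluster abundances are per-million-hpRNA tile sums over each
cluster.

The same stages are available programmatically
(`pirnakit.simulate`, `pirnakit.preprocess`, `pirnakit.align`,
`pirnakit.signatures`, `pirnakit.tiles`, `pirnakit.te_expression`,
`pirnakit.pipeline.run_pipeline`), and each CLI subcommand
(`preprocess`, `map`, `signatures`, `tiles`, `te-expr`) runs independently
on the previous stage's file outputs.

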