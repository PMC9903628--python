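# gbsquant

Relative-abundance quantification of closely related strains from
double-digest GBS (genotyping-by-sequencing) read data, with a
truth-tagged simulator so the whole workflow can be exercised and
benchmarked without any external data.

The workflow mirrors a reference-free msGBS quantification design:

1. **synthetic_data** — simulate strain genomes (controlled divergence,
   optional mosaic hybrid), PacI/NsiI double digestion with >150 bp size
   selection, and paired-end 2×150 libraries with per-strain yield biases
   (up to 32-fold), 3-nt UMIs, ~50 % PCR duplicates and substitution
   errors; plus study designs (monoclonal / calibration / mock samples)
   and simulated light-microscopy valve counts with a confusion matrix.
2. **preprocessing** — demultiplex by barcode, strip UMIs, merge read
   pairs (≥20 bp overlap, ≤10 % mismatches, else join with an N spacer),
   UMI-deduplicate, and dereplicate monoclonal reads (minimum unique
   size 5).
3. **meta_reference** — greedy centroid clustering at 95 % global
   identity per strain, a pluggable contaminant-filter hook, and
   concatenation into a strain-labelled meta-reference.
4. **read_mapping** — multi-mapping against the meta-reference
   (normalised score ≥ 0.8, max-score ties retained), fractional 1/k
   count-matrix allocation, and low-read sample exclusion (<3000 reads
   in the real-data regime).
5. **cluster_filtering** — homologous-cluster removal by three rules
   computed from monoclonal cross-mappings (non-target > target;
   target < 8; non-target/target > 1/15), plus target-mapping-rate QC.
6. **quantification** — per-strain calibration key from equal-proportion
   samples (mean read shares), conversion of mock read counts to
   calibrated relative abundances, and design-truth expected tables with
   renormalisation after strain exclusions.
7. **evaluation** — FP/FN detection tables, false-signal rates, Pearson
   correlation + OLS regression per sample/strain with strength classes
   (>0.7 strong, 0.5–0.7 moderate, <0.5 weak), and GBS-vs-LM comparison.

`gbsquant.pipeline.run_pipeline` chains all stages on a simulated study;
`SimulationConfig` holds every tunable.

## CLI

```bash
# simulate a study and run the full pipeline, writing TSV/FASTA/CSV outputs
gbsquant run --seed 1 --outdir out/

# only write the simulated study (FASTQ R1/R2, truth table, designs, genomes)
gbsquant simulate --seed 1 --outdir sim/

# both accept a YAML file of SimulationConfig overrides
gbsquant run --config my_config.yaml --seed 7 --outdir out/
```

## Library example

```python
from gbsquant import SimulationConfig, run_pipeline

result = run_pipeline(SimulationConfig(), seed=1)
print(result.key.factor)           # per-strain calibration factors
print(result.gbs.values)           # sample × strain abundance estimates
print(result.sample_stats_gbs.r)   # per-sample Pearson r vs design truth
```

## Notes on conventions

- Cluster identity is matches / alignment length of a gapped global
  alignment (match +1, mismatch −1, gap −2), end gaps included.
- Mapping scores are matches / read length under ungapped semi-global
  placement; the simulator emits substitution errors only, so this is
  exact and is verified against an independent sliding-window oracle.
- Joined reads map as two half-placements with pooled matches; their
  spacer Ns count as mismatches.
- Deduplication keys on (UMI, exact sequence) and runs before mapping.
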