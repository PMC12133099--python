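# regland

Analysis pipeline for environment-dependent promoter dissection with
massively parallel reporter assays (MPRAs): from mutagenized promoter
libraries and DNA/RNA barcode counts to per-base mutual-information
footprints, expression-shift matrices, automated footprint classification,
two-state-HMM binding-site calls, emergent σ70 −10 transcription-start-site
detection, and hierarchical clustering of growth conditions. A
statistical-mechanics synthetic-data generator provides ground-truth
datasets so every stage is testable end to end without sequencing data.

## Modules

| Module | Purpose |
|---|---|
| `regland.library_design` | 160-bp TSS-anchored promoter windows, random mutagenesis (rate 0.1, 1500 variants + wild type), oligo constructs, barcode maps |
| `regland.synthetic_data` | thermodynamic (Boltzmann-weight) expression model over energy matrices, multinomial DNA/RNA count simulation, full dataset generation |
| `regland.counts` | barcode-pair read filter (≥3 reads), Hamming-based variant assignment (incl. synthesis-error variants), barcode→variant count aggregation |
| `regland.footprints` | mutual-information footprints (bits), expression-shift matrices, Gaussian smoothing, footprint Pearson correlation |
| `regland.classification` | SITES / SPIKE / INACTIVE triage via coefficient-of-variation change under smoothing |
| `regland.site_calling` | two-state Gaussian HMM (Baum–Welch, forward–backward, Viterbi), interval decoding, repressor/activator sign from shifts |
| `regland.tss_scan` | single mutations completing the TATAAT key positions (1, 2, 6), shift-matrix corroboration |
| `regland.condition_clustering` | replicate QC, condition matrices, average-linkage clustering on 1 − Pearson, Newick export |
| `regland.scenarios` | canonical ground-truth architectures used by tests and benchmarks |

## CLI

```bash
regland design    --promoters meta.tsv --fasta genome.fa --rate 0.1 --n 1500 --seed 1 --out lib/
regland simulate  --arch arch.yaml --conditions condA,condB --replicates 2 --seed 1 --out sim/
regland counts    --map lib/p.barcodes.tsv --dna dna.tsv --rna rna.tsv --out counts.tsv
regland footprint --counts counts.tsv --library-fasta lib/p.library.fa --library-meta lib/p.window.tsv --out fp/
regland classify  --footprints fp/ --t-active 1e-6 --t-ratio 0.55
regland call-sites --footprints fp/ --min-len 4 --out sites.bed
regland scan-tss  --promoter p.fa --shift fp/p.c.rep0.shift.tsv --out tss.tsv
regland cluster   --footprints fp/ --out clust/
```

The architecture YAML schema for `simulate` is documented in
`regland.synthetic_data.arch_from_config`.

## Conventions

- Promoter windows span 115 bp upstream to 45 bp downstream of the TSS
  (160 bp); array index `i` carries promoter-relative label `i − 115`, so
  label 0 is the TSS base.
- Mutual information is computed between a base's mutation status
  (wild-type vs mutated) and read source (DNA vs RNA) with a pseudocount
  of 1 per joint cell, in bits.
- Expression shifts are fractional changes of pseudocounted normalized
  expression relative to the wild-type-base mean; wild-type entries are 0.
- Binding-site intervals are 0-based half-open; BED output uses mean
  posterior × 1000 as the score.

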