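# baitform

Differential **bait peptidoform** analysis for immunoprecipitation–mass-spectrometry
(IP-MS) open-search results.

Classical IP-MS analysis asks how the *prey* interactome of a bait protein
changes between conditions. `baitform` reverses the question: because the bait
is strongly enriched by the pulldown, its peptide-spectrum matches (PSMs) carry
enough depth to detect *which molecular forms of the bait itself* (mutations,
PTMs, chemical artifacts) differ between conditions. The package:

1. **Aggregates** FragPipe/MSFragger-style `psm.tsv` rows into *peptidoforms* —
   peptide sequence × open-search delta mass rounded to one decimal
   (`LVVVGAGGVGK@+58.0`) — as a peptidoform × sample count matrix.
2. **Normalizes** each sample's bait counts to the comparison sample with the
   fewest bait PSMs, after excluding peptidoforms with a single PSM in the
   whole dataset.
3. **Scores differential presence** per comparison with a probability (AvgP)
   and Bayesian FDR, via an external SAINTexpress binary (spectral-count
   input triple written for you) or a built-in two-component Poisson
   surrogate with the same output shape; significance is `BFDR < 0.05`.
4. **Describes** the peptidoform landscape: protein coverage against the
   gene's longest isoform, peptide positions, modification-state classes
   (unmodified / modified / multiple, with isotopic errors collapsed),
   bait-vs-prey enrichment summaries, and delta-mass annotation (known
   modifications, single amino-acid substitutions, and fixed-modification
   displacement, e.g. −9.0 on Cys ⇒ cysteic acid replacing carbamidomethyl).
5. **Clusters** samples on abundant peptidoforms (log2, zero-filled,
   Euclidean/complete linkage) and quantifies agreement with condition labels.

A first-class synthetic-data generator emits FragPipe-dialect PSM tables,
FASTA and a design manifest with known ground truth, so the full pipeline is
testable offline.

## CLI

```bash
# make a synthetic mutation scenario (ctrl emits LVVVGAGGVGK@+0.0,
# test emits LVVVGAGGVGK@+58.0)
baitform simulate --out sim/ --seed 7 --scenario mutation

# full pipeline: aggregate -> singleton filter -> normalize -> score ->
# BFDR -> calls, plus coverage, positions, enrichment, clustering
baitform run --design sim/design.yaml --fasta sim/proteins.fasta --out out/ \
    [--scorer internal|saintexpress] [--saint-binary PATH] [--saint-opts "..."] \
    [--bfdr 0.05] [--min-total 10] [--min-samples 2] [--decimals 1] [--seed 0]

# individual stages
baitform aggregate --design sim/design.yaml --out counts.tsv
baitform normalize --counts counts.tsv --out norm.tsv
baitform score     --counts counts.tsv --design sim/design.yaml \
                   --comparison test~ctrl --out results.tsv
baitform cluster   --counts norm.tsv --design sim/design.yaml --out clusters.tsv
baitform annotate  --delta -9.0 --residue C
```

`out/run_log.txt` records every default and decision actually used in a run.

The design manifest is YAML (or TSV):

```yaml
bait_gene: HRAS
bait_accessions: [P01112]
comparisons: [[G12D, WT]]
samples:
  - {sample_id: wt_1, psm_path: wt_1.psm.tsv, condition: WT}
  - {sample_id: mut_1, psm_path: mut_1.psm.tsv, condition: G12D}
```

## Notes on scope

- SAINTexpress internals are not reimplemented; the internal scorer is a
  documented surrogate (per-peptidoform Poisson mixture, prior 0.5,
  pseudocount 0.1, continuous-Poisson density for fractional counts) whose
  enriched rate is clamped to at least the control rate, so depletion is only
  discovered by scoring the reversed direction — comparisons run both ways.
- Open-search localization strings are propagated, never re-inferred.
- No raw-spectrum handling (mzML/pepXML) and no search-engine execution.
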