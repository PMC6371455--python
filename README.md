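# scsplice

Single-cell analysis of cassette-exon splicing and its DNA-methylation
determinants.

Parallel single-cell methylome-and-transcriptome protocols (scM&T-seq)
measure, in the same cell, both the splicing of cassette exons and the CpG
methylation of the surrounding sequence.  `scsplice` implements the full
analysis chain for such data:

* **PSI quantification** — per-cell splicing rates
  Ψ = inclusion / (inclusion + exclusion) with coverage floors (≥ 5 reads
  per entry, ≥ 10 cells per exon), pseudo-bulk aggregation and cross-cell
  dispersion;
* **cell/gene dispersion models** — the expected SD of Ψ across cells under
  the bimodal *cell model* (each cell expresses one isoform,
  SD = √(p(1−p))) versus the binomial *gene model*
  (SD ≈ √(p(1−p)/n), estimated by Monte Carlo at observed read depths);
* **featurization** — 607 genomic features (k ≤ 3 k-mer frequencies, mean
  conservation, lengths, splice-site PWM scores over the seven contexts C1,
  I1-5′, I1-3′, A, I2-5′, I2-3′, C2) and 826 methylation features (k-mers
  over the {A,G,T,M,U} alphabet in which every cytosine is rewritten as
  methylated M or unmethylated U, plus per-context methylation mean and
  variance);
* **association** — per-(exon, context) Spearman correlation between
  cell-level context methylation and Ψ, with Storey q-value FDR control and
  cross-state replication assessment;
* **prediction** — exon-stratified cross-validated ridge regression of
  single-cell and pseudo-bulk Ψ on the feature blocks, per-feature
  relevance, and PCA of the cell-by-feature relevance matrix;
* **splicing categories** — excluded / included / overdispersed /
  underdispersed / multimodal, assigned via Tukey fences on the deviation
  from a scaled-binomial dispersion fit; multinomial logistic-ridge category
  prediction (one-vs-rest AUC, macro-averaged), category-switch tables
  between cell states, switch prediction, and per-category methylation
  contrasts;
* **synthetic data** — a first-class generator that emits genome, GTF,
  conservation track, per-cell CpG reports and read counts with planted
  ground truth (coupling loci, categories, effect sizes), so every stage is
  verifiable end-to-end without external downloads.

## Worked example

```python
import scsplice as sc
from scsplice.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(n_exons=300, n_cells=(80, 80), seed=1))

psi = sc.compute_psi_matrix(ds.counts["A"])          # 300 exons x 80 cells
summ = sc.exon_summary(psi)
fit = sc.fit_expected_dispersion(summ["bpsi"], summ["psi_sd"])
assign = sc.assign_categories(summ, fit)

idx = sc.MethylationIndex(ds.methylation["A"])
meth = sc.context_methylation_matrix(ds.exons, ds.genome, idx)
res = sc.methylation_splicing_association(psi, meth)
print(len(res.table), "tests,", len(res.significant(0.05)), "hits at Q < 0.05")
```

Output on this configuration:

```
2096 tests, 30 hits at Q < 0.05
```

The 2096 tests are the (exon, context) pairs where both splicing and
methylation vary across ≥ 10 jointly observed cells; 30 reach Q < 0.05, of
which 28 sit at loci the generator truly coupled (the planted truth is in
`ds.truth`).  Testing the second cell state and applying the replication
rule (nominal p < 0.05 with consistent sign) replicates 28/30 discoveries
(93%).  The dispersion fit returns scale c = 0.533 with Tukey fences
−0.257 / +0.305, and the two-state category-switch table retains 95.3% of
the 300 shared exons on the diagonal.

The command line mirrors the library:

```bash
scsplice simulate --out data/ --seed 1 --n-exons 300
scsplice exons --gtf data/annotation.gtf --fasta data/genome.fa --out exons.tsv
scsplice psi --counts data/counts_A.tsv --out-prefix quantA
scsplice categories --summary quantA.summary.tsv --out catsA.tsv
scsplice run --config pipeline.yaml        # all stages, with a run manifest
```

## Layout

```
src/scsplice/
  types.py        domain types (CassetteExon, contexts, QC stats)
  io.py           GTF/FASTA/bedGraph/CpG-report/count-table readers & writers
  exons.py        candidate extraction, filters, cell QC
  simulate.py     synthetic-data generator with planted truth
  psi.py          PSI matrix, pseudo-bulk, dispersion
  dispersion.py   cell/gene model expectations
  features.py     607 genomic + 826 methylation features
  association.py  Spearman association, Storey/BH FDR, replication
  prediction.py   cross-validated ridge, relevance, PCA, transfer
  categories.py   five-way categories, switches, contrasts
  pipeline.py     stage orchestration with manifest + hashes
  cli.py          `scsplice` command group
docs/methods.md   models, parameters, design choices, limitations
```
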