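# vdnet

Integrative pathway- and network-based analysis of mRNA and microRNA
expression, built around the question: *which biological processes does a
treatment — for example 1,25-dihydroxyvitamin D3 in prostate cancer cells —
actually move, and how are they wired together and regulated?*

The package is aimed at computational biologists who have gene-level
differential-expression results (signed fold change and p-value per gene and
per microRNA) and want to go beyond a flat pathway list: merge the altered
pathways into one network, pull in the differentially expressed genes the
pathways miss, find the active subnetworks, name their functions, and overlay
the microRNA and transcription-factor regulation on top.

## The method

1. **Differential expression.** A gene is differentially expressed (DE) when
   |FC| > 1.5 and p < 0.05 (both strict); microRNAs use FC > 2 and p < 0.05.

2. **Pathway over-representation.** With N measured genes mapped to the
   pathway collection, R of them DE, and a pathway containing n measured
   genes of which r are DE, the pathway's standardized difference score is

       Z = (r − n·R/N) / sqrt( n·(R/N)·(1 − R/N)·(1 − (n−1)/(N−1)) ),

   i.e. the DE count standardized by its exact hypergeometric mean and
   standard deviation (finite-population correction included).  Significance
   comes from permuting the gene-level DE labels (add-one smoothed), and a
   pathway is *altered* when Z > 1.96, permutation p < 0.05 and r ≥ 5.

3. **Network of interconnected pathways.** Altered pathways are rewritten
   onto unified gene identifiers through a mapping table and merged; elements
   present in two or more pathways become *linking nodes*.

4. **Network extension.** DE genes that are first neighbours of pathway genes
   through protein–protein interactions (confidence score > 0.4) or
   TF→target interactions join the network, raising the fraction of the DE
   signal the network covers.

5. **Active modules.** Each gene gets z_i = Φ⁻¹(1 − p_i); a connected set A
   of k genes scores z_A = Σz_i/√k, calibrated against random gene sets of
   the same size: s = (z_A − μ_k)/σ_k.  Seeded greedy expansion from the
   top-scoring genes returns up to ten modules with bounded pairwise overlap.
   Module genes are then tested for term enrichment (hypergeometric tail,
   Benjamini–Hochberg) and terms are clustered into named groups by Cohen's
   kappa similarity of their gene memberships (κ ≥ 0.4 edges, overlapping
   neighbourhoods merged at the 50 % rule).

6. **Regulatory overlay.** MicroRNA→target interactions from a validated and
   a predicted linkset are draped over the network (one edge per pair, with
   dual-database provenance), the subnetwork of DE microRNAs and their
   targets is extracted, and a curated regulator target list (e.g.
   literature-curated vitamin-D-receptor targets) is annotated onto the nodes.

A seeded synthetic-data generator produces complete input bundles with
planted truth (DE-enriched pathways, a connected high-significance module,
DE microRNAs), so the whole chain is testable offline, and a truth manifest
lets each run be scored for recovery.

## Worked example

```python
from vdnet.simulate import ScenarioConfig, generate_scenario
from vdnet.pipeline import PipelineConfig, run_pipeline, validate_against_truth

generate_scenario(ScenarioConfig(seed=1), "bundle")
report = run_pipeline(PipelineConfig("bundle", "out", seed=1))
print(report["stages"]["expression"])
print(validate_against_truth(report, "bundle/manifest.json"))
```

prints (numbers are exact for seed 1):

```
{'n_genes': 2000, 'n_de_genes': 100, 'n_up': 50, 'n_down': 50,
 'n_mirnas': 30, 'n_de_mirnas': 9}
RecoveryMetrics(pathway_precision=0.667, pathway_recall=1.0,
                module_jaccard=0.682, de_coverage_before=0.71,
                de_coverage_after=0.96, regulator_completeness=1.0)
```

Reading the run: 100 of 2000 genes are DE (50 up, 50 down) and 9 microRNAs
are up-regulated.  The selection rule recovers all 8 planted pathways (recall
1.0) plus four background pathways (precision 0.667).  Merging the selected
pathways yields a network covering 71 % of the DE genes; first-neighbour
extension raises that to 96 %.  The top active module overlaps the planted
15-gene module at Jaccard 0.68, its genes are most enriched in the planted
annotation term, and all 9 DE microRNAs are recovered with their targets in
the overlay subnetwork.

The same run is available from the shell:

```sh
vdnet simulate --seed 1 --out bundle
vdnet pipeline run --bundle bundle --seed 1 --out out
vdnet pipeline validate --report out/report.json --manifest bundle/manifest.json
```

plus per-stage commands (`vdnet ora`, `build-net`, `extend-net`, `modules`,
`group-terms`, `overlay`) that read and write the standard formats
(TSV tables, JSON pathway documents, GMT gene sets, GraphML/SIF networks).

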