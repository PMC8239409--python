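# wpcna — weighted protein co-expression network analysis

`wpcna` is a tested, reusable implementation of a proteomics analysis
pipeline for anthracycline cardiotoxicity studies — and, more generally, for
any label-free proteomics study that asks *which groups of co-regulated
proteins respond to a treatment, and which of them matter in both an in
vitro model and patient tissue*.

Anthracyclines (doxorubicin, epirubicin, idarubicin) are effective
chemotherapeutics with dose-dependent cardiotoxicity. The analysis this
package implements starts from peptide-level LC-MS intensities of drug-exposed
cardiac microtissues (3 drugs × 2 doses × 7 timepoints, 139 samples) and of
heart-failure patient biopsies (16 samples, 3 groups), and proceeds:

1. **Hi3 quantification** (`wpcna.quantify`) — charge/modification variants
   of a peptide are consolidated by summation; redundant proteins are removed
   by Occam's razor (peptide-set containment); proteins need ≥2 unique
   peptides; protein intensity is the mean of its top-3 peptides by average
   intensity, log2-transformed.
2. **Normalization** (`wpcna.preprocess`) — per-sample additive median
   shifts: controls to the median-of-medians over proteins present in all
   controls, then each (drug, dose, timepoint) group to the median of its
   same-timepoint controls over the group's common protein set; biopsies to a
   common median over the core protein set. Values standardized to 6
   decimals; proteins with >50% missing values or zero variance removed.
3. **Signed network and modules** (`wpcna.coexnet`) — signed adjacency
   a_ij = ((1+cor)/2)^β (Pearson, pairwise-complete), scale-free topology
   diagnostics, topological overlap ω_ij = (l_ij + a_ij)/(min(k_i,k_j)+1−a_ij),
   average-linkage clustering of 1−ω, hybrid dynamic tree cut
   (deepSplit = 3, minClusterSize = 30, medoid-style assignment ignoring the
   dendrogram), module eigengenes (first principal component), merging at
   eigengene dissimilarity < 0.25, and module membership kME; proteins with
   kME ≥ 0.8 for their own module are the **weighted proteins**.
4. **Module selection and enrichment** (`wpcna.module_select`) — standardized
   treated-vs-control eigengene contrasts and a PCA separation score select
   treatment-affected modules; hypergeometric over-representation analysis
   with Benjamini–Hochberg q-values (p, q < 0.01); disease-set annotation
   counts per module.
5. **Integration and PPI hubs** (`wpcna.integrate`, `wpcna.ppi`) — proteins
   present in both datasets, weighted in either/both, log2 fold-change
   tables vs matched controls, a log2 > 10 high-expression filter, and the
   induced protein–protein interaction network on the weighted proteins
   (non-adding), with orphan removal and hub calling at degree ≥ 30.

A synthetic-data generator (`wpcna.synthetic`) reproduces the study's
structure — the 139-sample factorial design with the truncated toxic
idarubicin arm, planted co-expression modules with per-protein membership
targets, treatment effects, intensity-dependent missingness, a planted-hub
interaction graph, and a disease gene set — with full ground truth, so the
entire pipeline is testable offline.

## Worked example

Simulate a small two-module study (both planted modules carry
opposite-sign treatment shifts at the 72 h+ timepoints):

```bash
wpcna simulate --seed 1 --outdir sim --n-replicates 1 --modules 40,35 \
    --missing-rate 0.1 --effect-size 2
# wrote synthetic study (47 samples, 75 proteins) to sim
```

then analyze it with a config (`cfg.yaml`):

```yaml
inputs:
  invitro_matrix: sim/proteins.tsv
  invitro_design: sim/design.tsv
  disease_set: sim/disease.gmt
```

```bash
wpcna analyze --config cfg.yaml --dataset invitro --outdir out
# wpcna INFO invitro: 75 proteins after missingness filter
# wpcna INFO invitro: 2 modules, sizes {'turquoise': 40, 'blue': 35}
# results in out/invitro
```

`out/invitro/report.json` then contains, among other fields,

```json
"module_sizes": {"blue": 35, "turquoise": 40},
"selected_modules": ["turquoise", "blue"],
"contrasts": [
  {"module": "blue", "effect": -1.027083, "pca_separation": 0.077496},
  {"module": "turquoise", "effect": 1.042762, "pca_separation": 0.088897}
]
```

Both planted modules were recovered exactly (colors are assigned by
decreasing size), and both were flagged as anthracycline-affected: their
standardized treated-vs-control eigengene contrasts (+1.04 and −1.03,
opposite signs matching the planted up-/down-regulation) clear the
|effect| ≥ 1 selection threshold. `wpcna integrate --dir-a ... --dir-b ...`
combines two such runs into overlap sets, log2FC tables and the PPI hub
report.

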