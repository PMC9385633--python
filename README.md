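# mrgradient

Continuous prognostic stratification of bulk tumor transcriptomes by
master-regulator analysis. The package targets cohorts — such as pancreatic
ductal adenocarcinoma (PDAC) expression studies — where the clinically
relevant phenotype is not a discrete subtype but a gradient between
transcriptional programs (e.g. classical/progenitor versus basal-like, with
the immune microenvironment as a correction factor), and where that gradient
is driven by a compact core of transcription factors (TFs).

## What it computes

Given one or more log2 expression matrices (genes × samples), a gene-set
collection (GMT), a survival table, and a TF list, the pipeline:

1. **Harmonizes** the cohorts (quantile normalization to the pooled reference,
   gene median centering).
2. **Low-Rank ICA (LRICA)**: robust PCA splits the matrix into a low-rank
   part *L* (shared biology) and a sparse part *S* (aberrant entries) by
   principal component pursuit, min ‖L‖\* + λ‖S‖₁ s.t. L + S = M; then ICA
   with a smoothed-density contrast extracts independent gene-contribution
   components from *L*. Components are kept when they are heavy-tailed
   (|excess kurtosis| ≥ 3) and biologically enriched (pre-ranked GSEA
   FDR ≤ 0.05), and oriented so a reference signature scores positively.
3. **Regulon inference**: TF→target edges weighted by mutual information
   (adaptive equal-frequency binning with exact fixed-margin bias
   correction), kept at BH-adjusted permutation p ≤ 0.01, pruned by the data
   processing inequality (ARACNe-style), and signed by the Spearman
   correlation between regulator and target (activated / repressed mode).
4. **Master regulators (MR)**: each regulon is tested (hypergeometric tail)
   against a component's high-contribution genes (|loading − mean| > 2 SD)
   and weighted by the two-tailed enrichment score
   dES = ES(activated targets) − ES(repressed targets) on the component
   ranking. MRs pass at p < 0.01 and |dES| ≥ 1.
5. **MR-Gradient**: the per-patient score

   Gradient_j = Scale[ Σᵢ dESᵢ · GEᵢⱼ ]

   — each selected regulator's expression weighted by its dES, summed and
   standardized across the cohort (mean 0, SD 1). The score is a continuum,
   not a classifier; it can be projected onto new cohorts sharing ≥ 50% of
   the model's regulators.
6. **Survival association**: Cox proportional hazards on the standardized
   score (HR per SD, Efron ties), Kaplan–Meier with the optimal log-rank
   cutpoint (reported with the maximally-selected-rank-statistic correction),
   and PCA + Cox on component coordinates.
7. **Auxiliary omics**: marker-based stroma/immune abundance scores (log2
   geometric mean; association rule |r| > 0.2, p < 0.05), methylation
   component profiling (ICA on logit β, CpGs at |contribution| ≥ 3 SD,
   per-patient median β), and lipid subfamily medians correlated with the
   gradient.

A first-class synthetic-cohort generator plants every layer with known
ground truth (latent Laplace components, a signed TF→target network,
survival tied to the latent scores, β-methylation anti-correlated with the
gradient, lipid subfamilies tracking it), so the full pipeline is testable
offline; `evaluate_recovery` scores any output against the planted truth.

## Worked example

Generate a synthetic discovery cohort and run the full pipeline:

```bash
mrgradient simulate --preset default --seed 11 --out cohort/
cat > config.yaml <<EOF
expression_paths: [cohort/expression.tsv]
survival_path: cohort/survival.tsv
gene_sets_path: cohort/gene_sets.gmt
tf_list_path: cohort/tfs.txt
output_dir: run/
seed: 11
EOF
mrgradient run --config config.yaml
```

The run directory contains every intermediate (`L.tsv`, `contributions.tsv`,
`network.json`, `mrs.tsv`, `scores.tsv`, `model.json`, `survival.json`) plus
a `manifest.yaml` recording every threshold and seed used. For this seed the
manifest reports:

```
selected_components: [0, 1, 2]
prognostic_component: 2
n_master_regulators: 8
gradient_cox_hr_per_sd: 0.347
```

All three planted components pass the kurtosis + enrichment gate; component 2
(the one tracking the planted phenotype) has the strongest survival
association, and all 8 planted master regulators are recovered, e.g. from
`mrs.tsv`:

```
regulator component  enrichment_p       dES  selected
   TF0006     comp2  1.72e-64      1.918681      True
   TF0009     comp2  9.74e-19     -1.857925      True
   ...
```

A dES near +2 means the regulator's activated targets crowd the top of the
component ranking and its repressed targets the bottom (maximal activation);
the sign encodes the regulation direction along the gradient. The fitted
score yields `hazard_ratio: 0.347` per SD (95% CI 0.28–0.43, 136 events in
200 patients): higher gradient, markedly better survival — by construction,
since the generator's default ties the hazard to the first latent component
with log-HR −0.7 per unit.

Project the fitted model onto an independent cohort with
`mrgradient project --expr new_cohort.tsv --model run/model.json --out proj.tsv`,
or per stage: `mrgradient lrica|gsea|network|mra|score|survival|stroma|methyl|lipids --help`.

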