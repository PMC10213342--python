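# foldnet

Spectral coordination analysis of the BAG2–HSC70–STUB1–MAPT protein-folding
network across Alzheimer's disease severity stages.

## The problem

In Alzheimer's disease, misfolded tau (MAPT) escapes the chaperone system
that normally folds it or routes it to degradation: HSC70 (HSPA8) does the
folding, BAG2 exchanges its nucleotides, and STUB1 (CHIP) ubiquitinates
failed clients.  A natural question for transcriptomic data is whether the
*coordination* of this four-gene panel degrades as dementia progresses.
foldnet is a tested, reusable implementation of one way to ask that: for
each severity group (control / incipient / moderate / severe), form the
panel submatrix X (4 genes × n samples of log10(g+1) expression), take the
uncentered Gram matrix

    R = X Xᵀ,  R_ij = Σ_k x_ik x_jk,

eigendecompose R = Q Λ Qᵀ, and report the eigenvalues as fractions
λ̂_i = λ_i / Σ_k λ_k.  The leading fraction λ̂₁ measures how concentrated the
panel's joint (uncentered) energy is on one direction; in the study system
it climbs from ≈0.56 in controls to ≈0.79 in the severe group, and the
leading eigenvector's orientation flips between those groups (the published
control/severe leading vectors have dot product ≈ −0.944).

Around that core statistic the package provides the full analysis pipeline:
differential-expression screening (independent t-tests at p < 0.05), a
simplified soft-power co-expression module stage (|ρ_Spearman|^β with β = 8,
minimum module size 30, eigengene merging at cut 0.25), a from-scratch
4–32–1 sigmoid network regressing the MMSE cognitive score on the panel, a
from-scratch RBF max-margin classifier over (sum, SD) panel features with
ROC/AUC, and seeded synthetic-data generators that plant every structure the
pipeline assumes — so each stage is verifiable without downloading the
original accessions (GSE1297, GSE15222).  It is aimed at computational
biologists who want to apply or scrutinize the method on their own
expression tables.

## Worked example

Run the whole pipeline on a synthetic study (four panel genes over groups of
9/7/8/7 samples with planted spectra, plus 150 background genes organized
into three planted co-expression modules):

```python
from foldnet.pipeline import PipelineConfig, run_all

report = run_all(PipelineConfig(seed_sim=1, seed_nn=1, seed_svm=1,
                                out_dir="demo_out"))
print(report["spectral"]["trajectory"]["leading_fractions"])
# [0.6108129594, 0.6571283306, 0.6505354015, 0.7908318602]
print(report["modules"]["module_sizes"])
# {'unassigned': 34, 'module_1': 40, 'module_2': 40, 'module_3': 40}
print(report["nn"]["pearson_r"], report["svm"]["auc"])
# 0.9901018966 1.0
```

Reading the numbers: the leading Gram fraction rises from 0.61 (control) to
0.79 (severe) — the panel's expression becomes dominated by a single mode as
planted severity increases (the raw-intensity round trip floors log values
at zero, which lifts the low-coordination control group above its planted
0.56; the log-scale generator recovers 0.56 exactly — see
`docs/methods.md`).  The three planted 40-gene modules are recovered with
the 30 structureless noise genes plus the four panel genes left unassigned;
the held-out MMSE prediction correlates r = 0.99 with the planted linear
truth; and the classifier separates the two synthetic cohorts perfectly on
its small held-out split.

The same stages are available from the shell:

```bash
foldnet simulate --kind panel --seed 2 --out-dir sim/
foldnet preprocess --expression sim/expression.tsv --metadata sim/metadata.tsv --out-dir prep/
foldnet spectral   --expression sim/expression.tsv --metadata sim/metadata.tsv --out spectral.json
foldnet run-all --seed 1 --out-dir full_run/
```

Real data drop in the same way: `--expression` accepts a plain TSV
(first column `gene_id`) or a GEO series-matrix file
(`--dialect geo_series_matrix`), and `--metadata` a TSV with `sample_id`,
`group` (Control / Incipient AD / Moderate / Severe, or codes 1–4) and
optionally `mmse` and other clinical covariates.  Probe-to-symbol
collapsing (`foldnet.io.map_probes_to_genes`) supports max-mean, pinned
and averaging policies, with HSC70 ↔ HSPA8 aliasing built in.

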