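# sedq — mRNP condensation from Sed-seq fractionation data

`sedq` quantifies transcriptome-wide mRNA condensation from **Sed-seq**
experiments: cell lysate is fractionated by sedimentation (total /
supernatant / pellet), each fraction is RNA-sequenced, and the proportion
of each transcript's molecules in the supernatant (**pSup**) reports its
condensation state. The package is aimed at researchers studying stress
granules and translation-initiation-inhibited condensates (TIICs) in
yeast or similar systems, and at method developers who need a fully
simulated test bed with known ground truth.

## What it computes

**Mixing ratios and pSup.** Conservation of mass says `T_i = S_i + P_i`
for every transcript in the lysate, but library preparation rescales each
fraction, so in measured counts `T_i = a_S S_i + a_P P_i` with
per-experiment mixing ratios `a_S`, `a_P`. `sedq.quant` estimates the
ratios under negative-binomial count noise — by default with a
measurement-error-corrected moment estimator (the naive regression of T
on the observed S and P is attenuation-biased because S and P are noisy
too), falling back to a prior-regularized Bayesian MAP for small or
degenerate systems — and then computes

```
pSup_i = a_S S_i / (a_S S_i + a_P P_i)
```

A qPCR route (`psup_from_qpcr`, spike-in-referenced ddCq) covers
single-transcript validation experiments.

**Length-controlled condensation scores** (`sedq.scores`), all on the
log-odds scale `lopSup = log(p/(1-p))` with `mu(L)` a windowed mean over
log transcript length and `sigma(control)` the control residual SD:

- `dSed = [lopSup(control) - lopSup(treatment)] / sigma(control)` —
  stress-induced sedimentation, > 0 means condensation;
- `eSed = [(lopSup(T) - mu(L,T)) - (lopSup(ctrl) - mu(L,ctrl))] / sigma(control)`
  — escape from condensation relative to similar-length transcripts;
- `rSed` (sedScore) — within-length-bin Z-score of sedimentation (bins of
  100 transcripts, per-replicate Z averaged); > 0 sediments more than
  length-matched peers.

**Biophysical length-dependence model** (`sedq.sedmodel`): baseline
`pSup(L) = 1 - beta L^x`; under condensation the sedimented fraction is
multiplied by `exp(mu + nu L)` with a per-transcript term `mu` and a
per-nucleotide term `nu`. Fits are nonlinear least squares on the
log-odds scale; a nested F-test asks whether the length-independent term
`mu` is required.

**Translation metrics** (`sedq.translation`): spike-in-normalized
ribosome occupancy `bound/(bound+free)`, ribosome association
`TPM_bound/TPM_total`, and EDTA-corrected sucrose-cushion occupancy.

**Imaging** (`sedq.imaging`): per-cell smFISH colocalization Z-score
(spot-local marker intensity vs. 100 random in-cell windows) and the
median-rule stress-granule positivity call.

**Synthetic data** (`sedq.synth`): transcriptomes, true pSup surfaces,
NB fraction counts and spike-in polysome TPM tables with every
ground-truth quantity returned, so each stage above is testable without
any external download.

## Worked example

```bash
sedq run --out demo --seed 7
```

simulates a 2000-gene control/stress study (2 replicates, heat-shock-like
condensation `mu=0.7`, `nu=2e-4`, 5% induced genes escaping with +1.0
log-odds), quantifies it, scores it and fits the model. Highlights of the
printed report (from this exact command):

```yaml
mixing_fits:          # true a_S = 1.5, a_P = 3.0 in all four experiments
- {condition: control, replicate: 1, a_S: 1.416, a_P: 3.132, n_genes_used: 781}
- {condition: control, replicate: 2, a_S: 1.523, a_P: 2.643, n_genes_used: 774}
- {condition: stress,  replicate: 1, a_S: 1.412, a_P: 2.919, n_genes_used: 1095}
- {condition: stress,  replicate: 2, a_S: 1.455, a_P: 2.863, n_genes_used: 1113}
baseline_fit: {beta: 5.19e-05, x: 1.063}
median_delta_sed: 1.759
median_e_sed_induced: 1.203
condensation_detected: true
stress_fit: {mu: 1.472, nu: -6.71e-05, F: 619.6, p_value: 1.1e-120}
occupancy_rsed_spearman: -0.157
```

Read: the four mixing-ratio fits recover the simulated (1.5, 3.0) to
within ~10% from counts alone; the transcriptome median
dSed ≈ +1.8σ says most transcripts condensed under stress; induced genes
still escape (median eSed ≈ +1.2σ); the F-test sharply rejects a stress
model without the per-transcript condensation term; and ribosome
occupancy anti-correlates with relative sedimentation, the TIIC
signature. The individual `(beta, x)` and `(mu, nu)` values drift along
their correlated ridges here because deep stress pushes many estimated
pSup values to the measurement floor — the fitted curves still track the
data, and `docs/methods.md` discusses when the parameters themselves are
recoverable. Outputs (`counts.tsv`,
`psup.tsv`, `scores.tsv`, `model_fit.yaml`, `translation.tsv`,
`truth.tsv`, `report.yaml`) land in `demo/`, each stamped with the config
hash and seed; a rerun with the same config is byte-identical.

Every subcommand (`simulate`, `quantify`, `score`, `fitmodel`,
`translate`, `coloc`) is also a thin wrapper over the library functions —
see `sedq --help`.

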