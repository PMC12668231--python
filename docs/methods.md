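# Methods

This note documents the statistical models behind `sedq`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that matter when reproducing or
extending an analysis.

## The measurement model

A Sed-seq experiment fractionates lysate by centrifugation and sequences
three libraries: total (T), supernatant (S) and pellet (P). In the lysate
every transcript obeys conservation of mass, `T_i = S_i + P_i`. Library
preparation rescales each fraction by an unknown factor, so in measured
counts

    T_i = a_S * S_i + a_P * P_i

with per-experiment mixing ratios `a_S`, `a_P`. Counts carry
negative-binomial noise: `Var = m + m^2/phi` with a per-experiment size
parameter `phi` (`phi` around 20–100 is typical of biological RNA-seq
replication; the simulator default is 50). The quantity of interest is
the proportion of transcript i in the supernatant,

    pSup_i = a_S S_i / (a_S S_i + a_P P_i),

and its natural log-odds `lopSup`. pSup near 1 means soluble; low pSup
under stress is read as condensation.

### Estimating the mixing ratios

Only genes whose counts exceed `min_count` (default 20) in all three
fractions enter the ratio fit; pSup is still reported for every gene with
S + P > 0.

Two point estimators are provided (`model=` argument):

* **conditional** — the Bayesian regression `T_i ~ NB(a_S S_i + a_P P_i,
  phi)` with weakly-informative priors: LogNormal(0, 1) on each ratio
  (positive, median 1, unit log-scale) and half-Cauchy(0, 3) on the NB
  *overdispersion* `1/phi`. Placing the dispersion prior on `1/phi`
  rather than on `phi` matters: it is flat at the Poisson limit, so
  noise-free data are not penalized for implying `phi -> inf`. The MAP is
  found by L-BFGS on log-parameters from five restarts; full posterior
  sampling (emcee) is available via `mode="posterior"`.
* **moment** — a measurement-error-corrected least-squares estimator.
  The conditional regression treats S and P as fixed regressors, but they
  are NB measurements themselves; the resulting attenuation is small on
  `a_S` (S carries most of T) and is amplified roughly by the inverse
  pellet share on `a_P` (about +12% at `phi = 50` and mostly-soluble
  transcriptomes). The moment estimator removes the error variance from
  the Gram diagonal using the exactly unbiased NB identity
  `E[(S^2 - S) * phi/(phi+1)] = m^2`, estimates `phi` from the residual
  second moment, and shrinks the corrections to zero when residuals fall
  below the Poisson floor (so noise-free data reduce to plain least
  squares). Genes are stratified into 10 abundance groups by T and the
  group-level unbiased equations are combined with weights
  `1/mean(T)^1.5` — weights built only from group aggregates of T, which
  are independent of the S and P measurement errors, so unbiasedness is
  preserved while a handful of very abundant genes no longer dominate.
  Recovery error is ~3–4% per ratio at the standard study design
  (2000 genes, ~10^6-count fractions, `phi = 50`).

The default `model="auto"` uses the moment estimator for
well-conditioned experiments (>= 30 usable genes, identifiable S/(S+P)
spread) and the prior-regularized conditional MAP otherwise — tiny
systems and degenerate ridges (all genes with the same S/(S+P)) are
exactly where the priors are needed. When the supernatant proportion is
nearly constant across genes the ratios are only identified up to
`a_S c + a_P (1-c)`; the fit carries an identifiability warning and the
prior resolves the ridge at the symmetric point.

pSup values are clipped into `[1e-4, 1 - 1e-4]` before any log-odds
computation; genes with S = P = 0 are reported as missing.

### qPCR quantification

For single-transcript validation, per-fraction abundances come from the
spike-referenced ddCq: `A_f = E^-(Cq_target,f - Cq_spike,f)` with
amplification efficiency `E` (default 2). If different spike masses were
added to the fractions, the pellet abundance is multiplied by
`spike_mass_ratio` (pellet spike mass / supernatant spike mass, default
1) before forming pSup.

## Length-controlled scores

Sedimentation depends strongly on transcript length even without stress,
so all condensation scores control for length on the log-odds scale.

* The **windowed profile** computes, for each gene at log-length `l`, the
  mean `mu(L,T)` and SD `sigma(L,T)` of lopSup over genes within
  `l ± w/2`, where `w` is 0.02 of the full log-length range (default).
  Windows truncate at the data range; singleton windows yield a missing
  SD and a warning count. `sigma(control)` is the SD of
  `lopSup - mu(L)` over all genes in the control condition.
* **dSed** `= [lopSup(control) - lopSup(T)] / sigma(control)` — positive
  means increased sedimentation under treatment. Replicates are averaged
  on the log-odds scale before scoring.
* **eSed** `= [(lopSup(T) - mu(L,T)) - (lopSup(control) - mu(L,control))]
  / sigma(control)` — the treatment shift relative to length-matched
  transcripts; positive = escape. Because it is a difference of
  differences, any purely length-determined signal cancels exactly.
* **rSed / sedScore** sorts genes by total length (ties broken by gene
  id), bins them in groups of 100, Z-scores lopSup within each bin, flips
  the sign so positive = sediments more than length-matched peers, and
  averages Z across replicates. The final partial bin is merged into the
  preceding one rather than dropped, keeping the longest transcripts. A
  bin with zero within-bin variance yields z = 0 for its genes (each
  deviates from the bin mean by exactly nothing; 0 is the natural limit
  of the Z-score) plus a warning count; an SD below ~1e-12 of the bin
  scale is treated as zero to avoid floating-point dust from the mean
  subtraction.

Scoring is typically restricted to genes passing the all-fraction count
filter in every experiment (`quant.filter_quantified_genes`): a gene with
five pellet reads can swing its lopSup by several units, and those heavy
tails dominate score noise if left in.

## Biophysical length-dependence model

The baseline model for an unstressed transcriptome is a power law in
length for the sedimenting fraction:

    pSup(L) = 1 - beta * L^x.

Under condensation, inter-mRNA interactions multiply the sedimented
fraction by `exp(sign * (mu + nu L))`: `mu` acts per transcript, `nu` per
nucleotide. The typeset form of the stress multiplier is ambiguous about
the grouping and sign of the exponent, so the convention is an explicit
flag: `exponent_sign = +1` (default) means positive `mu`, `nu` increase
condensation; both conventions round-trip through the fitter.

Fitting minimizes squared error of logit(pSup) (residuals are
approximately normal on that scale, away from the boundary — see below).
The baseline fit uses trust-region least squares on `(log beta, log x)`
from a grid of 8 starts; the stress fit holds the control-condition
`(beta, x)` fixed and optimizes the enabled subset of `{mu, nu}`, seeding
the two-parameter fit with each single-parameter optimum so the full
model provably dominates its nested restrictions. Convergence tolerances
are 1e-12; predicted sedimented fractions are capped at `1 - 1e-6` before
the logit.

The need for the length-independent term is tested by the nested F-test

    F = ((RSS_reduced - RSS_full)/df_num) / (RSS_full/df_den),

`df_num` = difference in free parameters, `df_den = n - p_full`, p from
the F distribution.

**Boundary caveat.** `logit(1 - f)` has leverage `1/pSup` and severe
curvature as the sedimented fraction approaches 1. When a design places
transcripts at the pelleting boundary (essentially fully pelleted, pSup
at the measurement floor), the local-linear approximation behind the
F-test degrades and its type-I error can inflate several-fold; censoring
boundary observations does not fix this robustly because truncating the
noise distribution near a cut biases the neighboring residuals. The
calibration study in the acceptance suite therefore simulates from the
model's own assumptions — every true pSup interior (> 0.25; lengths
capped at 4.5 kb with `beta = 5e-5`, `nu = 5e-5`) — where the test is
well calibrated (type-I ~0.03–0.075 across designs at alpha = 0.05,
power ~1 for `mu = 0.5` at n = 3000, noise SD 0.3). For real analyses
with deeply condensed conditions, treat the F statistic as descriptive
rather than inferential, or fit on a length range where pSup stays off
the floor. Parameter point estimates share the caveat: under deep stress
`(mu, nu)` drift along their correlated ridge even though the fitted
curve tracks the data.

## Translation metrics

Polysome fractionation with spike-ins allows absolute occupancy:
abundances in each fraction are divided by the median abundance of the
spike-in transcripts with more than 100 estimated counts in that
fraction (error if none qualify), making the pipeline exactly invariant
to per-fraction sequencing depth. Then occupancy =
`bound/(bound + free)` per gene; ribosome association =
`TPM_bound/TPM_total` (no upper bound; suited to stressed samples where
condensed RNA may pellet out of the gradient). Sucrose-cushion occupancy
uses the EDTA contrast: EDTA dissolves ribosomes but not condensates, so
occupancy = `pSed(-EDTA) - pSed(+EDTA)`, floored at zero; a renormalized
variant divides by `1 - pSed(+EDTA)`. The correction formula is
deliberately simple — the assay does not resolve how EDTA-resistant
pelleting partitions within a single transcript pool, and both variants
are reported options.

## Imaging scores

The colocalization score asks whether RNA spots sit on brighter marker
(e.g. Pab1) regions than chance within the same cell: the spot statistic
is the mean over spots of the mean marker intensity in a 3x3 window
around each spot centroid; the null sample is 100 random in-mask 3x3
windows (centers uniform over mask pixels whose window fits the image,
drawn with replacement, not excluded from spot neighborhoods); the score
is `z = (spot statistic - null mean)/null SD`, computed independently
per cell so background differences cancel. The score is exactly invariant
to affine rescaling of the marker image. With one spot per cell the null
z is ~N(0,1) across cells; with k spots its SD shrinks toward 1/sqrt(k)
(the spot statistic averages k windows) — comparisons should therefore
use matched spot counts or rely on the per-cell null as here. Constant
marker images and spotless cells yield missing scores with warnings.

Populations are called SG-positive when the median number of stress
granules per cell exceeds zero; the even-count median uses the midpoint
convention, so a median of 0.5 is positive.

## The synthetic-data generator

`sedq.synth` emulates the study conditions end to end:

* transcript lengths log-normal (median 1.5 kb, log-SD 0.5, truncated to
  0.1–20 kb), UTR lengths log-normal around yeast medians;
* abundances log-normal (log-SD 1.0, about a 150-fold central range);
* true pSup from the biophysical model with baseline `beta = 1e-4`,
  `x = 1` — median-length transcripts ~0.85 soluble, short ones ~0.9,
  matching a mostly-soluble unstressed transcriptome — clipped to
  [0.001, 0.999] and jittered by Normal(0, 0.25) on the log-odds scale;
* stress applies `exp(mu + nu L)` (defaults `mu = 0.7`, `nu = 2e-4`) and
  adds an escape offset `delta_e` (default +1.0 log-odds) plus an
  abundance induction (default 4-fold) to the induced genes (default 5%);
* counts NB with `phi = 50` and fraction depth factors implying
  `a_S = 1.5`, `a_P = 3.0`; `simulate_study` draws the gene-level
  log-odds jitter once and shares it between control and stress
  (condition-persistent gene effects), so eSed isolates the escape
  offset;
* polysome TPM tables carry spike-in rows with one shared true abundance
  across fractions and arbitrary per-fraction scales.

Every operation is deterministic given its seed, and one master seed
drives a pipeline run.

What the generator does **not** emulate: UMI/duplication artifacts,
mappability and length-dependent quantification bias, replicate-specific
mixing-ratio drift, correlated dispersion across fractions, isoform
mixtures, and 3-D imaging. Passing tests demonstrate correctness of the
estimators under the stated noise model, not robustness to those
artifacts.

A note on attainable pSup accuracy: with `phi = 50` and a 3-fold
under-sampled pellet (`a_P = 3`), the plug-in pSup carries an irreducible
per-gene error of roughly `p(1-p) * sqrt(CV_S^2 + CV_P^2)` ≈ 0.03–0.04
even with the mixing ratios known exactly; averaging replicates, not
deeper modeling of single experiments, is the way past that floor.

## Pipeline and formats

All tables are TSV (UTF-8, `.` decimal, `NA` missing, gzip by
extension) with `#`-prefixed header lines carrying the config hash and
seed. The pipeline config is YAML with unknown keys rejected; all
randomness derives from one seed; timestamps go only to the run log, so
rerunning the same config produces byte-identical outputs. Stage order:
simulate (or load) → quantify → score → model fit → translation →
report. Filter counts (genes dropped by `min_count`, clipped pSup
values, undefined windows/bins) are logged.

## Known limitations

* Mixing-ratio estimation assumes a shared NB size across genes and
  fractions; strongly gene-dependent dispersion would bias `phi` though
  the stratified moment estimator keeps the ratios consistent.
* The F-test and the model parameters are untrustworthy when the data
  pile up at the pelleting boundary (above).
* eSed windows are truncated at the range edges, so the shortest and
  longest ~1% of transcripts have one-sided length cohorts.
* Differential abundance/association across conditions is consumed from
  external tools (e.g. DESeq2 log2FC), not recomputed here.
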