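# Methods

## The analysis

`erpstate` implements a state-based dynamic-functional-connectivity (DFC)
analysis of multichannel event-related potentials (ERPs). Two viewing
conditions ("comfort" and "discomfort") are compared within subjects. The
chain is:

1. **Epoch conditioning.** Trials (channels × time epochs from −200 ms to
   +3000 ms around stimulus onset) are re-referenced to the instantaneous
   average across channels and baseline-corrected on the pre-stimulus
   window [−200, 0) ms.
2. **ERP extraction.** The ERP is the element-wise mean across trials.
3. **Electrode selection.** Mean ERP amplitudes are computed in four
   component windows — P1 (90–130 ms), early N1 (100–140 ms), late N1
   (180–220 ms), P3 (280–320 ms); window sample inclusion is half-open
   [start, end) in post-onset time. Per channel × window, a two-sided
   paired t-test across subjects compares conditions; a channel is
   selected if any window has p < α (default 0.05, deliberately
   uncorrected). The selected set is the union over windows; the
   per-window table is emitted so any stricter pooling rule can be applied
   downstream.
4. **State inference.** A hidden Markov model with multivariate Gaussian
   emissions N(μ_k, Σ_k) is fitted to the selected channels' ERPs, one fit
   per condition with identical restart seeds. Each subject is a separate
   observation sequence sharing parameters (the chain restarts at the
   initial distribution π at subject boundaries — literal concatenation
   would fabricate a transition between subjects). Each channel is
   z-scored within subject before fitting (optional) so no subject's
   amplitude scale dominates the pooled covariances. By default only
   post-onset samples (0–3000 ms) enter the fit. Σ_k is read as state k's
   functional-connectivity pattern.
5. **State metrics.** From the Viterbi path: fraction of time (fractional
   occupancy), mean dwell time (mean run length, in samples with a ms
   conversion), and occupancy split into an early (≤ 1100 ms) and late
   (> 1100 ms) period. Group occupancy timecourses support a
   posterior-mean mode (default) and a decoded-proportion mode, since
   either convention is used in the field.
6. **Group statistics.** Subjects lacking a required state are excluded;
   then a 2×2×2 within-subject ANOVA (condition × state × period, states =
   the strong- and weak-connectivity states) on per-period fractional
   occupancy, all 12 simple effects, and per-state paired t-tests on
   overall occupancy and dwell time.

## HMM fitting

Maximum-likelihood EM (Baum–Welch). The E-step uses scaled (per-step
normalized) forward–backward recursions, numerically safe for sequences of
at least 10⁵ samples; emission log-densities are computed through Cholesky
factorizations, evaluated once per iteration on the pooled samples. The
M-step pools responsibilities across sequences; π is the mean of
per-sequence initial posteriors; covariance updates carry a ridge of
10⁻⁶ × mean diagonal to stay positive definite. Restarts are initialized
from random per-sample Dirichlet(1) responsibilities with seed
`seed + restart_index`; the restart with the highest final log-likelihood
wins (the maximum-likelihood analogue of choosing the minimum
variational free energy among runs). Convergence: relative log-likelihood
change < `tol` (default 10⁻⁶) or `max_iter` (default 500). A state whose
pooled responsibility falls below one sample-equivalent is re-initialized
once per restart from a random sample; a second collapse abandons the
restart. Viterbi runs in log space; argmax ties break toward the lower
state index, making decoding deterministic. The variational-Bayes
machinery of other HMM toolboxes (priors over parameters, free-energy
model scoring) is deliberately out of scope: the ML version is exactly
specified and testable against enumeration oracles.

Defaults follow the reference analysis: K = 4 states, 20 restarts.

### State identity across fits

The two conditions are fitted independently, so state labels are
arbitrary per fit. States are aligned by solving a linear assignment
problem on the Pearson correlation between the fits' connectivity
patterns (upper-triangle entries of the correlation-form Σ_k). On the
reference (comfort) fit, the "weak" state is the one with the smallest
mean |off-diagonal correlation| and the "strong" state the largest. The
permutation and per-pair similarities are written to `matching.json` so
the alignment is auditable.

## The synthetic study generator

No public recording exists for this design, so the generator reproduces
the statistical structure the analysis assumes — not EEG physiology:

- **States.** K states over M channels. Covariances are built from random
  Wishart-style correlation matrices via Q·diag(λ)·Qᵀ + εI
  (ε = 10⁻⁶·mean λ). The weak state's off-diagonal correlations are
  shrunk toward 0 (×0.1); the strong state is blended (weight 0.8) toward
  a rank-one structure with |correlation| 0.7 and sign-balanced loadings.
  The sign balance matters: a uniform-sign (common-mode) pattern would be
  removed by average re-referencing, which projects out the channel mean;
  real multichannel connectivity is not a single global factor, and the
  emulated strong state must survive the reference step the pipeline
  itself applies. With few channels the average reference still imposes a
  correlation floor of about −1/(M−1) on the weak state (≈0.14 at M = 8);
  the weak < strong ordering is preserved.
- **Means.** State means are i.i.d. N(0, `mu_scale`²) per channel
  (default 2): states differ in both mean and covariance, as ERP states
  do (components ride on connectivity changes).
- **Dynamics.** A sticky baseline transition matrix (self-probability
  0.92 per sample ⇒ mean dwell ≈ 12.5 samples). The chain is
  time-inhomogeneous: before the 1100 ms split the strong-state column is
  multiplied by an early bias (default 2.0); after it, the weak-state
  column by a per-condition late bias (defaults: comfort 1.0, discomfort
  2.5), rows renormalized. This makes late weak-state occupancy the
  condition effect, the pattern the statistics stage must detect.
  Per-subject transition matrices are Dirichlet perturbations of the
  baseline rows (concentration 200 ⇒ entry s.d. ≈ 0.02), giving realistic
  between-subject variability; each subject keeps one matrix across both
  conditions so the condition contrast is purely the late bias.
- **Signals.** The ERP template is a per-time-point draw from the active
  state's Gaussian, smoothed with a short moving average (default 5
  samples; at 512 Hz ≈ 10 ms — kept small relative to dwell time because
  the smoothing mixes adjacent states' samples and blurs the state
  covariances). One condition's template gets an additive component
  effect (default +2 signal units on 3 channels in 90–130 ms), emulating
  an ERP amplitude difference. Trials are template + white channel-
  independent noise (s.d. 1); pre-stimulus samples are noise only, so
  baseline correction operates on actual noise. Amplitude units are
  arbitrary; every threshold in the package is relative.

What the generator does **not** emulate: 1/f background spectra, ocular or
muscle artifacts, volume conduction, electrode geometry, spatially
correlated noise (available as an extension point, off by default).
Passing tests therefore demonstrate that the estimator chain recovers the
structure it assumes, not that it is robust to real-EEG nuisance
structure.

## Statistics

For a 2×2×2 all-within design every ANOVA effect has one numerator degree
of freedom, so each effect is computed exactly as the squared paired t of
its within-subject contrast (F = t², df (1, n−1)); sphericity corrections
are moot at 1 df. Simple effects are paired t-tests on the corresponding
slice. Zero-variance contrasts are flagged (`degenerate-zero`: t = 0,
p = 1; `degenerate-infinite`: |t| = ∞) rather than raised, so constant
cells cannot crash a run. Subject exclusion follows overall state
presence: a subject is dropped when a required state never occurs in
either condition's decoded path (a stricter per-period rule is available
via `per_period=True`, but with short scaled-down sequences it excludes
many subjects whose occupancy is merely 0 in one period, which is a valid
value for the ANOVA). No multiple-comparison correction is applied to
simple effects, matching the reference analysis; a Bonferroni option
exists downstream of the emitted tables.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at reduced size chosen
to preserve the estimation regime: 34 subjects, 8 channels, 64 Hz
sampling (192 post-onset samples), 8 trials, smoothing window scaled with
the sampling step (1 sample at 64 Hz ≈ the default 5 at 512 Hz), K = 4
and 20 restarts for the end-to-end runs; parameter-recovery experiments
use 20 sequences × 1500 samples drawn directly from the homogeneous HMM.
Calibration experiments use 500 simulated null studies of 30 subjects.
Key tolerances: EM convergence 10⁻⁶ relative (10⁻⁵ in pipeline-scale
runs); covariance ridge 10⁻⁶ × mean diagonal; oracle agreement asserted
at 10⁻¹⁰; identity checks at 10⁻¹²–10⁻⁸.

## Known limitations

- Gaussian emissions model zero-lag covariance only; no autoregressive or
  spectral state models, no time-delay embedding.
- Model order K is user-set; no free-energy or information-criterion
  model selection.
- The weak/strong labelling assumes the fitted states actually span a
  connectivity gradient; on data without such structure the labels are
  still assigned (argmin/argmax) but not meaningful.
- With very short sequences the Viterbi-based occupancy is biased toward
  sticky states relative to posterior-mean occupancy; both timecourse
  modes are exposed for this reason.
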