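# Methods notes

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model of the synthetic cohorts

Each simulated recording is the sum of three components:

1. **Microstate component.** A first-order Markov chain over k = 4 unit-norm,
   average-referenced template topographies; the active template is scaled by
   a band-limited (8–10 Hz) Gaussian carrier. The default mean dwell time is
   80 ms (geometric dwell distribution), inside the 50–100 ms range typical of
   resting microstates. Template amplitude defaults to 3 µV.
2. **Phase-lag couplings.** For each configured pair, a complex analytic
   carrier A(t) band-limited to the coupling band is synthesized in the
   frequency domain (positive-frequency support only, so Re A has A as its
   exact analytic signal). Channel i receives Re A; channel j receives
   s·Re(A e^{−iθ}) + (1−s)·Re B with B independent. At strength s = 1 the
   pair's true phase difference is the constant lag θ; at s = 0 the phases
   are independent. Planted covariate effects act on s: s = s₀ + slope·z(AES),
   clipped to [0, 1].
3. **White sensor noise**, default 1 µV.

Covariates are drawn through a Gaussian copula on a latent apathy variable:
AES = 18 + Gamma(1.8, 4.5) quantile-transformed from the latent (integer,
clipped to [18, 39]; right-skewed, median ≈ 24.5, mean ≈ 26, SD ≈ 6), age
68 ± 7.7 y, education 14.6 ± 3 y, MMS 25–30, LED log-normal (median ≈ 570
mg/day), sex 35% female, plus BDI and UPDRS-III. Default confound–apathy
copula correlations: age 0.30, sex 0.10, education −0.20, MMS −0.30, LED
0.20. Five cognitive z-scores load 0.7 on an initiation factor that loads
−0.45 on apathy, giving a composite with Cronbach's α ≈ 0.8; the two
speed-type scores are stored sign-flipped, as such tests arrive in practice.

**What the generator does not emulate:** volume conduction through a head
model (couplings are planted directly at sensors), artifacts (blinks,
muscle), 1/f background spectra, and non-stationarities beyond microstate
switching. Passing tests therefore demonstrate correctness of the *analysis
chain* under controlled truth, not robustness to real-world EEG artifacts.

### Desk-scale defaults and the cohort-level fast path

Defaults are 32 channels / 250 Hz / 180 s (the study-scale 256 channels /
1,000 Hz / 12 min remain configurable), so a full cohort runs in minutes.
Calibration experiments that need hundreds of replicate cohorts — the
family-wise error rate under the global null (400 replicates) and detection
power (50 replicates) — use `simulate_cohort_connectivity`, which draws
per-subject ROI-edge values directly from the same covariate model: edge
baselines U(0.05, 0.25), a small per-edge age loading (so residualization has
real work to do), measurement noise of SD 0.02 (the order of PLI sampling
noise from 16 × 4-s epochs), and planted effects acting multiplicatively in
log-connectivity units (the analysis operates on log-connectivity; an
additive effect would drive low-baseline edges into the floor and make power
non-monotone in the slope). The frozen default planted slope is −0.4
log-units per SD of apathy (~33% lower connectivity per SD). The full
time-series path is exercised end to end by the 40-subject planted-effect
cohort in the acceptance script and by the pipeline tests.

## Preprocessing

* **Filtering.** 4th-order Butterworth per band, applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase — essential, since PLI is a pure phase
  statistic. Bands: theta 4–8, alpha1 8–10, alpha2 10–13, beta 13–30 Hz;
  delta 1–4 Hz participates only in the band-power analysis (denominator
  range 1–30 Hz, configurable).
* **Sliding-window Hilbert phase.** 4-s Hann-tapered windows with 50%
  overlap; each window contributes the central half of its analytic signal,
  tiling the recording exactly once. The first/last quarter window and a
  filter-transient margin of max(3 s, 6 cycles of the band's low edge) at
  both recording ends are flagged invalid; samples with ~zero analytic
  amplitude get NaN phase (undefined) rather than phase 0, so they cannot
  bias PLI sign counts.
* **Numerical floor.** A finite Hann window leaks a small negative-frequency
  image into the analytic signal. For alpha-band carriers the induced phase
  jitter is ~2·10⁻⁵ rad, with spikes to ~10⁻⁴ rad where the narrowband
  envelope dips (after band-pass filtering). The planted-lag constancy test
  asserts < 5·10⁻⁴ rad; sub-10⁻⁶ recovery is not achievable with windowed
  analytic signals of this length and is not claimed.
* **Relative band power** uses Welch spectra (4-s Hann segments); frequency
  bins are assigned half-open (low ≤ f < high), so a band set tiling the
  total range sums to exactly 1 per channel.

## Microstates

Maps are sampled at local GFP maxima and clustered with polarity-invariant
k-means: assignment by squared spatial correlation, template update by the
leading eigenvector of the cluster scatter; best of n_restarts (default 10)
by within-cluster dispersion; backfitting labels every sample by maximal
|correlation|, with 30-ms minimum-segment smoothing (configurable) to avoid
1–2-sample flickers fragmenting epoch extraction. Models are fitted per
subject.

k is selected by the Krzanowski–Lai index
KL(k) = |DIFF(k)|/|DIFF(k+1)|, DIFF(k) = (k−1)^{2/m} W_{k−1} − k^{2/m} W_k,
maximized over the interior of a contiguous k range. Featureless data
(a single topography plus noise) produce a flat KL curve meandering around
1–2, while genuine k-fold structure yields peaks an order of magnitude
higher; a winning KL below 5 therefore triggers the documented fallback to
the smallest candidate k. k can always be fixed directly (the reference
analysis uses k = 4).

## Connectivity

Phase differences are wrapped to (−π, π] before sign-counting (unwrapped
differences of wrapped phases flip signs spuriously); sign(0) contributes 0,
NaN (undefined-phase) samples are excluded per pair. Epochs are the *first*
n stretches of each class in temporal order — deterministic and
reproducible. The per-stage default epoch length is the historical 4,000
samples; the pipeline config instead specifies the epoch in seconds (default
4 s × rate) so scaled-down sampling rates keep the same epoch duration.
Fewer than the target 4 epochs × k classes are tolerated: all available
matrices are averaged and the per-class coverage is reported in the results
bundle. ROI aggregation takes the mean over cross-region electrode pairs;
within-region pairs are excluded and the diagonal stays zero. The packaged
22-ROI map covers the default 32-channel montage (11 regions per hemisphere;
Fz/Cz/Pz/Oz deliberately unmapped).

A note on nulls: the expected PLI of L *independent* phase samples is
√(2/(πL)), but narrowband phase differences decorrelate only at ~1/bandwidth
(≈ 0.3 s in alpha2), so a 4-s epoch carries ~12 effective samples and the
null msPLI of uncoupled narrowband channels sits near 0.1, far above the
iid-sign level. Tests assert the iid identity on iid phases and the
narrowband null at its honest level.

## Graph measures

Edge length is 1/weight (∞ for absent links); shortest paths by Dijkstra;
Lw uses the harmonic-mean form so disconnected pairs contribute 0. The
weighted clustering coefficient is the triangle-intensity form
Ci = ΣΣ W_ik W_il W_kl / ΣΣ W_ik W_il (Ci = 0 for nodes with < 2 nonzero
links). Γ and Λ normalize by the mean over 50 surrogates obtained by
permuting the off-diagonal weights (symmetry and weight distribution
preserved; degree-preserving rewiring is ill-defined for dense weighted
matrices); an all-equal-weight matrix returns exactly 1. Radius and diameter
are the extreme node eccentricities (not the extreme pairwise distances —
the minimum pairwise distance would trivially be the strongest edge).
Assortativity Rw is the Pearson correlation of endpoint degrees over both
orderings of each edge, NaN (never silently 0) when degree variance is zero.
Degree is reported as mean link weight; degree diversity Kw uses node
*strength* (sum of weights), the convention under which the unit-star
fixture gives Kw = 2 — the two differ only by the constant factor (n−1),
which no correlation analysis can see.

## Statistics

AES is square-root transformed (right-skewed; normality is checked with the
Lilliefors test — table approximation by default, a 10,000-draw Monte-Carlo
null as an option). Connectivity is log transformed and residualized
edge-wise by OLS on age, sex (0/1), education, MMS and LED; only the
connectivity side is residualized by default (an option residualizes the
outcome too). Spearman ρ uses mid-ranks and the t-approximation for
uncorrected p. Family-wise correction: outcome permuted across subjects,
max-|ρ| over the edge family per permutation, p = (1+B)/(1+N) so p is never
zero. Testing is two-sided on |ρ|.

Because ranks are invariant under monotone maps, the sqrt/log transforms
change no Spearman statistic — asserted as a test, which also means the
transforms matter only for the normality summaries and any parametric
reading of the residuals.

**Calibration subtlety.** With confounds correlated to the outcome, the
residualize-values/permute-outcome scheme is *conservative*: the observed
outcome's confound component is annihilated against the residuals while
permuted outcomes' components are not, deflating the observed statistic
relative to its permutation null (measured FWER ≈ 0.02 at nominal 0.05).
Under the exchangeable global null (outcome independent of confounds) the
test is exact (measured 0.04–0.06). The acceptance suite checks the nominal
level on the exchangeable null and conservativeness (≤ 0.07) on the
confounded null. This is a property of the published procedure itself, not
of this implementation.

The median-split ROC classifies AES ≤ 24 vs ≥ 25 from a single edge's
connectivity, sweeping all thresholds (trapezoidal AUC, Youden-optimal
operating point); the score is used as given, so markers that decrease with
apathy should be negated by the caller (the pipeline does).

## Problem sizes used by tests and the acceptance script

Microstate recovery runs on 120-s recordings at noise 0.05 µV; k-selection
robustness on twenty 60-s recordings at noise 0.3 µV; FWER on 400 cohort
replicates (n = 40, 231 edges, 500 permutations); power on 50 replicates
(1,000 permutations); the end-to-end cohort on 40 subjects × 60 s with 2,000
permutations. The graph-measure oracle is exhaustive over all 4,096 weighted
graphs on ≤ 4 nodes with weights {0, 0.25, 0.5, 1} plus a seeded audit of
600 five-node graphs — the property is stated for the whole family; the
enumeration size is what a path-enumeration oracle makes practical.

## Known limitations

* Sensor-space analysis only; no source projection, no head model.
* The reference scheme of the emulated recordings is unstated upstream; the
  simulator produces average-referenced topographies and no re-referencing is
  applied (configurable average reference would be the natural extension).
* EDF can be read (via MNE) but not written — no EDF writer is available in
  the dependency set; the simulator's native on-disk format is the documented
  TSV matrix dialect.
* Group-level (multi-subject) microstate templates, alternative connectivity
  estimators (coherence, wPLI, AEC), minimum-spanning-tree metrics and
  FDR/Bonferroni alternatives are out of scope.
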