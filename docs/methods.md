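# Methods

`pvint` analyzes whole-cell current-clamp recordings of hippocampal CA1
parvalbumin-expressing interneurons (PV+INTs): it extracts the intrinsic
membrane and firing features that define the fast-spiking (FS),
intermediate-spiking (IS) and non-fast-spiking (NFS) physiological
subtypes, discovers those subtypes without supervision, quantifies unitary
inhibitory transmission and its short-term depression, detects
depolarization block, and measures axonal/dendritic morphometry.  Because
no raw recordings accompany the published feature tables, the package
ships a synthetic-data generator whose defaults reproduce the tabulated
per-genotype feature distributions; every estimator is validated by
parameter recovery against that generator.

## Units and sampling

All quantities use mV, pA, ms, MΩ, pF and Hz; converters live only at the
I/O boundary.  Traces are uniformly sampled (default 0.05 ms = 20 kHz).
Non-uniform sweeps are rejected at load rather than resampled, because the
10 mV/ms derivative criterion for the AP threshold is sensitive to the
sample grid.

## Intrinsic feature definitions

* **AP threshold** — voltage where the centred-difference dV/dt first
  reaches 10 mV/ms in the rising phase, found by walking back from each
  detected peak through the contiguous run of ≥ 10 mV/ms samples.
  Spike peaks are local maxima above −10 mV separated by ≥ 1 ms.
* **AP amplitude** — threshold to peak.  **Half-width** — width at
  threshold + amplitude/2 with linear interpolation of both crossings
  (0.05 ms sampling is coarse next to 0.4 ms widths).
* **AHP amplitude** — threshold voltage minus the trough between the peak
  and the next spike's threshold or +50 ms, whichever comes first.
* **Input resistance** — least-squares slope of steady-state deflection
  (mean of the last 200 ms of the step minus baseline) against step
  current over the −200..+50 pA family; sweeps containing spikes are
  excluded.  Steady state rather than peak deflection is used so the same
  window serves the sag computation.
* **Membrane time constant** — single-exponential fit to the average of
  ≥ 5 aligned −20 pA / 400 ms pulses, fit window onset +0.5 to +80 ms.
  The window is deliberately short: with a slow (≥ 100 ms) H-current sag
  superposed on the charge curve, an 80 ms window keeps the fit bias
  below 10% for τm up to 15 ms, whereas windows of 150–200 ms bias τm
  low by 12–16%.  The window is a parameter (`fit_ms`).
* **Capacitance** — Cm = 1000·τm/Rin (pF).
* **Rheobase** — smallest step of the ascending 50 pA family with ≥ 1
  spike; censored (None) when nothing fires.
* **Firing frequency** — spike count in the first 500 ms of the train at
  the sweep nearest 2× (3×) rheobase, divided by 0.5 s.  "Nearest grid
  sweep" resolves the ambiguity of non-grid multiples.  **Adaptation
  ratio** — mean of the last three inter-spike intervals over the first
  three; undefined (null) below 7 spikes.  When the 3× sweep is in
  depolarization block, FF3x is substituted by the maximum firing
  frequency across non-blocked sweeps.
* **Sag index** — (Vrest − Vsag)/(Vrest − Vhyp) on the hyperpolarizing
  sweep whose steady state lies nearest −80 mV; Vsag is the last-200 ms
  mean, Vhyp the extremum of a 2 ms boxcar-smoothed trace (smoothing
  removes the ~0.7 mV noise-floor bias of a raw 10⁴-sample minimum while
  leaving the ~100 ms sag trajectory untouched).
* **Depolarization block** — a sweep is *blocked* when spiking ceases
  before 80% of the step while the mean voltage over the final third
  stays above the cell's AP threshold; the block current is the first
  blocked amplitude of the ascending ramp, censored at 1500 pA.  Both
  constants are exposed (`BLOCK_CEASE_FRAC`, `BLOCK_PLATEAU_FRAC`); the
  published material shows example traces but no numeric rule.

## Subtype discovery

Clustering uses seven features: AP half-width, FF at 2× and 3× threshold,
adaptation ratio at 2×, input resistance, rheobase and sag index — each
log10-transformed and z-scored (SD floor 10⁻¹² tolerates constant columns
in toy inputs).  Cells with any missing clustering feature are excluded
and reported.

The cluster number is chosen by majority vote of five validity indices
evaluated on K-means partitions over k = 2..8: silhouette,
Calinski–Harabasz, Davies–Bouldin, Hartigan (smallest k with H(k) ≤ 10)
and the gap statistic (50 uniform-box reference sets, Tibshirani
one-standard-error rule, evaluated from k = 1).  Ties break by mean
silhouette.  A gap vote for k = 1 vetoes the others and declares the data
unclustered — the guard that keeps a single Gaussian blob from being
split in two (silhouette and Calinski–Harabasz otherwise prefer k = 2 on
any unimodal cloud).  The partition is K-means (k-means++, 100 restarts,
best within-cluster sum of squares, seeded) on the feature space
directly; PCA is computed for reporting only, because clustering in
feature space is the reproducible reading of the original procedure.
Ward-linkage agglomerative clustering at the same k provides a
cross-check, summarized as the adjusted Rand index between the two
partitions.

Semantic labels come from ranking cluster means of FF at 2× threshold —
FS fastest, NFS slowest, IS in the middle at k = 3 — the ordering that
holds in every genotype of the reference tables.  Composition tables
report nearest-integer percentages; note 67/83 = 80.7% prints as 81.

The composition test is a two-sided exact test of independence on the
r×c genotype-by-subtype table: full enumeration of tables with the
observed margins, summing probabilities of tables no more likely than the
observed one (for 2×2 this reduces to classical Fisher).  Above ~2·10⁶
candidate tables it falls back to Monte-Carlo sampling with fixed margins
and flags the result.

## Synaptic physiology

IPSCs recorded with a high-chloride internal at −70 mV are inward;
amplitudes are reported as positive magnitudes.  Per-trial responses are
peak deflections in a 0.5–8 ms window after the presynaptic AP peak,
relative to a local baseline (mean of the last 0.5 ms before the AP — a
short window so the decaying tail of the previous IPSC in 50 Hz trains
cancels instead of biasing the next pulse; the failure criterion's SD
uses the preceding 5 ms).  A trial fails when its peak stays below 3
baseline SDs; the threshold is a package constant, declared in place of
the unstated manual criterion of the original analysis.  Potency averages
successes; amplitude averages all trials with failures as zero, so
potency ≥ amplitude with equality iff nothing fails.  Latency is the
time from AP peak to the first 5%-of-potency crossing, averaged over
successes; decay is a single-exponential fit to the average success.
Train dynamics (25 APs at 50 Hz) normalize per-pulse mean amplitudes to
pulse 1; "end of train" is operationalized as pulses 21–25.  Even with
no depression, temporal summation leaves a ~2% bias in a
peak-minus-baseline estimator at 50 Hz; the tests budget for it.
Spontaneous EPSC detection is a hysteresis threshold crossing at 4× the
robust (MAD) SD of the raw baseline on a lightly smoothed trace, with
2 ms refractory merging; statistics are flagged insufficient below 50
events.  Connection probabilities carry Clopper–Pearson 95% intervals.

## Morphometry

Sholl profiles count segment crossings of concentric rings (default
10 µm spacing) centred on the soma centroid; a segment crosses ring r
when d_min < r ≤ d_max of its endpoint distances, so collinear chains
never double-count.  Polar histograms assign each segment's x–y projected
length to the 10° bin of its direction; horizontal (150–210°, 330–30°)
and vertical (60–120°, 240–300°) percentages are computed from exact
angles, not bin membership, to avoid quantization bias at band edges.
Rotating a reconstruction by 90° about the soma swaps the two
percentages exactly, and the Sholl total is rotation-invariant — both are
tested properties.

## The synthetic-data generator

The generator is a hybrid phenomenological model, not a conductance
model; its purpose is to make every extracted feature directly
controllable so parameter recovery is well-posed.

* **Subthreshold**: closed-form RC charge (designed Rin, τm) plus a slow
  (τ_H = 150 ms) relaxation producing the sag; the fast-component
  amplitude is calibrated per sweep so the realized deflection extremum
  equals steady-state/sag exactly.  The −20 pA τ-pulses are generated
  sag-free on the rationale that a 1–2 mV deflection barely engages the
  H-current.  Passive depolarization below rheobase is capped 2 mV below
  threshold.
* **Spiking**: spike times are scheduled from a designed f–I curve —
  piecewise linear through (rheobase, 2 Hz), (2×, FF2x), (3×, FF3x),
  extrapolated above and capped at 400 Hz — with geometric inter-spike
  intervals whose ratio realizes the designed adaptation ratio exactly
  (AR = r^(m−3) for m intervals).  A parametric AP waveform is spliced at
  each scheduled time: power-law limbs whose exponent is set by the
  designed half-width relative to the slope-limited triangular minimum,
  giving the designed threshold, amplitude, half-width, AHP depth and
  maximal rise/decay slopes; a 5 mV/ms approach ramp meets threshold
  exactly at spike time so the 10 mV/ms detector anchors on the waveform,
  never on passive charging.
* **Block**: above the cell's block current, a brief burst (first 30% of
  the step) is followed by a plateau 12 mV above threshold.
* **Dispersion**: per-cell features are drawn log-normally around the
  per-genotype subtype means with SD = SEM·√n (recovering the sample SD
  from tabulated mean ± SEM with n), arithmetic-mean-preserving.
  Rheobase and block current are realized on the 50 pA stimulus grid at
  draw time, since finer values are unobservable under the step
  protocol; recovery tests therefore compare against the grid-realized
  design.  Draws are clipped to the observable range (rheobase ≥ 100 pA
  so the +50 pA sweep stays subthreshold; block ≥ 2×rheobase + 100 pA so
  the 2× train is never cut short; spike peaks ≥ +5 mV so the −10 mV
  peak criterion always applies; sag ∈ (0.5, 1]).
* **Noise**: additive Gaussian, 0.2 mV on voltage and 3 pA on currents by
  default (unstated in the source material; chosen so detection operates
  clearly above the noise floor at physiological signal sizes).
* **Synapse**: release at each AP is Bernoulli with probability
  p0·R^0.4 and success amplitude potency·R, where the resource R
  depletes by the utilization factor U = 0.35 on release and recovers
  with τ_rec = 120 ms.  The exponent and U were set so a p0 = 0.99,
  171 pA connection reproduces the published end-of-train phenomenology
  (~70% amplitude reduction, ~29% failures at pulse 21–25 of a 50 Hz
  train).  IPSC kernels are double exponentials placed so the
  5%-of-peak crossing falls exactly at the designed latency.
* **Morphology**: flat branching trees whose segment directions are
  horizontal with probability equal to the orientation bias (uniform in
  the 60° horizontal wedges) and uniform over the complementary 240°
  otherwise, so the expected horizontal length fraction equals the bias.
* All generators are pure functions of (spec, seed).

### What the generator does and does not emulate

It reproduces the *feature-level* statistics of the recorded populations
(per-subtype means and dispersions, composition counts, depression and
failure phenomenology) but not biophysics: no conductance dynamics, no
channel noise, no electrode artifacts, no dendritic filtering, no
correlation structure between features within a cell beyond what the
protocol imposes.  Passing recovery and cluster-number tests therefore
demonstrates that the estimators and the selection procedure are
correct and well-calibrated *given* data with the published statistical
structure — not that real recordings would cluster identically.

## Problem sizes and determinism

Cohort simulations follow the published compositions (83 WT cells, 45
GlobalLis, 41 NkxLis, 38 EmxLis); cluster-number recovery is assessed as
the modal choice over ten seeded replicates.  Recovery bounds use 100
cells per subtype.  Elevated-potassium continuous assays are generated at
configurable sweep counts and durations; tests run them at a few seconds
per sweep, the protocol structure (evoked window at each sweep start)
being what matters to the classifier.  Every stochastic stage derives its
seed from one run seed via stable per-stage hashing, so reruns of a
configuration are bit-identical.

## Known limitations

* Features are drawn independently within a cell, which makes synthetic
  cohorts slightly easier to cluster than real ones where features
  correlate within subtype; the recovered ARIs should be read as upper
  bounds.
* The f–I curve is piecewise linear and the spike waveform is identical
  across a train (no amplitude accommodation or spike broadening).
* The 3×-threshold substitution rule makes FF3x a lower bound for cells
  that block below 3× rheobase, in the synthetic data exactly as in the
  original measurement procedure.
* Maximal rise/decay slopes recovered from 20 kHz centred differences
  run ~5–10% below the designed point slopes; half-width and amplitude
  are exact by construction.
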