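# Methods

This note documents the models, numerical choices and known limitations of
`fnirsnet`. It is the place where design decisions that were genuinely open
are recorded, in the package's own terms.

## Measurement model and preprocessing

Continuous-wave fNIRS measures light intensity `I(t)` at two wavelengths
per source–detector channel. The analysis chain is fixed in this order:

1. **Optical density.** `OD(t) = −ln(I(t)/Ī)` per channel and wavelength,
   with `Ī` the temporal mean of the trace. A constant trace maps to OD 0;
   for fluctuating traces the OD mean is slightly positive (Jensen).
2. **Trimming.** The first and last 60 s are dropped (settling and
   end-of-session effects), so a 300 s recording at 20 Hz yields 3600
   analyzed samples.
3. **Motion detection and spline correction.** A sample is flagged when the
   1 s moving-window SD exceeds 13.5× the trace's median moving SD, or the
   window peak-to-peak exceeds 0.4 OD (Homer-style defaults; all four
   numbers configurable). Flags from both wavelengths are pooled per
   channel, widened by a 0.5 s margin, and — because real artifacts often
   relax back slowly (optode re-settling) — each interval is extended
   forward until the wavelength-averaged trace returns within 3× its
   baseline moving-SD of the pre-artifact level, capped at 30 s. Without
   this extension, step-and-decay artifacts leave in-band recovery tails
   that are an order of magnitude larger than the hemodynamic signal.
   Correction is MARA-style: a smoothing spline (`scipy`
   `make_smoothing_spline`, roughness weight `λ = (1−p)/p·Δt³`, `p = 0.99`)
   is fitted to each flagged segment and subtracted, and the segment is
   re-leveled to the mean of the preceding clean samples. `p` near 1 makes
   the spline track the artifact closely, so the corrected segment carries
   roughly the measurement noise floor; unflagged samples are untouched.
4. **Band-pass, 0.01–0.1 Hz.** Zero-phase 3rd-order Butterworth. The low
   corner's impulse response spans minutes, so the filter is applied as its
   squared magnitude response in the frequency domain after odd-reflection
   padding — the transient-free ideal of forward–backward filtering. This
   realization is exactly time-reversal symmetric (to float rounding, the
   stated 1e-9 invariant) and meets the stated response targets: <3 dB loss
   at 0.05 Hz, >20 dB (measured ≈72 dB) at the respiration (~0.4 Hz) and
   cardiac (1–1.5 Hz) bands.
5. **Modified Beer–Lambert inversion.** Per channel and sample the 2×2
   system `ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)` is solved
   for (ΔHbO, ΔHbR) in µM. Defaults: ε from the standard compiled
   hemoglobin spectra, in mM⁻¹cm⁻¹ — 690 nm: (0.276, 2.05196); 830 nm:
   (0.974, 0.69304) for (HbO, HbR) — DPF = 6.0 at both wavelengths,
   d = 3 cm. The law itself fixes none of these constants, so all are
   configurable; the forward/inverse pair round-trips to <1e-9.

**Subject exclusion.** A subject is excluded (reason "head movement") when
more than 20 % of samples are masked on more than 30 % of channels; both
fractions are configurable. Only HbO continues into the network analysis.

## Connectivity and network construction

Pearson r over the full retained series for all channel pairs; the three
midline channels (25, 28, 29) are removed because they belong to neither
hemisphere, giving a 50×50 matrix. Fisher `z = artanh(r)` normalizes the
correlations for edgewise statistics; negative correlations are set to 0
(their physiological interpretation is ambiguous), the z diagonal is 0,
and off-diagonal r ≈ 1 (duplicate channels) is clamped at `1 − 1e-7` with
a warning. A channel with zero variance has its row/column zeroed and is
reported, keeping the matrix size fixed.

Binary graphs are built at the eleven thresholds 0.40–0.90 (step 0.05),
edge iff strength **strictly** exceeds τ. Thresholds are interpreted on
the **r scale** (configurable to z): a 0.9 threshold on z would demand
r > 0.716 of every retained edge and the sweep's upper range would be
unreachable for typical data, whereas "connectivity strength" thresholds
in this literature refer to r. The per-subject edge count profile over the
sweep, and its mean ("total number of edges"), summarize density.

## Topological metrics

All metrics operate on undirected binary graphs: NCp(i) = 2T(i)/(kᵢ(kᵢ−1))
with T(i) the triangles through i (0 when kᵢ < 2); NLe(i) = global
efficiency of the subgraph induced by i's neighbors; Eg = mean of 1/d over
distinct pairs with 1/∞ = 0; Cp and Eloc are the nodal means. Lp averages
shortest-path distances over **reachable pairs only** by default, keeping
it finite on the fragmenting high-τ graphs (the harmonic-mean convention,
`Lp = 1/Eg`, is available via config). An edgeless graph has no defined Lp
and contributes 0 to the metric curve, with a logged warning.

Small-worldness σ compares Cp and Lp against the means of 100 (config)
degree-preserving Maslov–Sneppen rewired graphs, 5 attempted swaps per
edge, seeded; graphs admitting no swap (stars) fall back to copies with a
warning. The implementation uses dense triangle counting (A³) and BFS
distance matrices (`scipy.sparse.csgraph`); the test suite verifies exact
agreement with brute-force enumeration (Floyd–Warshall, triangle listing)
on >100 random graphs and with networkx on a sample.

Every metric is reduced to the area under its curve across the sweep
(trapezoidal rule over τ; a rectangle-sum alternative is a one-line config
change), and nodal AUCs are averaged within the ten hemisphere × ROI
groups.

## Statistics

- Shapiro–Wilk per variable (logged, not gating — the comparisons are
  t-tests throughout, as is standard in this literature).
- Gender: Pearson chi-square on the 2×2 table (Yates correction off by
  default, configurable).
- Global AUCs and edge counts: two-sample Student t (Welch configurable),
  two-sided, α = 0.05, uncorrected — there are five global metrics and the
  convention in this design is plain t-tests at the global level.
- Nodal AUCs: t-tests across the ten ROIs per metric with
  Benjamini–Hochberg FDR at 0.05 (Benjamini–Yekutieli configurable).
- Edgewise: vectorized t over all 1225 z-value pairs, BH-FDR at 0.01;
  degenerate edges (zero variance in both groups) are excluded from the
  correction and logged.
- CRS-R correlations: Pearson r with two-sided p between per-subject
  metric AUCs and the total or a subscale, patients only, computed for
  metrics that survived the group comparison (a config flag disables the
  gating for exploratory runs). Correlation p-values are reported raw.

## Synthetic cohort: what it emulates, and what it does not

Defaults are the study conditions the package is validated under: 16 HC
vs 15 MCS, 53 channels, 20 Hz, 300 s.

- **Neural signal.** Band-limited (0.01–0.1 Hz) Gaussian signals with a
  block-structured target correlation: r = 0.85 within each hemisphere×ROI
  group, 0.45 between groups (the midline trio forms its own block). These
  levels were calibrated to the printed scales of the study design this
  package reproduces — edge counts that survive thresholds up to ~0.9 and
  nodal AUCs of ~0.2–0.37 over the 0.5-wide threshold axis both require
  within-block correlations near 0.85. The target matrix is projected to
  the nearest PSD matrix by eigenvalue clipping (tolerance 1e-10).
  Sources are whitened in-sample (empirical covariance to the −1/2 power)
  before Cholesky mixing, so the generated HbO matches the target
  correlation essentially exactly over the full record. With a 0.01–0.1 Hz
  band there are only ~40–50 effective temporal degrees of freedom in
  300 s — fewer than the 53 channels after trimming — so exactness cannot
  survive on the trimmed 180 s window; the residual ~0.1 mean absolute
  deviation there is irreducible sampling noise of the window, not
  generator error.
- **Group effect.** Every correlation involving a left-FPA or right-DLPFC
  channel is multiplied by a per-patient attenuation `aᵢ ~ 0.6 ± 0.15`
  (clipped to [0.2, 0.95]); each subject also carries a global coupling
  scale `~ 1 ± 0.12` that produces realistic between-subject metric SDs.
  The auditory CRS-R subscale is drawn from a latent variable correlated
  ρ = 0.75 with `aᵢ` and discretized to 0–4, so connectivity, topology and
  the clinical score share one ground truth.
- **Confounds.** HbR = −0.3·HbO + noise; incoherent sinusoids at ~0.1 Hz
  (Mayer, 0.08 µM), ~0.4 Hz (respiration, 0.25 µM), ~1.1 Hz (cardiac,
  0.6 µM) with per-channel random phases and slight frequency jitter; slow
  drift (0.02 OD) and Poisson-placed motion artifacts (0.3/min/channel)
  shaped as a step with 2 s exponential recovery, identical on both
  wavelengths; neural HbO SD 0.8 µM, upper-middle of the resting-state
  range, giving OD fluctuations ~0.01. Intensities are
  `I = I₀·exp(−OD) > 0` with per-channel baselines around 1000 counts.
- **Not emulated:** task-evoked hemodynamic responses, systemic physiology
  that co-varies across channels (coherent Mayer waves would raise all
  correlations), superficial/scalp contributions, optode-specific gain
  drift, and non-Gaussian neural dynamics. Passing tests on this cohort
  therefore demonstrate that the pipeline recovers a known block-and-
  attenuation structure under realistic noise — not that it is robust to
  every failure mode of clinical recordings.

## Problem sizes and determinism

The test suite and the acceptance script run the cohort at its design size
(31 subjects); small-worldness nulls use M = 100 rewired graphs per
subject and threshold in the acceptance script, and are skipped in the
pipeline-level tests where only threshold-sweep metrics are asserted. All
randomness flows from one master seed through `numpy` `SeedSequence`
spawning (per subject, per null ensemble), so identical configurations
reproduce identical cohorts, matrices and tables bit-for-bit.

## Known limitations

- With the reachable-pairs Lp convention, group fragmentation at high
  thresholds pulls Lp in the opposite direction from path elongation; the
  expected patient-group Lp increase is therefore directionally present
  but weak in the simulated design, and can flip at unlucky seeds. The
  harmonic convention is monotone with efficiency but explodes on
  near-empty graphs; neither is uniformly better, which is why both are
  exposed.
- σ on strongly fragmented graphs (high τ) compares tiny dense components
  against their rewirings and can take large values; its AUC should be
  read qualitatively.
- The packaged montage geometry and channel→ROI atlas are synthetic
  stand-ins with the correct counts and symmetry (53 channels from 16+16
  probes cannot all sit at exactly 30 mm in a planar alternating grid, so
  28 in-row channels sit at 30.0 mm and 25 diagonals at 34.6 mm within the
  5 mm tolerance); both files are user-replaceable, and studies with a
  digitized montage should substitute their own tables.
- The spline corrector replaces flagged segments with near-baseline
  residuals; heavy artifact loads therefore shrink correlations toward
  zero rather than biasing them upward — conservative, but a loss of
  signal.
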