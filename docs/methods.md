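# Methods

## The model

`looplight` studies recoverability of a *topological* neural code. The ground
truth is a ring: N event types whose evoked multivoxel patterns are N
equispaced points on a circle of radius 1, mapped into a V-voxel ROI by a
2×V orthonormal basis drawn uniformly at random (QR of two standard-normal
vectors; rotation invariance makes the spanned plane uniform). Because the
map is distance preserving, the N×N inter-pattern distance matrix is exactly
the circle's. The embedded values are shifted by their global minimum (so all
amplitudes are nonnegative) and scaled by one global factor so the largest
amplitude equals the requested percent signal change (PSC). A global affine
transform is used deliberately: any per-voxel shift or scale would destroy
the distance preservation the analysis is meant to detect. The degenerate
alternative (whether the original study shifted/scaled globally or per voxel)
is not decidable from its description; the global choice is the only one
consistent with its distance-preservation claim.

PSC here means evoked amplitude **relative to the baseline fluctuation SD**:
the noise generator is normalized so the in-mask temporal SD of the
fluctuation component is `sigma_system` (default 1), and patterns carry
amplitudes in those units, so `psc = 0.5` puts the strongest voxel's response
at half the baseline fluctuation. After per-run Z-scoring this is the
operative signal-to-noise ratio.

## The synthetic-data generator

What it emulates:

* **Design** — 1-s events, inter-stimulus gaps drawn i.i.d. from
  {7, 9, 11} s, every event type occurring `repetitions / n_runs` times per
  run in uniformly random order across 5 runs. "s apart" is read as
  offset-to-onset (onset-to-onset 8/10/12 s); an onset-to-onset convention is
  available. Runs get a 4-s lead-in and a 20-s tail so the hemodynamic
  response of the last event is captured; the common run duration is the
  longest run's requirement, rounded up to whole seconds. Session duration is
  whatever this computes to (for N = 12, 25 repetitions it is roughly an
  hour); it is reported, not calibrated to any target.
* **Hemodynamics** — the canonical double-gamma kernel (peak delay 6 s,
  undershoot delay 16 s, dispersions 1 s, undershoot ratio 1/6), sampled at
  dt = 0.1 s and peak-normalized. Event boxcars are convolved on this fine
  grid and then sampled at the TR (2 s), because 1-s events do not align with
  the TR grid.
* **Noise** — stationary AR(1) per voxel (`ar1_coef` default 0.3, a typical
  TR-2 autocorrelation), spatially smoothed with a Gaussian of
  `smooth_fwhm_mm` (default 4 mm at 3-mm voxels) and then rescaled back to
  `sigma_system` so smoothing does not silently shrink the fluctuation scale
  PSC is defined against, plus a slow cosine drift (`drift_amplitude` 0.3,
  period 128 s, random per-voxel phase). Each run is finally Z-scored over
  time per voxel (population SD; constant series map to zero).

What it does **not** emulate: noise estimated from real scans (physiological
cardiac/respiratory cycles, motion, spikes, scanner drift structure),
between-participant variability in evoked amplitude, and anatomical ROI
geometry (masks are synthetic ellipsoids and blobs). Passing tests therefore
show the *pipeline* behaves as designed under its stated noise model — they
are evidence about method feasibility, not about any particular dataset.

## Analysis choices

* **GLM** — per-run OLS with one HRF-convolved regressor per event type.
  An intercept is always included (run data are Z-scored, so a mean column is
  mandatory); a linear drift column is included by default as standard
  practice. No prewhitening: the design's long gaps make OLS bias acceptable
  and coefficient averaging across 5 runs suppresses variance. Betas are
  averaged across runs voxelwise.
* **Searchlight** — cubic, side 3 (side 7 available), centered on every
  in-mask voxel; cubes clipped at volume/mask boundaries are retained, and
  centers with fewer than `min_voxels` (default 2) in-mask voxels get an
  empty barcode. Patterns are Z-scored per event-type column (population SD;
  constant columns map to zero) before the Euclidean distance matrix; the
  normalization removes chance per-event mean offsets that would otherwise
  dominate the distances. A correlation distance (1 − Pearson, zero-variance
  columns defined as distance 1 to all others) is available.
* **Persistence** — Vietoris–Rips with coefficients in GF(2), dimensions
  capped at 1. Ties in filtration value are broken by dimension then
  lexicographic vertex order, making the reduction deterministic.
  Zero-persistence intervals are dropped (they are artifacts of simultaneous
  simplex entries), and the single essential H0 interval is excluded from
  cluster statistics. Two equivalent implementations exist — a general
  boundary-reduction over the explicit filtration and a fast union-find +
  triangle-reduction path used in the sweep — and the tests require them to
  agree with each other, with a naive dense GF(2) reduction, and with
  single-linkage merge scales for H0.
* **Ratio threshold** — loop intervals sorted by persistence descending are
  cut at the first position where an interval is at least `ratio` times
  longer than the next; the dominated remainder is discarded. Consequences,
  verified by property tests: the retained set is always a descending prefix,
  the longest bar survives every ratio (so `max_persistence` is invariant),
  and the retained count is monotone non-decreasing in the ratio. The
  single-loop indicator is computed on the unthresholded barcode by default.
* **Group test** — each participant's statistic map is demeaned over the
  brain (the statistics have an arbitrary positive baseline), the observed
  statistic is the TFCE-enhanced one-sample t map, and the null is the
  maximum enhanced value under sign flips of participant maps (exact under a
  symmetric voxelwise null). All 2^n flip patterns are enumerated when
  2^n ≤ 4096 (p = count/2^n, identity included); otherwise `n_perm` random
  flips with the add-one convention p = (1+count)/(1+n_perm), so p ∈
  [1/(n_perm+1), 1]. TFCE uses E = 0.5, H = 2, 26-connectivity and a
  per-map step of max/100 — common defaults, since no parameters are
  inherited from elsewhere. Voxels with zero variance across participants get
  t = 0 when their mean is 0 and a large finite t otherwise. The control ROI
  is the signal ROI mirrored across the first-axis mid-plane; synthetic masks
  place the ROI so signal and control are disjoint.

## Seeding and problem sizes

All randomness flows through numpy Generators derived from one base seed via
`SeedSequence` keyed by purpose (embedding, schedule, noise, permutations),
participant, run and condition, so reruns are bitwise reproducible and no
stream is reused across conditions. The embedding is fixed per participant
across runs and conditions (the ring's location in voxel space is a stable
property of a participant); whether it should also be shared *across*
participants is genuinely open — the default keeps it per participant, and a
caller can pass a common seed to share it.

The default grid configuration is scaled down so a full sweep runs on a
single desktop CPU: a 24×24×16 volume (ellipsoid brain of ~3.5k voxels),
60-voxel ROI, 6 participants, with ROI-restricted searchlight sweeps for
dose-response summaries and whole-brain sweeps when group inference is
requested. The acceptance script uses these sizes, plus a 14×14×10 volume
for the noiseless check and 200 repetitions × 8 participants × 16³ voxels
for the family-wise-error calibration. A published-scale configuration
(442-voxel ROI, 20 participants, whole-brain sweeps, all 60 cells) is a
matter of passing larger masks and `n_participants=20`.

## Known limitations

* The parametric noise model makes no claim of equivalence to noise fitted
  from real scans; absolute detection rates will differ on real data.
* Evoked amplitude is identical across simulated participants, which
  overstates group-level reliability relative to a real sample.
* OLS without prewhitening mildly misestimates coefficient variance under
  AR(1) noise; only coefficient *values* are used downstream, so this does
  not bias the distance matrices.
* Homology is computed only in dimensions 0 and 1; richer structures
  (spheres, interlocking rings) are out of scope.
* TFCE cluster extent is measured in voxels (no volume calibration), and the
  discrete threshold sum uses 100 steps; enhanced values are therefore
  comparable within, not across, step conventions.
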