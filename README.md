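# looplight

Searchlight persistent-homology analysis of simulated event-related fMRI.

`looplight` answers a feasibility question: if a brain region encodes a set of
stimuli on a **ring** — N event types whose multivoxel activity patterns lie
on a circle in a low-dimensional subspace of voxel space — can that topology
be recovered from realistically noisy event-related fMRI, and how much signal
and data does it take?  The package simulates the whole experiment and runs
the full recovery pipeline:

1. **Signal**: N equispaced points on a planar circle are pushed into a
   V-voxel region of interest (ROI) through a random orthonormal map, shifted
   nonnegative and scaled so the peak response equals a chosen percent signal
   change (PSC, expressed relative to the baseline fluctuation SD).
2. **Session**: randomized 1-s events (inter-stimulus intervals of 7/9/11 s),
   each type repeated equally across 5 runs, convolved with a double-gamma
   hemodynamic response, added to AR(1) + drift + spatially smoothed noise,
   and Z-scored over time per voxel (TR = 2 s).
3. **Recovery**: per-run mass-univariate GLM → run-averaged betas → a
   3×3×3 searchlight at every brain voxel → column-Z-scored voxels-by-events
   pattern → N×N Euclidean distance matrix → Vietoris–Rips persistent
   homology in dimensions 0 and 1.
4. **Statistics**: per searchlight, the persistence of the longest-lived loop
   (`max_persistence`) and an exactly-one-loop indicator (`single_loop`),
   optionally denoised with a ratio threshold on bar lengths.
5. **Group inference**: whole-brain demeaning, one-sample t across simulated
   participants, sign-flip permutations with threshold-free cluster
   enhancement (TFCE), family-wise corrected p-values, and
   signal-vs-mirrored-control ROI significance proportions.

The core quantity is the barcode of the Rips filtration built on the N×N
inter-event distance matrix d: vertices enter at scale 0, edge (i,j) at
d(i,j), triangles at the maximum of their edge scales; boundary-matrix
reduction over GF(2) yields intervals [birth, death) per homology dimension.
A ring of patterns shows up as a single long-lived H1 interval with birth at
the adjacent-point spacing 2·sin(π/N).

## Worked example

Simulate one participant at 0.5 PSC (N = 12 event types, 25 repetitions) and
sweep searchlights over the signal ROI and its mirrored control:

```python
import numpy as np, looplight as ll

brain, roi, control = ll.default_masks((14, 14, 10), roi_voxels=44)
noise = ll.NoiseParams()  # AR(1) + drift + smoothing, unit baseline fluctuation
hrf = ll.double_gamma_hrf()
runs, events = ll.simulate_session(
    12, 25, 0.5, brain, roi, noise, hrf, participant=0, base_seed=1)
centers = np.argwhere(roi | control)
res = ll.SearchlightTopology(runs, events, 12, brain, hrf=hrf, centers=centers).fit()
print(res.summary())
for stat in ll.STATISTICS:
    d = res.roi_mean(stat, roi) - res.roi_mean(stat, control)
    print(f"signal-minus-control {stat}: {d:.3f}")
```

prints

```
         statistic  n_searchlights      mean       max
0  max_persistence              88  1.271253  5.291948
1      single_loop              88  0.477273  1.000000
signal-minus-control max_persistence: 1.507
signal-minus-control single_loop: 0.909
```

The embedded ring is clearly visible: searchlights in the signal ROI carry
loops that outlive anything in the control ROI by ~1.5 persistence units, and
91 percentage points more of them contain exactly one loop.  Group-level
reliability across participants is then tested with
`ll.GroupTopologyTest([...stat maps...], brain).fit()`, and the full
condition grid (N ∈ {12,15,18} × repetitions ∈ {25,50} × PSC ∈ {0…1}) runs
via `ll.run_grid` or the CLI:

```bash
looplight grid --config config.yaml --seed 1 --out results/grid
```

CLI verbs: `simulate`, `analyze`, `group`, `grid` (checkpointed sweep),
`report`.

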