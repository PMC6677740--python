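# Methods

## Model and assumptions

The tissue is a fixed arrangement of cell centers on a 2-D torus; only
static geometry enters the dynamics (no motility, division or
rearrangement). Each cell's proneural activity u evolves as
τ du/dt = f(u − s) − u + η(t), with the inhibitory signal
s_i = s₀(x_i, t) + Σ_{j≠i} c_ij D*(u_j). Signaling is instantaneous; there
is no cis-inhibition and no explicit Notch/Delta biochemistry — the level
of description is the balance between self-activation and inhibition in a
single scalar per cell.

Functional forms, where the model class leaves them open, are the minimal
smooth choices:

- f(v) = logistic((v − θ)/ε): the simplest sigmoid with range (0, 1).
- D*(u): a logistic in u rescaled so D*(0) = 0 and D*(1) = 1 (clipped
  outside [0, 1]); a monotone saturating ligand-production map.
- c_ij = a · exp(−d_ij²/2ℓ²), zeroed beyond 3ℓ, with d_ij the
  minimum-image periodic distance; a smooth, range-parameterized decay.
- η: independent Gaussian white noise, Euler–Maruyama increment
  σ√dt·N(0,1).
- s₀(x, t): linear-in-time interpolation between an early and a late
  spatial profile, each a baseline plus signed periodic Gaussian bumps
  (floored at 0).

## Parameters, units, defaults

Lengths are in mean cell diameters (√(box area / n_cells)); time in units
of τ. Defaults (all overridable through the YAML config):

| parameter | default | meaning |
|---|---|---|
| τ | 1 | single-cell relaxation time |
| ε (f_steepness) | 0.05 | sigmoid width; sets the bistable window |
| θ (f_threshold) | 0 | sigmoid midpoint offset |
| σ (noise_sigma) | 0.02 | fluctuation amplitude per √time |
| ℓ (signaling_range) | 1.0 | coupling decay length |
| a (strength) | 2.0 | total inhibition a high neighbor can deliver |
| lattice | 1000 cells, 20 × 50 | five stripe positions spaced 4 diameters |
| disorder | 0.3 | jitter before centroidal relaxation |
| dt | 0.02 (τ/50) | Euler–Maruyama step (dt ≤ τ/10 enforced) |
| t_end | 30 τ | run length |
| gradient t_start → t_end | 8 → 16 τ | early→late transition |

With these values a cell clamped at s = 0 is monostable high and the
bistable window is s ∈ (0.2, 0.8): free cells turn on, and a single
committed neighbor at distance ℓ (weight 2·e^(−1/2) ≈ 1.21) suffices to
force its neighbors low. The early profile is a plateau of 1.0 (fully
suppressive) with permissive notches (amplitude −1.0, width 1.2) at the
stripe-1/3/5 positions x = 2, 10, 18; stripes 1, 3, 5 therefore emerge
first and resolve into rows. The late profile encodes the inhibition
produced around the flanking stripes 1 and 5 as a Gaussian shoulder
(amplitude 0.9, width 1.8) minus a narrower core notch (width 0.8)
centered on each, so the flank rows themselves remain permissive while
their surroundings are suppressed; as the template fades, the interior
gaps open up and stripes 2 and 4 emerge between the established rows —
reproducing the sequential order 3 (with 1, 5), then 2 and 4.

Calibration note: the model class itself does not fix these constants;
they were chosen once so that the defaults sit inside the bistable,
patterning regime (steep sigmoid, suppression radius ≈ 1.3 diameters,
template amplitudes spanning the bistable window) and are exposed in the
config rather than hard-coded.

## Fate calls and readouts

A cell is called an SOP when its terminal u exceeds a threshold. The
default threshold is the midpoint of the two stable branches evaluated at
the center of the bistability window — not at s = 0, where the calibrated
defaults have a single (high) fixed point and no separatrix exists. With
defaults this resolves to ≈ 0.5, far from both branches (≈ 0 and ≈ 1), so
the calls are insensitive to the exact choice.

Stripe detection bins mean u along x (bin 0.5) and counts contiguous
super-threshold runs at the half-range threshold (max+min)/2 with periodic
wraparound; a strict comparison with a 1e−9 guard makes a constant profile
count as zero stripes. Row structure of the resolved point pattern is a
different question from instantaneous stripes: any half-max threshold on a
spatially uniform noisy field splits it at shot-noise crossings, so
regime-level stripe structure is measured on the SOP x-histogram pooled
over replicates (bin 1.5, ≥ 10 seeds) rather than on single runs.

Time courses within a stripe are binned by |x − center| (default 3 bins to
halfwidth 2.4). The wild-type checks assert directions only: lateral bins
drop below half their peak mean u before the central non-SOP cells do, the
initial signal is highest on the stripe sides, and the central-bin mean s
overtakes the lateral bins once the stripe is established.

One property worth noting: raising a uniform extrinsic signal lowers every
cell's terminal u only in the cell-autonomous (uncoupled) setting. On a
coupled lattice, suppressing a winner disinhibits its neighbors, whose
low-branch equilibrium then sits slightly higher; the quantity that is
monotone under coupling is the precursor count. The tests assert exactly
that split.

## Geometry

Lattices are jittered hexagonal packings (jitter sd = disorder ×
cell diameter) relaxed by 20 Lloyd iterations of the periodic centroidal
Voronoi tessellation — a static stand-in for a mechanical vertex model
that yields near-uniform areas with disordered topology. At disorder 0 the
regular packing is returned unchanged (it is a fixed point of the
relaxation, and skipping it keeps the packing exact). Voronoi areas
partition the torus to 1e−9 relative error and the Delaunay adjacency has
mean degree exactly 6 (Euler characteristic 0); both are asserted. The
normalized coupling variant uses symmetric Sinkhorn–Knopp balancing so the
matrix is simultaneously symmetric and has exact row sums; the default is
the unnormalized kernel with explicit strength.

## Perturbation regimes

Presets are pure transformations of a base config: `no_template` removes
the early-profile notches (the template's spatial information) while
keeping the plateau; `reduced_late_inhibition` scales the coupling
strength by 0.6; `no_inhibition` zeroes the coupling and flattens the late
profile. Directions reproduced over ≥ 10 paired replicates: template loss
collapses the central (stripe 2–4) region to at most one broad domain
while the flank stripes persist; reduced late inhibition raises SOP
density (≈ +15% under defaults) at unchanged stripe count; inhibition
loss makes essentially every cell an SOP. These are direction-only
checks — absolute bristle counts and the wet-lab magnitude of the density
increase are outside the model's claims.

## Profiling pipeline

Per image and channel, raw intensities are divided by the 99th percentile
(default; `max` and `none` modes available — the exact "order one" scale
statistic is a convention, so both robust and literal maxima are kept).
Nuclei with normalized level strictly above the threshold (default 0.2)
are detectable. Signed distance to the centerline is the Euclidean
point-to-polyline distance, signed by the side of the nearest segment
(left of the traversal direction positive). The default statistic per bin
(width 2 μm over ±20 μm) is the sum of (normalized − threshold) over
detectable nuclei — an image with none contributes zeros, not missing
values; a per-bin mean-intensity mode is retained as an alternative
because the two conventions (sum vs mean) both appear in practice and
differ only by the bin occupancy factor. SEM across images is reported
only for n ≥ 2.

## Synthetic imaging data

The generator emulates the structure, not the optics, of the confocal
data: a hard-core point process of ~400 nuclei in an 80 × 60 μm field
(min spacing 2 μm), a proneural channel peaking on the stripe center
(boosted ×1.6 in SOPs), an early-onset channel with Gaussian flanks at
±7 μm, a late-onset channel as a broad central bump zeroed in SOPs, SOPs
planted every ~6 μm along the centerline with 1 μm jitter, lognormal
per-image gains (σ = 0.3) and additive Gaussian noise (sd 0.05, clipped at
0). The multiplicative gain exists precisely so normalization has
something to remove. Not modeled: point-spread functions, segmentation
errors, z-structure, spatially correlated background — so passing the
shape-recovery tests shows the pipeline recovers planted spatial structure
under per-image scaling and additive noise, not robustness to real imaging
artifacts.

## Numerical choices and limitations

- Explicit Euler–Maruyama; convergence is property-tested against
  fine-step references. Non-finite states abort with the offending step.
- Fixed points are bracketed on a 4001-point grid and refined by Brent's
  method; stability from the sign of the derivative.
- Problem sizes in the default test and acceptance runs (1000-cell
  lattices, 10 replicates per regime, 5-image synthetic fields) were
  chosen as the smallest that make the stripe/row statistics stable
  across seeds.
- The stripe-count conventions (half-range threshold, pooled histograms)
  are package-defined readouts; no quantitative row criterion exists for
  the biological images, so cross-regime comparisons are directional.
- Periodic boundaries mean flank effects of the real notum (medial/distal
  borders) are absent; the extrinsic profile carries all positional
  information.
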