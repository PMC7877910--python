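# Methods

This note records the models implemented in `cortopulse`, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a user extending the package should know about.

## Hexagon-grid pulse detection

**Grid.** The ventral-cortex ROI is tessellated with pointy-top hexagons in
axial coordinates; a hexagon of circumradius *R* has center
x = √3·R·(q + r/2), y = 1.5·R·r. Pixels are assigned by exact cube rounding
(nearest center), so included hexagons partition the ROI; hexagons whose
center falls outside the ROI are dropped and their boundary-sliver pixels
left unassigned. Default *R* = 1.0 µm (≈ 12 px at 0.08 µm/px TIRF sampling):
several pixels per bin for noise averaging, yet small against the ~2–3 µm
pulse footprint so a pulse activates a multi-hexagon component.

**Background and threshold.** The per-hexagon background is the temporal
median of its mean-intensity trace over the analysis window. A median is
insensitive to sparse pulses (a pulse occupies a small fraction of any
hexagon's trace at realistic rates) and robust to static spatial
heterogeneity; a global-ROI median is available
(`baseline="roi_median"`) for movies with negligible spatial structure.
A hexagon is active when intensity/background ≥ 1.3.

**Filters and linking.** Per frame, connected components (hexagon
6-adjacency) with fewer than `min_component_size = 3` hexagons are removed —
this is what suppresses single bright myosin puncta. Components in
consecutive frames sharing ≥ 1 hexagon belong to one event; a component
touching several open events merges them into the lowest event id
(components are processed in order of their smallest hexagon index, making
the linker fully deterministic). Events are kept when their frame span is at
least `min_duration_frames = 4` — "persisted more than three frames" read as
a strict inequality — and when they start inside the analysis window
(default: the first 30 min, counted from movie start). Raising the threshold
can split one linked event into two by removing a bridging hexagon, so event
*counts* are only monotone in the filters for well-separated pulses; the
total detected hexagon-frame volume is monotone unconditionally (both are
tested).

**Region assignment.** An event is counted in the region where it peaks: at
the frame of maximum intensity ratio, if the strict majority of active
hexagon centers lie inside the nucleus footprint the event is
`under_nucleus`, otherwise `outside`. One event, one count. A caveat
discovered with the synthetic ground truth: because a pulse's active
footprint is a disc of radius ~2 µm, the majority vote carries a curvature
bias at a convex nucleus boundary — pulses centered within roughly
(footprint radius)²/(2 × boundary curvature radius) inside the boundary are
voted `outside`. With a realistic nucleus (≥ ~18 µm diameter) this
misassigns only a few percent of under-nucleus pulses; with very small or
highly curved footprints it grows, and under/outside contrasts should then
be treated as slightly conservative.

## Pulse frequency statistics

Counts are conditioned within each cell: `freq_under` is the raw
under-nucleus count per window; the outside count is rescaled by
(nucleus area / outside area) so both are pulses per nucleus-equivalent area
per window. Outside area is ROI minus nucleus; if edge/lamella exclusion
masks are available they should simply be folded into the ROI mask before
summarizing. Per-cell pairs go into a two-sided paired *t*-test
(t = mean(d)/(sd(d)/√n), df = n−1) with a Q-Q report (Blom plotting
positions) for the normality check; all-zero differences raise instead of
returning a fabricated p-value. The Mann-Whitney *U* test uses the exact
null distribution when both samples are ≤ 8 observations without ties, else
the tie-corrected normal approximation with continuity correction; no
outlier trimming is ever applied.

## Fiber classification and kinetics

Live-cell inclusion rules: end-to-end length ≤ 10 µm ("maximum 10 µm" is
read as maximum fiber length), persistence ≥ 2 min, and a focal adhesion at
both ends (shared adhesions allowed; records with missing adhesion data are
flagged `unclassifiable`, never silently dropped). Under-nucleus label:
≥ 1 adhesion centroid inside the nucleus footprint — the 2D-projection
reading appropriate to TIRF, where only the ventral plane is imaged.
Fixed-cell rules: adhesions at both ends, at least partial overlap of the
fiber segment with the nucleus footprint, length smaller than the nucleus
diameter. The under-nucleus percentage is computed per cell and averaged
with an SEM over cells (a pooled mode exists, but the cohort-level SEM is
the default because cells, not fibers, are the independent units). The
half-life summary is the median observed lifetime with IQR and range —
deliberately not an exponential fit, since real lifetimes are reported as
highly variable rather than memoryless; censored records are excluded from
the median and counted separately.

Focus-flow speed fits least-squares lines to the x(t), y(t) of the
intensity-weighted centroid and reports the fitted-velocity magnitude.
Weights are taken only from pixels above background + 25% of the local
contrast: rectified noise spread over the whole ROI would otherwise pull the
centroid toward the ROI center and bias speeds low (an 18% underestimate at
realistic noise before this guard). Kymographs resample the polyline at
pixel pitch and reduce across the line width by max (default) or mean.

## Traction force microscopy

**Model.** Elastic half-space with Young's modulus E = 26 kPa (the
polyacrylamide substrate stiffness) and Poisson ratio ν = 0.5
(incompressible gel; configurable). In Fourier space

  Ĝ(k) = 2(1+ν)/(E·k³) · [[(1−ν)k² + ν·k_y², −ν·k_x·k_y],
                           [−ν·k_x·k_y, (1−ν)k² + ν·k_x²]]

with the real-space check u = (1+ν)F/(πE·r) along the axis of a tangential
point force F. The k = 0 mode is removed (mean displacement is not
observable), so all computed displacement fields carry a zero-mean gauge;
comparisons against closed forms are made as differences to a reference
point.

**Forward model / bead scenes.** Tractions are zero-padded to ≥ 2× extent
before the transform to suppress periodic wrap-around. Beads are isotropic
Gaussian spots (default σ = 0.2 µm, the microsphere scale); the stressed
frame shifts each spot center by the interpolated surface displacement, so
the ground truth is exact by construction. Single-node point loads alias
(the 1/k kernel is not band-limited); near-point loads are modeled as
narrow Gaussians of ~1.5 grid spacings.

**PIV.** Windowed (default 32 px, 50% overlap) normalized cross-correlation
against a ±half-window search region; 3-point Gaussian peak interpolation
per axis, skipped when the correlation peak is numerically 1 — a perfect
match implies an exactly integral shift, which keeps integer displacements
exact. Featureless and low-quality (NCC < 0.3) vectors are flagged and
replaced by the local 3×3 median. The displacement noise floor is the RMS
vector magnitude over a cell-free region.

**Inversion.** Zeroth-order Tikhonov:
t̂ = (ĜᵀĜ + λI)⁻¹ Ĝᵀ û per wavevector, λ in (µm/Pa)². λ = 0 is allowed and
is what the round-trip accuracy is quoted at. The default
λ = 3.2 × 10⁻¹¹ (µm/Pa)² is the L-curve corner (`choose_lambda_lcurve`)
measured on the package's noisy reference bead scene. The displacement crop
is padded with a circularly smooth raised-cosine blend between opposite
edges — a hard zero step at the crop edge would be amplified across the
whole reconstruction by the high-pass inverse kernel (an 83% → 15% → <5%
round-trip-error progression during development motivated this). An
optional Tukey `edge_taper` exists for fields that do not decay within the
FOV, off by default because it deletes real long-range signal.

**Accuracy regime.** The <5% round-trip figure holds for balanced,
band-limited traction patterns (contractile dipole pairs, the physical case
for adherent cells) whose displacement decays within the field of view.
Monopole-like net forces leave a slowly decaying 1/r field whose crop cannot
be inverted accurately near the boundary — error then concentrates in the
outer ~12% of the field while the interior stays at the few-percent level.

## Synthetic study conditions

The generator's defaults describe one fixed set of study conditions chosen
to be realistic for TIRF movies of migrating U2OS-like cells; they were
fixed once, before the validation studies were frozen:

| parameter | default | rationale |
|---|---|---|
| field | 42 × 30 µm | spread mesenchymal cell footprint (~1260 µm²) |
| nucleus | ellipse, semi-axes 12 × 9 µm | ~27% of cell area (nucleus typically < 30%) |
| pixels / frames | 0.08 µm, 10 s × 180 | TIRF sampling; 30 min analysis window |
| pulse rates | 0.0015 / 0.00075 ev·µm⁻²·min⁻¹ (in/out) | ~33 pulses per cell per 30 min, sparse pulsing, 2× enrichment under the nucleus |
| pulse shape | Gaussian σ = 1.2 µm × raised-cosine, FWHM 6 ± 1 frames (min 5) | ~2.8 µm footprint, ~60 s pulses |
| amplitude | 2.0 × background at the spatiotemporal peak | clearly supra-threshold (1.3) yet noise-limited |
| noise | Poisson shot noise + Gaussian read noise (sd 5 at baseline 100) | sCMOS-like; both toggleable for exact tests |

The pulse *duration* parameter is the FWHM of the raised-cosine envelope
(full support = 2× FWHM); ground-truth start/end frames delimit the FWHM
span, which is also the span a 1.3-ratio threshold approximately recovers at
2× amplitude. Pulse centers are sampled ≥ 2 µm from the field edge, and the
returned ROI mask excludes the same margin — the analyzed cortex excludes
cell edges, where intensity artifacts would otherwise dominate.

Validation studies (tests and `scripts/acceptance.py`) run these conditions
on a 0.25 µm raster rather than 0.08 µm: the hexagon binning (1 µm radius)
is the resolution-limiting element, the coarser raster leaves ≥ 4 px per
hexagon radius, and a full 19-cell cohort then simulates in seconds. The
large-replicate null study (type-I error, 500 cohorts) samples ground-truth
event counts directly without rendering movies, because the property under
test — behavior of paired per-cell counts — does not depend on the renderer.

What the generator does **not** emulate: photobleaching (the median
baseline absorbs slow trends but no bleach model is rendered), cell-shape
changes and nucleus movement during the window, pulse shape irregularity and
spatial clustering beyond Poisson, fiber tracking errors, bead detachment,
and gel nonlinearity or finite thickness. Passing tests therefore
demonstrate correctness of the *analysis chain* under the stated statistical
structure, not performance on any particular microscope's data.

Fiber tables: lengths log-normal (median 5 µm, σ_log 0.4, capped at 45% of
the short field side), lifetimes exponential with 25 min median, 2 adhesions
per fiber, under-nucleus placement with probability 0.8, 101 fibers over 19
cells — a cohort of the scale a live-cell blind count produces.

## Known limitations

- The linker merges genuinely overlapping pulses; at the default sparse
  rates this loses ~5–10% of events (region-asymmetrically when rates
  differ), and frequency ratios are accordingly a few percent conservative.
- The majority-vote region rule has the curvature bias described above.
- FTTC assumes an infinite-thickness substrate; finite-thickness
  corrections and 3D TFM are out of scope.
- The classifier consumes track tables; fiber detection/tracking from raw
  movies is intentionally not provided (manual or external tracking is
  assumed, as in blind scoring).
- Pipeline stages hold intermediate products in memory; movies well beyond
  ~10⁸ voxels would need chunked processing.
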