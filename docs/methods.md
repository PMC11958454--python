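# Methods

`slimquant` quantifies fluorescent protein aggregates in single budding
yeast cells from two kinds of acquisition: millisecond-sampled Slimfield
movies, from which it estimates how many reporter molecules each aggregate
contains and how fast it diffuses, and slower dual-channel confocal
time-lapses, from which it scores aggregate-positive fractions,
mother/daughter asymmetry, organelle colocalization and inheritance. Because
raw microscopy of this kind is not reproducible at desk scale, the package
ships a simulator that generates both acquisition styles with full ground
truth; every analysis stage is validated by recovering what the simulator
put in.

## The simulator (the stated world)

An aggregate is modelled as a sub-resolution cluster of N fluorophores at a
common centre. Per frame, each photoactive fluorophore contributes an
isotropic pixel-integrated 2D Gaussian of width `psf_sigma` (default 87 nm =
0.25·λ/NA at λ = 488 nm, NA 1.4) and an expected
`photons_per_fluorophore_per_frame` (default 300 detected photons). Pixel
values are Poisson(signal + background) plus Gaussian read noise, clipped
and quantised to uint16 — a unit-gain integrating camera; EMCCD excess noise
is deliberately omitted.

Stochastic processes:

* **Motion.** 2D Brownian displacements with per-axis variance 2·D·Δt,
  reflected at the cell boundary (circular cells by default). Default
  Δt = 5 ms, 1,000 frames per movie.
* **Photobleaching.** Each non-dark fluorophore bleaches once,
  geometrically, with per-frame probability `bleach_prob` (default 0.01,
  chosen so a few-hundred-molecule aggregate reaches the single-molecule
  level well inside a 1,000-frame acquisition). The photoactive count per
  aggregate is non-increasing by construction.
* **Dark fraction.** A fraction `dark_fraction` (default 0.07) of
  fluorophores never matures to a photoactive state. This is the stated
  maturation shortfall of this reporter class; it makes uncorrected molecule
  counts ~7% low.

The photon budget, background (10 photons/pixel/frame) and read noise
(sd 1 count) are calibration choices, not measured values: together they put
single-molecule localization precision near 10 nm RMS, comfortably inside
the ~40 nm figure the pipeline is required to meet, with realistic
single-frame SNR (~35 for one fluorophore).

Confocal fixtures reuse the same rendering at 10-minute intervals over
90 min with bleaching off: a mother cell with a linearly growing bud, an
organelle marker in a second channel that acquires a copy in the bud at the
stage-typical time (vacuole ~20 min into budding, nucleus ~60 min), and
aggregates retained in the mother under the default inheritance policy.

What the simulator does **not** emulate: aggregate spatial extent (all
fluorophores co-located), fluorophore blinking, stage drift, spectral
crosstalk, 3D/vectorial PSFs, or z-stacks. A green recovery test therefore
establishes correctness of the estimators under this world, not robustness
to every artefact of real data.

## Detection

Cell outlines either pass through from a label mask or come from a
magic-wand-style ray search on brightfield: from each seed, the darkest
contiguous stretch along each of 90 rays (the cell rim) marks the boundary,
and the enclosed polygon becomes the mask; masks are made disjoint in seed
order. Foci are detected per cell: the threshold (Otsu by default; mean /
percentile / fixed available) is computed from that cell's pixels only, and
8-connected components of at least `min_area_px` (default 4) become focus
records. Centroid and area describe the thresholded object; integrated
intensity is measured over the object dilated by 2 px (clipped to the cell)
so PSF tails below threshold are counted. Intensities are reported raw, with
the in-cell background median carried alongside for optional subtraction.
Outlier removal for population summaries uses the standard interquartile
fence (k = 1.5, linear-interpolation quartiles).

## Localization, linking, diffusion

Sub-pixel localization is iterative Gaussian fitting in two stages inside a
17×17 window: Gaussian-mask iteration (Gaussian-weighted centroid, mask
re-centred each step, converged at <10⁻³ px) followed by a Gauss–Newton
least-squares polish of centre, flux and flat background that removes the
mask stage's small pixelation bias. Flux is the fitted Gaussian's
background-corrected integral; fits whose flux is below 4 standard errors of
the background are rejected explicitly (flat windows, post-bleach frames).
The per-localization precision estimate uses the photon-statistics
(Thompson) formula.

Linking is greedy nearest-neighbour, closest pairs first, with links beyond
`max_disp` (default 5 px) forbidden and no gap closing — at 5 ms sampling,
gaps are rare, and on well-separated spots greedy linking matches the
optimal assignment (tested against the Hungarian algorithm). The MSD of a
track is the time-average over all frame pairs at each lag; D is the slope/4
of a weighted least-squares line through the first 4 MSD points (weights =
pair counts), with the intercept retained as the localization-noise offset
(≈4σ_loc² for a static emitter). Purely viscous diffusion is assumed; no
anomalous exponents or motion-blur corrections.

## Molecule counting

The stoichiometry of a tracked aggregate is S = I₀ / I_single.

* **I₀** is the initial unbleached intensity: a single-exponential decay is
  fitted to the track's intensity trace — restricted to the unbleached
  portion (above 5% of the trace maximum), since the exponential does not
  describe the post-bleach background tail — and evaluated at frame 0.
  Using absolute frame numbers makes the estimate robust to tracks that
  lock on a few frames late. Fallback on fit failure: mean of the first 4
  frames.
* **I_single** is calibrated in situ from stepwise photobleaching. Traces
  are extended past the end of each track by reading the flux at the last
  fitted position, so the full bleach tail is recorded. After Chung–Kennedy
  filtering (window 10, weighting exponent 2 — forward/backward running
  means weighted by inverse predictor variance, which preserves step edges),
  downward steps are detected as change points where the mean over the next
  `min_dwell` = 5 frames sits at least `min_step` below the previous 5, with
  non-maximum suppression; `min_step` is set per trace at 4× a robust noise
  estimate. The calibration value is the KDE mode of the terminal step sizes
  of traces that bleach to completion, with a percentile bootstrap CI. An
  alternative pairwise-difference calibration (mode of all suprathreshold
  level differences within traces) is provided for cross-checking.
* **Dark correction** multiplies S by 1/(1 − p_dark). It is off by default —
  reported values in this field are conventionally uncorrected — but the
  recovery benchmarks enable it at the simulated dark fraction (0.07), which
  is what makes ground-truth molecule counts recoverable without bias.

Population distributions are rendered by Gaussian KDE on [0, 1.2·max] with
a Silverman-scaled bandwidth (overridable); densities are renormalised to
unit mass on the grid, and peaks are local maxima above 5% of the global
maximum. In the pipeline, one stoichiometry is reported per cell (its
longest track) to avoid double-counting fragmented tracks; diffusion is
reported per track.

## Population statistics

A cell is aggregate-positive if it contains ≥1 detected focus. A focus is
colocalized with an organelle if its centroid lies within `max_distance`
(default 250 nm, the optical resolution criterion) of the organelle mask,
via a Euclidean distance transform. Inheritance scoring counts foci in
mother vs bud per time point (conservation: mother + bud = total) and flags
organelle presence in the bud. Two-condition comparisons use Welch's t-test
or the Mann–Whitney U (exact enumeration for tie-free samples up to n = 20,
tie-corrected normal approximation above; cross-checked against brute-force
counting of pairwise wins). Because "a decrease of X%" is printed ambiguously
in this literature, fold-change output reports the ratio, the percent
increase, the percent decrease *and* the remaining percentage explicitly.

## Numerical and design choices

* Coordinates are 0-based (row, col) with pixel centres at integers; areas
  convert to µm² via `pixel_size`².
* Uniform ROIs (zero variance) yield no foci rather than an Otsu error.
* Degenerate KDE inputs (all equal) yield a narrow delta-like peak.
* Identical zero-variance samples under the t-test return p = 1 with a
  warning instead of NaN.
* Mother/daughter roles come from ROI annotations (simulator lineage or
  user labels); there is no automatic bud detection.
* Determinism: one seed drives every random draw; identical configs produce
  byte-identical movies and CSVs.

## Known limitations

Stoichiometry recovery assumes aggregates are detectable in the early
frames and bleach to completion within the movie; very slow bleaching or
extremely dim aggregates would bias the calibration. Diffusion from
pipeline-derived tracks inside small cells is mildly confined (reflecting
boundaries), so per-track D from the image pipeline reads a few percent
below the free-space input; the diffusion benchmark therefore follows the
stated protocol of measuring the MSD estimator on free Brownian tracks with
localization noise. Colocalization percentages and absolute focus
areas/intensities depend on acquisition specifics and are not meaningful to
compare against published values from real data.
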