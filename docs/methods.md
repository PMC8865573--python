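# Methods

## The physical model

A tapered optical fiber (TF) narrows linearly from its untapered core
radius `a0` to a sub-micrometer tip; we measure the axial coordinate `z`
from the tip, so the local radius is `a(z) = min(a0, z·tanψ)` with taper
half-angle `ψ`. The defaults describe a 0.37 NA fiber with
`a0 = 100 μm`, `ψ = 5°` and an emission length of 1250 μm. Micro-apertures
("slots", 100 × 20 μm²) are placed at taper diameters of 30, 50 and 80 μm;
positions are stored as local diameters and converted through
`z = (d/2)/tanψ`.

Light entering the taper at local radius `a` couples to guided modes whose
transversal wavevector `k_t` (always expressed in units of `2π/λ`, hence
wavelength-free and bounded by the NA) grows with `a`. The exact relation
follows from the waveguide's mode structure; this package deliberately uses
a phenomenological stand-in instead of an eigenmode solver: the collected
band is `[f·k_hi, k_hi]` with `k_hi = NA·a/a0` and inner-edge fraction
`f = 0.7`. This preserves the two properties the method actually relies on
— monotonicity of `k_t` with collection diameter, and the NA cap in the
untapered limit — without claiming modal accuracy. The inner-edge fraction
is a free parameter of the forward model; 0.7 is chosen so that the bands
of the standard 30/50/80 μm slots are pairwise disjoint (an inner edge at
half the outer edge would make adjacent bands overlap whenever the ratio of
adjacent slot diameters exceeds 0.5, which 30/50 and 50/80 both do, and
non-overlapping bands are the premise of the whole demultiplexing scheme).

The far-field relay maps a plane-wave component to camera radius `R` with
`k_t/(2π/λ) = sin(arctan(f2/(f1·f3)·R))`, using `f1 = 32 mm`,
`f2 = 250 mm`, `f3 = 100 mm`. The camera is a 2048² sCMOS binned 4× to
512² with a 26 μm effective pitch. `RelayOptics.coarse(n)` keeps the same
optical field at `n×n` sampling (e.g. 128² at 104 μm pitch); the test
suite and the acceptance script run at 128² so that full pipelines finish
in seconds, which leaves every qualitative property and every tolerance
intact (band edges move by at most one 0.005-wide histogram bin).

## Synthetic data generator

The generator emulates the statistical structure of real acquisitions, not
their optics in detail:

- **Annular patterns.** Each slot contributes intensity `∝ 1/R` on the
  pixels whose `k_t` falls in its band. The 1/R profile makes the
  circumference-corrected histogram used downstream flat over the band, so
  a top-hat is the correct limiting shape.
- **Collection lobes.** A source at `(x, z)` couples into a slot with a
  separable efficiency: a smoothed axial top-hat over the slot's 100 μm
  footprint (edge width 5 μm — a sharply milled aperture; wider edges let
  a slot's tail excite its neighbour at the ~10⁻³ level, which the
  count-based histogram magnifies because the neighbouring ring covers
  more pixels) times `exp(−|x|/200 μm)` off-axis, matching the ~200 μm
  lobes observed for real slots.
- **Noise.** Gaussian blur (σ = 1 px) stands in for tissue scattering,
  photon noise is Poisson on the blurred counts, camera dark noise is
  Gaussian (mean 100, SD 10 counts) quantized to integers and clipped at
  16 bits. No camera model is claimed beyond "the minimal one that makes
  the algorithm's thresholds meaningful".
- **Background.** A broad radial Gaussian in k-space models the
  autofluorescence generated inside the patch cord and taper; versor and
  depth acquisitions add it before noise, and the analysis subtracts a
  separately acquired background frame, as one would in the lab.
- **Amplitudes.** Scan-point sources peak at 2000 counts, versor-quality
  calibration acquisitions at 20 000 counts. Versor calibration frames are
  rendered without scattering blur (`SimConfig.clear_solution()`): they
  are acquired in a clear fluorescein droplet, not through tissue.
- **Grids.** Presets reproduce the standard characterization grids:
  25 × 8 at 50 μm (bare fiber, N = 200), 41 × 5 at 20 μm (slotted,
  N = 205), 26 × 11 at 10 μm (slot close-up, N = 286). The long grid axis
  runs along `z`; grid extent follows the `(n−1)·spacing` lattice
  convention. A bare taper is simulated by discretizing the collection
  length into 50 μm axial segments, each treated as a micro-slot.

All randomness flows through one seed; per-frame streams are spawned from
a `SeedSequence`, so stacks are bit-reproducible and independent of
chunking. What the generator does **not** emulate: diffraction at the slot
aperture, speckle, polarization, chromatic effects, tissue heterogeneity,
or the mode-theoretic fine structure of real far fields. Tests passing on
synthetic data therefore validate the *algorithms* (segmentation,
histogram weighting, top-hat fitting, interval logic, projection algebra)
under controlled conditions, not the optical physics of any particular
fiber.

## Extraction

Per frame: gamma correction (γ = 1.4) is applied to the max-normalized
image with the raw-count threshold transformed consistently, which makes
segmentation amplitude-invariant (the binary mask equals
`counts > seg_threshold`). Segmented pixels enter a `k_t` histogram
(bin width 0.005, a value chosen well below the narrowest slot band);
per-bin mass is divided by the bin's mean pixel radius to undo the
spreading of a ring's fixed energy over a circumference ∝ R; bins under
0.3 of the histogram maximum are zeroed. The top-hat "fit" takes the
contiguous non-zero run containing the global maximum (ties toward lower
`k`) as the support `[k_min, k_max]` and the weighted median of the
in-support mass as `k_median`; a least-squares boxcar would differ by at
most the bin width on top-hat-shaped histograms, so the thresholded
support is the default and only implementation.

Thresholds default to the camera's dark statistics with a 5σ margin:
segmentation at `dark_mean + 5·dark_sd` (floored at half a count — the
histogram weights pixels by count, not intensity, so sub-quantization
residues must never segment) and frame validity at
`n_px·dark_mean + 5·√n_px·dark_sd`. With `dark_sd = 0` both reduce to the
plain dark means; without the margin, symmetric dark noise would put half
of all background pixels above a mean-level threshold.

Degenerate inputs: an all-dark frame is reported invalid (`NaN`
wavevectors), never an exception; a fully saturated frame produces a
warning; an empty histogram invalidates the frame.

## Classification

Each slot's ROI footprint is the set of valid grid points within the
slot's own axial footprint (± half the slot length, so neighbouring lobes
are not mixed in) whose intensity reaches 50% of the lobe maximum. The
interval is `k̄_t ± σ` over the footprint's `k_median` values; the model is
"orthogonal" iff the intervals are pairwise disjoint, and classification
refuses non-orthogonal models rather than guessing. A blind excitation is
classified by containment of its `k_median` — the median only, not the
band edges — with invalid frames and uncontained values assigned to
`Out`. True classes for synthetic experiments come from nearest-grid-point
footprint membership. At the defaults, the binned `k_median` is so stable
that footprint SDs can be exactly zero; degenerate intervals are flagged
and classification then amounts to exact bin matching, which the noise
analysis shows is the expected behaviour rather than an artifact.

Metrics are one-vs-rest `TP/TN/FP/FN` per class. Two F1 conventions are
reported side by side: `f1 = P·R/(P+R)` reproduces the convention used in
the reference workflow literally (a perfect classifier scores 0.5), and
`f1_standard = 2PR/(P+R)` is the conventional harmonic mean. Ratios of the
form 0/0 are reported as NaN, never silently as zero.

## Demultiplexing

Versors are `clip(slot_image − background, 0)` normalized to unit total
intensity (`unit-sum`). The normalization is configurable (`unit-l2`,
`max-1`) because the choice matters: with unit-sum versors the projection
coefficient of a mixture of the versors themselves is `c_j = w_j·‖v_j‖²`,
so exact weight recovery additionally requires equal L2 masses across
versors (automatic for equal-area uniform supports, or under `unit-l2`
normalization). For realistic ring versors of different areas the
percentages `m_ij` are therefore a *relative* depth-assignment measure,
not calibrated signal fractions — a known limitation of the direct
Hadamard projection, which is reproduced deliberately; non-negative
least-squares unmixing is intentionally not substituted for it.

Orthogonality is scored as the cosine-normalized pairwise overlap
`Σ v_i⊙v_j / √(Σv_i² Σv_j²)`; the declared criterion for a usable basis is
a maximum off-diagonal score below 0.05 (simulated defaults reach
~0.002). For a single-slot input the leaked percentage into channel `j`
is bounded by `100·s/(1+s)` at overlap score `s`, which the tests verify
numerically.

## Problem sizes and numerical choices

Test-suite and acceptance runs use the 128² relay, the 41 × 5
characterization grid, 400-point blind experiments and four-row mixture
matrices; each full pipeline takes a few seconds. Histogram bin width
0.005; interval containment is closed on both ends; top-hat ties prefer
the lower-`k` run; the optical center is taken from configuration (an
auto-centering step is out of scope — synthetic data has a known center).
Map exclusion is exactly the set of frames failing the validity rule, so
excluded ("gray") points carry no wavevector.

## Known limitations

- The band model is phenomenological; absolute `k̄_t` values from real
  fibers (which depend on the fiber's modal structure) are not
  reproduced, only their ordering and separability.
- Scattering is a Gaussian blur; real tissue produces angle-dependent,
  depth-dependent distortion.
- Demultiplexed percentages are uncalibrated relative measures (see
  above) unless the versors have equal L2 mass.
- The blind experiment's accuracy depends on the footprint geometry of
  the simulated lobes; it mirrors the boundary-dominated failure mode of
  real experiments but not their absolute error rates.
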