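# Methods

## Scattering model

The package evaluates the kinematic structure factor of a finite crystallite
by direct summation,

F(**H**) = Σ_ΔU Σ_S Σ_n  w_n · f_n(d*) · exp(−2π² u_n d*²) ·
           exp(2πi **H**·(R_S x_n + T_S + ΔU)),

at integral or fractional Miller indices **H**. Assumptions: kinematic
(single-scattering) diffraction; isotropic harmonic displacements; real
scattering factors (no anomalous terms); a parallelepiped crystallite of
N₁×N₂×N₃ whole unit cells with no cell-to-cell disorder.

* **Reciprocal spacing.** d*² = **H**ᵀ G* **H** with G* the inverse of the
  real-space metric tensor; the orthogonalization matrix follows the
  standard PDB convention (a along x, b in the x–y plane).
* **Form factors.** The standard 4-Gaussian-plus-constant parametrization
  f(s) = Σ aᵢ exp(−bᵢ s²) + c with s = d*/2, tabulated for H, C, N, O, P, S
  and Fe from the international tables; any other element must be given
  explicit coefficients. The built-in rows are unit-tested against gemmi's
  tabulation.
* **Displacement.** The isotropic Debye–Waller factor is
  exp(−2π² u_iso d*²), equivalently exp(−B s²) with B = 8π² u_iso. PDB
  B-factors are converted on input. This convention was confirmed
  numerically against an independent direct-summation implementation
  (gemmi), which agrees to ~10⁻⁷ relative.
* **Symmetry.** The operator table is deliberately minimal and explicit —
  P1, P2₁, C2, P2₁2₁2₁ and P6₃, each stored as a literal Jones-faithful
  operator list (C2 carries its centering translations explicitly). A full
  space-group engine is out of scope; correctness is enforced by two
  oracles: operator-by-operator equality with gemmi, and equality of
  symmetry-aware F with F of the P1-expanded structure (tolerance 1e−10
  relative). Screw-axis extinctions (P2₁ 0k0 with odd k, P6₃ 00l with odd
  l) emerge from the sum and are asserted, not special-cased.
  `expand_to_p1` applies every operator verbatim without merging special
  positions: the summation treats operators literally, and all test
  structures use general positions.

## Lattice sum

Because the cell offsets separate, Σ_ΔU exp(2πi **H**·ΔU) factorizes into
per-axis geometric series Σ_{u=0}^{N−1} exp(2πi h u) =
exp(iπh(N−1))·sin(πhN)/sin(πh). Near-integer h is the removable
singularity; the implementation switches to the limit N·exp(iπh(N−1)) when
|sin(πh)| < 10⁻⁹. Offsets run over {0..N−1} per axis (not centred); the
resulting overall phase does not affect any amplitude. An explicit sum over
all ΔU offsets is retained as a test oracle (capped at 10⁶ cells) and
agrees with the factorized form to 1e−8 relative on random fractional
indices.

Along an axis of N cells the interference function has N−1 zeros per unit
index interval and N−2 subsidiary maxima between adjacent main peaks; at
integer **H** the full factor is N₁N₂N₃, so Bragg intensities scale as
(N₁N₂N₃)². Both properties are asserted directly.

## Precision modes

Batches evaluate in 64-bit ("double") or 32-bit ("single") inner
arithmetic. The single path fixes the accumulation order (symmetry
operators outer, scatterers innermost, one column at a time) and uses
Kahan-compensated summation in complex64, which makes results independent
of internal chunking up to single rounding; the double path is plainly
chunk-stable to better than 1e−12 relative. On the benchmark structure
(below) the mean relative amplitude difference between the two modes is
~3·10⁻⁶, i.e. orders of magnitude below the ~0.8 % accuracy loss commonly
quoted for the FFT approximation — the basis for treating 32-bit direct
summation as safe.

## FFT reference

`fft_reference_sf` is an accuracy cross-check, not the method: each atom's
Gaussian density (displacement folded analytically into each bᵢ; the
constant term c carried as a Gaussian of width B = 8π²u) is sampled on a
grid of spacing d_min/grid_factor and Fourier-transformed. Sampling a sharp
atom on a coarse grid aliases badly, so a fixed extra smearing
B_extra = 8π²(d_min/3)² is added to every Gaussian and deconvolved exactly
(multiplication by exp(+B_extra s²)) after the transform. Because B_extra
is fixed in absolute terms, the residual error is pure grid aliasing and
falls monotonically as grid_factor grows (measured: ~7·10⁻² → 2·10⁻⁵ →
2·10⁻⁸ mean relative error at grid_factor 2, 3, 4 on the benchmark
structure). Atom density is accumulated over a local window truncated where
the densest Gaussian falls to 10⁻⁶ of its peak, with *unwrapped* offsets
folded onto the periodic grid — minimum-imaging inside a window wider than
one cell would double-count near images. Defaults: grid_factor 3,
FFT-friendly grid dimensions, P1 (or pre-expanded) structures only.

## Benchmark structure

Precision and FFT comparisons use a fixed synthetic benchmark: 500 atoms
drawn uniformly in a 40×50×60 Å orthorhombic P1 cell, elements sampled from
{C, N, O, S}, occupancy 1, u_iso uniform in [0.02, 0.05] Å² (B ≈ 1.6–3.9 Å²),
structure seed 20130618; all 32 068 integer reflections to d_min = 2.5 Å.
The size was chosen to be protein-like in atom density yet re-computable in
seconds. Amplitude-comparison statistics exclude reflections below
10⁻⁸ × max|F| to avoid division blow-ups on near-extinct reflections, and
report mean and max of |ΔF|/F plus the Pearson correlation of amplitudes.

## Synthetic detector frames

The frame generator emulates a small photon-counting pixel-array detector
(default 256×256 px of 0.1 mm, 100 mm distance, 1 Å wavelength, beam centre
mid-frame): a flat Poisson background (default mean 10 ADU), planted spots
as *pixel-integrated* 2D Gaussians (error-function differences, so the
planted integrated intensity is exact ground truth), optional azimuthal
Gaussian ring profiles at given d-spacings, rectangular inactive regions,
and a saturation cap. The whole expectation map is Poisson-sampled in one
seeded draw, making frames byte-identical per seed across platforms.

Study conditions for recovery tests follow the stated regime — signal-to-
noise ≥ 10 and centre separations ≥ 5 spot sigmas: planted intensity
600 ADU with σ = 1.5 px gives peak ≈ 42 ADU over a background sigma of
≈ 3.2 ADU (SNR ≈ 13); spot centres are placed on a jittered grid that
guarantees the minimum separation. Streams are Bernoulli hit/miss sequences
at 120 Hz (timestamps i/120 s); hits carry 25 planted spots and misses 5,
straddling the hit threshold of 16 so ground-truth labels are deterministic.

What the generator does *not* model: detector point spread and charge
sharing, per-tile gain variation and metrology errors, diffuse/background
anisotropy, partiality physics of still shots, compressed vendor formats.
Passing recovery tests therefore demonstrates the pipeline logic (labeling,
masking, ring geometry, statistics) rather than robustness to real-detector
artefacts.

## Spotfinding pipeline

1. **Background**: per-tile (default 64 px) median and MAD-derived sigma
   (1.4826·MAD) over active pixels — robust to the spots themselves.
2. **Classification**: active pixels with counts > median + n_sigma·sigma
   (default n_sigma 3.5); inactive pixels are never signal.
3. **Spots**: 8-connected components with ≥ min_pixels (default 2) pixels;
   intensity-weighted centroids on background-subtracted counts; resolution
   per spot from the centroid radius via d = λ / (2 sin(½ atan(r/D))),
   pixel centres at half-integer indices.
4. **Rings**: signal occupancy per d* shell (default width 0.002 Å⁻¹);
   shells above the occupancy cut (default 0.25) merge into rejection
   intervals. A built-in list of strong hexagonal-ice d-spacings
   (3.90/3.67/3.44 Å) can pre-seed intervals. This detects any azimuthally
   extended powder feature without chemistry assumptions.
5. **Quality**: pixel-count cap (400), bounding-box elongation bound (4),
   peak-to-total concentration bound (0.95), and a peak-significance bound
   (peak ≥ 7 local sigmas). The last exists because two adjacent noise
   excursions can clear a 3.5σ per-pixel threshold vastly more often than
   they produce a strong maximum; demanding a significant peak is what
   makes exact precision = 1 achievable on noise-only frames.
6. **Statistics**: accepted-spot count, summed intensity, and a resolution
   limit defined as the 80th-percentile d* of accepted spots (in Å) — a
   stable convention that only extends when genuinely higher-resolution
   spots appear. Reports are fixed-format key/value text (XML/JSON mirrors)
   and byte-stable for identical inputs.

Two-lattice overlap uses predicted centroid lists from two oriented cells
(reflections within a still-diffraction excitation tolerance, default
0.002 Å⁻¹, projected onto the detector): pairs at centre distance ≤ box are
"overlapping", ≤ 2·box "close", otherwise "separated". The box is the
integration-box half-size in pixels; the taxonomy is geometric by design.

## Hit-rate monitoring

A hit is a frame with n_spots ≥ threshold (default 16). The hit rate at a
frame's timestamp t is hits/frames over the trailing window (t − w, t]
(default w = 5 s); the anchor frame is inside its own window so the
denominator is never zero, and the denominator is the *observed* frame
count, not a nominal rate × w (the choice matters only when frames drop).
Totals (frames, hits, fraction, per-run breakdown) are additive, so
contiguous chunks processed independently merge to exactly the serial
result — the contract that makes multiprocess monitoring safe. Decreasing
timestamps raise an error naming the offending record.

## Numerical and interface choices

* Fractional coordinates are reduced to [0, 1) on input; occupancies are
  validated into [0, 1]; the first symmetry operator must be the identity.
* Pixel convention: 0-based (slow, fast); detector x runs along fast.
* SMV image I/O: 512-byte ASCII header (SIZE1 = fast, SIZE2 = slow,
  little-endian unsigned 16-bit payload); counts above 65535 refuse to
  write rather than silently wrap.
* Caps guard accidental resource blow-ups: 10⁶ cells for explicit lattice
  sums, 10⁶ grid points for fringe maps, 512³ FFT grid points; exceeding
  one raises a resource-limit error (CLI exit code 4).
* CLI exit codes: 0 success, 2 usage, 3 input error, 4 resource limit.

## Known limitations

Only the five listed space groups; no anisotropic displacement, anomalous
scattering, charge states or mmCIF input; spot-quality heuristics are a
documented re-interpretation of common practice, with no claim of output
parity with any existing spotfinder; the two-lattice model predicts
positions only (no intensities, no mosaic broadening); the fringe renderer
draws plane sections of reciprocal space, not Ewald-sphere projections.
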