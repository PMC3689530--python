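# braggkit

Tools for two computational problems at the heart of modern crystallographic
data collection:

1. **Direct-summation structure factors for finite crystallites.**
   Macromolecular structure factors are usually obtained by FFT of a sampled
   electron density, but that approximation only exists at integer Miller
   indices. For crystallites a few unit cells wide — the regime of serial
   femtosecond crystallography (SFX) — the diffraction between Bragg peaks
   carries interference fringes that can only be computed by summing the
   scattering expression directly, at *fractional* Miller indices:

   F(**H**) = Σ_ΔU Σ_S Σ_n  w_n · f_n(d*) · exp(−2π²·u_n·d*²) ·
              exp(2πi·**H**·(R_S·x_n + T_S + ΔU))

   with ΔU running over the N₁×N₂×N₃ unit cells of the crystallite, S over
   the space-group operators (rotation R, translation T), and n over the
   scatterers of the asymmetric unit (form factor f_n, occupancy w_n,
   isotropic displacement u_n, d* the reciprocal spacing of **H**).
   The lattice sum factorizes into per-axis geometric series (the Laue
   interference function), which the package exploits and verifies against
   the explicit sum. Summation runs in 64-bit or 32-bit arithmetic, with an
   FFT-based sampled-density reference available as an accuracy cross-check.

2. **Bragg spotfinding and hit-rate monitoring on detector frames.**
   A per-image pipeline — robust per-tile background estimation, signal-pixel
   classification, connected-component spot detection, ice/powder-ring
   rejection by resolution-shell occupancy, spot-quality heuristics — plus
   per-image quality statistics (spot count, total intensity, resolution
   limit), sliding-window hit-rate monitoring for 120 Hz frame streams
   (a *hit* being an image with ≥ 16 strong spots), and a classifier for
   spot overlap between two lattices in the same exposure. Everything is
   exercised on seeded synthetic frames with exact ground truth, so
   precision and recall are checkable to equality.

The intended users are beamline-software and methods developers who need a
small, dependency-light, fully testable reference implementation of these
steps rather than a production data-reduction stack.

## Worked example

```python
import numpy as np
from braggkit.crystal_model import random_p1_structure
from braggkit.direct_summation import (
    CrystalliteExtent, compare_amplitudes, enumerate_hkl, sf_batch,
    sf_finite_crystal, sf_single_cell,
)

# 500 random protein-like atoms in a 40 x 50 x 60 A P1 cell
structure = random_p1_structure(n_atoms=500, seed=20130618)
hkl = enumerate_hkl(structure.cell, d_min=2.5)

rs64 = sf_batch(structure, hkl, precision="double")
rs32 = sf_batch(structure, hkl, precision="single")
cmp_ = compare_amplitudes(rs64, rs32)
print(f"{len(hkl)} reflections, mean |dF|/F = {100 * cmp_.mean_rel_err:.6f}%")

# fringes: a 10 x 12 x 14-cell crystallite at a fractional index
f = sf_finite_crystal(structure, CrystalliteExtent(10, 12, 14), (1.25, 0.0, 0.0))
print(f"|F(1.25,0,0)| = {abs(f):.3f}  vs single cell "
      f"{abs(sf_single_cell(structure, (1.25, 0.0, 0.0))):.3f}")
```

prints

```
32068 reflections, mean |dF|/F = 0.000263%
|F(1.25,0,0)| = 197498.805  vs single cell 831.266
```

The first line shows that 32-bit summation loses far less accuracy than the
~0.8 % typically attributed to the FFT approximation, so single precision is
a safe speed trade for fringe simulation. The second line shows the finite
crystallite amplifying the fractional-index point by its lattice
interference factor (|sin(12.5π)/sin(1.25π)| · 12 · 14 ≈ 237.6 here, since
k and l sit at integer values).

On the imaging side:

```sh
braggkit simulate --spec examples/frame.json --n 1 --seed 7 --outdir frames/
braggkit spotfind frames/frame_00000.img
```

prints a stable key/value report (`Spot Total`, `Ring Rejected`,
`Quality Rejected`, `Total Intensity`, `Resolution Limit`); `--xml` and
`--json` emit the same fields in other formats. `braggkit monitor
counts.tsv --threshold 16 --window 5` turns a per-frame spot-count stream
into hit totals and a sliding hit-rate series, and `braggkit serve` exposes
the spotfinder as a tiny HTTP service.

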