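# Methods

This note records the models, numerical choices and limitations behind
`pakit`, in the order of the processing chain.

## Thermoacoustic model (`pakit.media`)

A medium is a set of SI constants: density ρ, isobaric/isochoric
specific heats Q_p and Q_v, volumetric thermal expansion μ, sound speed
c, thermal diffusivity D, optional isothermal compressibility s and an
optional pinned Gruneisen coefficient Γ.  Derived quantities:

- relaxation times `T_r = l²/D`, `T_y = l/c` for a feature of size `l`;
- confinement: a pulse is confined iff `width ≤ θ·min(T_r, T_y)` with
  θ = 0.1 by default ("much shorter than" made concrete; θ is a
  parameter because no universal threshold exists);
- compressibility `s = Q_p/(ρ c² Q_v)` and Gruneisen `Γ = μ c²/Q_p` —
  the standard dimensionally consistent forms.  Several textbook-style
  presentations of these relations circulate with ρ and Q_v placed
  ambiguously; the forms above are the ones whose units close, and the
  consistency test (`tests/test_media.py`) verifies that the Γ route and
  the s⁻¹μΔT route produce identical pressure for any constants;
- temperature rise `ΔT = X_p/(ρ Q_v)` (100 % photothermal conversion)
  and initial pressure `p0 = Γ·X_p`.

Presets: `water` (Γ pinned at 0.11) and `soft_tissue` (Γ pinned at
0.25, μ = 4×10⁻⁴ 1/K, c = 1500 m/s).  The pinned Γ values are the
room-temperature literature values and take precedence over the
computed form, so preset behaviour does not drift with the other
constants.  A computed Γ outside (0, 2) is physically implausible and
logged, not raised — the caller may be exploring parameter space.

The fractional volume change `dV/V = −s·p + μ·ΔT` is exposed only as a
diagnostic (`relative_volume_change`); the imaging chain assumes it
vanishes, which is an identity under the Γ chain.

## Grids and phantoms (`pakit.grids`, `pakit.phantoms`)

Grids are 2-D or 3-D with per-axis pitch in micrometres; node (i, j, k)
sits at `origin + index·spacing`, 0-based, depth last and increasing
away from the scanned surface.  Physics is SI internally; imaging
geometry is μm at the API surface.

Shape generators (points, fibers, spheres/discs, agar blocks with
inclusions, layered vessel networks) are pure functions of their
arguments and seed.  Fibers and spheres are rasterized with
area-fraction anti-aliasing: the inside indicator is averaged over a
deterministic 5× per-axis subdivision of each cell (axes parallel to a
grid-aligned fiber are skipped — they cannot change the distance).
This keeps sub-resolution structure representable — the resolution
worked example hinges on an 8.2 μm fiber being faithful on a 0.5–1 μm
grid — and bounds the mass error against the analytic cross-section
(≲ 0.5 % at pitch ≤ feature/8).  Vessel segments are rasterized as
capsules with a cheaper linear-ramp edge (one pitch wide); vascular
phantoms are qualitative emulations, so the ~1 % edge bias is
irrelevant there.

The layered oral phantom places U-shaped capillary loops (limb length
3–6 diameters, apex radius 1–2 diameters — invented geometry exposed in
the layer spec) at ~100 μm depth, a branching reticular polyline mesh
at ~500 μm and few thick meandering trunks at ~1 mm, with diameter
ranges 8–15, 25–45 and 80–120 μm.  No quantitative density or diameter
statistics exist for the target tissue in this setting; the defaults
are chosen so sections at 100/500/1000 μm reproduce the qualitative
depth ordering (loops → mesh → trunks, diameter strictly increasing).
Structure counts are Poisson in the field area at the configured
density, with a floor of one structure per layer: a specified layer
that silently came out empty would break the layering contract the
phantom exists to provide.

## Forward model (`pakit.forward`)

Geometry is always 3-D free space; a 2-D map is treated as a slab one
voxel thick so the same kernel — and the analytic sphere oracle —
applies to the annular-array tomographic plane.

Discretization: for each element, every voxel contributes
`p0 · V_vox / r` to the time bins whose distance interval
`[c(t−dt/2), c(t+dt/2))` overlaps the voxel's own radial footprint
`[r − dr/2, r + dr/2]`, with the overlap fraction as weight (dr = the
smallest pitch).  This partial-shell weighting was chosen over
nearest-bin assignment to suppress staircase artifacts, and it is the
single code path shared with the system matrix.

Pulse handling fixes a subtlety: the **delta-pulse response is defined
as this raw non-negative geometry sum** (the quantity the system matrix
tabulates), while physical pressure is its time derivative.  A
gaussian pulse of FWHM w convolves the geometry sum with L′(t) and the
calibration 1/(4π c²), delivering pressure in Pa — for a uniform
sphere, the bipolar N-wave `p = p0(r−ct)/(2r)` with endpoints
±p0R/(2r).  Validation compares simulation and closed form pointwise
away from the two jump discontinuities (a guard of ~3 pulse widths,
since any finite pulse rounds an ideal step) and recovers the endpoint
amplitudes by extrapolating the interior ramp, which is exact.  The
closed form itself is verified against an independent spherical-mean
quadrature (fractional-coverage polar integration plus a central
difference) to 0.1 % — in practice ~10⁻⁹.

Defaults where the annular-array geometry is otherwise unconstrained:
64 elements, ring radius twice the grid half-extent (elements always
outside the support), `dt = pitch/(2c)`, time window sized to the
farthest voxel.  Element sensitivity models: `ideal` (weight 1),
`line_focused` (flat inside a slab around the element's look axis,
cosine² roll-off outside) and `flat_field` (cosine directivity to a
power).  Only the uniformity *ordering* of the latter two is asserted
anywhere — their shapes are plausible parametrisations, not calibrated
hardware curves.

Noise: seeded white gaussian at a peak-relative SNR in dB, or an
absolute σ; all-zero signals reject a relative SNR with a pointer to
the absolute mode.

## System matrix and solvers (`pakit.sysmatrix`, `pakit.recon`)

`SystemMatrix` stores the delta-pulse geometry matrix and the banded
pulse-convolution operator as separate sparse factors; `apply()` runs
the identical scipy CSR products as `simulate_signals`, which is why
the matched-operator test can demand *exact* equality rather than a
tolerance.  Column b of G is, by construction, the flattened signal of
the indicator image of pixel b.  A provenance hash of the
(grid, array, pulse, medium, dt) tuple guards against pairing a matrix
with data it was not built for.  A matrix-free mode rebuilds the
factors per application for grids whose explicit matrix would exceed a
memory cap; both modes satisfy the same apply/adjoint contracts.

Kaczmarz/ART sweeps rows in shuffled (seeded) order by default —
faster convergence — with a sequential mode for textbook
reproducibility; zero-norm rows (bins no voxel can reach) are skipped;
relaxation λ ∈ (0, 2]; optional projection onto Z ≥ 0 after each sweep;
stop at a fixed sweep count or when the relative residual change drops
below 10⁻⁶ (no principled tolerance exists for "iterate until
optimal", so both knobs are exposed).  Landweber uses
μ ≤ 1/σ_max(G)² from a partial SVD, under which the residual norm is
provably non-increasing; growth by 10× over 5 iterations raises with
advice to shrink the step.

`backproject` is the plain delay-and-sum contract: pixel value = mean
over elements of the linearly interpolated sample at the retarded time.
`filtered_backproject` is the field-standard quantitative baseline
(universal backprojection): convert monopolar geometry sums to pressure
by the same short-gaussian derivative the forward model uses, apply
`b(t) = 2p − 2t·∂p/∂t`, delay-and-sum, clip at zero.
`compare_sparse_view` uses the filtered variant and reports
scale-fitted relative L2 errors, because delay-and-sum amplitude is
arbitrary while relative amplitudes are the model's contract.

## OR-PAM simulator (`pakit.orpam`)

The microscopy path is a linear PSF model — lateral gaussian blur at
the optical spot FWHM, axial gaussian blur for detector bandwidth
(default 30 μm FWHM; the axial/lateral asymmetry of OR-PAM is real but
unquantified here), amplitude scaled by Γ — with no acoustic
propagation.  This is justified because OR-PAM lateral resolution is
optically determined; the acoustic path is exercised by the tomography
modules.  Consequences: apparent FWHM of a point ≈ spot FWHM; an
8.2 μm fiber under a 9.9 μm spot reads ≈ 11.2 μm (tophat ⊛ gaussian,
consistent with the quadrature-broadening law within its validity);
nothing reads below ~0.95× the spot.

Raster scans sample a centred rectangular grid; rotary scans sample
evenly rotated diameters of a disc (angular count chosen so the rim
arc step ≤ the linear step) and regrid to Cartesian by linear
interpolation.  An optional jitter model accumulates seeded lateral
drift per A-line, emulating tissue motion during slow scans.  B-scans,
MAPs and depth sections are maxima along the respective axes; a depth
section is the max over a slab of configurable thickness.

## Metrology (`pakit.metrics`)

FWHM: half level = baseline + (max − baseline)/2, baseline = median of
the outer decile of samples (robust to DC offsets in MAP profiles —
whether published apparent-size numbers are FWHM or full support is
rarely stated; FWHM is adopted), crossings by linear interpolation.
SNR: 20·log10(peak(signal region)/std(noise region)).  Relative RMSE
with an optional least-squares scale fit.  Sensitivity/specificity by
direct confusion counting at a threshold.

Morphometry: binarize (Otsu by default, threshold exposed),
skeletonize, diameter = 2 × distance transform at skeleton pixels,
length from skeleton adjacency (diagonal steps ×√2, with diagonal
edges dropped when an orthogonal neighbour already connects the pair —
suppresses staircase double counting), density as foreground fraction
and length per area, loop count = independent cycles of the skeleton
graph (E − V + components).  On images blurred by the scan PSF the
apparent diameter is broadened accordingly; the depth-ordering claims
compare sections measured identically, so the ordering is unaffected.

## Problem sizes

Default validation scales, chosen to keep every check at desk scale:
sphere oracle on a 48³ grid at R/20 pitch; matched-operator and
sparse-view studies on 32×32 grids (16–64 elements); solver-recovery on
16×16 with 64 elements; resolution scans on 0.5 μm-pitch fiber maps;
the oral phantom at 128×128×56 voxels (10/20 μm pitch).  All scale up
by configuration.

## Known limitations

- Uniform fluence: no light-transport modelling, so depth-dependent
  optical attenuation and scattering (the role of the agar/milk
  phantom's scatterers) are absent; absorbed energy is proportional to
  the absorption coefficient everywhere.
- No acoustic attenuation, heterogeneous sound speed, or transducer
  impulse response; absolute pressure calibration is limited to the
  documented 1/(4πc²) constant — relative amplitudes are the contract.
- Synthetic vasculature is a geometric emulation: no flow, oxygenation,
  or multi-wavelength contrast, and its density/diameter statistics are
  plausible rather than measured, so passing tests demonstrate
  correctness of the *pipeline*, not fidelity to any particular tissue.
- Hardware-level detection performance (classification
  sensitivity/specificity of real detectors) is out of scope; only the
  uniformity ordering of the sensitivity models and the exactness of
  the confusion-matrix arithmetic are claimed.
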