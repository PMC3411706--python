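# Methods

This note records the models, algorithms, parameter choices and known
limitations of `vqmouse`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory.

## Data model and conventions

All images are 3-D scalar grids with isotropic voxel spacing (`Volume`),
read and written as NIfTI-1 through nibabel. Axis 2 is axial with the
lung apex at the high index by default (configurable where orientation
matters). Voxel centres are 0-based indices; world coordinates are
`origin + index * spacing` in mm. CT volumes are expressed in Hounsfield
units after a two-anchor linear calibration (air ROI → −1000, water ROI →
0); the ROI means are user-supplied because acquisition protocols differ.
SPECT volumes carry reconstructed counts; during any resampling they are
treated as count *densities* (value scaled by the voxel-volume ratio), so
total activity is approximately conserved across grid changes and the
relative-frequency normalization downstream does not depend on the grid.
Anisotropic inputs are rejected rather than silently resampled.

The Gaussian pre-filter used before segmentation and registration takes
its width in voxel units (σ = 0.8 by default); interpreted in mm it would
smooth less than one voxel and do nothing useful.

## Lung segmentation

The label is produced in four deterministic steps on the calibrated,
smoothed CT: (1) region growing from a seed voxel keeping HU ≤ −50
(6-connected by default), (2) a bounded volume-growing step — by default
two one-voxel dilations that admit only neighbours below +100 HU — which
recovers denser parenchyma while the +100 HU gate excludes chest wall and
bone, (3) 3-D hole filling so enclosed vessels count as lung, and
(4) removal of the trachea and main bronchi above a user-given carina
plane (or within a user mask) for the ventilation label only; above the
carina the airway is a separate midline component, so only the component
nearest the transverse centroid is removed and the lung apices are
untouched. Threshold conventions: ≤ for the −50 HU inclusion, strict <
for the +100 HU gate.

The seed defaults to the minimum-HU voxel inside the central 40 % slab of
the volume — reproducible and almost always inside the airspace of a
thorax scan. The original workflow's manual inspection step is replaced
by logged QC metrics (component count, largest-component fraction,
labelled volume) that a study should range-check.

On the default phantom the recipe reaches a Dice overlap of ≥ 0.95
against the true label (measured ≈ 0.9998).

## Mutual-information rigid registration

Similarity: Shannon MI (nats), `H(A) + H(B) − H(A,B)`, of the joint
intensity histogram over labelled voxels only. Binning is per-volume
min–max with 64 bins. Two estimator refinements proved necessary on
phantom data and are defaults (both configurable off):

* **Partial-volume interpolation** — each sample distributes its
  trilinear weights over the moving-volume bins of its 8 lattice
  neighbours instead of binning an interpolated value. Trilinear-then-bin
  showed a 0.2–1° bias of the MI optimum.
* **Parzen smoothing** (Gaussian, σ = 1 bin) of the joint histogram, and
  a **fixed sub-voxel jitter** of the sample positions (deterministic,
  seeded internally). Without the jitter, interpolation dispersion
  vanishes at exact-voxel alignments and MI is spuriously inflated there;
  the optimizer then locks onto integer-voxel translations.

Optimizer: Powell's direction-set method over (tx, ty, tz, rx, ry, rz) —
translations in mm, intrinsic X-then-Y-then-Z rotations in degrees about
the lung-label centroid. Each cycle line-searches the six axes and then
the net cycle direction; each 1-D search is a bounded golden-section /
parabolic-interpolation minimisation (scipy's bounded Brent) on a window
of ±1.5 mm / ±5° that contracts (at most halving per cycle) as cycle
displacements shrink. Convergence requires every translation to change
by < 0.01 mm and every rotation by < 0.01° over a full cycle.

SPECT-to-CT fusion starts from an activity-centroid capture step: the
translation aligning the SPECT activity centroid with the label centroid.
This lands within ~0.2 mm of truth on phantoms and keeps Powell inside
the capture basin; without it, misalignments beyond ~1 mm can settle on
secondary maxima of the smooth-texture MI surface.

The study flow mirrors the acquisition protocol: the perfusion SPECT↔CT
transform is computed and applied unchanged to the ventilation pair (the
animal does not move between a SPECT scan and the adjacent CT); the
perfusion CT is co-registered to the ventilation CT by the same MI
machinery within the ventilation lung label; the composed map carries the
perfusion SPECT onto the ventilation-CT grid. Internally the CT–CT step
runs first so the label can be mapped into the perfusion frame for the
SPECT fusion — the composition is order-independent. Transform objects
carry frame tags and refuse inconsistent composition.

Measured accuracy on noise-free phantoms: mono-modal known-transform
recovery has median error ≈ 0.002 mm / 0.02° over 20 random motions
within ±2 mm / ±5° (bound: 0.1 mm / 0.2°); the end-to-end two-stage study
alignment errs ≤ 0.2 voxel at the label centroid (bound: 0.5 voxel).
Cross-modal SPECT→CT fusion plateaus at a voxelwise correlation of
≈ 0.988 between fused and truth-aligned volumes: the residual
0.05 mm / 0.15° is a bias of the MI surface itself on stochastic texture
(MI at the solution exceeds MI at truth), not an optimizer failure.

## Per-voxel log(V/Q)

V and Q are converted to relative frequencies — voxel activity divided by
total label activity × 100 — making every downstream quantity invariant
to global activity scalings (the ~24:1 Q:V total-activity ratio of the
acquisition must be, and is, immaterial; this is tested for every result
field). The per-voxel value is log₁₀(v_rel/q_rel). Category conventions:
V = 0, Q > 0 → −∞ (unventilated); Q = 0, V > 0 → +∞ (unperfused); both
zero → noted, displayed as 0. Moments (mean, SD, skewness g₁, excess
kurtosis g₂) are population-style and computed over finite voxels only;
at ~46 000 voxels estimator bias is negligible. Both-zero voxels are
excluded from moments by default — their stored 0 is a display
convention, not a measured ratio — with a toggle to include them.

Mismatch is the % of total lung volume beyond ±2 *reference* SD from the
reference mean; the reference is a supplied cohort average (so aged or
diseased subjects are judged against healthy thresholds) or,
fallback-with-warning, the subject itself. Ties exactly on a threshold
count as matched. The "total" low/high figures add the −∞/+∞ categories
respectively. The distribution table reports % TLV per 0.05-wide bin
(plot convenience only) with named rows for the special categories, so
rows always total 100 % TLV.

## Regionalization

Apex/middle/base: cumulative labelled-voxel counts along the axial axis;
each boundary is the slice whose cumulative fraction is nearest 33 % /
66 % (lower index on ties) and the boundary slice belongs to the lower
slab — a declared convention, since any choice shifts one slice at most.
Inner/outer: binary erosion with the 6-neighbour structuring element,
depth 3; inner = survivor, outer = difference. Both partitions are exact
(disjoint, union = label) by construction and by property test; erosion
equals a longhand per-voxel oracle on small grids.

## CT densitometry and air volumes

The air coefficient of a voxel is `clamp(−HU/1000, 0, 1)` — 1 at
−1000 HU, 0.5 at −500 HU, 0 at 0 HU and beyond; values outside the range
clamp because an air fraction is physically bounded. Histograms use
25 HU/bin with edges placed so a bin centre falls exactly on −500 HU,
making the canonical worked value exact. Air volume is
Σ count × coefficient × voxel volume; FRC is the expiratory-image air
volume and TV the inspiratory−expiratory difference (negative TV is
returned with a warning — it indicates a gating or ROI problem). Because
the coefficient is linear inside the clamp range, the binned estimate
differs from the exact per-voxel sum by at most (bin width/2)/1000 of the
ROI volume; this bound is tested across bin widths. The thoracic ROI of
the original protocol was drawn manually; the package accepts any mask
and offers a dilated lung label as a reproducible stand-in (tissue voxels
contribute ~0 air, so modest over-inclusion is harmless).

## The digital thorax phantom

The phantom is the package's test bed: a stylized mouse thorax with every
ground truth recorded *from the generated voxels*, never echoed from the
requested parameters.

**Geometry.** A body ellipsoid (+40 HU) in air contains two elongated
lung ellipsoids joined by a bronchial channel, and a trachea that ends
inside the body (the intubated airway is not connected to outside air,
which keeps region growing confined — the real-world analogue is the
closed ventilation circuit). A 2-voxel shell of +150 HU (chest
wall/pleura) surrounds the airspace; this dense boundary is what makes
the +100 HU exclusion gate effective, as ribs and intercostal tissue do
in vivo. Default grid: 88×88×128 at 0.23 mm — the analysis resolution —
giving ≈ 46 200 label voxels (0.56 mL), the per-animal scale of the
source protocol. The lungs are deliberately elongated so that the
3-voxel outer shell holds ≈ 55 % of the volume, matching the
surface-to-volume ratio regionalization observed in vivo; real mouse
lungs achieve the same ratio with more irregular shapes.

**CT.** Lung voxels draw HU from a bimodal mixture: smooth parenchyma
centred at −325 HU and interior vessel-like blobs centred at −25 HU, each
mixing a shared smooth texture field with white noise. The vessel volume
share is *derived* from consistency between the target FRC and the lung
volume at the stated peaks (≈ 35 %), and each blob keeps a 2-voxel
clearance from the lung surface so hole filling recovers it. A final
global shift on lung HU is solved (bisection) so the exact per-voxel
air-fraction sum over the thoracic ROI equals FRC (expiratory) or
FRC + TV (inspiratory); inspiration therefore shifts the density
distribution toward lower HU, as respiratory-gated imaging shows.

**V/Q fields and the normalized-mean constraint.** Perfusion is
log-normal in a smooth Gaussian field G, Q = exp(a·G); the log-ratio
field is σ·X with X = ρG + √(1−ρ²)H, H an independent smooth field, and
V = Q·10^(σX). A key structural fact drives the design: after both
fields are normalized to relative frequencies, the *mean* of finite
log(V/Q) is no longer a free location parameter — any global scaling of V
or Q cancels — but is fixed by the distribution's shape and its
correlation with Q (for an independent normal log-ratio field of SD σ the
normalized mean is forced to ≈ −σ²ln10/2, i.e. −0.15 at σ = 0.361). A
generator that must realize a *requested* mean therefore has to shape the
joint distribution. `vqmouse` does this through the Gaussian copula: it
solves (a, ρ) numerically — nested bisection on the empirical fields — so
that the realized normalized mean and the per-voxel Pearson correlation
equal their requested values exactly. The realized SD equals σ by
construction (X is standardized over finite voxels). The solved values
land near a ≈ 0.8, ρ ≈ −0.2 for the default condition: mild negative
coupling, i.e. strongly perfused regions run slightly ventilation-poor.

Zero-ventilation and zero-perfusion defects are placed as contiguous
patches at the label periphery (depth-plus-noise ranking; uniform
placement would be a one-line change), with exact voxel counts, because
unventilated voxels in vivo concentrate at the label perimeter. Vessels
suppress both V and Q by a common factor (no alveoli, no trapped tracer
there), which leaves the log-ratio untouched while giving the CT and
SPECT a shared spatial structure; together with the shared parenchymal
texture (weight 0.9 between CT density and perfusion) this provides the
cross-modal statistical dependence that MI registration genuinely needs —
a phantom with independent CT and SPECT textures makes MI fusion fail for
structural reasons (misalignment-induced boundary structure out-scores
the true pose), not implementation ones. Study outputs additionally
receive a 1-voxel PSF-like blur, since reconstructed SPECT activity
decays smoothly across the lung boundary.

**What the phantom does not emulate.** Collimator/PSF physics beyond the
Gaussian blur, scatter and attenuation, cardiac/respiratory motion
blur, lobar anatomy, airway trees, and the negative skew (−1.7) and high
kurtosis (≈ 10) of real log(V/Q) distributions — the default log-ratio
marginal is normal (a reversed-lognormal skew option exists, off by
default), so skewness/kurtosis recovery is not a supported claim.
Per-voxel Poisson noise is available but off by default; it is a
stand-in, as no noise model for reconstructed SPECT voxels is specified
by the source protocol. Passing tests therefore demonstrate correctness
of the analysis chain under controlled conditions, not performance on
scanner data.

## Problem sizes and determinism

Tests run on the default phantom (≈ 46k label voxels) and a coarse 0.4 mm
variant (≈ 9k voxels) for cheap cases; the registration battery uses 20
random transforms on the default phantom. The full suite takes about two
minutes on one CPU; `scripts/acceptance.py` a few seconds. The same seed
reproduces every phantom bitwise; different seeds reproduce the solved
statistics to the solver tolerance (the mean/SD/R are solved per
realization, so they agree across seeds to ~1e-4).
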