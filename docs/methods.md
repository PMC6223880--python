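# Methods

`liverloc` implements a tumour-localisation experiment for CT-guided
percutaneous liver ablation: can a computer transfer the tumour position
from a diagnostic contrast-enhanced CT (CECT) onto an intraprocedural scan
*without* giving the intraprocedural scan contrast? The experiment works on
a *virtually unenhanced CT* (VUCT): an intraprocedural CECT whose
contrast-revealed structures have been computationally replaced with
parenchyma-like values, so the tumour is inconspicuous, while the original
CECT retains the ground-truth tumour location. Three localisation methods
are compared per tumour by their target registration error (TRE): rigid
registration, rigid + B-spline non-rigid registration, and simulated
"mental registration" by human observers.

Because no clinical CT pairs ship with the package, every experiment runs on
a synthetic abdominal phantom with exactly known ground truth. All world
coordinates are millimetres in the LPS convention; transforms between the
two scans are stored as maps from intraprocedural (fixed) world points to
diagnostic (moving) world points — the resampling convention — so warping a
diagnostic mask onto the intraprocedural grid is a direct inverse-mapping
resample.

## Synthetic phantom

The anatomy is a set of analytic implicit surfaces in the diagnostic frame:
a body ellipsoid with a subcutaneous fat ring (−50 HU) around soft tissue
(40 HU), a spine cylinder (700 HU), a liver built from three overlapping
ellipsoids (enhanced parenchyma 110 HU), tubular portal-vein-like vessels
(160 HU), spherical tumours — hypervascular at parenchyma +30 HU,
hypovascular at −35 HU, mixed 35:56 as in a typical ablation cohort — and
optional surgical clips (1000 HU). Tissue interfaces are blended over a
2 mm edge, mimicking partial-volume averaging. A smooth zero-mean texture
(sum of random plane waves, sd 6 HU, wavelengths 25–60 mm) is added to all
soft tissue; it is tied to the anatomy frame and therefore warps with the
patient. Without such texture a de-enhanced liver would be piecewise
constant and its rotational alignment ill-posed, which no real liver is.

Tumour diameters are drawn from a truncated normal (mean 20.4 mm, sd
9.4 mm, clipped to 6.1–60.0 mm, matching the cohort the generator
emulates); centres are rejection-sampled inside the liver with a safety
margin (1000 attempts, then a placement error). Volumes default to 96³
voxels at 2 mm isotropic; slice thickness is a free choice since typical
intraprocedural protocols vary.

The intraprocedural scan is the same anatomy pulled back through the ground
truth transform `T(x) = R(x) + w(R(x))·u(x)`: a rigid patient motion `R`
(rotation about the cranio-caudal axis + translation) composed with a
random cubic B-spline displacement `u` (control spacing 24 mm,
coefficients uniform in ±amplitude, lightly smoothed and rescaled so the
largest coefficient equals the requested amplitude; the partition-of-unity
property of the B-spline basis then bounds the dense displacement by the
amplitude). The window `w` is 1 inside the liver and decays to 0 within
25 mm of its surface, so the spine stays rigid — deformation in this
setting is breathing- and posture-induced and liver-local. Both volumes
receive independent Gaussian noise (default sd 10 HU). Because the two
scans are the *same* analytic anatomy sampled at warped positions, tumour
masks, liver masks and tumour centres are consistent by construction; the
reference centre of each tumour is the centre of gravity of its
intraprocedural mask.

What the phantom does **not** model: beam hardening, scatter, spatially
correlated CT noise, respiratory sliding interfaces, perfusion
heterogeneity inside tumours, and neighbouring organs that could distract a
registration. Passing results therefore show the pipeline is correct and
self-consistent under realistic geometry and noise — not that it reaches
clinical accuracy on real patients.

## Virtual de-enhancement

Parenchyma statistics are estimated robustly (median, MAD-scaled sd) from
liver voxels inside a plausibility band (0–300 HU). Liver voxels above an
adaptive hyper threshold (mean + 1.5 sd by default) and all voxels of
explicitly segmented hypovascular tumour masks are replaced by draws from
N(mean, sd) — truncated at the threshold, so no replaced voxel re-exceeds
it; voxels at or above the clip threshold (500 HU) and everything outside
the liver are preserved bit-exactly. The replacement is feathered outward
(Gaussian, default 2 mm) into the surrounding parenchyma to avoid step
artefacts that would give the lesion away. The 1.5 sd default balances
lesion suppression (a +3 sd hypervascular lesion keeps <8% of its voxels)
against false replacement of normal parenchyma (~7%, refilled with
same-statistics values, hence harmless); a 3 sd threshold would leave half
of such a lesion visible. Hypovascular lesions are only ever replaced via
explicit masks — their intensity band overlaps normal tissue variation, so
thresholding them is unsafe.

## Registration

**Initialisation.** Translation aligns the liver-mask centroids. When
anteroposterior axis landmarks are available (spinous process → sternum, the
line an interventionalist can draw in seconds), an in-plane rotation about
the cranio-caudal axis aligns the two axes first; this brings even an
extremely rotated patient (180°) into the capture range of the intensity
refinement.

**Rigid stage.** Mattes mutual information (32 bins) over the fixed liver
mask dilated by 5 mm, 25% random sampling with a fixed seed
(deterministic), a 3-level image pyramid (shrink 4/2/1), optimised with
Powell's direction-set method (10 iterations × 10 line iterations, scales
from physical shift). Mutual information is used because the CECT↔VUCT
intensity relationship is non-linear; Powell because its derivative-free
line searches are robust to metric sampling noise — on noise-free phantoms
it recovers motion to ~0.3° / 0.4 mm where gradient-based optimisers
stalled at 1.5–3.5°.

**Non-rigid stage.** The deformation model is a cubic B-spline free-form
deformation on a regular lattice (final control spacing 16 mm). The
displacement itself is estimated by multi-resolution symmetric-forces
Demons (levels at shrink 4 and 2; 60/40 iterations; Gaussian smoothing of
update and total field, sd 2 voxels, which is the regulariser) between the
fixed VUCT and the *de-enhanced* diagnostic scan resampled through the
rigid result. De-enhancing both sides reduces the problem to same-modality
matching: vessels and lesions, which exist on only one side and would
otherwise attract spurious forces, are gone from both. Outside the fixed
liver dilated by 10 mm the moving values are replaced by the fixed values,
so no forces arise there — the alignment is restricted to the liver
region. The dense field is then projected onto the B-spline lattice
(low-pass at the lattice scale, sampled at control points, prefiltered to
interpolating coefficients), which acts as a final smoothness constraint
and yields a compact, serialisable, composable transform. A
direct optimisation of lattice coefficients against masked mutual
information (the textbook alternative) was implemented first and
consistently *degraded* accuracy here — without a bending-energy term the
mostly-flat de-enhanced liver lets the lattice chase noise — and was an
order of magnitude slower; the Demons route is the package's deliberate
numerical choice, with the B-spline lattice retained as the transform
model.

**Failure detection.** The warped moving liver is compared with the fixed
liver by Dice overlap; below 0.3 the result is flagged failed ("the livers
do not overlap") rather than raising, and the affected tumours are excluded
pairwise from all methods' summaries. 0.3 separates gross misconvergence
from merely imperfect alignment.

**Similarity surface.** `similarity` reports normalised mutual information
NMI = (H(A)+H(B))/H(A,B) from a 32×32 joint histogram over masked voxels
(2 for identical images up to an intensity bijection, →1 for independent
ones; a constant image has zero joint entropy and the value is defined
as 2).

## Mental registration simulation

Each of four observers annotates every tumour once: true centre + bias +
zero-mean Gaussian noise (default sd 12 mm per axis, bias 0), optionally
snapped to the nearest axial slice centre (observers annotate in-plane).
The four annotations are averaged per tumour. The 12 mm default makes the
4-observer mean err by ≈9 mm median in 3D, emulating the accuracy human
experts reach when transferring a tumour position mentally between scans;
it is a model of expert performance, not a measurement.

## Evaluation and statistics

TRE is the Euclidean distance between the annotated centre and the
reference centre (centre of gravity of the intraprocedural tumour
segmentation; an in-plane-snapped truth variant is recorded per record and
available for the mental method). Per tumour, the method with the strictly
smallest TRE "wins"; exact ties yield no winner and are counted separately
— silently awarding them would bias the counts. Methods are compared
pairwise with the Wilcoxon signed-rank test: zero differences dropped
(classic convention), mid-ranks for ties, exact p-values by enumerating all
2ⁿ sign assignments via a generating-polynomial convolution over doubled
mid-ranks (n ≤ 25), otherwise a normal approximation with tie-corrected
variance and continuity correction; two-sided p doubles the smaller tail,
capped at 1. The family of m pairwise comparisons is Bonferroni-controlled
at α/m (0.05/3 ≈ 0.0167 for three methods). Tumours are treated as
independent even when several share a case — the clinical analysis this
mirrors does the same, and the caveat carries over.

## Numerical and degenerate-input choices

- Identical seeds give bit-identical outputs end to end; every stochastic
  component draws from its own stream spawned from the case seed.
- Masks are resampled with linear interpolation thresholded at 0.5;
  whole-voxel translations are exact.
- B-spline evaluation outside the lattice's valid support returns zero
  displacement (rigid-only extrapolation, with a warning from
  `transform_point`).
- An all-zero paired difference vector gives p = 1 with a warning; a single
  TRE record reports its value with the sd absent.
- De-enhancing an image with nothing above threshold returns it bit-identical.
- Default problem sizes (96³ voxels, 20-case suites, 3 tumours/case ≈ 60
  tumours) keep a full study at roughly 20–25 s per case on one CPU while
  leaving tumours ≥ 3 voxels across.

## Known limitations

- The Demons/VUCT-to-VUCT route assumes the de-enhancement leaves
  comparable intensities on both sides; strongly different enhancement
  phases would stress it.
- No bending-energy diagnostics are enforced at optimisation time; extreme
  true deformations (amplitude ≫ control spacing) could fold.
- The observer model is Gaussian and unbiased by default; real experts show
  structured, anatomy-dependent errors.
- Winner percentages and TRE summaries are reported to 1 decimal; exact TRE
  ties, essentially impossible with continuous noise, are surfaced rather
  than resolved.
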