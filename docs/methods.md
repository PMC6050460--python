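# Methods

## Forward model and corrections

The observed PET image is modelled as the true activity convolved with a
separable Gaussian point-spread function (PSF), `O = T ⊗ h`, with per-axis
FWHM in mm (default 6 mm isotropic, a typical measured brain-PET
reconstruction resolution). The discrete kernel samples the Gaussian at
integer voxel offsets, truncates at ±4σ (truncation error < 1e-4 of kernel
mass; minimum half-width one voxel) and renormalises to unit sum, so
smoothed binary masks stay in [0, 1]. Convolution zero-pads outside the
grid — the physical statement that there is no activity outside the field
of view; all divisions happen inside tissue where the smoothed-mask
thresholds bound the padding influence. A zero FWHM axis is the exact
identity, which makes "delta-PSF ⇒ every correction is the identity" a
machine-checkable contract rather than an approximation.

The three corrections and their assumptions:

* **Meltzer** divides by the smoothed whole-brain tissue mask. Assumes
  activity homogeneity is not needed — it only undoes spill-out across the
  brain/CSF boundary — so it under-corrects within-brain heterogeneity by
  construction.
* **mMG** subtracts an estimated WM contribution and divides by the
  smoothed GM mask. Assumes one representative WM activity and zero CSF
  activity. The WM estimate defaults to a two-region GTM on {GM, WM}
  (`wm_mode="gtm2"`); an eroded-WM mean (`wm_mode="erosion"`, erosion depth
  one FWHM, falling back to gtm2 if erosion empties the mask) is available
  because the "modified" Müller-Gärtner lineage replaces manual WM sampling
  with a model-based estimate and the exact variant differs between sites.
  Negative corrected voxels are retained as data (they carry the sign of
  over-subtraction), counted in the run log, and can be clamped to zero via
  a flag for sensitivity analysis.
* **GTM/RBV**: the transfer matrix Ω is assembled from region-averaged
  smoothed region masks and solved densely without a nonnegativity
  constraint (region counts are at most a few hundred; the default phantom
  has ~13). The condition number is recorded and warned about above 1e4.
  RBV rescales the observation by `s / (s ⊗ h)` with the piecewise-constant
  synthetic image `s`; voxels outside every region pass through unchanged
  with validity 0 so they can never contaminate downstream GM-restricted
  means.

Thresholds: τ = τ_GM = 0.1 on smoothed masks excludes voxels whose observed
signal would be ≥ 90 % spill-in, bounding division noise. Validity masks
propagate through sampling: regional means ignore invalid voxels rather
than zero-filling, and the voxel counts actually used are reported in every
SUVR record.

On noiseless piecewise-constant phantoms with a matched PSF, GTM and RBV
are *algebraically exact* (the observation is exactly `s ⊗ h`), and mMG is
exact wherever the GM activity is locally constant; the acceptance tests
exploit this to pin the implementations at 1e-6–1 % tolerances instead of
hand-waving.

## The phantom

An analytic ellipsoid brain on a 96³ grid of 2 mm voxels (world coordinates
centred; all geometry in mm via the affine):

* cerebral WM ellipsoid (semi-axes 56×66×48 mm) with nonspecific uptake 1.5;
* cortical GM ribbon of thickness d (default 4 mm) sitting directly on the
  WM surface — atrophy thins the ribbon, which retracts from the fixed
  outer envelope so CSF expands on the pial side while cortex stays
  attached to WM, as in real atrophy;
* radial gyral WM fingers through the lower 70 % of the ribbon at azimuthal
  period ~12 mm (below 2×FWHM), giving cortex the lateral WM exposure of
  folded anatomy — without them a smooth shell grossly understates WM
  spill-in and the low-binding regime cannot reproduce the known
  WM-contamination behaviour;
* the ribbon is split into 8 azimuthal sectors (within-GM anatomical
  boundaries for the GTM/RBV parcellation); one sector hosts the target
  pathology;
* a cerebellar reference: 6 mm effective GM sheet over a small
  arbor-vitae-scale WM core (16×19×11 mm). The reference is deliberately
  *less* PVE- and WM-affected than target cortex (thicker sheet, small WM
  neighbour) but not immune — the field's empirical reason for using
  cerebellar GM as reference;
* an autopsy-style target VOI: a wedge of the target sector spanning
  cortex plus underlying WM (like a tissue block), later intersected with
  the GM mask before sampling, and inserted into the parcellation by
  splitting every region it intersects into in/out sub-regions.

CSF carries zero activity everywhere. Tissue masks are the generating
truth: segmentation error is out of scope by design.

## The simulated cohort

Each subject draws a latent pathology load L ~ Uniform(0.25, 14), chosen to
span percent-area ranges typical of autopsy series. From L follow:

* target-sector GM activity a(L) = 1.0 + 0.12 L (so ~1.0 in amyloid-free
  subjects up to ~2.7 at the highest load, bracketing the nonspecific WM
  level 1.5 — the crossover that makes correction direction
  subject-dependent);
* cortical thickness d(L) = 4 − 0.15 L mm, floored at 2 mm (load-coupled
  atrophy, the CSF-bordering-thinning confound);
* two histology percent-area measures H6 = 0.75 L + ε and H4 = 1.0 L + ε,
  ε ~ N(0, 0.8²), floored at 0.01 % (two stains of the same pathology with
  independent measurement error);
* scan noise: i.i.d. Gaussian with sd = 0.03 × whole-brain mean added
  after blurring.

Non-target cortex keeps a mild nonspecific GM level (1.4); the
normal-control preset (`CohortSpec.nc_like` + `nc_like_phantom`) sets all
cortex to 1.0 with loads in [0.25, 2], since controls are amyloid-free
everywhere, not only in the target region.

All randomness flows from one seeded generator in a fixed order — loads
first, then per-subject scan-noise fields, then the two histology error
vectors — and zero-variance stages draw nothing, so partial configurations
cannot silently shift later draws. Identical config + seed reproduces every
CSV byte-identically (the file-based stages parse CSVs with round-trip
float precision for the same reason).

Subject weight/dose metadata are deterministic mild variations (65 + 2i kg,
480 + 15i kBq); SUV scaling is exercised end-to-end but SUVR is invariant
to it, by design of the ratio.

## What the generator does and does not emulate

It emulates: resolution-induced spill-in/spill-out with the correct
adjacency structure (GM on WM, CSF outside, sub-FWHM folding), a reference
region that is less but not un-affected, atrophy correlated with disease
severity, and paired noisy pathology measures driven by the same latent
cause as the imaging signal.

It does not emulate: realistic cortical topology (an atlas-based phantom
would need external data), count-statistics (Poisson/sinogram) noise,
segmentation or registration error (masks are truth by construction),
PET-to-MR misalignment, or scanner-specific non-Gaussian PSFs. A practical
consequence: on the phantom the corrections can only help the
imaging-pathology correlation (they remove a modelled bias and their inputs
are exact), so the pipeline reproduces the qualitative finding that all
methods remain strongly significantly correlated with pathology, but not
the subtler real-data observation that correction can *minimally lower*
correlations — that effect lives in the noise sources listed above.
Passing tests therefore certify the algorithms and the pipeline, not
real-data performance.

## Numerical and design choices

* Frame averaging includes only frames fully inside the requested window
  (frames are indivisible acquisitions; no fractional weighting). The SUV
  window is a parameter, not a constant, because acquisition protocols
  differ across subjects.
* Masks and images must share an identical grid; there is no implicit
  resampling — mismatches raise.
* One global PSF serves simulation and correction by default;
  `correction.fwhm_mm` can override it to study model mismatch.
* The cerebellar reference for mMG is sampled from the corrected image's
  valid GM voxels — "equivalently corrected" numerator and denominator by
  construction.
* Percent change is reported both as the mean of per-subject percent
  changes and as the percent change of mean SUVRs; the two differ and
  published summaries are often ambiguous between them, so both are
  emitted and the per-subject mean is treated as primary.
* Significance uses a fixed two-sided α = 0.01 with no multiple-testing
  correction (matching the analysis convention being emulated); the report
  metadata flags this.
* Problem sizes: single-phantom checks run at the default 96³/2 mm grid;
  the 50-seed correlation sweep in the acceptance tests uses the same mm
  geometry on a 64³/3 mm grid, which leaves all mechanisms intact while
  keeping the sweep a few minutes long on one CPU.

## Known limitations

The ellipsoid-sector anatomy makes region conditioning benign (GTM cond ~5
to 10); heavily interdigitated real parcellations can be far worse
conditioned, where the logged condition number and warning matter. The
erosion-based WM estimate degenerates on thin WM structures (it then falls
back to gtm2). The Meltzer implementation is the pure two-compartment
division; historical "modified Meltzer" variants with partial CSF terms are
out of scope. Histology noise is Gaussian and homoscedastic, which real
percent-area measurements are not.
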