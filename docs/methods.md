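# Methods

`thamar` quantifies how well different CT reconstructions suppress metal
artifacts around total hip arthroplasty (THA) implants, using a fully
synthetic phantom study so that every number in the analysis is
reproducible from a seed. This note describes the model behind the
simulator, the measurement and statistics conventions, the parameters that
matter, and what the synthetic study can and cannot say about real
scanner data.

## The phantom and the study design

The digital phantom mirrors a water-filled PMMA body of 320 × 290 mm
(10 mm shell, rounded corners) carrying 18 cylindrical bone-surrogate
pellets of 10 mm diameter, nine per side: two at the acetabular
(DeLee/Charnley) zones and seven around the femoral (Gruen) zones. The
published description gives zones but no millimetre coordinates, so the
packaged default layout (`thamar/data/pellet_layout.csv`, mirrored
left/right, configurable) places the pellets in those zones such that, at
the default artifact severity, one-sided implants produce only mild
artifacts while two-sided implants also produce severe ones — the
qualitative pattern the analysis is built to probe. Pellet nominal HU is
the no-prosthesis reference mean of each reconstruction family: 248.4 HU
on conventional 140 kVp images and 150.4 HU on 130 keV virtual
monochromatic images (VMI).

Prosthesis components are simplified 2-D cross-sections: a hemispherical
cup (half-annulus), a femoral head (disk, ⌀32 mm) and a femoral stem
(12 mm wide bar). The unilateral configuration uses a polyethylene cup
(UHMWPE), ceramic head (ZTA) and titanium stem (TiAlV); the bilateral
configuration adds a deliberately artifact-aggravating all-CoCrMo
cup/head on the left. Nominal HU: UHMWPE 80 (below the 2500 HU metal
threshold — polyethylene does not streak), TiAlV 8000, ZTA 10000,
CoCrMo 12000. Only the ordering matters for the artifact pattern.

The study crosses {none, unilateral, bilateral} × {conventional, 130 keV
VMI} × {MAR off, MAR on}: 12 coronal slices. MAR on/off and
conventional/VMI share one simulated acquisition per configuration
(dual-layer scanner), so MAR on/off are bit-identical when no metal is
present, and the VMI inherits the acquisition's noise rather than drawing
its own.

## The simulated CT chain

1. **Rasterization.** Materials are painted by signed distance with
   1-pixel antialiasing; water is exactly 0 HU, air −1000 HU. Default
   grid: FOV 330 mm on 512 × 512 (0.645 mm pixels), per the scanned
   protocol.
2. **Forward projection.** HU converts to linear attenuation via
   μ = μ_water·(1 + HU/1000) with μ_water = 0.0192 mm⁻¹, so air projects
   to exactly zero. Parallel-beam line integrals use the scikit-image
   Radon transform over 720 uniform angles in [0, π), with
   inscribed-circle padding whose parity keeps the image centre on the
   projector's rotation centre. Each ray also records its metal path
   length m (zeroed below a 0.5 mm trace threshold).
3. **Beam hardening.** Metal-crossing rays are depressed by
   β·min(m, m_cap)², the lowest-order polychromatic bias with a
   saturation cap m_cap = 45 mm: on a coronal slice the stem lies in
   plane, and an uncapped quadratic on a ~100 mm metal path would produce
   image-dominating artifacts that no polychromatic spectrum can deliver —
   once the low-energy half of the spectrum is exhausted, extra path
   hardens the beam no further. Default β = 3·10⁻³ mm⁻².
4. **Photon starvation.** Detector counts are Poisson with mean
   i0·e^(−p) and re-logged with a continuity correction,
   p̂ = −log((N + ½)/i0), which is nearly unbiased at moderate counts
   and saturates at log(2·i0) for fully starved rays. Default
   i0 = 3.3·10⁷ reproduces the 6.9 HU no-prosthesis pellet noise of the
   conventional reference images at the full 512/720 scale. Rays whose
   expected counts exceed 10⁸ are passed through deterministically.
5. **FBP.** Ramp-filtered back projection (scikit-image `iradon`) back to
   HU.
6. **MAR emulation.** The vendor's orthopedic MAR algorithm is a black
   box; it is emulated as normalized sinogram inpainting: bins with more
   than 16 mm of metal path are replaced by 1-D linear interpolation —
   computed in a prior-normalized domain and anchored on metal-free bins —
   after which the implant's own clean projection is reinserted. The
   prior is the no-prosthesis projection of the same phantom, standing in
   for the tissue-class prior a vendor implementation builds internally;
   the reinserted metal estimate is likewise the simulator's exact one.
   Rays with less metal keep their mild beam-hardening bias, so the
   correction is strong but imperfect, as residual streaks survive real
   MAR. The operation is idempotent and leaves metal-free sinograms
   untouched.
7. **VMI emulation.** The 130 keV VMI of an acquisition is derived from
   the same detected quanta as its conventional reconstruction, so the
   conventional chain's noise-and-saturation residual transfers (scaled
   by the 8.0/6.9 reference-noise ratio) instead of being redrawn, and is
   amplified 3× on starved rays (< 50 expected counts), emulating the
   ill-conditioning of spectral decomposition where almost nothing
   reaches the detector. The VMI's own raster scales metal HU by 0.45 —
   the attenuation drop at high virtual energy that is the mechanism of
   VMI artifact reduction — and its beam hardening is 0.1·β. A
   bright-streak term γ·m (γ = 0.02) is added on every ~16th metal-trace
   view, reproducing the positive streaks high-keV VMI introduces near
   implants.

**Severity parameters** (one `Severity` object): β [mm⁻²] beam-hardening
strength; i0 [counts] incident flux; γ bright-streak amplitude;
m_cap [mm] hardening saturation. All stochastic draws flow from one
`numpy` SeedSequence; the documented order is one child generator per
prosthesis configuration (none, unilateral, bilateral), consumed by that
configuration's conventional acquisition.

**Injected severity classes.** Alongside the images, the generator labels
every pellet-instance with the class implied by the zero-variance limit of
the corruption model (full beam hardening plus the deterministic
starvation saturation, no Poisson draw). Category-recovery tests compare
measured classes against these labels; disagreements can arise only from
noise at class borders.

## Measurement and categorization

Circular ROIs of 6.75 mm diameter are placed at every pellet centre plus
one background ROI in artifact-free water below the stems. The physical
6.75 mm is kept rather than the 15-pixel operational equivalent because at
0.645 mm pixels a 15-pixel ROI would be 9.7 mm — as large as the pellet
itself — defeating the purpose of limiting partial-volume effects. Pixel
membership is centre-in-circle (strict); an ROI must cover at least 9
pixels. Noise is the population SD within the ROI (the n−1 estimator is
available; the difference is < 1% at ≥ 100 pixels), SNR = mean/noise, and
CNR = (pellet − background) / mean(pellet noise, background noise). CNR
is signed: under severe artifacts a pellet can fall below water, and the
sign carries that information. Zero-noise ROIs yield NaN ratios, never
infinities.

Each pellet-instance (pellet × prosthesis configuration) is categorized
from its mean HU on the conventional no-MAR image: < 0 HU severe,
0–235 HU mild, ≥ 235 HU unaffected. Exactly 0 HU goes to mild (the
boundary has measure zero but the function must be total). The 235 HU
constant is the published operating cutoff; `derive_cutoff`
(mean − k·SD, floored to a 5 HU step) rebuilds a cutoff for phantoms with
other pellet densities but does not replace the default.

## Artifact quantification and statistics

For metric V ∈ {mean HU, CNR, SNR, noise} of one pellet-instance,

    dV = | 1 − V_with_prostheses / V_no_prostheses |

with V_no_prostheses the all-pellet reference mean of the matching
reconstruction family (conventional 248.4/37.3/36.5/6.9;
VMI 150.4/18.0/19.3/8.0) — normalization makes the families comparable
despite their different HU scales, and the nonzero noise reference keeps
dV defined for noise. Two reconstructions are compared per category by

    relative MAR (%) = (1 − dV_reconstruction / dV_standard) · 100,

negative values meaning aggravation. Category cells use the ratio of
category-mean dV (robust to near-zero per-pellet standards); a
mean-of-per-pellet-ratios mode exists behind a flag. Each cell carries a
two-sided paired Wilcoxon signed-rank p over the per-pellet dV pairs.

The signed-rank test conditions on the observed |differences|: each of
the 2ⁿ sign assignments is equally likely under the null, and the exact
distribution of W is built by subset-sum convolution over the midranks
(equivalent to enumeration, polynomial time). Zeros are dropped
(Wilcoxon's rule; Pratt's available), ties get midranks, and above n = 20
a tie-corrected normal approximation with continuity correction takes
over. All study cells have n ≤ 18, so the exact path is the one used.

## Numerical choices and degenerate inputs

* The rotation-interpolation projector has ~1–2% angular anisotropy
  concentrated at sharp edges; round-trip pellet means are accurate to
  well under 5%.
* A metal trace covering an entire detector row is inpainted with the
  prior and flagged with a warning.
* Undefined values (zero reference, zero standard-artifact, zero noise)
  are NaN plus a warning, and the affected pellet is excluded from the
  cell with its exclusion logged; an all-zero difference vector yields a
  degenerate test result (p = 1), not an exception.
* CSVs are written with a fixed float format and the analysis tables are
  rebuilt from the exported CSV, so a simulate run and a re-analysis of
  its own export are byte-identical.

## Problem sizes

The default `PhantomSpec` is the full acquisition geometry (512 matrix,
720 views); `scripts/acceptance.py` runs the complete study at this
scale. The test suite and the numbered analysis scripts run the same
study at 256/360 — the qualitative pattern (severe pellets only
bilateral, strict MAR improvement, VMI bright streaks, ≥ 90% category
recovery across a 3×3 severity grid) holds at both scales — and a few
pipeline tests use 192/180 where only determinism is at stake.

## Limitations

The simulator emulates the *phenomenology* of polychromatic CT around
metal, not its physics: no scatter, no spectral detector model, 2-D
parallel-beam rather than 3-D helical fan-beam, simplified implant
cross-sections, and MAR/VMI emulations that borrow the simulator's own
ground truth as the prior a vendor algorithm must estimate. Passing tests
therefore demonstrate that the measurement, categorization, normalization
and statistics machinery behaves correctly on images with
realistic-looking artifacts — not that the simulator predicts any
particular scanner's artifact magnitudes. One known divergence from
scanner behaviour: in this model the 130 keV VMI without MAR does not
aggravate severely affected pellets relative to conventional imaging with
MAR, because the emulated metal-attenuation drop cleans severe zones more
than a real dual-layer spectral chain does; the real aggravation
mechanism (spectral noise blow-up near total starvation) is only partially
captured by the starved-ray amplification term. Soft tissue is absent by
design: the phantom assesses bone-surrogate pellets only.
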