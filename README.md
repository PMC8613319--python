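# thamar — quantitative metal artifact reduction for THA CT phantoms

CT of patients with total hip arthroplasty (THA) is degraded by metal
artifacts: beam hardening and photon starvation throw dark and bright
streaks across the bone and soft tissue a radiologist needs to read. Two
countermeasures are standard on modern scanners — projection-domain metal
artifact reduction (MAR) software and high-energy virtual monochromatic
images (VMI) from dual-energy acquisitions — and the practical question is
how much each, alone or combined, actually helps.

`thamar` implements a quantitative phantom analysis of that question as a
tested, reproducible pipeline. A synthetic water/PMMA hip phantom with 18
bone-density pellets and configurable prostheses is pushed through a
simulated CT chain (forward projection → beam hardening + photon
starvation → filtered back projection, with a MAR emulation by normalized
sinogram inpainting and a 130 keV VMI emulation sharing the acquisition's
detected quanta). Image quality is measured with a standardized ROI
template, pellets are categorized by artifact severity, and reconstructions
are compared with the normalized artifact metric

    dV = | 1 − V_with_prostheses / V_no_prostheses |

(V ∈ {mean HU, CNR, SNR, noise}, normalized by the no-prosthesis reference
of each reconstruction family) and the relative metal artifact reduction

    relative MAR (%) = (1 − dV_reconstruction / dV_standard) · 100,

with an exact paired Wilcoxon signed-rank p for every table cell. It is
intended for medical-physics users who want artifact-reduction metrics with
an auditable, seeded simulation behind them — and for re-analysis of real
per-pellet ROI measurements through the same machinery.

## Worked example

```python
from thamar import generate_study, measure_study, build_tables
from thamar.phantom import PhantomSpec
from thamar.categorize import tabulate_categories

spec = PhantomSpec(matrix_size=256, n_angles=360)   # reduced-scale study
study = generate_study(seed=1, spec=spec)            # 12 condition images
meas = measure_study(study)                          # ROI stats + categories

inst = meas[(meas.label != "BG") & (meas.config != "none")
            & (meas.recon_key == "conventional")]
print(tabulate_categories(inst[["config", "label", "category"]]))
```

prints the pellet severity split on the uncorrected conventional images:

```
            unaffected  mild  severe
config
bilateral            4     9       5
unilateral          14     4       0
```

Severely affected pellets (mean CT value below water) occur only with
bilateral implants, where photon starvation between the two prostheses
dominates. `build_tables(meas)` then yields both relative-MAR tables; at
this seed the conventional+MAR row reduces the mild-pellet HU artifact by
79% (p = 0.001) and VMI+MAR by 91% (p < 0.001) relative to uncorrected
conventional imaging, and VMI with MAR is the strongest reconstruction
overall — while VMI *without* MAR shows no statistically significant HU
improvement on severe artifacts over conventional+MAR (p = 0.3).

The same steps are packaged as a CLI (`thamar simulate / measure /
reanalyze / report`) and as numbered drivers under `analysis/` that write
their tables and figures to `results/`. `thamar reanalyze` accepts any
long-format per-pellet CSV (`config, reconstruction, omar, label, mean_hu,
noise_hu, snr, cnr`), so measurements exported from real DICOM series can
be run through the identical categorization, metric and statistics code.

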