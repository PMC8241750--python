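# crmoco

**Cardiorespiratory motion compensation for simultaneous [18F]NaF PET/MR
coronary plaque imaging — a desk-scale, fully testable re-implementation.**

Focal [18F]NaF uptake marks micro-calcifications in vulnerable coronary
plaques, but the hotspots are millimetres across and ride on both
respiration (~15 mm) and the heartbeat.  Motion blurs the uptake and —
because the coronaries sit right next to the lungs — misaligns the
attenuation-correction (AC) map with the emission data, producing the
"banana" artefact at the lung–soft-tissue boundary.  The remedy studied
here is MR-based motion-corrected image reconstruction (MCIR): bin
simultaneously acquired multi-echo Dixon MR k-space into respiratory and
cardiac states using belt/ECG surrogates, reconstruct motion-resolved
water/fat images, estimate non-rigid motion models by registration with
the dual-channel cost

    C(m_t) = w·S(I_W ∘ m_t, I_W,ref) + (1−w)·S(I_F ∘ m_t, I_F,ref) + r·R(m_t)

(S = normalised mutual information, R = bending energy, w = 0.5),
derive a 4-tissue AC map (k-means on |W|,|F|; stent signal voids
inpainted morphologically), and reconstruct PET with OSEM (21 subsets,
3 iterations, 4 mm Gaussian post-filter) in which every motion bin's
data is compared against the motion-transformed image estimate and
motion-transformed μ-map.  Hotspots are quantified by the
target-to-background ratio `TBR = s/b`, contrast-to-background ratio
`CBR = |s−b|/σ(b)` (blood-pool background) and the width
`D = 2√(2 ln 2)·c` of a constrained Gaussian-plus-linear profile fit.

Because no clinical raw data of this kind is public, the package ships a
**dynamic 2D thorax phantom** with analytic (hence exactly known)
respiratory and cardiac deformations, physiological surrogate traces, a
multi-echo golden-angle radial MR simulator and a binned PET emission
simulator — so every stage, from the k-space signal model to the
Wilcoxon test, is validated against independent oracles.  It is aimed at
researchers who want a transparent, dependency-light sandbox for
motion-compensated PET/MR reconstruction methods.

## Worked example

```bash
crmoco run-all --seed 0 --outdir run --grid 64 --pixel 2.0
crmoco report --outdir run
```

which executes the full chain (phantom → MR simulation → binning →
water/fat reconstruction → respiratory and cardiac motion models →
AC map → PET simulation → AVG and cr-MCIR OSEM → quantification) and
prints the study-table row, e.g.:

```
 plaque  TBR_stat  TBR_dual  TBR_ratio  CBR_stat  CBR_dual  CBR_ratio  FWHM_stat  FWHM_dual  FWHM_ratio
      1  0.649514  0.931311         43  4.434828  0.838217        -81  10.934874   4.202823         -62
```

Read: on the motion-averaged image (`_stat`) the plaque measures
TBR 0.65 — the smeared hotspot sits below the blood-pool background —
and its fitted width is ~11 mm, mostly respiratory blur.  The
cardiorespiratory MCIR image (`_dual`) lifts TBR to 0.93 (+43%) and
shrinks the width to 4.2 mm (−62%): the motion model re-concentrates
the counts that respiration and the heartbeat had spread out.  CBR is
the noisiest of the three metrics at these count levels (here it drops,
because deblurring also lowers the |s−b| contrast term faster than the
blood-pool noise σ(b) in this particular realisation).  The same
library calls are available programmatically via
`crmoco.pipeline.run_full(RunConfig(...))`, and
`crmoco.metrics.summarize` reproduces clinical-style summary tables
(means, sample SDs, exact Wilcoxon signed-rank p-values).

## Layout

| module | role |
| --- | --- |
| `crmoco.phantom` | dynamic thorax phantom, analytic motion, surrogates |
| `crmoco.mr_sim` | golden-angle radial multi-echo Dixon k-space |
| `crmoco.mr_recon` | surrogate binning + CGLS water/fat reconstruction |
| `crmoco.motion_model` | dual-channel B-spline registration, model assembly, belt alignment |
| `crmoco.atten` | 4-tissue μ-map: k-means, stent inpainting, warping |
| `crmoco.pet_sim` | parallel-beam projector, attenuation, binned Poisson emission |
| `crmoco.pet_recon` | AVG and cr-MCIR OSEM, post-filter, SUV |
| `crmoco.metrics` | TBR/CBR/width, study table, exact Wilcoxon |
| `crmoco.pipeline` | end-to-end orchestration, manifests; `crmoco.cli` |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
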