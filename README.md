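# psmagtv

Benchmarking manual and semi-automatic gross-tumour-volume (GTV)
segmentation on PSMA-PET against a histopathology reference.

## The problem

Focal-boost radiotherapy of prostate cancer escalates dose to the dominant
intraprostatic lesion, so the accuracy of the GTV drawn on [68Ga]-PSMA-PET
directly affects both tumour control and toxicity. Delineations can be made
manually (with substantial interobserver variability) or semi-automatically
by thresholding the standardized-uptake-value (SUV) image. Validating either
requires a voxel-level ground truth, which only whole-mount histopathology
registered to the in-vivo PET grid can provide — and such patient data is
rarely shareable.

`psmagtv` implements the full comparison pipeline as a tested, reusable
library with a synthetic-phantom front end, so every stage can be exercised,
validated and extended without patient data:

* **Phantom generator** — SUV volumes on a 2.34 × 2.34 × 2.78 mm PET grid
  with a prostate, an adjacent hot bladder, intraprostatic lesions with a
  Gleason-3-style rim, Gaussian point-spread blurring and signal-dependent
  noise; plus simulated manual observers with controllable per-voxel
  sensitivity/specificity.
* **Pre-processing** — trim the PET volume to the prostate with a 2-voxel
  margin and remove the bladder (zeroing its uptake so no operator can see
  it).
* **Segmentation operators** — absolute SUV thresholds (SUV > 2 … 4.5),
  relative thresholds (20–50 % of SUVmax), adaptive local-mean thresholding
  with sensitivity S, and multi-level Otsu (2 or 3 thresholds, top class =
  GTV). Threshold methods keep the connected component containing the
  SUVmax voxel.
* **STAPLE consensus** — binary expectation-maximization fusion of the
  manual observers into a consensus GTV, with per-rater sensitivity p and
  specificity q estimates, plus pooled pairwise interobserver Dice.
* **Metrics** — Dice similarity coefficient (DSC), 95th-percentile Hausdorff
  distance (HD95, mm), lesion coverage ratio, volumetric false discovery
  rate (FDR) and GTV/reference volume ratio — all *exclusion-aware*:
  Gleason-3 voxels are treated as neither positive nor negative.
* **Reporting** — per-method median (IQR) table with a two-sided Wilcoxon
  signed-rank comparison of GTV volumes against the reference volumes.

## Core definitions

With prediction P, reference positive mask T, and exclusion mask E
(P′ = P \ E):

* DSC = 2|P′ ∩ T| / (|P′| + |T|)
* coverage = |P ∩ T| / |T|
* FDR = |P′ \ T| / |P′|
* volume ratio = vol(P) / vol(T)
* HD95 = max of the two directed 95th percentiles of Euclidean
  boundary-to-boundary voxel-centre distances (anisotropic spacing).

STAPLE estimates the latent true segmentation and rater performance
(p_j, q_j) by EM; the posterior foreground weight of voxel i is

W_i = γ·∏_j a_ij / (γ·∏_j a_ij + (1 − γ)·∏_j b_ij),
a_ij = p_j^{D_ij}(1 − p_j)^{1−D_ij}, b_ij = (1 − q_j)^{D_ij} q_j^{1−D_ij},

with fixed prior γ; the consensus is W ≥ 0.5.

## Worked example

```python
from psmagtv import *

spec = PhantomSpec(seed=7)
suv, prostate, bladder, ref = generate_phantom(spec)
region = remove_bladder(crop_to_prostate(suv, prostate, 2), bladder)

res = absolute_threshold(region, 4.0)
rec = evaluate_case(embed_mask(region, res.gtv), ref, "case000", res.method_label)
print(rec.dsc, rec.hd95_mm, rec.coverage, rec.fdr, rec.volume_ratio)

obs = simulate_observers(ref.positive, prostate, ObserverModel(seed=7))
fusion = staple(obs)
print(interobserver_dsc(obs), fusion.p_hat, fusion.q_hat)
```

prints (for this seed):

```
SUV > 4: DSC=0.995 HD95=3.31 mm coverage=0.991 FDR=0.000 volume ratio=1.81
interobserver DSC=0.706; STAPLE p_hat=[0.845 0.836 0.791 0.855], q_hat=[0.999 0.999 0.999 0.999]
```

i.e. on this phantom the SUV > 4 cut recovers essentially the whole lesion
(coverage 0.99) while still over-segmenting its volume by ~80 % — the blur
spreads lesion activity beyond the histological boundary — and STAPLE
correctly estimates the observers' ~0.85 sensitivity. The same pipeline over
many cases is one command:

```sh
psmagtv run-study --n-cases 20 --seed 1234 --no-volumes --out-dir out/
```

which writes `metrics.csv` (one row per case × method), `summary.csv` /
`summary.md` (the 14-row median/IQR table: Manual, six absolute cuts, four
relative cuts, Adaptive, Otsu2, Otsu3, with Wilcoxon stars) and a manifest
with every derived seed. `psmagtv simulate / preprocess / segment / staple /
evaluate / report` expose each stage separately on NIfTI files.

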