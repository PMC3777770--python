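# mslseg

Automated tissue and lesion segmentation of multichannel 3D MR brain images
in multiple sclerosis (MS).

White-matter lesions appear hyperintense on T2-weighted and FLAIR images and
hypointense on T1; quantifying their volume is central to MS research, but
manual delineation of diffuse 3D lesions is slow and unreliable. `mslseg`
implements a fully automated pipeline that combines a non-parametric and a
parametric classifier with anatomical priors:

1. **Preprocessing** — edge-preserving Perona–Malik diffusion, histogram-
   threshold brain extraction from the fat-sat T2, and decile-based
   piecewise-linear intensity standardization (Nyúl–Udupa), so one trained
   feature map serves every scan.
2. **Parzen-window classification** — a 2D Gaussian-kernel density feature
   map on (T2, FLAIR) separates parenchyma / CSF / lesions; a second map on
   (T1, T2) provides GM / WM / CSF seeds. For class *k* with training
   points *t<sub>i</sub>*,

   p̂ₖ(x) = (1/nₖ) Σᵢ (2π hₓ h_y)⁻¹ exp(−‖(x−tᵢ)/h‖²/2)

   and each voxel takes the class of maximal density in its intensity bin.
3. **EM-HMRF tissue segmentation** — multivariate Gaussian classes with a
   hidden Markov random field (Potts) prior over the 6-neighbourhood,
   per-voxel energy

   U(xᵢ=k) = −log πₖ + ½ log|Σₖ| + ½ (yᵢ−μₖ)ᵀ Σₖ⁻¹ (yᵢ−μₖ) + β·#{j∼i : xⱼ≠k},

   minimized by ICM inside an EM loop with log-domain polynomial bias-field
   correction. The cerebellum is segmented separately (its GM/WM contrast
   differs from the cerebrum).
4. **False-positive minimization** — atlas-driven rules: lesions inside the
   cortical-GM mask become GM, lesions within 2 voxels of the brain surface
   become GM, lesion components of ≤ 3 voxels are removed, lesions inside
   the dilated lateral-ventricle mask (choroid plexus) become CSF, and WM
   inside the deep-GM mask becomes GM.
5. **Fuzzy-connectedness delineation** — lesions grow to voxels whose
   max-min path strength from the lesion seeds exceeds θ, with affinity
   κ(c,d) = w₁ exp(−((f(c)+f(d))/2−m)²/2s²) + w₂ exp(−(|f(c)−f(d)|−m_g)²/2s_g²).
6. **Evaluation** — absolute volume difference %, average symmetric surface
   distance (mm), voxel- and lesion-level TPR/FPR, Bland–Altman limits of
   agreement and Pearson correlation.

A deterministic synthetic phantom (nested-ellipsoid brain with ventricles,
cortical ribbon, deep-GM blobs, cerebellum, WM lesions, choroid-plexus
decoys, bias field and noise) exercises every stage with exact ground truth.

## Worked example

```python
from mslseg import PhantomSpec, generate_phantom
from mslseg.pipeline import run_phantom_pipeline

phantom = generate_phantom(PhantomSpec(seed=1))
result = run_phantom_pipeline(phantom)
for name, m in result.stage_metrics:
    print(f"{name:8s} {m.dice:6.3f} {m.vol_diff:10.2f} "
          f"{m.avg_dist:11.3f} {m.tpr:6.1f} {m.fpr:6.1f}")
```

prints the lesion metrics (Dice, volume difference %, average surface
distance, component-level TPR/FPR) after each cascade stage:

```
input     0.914      18.51       1.727  100.0   92.1
cgm       0.951      10.01       0.988  100.0   80.0
rim       0.951      10.01       0.988  100.0   80.0
small     0.959       8.29       0.781  100.0   45.5
fuzzy     0.950      10.22       0.941  100.0   40.0
lvc       0.968       6.28       0.753  100.0   14.3
dgm       0.968       6.28       0.753  100.0   14.3
```

The Parzen first pass finds every lesion (TPR 100%) but also many false
positives (FPR 92%: hyperintense cortical voxels and the choroid-plexus
decoys). The cortical-GM rule, the small-component rule and the
ventricular-CSF rule remove them step by step; the final lesion mask
reaches Dice 0.97 against the phantom's ground truth with all six true
lesions detected.

The same flow is available from the shell:

```bash
mslseg phantom --seed 1 --out-dir data/
mslseg run --config config.yaml        # paths + parameters, YAML
mslseg evaluate --seg out/final_labels.nii.gz --ref data/truth.nii.gz
```

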