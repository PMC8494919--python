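# livereit

Non-invasive detection of hepatic steatosis (fatty liver) is a standing
clinical problem: biopsy is risky, and MRI proton-density fat fraction
(PDFF) — the non-invasive reference standard — is costly. Electrical
impedance tomography (EIT) offers a portable alternative: fat-infiltrated
liver tissue is less conductive than lean tissue, so the absolute liver
conductivity reconstructed from boundary-voltage measurements should fall
as liver fat rises.

`livereit` is a tested, end-to-end implementation of that analysis for
researchers studying bio-impedance imaging of the liver. It provides

- **parametric 2-D abdomen phantoms** (elliptical cross-section, labelled
  liver / fat / spine polygons, a 32-electrode belt) triangulated into
  finite-element meshes that carry the anatomical prior;
- a **FEM forward model** of the conductivity equation ∇·(−σ∇V) = 0 with
  both point and complete electrode models and skip-*s* pairwise
  stimulation ("skip 4" with 32 electrodes being the canonical belt
  protocol);
- an **absolute-conductivity inverse solver**: iterated Gauss–Newton with
  Tikhonov regularization,

  σₙ₊₁ = σₙ + (JᵀJ + λΓᵀΓ)⁻¹ Jᵀ (V₀ − f(σₙ)),

  where J is the adjoint-method Jacobian and Γ an anatomically weighted
  graph Laplacian that smooths within organs but lets conductivity jump at
  organ boundaries;
- a **synthetic cohort generator** emulating an overweight study
  population with a monotone-decreasing liver-conductivity-vs-PDFF law
  plus measurement noise; and
- the **cohort correlation analysis**: Pearson r, two-sided p-values, 95 %
  confidence intervals of the linear slope, and Bonferroni correction, on
  either synthetic cohorts or the packaged per-subject tables of a
  19-subject pilot cohort (BMI, age, waist, height, weight, injection
  current, liver EIT conductivity, MRI PDFF).

## Worked example

Reconstruct the reference abdomen phantom (background 0.45 S/m, liver
0.30 S/m, 32 electrodes, skip-4, 0.1 % additive noise) and estimate the
liver conductivity:

```python
from livereit import (
    reference_abdomen_phantom, build_phantom, phantom_conductivity,
    ConductivityField, make_skip_pattern, solve_forward, add_noise,
    NoiseModel, reconstruct, liver_conductivity,
)

spec = reference_abdomen_phantom(liver_conductivity=0.30)
mesh = build_phantom(spec, target_element_size=1.2)          # cm
truth = ConductivityField.from_values(mesh, phantom_conductivity(mesh, spec))
pattern = make_skip_pattern(n_electrodes=32, skip=4, current_ma=2.0)
data = add_noise(solve_forward(mesh, truth, pattern),
                 NoiseModel("additive_relative", 0.001), seed=42)
result = reconstruct(mesh, data)
mean, sd = liver_conductivity(result, mesh)
print(f"liver: {mean:.4f} ± {sd:.4f} S/m after {result.iterations} iterations")
```

This prints

```
liver: 0.3050 ± 0.0106 S/m after 12 iterations
```

— the reconstructed liver mean is within 2 % of the true 0.30 S/m and well
below the 0.45 S/m background, the separation that makes conductivity a
usable steatosis marker.

The same analysis on the packaged cohort tables, from the shell:

```bash
livereit stats --fixture --policy study_n16 --out out/stats
# EIT vs PDFF: r=-0.691 p=0.0030 n=16
```

i.e. with the three flagged subjects excluded (electrode malfunction,
renal failure, leukemia), liver conductivity is strongly inversely
correlated with MRI fat fraction, while no demographic variable survives
the Bonferroni-corrected threshold. `livereit simulate`, `livereit
reconstruct` and `livereit end-to-end` drive the physics stages from a
single JSON/YAML config; every output directory contains a manifest
(config + hash + seed) sufficient to re-run the stage bit-identically.

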