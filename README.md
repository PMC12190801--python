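# thoraxcomp

Opportunistic body-composition analysis for thoracic CT attenuation
maps, with the downstream survival modelling used to study its
prognostic value.

Low-dose CT scans acquired for PET attenuation correction contain
untapped information about skeletal muscle, bone and adipose tissue.
`thoraxcomp` implements the quantification chain for such scans:

1. **Compartmentalisation** — the body mask is extracted by
   thresholding at −500 HU (largest connected component, slice-wise
   hole filling), then split into an *intrathoracic* compartment (the
   slice-wise convex hull over the lungs, heart and epicardial fat,
   excluding bone-density voxels) and an *extrathoracic* remainder.
   Everything is restricted to the cranio-caudal slab spanned by
   vertebrae **T5–T11**; scans without full T5–T11 coverage are
   rejected.
2. **Tissue attribution** — closed Hounsfield-unit intervals define
   density classes: adipose −190…−30 HU, muscle −29…+150 HU, bone
   +151…+1200 HU. Intrathoracic adipose is **VAT** unless covered by
   the epicardial fat mask (**EAT**); extrathoracic muscle is **SM**,
   bone-density voxels are **bone**, and extrathoracic adipose is
   **SAT** when its connected component touches the skin, otherwise
   **IMAT**.
3. **Quantification** — per-tissue volume (cm³), volume indexed to
   body surface area (DuBois: BSA = 0.007184·W^0.425·H^0.725, giving
   cm³/m²), volume as a percentage of total thoracic volume, and mean
   density (HU) over the entire tissue volume.
4. **Risk analysis** — sex-specific abnormality cut-offs by maximising
   Youden's J = sensitivity + specificity − 1; Cox
   proportional-hazards models with per-SD hazard ratios (designated
   covariates log-transformed, coronary calcium entered categorically
   with 0 as reference); likelihood-ratio χ² = 2·ΔLL increments
   between nested models gated at P < .001; Kaplan–Meier
   stratification; a Fine–Gray subdistribution-hazard model for MI
   with death as the competing risk; and Schoenfeld-residual checks of
   proportionality.

Because clinical DICOM data cannot ship with the package, both inputs
are synthesised by first-class modules: a **thoracic phantom
generator** with exactly known per-tissue voxel counts and densities,
and a **cohort simulator** whose composition metrics have a configured
correlation structure and whose event times follow cause-specific
proportional-hazards models with known per-SD log-hazards.

## Worked example

```python
from thoraxcomp import (PhantomSpec, generate_phantom, run_segmentation,
                        summarize_composition, compute_bsa)

volume, masks, truth = generate_phantom(PhantomSpec())     # 160×160×120, 2.5×2.5×3 mm
seg = run_segmentation(volume, masks)
metrics = summarize_composition(seg.labels, volume, seg.compartments,
                                lungs_mask=masks.masks["lungs"],
                                bsa_m2=compute_bsa(175, 80))
for t in ("sm", "bone", "sat", "imat", "vat", "eat"):
    m = metrics.tissues[t]
    print(f"{t:>4}: {m.volume_cm3:9.3f} cm3  {m.indexed_volume_cm3_m2:8.3f} cm3/m2  "
          f"{m.mean_density_hu:7.1f} HU   (truth {truth.volumes_cm3[t]:.3f} cm3)")
```

prints

```
  sm:  3493.650 cm3  1786.065 cm3/m2     40.0 HU   (truth 3493.650 cm3)
bone:    71.400 cm3    36.502 cm3/m2    400.0 HU   (truth 71.400 cm3)
 sat:  2511.000 cm3  1283.703 cm3/m2   -100.0 HU   (truth 2511.000 cm3)
imat:    10.800 cm3     5.521 cm3/m2   -100.0 HU   (truth 10.800 cm3)
 vat:    10.688 cm3     5.464 cm3/m2   -100.0 HU   (truth 10.688 cm3)
 eat:   147.150 cm3    75.228 cm3/m2   -100.0 HU   (truth 147.150 cm3)
```

— on a noise-free phantom, every volume and mean density equals the
generator's ground truth exactly; under Gaussian HU noise (SD 15) the
per-tissue volume error stays ≈ 1%.

The same stages are available from the shell:

```
thoraxcomp phantom --seed 1 --out phantom/
thoraxcomp segment --volume phantom/phantom_ct.nii.gz --masks phantom/masks.json --out seg/
thoraxcomp cohort --n 10085 --seed 1 --out cohort/
thoraxcomp fit --cohort cohort/cohort.csv --model model.yaml --out fit/
thoraxcomp run-all --config run.yaml
```

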