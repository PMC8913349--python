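# voxatlas

Voxelised statistical atlas construction for prostate cancer.

Radiotherapy that boosts dose to tumour subvolumes needs to know, voxel
by voxel, how likely a tumour is at each location and how cell density
varies there across a population.  `voxatlas` builds that statistical
atlas from per-patient, histology-derived data — graded tumour
annotations and cell-density maps defined on sparse axial slices of
co-registered ex-vivo imaging — by:

1. **Slice interpolation** — histology exists every 5 mm on a 2.5 mm
   slice grid; contours are filled morphologically, cell density by
   neighbour averaging (then converted to volumetric units,
   c ↦ c^{3/2}), and graded lesions probabilistically (weight 0.5 on
   slices adjacent to an annotated lesion, capped at 1).
2. **Reference geometry** — per-patient glands are principal-moment
   aligned and the consensus ("half or more" coverage) defines the
   reference prostate; a similar consensus after registration defines
   the reference peripheral zone (PZ), plus a splined 1.5 mm-radius
   reference urethra.
3. **Distance-preserving registration** — an anisotropic similarity
   transform followed by log-domain symmetric-forces demons driven by
   *normalised distance maps*, so every interior shell of the patient
   gland maps to the equal-depth shell of the reference (not just the
   boundary); a second PZ stage runs with the deformation pinned to zero
   at the prostate border.
4. **Voxel statistics** — at each reference voxel x with n(x) sampled
   patients: tumour occurrence F(x) ~ B(n(x), p(x)) ≈
   N(np, np(1−p)) with CV = √((1−p)/(np)); cell density C(x) fitted by
   normal and log-normal models (1/n variance forms), compared by the
   Kullback–Leibler divergence D_KL(C_KDE ‖ C_model) in bits against a
   Scott's-rule Gaussian KDE of the empirical distribution.

No external data are needed: the `phantom` module generates synthetic
cohorts with the same structure (sparse annotation, missing apex/base,
log-normal density, posterolateral-PZ lesion preference) *and* exact
closed-form latent fields, so every stage is testable end to end.

## Worked example

```bash
python examples/04_statistical_atlas.py
```

builds a 60-patient phantom cohort and runs the full pipeline (about a
minute), printing:

```
reference prostate: 2880 voxels at 2.0 mm; PZ inside prostate: True
sampling frequency: max 60 of 60 patients (tapering to 0 at apex/base, where histology is missing)
tumour probability (well-sampled region): max 0.12 at n=60, CV there 0.345 (= sqrt((1-p)/(n p)))
log-normal density model: mu 10.56 log(cells/mm^3), mean CV 0.305
KL divergence (information lost, bits): normal 0.283 +- 0.174, lognormal 0.211 +- 0.173
-> the lognormal model loses less information on this lognormal-density cohort
```

Reading the numbers: the sampling frequency n(x) is complete mid-gland
and tapers toward the poles because histology misses the apex and base;
the tumour-probability map peaks in the posterolateral PZ (the phantom
seeds ~45% of lesions there); its CV shows how the per-voxel uncertainty
grows where p or n is small; and the per-voxel KL comparison prefers
the log-normal density model on a cohort whose densities are log-normal
— the direction reverses on a normal-density control cohort.

Other examples: `01_phantom_cohort.py` (cohort structure and latent
truth), `02_slice_interpolation.py` (the three interpolation rules),
`03_registration.py` (shell preservation vs a boundary-only control).

## Command line

The same pipeline is scriptable via thin subcommands:

```bash
voxatlas phantom   --n-patients 10 --seed 1 --output-dir run/
voxatlas slicefill --cohort-dir run/cohort --output-dir run/
voxatlas refgeom   --cohort-dir run/cohort --output-dir run/ref
voxatlas register  --cohort-dir run/cohort --output-dir run/reg
voxatlas atlas     --cohort-dir run/cohort --output-dir run/atlas
voxatlas evaluate  --cohort-dir run/cohort --output-dir run/eval
```

All stages accept `--config` (YAML overriding `PipelineConfig` defaults:
0.8 mm working resolution, consensus fraction 0.5, urethra radius
1.5 mm, density exponent 3/2, demons schedule), log their resolved
configuration and seed, and write volumes as NIfTI plus CSV summaries.

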