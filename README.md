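# hepatofat

Liver fat quantification and downstream multiomics statistics, end to end
on synthetic data.

Population studies of non-alcoholic fatty liver disease (NAFLD) phenotype
tens of thousands of participants by estimating the liver **proton-density
fat fraction (PDFF)** from single-slice multi-echo MR, then feed that
quantitative phenotype into statistical genetics and proteomics. The raw
cohort data behind such studies are access-controlled; this package
reimplements the bespoke computational core so that every step is
exercisable — and testable against known ground truth — on simulated
inputs:

* **Phantom and cohort simulation** — complex multi-echo slices from the
  voxelwise signal model
  `y_i = (ρ_w + ρ_f e^{−j2πΔf t_i}) e^{−j2πφ t_i} e^{−R2* t_i} + ε_i`,
  with configurable PDFF distribution, field map, R2* and noise; genotype
  cohorts under Hardy–Weinberg with planted additive and interaction
  effects; protein panels with planted case/control shifts.
* **Three-point Dixon** — variable-projection fit of three echoes of a
  10-echo GRE train (TE 2.38–23.82 ms), field frequency searched over the
  principal interval, R2* neglected.
* **IDEAL** — full four-parameter fit (ρ_w, ρ_f, φ, R2*) of the 6-echo
  acquisition (TE 1.2–11.2 ms) by alternating linear solves and damped
  Gauss–Newton, with multi-start protection against water–fat swaps.
* **ROI report** — eight 25-voxel ROIs placed deterministically in the
  liver mask; the reported PDFF is the mean of the lowest-s.d. ROI (which
  avoids water–fat-swapped regions); iron concentration from
  `0.202 + 0.0254·R2*` (mg/g).
* **Genetic statistics** — rank-based inverse-normal trait
  standardization, additive association, the three-group
  genotype–genotype interaction LRT (`β_g = b + γ·g_p`, 1 df),
  fixed-effects inverse-variance meta-analysis with Cochran's Q, tiered
  genome-wide significance thresholds, genetic risk scores, and
  IVW/Egger Mendelian randomization.
* **Proteomic staging** — per-analyte logistic association with
  Bonferroni control, Yeo–Johnson + train-fold scaling, shadow-feature
  (Boruta-style) selection, an elastic-net logistic classifier tuned by
  cross-validated average precision, and repeated stratified tenfold CV
  reporting mean ± s.e.m. ROC AUC against an enzymes-only baseline.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Run the whole synthetic pipeline (phantom → both fits → ROI reports →
cohort statistics) from Python:

```python
from hepatofat.pipeline import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(seed=5))
```

which prints (via `json.dumps(summary, indent=1)`):

```json
{
 "version": "0.1.0",
 "config_hash": "15b15c2257a9f342",
 "seed": 5,
 "phantom": {"true_mean_pdff_percent": 9.979192561976438},
 "dixon": {
  "reported_pdff_percent": 52.57982626700747,
  "selected_roi": 7,
  "iron_mg_per_g": null
 },
 "ideal": {
  "reported_pdff_percent": 9.880268974738684,
  "selected_roi": 6,
  "iron_mg_per_g": 1.2068770092719654
 },
 "cohort": {
  "assoc_beta": 0.11732430145793322,
  "assoc_p": 0.0008110894685010156,
  "interaction_gamma": -0.04673643241702288,
  "interaction_p": 0.40209720641452795,
  "meta_effect": 0.11753684521964736,
  "meta_se": 0.03498076349543582
 }
}
```

Reading the numbers: the phantom's true mean PDFF is ~10 %. The IDEAL
report recovers it (9.88 %) and converts the ROI's mean R2* (~40 1/s) to
an iron estimate of 1.21 mg/g via the fixed calibration. The default
phantom draws true R2* in 30–50 1/s, and the three-point Dixon fit —
which neglects R2* — is strongly biased there (52.6 %): that bias is a
documented property of the method at this echo selection, quantified in
the test suite, and disappears on R2* = 0 phantoms where Dixon and IDEAL
agree to within 1 % (slope ≈ 1.000 in the cross-protocol calibration).
On the cohort side, the planted per-allele effect (0.15 s.d. before
trait standardization) is detected (β̂ = 0.117, p = 8×10⁻⁴), the absent
genotype–genotype interaction is correctly not detected (p = 0.40), and
meta-analyzing the two half-cohorts reproduces the full-cohort estimate.

The same stages are available from the shell:

```bash
hepatofat simulate-phantom --out demo --seed 2 --shape 48x48 --protocol IDEAL
hepatofat fit-pdff --stem demo/echoes_ideal --method ideal --out demo/pdff.nii.gz
hepatofat report --pdff demo/pdff.nii.gz --mask demo/truth_mask.nii.gz
hepatofat run --seed 5            # full pipeline, JSON summary
```

plus `simulate-cohort`, `simulate-proteome`, `assoc`, `interaction`,
`meta`, `grs`, `mr` and `stage` subcommands (`hepatofat --help`).

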