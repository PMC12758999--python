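# csidose

Imaging-dose accounting and EUD/NTCP risk modelling for pediatric
craniospinal radiotherapy.

Children irradiated for medulloblastoma receive dose to normal organs from
three sources: the planning CT, repeated cone-beam CT (CBCT) positioning
scans, and the treatment itself. `csidose` is a library + CLI for medical
physicists and researchers who want to follow that exposure quantitatively
through the whole pathway:

* **OSL calibration** — convert optically-stimulated-luminescence dosimeter
  counts to absorbed dose per modality, with replicate statistics,
  correction factors, bleaching checks and uncertainty budgets
  (quadrature or Monte-Carlo).
* **Workflow accounting** — accumulate per-organ imaging dose
  (`D_CT + n·D_CBCT`, uncertainties in quadrature) and express it relative
  to the prescription.
* **Radiobiology** — reduce per-organ dose-volume histograms to Niemierko's
  equivalent uniform dose and a logistic complication probability, and
  compare delivery techniques (conformal vs arc therapy) as organ × technique
  matrices:

  ```
  EUD  = ( Σᵢ vᵢ Dᵢᵃ )^(1/a)
  NTCP = 1 / ( 1 + (D₅₀ / EUD)^(4γ₅₀) )
  ```

  `fit_ntcp_params` inverts the sigmoid from observed (EUD, NTCP) pairs —
  closed-form for two pairs, logit-scale least squares otherwise — so
  published complication figures can be checked for self-consistency even
  when the underlying (D₅₀, γ₅₀) were never reported.
* **Synthetic studies** — seeded generators for noisy counts, organ dose
  tables and parametric DVHs, so every stage is testable with known ground
  truth.

## Worked example

Invert the heart dose-response from two published (mean dose, NTCP) points
and check it back:

```bash
$ csidose fit-ntcp --pair 16:0.30 --pair 6.6:0.004 --organ heart
{
  "organ": "heart",
  "d50_gy": 18.788535331992094,
  "gamma50": 1.3184795159639904,
  "a": 1.0
}
```

So a 30% complication probability at 16 Gy mean heart dose together with
0.4% at 6.6 Gy implies a tolerance dose `D50 ≈ 18.8 Gy` and slope
`γ50 ≈ 1.32`; substituting either dose back into the sigmoid reproduces the
input probabilities exactly.

Accumulate imaging dose over a course with 15 positioning CBCTs (the
package ships a phantom-measured per-organ CT/CBCT dose table):

```python
from csidose import (Prescription, build_exposure_report, exposure_frame,
                     reference_imaging_doses)

rows = build_exposure_report(reference_imaging_doses(), Prescription(), n_cbct=15)
print(exposure_frame(rows, rounded=True))
```

```
           organ  imaging_total_mgy  cbct_only_total_mgy  pct_of_prescription  pct_of_total_with_boost
           brain               91.0                 86.0                 0.25                     0.17
       brainstem               93.0                 88.0                 0.26                     0.17
         thyroid               62.0                 54.0                 0.17                     0.11
           heart               72.0                 66.0                 0.20                     0.13
abdominal_cavity              101.0                 95.0                 0.28                     0.19
       vertebrae               53.0                 48.0                 0.15                     0.10
```

(columns abridged): the brain receives 86 mGy from 15 CBCTs; across all 20
organs the cumulative imaging dose stays between 48 mGy (vertebrae) and
95 mGy (abdominal cavity) from CBCT alone and below 0.3% of the 36 Gy
prescription even with the planning CT included.

Compare techniques as NTCP matrices (percent):

```python
from csidose import DoseValue, compare_techniques, default_organ_params

comp = compare_techniques(
    {"3dcrt": {"heart": DoseValue(16, "Gy"), "thyroid": DoseValue(27.1, "Gy")},
     "vmat":  {"heart": DoseValue(6.6, "Gy"), "thyroid": DoseValue(8.7, "Gy")}},
    default_organ_params(), reference="3dcrt")
print(comp.ntcp_pct.round(2))
```

```
         3dcrt  vmat
organ
heart     30.0   0.4
thyroid   12.0   0.9
```

Arc therapy cuts the predicted cardiac complication risk from 30% to 0.4%
and thyroid dysfunction from 12% to below 1%.

A full synthetic round trip from the shell:

```bash
csidose simulate --out study/in --seed 42
csidose run --config run.yaml        # calibration → accounting → EUD/NTCP → matrices + manifest
```

The run writes `exposure_report.csv`, `eud_matrix.csv`, `ntcp_matrix.csv`,
`comparison_long.csv` and a `manifest.json` with SHA-256 digests of every
input, the seed and parameter provenance — enough to reproduce the run
byte-for-byte.

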