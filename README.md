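# nmsn — neuromelanin-sensitive MRI quantification of the substantia nigra

Dopaminergic neurons of the substantia nigra pars compacta (SNpc) contain
neuromelanin (NM), a paramagnetic pigment that appears hyperintense on
T1-weighted turbo-spin-echo MRI of the midbrain. In Parkinson's disease (PD)
those neurons degenerate, and the NM-based SN signal shrinks measurably over
a couple of years — which makes NM-sensitive MRI a candidate progression
biomarker for disease-modifying trials.

`nmsn` is a tested Python implementation of the full quantification and
analysis chain for such studies, aimed at neuroimaging methodologists and
trial statisticians:

* **Per-scan measurements** from an NM-sensitive image plus SN/background
  ROI masks (NIfTI):

  - `Vol` — SN voxel count on the **3 lowest contiguous slices** where the
    SN is visible, × voxel volume (mm³, voxels 0.4 × 0.4 × 3 mm³);
  - `C_vol = Vol / TIV` — volume corrected for total intracranial volume
    (mm³/cm³);
  - `SNR = mean_slices(Sig_SN / Sig_BND) × 100` — 100 means no contrast;
  - `CNR = mean_slices((Sig_SN − Sig_BND) / SD_BND)`.

  Percent differences use the plain ratio for Vol/C_vol/CNR and the
  background-referenced form `(SNR_a − SNR_b)/(SNR_b − 100) × 100` for SNR;
  annualized rates divide the per-subject percent change by the inter-visit
  delay in years.

* **Group statistics**: demographics tests, Shapiro–Wilk gate,
  cross-sectional group × sex ANOVA with age covariate (Type-III,
  sum-to-zero coding), mixed-design longitudinal ANOVA with visit as the
  within-subject factor, scanner-effect ANOVA, ROC diagnostics, and Pearson
  correlations with a max-|r| multivariate permutation correction.

* **Reliability**: Dice overlap of rater masks and ICC(2,1) of rater
  measurements.

* **Trial sizing**: per-arm sample sizes to detect a 30/50/70% slowing of
  the 1-year decline at 80/90% power, by the two-arm normal-approximation
  formula and by direct t-test simulation.

* **Synthetic cohorts**: a midbrain phantom generator (hyperintense SN
  ellipsoids of exact target volume on a noisy tegmentum background, with
  ROI masks and simulated second raters) and a cohort generator that
  programs baseline deficits, annualized declines, sex/scanner offsets and
  clinically correlated scores — so the entire pipeline is testable
  end-to-end without patient data.

## Worked example

```python
import numpy as np
from nmsn import (CohortDesign, PhantomSpec, generate_cohort,
                  generate_phantom, measure, percent_difference)
from nmsn import quantify as q

# one healthy-scale phantom, measured end to end
spec = PhantomSpec(sn_target_volume=136.6, sn_target_snr=112.1, bnd_sd=7.7)
image, masks = generate_phantom(spec, seed=42)
m = measure(image, masks, tiv_cm3=1438.0)
print(f"Vol  = {m.vol_mm3:.2f} mm^3   (slices {m.slices_used})")
print(f"Cvol = {m.cvol:.3f} mm^3/cm^3")
print(f"SNR  = {m.snr:.1f}")
print(f"CNR  = {m.cnr:.2f}")

# group percent differences from cohort-level means
print(f"{percent_difference(242.5, 273.2, 'vol'):+.1f} %")
print(f"{percent_difference(110.0, 112.1, 'snr'):+.1f} %")

# a full synthetic early-PD cohort and its annualized decline
subjects, phantoms = generate_cohort(CohortDesign(seed=42))
t = subjects[subjects.group == "PD"].rename(columns={"vol_mm3": "vol"})
rates, n_excl = q.mean_annual_rates(t, measures=("vol", "snr", "cnr"))
print({k: round(v, 1) for k, v in rates.items()})
```

prints

```
Vol  = 273.60 mm^3   (slices (4, 5, 6))
Cvol = 0.190 mm^3/cm^3
SNR  = 111.9
CNR  = 1.56
-11.2 %
-17.4 %
{'vol': -6.3, 'snr': 1.4, 'cnr': 1.5}
```

The measured phantom reproduces its targets (volume within one voxel,
SNR within estimator noise); the two percent differences are the
healthy-vs-early-PD baseline contrasts recomputed from the group means; the
cohort's patients decline at roughly the programmed −5.8 %/yr in volume
(−6.3 over this particular 84-patient draw) while SNR/CNR drift slightly
upward, as programmed.

## Command line

```sh
nmsn simulate --cohort early --out run/ --seed 1         # phantoms + tables
nmsn quantify --image scan.nii.gz --labels rois.nii.gz --tiv 1438 --out meas.csv
nmsn reliability --masks-a a/ --masks-b b/ --out rel.json
nmsn stats --measurements run/measurements.csv --design cohort1 --out run/
nmsn power --changes run/measurements.csv --out power.csv
nmsn run --config config.json                            # full pipeline
```

`nmsn run` executes the configured stages in order, stamps every output
with the config hash and seed, and writes a `report.json` with output
hashes and exclusion accounting; identical configs give byte-identical
outputs.

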