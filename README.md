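# atriasim

Desk-scale in-silico trials of atrial-fibrillation (AF) therapy on
synthetic human atria.

Patients with persistent AF frequently relapse after pulmonary-vein
isolation (PVI), and there is no consensus on the best second-line
treatment — more ablation lines, ablation of low-voltage areas (LVAs),
antiarrhythmic drugs, or combinations. In-silico trials attack this
question by building a *cohort of virtual patients* — atrial models with
realistic variability in ionic currents, chamber size and structural
remodelling — inducing re-entrant arrhythmia in each, applying candidate
therapies, and asking which patient characteristics predict which therapy
succeeds.

`atriasim` implements that entire workflow at workstation scale:

- **Cell model** — the Courtemanche–Ramirez–Nattel human atrial action
  potential with chronic-AF remodelling, per-current conductance scaling
  (population variability), seven regional electrophysiology classes, and
  pore-block pharmacology (amiodarone, vernakalant presets).
- **Virtual cohort** — uniform ±50 % sampling of nine current densities,
  biomarker-based calibration of the population of models, chamber-volume
  sampling (RA 127 ± 51 mL, LA 105 ± 39 mL), and assembly into
  profile × anatomy × LVA-status patients (40 × 10 × 2 = 800 at full size).
- **Synthetic geometry** — labelled two-chamber atrial templates (valve
  annuli, pulmonary-vein sleeves, posterior/anterior wall, isthmus
  corridors, inter-atrial bridges) plus smooth random LVA probability maps
  thresholded to ≥ 15 % coverage per chamber.
- **Monodomain solver** — anisotropic 2D reaction–diffusion on quad meshes
  (400 µm default), operator splitting with Rush–Larsen gates, no-flux
  lesions by element removal.
- **Protocols** — plane-wave conduction-velocity (CV) measurement and
  calibration to 80 cm/s, S1–S2 tissue effective refractory period (ERP),
  minimal circumferential PVI, spiral-wave induction by phase
  distribution, 7 s sustainment assessment.
- **Arrhythmia metrics** — phase maps, topological-charge rotor-tip
  detection and tracking, rotor-regime taxonomy, pseudo-ECG and dominant
  frequency.
- **Trial engine** — nine ablation strategies and three drug arms,
  per-therapy efficacy tables split by LVA stratum, and the stratification
  cascade: LVA presence, right-/left-atrial volume thresholds (60 / 90 mL)
  and tissue ERP (170 ms) map each patient to a recommended therapy.

The core quantities follow the monodomain formulation
χ Cm ∂V/∂t = ∇·(σ∇V) − χ I_ion(V, s), with I_ion from the CRN model and
conductance g_eff(X) = g(X) · remodelling · profile · region · (1 − block)
for each current X.

## Worked example

```python
from atriasim import protocols, tissue_model as tm
from atriasim.cell_dynamics import IonicProfile, DRUG_PRESETS, percent_block
from atriasim.trial_engine import PatientFeatures, stratify

sheet = protocols.cv_measurement_sheet(400.0)          # 30 mm strip
sigma = tm.calibrate_baseline_conductivity(sheet)      # target 80 cm/s
props = tm.baseline_properties(sheet, sigma)
print(f"sigma_l = {sigma:.3f} mS/mm")
print(f"CV baseline  = {protocols.measure_cv(sheet, props):.1f} cm/s")
slow = IonicProfile('ina_low', scale_INa=0.5)
print(f"CV INa x0.5  = {protocols.measure_cv(sheet, props, profile=slow):.1f} cm/s")
print(f"IKr block (amiodarone 3 uM) = "
      f"{percent_block('IKr', DRUG_PRESETS['amiodarone_3.0']):.0f} %")
rec = stratify(PatientFeatures(has_lva=True, ra_volume_ml=100.0,
                               la_volume_ml=110.0, erp_ms=160.0))
print(f"recommended therapy: {rec.therapy}")
```

prints

```
sigma_l = 0.451 mS/mm
CV baseline  = 80.0 cm/s
CV INa x0.5  = 58.0 cm/s
IKr block (amiodarone 3 uM) = 70 %
recommended therapy: LVA_LA-RA+CTI
```

The calibrated strip conducts at exactly the 80 cm/s bulk target; halving
the sodium-current density slows conduction to 58 cm/s (the slow end of
the cohort's CV spread); the high-dose amiodarone preset removes 70 % of
the peak rapid delayed-rectifier current under voltage clamp; and a
patient with LVAs, a dilated right atrium and short refractoriness is
stratified to bi-atrial LVA ablation with cavo-tricuspid-isthmus block.

A command-line interface wraps the same library:

```bash
atriasim --outdir out cohort build --n-profiles 8 --n-anatomies 2
atriasim --outdir out calibrate cv
atriasim --outdir out trial run --demo --n-profiles 2 --n-anatomies 1
atriasim --outdir out stratify --features-csv features.csv
```

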