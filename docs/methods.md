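# Methods

`atriasim` rebuilds, at desk scale, the workflow of an in-silico trial of
atrial-fibrillation (AF) therapy: a virtual cohort with electrophysiological,
anatomical and structural variability; monodomain simulation of re-entrant
arrhythmia on synthetic atrial tissue; virtual ablation and pore-block
pharmacology; and a feature-based decision cascade recommending a therapy
per patient. This note records the models, the defaults and why they were
chosen, the numerics, and the limits of what the synthetic setting can show.

## Cellular model

The reaction term is the Courtemanche–Ramirez–Nattel (CRN, 1998) human
atrial action-potential model — 21 state variables, 12 membrane currents,
three calcium compartments — implemented once as a compiled per-cell kernel
shared by the single-cell and tissue paths. With all multipliers at 1 and
no chronic remodelling the implementation reproduces the published AP
morphology at 1 Hz (APD90 ≈ 292 ms, resting potential ≈ −81 mV, overshoot
≈ +31 mV), which the test suite asserts against the published ranges.

Persistent AF is represented by a fixed electrical-remodelling set applied
to the baseline conductances — ICaL ×0.35, Ito ×0.35, IKur ×0.5, IK1 ×2.0 —
the standard chronic-AF variant of CRN. It shortens APD90 to ≈ 155 ms at
1 Hz and hyperpolarises rest to ≈ −84 mV, placing tissue refractoriness in
the persistent-AF range. The set is a parameter (`remodelling=`) and can be
replaced wholesale.

Population variability enters as per-current conductance multipliers
(`IonicProfile`, nine scaled currents: INa, ICaL, IK1, IKr, IKs, Ito, IKur,
INaK, INCX) sampled uniformly in [1−s, 1+s] with default spread s = 0.5,
i.e. ±50 % — the spread quoted for sodium-current density generalised to
all nine currents. Regional electrophysiology uses seven classes (right
atrial baseline plus six heterogeneous regions); the per-region adjustment
tables are stated defaults following the usual regional-gradient
conventions for human atrial models (e.g. higher IKr in the left atrium
and pulmonary-vein sleeves, higher ICaL at the crista terminalis) and are
configurable. Drugs are simple pore blocks: conductance × (1 − fraction),
with three shipped dose presets (amiodarone 1.5 µM and 3.0 µM, vernakalant
30 µM) whose per-current percentages are the clinically derived values used
by the trial. All factors — remodelling, profile, region, low-voltage-area
(LVA) remodelling, drug block — compose multiplicatively and therefore
commute.

Profile calibration ("population of models") paces each sampled profile to
quasi-steady state at 1 Hz and keeps those whose biomarkers fall inside
acceptance intervals. Defaults: APD90 ∈ [100, 300] ms, resting Vm ∈
[−86, −65] mV, peak Vm ∈ [5, 45] mV, max dVm/dt ∈ [40, 400] V/s. The upstroke
velocity is measured on the 0.5 ms-sampled trace, which underestimates the
instantaneous maximum; the interval accounts for this. Intervals are data
of the run, not code.

## Tissue model and numerics

The monodomain equation is solved on 2D structured quadrilateral meshes
(default edge length h = 400 µm). Geometry is a planar-unfolded surface
rather than a volumetric atrium: the re-entrant phenomena of interest are
surface phenomena, and this is the reduction that makes desk-scale trials
possible. Chamber "volume" maps to sheet area through a fixed-thickness
convention A = V / t with t = 10 mm, chosen so a 105 mL left atrium unfolds
to ≈ 105 cm², a realistic epicardial surface area; area is then strictly
proportional to the requested volume.

Diffusion uses bilinear quads with a 2×2 Gauss-point stiffness matrix per
element and a lumped mass matrix; the conductivity tensor is the
fiber-rotated diag(σl, σt). Removed or inactive elements are simply not
assembled, which makes every lesion and hole a no-flux internal boundary
and makes the solver's coupling graph identical to the connectivity graph
used for isolation checks. Membrane constants are fixed (Cm = 1 µF/cm²,
surface-to-volume 1400 cm⁻¹); only conductivity is calibrated. Time
stepping is operator splitting: Rush–Larsen for all 15 gates and forward
Euler for voltage and concentrations (reaction), forward Euler for
diffusion; dt = 0.02 ms default (0.05 ms in reduced demos). An explicit
stability check dt ≤ h²/(4 Dmax) runs before every simulation, and the
solver aborts with diagnostics if |Vm| exceeds 200 mV.

Baseline longitudinal conductivity is calibrated by bisection until a plane
wave on a 30 mm strip travels at 80 cm/s (tolerance 1 cm/s); with the
defaults this gives σl ≈ 0.45 mS/mm. Bulk anisotropy defaults to 4:1
(σt = σl/4), a stated assumption. Conduction velocity is measured from the
activation-time difference (maximal temporal derivative) between two
centreline sites ≥ 10 mm apart; failure to reach the distal site raises an
explicit `ConductionBlock`, never a number.

Numerical accuracy statements the package itself measures: halving dt
changes plane-wave CV by < 2 %; refining the grid from 400 µm to 200 µm
changes CV by ≈ 7 % (the lumped-mass discretization slows waves at coarse
h), so convergence between those resolutions is asserted at 10 %; the
continuum CV ∝ √σ law holds to 3 % at h = 200 µm. Propagation at
physiological coupling fails outright for h ≳ 1.5–2 mm (discrete conduction
block), so reduced demos use h = 800 µm, never coarser.

## Low-voltage areas and ablation

LVA remodelling follows the stated prescription: longitudinal conductivity
×0.7, anisotropy forced to 8:1 on the element's final σl (the "after
regional scaling" reading, documented here as the package's choice), and
ionic reductions ICaL ×0.5, INa ×0.6, IK1 ×0.5 composed with the patient's
profile. Applying the remodelling twice is guarded to be idempotent.

Synthetic LVA maps emulate the probabilistic map the study derived from
patient voltage data: Gaussian-smoothed white noise on the element lattice,
rescaled to [0, 1], with an additive bias (0.35) on the anterior/posterior
wall landmarks where clinical low-voltage substrate concentrates. The
binary labelling takes elements per chamber in descending probability
(ties broken by element index) until ≥ 15 % of each chamber's area is
labelled — the smallest such set under that ordering.

Ablation removes elements from the mesh. Lesion sets are named components
resolved against landmarks: posterior-wall box isolation (the outer two
element layers of the posterior-wall patch), mitral-isthmus line, anterior
mitral line, cavo-tricuspid-isthmus line, roof (dome) line, a
Marshall-bundle surrogate segment (an extra epicardial-course line beside
the mitral isthmus — ethanol infusion of the vein of Marshall cannot be
represented by element removal, and the surrogate is flagged as such), and
per-chamber LVA ablation. Pulmonary-vein isolation searches, per vein, the
smallest circumferential ring (half-edge radial steps) whose removal
graph-disconnects the vein sleeve from the left-atrial body; it is
idempotent and records the chosen radii.

## Synthetic anatomy

The two-chamber template is deterministic given the chamber volumes: RA and
LA rectangles (aspect 4:3) with circular holes for the valve annuli, caval
veins and pulmonary-vein lumina; annular PV sleeves; posterior/anterior
wall, roof, appendage, crista terminalis and isthmus-corridor labels; and
two inter-atrial bridges (roof-level and coronary-sinus-level). Landmark
positions are fixed fractions of chamber size; every required landmark is
checked non-empty at the requested resolution and the builder raises if the
volume cannot host the template at that h. This stands in for the
unavailable imaging-derived anatomy; it preserves the topology that the
therapies manipulate (holes to anchor macro-re-entry, corridors to block,
veins to isolate) and nothing more.

## Arrhythmia induction and metrics

Re-entry is imposed as an initial condition by phase distribution: a
single-cell limit cycle is pre-computed by pacing the bulk substrate at the
induction specification's cycle length (default 190 ms), and each node
receives the state at
phase φ(x) = Σk qk·θk(x) − 2π·r(x)/λ, where θk is the polar angle about
core k (alternating chirality qk = ±1), r is the distance to the nearest
core and λ is the Archimedean pitch (default 100 mm). The radial term makes
the reconstructed arm an outward-rotating spiral; without it the returning
front lands in its own refractory tail and the rotor dies within one turn.
Default placement is three cores at landmark-relative sites with seeded
jitter. On a 70 mm sheet at h = 800 µm a single imposed rotor sustains for
the full analysis window; the package's own demonstration uses a
rapid-repolarisation profile (IKr ×1.5, ICaL ×0.7, INa ×1.2) so the re-entry
wavelength fits the sheet.

Sustainment over the analysis window (default 7 s; reduced demos use
shorter windows) is a pure function of the Vm movie: sustained iff any node
shows an activation (inter-frame dVm/dt above 5 mV/ms while crossing
−40 mV) in the final 500 ms.

Phase maps use the analytic-signal method on mean-subtracted Vm (stride
≤ 5 ms, ≥ 1 s of data); quiescent nodes are flagged undefined. Phase
singularities are plaquette winding numbers (±1) on the node lattice;
tips are linked frame-to-frame by nearest neighbour within a 4 mm gate.
Taxonomy thresholds are stated defaults, not published values: a track is
stationary if its tip excursion stays under 5 mm; a track is anchored to
LVA if ≥ 80 % of its samples lie within 2 mm of labelled elements; regimes
are none / stationary-only / one-meandering / two-plus-unstable / break-up.
The pseudo-ECG is the infinite-volume-conductor dipole sum
Φ = Σ σ ∇Vm·∇(1/r) dA (the torso-resolved 12-lead ECG is out of scope), and
dominant frequency is the Welch-periodogram peak in 1–15 Hz from ≥ 4 s of
signal.

## Trial engine and stratification

A campaign runs per patient: PVI → imposed-rotor induction → sustainment
verdict; sustained patients receive each therapy independently (lesion
removal and/or drug, state carried over node-by-node), and outcomes are
tabulated as freedom-from-arrhythmia per therapy split by LVA stratum,
with failed runs logged and excluded from denominators. Planned-run
accounting is |cohort| + |sustained| × |therapies|. Campaigns are
deterministic given the config seed; a provenance manifest (seeds, config,
version, per-patient induction outcomes) accompanies every records table.

The decision cascade recommends, from four features (LVA presence, RA and
LA volume, tissue ERP): with LVAs — RA < 60 mL → LVA ablation in the LA
alone; RA ≥ 60 mL and ERP < 170 ms → bi-atrial LVA ablation + CTI;
RA ≥ 60 mL and ERP ≥ 170 ms → LA LVA ablation + CTI. Without LVAs —
RA ≥ 60 mL and LA < 90 mL → Marshall-PLAN; RA ≥ 60 mL and LA ≥ 90 mL →
MiLine+CTI (alternative PWI+MI+CTI); RA < 60 mL and LA ≥ 90 mL → MiLine
(alternative PWI+MI); and ERP < 170 ms adds low-dose amiodarone as an
adjunct. Boundary values go to the "large/long" branch (≥). The
(no-LVA, small-RA, small-LA) corner corresponds to flutter-specific
circuit ablation, which has no single empirical lesion set; it is returned
as an explicit placeholder requiring user choice. Tissue ERP is measured
on a strip with a 4-beat S1 train at 600 ms cycle length (a stated
convention) and binary-searched S2 to a ≤ 5 ms grid; non-capture returns
+∞ with a diagnostic.

## Problem sizes

The package's own demonstrations run at sizes a workstation handles:
conductivity calibration and CV measurements on 30 mm strips at 400 µm;
rotor demonstrations on 70 mm sheets at 800 µm for 4.4 s; reduced trial
campaigns on 25 mL chamber templates at 800 µm with windows of a few
hundred milliseconds and a handful of patients. Full-size settings
(127/105 mL chambers at 400 µm, 7 s windows, 800 patients, 12 therapies)
are expressible in the same `TrialConfig` but are compute-campaign scale
by design and are not exercised by the shipped tests.

## What the synthetic setting does and does not show

The generator reproduces the *statistics and topology* the trial design
relies on: chamber-size distributions (RA 127 ± 51 mL, LA 105 ± 39 mL,
truncated > 20 mL), ≥ 15 % LVA coverage per chamber with wall-biased smooth
fields, landmark regions for every lesion set, and ±50 % ionic variability
calibrated against AP biomarkers. It does not reproduce patient-specific
shape variation (the anatomy is a template scaled by volume), fiber
architecture beyond a crista-terminalis orientation, endo/epicardial
layering, or the empirical 20-patient voltage map. Passing tests therefore
demonstrate that the pipeline — calibration, remodelling, induction,
ablation, pharmacology, tabulation, stratification — behaves correctly and
reproducibly on substrates with the stated properties; they do not validate
clinical efficacy numbers, which in the source setting required full
bi-atrial anatomies and orders of magnitude more compute.

## Known limitations

- CRN's conduction velocity scales ≈ √gNa; with the stated LVA prescription
  the most depressed profile (INa ×0.5 ×0.6) fails to conduct transversally
  at 400 µm (discrete block), so "slowest LVA velocity" is reported over
  the profiles that still conduct — the same observational definition the
  trial uses. Longitudinal LVA velocity comes out ≈ 36 cm/s here, slower
  than the ≈ 50 cm/s a weaker CV–INa dependence would give.
- The fixed 500 ms quiescence criterion makes short demo windows
  conservative: any activation inside a window shorter than 500 ms counts
  as sustained.
- Lumped-mass explicit diffusion underestimates CV at coarse h; all
  quantitative CV work is done at 400 µm or finer.
- Drug action is pure pore block at fixed concentration: no kinetics,
  use-dependence or dose–response.
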