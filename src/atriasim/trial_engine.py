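"""In-silico trial orchestration.

Applies the nine ablation strategies and the drug arms to virtual patients
with sustained post-PVI arrhythmia, tabulates per-therapy efficacy split
by low-voltage-area (LVA) status, and implements the feature-based
decision cascade (chamber volumes and tissue ERP) recommending a therapy
per patient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.ndimage

from . import __version__ as _pkg_version
from . import cell_dynamics as cd
from . import monodomain_solver as solver
from . import protocols
from . import tissue_model as tm
from .arrhythmia_metrics import (compute_phase, detect_singularities,
                                 track_and_classify)
from .cohort import VirtualPatient
from .geometry_synth import (Landmark, TissueMesh, LVAMap, CHAMBER_LA,
                             CHAMBER_RA, make_idealized_atria,
                             make_lva_probability_field, threshold_lva)
from .monodomain_solver import SolverConfig, Trajectory


# ---------------------------------------------------------------------------
# Therapies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Therapy:
    """A lesion set (by named components) and/or a pore-block drug."""

    name: str
    lesions: tuple = ()
    drug: cd.DrugSpec | None = None


#: The trial's treatment arms.  Ablation components are resolved against
#: mesh landmarks by :func:`build_lesion_set`; PVI is applied to every
#: patient beforehand and is not part of these sets.  The synergistic arm
#: adds low-dose amiodarone on top of an extensive ablation set.
THERAPIES: dict[str, Therapy] = {
    "PWI": Therapy("PWI", ("PWI",)),
    "PWI+MI": Therapy("PWI+MI", ("PWI", "MI")),
    "PWI+MI+CTI": Therapy("PWI+MI+CTI", ("PWI", "MI", "CTI")),
    "MiLine": Therapy("MiLine", ("MiLine",)),
    "MiLine+CTI": Therapy("MiLine+CTI", ("MiLine", "CTI")),
    "Marshall-PLAN": Therapy("Marshall-PLAN",
                             ("RoofLine", "MI", "CTI", "Marshall")),
    "LVA_LA": Therapy("LVA_LA", ("LVA_LA",)),
    "LVA_LA+CTI": Therapy("LVA_LA+CTI", ("LVA_LA", "CTI")),
    "LVA_LA-RA+CTI": Therapy("LVA_LA-RA+CTI", ("LVA_LA", "LVA_RA", "CTI")),
    "amiodarone3.0": Therapy("amiodarone3.0",
                             drug=cd.DRUG_PRESETS["amiodarone_3.0"]),
    "vernakalant30": Therapy("vernakalant30",
                             drug=cd.DRUG_PRESETS["vernakalant_30"]),
    "ablation+amiodarone1.5": Therapy("ablation+amiodarone1.5",
                                      ("MiLine", "CTI"),
                                      cd.DRUG_PRESETS["amiodarone_1.5"]),
}

_TAG_OF = {
    "MI": Landmark.MI_CORRIDOR,
    "CTI": Landmark.CTI_CORRIDOR,
    "MiLine": Landmark.MILINE_PATH,
    "RoofLine": Landmark.ROOF_LINE,
    "Marshall": Landmark.MARSHALL_SEG,
}


def _pwi_ring(mesh: TissueMesh) -> np.ndarray:
    """Box-isolation ring: the outer two element layers of the posterior wall."""
    pw = ((mesh.landmark & int(Landmark.POSTERIOR_WALL)) != 0)
    grid = pw.reshape(mesh.ny - 1, mesh.nx - 1)
    interior = scipy.ndimage.binary_erosion(grid, iterations=2)
    ring = grid & ~interior
    return np.nonzero(ring.ravel() & mesh.conducting)[0]


def build_lesion_set(mesh: TissueMesh, therapy: Therapy,
                     lva_label: np.ndarray | None = None) -> np.ndarray:
    """Element set realising a therapy's named lesion components.

    Composite therapies union their parts.  LVA components on an
    LVA-absent patient warn and contribute nothing.  Missing landmarks
    raise, naming the landmark.
    """
    parts = []
    for comp in therapy.lesions:
        if comp == "PWI":
            e = _pwi_ring(mesh)
            if e.size == 0:
                raise ValueError("landmark POSTERIOR_WALL absent or empty")
        elif comp in _TAG_OF:
            e = mesh.elements_with(_TAG_OF[comp])
            if e.size == 0:
                raise ValueError(f"landmark {_TAG_OF[comp].name} absent")
        elif comp in ("LVA_LA", "LVA_RA"):
            chamber = CHAMBER_LA if comp == "LVA_LA" else CHAMBER_RA
            if lva_label is None or not lva_label.any():
                warnings.warn(f"{comp} lesion requested on LVA-absent patient: "
                              "empty set")
                e = np.empty(0, int)
            else:
                e = np.nonzero(lva_label & (mesh.chamber == chamber)
                               & mesh.conducting)[0]
        else:
            raise ValueError(f"unknown lesion component {comp!r}")
        parts.append(e)
    if not parts:
        return np.empty(0, int)
    return np.unique(np.concatenate(parts)).astype(int)


# ---------------------------------------------------------------------------
# Records and treatment runs
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """Per-patient, per-treatment outcome."""

    patient_id: str
    therapy: str
    outcome: str                 # terminated | sustained | failed-run
    termination_ms: float | None = None
    rotor_count: float = 0.0
    regime: str = "none"
    driver_class: str = "none"   # LA | RA-healthy | RA-LVA | none
    has_lva: bool = False


def classify_drivers(traj: Trajectory, mesh: TissueMesh,
                     lva_label: np.ndarray | None,
                     frame_stride: int = 5) -> tuple[str, float, str]:
    """(driver location class, mean rotor count, regime) from a Vm movie.

    Driver class is the majority chamber of all tracked tip samples, with
    right-atrial tips further split by LVA membership (2 mm halo).  Short
    movies (< 1.2 s) cannot support phase mapping and return "none".
    """
    if traj.times[-1] - traj.times[0] < 1200.0 or traj.vm.shape[0] < 16:
        return "none", 0.0, "none"
    phase = compute_phase(traj)
    frames = [detect_singularities(phase[i], mesh, float(traj.times[i]))
              for i in range(0, phase.shape[0], frame_stride)]
    cls = track_and_classify(frames, mesh, lva_label)
    tips = [(s.element, s.x_mm, s.y_mm) for f in frames for s in f]
    if not tips or not cls.tracks:
        return "none", cls.rotor_count, cls.regime
    elems = np.array([t[0] for t in tips])
    chambers = mesh.chamber[elems]
    n_la = int((chambers == CHAMBER_LA).sum())
    n_ra = int((chambers == CHAMBER_RA).sum())
    if n_la >= n_ra:
        return "LA", cls.rotor_count, cls.regime
    if lva_label is not None and lva_label.any():
        xy = np.array([(t[1], t[2]) for t in tips])[chambers == CHAMBER_RA]
        lva_xy = mesh.element_centers()[np.asarray(lva_label, bool)]
        d = np.min(np.hypot(xy[:, None, 0] - lva_xy[None, :, 0],
                            xy[:, None, 1] - lva_xy[None, :, 1]), axis=1)
        if np.mean(d <= 2.0) > 0.5:
            return "RA-LVA", cls.rotor_count, cls.regime
    return "RA-healthy", cls.rotor_count, cls.regime


def run_treatment(mesh: TissueMesh, props: tm.TissueProperties,
                  patient: VirtualPatient, therapy: Therapy,
                  post_induction_states: np.ndarray,
                  window_ms: float, config: SolverConfig,
                  lva_label: np.ndarray | None = None,
                  remodelling=cd.PERSISTENT_AF_REMODELLING) -> TrialRecord:
    """Apply a therapy to a running arrhythmia and record the outcome.

    Lesions are removed from the mesh (states carry over by node), drugs
    enter the conductance scalings, and the arrhythmia is re-assessed over
    the analysis window.  Solver aborts yield outcome ``failed-run``.
    """
    try:
        lesion = build_lesion_set(mesh, therapy, lva_label)
        mesh2 = tm.apply_ablation(mesh, lesion) if lesion.size else mesh
        scales = tm.node_scale_matrix(mesh2, props, profile=patient.profile,
                                      drug=therapy.drug,
                                      remodelling=remodelling)
        traj = solver.run(mesh2, props, scales, window_ms, config=config,
                          initial_states=post_induction_states)
        verdict = protocols.assess_sustainment(traj, window_ms)
        driver, count, regime = ("none", 0.0, "none")
        if verdict.sustained:
            driver, count, regime = classify_drivers(traj, mesh2, lva_label)
        return TrialRecord(
            patient_id=patient.patient_id, therapy=therapy.name,
            outcome="sustained" if verdict.sustained else "terminated",
            termination_ms=verdict.termination_ms,
            rotor_count=count, regime=regime, driver_class=driver,
            has_lva=patient.has_lva)
    except solver.SolverInstability as e:
        warnings.warn(f"solver aborted for {patient.patient_id}/"
                      f"{therapy.name}: {e}")
        return TrialRecord(patient_id=patient.patient_id,
                           therapy=therapy.name, outcome="failed-run",
                           has_lva=patient.has_lva)


# ---------------------------------------------------------------------------
# Efficacy table
# ---------------------------------------------------------------------------

def efficacy_table(records: list[TrialRecord]) -> pd.DataFrame:
    """Freedom-from-arrhythmia per therapy, split by LVA stratum.

    ``failed-run`` records are excluded from denominators.  Percentages
    are invariant to record order.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame([asdict(r) for r in records])
    df = df[df.outcome != "failed-run"]
    rows = []
    for therapy, g in df.groupby("therapy", sort=True):
        row = {"therapy": therapy}
        for label, sel in (("absence_lva", ~g.has_lva),
                           ("presence_lva", g.has_lva), ("total", slice(None))):
            gg = g if label == "total" else g[sel]
            n, free = len(gg), int((gg.outcome == "terminated").sum())
            row[f"{label}_n"] = n
            row[f"{label}_free"] = free
            row[f"{label}_pct"] = 100.0 * free / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stratification (decision cascade)
# ---------------------------------------------------------------------------

#: Decision thresholds: right-atrial volume, left-atrial volume, tissue ERP.
RA_VOLUME_THRESHOLD_ML = 60.0
LA_VOLUME_THRESHOLD_ML = 90.0
ERP_THRESHOLD_MS = 170.0


@dataclass(frozen=True)
class PatientFeatures:
    """Features feeding the decision cascade."""

    has_lva: bool
    ra_volume_ml: float
    la_volume_ml: float
    erp_ms: float


@dataclass(frozen=True)
class Recommendation:
    therapy: str
    drug_adjunct: str | None = None
    alternatives: tuple = ()


def stratify(features: PatientFeatures) -> Recommendation:
    """Therapy recommendation from LVA status, chamber volumes and ERP.

    Boundary convention: values at exactly 60 mL / 90 mL / 170 ms follow
    the "big/long" branch (>= goes right).  The LVA-absent, small-RA,
    small-LA corner maps to flutter-specific circuit ablation, which has
    no single empirical lesion set and is returned as a placeholder
    requiring user choice.
    """
    for name in ("has_lva", "ra_volume_ml", "la_volume_ml", "erp_ms"):
        if getattr(features, name) is None:
            raise ValueError(f"missing feature {name}")
    ra, la, erp = (features.ra_volume_ml, features.la_volume_ml,
                   features.erp_ms)
    if features.has_lva:
        if ra < RA_VOLUME_THRESHOLD_ML:
            return Recommendation("LVA_LA")
        if erp < ERP_THRESHOLD_MS:
            return Recommendation("LVA_LA-RA+CTI")
        return Recommendation("LVA_LA+CTI")
    adjunct = ("amiodarone_1.5" if erp < ERP_THRESHOLD_MS else None)
    if ra >= RA_VOLUME_THRESHOLD_ML:
        if la < LA_VOLUME_THRESHOLD_ML:
            return Recommendation("Marshall-PLAN", adjunct)
        return Recommendation("MiLine+CTI", adjunct, ("PWI+MI+CTI",))
    if la >= LA_VOLUME_THRESHOLD_ML:
        return Recommendation("MiLine", adjunct, ("PWI+MI",))
    return Recommendation("flutter-circuit", adjunct)


# ---------------------------------------------------------------------------
# Trial orchestration
# ---------------------------------------------------------------------------

def planned_run_count(n_cohort: int, n_sustained: int,
                      n_therapies: int) -> int:
    """Induction runs plus one treatment run per sustained patient/therapy."""
    return n_cohort + n_sustained * n_therapies


@dataclass
class TrialConfig:
    """Problem sizes and numerics of one trial campaign."""

    h_um: float = 400.0
    window_ms: float = 7000.0
    dt_ode: float = 0.02
    dt_pde: float = 0.02
    output_stride_ms: float = 2.0
    sigma_l: float | None = None      # None -> calibrate to 80 cm/s
    lva_fraction: float = 0.15
    n_rotors: int = 3
    cycle_ms: float = 220.0
    erp_s1_beats: int = 4
    erp_s1_cl: float = 600.0
    erp_h_um: float = 800.0
    measure_erp: bool = True
    seed: int = 0

    def solver_config(self) -> SolverConfig:
        return SolverConfig(dt_ode=self.dt_ode, dt_pde=self.dt_pde,
                            output_stride_ms=self.output_stride_ms,
                            seed=self.seed)


def demo_config(seed: int = 0) -> TrialConfig:
    """Reduced desk-scale defaults (coarse mesh, short window)."""
    return TrialConfig(h_um=2000.0, window_ms=1500.0, dt_ode=0.05,
                       dt_pde=0.05, output_stride_ms=4.0,
                       erp_s1_beats=2, erp_s1_cl=500.0, seed=seed)


def run_trial(cohort: list[VirtualPatient],
              therapies: list[Therapy] | None = None,
              config: TrialConfig | None = None,
              ) -> tuple[list[TrialRecord], dict]:
    """Full campaign: PVI -> induction -> sustainment -> treatments.

    Returns the treatment records and a provenance report (seeds, config,
    versions, per-patient induction outcomes, planned-run accounting).
    Deterministic given config.seed.
    """
    config = config or TrialConfig()
    therapies = list(THERAPIES.values()) if therapies is None else therapies
    sc = config.solver_config()

    if config.sigma_l is None:
        strip = protocols.cv_measurement_sheet(400.0)
        sigma = tm.calibrate_baseline_conductivity(strip)
    else:
        sigma = config.sigma_l

    # per-anatomy caches: mesh, PVI mesh, LVA map
    anat: dict[str, dict] = {}
    for i, p in enumerate(cohort):
        if p.anatomy_id in anat:
            continue
        mesh = make_idealized_atria(p.ra_volume_ml, p.la_volume_ml,
                                    config.h_um)
        pvi = protocols.apply_pvi(mesh)
        fieldv = make_lva_probability_field(
            pvi, seed=config.seed * 1009 + len(anat))
        lva = threshold_lva(fieldv, pvi, config.lva_fraction)
        anat[p.anatomy_id] = dict(mesh=pvi, lva=lva)

    erp_cache: dict[str, float] = {}
    erp_strip_mesh = protocols.erp_strip(config.erp_h_um)
    erp_props = tm.baseline_properties(erp_strip_mesh, sigma)

    records: list[TrialRecord] = []
    induction_rows = []
    n_sustained = 0
    for k, patient in enumerate(cohort):
        a = anat[patient.anatomy_id]
        mesh = a["mesh"]
        props = tm.baseline_properties(mesh, sigma)
        lva_label = None
        if patient.has_lva:
            props = tm.apply_lva_remodelling(props, a["lva"])
            lva_label = a["lva"].label

        erp = np.nan
        if config.measure_erp:
            pid = patient.profile.profile_id
            if pid not in erp_cache:
                erp_cache[pid] = protocols.measure_erp(
                    erp_strip_mesh, erp_props, profile=patient.profile,
                    s1_cl=config.erp_s1_cl, s1_beats=config.erp_s1_beats)
            erp = erp_cache[pid]

        scales = tm.node_scale_matrix(mesh, props, profile=patient.profile)
        spec = protocols.InductionSpec(
            n_rotors=config.n_rotors, window_ms=config.window_ms,
            cycle_ms=config.cycle_ms, seed=config.seed * 7919 + k)
        init = protocols.induce_reentry(mesh, props, scales, spec)
        try:
            traj = solver.run(mesh, props, scales, config.window_ms,
                              config=sc, initial_states=init)
            verdict = protocols.assess_sustainment(traj, config.window_ms)
        except solver.SolverInstability as e:
            warnings.warn(f"induction aborted for {patient.patient_id}: {e}")
            induction_rows.append(dict(patient_id=patient.patient_id,
                                       sustained=False, erp_ms=erp,
                                       failed=True))
            continue
        induction_rows.append(dict(patient_id=patient.patient_id,
                                   sustained=verdict.sustained, erp_ms=erp,
                                   failed=False))
        if not verdict.sustained:
            continue
        n_sustained += 1
        for therapy in therapies:
            records.append(run_treatment(
                mesh, props, patient, therapy, traj.final_states,
                config.window_ms, sc, lva_label))

    report = {
        "version": _pkg_version,
        "config": asdict(config),
        "sigma_l_ms_mm": float(sigma),
        "n_cohort": len(cohort),
        "n_sustained": n_sustained,
        "n_therapies": len(therapies),
        "planned_runs": planned_run_count(len(cohort), n_sustained,
                                          len(therapies)),
        "induction": induction_rows,
    }
    return records, report


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
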