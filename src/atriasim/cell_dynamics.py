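"""Single-cell atrial electrophysiology: profiles, regions, drugs, biomarkers.

A virtual patient's cellular substrate is described by an
:class:`IonicProfile` (per-current conductance multipliers), a
:class:`RegionKind` (one of seven regional electrophysiology classes), an
optional :class:`DrugSpec` (pore-block fractions per current) and a chronic
atrial-fibrillation remodelling set applied to the baseline
Courtemanche–Ramirez–Nattel model.  All four compose multiplicatively into
a 9-vector of effective conductance scalings:

    g_eff(X) = g_baseline(X) * remodelling(X) * profile(X) * region(X)
               * (1 - block(X))

which is the only coupling between pharmacology/population variability and
the numerical model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping

import numpy as np

from . import _crn
from ._crn import CURRENT_NAMES, CURRENT_INDEX, N_STATE


class IntegrationError(RuntimeError):
    """Raised when the cell model produces a non-finite state variable."""


class NoUpstrokeError(ValueError):
    """Raised when an AP trace contains no detectable upstroke."""


# ---------------------------------------------------------------------------
# Ionic profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonicProfile:
    """Per-current conductance multipliers defining one patient's substrate."""

    profile_id: str = "baseline"
    scale_INa: float = 1.0
    scale_ICaL: float = 1.0
    scale_IK1: float = 1.0
    scale_IKr: float = 1.0
    scale_IKs: float = 1.0
    scale_Ito: float = 1.0
    scale_IKur: float = 1.0
    scale_INaK: float = 1.0
    scale_INCX: float = 1.0

    def __post_init__(self):
        for name in CURRENT_NAMES:
            val = getattr(self, f"scale_{name}")
            if not (val > 0):
                raise ValueError(f"scale_{name} must be strictly positive, got {val}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f"scale_{n}") for n in CURRENT_NAMES])

    def with_scale(self, current: str, value: float) -> "IonicProfile":
        """Copy of this profile with one multiplier replaced."""
        d = asdict(self)
        d[f"scale_{current}"] = value
        d["profile_id"] = f"{self.profile_id}|{current}x{value:g}"
        return IonicProfile(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @staticmethod
    def from_json(s: str) -> "IonicProfile":
        return IonicProfile(**json.loads(s))


BASELINE_PROFILE = IonicProfile()


# ---------------------------------------------------------------------------
# Chronic-AF remodelling of the baseline model
# ---------------------------------------------------------------------------

#: Persistent-AF electrical remodelling applied to the baseline model:
#: reduced L-type calcium and transient-outward conductance, reduced
#: ultra-rapid delayed rectifier, up-regulated inward rectifier.  This is
#: the standard chronic-AF variant of the CRN model and shortens APD/ERP
#: into the persistent-AF range.
PERSISTENT_AF_REMODELLING: Mapping[str, float] = {
    "ICaL": 0.35,
    "Ito": 0.35,
    "IKur": 0.5,
    "IK1": 2.0,
}

NO_REMODELLING: Mapping[str, float] = {}


# ---------------------------------------------------------------------------
# Regional heterogeneity
# ---------------------------------------------------------------------------

class RegionKind(Enum):
    """Seven regional electrophysiology classes.

    The right-atrial baseline is the identity; the six heterogeneous
    regions carry per-current adjustments on top of a patient's profile.
    """

    RA_BASELINE = "ra_baseline"
    LA_BODY = "la_body"
    PV_SLEEVE = "pv_sleeve"
    CRISTA_TERMINALIS = "crista_terminalis"
    APPENDAGE_PECTINATE = "appendage_pectinate"
    AV_RING = "av_ring"
    CS_SEPTUM = "cs_septum"


#: Default per-region current adjustments (multiplicative, on top of the
#: patient profile).  Values follow the usual regional-gradient conventions
#: for human atrial models (shorter APD in PV sleeves via higher IKr and
#: lower IK1/ICaL; longer plateau at the crista terminalis via higher ICaL;
#: shorter APD at the atrio-ventricular ring).  Configurable per study.
REGION_ADJUSTMENTS: Mapping[RegionKind, Mapping[str, float]] = {
    RegionKind.RA_BASELINE: {},
    RegionKind.LA_BODY: {"IKr": 1.6},
    RegionKind.PV_SLEEVE: {"IKr": 2.2, "IK1": 0.67, "ICaL": 0.75, "Ito": 0.75},
    RegionKind.CRISTA_TERMINALIS: {"ICaL": 1.67, "Ito": 1.35},
    RegionKind.APPENDAGE_PECTINATE: {"Ito": 1.35, "IKur": 0.8},
    RegionKind.AV_RING: {"ICaL": 0.67, "Ito": 0.6},
    RegionKind.CS_SEPTUM: {"ICaL": 0.8, "Ito": 0.8, "IK1": 0.8},
}


# ---------------------------------------------------------------------------
# Drugs (simple pore block)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugSpec:
    """Pore-block drug: fractional conductance removal per current."""

    name: str
    concentration_um: float
    block_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for cur, frac in self.block_fractions.items():
            if cur not in CURRENT_INDEX:
                raise ValueError(f"unknown current {cur!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"block fraction for {cur} outside [0,1]: {frac}")

    def block(self, current: str) -> float:
        return self.block_fractions.get(current, 0.0)

    def to_json(self) -> str:
        return json.dumps({"name": self.name,
                           "concentration_um": self.concentration_um,
                           "block_fractions": dict(self.block_fractions)})


#: Shipped presets: clinically relevant doses with their per-current block
#: percentages (pore-block model, fractions of maximal conductance).
DRUG_PRESETS: Mapping[str, DrugSpec] = {
    "amiodarone_1.5": DrugSpec("amiodarone", 1.5, {
        "IKr": 0.40, "IKs": 0.30, "INCX": 0.30, "INa": 0.20,
    }),
    "amiodarone_3.0": DrugSpec("amiodarone", 3.0, {
        "IKr": 0.70, "Ito": 0.30, "IK1": 0.20, "IKs": 0.50,
        "INaK": 0.40, "INCX": 0.50, "INa": 0.50,
    }),
    "vernakalant_30": DrugSpec("vernakalant", 30.0, {
        "IKur": 0.70, "IKr": 0.60, "Ito": 0.70, "ICaL": 0.20, "INa": 0.70,
    }),
}


def region_table_json() -> str:
    """Region adjustment tables and drug presets, JSON-serialized."""
    return json.dumps({
        "regions": {r.value: dict(adj) for r, adj in REGION_ADJUSTMENTS.items()},
        "remodelling": dict(PERSISTENT_AF_REMODELLING),
        "drugs": {k: json.loads(v.to_json()) for k, v in DRUG_PRESETS.items()},
    }, indent=2)


def effective_scales(profile: IonicProfile | None = None,
                     region: RegionKind = RegionKind.RA_BASELINE,
                     drug: DrugSpec | None = None,
                     extra: Mapping[str, float] | None = None,
                     remodelling: Mapping[str, float] = PERSISTENT_AF_REMODELLING,
                     ) -> np.ndarray:
    """Compose remodelling x profile x region x extra x (1 - block) -> (9,).

    Multiplicative and therefore order-independent.  ``extra`` carries e.g.
    low-voltage-area ionic remodelling from the tissue model.
    """
    sc = np.ones(len(CURRENT_NAMES))
    for name, mult in remodelling.items():
        sc[CURRENT_INDEX[name]] *= mult
    if profile is not None:
        sc *= profile.as_array()
    for name, mult in REGION_ADJUSTMENTS[region].items():
        sc[CURRENT_INDEX[name]] *= mult
    if extra:
        for name, mult in extra.items():
            sc[CURRENT_INDEX[name]] *= mult
    if drug is not None:
        for name, frac in drug.block_fractions.items():
            sc[CURRENT_INDEX[name]] *= (1.0 - frac)
    return sc


# ---------------------------------------------------------------------------
# Cell state and stepping
# ---------------------------------------------------------------------------

@dataclass
class CellState:
    """One cell's full model state plus simulation clock."""

    y: np.ndarray
    time: float = 0.0

    @staticmethod
    def resting() -> "CellState":
        return CellState(_crn.baseline_state(), 0.0)

    def validate(self) -> None:
        if self.y.shape != (N_STATE,):
            raise ValueError(f"state must have {N_STATE} variables")
        bad = ~np.isfinite(self.y)
        if bad.any():
            name = _crn.STATE_NAMES[int(np.nonzero(bad)[0][0])]
            raise IntegrationError(f"non-finite state variable: {name}")


def step_cell(state: CellState,
              profile: IonicProfile | None = None,
              region: RegionKind = RegionKind.RA_BASELINE,
              drug: DrugSpec | None = None,
              i_stim: float = 0.0,
              dt: float = 0.02,
              n_steps: int = 1,
              remodelling: Mapping[str, float] = PERSISTENT_AF_REMODELLING,
              ) -> CellState:
    """Advance a single cell n_steps of dt (ms); returns a new CellState."""
    if not (0.0 < dt <= 0.05):
        raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")
    state.validate()
    y = state.y.copy().reshape(1, N_STATE)
    sc = effective_scales(profile, region, drug, remodelling=remodelling)
    _crn.step_states(y, sc.reshape(1, -1), np.array([i_stim]), dt, n_steps)
    out = CellState(y[0], state.time + n_steps * dt)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Paced action potentials
# ---------------------------------------------------------------------------

@dataclass
class APTrace:
    """Sampled membrane-potential trace of one (last) paced beat."""

    times: np.ndarray   # ms, from stimulus onset
    vm: np.ndarray      # mV

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.vm]),
                   delimiter=",", header="time_ms,Vm_mV", comments="")


STIM_AMPLITUDE = 25.0   # pA/pF, approx. 2x diastolic threshold
STIM_DURATION = 2.0     # ms


def run_ap(profile: IonicProfile | None = None,
           region: RegionKind = RegionKind.RA_BASELINE,
           drug: DrugSpec | None = None,
           pacing_cl: float = 1000.0,
           n_beats: int = 5,
           dt: float = 0.02,
           sample_ms: float = 0.5,
           remodelling: Mapping[str, float] = PERSISTENT_AF_REMODELLING,
           initial: CellState | None = None,
           ) -> APTrace:
    """Pace a single cell and return the last beat's Vm(t).

    Pre-beats are discarded so the returned beat is near its pacing
    limit cycle.  Raises :class:`NoUpstrokeError` on failure to capture.
    """
    if pacing_cl < 200:
        raise ValueError("pacing_cl must be >= 200 ms")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    sc = effective_scales(profile, region, drug, remodelling=remodelling)
    y = (initial.y.copy() if initial is not None
         else _crn.baseline_state()).reshape(1, N_STATE)
    sc2 = sc.reshape(1, -1)
    n_sub = max(1, int(round(sample_ms / dt)))
    samples_per_beat = int(round(pacing_cl / sample_ms))
    stim_samples = max(1, int(round(STIM_DURATION / sample_ms)))
    i_on = np.array([STIM_AMPLITUDE])
    i_off = np.zeros(1)
    trace = np.empty(samples_per_beat)
    for beat in range(n_beats):
        last = beat == n_beats - 1
        for s in range(samples_per_beat):
            if last:
                trace[s] = y[0, 0]
            stim = i_on if s < stim_samples else i_off
            _crn.step_states(y, sc2, stim, dt, n_sub)
        if not np.isfinite(y).all():
            raise IntegrationError("non-finite state during pacing")
    times = np.arange(samples_per_beat) * sample_ms
    out = APTrace(times, trace)
    if out.vm.max() < -40.0:
        raise NoUpstrokeError("stimulus failed to elicit an upstroke")
    return out


# ---------------------------------------------------------------------------
# Biomarkers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellBiomarkers:
    """Standard single-cell AP biomarkers."""

    apd90_ms: float
    resting_vm_mv: float
    peak_vm_mv: float
    dvdt_max_v_s: float
    erp_cell_ms: float | None = None

    def __post_init__(self):
        if not (self.apd90_ms > 0):
            raise ValueError("APD90 must be positive")
        if not (self.peak_vm_mv > self.resting_vm_mv):
            raise ValueError("peak Vm must exceed resting Vm")


def measure_biomarkers(trace: APTrace) -> CellBiomarkers:
    """APD90, resting/peak Vm and max upstroke velocity from one beat.

    APD90 is measured from the instant of maximal dVm/dt to 90 %
    repolarisation toward the resting potential.
    """
    t, vm = np.asarray(trace.times, float), np.asarray(trace.vm, float)
    if vm.max() - vm.min() < 10.0 or vm.max() < -40.0:
        raise NoUpstrokeError("no upstroke detected in trace")
    dvdt = np.gradient(vm, t)          # mV/ms == V/s
    i_up = int(np.argmax(dvdt))
    resting = float(vm[:max(i_up, 1)].min()) if i_up > 0 else float(vm.min())
    peak = float(vm.max())
    v90 = peak - 0.9 * (peak - resting)
    i_peak = i_up + int(np.argmax(vm[i_up:]))
    below = np.nonzero(vm[i_peak:] <= v90)[0]
    if below.size == 0:
        raise NoUpstrokeError("trace does not repolarise to 90 %")
    k = i_peak + below[0]
    # linear interpolation of the crossing time
    if k > i_up and vm[k - 1] != vm[k]:
        frac = (vm[k - 1] - v90) / (vm[k - 1] - vm[k])
        t90 = t[k - 1] + frac * (t[k] - t[k - 1])
    else:
        t90 = t[k]
    return CellBiomarkers(
        apd90_ms=float(t90 - t[i_up]),
        resting_vm_mv=resting,
        peak_vm_mv=peak,
        dvdt_max_v_s=float(dvdt.max()),
    )


# ---------------------------------------------------------------------------
# Voltage clamp (for pore-block worked examples)
# ---------------------------------------------------------------------------

#: Clamp protocols per current: (holding mV, step mV, step duration ms).
CLAMP_PROTOCOLS: Mapping[str, tuple] = {
    "INa": (-100.0, -20.0, 20.0),
    "ICaL": (-80.0, 10.0, 300.0),
    "IKr": (-80.0, 20.0, 500.0),
    "IKs": (-80.0, 20.0, 2000.0),
    "Ito": (-80.0, 40.0, 300.0),
    "IKur": (-80.0, 40.0, 300.0),
    "IK1": (-100.0, -60.0, 300.0),
}


def voltage_clamp_peak(current: str,
                       profile: IonicProfile | None = None,
                       drug: DrugSpec | None = None,
                       dt: float = 0.02,
                       remodelling: Mapping[str, float] = PERSISTENT_AF_REMODELLING,
                       ) -> float:
    """Peak |current| (pA/pF) elicited by a standard clamp step.

    The cell is equilibrated at the holding potential, stepped, and the
    absolute extremum of the named current during the step is returned.
    """
    if current not in CLAMP_PROTOCOLS:
        raise ValueError(f"no clamp protocol for {current}")
    hold, step, dur = CLAMP_PROTOCOLS[current]
    sc = effective_scales(profile, drug=drug, remodelling=remodelling)
    y = _crn.baseline_state().reshape(1, N_STATE)
    sc2 = sc.reshape(1, -1)
    _crn.step_states_clamped(y, sc2, hold, dt, int(round(500.0 / dt)))
    peak = 0.0
    n_steps = int(round(dur / dt))
    sample = max(1, int(round(0.05 / dt)))
    for k in range(0, n_steps, sample):
        _crn.step_states_clamped(y, sc2, step, dt, sample)
        val = abs(float(compute_currents_of(y[0], sc)[current]))
        if val > peak:
            peak = val
    return peak


def compute_currents_of(y: np.ndarray, scales: np.ndarray) -> dict:
    """Named instantaneous currents for a state vector (thin wrapper)."""
    return _crn.compute_currents(y, scales)


def percent_block(current: str, drug: DrugSpec, **kw) -> float:
    """100 x (1 - peak_blocked / peak_control) for a clamp step."""
    control = voltage_clamp_peak(current, drug=None, **kw)
    blocked = voltage_clamp_peak(current, drug=drug, **kw)
    return 100.0 * (1.0 - blocked / control)
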