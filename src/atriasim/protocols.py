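"""Measurement and arrhythmia-induction protocols.

Plane-wave conduction-velocity measurement, tissue effective refractory
period (S1–S2), circumferential pulmonary-vein isolation, spiral-wave
initial conditions by phase distribution, and the sustainment verdict over
the analysis window (default 7 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _crn, cell_dynamics as cd
from . import monodomain_solver as solver
from .geometry_synth import (TissueMesh, Landmark, PV_TAGS, REGION_CODES,
                             CHAMBER_LA)
from .cell_dynamics import RegionKind
from .monodomain_solver import SolverConfig, Stimulus, Trajectory
from .tissue_model import TissueProperties, node_scale_matrix


class ConductionBlock(RuntimeError):
    """Raised when a wavefront fails to reach the distal recording site."""


# ---------------------------------------------------------------------------
# Conduction velocity
# ---------------------------------------------------------------------------

def _activation_time(times: np.ndarray, vm: np.ndarray) -> float:
    """Activation instant: maximal temporal derivative of the upstroke."""
    if vm.max() < -40.0:
        raise ConductionBlock("site never depolarised")
    dv = np.diff(vm) / np.diff(times)
    return float(times[int(np.argmax(dv))])


def measure_cv(mesh: TissueMesh, props: TissueProperties,
               profile: cd.IonicProfile | None = None,
               drug: cd.DrugSpec | None = None,
               direction: str = "longitudinal",
               config: SolverConfig | None = None,
               remodelling=cd.PERSISTENT_AF_REMODELLING,
               max_ms: float = 800.0) -> float:
    """Plane-wave conduction velocity (cm/s) on a rectangular sheet.

    A plane stimulus is applied on one edge; activation times are read at
    two centerline sites >= 10 mm apart placed at 25 % and 75 % of the
    sheet extent along the propagation axis.  Fibers are assumed aligned
    with x, so ``direction="longitudinal"`` propagates along x and
    ``"transversal"`` along y.  Raises :class:`ConductionBlock` if the far
    site is never activated.
    """
    config = config or SolverConfig(output_stride_ms=0.2)
    nx, ny, h = mesh.nx, mesh.ny, mesh.h_mm
    if direction == "longitudinal":
        cols = np.arange(ny) * nx
        stim_nodes = np.concatenate([cols, cols + 1, cols + 2])
        mid = (ny // 2) * nx
        i1, i2 = int(0.25 * (nx - 1)), int(0.75 * (nx - 1))
        site1, site2 = mid + i1, mid + i2
        dist = (i2 - i1) * h
    elif direction == "transversal":
        stim_nodes = np.arange(3 * nx)
        mid = nx // 2
        j1, j2 = int(0.25 * (ny - 1)), int(0.75 * (ny - 1))
        site1, site2 = j1 * nx + mid, j2 * nx + mid
        dist = (j2 - j1) * h
    else:
        raise ValueError("direction must be 'longitudinal' or 'transversal'")
    if dist < 10.0:
        raise ValueError(f"recording sites only {dist:.1f} mm apart (< 10 mm)")

    scales = node_scale_matrix(mesh, props, profile=profile, drug=drug,
                               remodelling=remodelling)
    stim = [Stimulus(stim_nodes, t_start=1.0, duration=3.0, amplitude=60.0)]
    # advance in chunks; stop as soon as the distal site has activated
    chunk = 50.0
    t, states = 0.0, None
    times_acc, v1_acc, v2_acc = [], [], []
    while t < max_ms:
        traj = solver.run(mesh, props, scales, chunk, config=config,
                          stimuli=stim, initial_states=states, t0=t)
        skip = 1 if times_acc else 0   # drop duplicated boundary frame
        times_acc.append(traj.times[skip:])
        v1_acc.append(traj.vm[skip:, site1])
        v2_acc.append(traj.vm[skip:, site2])
        states = traj.final_states
        t += chunk
        if np.concatenate(v2_acc).max() > -20.0 and t > 3 * chunk:
            break
    times = np.concatenate(times_acc)
    t1 = _activation_time(times, np.concatenate(v1_acc).astype(float))
    t2 = _activation_time(times, np.concatenate(v2_acc).astype(float))
    if t2 <= t1:
        raise ConductionBlock("distal site activated before proximal site")
    return float(dist / (t2 - t1) * 100.0)   # mm/ms -> cm/s


def cv_measurement_sheet(h_um: float = 400.0, length_mm: float = 30.0,
                         width_mm: float = 2.0,
                         direction: str = "longitudinal") -> TissueMesh:
    """Standard bulk-tissue strip for CV calibration (fibers along x)."""
    from .geometry_synth import make_sheet
    h = h_um / 1000.0
    nl = int(round(length_mm / h)) + 1
    nw = max(int(round(width_mm / h)) + 1, 4)
    if direction == "longitudinal":
        return make_sheet(nl, nw, h_um, fiber_angle_deg=0.0)
    return make_sheet(nw, nl, h_um, fiber_angle_deg=0.0)


# ---------------------------------------------------------------------------
# Effective refractory period
# ---------------------------------------------------------------------------

def measure_erp(mesh: TissueMesh, props: TissueProperties,
                profile: cd.IonicProfile | None = None,
                drug: cd.DrugSpec | None = None,
                s1_cl: float = 600.0, s1_beats: int = 4,
                s2_grid_ms: float = 5.0,
                bounds=(100.0, 400.0),
                config: SolverConfig | None = None,
                remodelling=cd.PERSISTENT_AF_REMODELLING) -> float:
    """Tissue ERP (ms): shortest S1–S2 interval that still propagates 10 mm.

    An S1 train conditions the strip from its left edge; the tissue state
    after the last S1 is checkpointed and premature S2 stimuli are binary
    searched to the grid resolution.  Returns ``inf`` when even the
    longest tested coupling fails to capture.
    """
    if s2_grid_ms > 5.0:
        raise ValueError("S2 grid must be <= 5 ms")
    config = config or SolverConfig(output_stride_ms=1.0)
    nx, ny, h = mesh.nx, mesh.ny, mesh.h_mm
    stim_nodes = np.concatenate([np.arange(ny) * nx, np.arange(ny) * nx + 1])
    i_far = int(round(12.0 / h))
    if i_far >= nx:
        raise ValueError("strip shorter than the 12 mm propagation distance")
    far = (ny // 2) * nx + i_far

    scales = node_scale_matrix(mesh, props, profile=profile, drug=drug,
                               remodelling=remodelling)
    s1 = [Stimulus(stim_nodes, t_start=1.0 + k * s1_cl) for k in range(s1_beats)]
    t_last = 1.0 + (s1_beats - 1) * s1_cl
    train = solver.run(mesh, props, scales, t_last + 5.0, config=config,
                       stimuli=s1, record=False)
    y0, t0 = train.final_states, t_last + 5.0

    def captures(ci: float) -> bool:
        t_s2 = 1.0 + (s1_beats - 1) * s1_cl + ci
        horizon = t_s2 - t0 + 180.0
        traj = solver.run(mesh, props, scales, horizon, config=config,
                          stimuli=[Stimulus(stim_nodes, t_start=t_s2)],
                          initial_states=y0, t0=t0)
        sel = traj.times >= t_s2
        v = traj.vm[sel, far].astype(float)
        # a new upstroke at the distal site: from repolarised to depolarised
        return bool(v.size and v.min() < -60.0 and v.max() > -30.0
                    and np.argmax(v) > np.argmin(v))

    lo, hi = bounds
    if not captures(hi):
        return float("inf")
    if captures(lo):
        return float(lo)
    while hi - lo > s2_grid_ms:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return float(np.ceil(hi / s2_grid_ms) * s2_grid_ms)


def erp_strip(h_um: float = 400.0) -> TissueMesh:
    """Standard strip for ERP measurement (16 mm x 1.6 mm)."""
    return cv_measurement_sheet(h_um, length_mm=16.0, width_mm=1.6)


# ---------------------------------------------------------------------------
# Pulmonary vein isolation
# ---------------------------------------------------------------------------

def _pv_ring(mesh: TissueMesh, center: np.ndarray, r: float) -> np.ndarray:
    c = mesh.element_centers()
    d = np.hypot(c[:, 0] - center[0], c[:, 1] - center[1])
    return np.nonzero((d >= r) & (d < r + 1.9 * mesh.h_mm) & mesh.conducting)[0]


def apply_pvi(mesh: TissueMesh) -> TissueMesh:
    """Circumferential isolation of all four pulmonary-vein sleeves.

    For each vein the smallest ring radius (searched in half-edge steps
    outward from the sleeve) whose removal graph-disconnects the sleeve
    from the left-atrial body is ablated.  Idempotent: already-isolated
    veins are left untouched.
    """
    out = mesh.copy()
    la_body = np.nonzero((out.region == REGION_CODES[RegionKind.LA_BODY])
                         & (out.chamber == CHAMBER_LA) & out.conducting)[0]
    if la_body.size == 0:
        raise ValueError("mesh has no left-atrial body")
    c = out.element_centers()
    rings: dict[str, dict] = {}
    for tag in PV_TAGS:
        sleeve = out.elements_with(tag)
        if sleeve.size == 0:
            raise ValueError(f"missing pulmonary-vein landmark {tag.name}")
        center = c[sleeve].mean(axis=0)
        d_body = np.hypot(c[la_body, 0] - center[0], c[la_body, 1] - center[1])

        def far_body(r):
            # body tissue clearly outside the candidate ring
            return la_body[d_body > r + 3.0 * out.h_mm]

        r0 = float(np.hypot(*(c[sleeve] - center).T).max()) + 0.5 * out.h_mm
        if not out.connected(sleeve, far_body(r0)):
            continue   # already isolated
        done = False
        for k in range(40):
            r = r0 + k * 0.5 * out.h_mm
            ring = np.setdiff1d(_pv_ring(out, center, r), sleeve)
            if ring.size == 0:
                continue
            trial = out.copy()
            trial.removed[ring] = True
            s = trial.elements_with(tag)
            if s.size and not trial.connected(s, far_body(r)):
                out = trial
                rings[tag.name] = {"center": tuple(center), "radius_mm": r}
                done = True
                break
        if not done:
            raise RuntimeError(f"could not isolate vein {tag.name}")
    out.pvi_info = rings   # per-vein minimal ring radii, for inspection
    return out


# ---------------------------------------------------------------------------
# Re-entry induction (phase distribution)
# ---------------------------------------------------------------------------

@dataclass
class InductionSpec:
    """Imposed-rotor initial condition specification."""

    n_rotors: int = 3
    cores_mm: list | None = None       # explicit [(x, y), ...] in mm
    window_ms: float = 7000.0
    cycle_ms: float = 190.0            # limit-cycle pacing period
    pitch_mm: float = 100.0            # Archimedean wavelength of the arm
    jitter_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.window_ms <= 0:
            raise ValueError("analysis window must be positive")


def default_cores(mesh: TissueMesh, n: int, seed: int = 0,
                  jitter_mm: float = 4.0) -> list[tuple[float, float]]:
    """Landmark-relative default rotor sites with seeded jitter.

    Order of preference: LA posterior wall, RA free wall, LA anterior
    wall, RA appendage — mirroring where re-entrant drivers preferentially
    organise.
    """
    rng = np.random.default_rng(seed)
    c = mesh.element_centers()
    sites = []
    pw = mesh.elements_with(Landmark.POSTERIOR_WALL)
    if pw.size:
        sites.append(c[pw].mean(axis=0))
    ra = mesh.elements_in_region(RegionKind.RA_BASELINE)
    if ra.size:
        sites.append(c[ra].mean(axis=0))
    aw = mesh.elements_with(Landmark.ANTERIOR_WALL)
    if aw.size:
        sites.append(c[aw].mean(axis=0))
    ap = mesh.elements_with(Landmark.APPENDAGE)
    if ap.size:
        sites.append(c[ap].mean(axis=0))
    if not sites:
        raise ValueError("mesh has no landmark regions to place rotors")
    out = []
    for k in range(n):
        base = sites[k % len(sites)]
        out.append(tuple(base + rng.uniform(-jitter_mm, jitter_mm, 2)))
    return out


def _limit_cycle(scales: np.ndarray, cycle_ms: float,
                 n_pre: int = 3, dt: float = 0.02) -> np.ndarray:
    """(n_samples, 21) single-cell states over one paced cycle (1 ms grid)."""
    y = _crn.baseline_state().reshape(1, -1)
    sc = np.ascontiguousarray(scales.reshape(1, -1))
    n_sub = int(round(1.0 / dt))
    n_samp = int(round(cycle_ms))
    for beat in range(n_pre):
        for s in range(n_samp):
            stim = np.array([25.0]) if s < 2 else np.zeros(1)
            _crn.step_states(y, sc, stim, dt, n_sub)
    cycle = np.empty((n_samp, _crn.N_STATE))
    for s in range(n_samp):
        cycle[s] = y[0]
        stim = np.array([25.0]) if s < 2 else np.zeros(1)
        _crn.step_states(y, sc, stim, dt, n_sub)
    return cycle


def induce_reentry(mesh: TissueMesh, props: TissueProperties,
                   node_scales: np.ndarray,
                   spec: InductionSpec | None = None) -> np.ndarray:
    """Initial tissue state hosting imposed spiral re-entries.

    Each node is assigned a state sampled along a pre-computed single-cell
    limit cycle at a phase given by the composed polar angles about the
    rotor cores (alternating chirality).  Deterministic given the spec.
    Returns (n_nodes, 21) initial states for :func:`monodomain_solver.run`.
    """
    spec = spec or InductionSpec()
    cores = (spec.cores_mm if spec.cores_mm is not None
             else default_cores(mesh, spec.n_rotors, spec.seed, spec.jitter_mm))
    if len(cores) == 0:
        return _crn.baseline_states(mesh.n_nodes)
    cent = mesh.element_centers()
    conducting = np.nonzero(mesh.conducting)[0]
    for (x, y) in cores:
        d = np.hypot(cent[:, 0] - x, cent[:, 1] - y)
        nearest = int(np.argmin(d))
        if not mesh.conducting[nearest]:
            raise ValueError(f"rotor core ({x:.1f}, {y:.1f}) mm lies on "
                             "removed/inactive tissue")
    bulk = node_scales[node_scales.shape[0] // 2]
    cycle = _limit_cycle(bulk, spec.cycle_ms)
    coords = mesh.node_coords()
    phase = np.zeros(mesh.n_nodes)
    r_min = np.full(mesh.n_nodes, np.inf)
    for k, (x, y) in enumerate(cores):
        sign = 1.0 if k % 2 == 0 else -1.0
        phase += sign * np.arctan2(coords[:, 1] - y, coords[:, 0] - x)
        r_min = np.minimum(r_min, np.hypot(coords[:, 0] - x,
                                           coords[:, 1] - y))
    # outward Archimedean arm: radial phase decreases away from the core,
    # so the reconstructed wave rotates and sheds outward
    phase -= 2.0 * np.pi * r_min / spec.pitch_mm
    frac = (phase / (2.0 * np.pi)) % 1.0
    idx = np.minimum((frac * len(cycle)).astype(int), len(cycle) - 1)
    return cycle[idx]


# ---------------------------------------------------------------------------
# Sustainment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SustainmentResult:
    sustained: bool
    termination_ms: float | None   # last activation time when terminated


def assess_sustainment(traj: Trajectory, window_ms: float = 7000.0,
                       quiet_ms: float = 500.0,
                       dvdt_threshold: float = 5.0) -> SustainmentResult:
    """Sustained iff any node activates within the final ``quiet_ms``.

    Activation: inter-frame dVm/dt above threshold (mV/ms) while crossing
    above -40 mV.  A pure function of the Vm trajectory.
    """
    span = traj.times[-1] - traj.times[0]
    if span + traj.stride_ms + 1e-6 < window_ms:   # allow one output stride
        raise ValueError(f"trajectory spans {span:.0f} ms < window {window_ms:.0f} ms")
    live = solver.live_nodes(traj.mesh)
    vm = traj.vm[:, live].astype(float)
    dt = np.diff(traj.times)[:, None]
    act = (np.diff(vm, axis=0) / dt > dvdt_threshold) & (vm[1:] > -40.0)
    act_any = act.any(axis=1)
    t_mid = traj.times[1:]
    t_end = traj.times[0] + window_ms
    in_final = t_mid > t_end - quiet_ms
    if act_any[in_final].any():
        return SustainmentResult(True, None)
    last = t_mid[act_any][-1] if act_any.any() else traj.times[0]
    return SustainmentResult(False, float(last))
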