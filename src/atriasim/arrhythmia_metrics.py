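"""Quantification of simulated arrhythmia.

Phase maps (analytic signal), phase-singularity detection by topological
winding number on the node lattice, frame-to-frame tip tracking with a
rotor-dynamics taxonomy, infinite-volume-conductor pseudo-ECG, and
dominant-frequency estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .geometry_synth import TissueMesh
from .monodomain_solver import Trajectory, live_nodes


# ---------------------------------------------------------------------------
# Phase maps
# ---------------------------------------------------------------------------

def compute_phase(traj: Trajectory, min_amplitude_mv: float = 5.0) -> np.ndarray:
    """Per-node activation phase via the analytic-signal (Hilbert) method.

    Returns (T, n_nodes) phase in (-pi, pi]; nodes whose Vm excursion is
    below ``min_amplitude_mv`` (quiescent or inactive) are flagged NaN.
    Requires >= 1 s of data sampled at <= 5 ms stride.
    """
    if traj.stride_ms > 5.0:
        raise ValueError("phase mapping needs <= 5 ms output stride")
    if traj.times[-1] - traj.times[0] < 1000.0:
        raise ValueError("phase mapping needs >= 1 s of data")
    vm = traj.vm.astype(float)
    centred = vm - vm.mean(axis=0, keepdims=True)
    analytic = scipy.signal.hilbert(centred, axis=0)
    phase = np.angle(analytic)
    quiet = np.ptp(vm, axis=0) < min_amplitude_mv
    phase[:, quiet] = np.nan
    return phase


def phase_frame_to_grid(phase_frame: np.ndarray, mesh: TissueMesh) -> np.ndarray:
    return phase_frame.reshape(mesh.ny, mesh.nx)


# ---------------------------------------------------------------------------
# Singularities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSingularity:
    """A rotor tip at one instant."""

    time_ms: float
    element: int            # plaquette == element index
    x_mm: float
    y_mm: float
    charge: int             # +-1 topological charge


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def detect_singularities(phase_frame: np.ndarray, mesh: TissueMesh,
                         time_ms: float = 0.0) -> list[PhaseSingularity]:
    """Phase singularities of one frame by plaquette winding number.

    The winding of the wrapped phase differences around each conducting
    quad is +-2 pi at a rotor tip and 0 elsewhere; |winding| = 1 (in units
    of 2 pi) is reported.  Plaquettes touching NaN-phase nodes are skipped.
    """
    p = phase_frame.reshape(mesh.ny, mesh.nx)
    p00 = p[:-1, :-1]
    p10 = p[:-1, 1:]
    p11 = p[1:, 1:]
    p01 = p[1:, :-1]
    wind = (_wrap(p10 - p00) + _wrap(p11 - p10)
            + _wrap(p01 - p11) + _wrap(p00 - p01)) / (2.0 * np.pi)
    ok = np.isfinite(wind).ravel() & mesh.conducting
    charge = np.zeros(mesh.n_elements, int)
    w = wind.ravel()
    charge[ok & (np.abs(w - 1.0) < 0.5)] = 1
    charge[ok & (np.abs(w + 1.0) < 0.5)] = -1
    idx = np.nonzero(charge)[0]
    cent = mesh.element_centers()
    return [PhaseSingularity(time_ms, int(e), float(cent[e, 0]),
                             float(cent[e, 1]), int(charge[e]))
            for e in idx]


# ---------------------------------------------------------------------------
# Tracking and classification
# ---------------------------------------------------------------------------

@dataclass
class RotorTrack:
    """Linked tip positions of one rotor over time."""

    track_id: int
    charge: int
    times: list = field(default_factory=list)
    xs: list = field(default_factory=list)
    ys: list = field(default_factory=list)

    @property
    def lifetime_ms(self) -> float:
        return self.times[-1] - self.times[0] if len(self.times) > 1 else 0.0

    @property
    def excursion_mm(self) -> float:
        xs, ys = np.asarray(self.xs), np.asarray(self.ys)
        return float(np.hypot(xs - xs[0], ys - ys[0]).max()) if len(xs) else 0.0


@dataclass
class RotorClassification:
    """Per-track labels and overall trajectory regime."""

    track_labels: dict            # track_id -> "stationary" | "meandering"
    regime: str                   # none | stationary-only | one-meandering
                                  # | two-plus-unstable | break-up
    rotor_count: float            # mean simultaneous tips
    anchored_to_lva: dict         # track_id -> bool (empty without LVA map)
    tracks: list = field(default_factory=list)


def track_singularities(frames: list[list[PhaseSingularity]],
                        gate_mm: float = 4.0) -> list[RotorTrack]:
    """Nearest-neighbour frame-to-frame linking of rotor tips."""
    tracks: list[RotorTrack] = []
    open_tracks: list[RotorTrack] = []
    next_id = 0
    for sings in frames:
        used = set()
        still_open = []
        for tr in open_tracks:
            best, best_d = None, gate_mm
            for i, s in enumerate(sings):
                if i in used or s.charge != tr.charge:
                    continue
                d = float(np.hypot(s.x_mm - tr.xs[-1], s.y_mm - tr.ys[-1]))
                if d < best_d:
                    best, best_d = i, d
            if best is not None:
                s = sings[best]
                used.add(best)
                tr.times.append(s.time_ms)
                tr.xs.append(s.x_mm)
                tr.ys.append(s.y_mm)
                still_open.append(tr)
        open_tracks = still_open
        for i, s in enumerate(sings):
            if i in used:
                continue
            tr = RotorTrack(next_id, s.charge, [s.time_ms], [s.x_mm], [s.y_mm])
            next_id += 1
            tracks.append(tr)
            open_tracks.append(tr)
    return tracks


def track_and_classify(frames: list[list[PhaseSingularity]],
                       mesh: TissueMesh,
                       lva_label: np.ndarray | None = None,
                       gate_mm: float = 4.0,
                       stationary_mm: float = 5.0,
                       anchor_fraction: float = 0.8,
                       lva_halo_mm: float = 2.0,
                       min_lifetime_ms: float = 100.0) -> RotorClassification:
    """Classify rotor dynamics from per-frame singularity lists.

    A track is *stationary* if its tip excursion stays below
    ``stationary_mm`` over its lifetime, else *meandering*.  The regime
    label summarises the whole trajectory; a track is anchored to LVA
    tissue if >= ``anchor_fraction`` of its tip samples lie inside or
    within ``lva_halo_mm`` of labelled elements.
    """
    tracks = track_singularities(frames, gate_mm)
    main = [t for t in tracks if t.lifetime_ms >= min_lifetime_ms]
    labels = {t.track_id: ("stationary" if t.excursion_mm < stationary_mm
                           else "meandering") for t in main}
    counts = np.array([len(f) for f in frames], float)
    rotor_count = float(counts.mean()) if len(counts) else 0.0

    n_meander = sum(1 for v in labels.values() if v == "meandering")
    if not main:
        regime = "none"
    elif counts.max(initial=0) >= 6 or rotor_count > 4.5:
        regime = "break-up"
    elif n_meander >= 2:
        regime = "two-plus-unstable"
    elif n_meander == 1:
        regime = "one-meandering"
    else:
        regime = "stationary-only"

    anchored: dict[int, bool] = {}
    if lva_label is not None and lva_label.any():
        lva_xy = mesh.element_centers()[np.asarray(lva_label, bool)]
        for t in main:
            pts = np.column_stack([t.xs, t.ys])
            d = np.min(np.hypot(pts[:, None, 0] - lva_xy[None, :, 0],
                                pts[:, None, 1] - lva_xy[None, :, 1]), axis=1)
            anchored[t.track_id] = bool(np.mean(d <= lva_halo_mm)
                                        >= anchor_fraction)
    return RotorClassification(labels, regime, rotor_count, anchored, main)


# ---------------------------------------------------------------------------
# Pseudo-ECG
# ---------------------------------------------------------------------------

def pseudo_ecg(traj: Trajectory, electrodes_mm: np.ndarray,
               sigma: float = 1.0) -> np.ndarray:
    """Infinite-volume-conductor dipole-sum electrogram, (T, n_electrodes).

    phi(t) = sum_elements sigma * grad(Vm) . grad(1/r) * dA over conducting
    elements; electrodes are 3D points (mm) and must sit off the tissue
    plane or outside it by at least one edge length.
    """
    mesh = traj.mesh
    el = np.atleast_2d(np.asarray(electrodes_mm, float))
    if el.shape[1] == 2:
        el = np.column_stack([el, np.zeros(len(el))])
    cent = mesh.element_centers()
    act = np.nonzero(mesh.conducting)[0]
    quads = mesh.element_nodes()[act]
    h = mesh.h_mm
    for e in el:
        d = np.hypot(cent[act, 0] - e[0], cent[act, 1] - e[1])
        if e[2] == 0.0 and d.min() < h:
            raise ValueError("electrode lies on the tissue")
    # grad(1/r): (source - electrode)/r^3 evaluated per element
    out = np.zeros((traj.vm.shape[0], len(el)))
    src = np.column_stack([cent[act], np.zeros(len(act))])
    for j, e in enumerate(el):
        rv = src - e
        r = np.linalg.norm(rv, axis=1)
        w = rv[:, :2] / r[:, None] ** 3   # in-plane part couples to grad Vm
        vm = traj.vm.astype(float)
        v00, v10 = vm[:, quads[:, 0]], vm[:, quads[:, 1]]
        v01, v11 = vm[:, quads[:, 2]], vm[:, quads[:, 3]]
        gx = ((v10 + v11) - (v00 + v01)) / (2.0 * h)
        gy = ((v01 + v11) - (v00 + v10)) / (2.0 * h)
        out[:, j] = sigma * h * h * (gx @ w[:, 0] + gy @ w[:, 1])
    return out


# ---------------------------------------------------------------------------
# Dominant frequency
# ---------------------------------------------------------------------------

def dominant_frequency(signal: np.ndarray, fs_hz: float,
                       band_hz=(1.0, 15.0)) -> float | None:
    """Welch-periodogram peak frequency within the band; None if silent."""
    x = np.asarray(signal, float)
    if x.size < 8 or np.ptp(x) < 1e-9:
        return None
    if x.size / fs_hz < 4.0:
        raise ValueError("dominant frequency needs >= 4 s of signal")
    nper = min(x.size, int(4.0 * fs_hz))
    f, p = scipy.signal.welch(x - x.mean(), fs=fs_hz, nperseg=nper)
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    if not sel.any() or p[sel].max() <= 0:
        return None
    return float(f[sel][int(np.argmax(p[sel]))])
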