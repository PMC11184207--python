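"""Phase maps, singularity detection/tracking, pseudo-ECG, dominant freq."""

import numpy as np
import pytest

from atriasim import arrhythmia_metrics as am
from atriasim import monodomain_solver as solver
from atriasim import tissue_model as tm
from atriasim.geometry_synth import make_sheet
from atriasim.monodomain_solver import SolverConfig, Stimulus, Trajectory


def _traj_from_vm(mesh, times, vm):
    return Trajectory(np.asarray(times, float), vm.astype(np.float32),
                      mesh, solver._crn.baseline_states(mesh.n_nodes))


# ---------------------------------------------------------------------------
# Phase
# ---------------------------------------------------------------------------

def test_sinusoid_phase_rotates_uniformly():
    mesh = make_sheet(6, 6)
    t = np.arange(0.0, 2000.0, 5.0)
    vm = -80.0 + 20.0 * np.sin(2 * np.pi * 5.0 * t / 1000.0)
    movie = np.tile(vm[:, None], (1, mesh.n_nodes))
    phase = am.compute_phase(_traj_from_vm(mesh, t, movie))
    dp = np.diff(np.unwrap(phase[:, 0]))
    interior = dp[20:-20]
    assert np.std(interior) < 0.1 * np.abs(np.mean(interior))


def test_quiescent_node_flagged_undefined():
    mesh = make_sheet(6, 6)
    t = np.arange(0.0, 1500.0, 5.0)
    movie = np.full((t.size, mesh.n_nodes), -80.0)
    movie[:, 0] = -80.0 + 30.0 * np.sin(2 * np.pi * 4.0 * t / 1000.0)
    phase = am.compute_phase(_traj_from_vm(mesh, t, movie))
    assert np.isfinite(phase[:, 0]).all()
    assert np.isnan(phase[:, 1]).all()


def test_phase_of_time_reversed_signal_negated():
    mesh = make_sheet(6, 6)
    t = np.arange(0.0, 2000.0, 5.0)
    vm = -80.0 + 20.0 * np.sin(2 * np.pi * 3.0 * t / 1000.0)
    fwd = am.compute_phase(_traj_from_vm(
        mesh, t, np.tile(vm[:, None], (1, mesh.n_nodes))))
    rev = am.compute_phase(_traj_from_vm(
        mesh, t, np.tile(vm[::-1, None], (1, mesh.n_nodes))))
    a = fwd[30:-30, 0]
    b = -rev[::-1, 0][30:-30]
    diff = np.angle(np.exp(1j * (a - b)))
    assert np.abs(diff).max() < 0.15


def test_phase_needs_enough_data():
    mesh = make_sheet(5, 5)
    t = np.arange(0.0, 500.0, 5.0)
    with pytest.raises(ValueError):
        am.compute_phase(_traj_from_vm(
            mesh, t, np.zeros((t.size, mesh.n_nodes))))


# ---------------------------------------------------------------------------
# Singularities on constructed fields
# ---------------------------------------------------------------------------

def _grid_phase(mesh, fn):
    xy = mesh.node_coords()
    return fn(xy[:, 0], xy[:, 1])


def test_planar_wave_has_no_singularity():
    mesh = make_sheet(30, 30)
    phase = _grid_phase(mesh, lambda x, y: np.angle(
        np.exp(1j * (2 * np.pi * x / 5.0))))
    assert am.detect_singularities(phase, mesh) == []


def test_ideal_spiral_yields_single_positive_tip():
    mesh = make_sheet(31, 31)
    cx = cy = 15 * mesh.h_mm + 0.2 * mesh.h_mm
    phase = _grid_phase(mesh, lambda x, y: np.arctan2(y - cy, x - cx))
    sings = am.detect_singularities(phase, mesh, 0.0)
    assert len(sings) == 1
    s = sings[0]
    assert s.charge == 1
    assert abs(s.x_mm - cx) <= 1.5 * mesh.h_mm
    assert abs(s.y_mm - cy) <= 1.5 * mesh.h_mm


def test_figure_of_eight_two_tips_net_zero():
    mesh = make_sheet(41, 41)
    h = mesh.h_mm
    c1 = (12 * h + 0.3 * h, 20 * h + 0.3 * h)
    c2 = (28 * h + 0.3 * h, 20 * h + 0.3 * h)
    phase = _grid_phase(mesh, lambda x, y: np.angle(np.exp(1j * (
        np.arctan2(y - c1[1], x - c1[0])
        - np.arctan2(y - c2[1], x - c2[0])))))
    sings = am.detect_singularities(phase, mesh, 0.0)
    assert len(sings) == 2
    assert sum(s.charge for s in sings) == 0


def test_net_charge_equals_boundary_winding():
    """Sum of plaquette charges equals the winding along the outer loop."""
    mesh = make_sheet(41, 41)
    h = mesh.h_mm
    c1 = (12 * h + 0.3 * h, 20 * h + 0.3 * h)
    c2 = (27 * h + 0.3 * h, 17 * h + 0.3 * h)
    phase = _grid_phase(mesh, lambda x, y: np.angle(np.exp(1j * (
        np.arctan2(y - c1[1], x - c1[0])
        + np.arctan2(y - c2[1], x - c2[0])))))
    sings = am.detect_singularities(phase, mesh, 0.0)
    net = sum(s.charge for s in sings)
    # brute-force loop integral around the full boundary
    p = phase.reshape(mesh.ny, mesh.nx)
    loop = np.concatenate([p[0, :], p[1:, -1], p[-1, -2::-1], p[-2:0:-1, 0]])
    wind = np.round(am._wrap(np.diff(
        np.concatenate([loop, loop[:1]]))).sum() / (2 * np.pi))
    assert net == int(wind) == 2


def test_detection_invariant_to_global_phase_offset():
    mesh = make_sheet(25, 25)
    cx = cy = 12 * mesh.h_mm + 0.25 * mesh.h_mm
    base = _grid_phase(mesh, lambda x, y: np.arctan2(y - cy, x - cx))
    s0 = am.detect_singularities(base, mesh)
    s1 = am.detect_singularities(
        np.angle(np.exp(1j * (base + 1.234))), mesh)
    assert [(s.element, s.charge) for s in s0] == \
           [(s.element, s.charge) for s in s1]


# ---------------------------------------------------------------------------
# Tracking and classification
# ---------------------------------------------------------------------------

def _frames_from_positions(positions, charge=1):
    return [[am.PhaseSingularity(t * 10.0, 0, x, y, charge)]
            for t, (x, y) in enumerate(positions)]


def test_fixed_tip_classified_stationary():
    mesh = make_sheet(30, 30)
    frames = _frames_from_positions([(20.0 + 0.2 * (i % 3), 20.0)
                                     for i in range(40)])
    cls = am.track_and_classify(frames, mesh)
    assert list(cls.track_labels.values()) == ["stationary"]
    assert cls.regime == "stationary-only"
    assert cls.rotor_count == pytest.approx(1.0)


def test_drifting_tip_classified_meandering():
    mesh = make_sheet(30, 30)
    frames = _frames_from_positions([(5.0 + 0.5 * i, 10.0)
                                     for i in range(40)])
    cls = am.track_and_classify(frames, mesh)
    assert "meandering" in cls.track_labels.values()
    assert cls.regime == "one-meandering"


def test_no_singularities_regime_none():
    mesh = make_sheet(10, 10)
    cls = am.track_and_classify([[] for _ in range(30)], mesh)
    assert cls.regime == "none"
    assert cls.rotor_count == 0.0


def test_lva_anchoring_detection():
    mesh = make_sheet(30, 30, 1000.0)   # 29 x 29 mm
    lva = np.zeros(mesh.n_elements, bool)
    centres = mesh.element_centers()
    lva[np.hypot(centres[:, 0] - 20.0, centres[:, 1] - 20.0) < 3.0] = True
    anchored = _frames_from_positions([(20.0, 20.0)] * 40)
    away = _frames_from_positions([(5.0, 5.0)] * 40)
    cls_a = am.track_and_classify(anchored, mesh, lva_label=lva)
    cls_b = am.track_and_classify(away, mesh, lva_label=lva)
    assert list(cls_a.anchored_to_lva.values()) == [True]
    assert list(cls_b.anchored_to_lva.values()) == [False]


def test_real_rotor_tracked(rotor_run):
    """The simulated rotor produces a persistent tracked singularity."""
    traj, mesh = rotor_run["traj"], rotor_run["mesh"]
    phase = am.compute_phase(traj)
    i0 = int(np.argmin(np.abs(traj.times - 400.0)))
    frames = [am.detect_singularities(phase[i], mesh, float(traj.times[i]))
              for i in range(i0, i0 + 100, 2)]
    assert sum(len(f) for f in frames) > 30
    cls = am.track_and_classify(frames, mesh)
    assert cls.regime != "none"
    assert cls.rotor_count >= 0.5


# ---------------------------------------------------------------------------
# Pseudo-ECG
# ---------------------------------------------------------------------------

def test_uniform_vm_gives_zero_signal():
    mesh = make_sheet(15, 15)
    t = np.arange(0.0, 100.0, 5.0)
    movie = np.full((t.size, mesh.n_nodes), -30.0)
    ecg = am.pseudo_ecg(_traj_from_vm(mesh, t, movie),
                        np.array([[3.0, 3.0, 20.0]]))
    assert np.abs(ecg).max() < 1e-9


def test_electrode_on_tissue_rejected():
    mesh = make_sheet(10, 10)
    t = np.arange(0.0, 50.0, 5.0)
    movie = np.zeros((t.size, mesh.n_nodes))
    with pytest.raises(ValueError, match="electrode"):
        am.pseudo_ecg(_traj_from_vm(mesh, t, movie),
                      np.array([[2.0, 2.0, 0.0]]))


@pytest.fixture(scope="module")
def plane_wave_traj(calibrated_sigma):
    mesh = make_sheet(51, 9, 400.0)
    props = tm.baseline_properties(mesh, calibrated_sigma)
    scales = tm.node_scale_matrix(mesh, props)
    cols = np.arange(9) * 51
    stim = [Stimulus(np.concatenate([cols, cols + 1, cols + 2]),
                     1.0, 3.0, 60.0)]
    cfg = SolverConfig(output_stride_ms=1.0)
    return solver.run(mesh, props, scales, 60.0, config=cfg, stimuli=stim)


def test_plane_wave_gives_biphasic_deflection(plane_wave_traj):
    ecg = am.pseudo_ecg(plane_wave_traj, np.array([[10.0, 1.8, 15.0]]))[:, 0]
    # positive lobe while the front approaches, negative as it recedes
    assert ecg.max() > 0 and ecg.min() < 0
    assert abs(ecg.min()) > 0.05 * ecg.max()


def test_amplitude_decays_with_distance(plane_wave_traj):
    els = np.array([[10.0, 1.8, z] for z in (10.0, 20.0, 40.0)])
    ecg = am.pseudo_ecg(plane_wave_traj, els)
    amps = np.abs(ecg).max(axis=0)
    assert amps[0] > amps[1] > amps[2]


# ---------------------------------------------------------------------------
# Dominant frequency
# ---------------------------------------------------------------------------

def test_pure_sinusoid_df():
    t = np.arange(0.0, 6000.0, 5.0)
    sig = np.sin(2 * np.pi * 6.0 * t / 1000.0)
    assert am.dominant_frequency(sig, 200.0) == pytest.approx(6.0, abs=0.25)


def test_silent_signal_undefined():
    assert am.dominant_frequency(np.zeros(4000), 200.0) is None


def test_df_needs_four_seconds():
    with pytest.raises(ValueError):
        am.dominant_frequency(np.sin(np.arange(300) * 0.3), 200.0)


def test_paced_cell_df_matches_pacing_rate():
    """A 500 ms pacing cycle shows up as a 2 Hz dominant frequency."""
    from atriasim.cell_dynamics import run_ap
    import numpy as np
    beats = [run_ap(pacing_cl=500.0, n_beats=k + 1).vm for k in range(1)]
    # build a 5 s signal by pacing one cell continuously
    from atriasim import _crn, cell_dynamics as cd
    sc = cd.effective_scales().reshape(1, -1)
    y = _crn.baseline_state().reshape(1, -1)
    sig = []
    for beat in range(10):
        for s in range(100):   # 5 ms sampling, 500 ms cycle
            stim = np.array([25.0]) if s < 1 else np.zeros(1)
            _crn.step_states(y, np.ascontiguousarray(sc), stim, 0.05, 100)
            sig.append(y[0, 0])
    df = am.dominant_frequency(np.array(sig), 200.0)
    assert df == pytest.approx(2.0, abs=0.25)


def test_rotor_df_in_af_band(rotor_run):
    """Sustained re-entry pseudo-ECG peaks inside the clinical AF band."""
    traj = rotor_run["traj"]
    ecg = am.pseudo_ecg(traj, np.array([[35.0, 35.0, 30.0]]))[:, 0]
    fs = 1000.0 / traj.stride_ms
    df = am.dominant_frequency(ecg, fs)
    assert df is not None
    assert 3.5 <= df <= 10.3
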