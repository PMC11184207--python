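"""Shared fixtures.

The expensive tissue-level artefacts (calibrated conductivity, the
sustained-rotor trajectory) are session-scoped so the whole suite pays for
them once.
"""

import numpy as np
import pytest

from atriasim import tissue_model as tm, monodomain_solver as solver
from atriasim import protocols
from atriasim.geometry_synth import make_idealized_atria, make_sheet
from atriasim.monodomain_solver import SolverConfig


@pytest.fixture(scope="session")
def cv_sheet():
    """Standard 30 mm bulk strip at 400 um for CV work."""
    return protocols.cv_measurement_sheet(400.0)


@pytest.fixture(scope="session")
def calibrated_sigma(cv_sheet):
    """Longitudinal conductivity calibrated to an 80 cm/s plane wave."""
    return tm.calibrate_baseline_conductivity(cv_sheet, target_cv_cm_s=80.0)


@pytest.fixture(scope="session")
def demo_atria():
    """Small two-chamber atria at 800 um with PVI applied."""
    mesh = make_idealized_atria(25.0, 25.0, h_um=800.0)
    return protocols.apply_pvi(mesh)


@pytest.fixture(scope="session")
def rotor_run(calibrated_sigma):
    """A sustained single-rotor simulation on a 70 mm sheet (4.4 s).

    The workhorse re-entry trajectory: used for singularity detection on a
    real run, the sustainment verdict, rotor tracking and the
    dominant-frequency band check.
    """
    from atriasim.cell_dynamics import IonicProfile
    mesh = make_sheet(88, 88, h_um=800.0)
    props = tm.baseline_properties(mesh, calibrated_sigma)
    # a short-APD member of the sampled population: rapid repolarisation
    # shortens the re-entry wavelength so the rotor fits the sheet
    profile = IonicProfile(profile_id="fast_repol", scale_IKr=1.5,
                           scale_ICaL=0.7, scale_INa=1.2)
    scales = tm.node_scale_matrix(mesh, props, profile=profile)
    spec = protocols.InductionSpec(n_rotors=1, cores_mm=[(34.8, 34.8)],
                                   window_ms=4400.0, cycle_ms=170.0)
    init = protocols.induce_reentry(mesh, props, scales, spec)
    cfg = SolverConfig(dt_ode=0.05, dt_pde=0.05, output_stride_ms=5.0)
    traj = solver.run(mesh, props, scales, 4400.0, config=cfg,
                      initial_states=init)
    return dict(mesh=mesh, props=props, scales=scales, traj=traj)
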