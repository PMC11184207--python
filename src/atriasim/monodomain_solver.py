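"""2D monodomain reaction–diffusion solver on labelled quad meshes.

Operator splitting per PDE step: the ionic reaction advances with the
compiled cell kernel (Rush–Larsen / Euler), then the transmembrane voltage
diffuses through a pre-assembled finite-element operator.  Diffusion uses
bilinear quads with a 2x2 Gauss-point stiffness matrix per element and a
lumped mass matrix; the conductivity tensor is the fiber-rotated
diag(sigma_l, sigma_t) so anisotropy follows the local fiber angle.
Removed/inactive elements are simply not assembled, which yields no-flux
internal boundaries (ablation lesions and mesh holes).

Voltage is in mV, time in ms, conductivity in mS/mm; the diffusivity seen
by the PDE is D = sigma / (chi * Cm) in mm^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

from . import _crn
from .geometry_synth import TissueMesh
from .tissue_model import TissueProperties, SIGMA_PER_D


class StabilityError(RuntimeError):
    """Raised when the explicit diffusion step violates its CFL-type bound."""


class SolverInstability(RuntimeError):
    """Raised when the voltage diverges during time stepping."""


@dataclass
class SolverConfig:
    """Time-stepping and output configuration."""

    dt_ode: float = 0.02       # ms, reaction substep
    dt_pde: float = 0.02       # ms, diffusion step (multiple of dt_ode)
    output_stride_ms: float = 2.0
    check_every_ms: float = 10.0
    seed: int = 0

    def __post_init__(self):
        n = self.dt_pde / self.dt_ode
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("dt_pde must be a positive multiple of dt_ode")

    @property
    def n_sub(self) -> int:
        return int(round(self.dt_pde / self.dt_ode))


@dataclass
class Stimulus:
    """Current injection on a node set over [t_start, t_start + duration)."""

    nodes: np.ndarray
    t_start: float
    duration: float = 2.0
    amplitude: float = 25.0    # pA/pF


@dataclass
class Trajectory:
    """Vm movie plus final full state of a simulation run."""

    times: np.ndarray          # (T,) ms
    vm: np.ndarray             # (T, n_nodes) float32 mV
    mesh: TissueMesh
    final_states: np.ndarray   # (n_nodes, 21)

    @property
    def stride_ms(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.times)
            f.create_dataset("vm_mv", data=self.vm, compression="gzip")
            f.create_dataset("final_states", data=self.final_states)

    def save_vtk_series(self, directory, every: int = 1) -> None:
        """Write Vm frames as a legacy-VTK POINT_DATA time series."""
        from pathlib import Path
        from .geometry_synth import write_vtk
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        base = directory / "mesh.vtk"
        write_vtk(self.mesh, base)
        for i in range(0, len(self.times), every):
            with open(directory / f"vm_{i:05d}.vtk", "w") as fh:
                fh.write("# vtk DataFile Version 3.0\n"
                         f"vm t={self.times[i]} ms\nASCII\n"
                         "DATASET STRUCTURED_POINTS\n"
                         f"DIMENSIONS {self.mesh.nx} {self.mesh.ny} 1\n"
                         "ORIGIN 0 0 0\n"
                         f"SPACING {self.mesh.h_mm} {self.mesh.h_mm} 1\n"
                         f"POINT_DATA {self.mesh.n_nodes}\n"
                         "SCALARS vm float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.3f}" for v in self.vm[i]) + "\n")

    def extend(self, other: "Trajectory") -> "Trajectory":
        """Concatenate a continuation run (times must continue)."""
        return Trajectory(np.concatenate([self.times, other.times]),
                          np.vstack([self.vm, other.vm]),
                          other.mesh, other.final_states)


def stability_check(config: SolverConfig, props: TissueProperties,
                    mesh: TissueMesh) -> None:
    """Explicit-diffusion bound dt <= h^2 / (4 D_max); raises if violated."""
    ok = mesh.conducting
    if not ok.any():
        return
    d_max = float(props.sigma_l[ok].max()) / SIGMA_PER_D
    if d_max <= 0:
        return
    bound = mesh.h_mm ** 2 / (4.0 * d_max)
    if config.dt_pde > bound:
        raise StabilityError(
            f"dt_pde={config.dt_pde} ms exceeds stability bound "
            f"h^2/(4*D_max)={bound:.4g} ms (h={mesh.h_mm} mm, "
            f"D_max={d_max:.4g} mm^2/ms)")


def assemble_diffusion(mesh: TissueMesh, props: TissueProperties) -> sp.csr_matrix:
    """Assemble A with dV/dt = A V: A = -M_lumped^-1 K / (chi Cm).

    K is the anisotropic bilinear-quad stiffness matrix over conducting
    elements; M is the lumped mass.  Rows of isolated nodes are zero.
    """
    h = mesh.h_mm
    act = np.nonzero(mesh.conducting)[0]
    quads = mesh.element_nodes()[act]
    theta = mesh.fiber_angle[act]
    dl = props.sigma_l[act] / SIGMA_PER_D
    dt_ = props.sigma_t[act] / SIGMA_PER_D
    ct, st = np.cos(theta), np.sin(theta)
    dxx = dl * ct ** 2 + dt_ * st ** 2
    dyy = dl * st ** 2 + dt_ * ct ** 2
    dxy = (dl - dt_) * ct * st

    # shape-function gradients at the 4 Gauss points of a square of side h
    g = 1.0 / np.sqrt(3.0)
    gp = np.array([(-g, -g), (g, -g), (-g, g), (g, g)])
    # local node order (00, 10, 01, 11) in xi, eta in [-1, 1]
    def dshape(xi, eta):
        dxi = 0.25 * np.array([-(1 - eta), (1 - eta), -(1 + eta), (1 + eta)])
        deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 - xi), (1 + xi)])
        return dxi * 2.0 / h, deta * 2.0 / h   # physical gradients

    ne = len(act)
    ke = np.zeros((ne, 4, 4))
    w = (h / 2.0) ** 2   # Gauss weight * |J|
    for xi, eta in gp:
        gx, gy = dshape(xi, eta)
        for i in range(4):
            for j in range(4):
                ke[:, i, j] += w * (
                    dxx * gx[i] * gx[j] + dyy * gy[i] * gy[j]
                    + dxy * (gx[i] * gy[j] + gy[i] * gx[j]))

    n = mesh.n_nodes
    rows = np.repeat(quads, 4, axis=1).ravel()
    cols = np.tile(quads, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    mass = np.zeros(n)
    np.add.at(mass, quads.ravel(), h * h / 4.0)
    inv_m = np.zeros(n)
    live = mass > 0
    inv_m[live] = 1.0 / mass[live]
    return (-sp.diags(inv_m) @ K).tocsr()


def live_nodes(mesh: TissueMesh) -> np.ndarray:
    """Nodes incident to at least one conducting element."""
    quads = mesh.element_nodes()[mesh.conducting]
    mask = np.zeros(mesh.n_nodes, bool)
    mask[quads.ravel()] = True
    return mask


def run(mesh: TissueMesh,
        props: TissueProperties,
        node_scales: np.ndarray,
        duration_ms: float,
        config: SolverConfig | None = None,
        stimuli: list[Stimulus] | None = None,
        initial_states: np.ndarray | None = None,
        t0: float = 0.0,
        diffusion_only: bool = False,
        record: bool = True) -> Trajectory:
    """Advance the monodomain model and record a Vm movie.

    ``node_scales`` is the (n_nodes, 9) matrix from
    :func:`atriasim.tissue_model.node_scale_matrix`.  ``initial_states``
    ((n_nodes, 21)) defaults to the resting cell everywhere.  Raises
    :class:`SolverInstability` if |Vm| exceeds 200 mV.
    """
    config = config or SolverConfig()
    stability_check(config, props, mesh)
    n = mesh.n_nodes
    Y = (initial_states.copy() if initial_states is not None
         else _crn.baseline_states(n))
    if Y.shape != (n, _crn.N_STATE):
        raise ValueError("initial_states has wrong shape")
    v0 = Y[:, 0]
    if not np.isfinite(v0).all() or np.abs(v0).max() > 200.0:
        raise SolverInstability(
            f"initial |Vm| = {np.abs(v0).max():.1f} mV exceeds 200 mV")
    scales = np.ascontiguousarray(node_scales)
    A = assemble_diffusion(mesh, props)
    live = live_nodes(mesh)

    dt = config.dt_pde
    n_steps = int(round(duration_ms / dt))
    stride = max(1, int(round(config.output_stride_ms / dt)))
    check = max(1, int(round(config.check_every_ms / dt)))
    n_frames = n_steps // stride + 1
    vm_movie = np.empty((n_frames, n), np.float32) if record else None
    times = np.empty(n_frames)
    istim = np.zeros(n)
    stimuli = stimuli or []

    frame = 0
    if record:
        vm_movie[0] = Y[:, 0]
    times[0] = t0
    for k in range(n_steps):
        t = t0 + k * dt
        istim[:] = 0.0
        for s in stimuli:
            if s.t_start <= t < s.t_start + s.duration:
                istim[s.nodes] = s.amplitude
        if not diffusion_only:
            try:
                _crn.step_states(Y, scales, istim, config.dt_ode, config.n_sub)
            except (ZeroDivisionError, FloatingPointError) as e:
                raise SolverInstability(
                    f"cell-model arithmetic failure at t = {t:.1f} ms "
                    f"({e})") from e
        v = Y[:, 0]
        v += dt * (A @ v)
        if (k + 1) % check == 0:
            vmax = float(np.abs(v[live]).max()) if live.any() else 0.0
            if vmax > 200.0 or not np.isfinite(vmax):
                raise SolverInstability(
                    f"|Vm| = {vmax:.1f} mV at t = {t + dt:.1f} ms")
        if (k + 1) % stride == 0:
            frame += 1
            if record:
                vm_movie[frame] = v
            times[frame] = t0 + (k + 1) * dt
    return Trajectory(times[:frame + 1],
                      vm_movie[:frame + 1] if record else
                      np.empty((0, n), np.float32),
                      mesh, Y)
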