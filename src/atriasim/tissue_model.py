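"""Per-element conduction and ionic tissue parameters.

Carries the monodomain conductivities (longitudinal/transversal, mS/mm),
the fixed membrane constants, low-voltage-area (LVA) remodelling and
ablation application.  LVA tissue is modelled as slow, strongly
anisotropic, ionically remodelled myocardium: longitudinal conductivity
reduced by 30 %, anisotropy raised to 8:1, and ICaL/INa/IK1 reduced by
50/40/50 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import cell_dynamics as cd
from ._crn import CURRENT_INDEX, N_CURRENTS
from .geometry_synth import TissueMesh, LVAMap

# Monodomain membrane constants (fixed; only conductivity is calibrated).
CM_UF_CM2 = 1.0          # membrane capacitance per area
CHI_PER_CM = 1400.0      # surface-to-volume ratio
#: sigma [mS/mm] = D [mm^2/ms] * SIGMA_PER_D
SIGMA_PER_D = CHI_PER_CM * CM_UF_CM2 / 1000.0   # = 1.4 uF/mm^3

#: LVA ionic remodelling: multipliers composed with the patient profile.
LVA_IONIC = {"ICaL": 0.5, "INa": 0.6, "IK1": 0.5}
LVA_SIGMA_L_FACTOR = 0.7
LVA_ANISOTROPY = 8.0

#: Default bulk anisotropy ratio outside LVAs (longitudinal : transversal).
BULK_ANISOTROPY = 4.0


@dataclass
class TissueProperties:
    """Per-element conductivities and ionic adjustment multipliers."""

    sigma_l: np.ndarray                # (ne,) mS/mm
    sigma_t: np.ndarray                # (ne,) mS/mm
    ionic: np.ndarray                  # (ne, 9) multipliers (LVA remodelling)
    lva_applied: bool = False
    lva_label: np.ndarray | None = None

    def validate(self, mesh: TissueMesh) -> None:
        ok = mesh.conducting
        if not np.all(self.sigma_l[ok] >= self.sigma_t[ok]):
            raise ValueError("sigma_l < sigma_t on conducting elements")
        if not np.all(self.sigma_t[ok] > 0):
            raise ValueError("non-positive transversal conductivity")

    def copy(self) -> "TissueProperties":
        return TissueProperties(self.sigma_l.copy(), self.sigma_t.copy(),
                                self.ionic.copy(), self.lva_applied,
                                None if self.lva_label is None
                                else self.lva_label.copy())


def baseline_properties(mesh: TissueMesh, sigma_l: float = 0.2,
                        anisotropy: float = BULK_ANISOTROPY) -> TissueProperties:
    """Uniform bulk properties: sigma_l everywhere, sigma_t = sigma_l / ratio."""
    ne = mesh.n_elements
    return TissueProperties(
        sigma_l=np.full(ne, sigma_l),
        sigma_t=np.full(ne, sigma_l / anisotropy),
        ionic=np.ones((ne, N_CURRENTS)))


def apply_lva_remodelling(props: TissueProperties,
                          lva: LVAMap) -> TissueProperties:
    """Return properties with LVA remodelling applied on labelled elements.

    Longitudinal conductivity x0.7, anisotropy forced to 8:1 (on the
    element's final sigma_l), ICaL x0.5 / INa x0.6 / IK1 x0.5 composed with
    whatever ionic adjustment is already present.  Idempotent by flag.
    """
    if props.lva_applied:
        return props
    out = props.copy()
    m = lva.label
    out.sigma_l[m] = LVA_SIGMA_L_FACTOR * props.sigma_l[m]
    out.sigma_t[m] = out.sigma_l[m] / LVA_ANISOTROPY
    for cur, mult in LVA_IONIC.items():
        out.ionic[m, CURRENT_INDEX[cur]] *= mult
    out.lva_applied = True
    out.lva_label = m.copy()
    return out


def apply_ablation(mesh: TissueMesh, lesion: np.ndarray) -> TissueMesh:
    """Return a mesh with lesion elements flagged removed (no-flux holes)."""
    lesion = np.asarray(lesion, dtype=int)
    if lesion.size == 0:
        warnings.warn("empty lesion set: ablation is a no-op")
        return mesh.copy()
    if not mesh.active[lesion].all():
        raise ValueError("lesion contains elements outside active tissue")
    out = mesh.copy()
    out.removed[lesion] = True
    return out


def node_scale_matrix(mesh: TissueMesh, props: TissueProperties,
                      profile=None, drug=None,
                      remodelling=cd.PERSISTENT_AF_REMODELLING) -> np.ndarray:
    """Effective per-node (n_nodes, 9) conductance scalings for the solver.

    Element-level scalings (profile x regional adjustment x LVA ionic x
    drug block x chronic remodelling) are averaged onto incident nodes;
    nodes with no conducting neighbour element get the bulk scaling.
    """
    base = cd.effective_scales(profile, drug=drug, remodelling=remodelling)
    ne = mesh.n_elements
    elem_sc = np.tile(base, (ne, 1))
    for kind, adj in cd.REGION_ADJUSTMENTS.items():
        if not adj:
            continue
        mask = mesh.region == list(cd.RegionKind).index(kind)
        for cur, mult in adj.items():
            elem_sc[mask, CURRENT_INDEX[cur]] *= mult
    elem_sc *= props.ionic
    quads = mesh.element_nodes()[mesh.conducting]
    n = mesh.n_nodes
    rows = quads.ravel()
    cols = np.repeat(np.arange(quads.shape[0]), 4)
    inc = sp.coo_matrix((np.ones(rows.size), (rows, cols)),
                        shape=(n, quads.shape[0])).tocsr()
    counts = np.asarray(inc.sum(axis=1)).ravel()
    out = inc @ elem_sc[mesh.conducting]
    has = counts > 0
    out[has] /= counts[has, None]
    out[~has] = base
    return out


def calibrate_baseline_conductivity(mesh: TissueMesh, profile=None,
                                    target_cv_cm_s: float = 80.0,
                                    tol_cm_s: float = 1.0,
                                    sigma_bounds=(0.05, 1.4),
                                    anisotropy: float = BULK_ANISOTROPY,
                                    **cv_kwargs) -> float:
    """Bisection over sigma_l until the measured plane-wave CV hits target.

    Returns the calibrated longitudinal conductivity (mS/mm); the search
    interval must bracket the target.  CV is re-measured with
    :func:`atriasim.protocols.measure_cv` on the given sheet.
    """
    from .protocols import measure_cv, ConductionBlock

    def cv_of(sigma):
        props = baseline_properties(mesh, sigma, anisotropy)
        try:
            return measure_cv(mesh, props, profile=profile, **cv_kwargs)
        except ConductionBlock:
            return 0.0

    lo, hi = sigma_bounds
    cv_lo, cv_hi = cv_of(lo), cv_of(hi)
    if not (cv_lo < target_cv_cm_s < cv_hi):
        raise ValueError(
            f"search interval does not bracket target: CV({lo})={cv_lo:.1f}, "
            f"CV({hi})={cv_hi:.1f}, target={target_cv_cm_s}")
    # quadratic-scaling warm start (CV ~ sqrt(sigma)) then bisection
    sigma = lo + (hi - lo) / 2.0
    for _ in range(40):
        cv = cv_of(sigma)
        if abs(cv - target_cv_cm_s) <= tol_cm_s:
            return float(sigma)
        if cv < target_cv_cm_s:
            lo = sigma
        else:
            hi = sigma
        sigma = 0.5 * (lo + hi)
    raise RuntimeError("conductivity calibration did not converge")
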