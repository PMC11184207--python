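"""Synthetic labelled tissue geometries and probabilistic low-voltage maps.

Generates the study's tissue substrates at desk scale: calibration cables
and sheets, and an idealized two-chamber atrial template that stands in for
imaging-derived anatomy.  Geometry is a 2D manifold (planar-unfolded
chamber sheets joined by inter-atrial bridges): the re-entrant phenomena of
interest are surface-dominated, and chamber "volume" maps to sheet area by
a fixed-thickness convention A = V / t (t = 10 mm), so requested volumes
(mL) drive proportional, monotone geometric scaling.

All meshes are structured quadrilateral grids (edge length ``h``, default
400 um) with per-element fiber angles, region labels
(:class:`~atriasim.cell_dynamics.RegionKind`), landmark bitmasks and
active/removed flags.  Holes (valve annuli, vein lumina, caval ostia) are
inactive elements; ablation lesions are flagged ``removed``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from enum import IntFlag, auto

import numpy as np
import scipy.ndimage
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .cell_dynamics import RegionKind

REGION_CODES = {r: i for i, r in enumerate(RegionKind)}
REGION_FROM_CODE = {i: r for r, i in REGION_CODES.items()}


class Landmark(IntFlag):
    """Anatomical landmark tags (an element may carry several)."""

    PV_LS = auto()          # left-superior pulmonary vein sleeve
    PV_LI = auto()          # left-inferior
    PV_RS = auto()          # right-superior
    PV_RI = auto()          # right-inferior
    POSTERIOR_WALL = auto()
    ANTERIOR_WALL = auto()
    ROOF = auto()
    MI_CORRIDOR = auto()    # mitral isthmus (annulus <-> li-PV)
    CTI_CORRIDOR = auto()   # cavo-tricuspid isthmus (annulus <-> IVC)
    APPENDAGE = auto()
    INTERATRIAL = auto()    # Bachmann / coronary-sinus bridges
    MILINE_PATH = auto()    # anterior mitral line (annulus -> roof edge)
    ROOF_LINE = auto()      # dome line between superior PVs
    MARSHALL_SEG = auto()   # Marshall-bundle surrogate segment


PV_TAGS = (Landmark.PV_LS, Landmark.PV_LI, Landmark.PV_RS, Landmark.PV_RI)

CHAMBER_LA = 0
CHAMBER_RA = 1
CHAMBER_NONE = -1


@dataclass
class TissueMesh:
    """Structured quadrilateral tissue mesh with labels.

    Node (ix, iy) has index iy*nx + ix and coordinates (ix*h, iy*h) mm.
    Element (ex, ey) has index ey*(nx-1) + ex.
    """

    nx: int
    ny: int
    h_mm: float
    active: np.ndarray          # (ne,) bool: structural tissue
    removed: np.ndarray         # (ne,) bool: ablated
    fiber_angle: np.ndarray     # (ne,) rad
    region: np.ndarray          # (ne,) int8 codes into RegionKind
    landmark: np.ndarray        # (ne,) int64 bitmask
    chamber: np.ndarray         # (ne,) int8: 0 LA, 1 RA, -1 none
    name: str = "mesh"

    # ---------------- basic queries ----------------

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def n_elements(self) -> int:
        return (self.nx - 1) * (self.ny - 1)

    @property
    def conducting(self) -> np.ndarray:
        """Active and not ablated."""
        return self.active & ~self.removed

    def node_coords(self) -> np.ndarray:
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        return np.column_stack([ix.ravel(), iy.ravel()]) * self.h_mm

    def element_nodes(self) -> np.ndarray:
        """(ne, 4) node indices per quad: (00, 10, 01, 11)."""
        ex, ey = np.meshgrid(np.arange(self.nx - 1), np.arange(self.ny - 1))
        n00 = ey.ravel() * self.nx + ex.ravel()
        return np.column_stack([n00, n00 + 1, n00 + self.nx, n00 + self.nx + 1])

    def element_centers(self) -> np.ndarray:
        ex, ey = np.meshgrid(np.arange(self.nx - 1), np.arange(self.ny - 1))
        return (np.column_stack([ex.ravel(), ey.ravel()]) + 0.5) * self.h_mm

    def elements_with(self, tag: Landmark) -> np.ndarray:
        """Indices of conducting elements carrying a landmark tag."""
        return np.nonzero(((self.landmark & int(tag)) != 0) & self.conducting)[0]

    def elements_in_region(self, kind: RegionKind) -> np.ndarray:
        return np.nonzero((self.region == REGION_CODES[kind]) & self.conducting)[0]

    def element_area(self) -> float:
        return self.h_mm ** 2

    def chamber_area(self, chamber: int) -> float:
        return float(((self.chamber == chamber) & self.conducting).sum()) \
            * self.element_area()

    # ---------------- connectivity ----------------

    def node_adjacency(self) -> sp.csr_matrix:
        """Node graph induced by conducting elements (all 6 pairs per quad)."""
        quads = self.element_nodes()[self.conducting]
        pairs = []
        for a, b in ((0, 1), (0, 2), (1, 3), (2, 3), (0, 3), (1, 2)):
            pairs.append(quads[:, [a, b]])
        ij = np.vstack(pairs)
        n = self.n_nodes
        m = sp.coo_matrix((np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(n, n))
        return (m + m.T).tocsr()

    def node_components(self) -> np.ndarray:
        """Connected-component label per node (isolated nodes get their own)."""
        _, labels = connected_components(self.node_adjacency(), directed=False)
        return labels

    def connected(self, elems_a: np.ndarray, elems_b: np.ndarray) -> bool:
        """True if any node of elems_a reaches any node of elems_b."""
        labels = self.node_components()
        quads = self.element_nodes()
        la = np.unique(labels[quads[np.asarray(elems_a)].ravel()])
        lb = np.unique(labels[quads[np.asarray(elems_b)].ravel()])
        return bool(np.intersect1d(la, lb).size)

    def copy(self) -> "TissueMesh":
        return replace(self,
                       active=self.active.copy(), removed=self.removed.copy(),
                       fiber_angle=self.fiber_angle.copy(),
                       region=self.region.copy(), landmark=self.landmark.copy(),
                       chamber=self.chamber.copy())


# ---------------------------------------------------------------------------
# Calibration geometries
# ---------------------------------------------------------------------------

def _blank(nx: int, ny: int, h_mm: float, name: str) -> TissueMesh:
    ne = (nx - 1) * (ny - 1)
    return TissueMesh(
        nx=nx, ny=ny, h_mm=h_mm,
        active=np.ones(ne, bool), removed=np.zeros(ne, bool),
        fiber_angle=np.zeros(ne), region=np.zeros(ne, np.int8),
        landmark=np.zeros(ne, np.int64),
        chamber=np.full(ne, CHAMBER_NONE, np.int8), name=name)


def make_cable(n_nodes: int, h_um: float = 400.0) -> TissueMesh:
    """1D strand (one element row); length = (n_nodes - 1) * h."""
    if n_nodes < 3:
        raise ValueError("cable needs at least 3 nodes")
    return _blank(n_nodes, 2, h_um / 1000.0, "cable")


def make_sheet(nx: int, ny: int, h_um: float = 400.0,
               fiber_angle_deg: float = 0.0) -> TissueMesh:
    """Rectangular sheet of nx x ny nodes with uniform fiber direction."""
    if nx < 2 or ny < 2 or h_um <= 0:
        raise ValueError("invalid sheet dimensions")
    m = _blank(nx, ny, h_um / 1000.0, "sheet")
    m.fiber_angle[:] = np.deg2rad(fiber_angle_deg)
    return m


# ---------------------------------------------------------------------------
# Idealized two-chamber atria
# ---------------------------------------------------------------------------

#: Fixed-thickness convention mapping chamber volume to sheet area:
#: A = V / CHAMBER_THICKNESS_MM.  10 mm yields realistic epicardial
#: surface areas (a 105 mL left atrium unfolds to 105 cm^2) and makes
#: area strictly proportional to the requested volume.
CHAMBER_THICKNESS_MM = 10.0


def chamber_area_mm2(volume_ml: float) -> float:
    """Sheet area assigned to a chamber of given volume (fixed thickness)."""
    return float(volume_ml * 1000.0 / CHAMBER_THICKNESS_MM)


def _dims(area: float, aspect: float = 4.0 / 3.0) -> tuple[float, float]:
    w = float(np.sqrt(area * aspect))
    return w, area / w


def _in_rect(c, x0, y0, x1, y1):
    return (c[:, 0] >= x0) & (c[:, 0] < x1) & (c[:, 1] >= y0) & (c[:, 1] < y1)


def _in_disc(c, cx, cy, r):
    return (c[:, 0] - cx) ** 2 + (c[:, 1] - cy) ** 2 < r ** 2


def _near_segment(c, p0, p1, width):
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    t = np.clip(((c - p0) @ d) / L2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.hypot(*(c - proj).T) < width


def make_idealized_atria(ra_volume_ml: float = 127.0,
                         la_volume_ml: float = 105.0,
                         h_um: float = 400.0,
                         seed: int = 0) -> TissueMesh:
    """Two planar-unfolded chamber sheets joined by two bridges.

    The RA sheet sits left, the LA sheet right, separated by an inactive
    gap crossed by a roof-level (Bachmann) and a floor-level
    (coronary-sinus) bridge.  Every landmark region of the template is
    checked non-empty; too-small volumes for the requested ``h`` raise.
    The template is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    if ra_volume_ml <= 20 or la_volume_ml <= 20:
        raise ValueError("chamber volumes must exceed 20 mL")
    h = h_um / 1000.0
    wra, hra = _dims(chamber_area_mm2(ra_volume_ml))
    wla, hla = _dims(chamber_area_mm2(la_volume_ml))
    gap = max(4.0 * h, 0.06 * (wra + wla))
    width, height = wra + gap + wla, max(hra, hla)
    nx, ny = int(np.ceil(width / h)) + 2, int(np.ceil(height / h)) + 2
    m = _blank(nx, ny, h, "idealized_atria")
    c = m.element_centers()

    active = np.zeros(m.n_elements, bool)
    region = np.zeros(m.n_elements, np.int8)
    landmark = np.zeros(m.n_elements, np.int64)
    chamber = np.full(m.n_elements, CHAMBER_NONE, np.int8)
    fiber = np.zeros(m.n_elements)

    # ---- right atrium ----
    ra = _in_rect(c, 0, 0, wra, hra)
    sra = min(wra, hra)
    tv = (0.45 * wra, 0.30 * hra, 0.11 * sra)     # tricuspid annulus hole
    ivc = (0.82 * wra, 0.10 * hra, 0.07 * sra)    # inferior vena cava
    svc = (0.82 * wra, 0.90 * hra, 0.07 * sra)    # superior vena cava
    holes_ra = (_in_disc(c, *tv) | _in_disc(c, *ivc) | _in_disc(c, *svc))
    active |= ra & ~holes_ra
    chamber[ra] = CHAMBER_RA
    region[ra] = REGION_CODES[RegionKind.RA_BASELINE]

    av_ra = ra & _in_disc(c, tv[0], tv[1], tv[2] + 2.5 * h) & ~holes_ra
    region[av_ra] = REGION_CODES[RegionKind.AV_RING]
    crista = ra & _in_rect(c, 0.68 * wra, 0.15 * hra,
                           0.68 * wra + max(0.05 * wra, 1.5 * h), 0.85 * hra)
    region[crista] = REGION_CODES[RegionKind.CRISTA_TERMINALIS]
    fiber[crista] = np.pi / 2.0
    raa = ra & _in_rect(c, 0, 0.70 * hra, 0.16 * wra, hra) & ~holes_ra
    region[raa] = REGION_CODES[RegionKind.APPENDAGE_PECTINATE]
    landmark[raa] |= Landmark.APPENDAGE
    cti = ra & _near_segment(c, (tv[0], tv[1]), (ivc[0], ivc[1]),
                             max(1.1 * h, 0.02 * sra)) & ~holes_ra
    landmark[cti] |= Landmark.CTI_CORRIDOR

    # ---- left atrium ----
    ox = wra + gap
    la = _in_rect(c, ox, 0, ox + wla, hla)
    sla = min(wla, hla)
    cla = c - np.array([ox, 0.0])
    mv = (0.42 * wla, 0.14 * hla, 0.10 * sla)     # mitral annulus hole
    pv_centers = {
        Landmark.PV_LS: (0.58 * wla, 0.80 * hla),
        Landmark.PV_LI: (0.58 * wla, 0.48 * hla),
        Landmark.PV_RS: (0.87 * wla, 0.80 * hla),
        Landmark.PV_RI: (0.87 * wla, 0.48 * hla),
    }
    r_lumen = 0.050 * sla
    r_sleeve = max(0.105 * sla, r_lumen + 1.6 * h)
    holes_la = _in_disc(cla, *mv)
    for (px, py) in pv_centers.values():
        holes_la |= _in_disc(cla, px, py, r_lumen)
    active |= la & ~holes_la
    chamber[la] = CHAMBER_LA
    region[la] = REGION_CODES[RegionKind.LA_BODY]

    for tag, (px, py) in pv_centers.items():
        sleeve = la & _in_disc(cla, px, py, r_sleeve) & ~holes_la
        region[sleeve] = REGION_CODES[RegionKind.PV_SLEEVE]
        landmark[sleeve] |= tag
    av_la = la & _in_disc(cla, mv[0], mv[1], mv[2] + 2.5 * h) & ~holes_la
    region[av_la] = REGION_CODES[RegionKind.AV_RING]

    post = la & _in_rect(cla, 0.52 * wla, 0.38 * hla, 0.93 * wla, 0.90 * hla) \
        & (region != REGION_CODES[RegionKind.PV_SLEEVE]) & ~holes_la
    landmark[post] |= Landmark.POSTERIOR_WALL
    roof = la & (cla[:, 1] >= 0.92 * hla)
    landmark[roof] |= Landmark.ROOF
    ant = la & _in_rect(cla, 0.0, 0.30 * hla, 0.45 * wla, 0.92 * hla) & ~holes_la
    landmark[ant] |= Landmark.ANTERIOR_WALL
    laa = la & _in_rect(cla, 0.0, 0.55 * hla, 0.14 * wla, 0.92 * hla) & ~holes_la
    region[laa] = REGION_CODES[RegionKind.APPENDAGE_PECTINATE]
    landmark[laa] |= Landmark.APPENDAGE

    wline = max(1.1 * h, 0.015 * sla)
    mi = la & _near_segment(cla, (mv[0], mv[1]), pv_centers[Landmark.PV_LI],
                            wline) & ~holes_la
    landmark[mi] |= Landmark.MI_CORRIDOR
    miline = la & _near_segment(cla, (mv[0], mv[1]), (0.30 * wla, hla), wline) \
        & ~holes_la
    landmark[miline] |= Landmark.MILINE_PATH
    roofline = la & _near_segment(cla, pv_centers[Landmark.PV_LS],
                                  pv_centers[Landmark.PV_RS], wline) & ~holes_la
    landmark[roofline] |= Landmark.ROOF_LINE
    marshall = la & _near_segment(cla, (mv[0] - 0.08 * wla, mv[1]),
                                  (pv_centers[Landmark.PV_LI][0] - 0.10 * wla,
                                   pv_centers[Landmark.PV_LI][1]), wline) & ~holes_la
    landmark[marshall] |= Landmark.MARSHALL_SEG

    # ---- inter-atrial bridges ----
    hmin = min(hra, hla)
    for y0f, kind in ((0.80, RegionKind.RA_BASELINE),
                      (0.10, RegionKind.CS_SEPTUM)):
        y0 = y0f * hmin
        bridge = _in_rect(c, wra - 1.5 * h, y0, ox + 1.5 * h,
                          y0 + max(2.0 * h, 0.04 * hmin))
        newly = bridge & ~active
        active |= bridge
        region[newly] = REGION_CODES[kind]
        landmark[bridge] |= Landmark.INTERATRIAL
        chamber[newly] = CHAMBER_NONE

    m.active = active
    m.region = region
    m.landmark = landmark
    m.chamber = chamber
    m.fiber_angle = fiber

    required = list(PV_TAGS) + [Landmark.POSTERIOR_WALL, Landmark.ANTERIOR_WALL,
                                Landmark.ROOF, Landmark.MI_CORRIDOR,
                                Landmark.CTI_CORRIDOR, Landmark.APPENDAGE,
                                Landmark.INTERATRIAL, Landmark.MILINE_PATH,
                                Landmark.ROOF_LINE, Landmark.MARSHALL_SEG]
    for tag in required:
        if m.elements_with(tag).size == 0:
            raise ValueError(
                f"volume too small to host landmark {tag.name} at h={h_um} um")
    return m


# ---------------------------------------------------------------------------
# LVA probability fields
# ---------------------------------------------------------------------------

@dataclass
class LVAMap:
    """Per-element LVA probability and the thresholded binary labelling."""

    probability: np.ndarray            # (ne,) in [0,1]
    label: np.ndarray                  # (ne,) bool
    target_fraction: float = 0.15

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.probability, self.label]),
                   delimiter=",", header="probability,label", comments="")


def make_lva_probability_field(mesh: TissueMesh, smoothness_mm: float = 6.0,
                               seed: int = 0,
                               wall_bias: float = 0.35) -> np.ndarray:
    """Smooth random field in [0,1] marking likely low-voltage remodelling.

    Gaussian-smoothed white noise on the element lattice, rescaled to
    [0, 1], with an additive bias toward the anterior/posterior-wall
    landmarks where clinical low-voltage substrate is most frequent.
    """
    rng = np.random.default_rng(seed)
    shape = (mesh.ny - 1, mesh.nx - 1)
    noise = rng.standard_normal(shape)
    sigma = max(smoothness_mm / mesh.h_mm, 1e-6)
    smooth = scipy.ndimage.gaussian_filter(noise, sigma, mode="nearest").ravel()
    lo, hi = smooth.min(), smooth.max()
    p = (smooth - lo) / (hi - lo) if hi > lo else np.full(smooth.size, 0.5)
    bias = ((mesh.landmark & int(Landmark.POSTERIOR_WALL | Landmark.ANTERIOR_WALL))
            != 0).astype(float)
    p = p + wall_bias * bias
    p[~mesh.active] = 0.0
    return np.clip(p / max(p.max(), 1e-12), 0.0, 1.0)


def threshold_lva(field: np.ndarray, mesh: TissueMesh,
                  fraction: float = 0.15) -> LVAMap:
    """Greedy per-chamber thresholding of the probability field.

    Elements are taken in descending probability (ties broken by element
    index) until the labelled area fraction of each chamber reaches
    ``fraction``; deterministic given the field.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    label = np.zeros(mesh.n_elements, bool)
    for chamber in (CHAMBER_LA, CHAMBER_RA):
        idx = np.nonzero((mesh.chamber == chamber) & mesh.conducting)[0]
        if idx.size == 0:
            continue
        need = int(np.ceil(fraction * idx.size - 1e-9))
        order = idx[np.lexsort((idx, -field[idx]))]
        label[order[:need]] = True
    return LVAMap(probability=np.asarray(field, float), label=label,
                  target_fraction=fraction)


# ---------------------------------------------------------------------------
# Legacy VTK I/O (ASCII)
# ---------------------------------------------------------------------------

def write_vtk(mesh: TissueMesh, path, lva: LVAMap | None = None) -> None:
    """Write the mesh as legacy ASCII VTK UNSTRUCTURED_GRID with CELL_DATA."""
    pts = mesh.node_coords()
    quads = mesh.element_nodes()
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write(f"atriasim nx={mesh.nx} ny={mesh.ny} h={mesh.h_mm} name={mesh.name}\n")
    buf.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} float\n")
    for x, y in pts:
        buf.write(f"{x:.6g} {y:.6g} 0\n")
    ne = mesh.n_elements
    buf.write(f"CELLS {ne} {5 * ne}\n")
    for q in quads:
        buf.write(f"4 {q[0]} {q[1]} {q[3]} {q[2]}\n")
    buf.write(f"CELL_TYPES {ne}\n")
    buf.write("9\n" * ne)
    buf.write(f"CELL_DATA {ne}\n")
    arrays = {
        "region": mesh.region.astype(int),
        "landmark": mesh.landmark.astype(int),
        "removed": mesh.removed.astype(int),
        "active": mesh.active.astype(int),
        "chamber": mesh.chamber.astype(int),
    }
    if lva is not None:
        arrays["lva"] = lva.label.astype(int)
    for name, arr in arrays.items():
        buf.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
        buf.write("\n".join(str(v) for v in arr) + "\n")
    buf.write("SCALARS fiber_angle float 1\nLOOKUP_TABLE default\n")
    buf.write("\n".join(f"{v:.6g}" for v in mesh.fiber_angle) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_vtk(path) -> TissueMesh:
    """Read a mesh previously written by :func:`write_vtk`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = dict(kv.split("=", 1) for kv in lines[1].split() if "=" in kv)
    nx, ny, h = int(meta["nx"]), int(meta["ny"]), float(meta["h"])
    m = _blank(nx, ny, h, meta.get("name", "mesh"))
    i = next(k for k, ln in enumerate(lines) if ln.startswith("CELL_DATA"))
    arrays: dict[str, np.ndarray] = {}
    k = i + 1
    ne = m.n_elements
    while k < len(lines):
        if lines[k].startswith("SCALARS"):
            name = lines[k].split()[1]
            vals: list[str] = []
            k += 2
            while len(vals) < ne:
                vals.extend(lines[k].split())
                k += 1
            arrays[name] = np.array(vals, float)
        else:
            k += 1
    m.region = arrays["region"].astype(np.int8)
    m.landmark = arrays["landmark"].astype(np.int64)
    m.removed = arrays["removed"].astype(bool)
    m.active = arrays["active"].astype(bool)
    m.chamber = arrays["chamber"].astype(np.int8)
    m.fiber_angle = arrays["fiber_angle"]
    return m
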