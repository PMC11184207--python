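"""Virtual-patient cohort: sampling, calibration and assembly.

The population-of-models workflow: sample per-current conductance
multipliers uniformly around the baseline (default +-50 %), keep the
profiles whose single-cell biomarkers fall within physiological acceptance
intervals, pair them with anatomy scales drawn from the clinical chamber
volume distributions (RA 127 +- 51 mL, LA 105 +- 39 mL), and duplicate
every patient into with/without low-voltage-area twins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cell_dynamics as cd
from ._crn import CURRENT_NAMES


@dataclass(frozen=True)
class VirtualPatient:
    """One virtual patient: profile x anatomy x LVA status."""

    patient_id: str
    profile: cd.IonicProfile
    anatomy_id: str
    ra_volume_ml: float
    la_volume_ml: float
    has_lva: bool
    erp_ms: float | None = None   # filled by the tissue ERP protocol

    def __post_init__(self):
        if self.ra_volume_ml <= 0 or self.la_volume_ml <= 0:
            raise ValueError("chamber volumes must be positive")


@dataclass(frozen=True)
class CalibrationRanges:
    """Acceptance intervals for single-cell biomarkers (lower, upper)."""

    apd90_ms: tuple = (100.0, 300.0)
    resting_vm_mv: tuple = (-86.0, -65.0)
    peak_vm_mv: tuple = (5.0, 45.0)
    dvdt_max_v_s: tuple = (40.0, 400.0)

    def __post_init__(self):
        for name, (lo, hi) in asdict(self).items():
            if not lo < hi:
                raise ValueError(f"empty interval for {name}")

    def check(self, bm: cd.CellBiomarkers) -> list[str]:
        """Names of biomarkers falling outside their interval."""
        out = []
        for name, (lo, hi) in asdict(self).items():
            v = getattr(bm, name)
            if not (lo <= v <= hi):
                out.append(name.split("_")[0].upper() if name.startswith("apd")
                           else name)
        return out


#: Default acceptance intervals for persistent-AF human atrial myocytes
#: paced at 1 Hz (APD90 and upstroke measured on the 0.5 ms-sampled trace).
DEFAULT_CALIBRATION_RANGES = CalibrationRanges()


def sample_profiles(n: int, spread: float = 0.5, seed: int = 0,
                    per_current_spread: dict | None = None
                    ) -> list[cd.IonicProfile]:
    """Sample ionic profiles with uniform multipliers in [1-spread, 1+spread].

    Multipliers are drawn independently per current; ``per_current_spread``
    overrides the spread for named currents.  Reproducible under seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < spread <= 1.0):
        raise ValueError("spread must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        kw = {}
        for cur in CURRENT_NAMES:
            s = (per_current_spread or {}).get(cur, spread)
            kw[f"scale_{cur}"] = float(rng.uniform(1.0 - s, 1.0 + s))
        out.append(cd.IonicProfile(profile_id=f"p{k:03d}", **kw))
    return out


def calibrate_profiles(profiles: list[cd.IonicProfile],
                       ranges: CalibrationRanges = DEFAULT_CALIBRATION_RANGES,
                       pacing_cl: float = 1000.0, n_beats: int = 4,
                       ) -> tuple[list[cd.IonicProfile], pd.DataFrame]:
    """Keep profiles whose biomarkers fall inside all acceptance intervals.

    Returns (accepted, report); the report lists per-profile biomarkers and
    rejection reasons.  An empty accepted set warns rather than raising.
    """
    import warnings

    rows, accepted = [], []
    for p in profiles:
        try:
            bm = cd.measure_biomarkers(cd.run_ap(p, pacing_cl=pacing_cl,
                                                 n_beats=n_beats))
            reasons = ranges.check(bm)
            row = dict(profile_id=p.profile_id, apd90_ms=bm.apd90_ms,
                       resting_vm_mv=bm.resting_vm_mv,
                       peak_vm_mv=bm.peak_vm_mv,
                       dvdt_max_v_s=bm.dvdt_max_v_s)
        except (cd.NoUpstrokeError, cd.IntegrationError) as e:
            reasons = [type(e).__name__]
            row = dict(profile_id=p.profile_id, apd90_ms=np.nan,
                       resting_vm_mv=np.nan, peak_vm_mv=np.nan,
                       dvdt_max_v_s=np.nan)
        row["accepted"] = not reasons
        row["rejection_reasons"] = ";".join(reasons)
        rows.append(row)
        if not reasons:
            accepted.append(p)
    if not accepted:
        warnings.warn("calibration accepted no profiles")
    return accepted, pd.DataFrame(rows)


def sample_anatomy_scales(n: int, seed: int = 0,
                          ra_mean: float = 127.0, ra_sd: float = 51.0,
                          la_mean: float = 105.0, la_sd: float = 39.0,
                          min_ml: float = 20.0) -> list[tuple[float, float]]:
    """(ra_volume_ml, la_volume_ml) pairs from truncated normals (> 20 mL)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def draw(mean, sd, size):
        out = np.empty(0)
        while out.size < size:
            x = rng.normal(mean, sd, size * 2)
            out = np.concatenate([out, x[x > min_ml]])
        return out[:size]

    ra = draw(ra_mean, ra_sd, n)
    la = draw(la_mean, la_sd, n)
    return [(float(r), float(l)) for r, l in zip(ra, la)]


def build_cohort(profiles: list[cd.IonicProfile],
                 anatomies: list[tuple[float, float]],
                 with_and_without_lva: bool = True) -> list[VirtualPatient]:
    """Cartesian cohort assembly: |profiles| x |anatomies| x (2 or 1).

    The LVA-present patient shares profile and anatomy with its LVA-absent
    twin.  Pure function of its arguments.
    """
    if not profiles or not anatomies:
        raise ValueError("need at least one profile and one anatomy")
    ids = [p.profile_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate profile ids in cohort")
    lva_states = (False, True) if with_and_without_lva else (False,)
    out = []
    for p in profiles:
        for a, (ra, la) in enumerate(anatomies):
            for has_lva in lva_states:
                out.append(VirtualPatient(
                    patient_id=f"{p.profile_id}-a{a:02d}-"
                               f"{'lva' if has_lva else 'nolva'}",
                    profile=p, anatomy_id=f"a{a:02d}",
                    ra_volume_ml=ra, la_volume_ml=la, has_lva=has_lva))
    return out


def cohort_table(cohort: list[VirtualPatient]) -> pd.DataFrame:
    """Flat cohort table (CSV-ready)."""
    return pd.DataFrame([
        dict(patient_id=p.patient_id, profile_id=p.profile.profile_id,
             anatomy_id=p.anatomy_id, ra_ml=p.ra_volume_ml,
             la_ml=p.la_volume_ml, has_lva=p.has_lva, erp_ms=p.erp_ms)
        for p in cohort])
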