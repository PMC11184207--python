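"""Trial engine: lesions, efficacy accounting, stratification, campaigns."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from atriasim import trial_engine as te
from atriasim import cohort
from atriasim.cell_dynamics import IonicProfile
from atriasim.geometry_synth import (Landmark, CHAMBER_LA, CHAMBER_RA,
                                     make_sheet, make_lva_probability_field,
                                     threshold_lva)
from atriasim.trial_engine import (PatientFeatures, Recommendation,
                                   THERAPIES, TrialRecord, build_lesion_set,
                                   efficacy_table, planned_run_count,
                                   stratify)


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

def test_composite_lesions_union_their_parts(demo_atria):
    mi = build_lesion_set(demo_atria, THERAPIES["MiLine"])
    both = build_lesion_set(demo_atria, THERAPIES["MiLine+CTI"])
    cti = build_lesion_set(demo_atria, te.Therapy("CTI", ("CTI",)))
    assert set(both) == set(mi) | set(cti)


def test_lva_lesion_on_absent_patient_warns_empty(demo_atria):
    with pytest.warns(UserWarning, match="LVA-absent"):
        lesion = build_lesion_set(demo_atria, THERAPIES["LVA_LA"],
                                  lva_label=None)
    assert lesion.size == 0


def test_lva_lesion_targets_named_chamber(demo_atria):
    field = make_lva_probability_field(demo_atria, seed=2)
    lva = threshold_lva(field, demo_atria, 0.15)
    la = build_lesion_set(demo_atria, THERAPIES["LVA_LA"], lva.label)
    assert la.size > 0
    assert np.all(demo_atria.chamber[la] == CHAMBER_LA)
    both = build_lesion_set(demo_atria, THERAPIES["LVA_LA-RA+CTI"], lva.label)
    assert (demo_atria.chamber[both] == CHAMBER_RA).any()


def test_missing_landmark_named_in_error():
    plain = make_sheet(12, 12)
    with pytest.raises(ValueError, match="MILINE_PATH"):
        build_lesion_set(plain, THERAPIES["MiLine+CTI"])


def test_pwi_box_disconnects_posterior_interior(demo_atria):
    from atriasim import tissue_model as tm
    lesion = build_lesion_set(demo_atria, THERAPIES["PWI"])
    cut = tm.apply_ablation(demo_atria, lesion)
    pw = cut.elements_with(Landmark.POSTERIOR_WALL)
    assert pw.size > 0   # interior survives
    c = cut.element_centers()
    la = np.nonzero((cut.chamber == CHAMBER_LA) & cut.conducting)[0]
    centre = c[pw].mean(axis=0)
    far = la[np.hypot(c[la, 0] - centre[0], c[la, 1] - centre[1]) > 18.0]
    assert not cut.connected(pw, far)


# ---------------------------------------------------------------------------
# Efficacy
# ---------------------------------------------------------------------------

def _rec(pid, therapy, outcome, lva):
    return TrialRecord(patient_id=pid, therapy=therapy, outcome=outcome,
                       has_lva=lva)


def test_all_terminated_is_100_percent():
    recs = [_rec(f"p{i}", "MiLine", "terminated", i % 2 == 0)
            for i in range(6)]
    table = efficacy_table(recs)
    assert (table.total_pct == 100.0).all()


def test_efficacy_counts_match_bruteforce_tally():
    rng = np.random.default_rng(5)
    recs = []
    for i in range(200):
        recs.append(_rec(f"p{i}", rng.choice(["A", "B"]),
                         rng.choice(["terminated", "sustained"]),
                         bool(rng.integers(2))))
    table = efficacy_table(recs).set_index("therapy")
    for therapy in ("A", "B"):
        sel = [r for r in recs if r.therapy == therapy]
        free = sum(r.outcome == "terminated" for r in sel)
        assert table.loc[therapy, "total_n"] == len(sel)
        assert table.loc[therapy, "total_free"] == free
        for lva, label in ((False, "absence_lva"), (True, "presence_lva")):
            ss = [r for r in sel if r.has_lva == lva]
            assert table.loc[therapy, f"{label}_n"] == len(ss)


def test_strata_sum_to_totals_and_order_invariance():
    rng = np.random.default_rng(7)
    recs = [_rec(f"p{i}", "X", rng.choice(["terminated", "sustained"]),
                 bool(rng.integers(2))) for i in range(50)]
    t1 = efficacy_table(recs)
    t2 = efficacy_table(list(reversed(recs)))
    pd.testing.assert_frame_equal(t1, t2)
    row = t1.iloc[0]
    assert row.absence_lva_n + row.presence_lva_n == row.total_n
    assert row.absence_lva_free + row.presence_lva_free == row.total_free


def test_failed_runs_excluded_from_denominators():
    recs = [_rec("a", "X", "terminated", False),
            _rec("b", "X", "failed-run", False)]
    table = efficacy_table(recs)
    assert table.iloc[0].total_n == 1
    assert table.iloc[0].total_pct == 100.0


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("features, therapy", [
    # LVA arm
    (PatientFeatures(True, 55.0, 100.0, 200.0), "LVA_LA"),
    (PatientFeatures(True, 100.0, 100.0, 160.0), "LVA_LA-RA+CTI"),
    (PatientFeatures(True, 100.0, 100.0, 200.0), "LVA_LA+CTI"),
    # no-LVA arm
    (PatientFeatures(False, 80.0, 85.0, 200.0), "Marshall-PLAN"),
    (PatientFeatures(False, 80.0, 120.0, 200.0), "MiLine+CTI"),
    (PatientFeatures(False, 50.0, 120.0, 200.0), "MiLine"),
    (PatientFeatures(False, 50.0, 80.0, 200.0), "flutter-circuit"),
])
def test_stratification_cascade(features, therapy):
    assert stratify(features).therapy == therapy


def test_short_erp_adds_amiodarone_adjunct():
    r = stratify(PatientFeatures(False, 80.0, 85.0, 160.0))
    assert r.therapy == "Marshall-PLAN"
    assert r.drug_adjunct == "amiodarone_1.5"
    r2 = stratify(PatientFeatures(False, 80.0, 85.0, 171.0))
    assert r2.drug_adjunct is None


def test_boundary_values_go_to_big_long_branch():
    assert stratify(PatientFeatures(True, 60.0, 100.0, 170.0)).therapy \
        == "LVA_LA+CTI"          # RA == 60 -> big branch; ERP == 170 -> long
    assert stratify(PatientFeatures(False, 60.0, 90.0, 170.0)).therapy \
        == "MiLine+CTI"          # LA == 90 -> big branch


def test_stratify_total_on_feature_grid():
    """The cascade is total and deterministic over the feature lattice."""
    names = set(THERAPIES) | {"flutter-circuit"}
    for lva in (False, True):
        for ra in (30.0, 60.0, 90.0):
            for la in (60.0, 90.0, 130.0):
                for erp in (150.0, 170.0, 220.0):
                    r = stratify(PatientFeatures(lva, ra, la, erp))
                    assert r.therapy in names
                    assert r == stratify(PatientFeatures(lva, ra, la, erp))


@given(lva=st.booleans(), ra=st.floats(21.0, 300.0),
       la=st.floats(21.0, 300.0), erp=st.floats(50.0, 400.0))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_stratify_always_returns_known_therapy(lva, ra, la, erp):
    """The cascade is total over the continuous feature space."""
    r = stratify(PatientFeatures(lva, ra, la, erp))
    assert r.therapy in set(THERAPIES) | {"flutter-circuit"}
    if lva:
        assert r.drug_adjunct is None
    elif erp < te.ERP_THRESHOLD_MS:
        assert r.drug_adjunct == "amiodarone_1.5"


def test_missing_feature_rejected():
    with pytest.raises(ValueError, match="erp"):
        stratify(PatientFeatures(True, 55.0, 100.0, None))


# ---------------------------------------------------------------------------
# Campaign accounting
# ---------------------------------------------------------------------------

def test_planned_run_accounting_matches_headline():
    assert planned_run_count(800, 522, 12) == 7064
    assert planned_run_count(4, 0, 12) == 4


def test_trial_with_no_rotors_terminates_everyone():
    """Cohort of 4, nothing induced: 4 runs, empty records."""
    profiles = cohort.sample_profiles(2, seed=1)
    patients = cohort.build_cohort(profiles, [(25.0, 25.0)], True)
    cfg = te.TrialConfig(h_um=800.0, window_ms=150.0, dt_ode=0.05,
                         dt_pde=0.05, output_stride_ms=4.0, sigma_l=0.45,
                         n_rotors=0, measure_erp=False, seed=1)
    records, report = te.run_trial(patients, [THERAPIES["MiLine"]], cfg)
    assert records == []
    assert report["n_cohort"] == 4
    assert report["n_sustained"] == 0
    assert report["planned_runs"] == 4
    assert all(not row["sustained"] for row in report["induction"])
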