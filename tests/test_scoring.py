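"""Normalisation to the siControl+vehicle frame, Δ and CDI arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import blisscreen as b
from blisscreen.errors import (
    DegenerateReferenceError,
    DomainError,
    MissingReferenceError,
)
from blisscreen.scoring import plate_control_reference


def _well(plate, pos, reagent, gene, rclass, arm, count):
    return b.WellRecord(plate, pos, reagent, gene, rclass, arm, count)


class TestPlateControlReference:
    def test_median_of_control_counts(self):
        wells = [
            _well("p", f"A{i+1:02d}", "siControl", "", "nontargeting_control", "vehicle", c)
            for i, c in enumerate([1000, 1200, 1400])
        ]
        assert plate_control_reference(wells) == 1200

    def test_single_control_well(self):
        wells = [_well("p", "A01", "siControl", "", "nontargeting_control", "vehicle", 900)]
        assert plate_control_reference(wells) == 900

    def test_all_zero_controls_are_degenerate(self):
        wells = [
            _well("p", f"A{i+1:02d}", "siControl", "", "nontargeting_control", "vehicle", 0)
            for i in range(2)
        ]
        with pytest.raises(DegenerateReferenceError):
            plate_control_reference(wells)

    def test_no_controls_missing_reference(self):
        wells = [_well("p", "A01", "x", "G1", "pool", "vehicle", 500)]
        with pytest.raises(MissingReferenceError):
            plate_control_reference(wells)


class TestCdiAndDelta:
    def test_printed_formula_hand_example(self):
        assert b.cdi(0.3, 0.8, 0.6) == pytest.approx(0.625, abs=1e-15)

    def test_exact_bliss_independence_gives_one(self):
        assert b.cdi(0.8 * 0.6, 0.8, 0.6) == pytest.approx(1.0, abs=1e-15)

    def test_zero_denominator_is_undefined_flag(self):
        assert math.isnan(b.cdi(0.3, 0.0, 0.6))
        assert math.isnan(b.cdi(0.3, 0.8, 0.0))

    def test_negative_input_is_domain_error(self):
        with pytest.raises(DomainError):
            b.cdi(-0.1, 0.8, 0.6)

    @pytest.mark.parametrize(
        "rv,rd,expected", [(0.8, 0.3, 0.5), (0.5, 0.5, 0.0), (0.3, 0.8, -0.5)]
    )
    def test_interaction_difference(self, rv, rd, expected):
        assert b.interaction_difference(rv, rd) == pytest.approx(expected)

    @given(
        r_ab=st.floats(0, 2), r_a=st.floats(0.01, 2), r_b=st.floats(0.01, 2)
    )
    def test_cdi_matches_straight_line_oracle(self, r_ab, r_a, r_b):
        # independent recomputation of the Bliss-ratio definition
        oracle = r_ab / (r_a * r_b)
        assert abs(b.cdi(r_ab, r_a, r_b) - oracle) <= 1e-12


def _two_arm_screen(ctrl_vehicle, ctrl_drug, sirna_vehicle, sirna_drug):
    """Minimal 1-gene, 1-plate-per-arm screen from explicit counts."""
    wells = []
    for i, c in enumerate(ctrl_vehicle):
        wells.append(_well("v1", f"A{i+1:02d}", "siControl", "", "nontargeting_control", "vehicle", c))
    for i, c in enumerate(ctrl_drug):
        wells.append(_well("d1", f"A{i+1:02d}", "siControl", "", "nontargeting_control", "drug", c))
    wells.append(_well("v1", "B01", "pool_G1", "G1", "pool", "vehicle", sirna_vehicle))
    wells.append(_well("d1", "B01", "pool_G1", "G1", "pool", "drug", sirna_drug))
    return wells


def test_cross_arm_rescaling_hand_arithmetic(design):
    # control-vehicle median 1000, control-drug 600, siRNA drug well 300:
    # r_sirna_drug = (300/600) x (600/1000) = 0.30
    wells = _two_arm_screen([1000, 1000], [600, 600], 800, 300)
    scores = b.score_screen(wells, design)
    row = scores.iloc[0]
    assert row.r_control_drug == pytest.approx(0.6)
    assert row.r_sirna_drug == pytest.approx(0.30)
    assert row.r_sirna_vehicle == pytest.approx(0.8)
    assert row.delta == pytest.approx(0.5)
    assert row.cdi == pytest.approx(0.625)


def test_identity_reagent_tracks_controls(design):
    wells = _two_arm_screen([1000], [600], 1000, 600)
    scores = b.score_screen(wells, design)
    row = scores.iloc[0]
    assert row.r_sirna_vehicle == pytest.approx(1.0)
    assert row.r_sirna_drug == pytest.approx(row.r_control_drug)
    assert row.cdi == pytest.approx(1.0)


def test_vehicle_sicontrol_maps_to_exactly_one(design, noiseless_wells):
    wells, _ = noiseless_wells
    rel = b.relative_cell_numbers(wells, design)
    ctrl = rel[(rel.reagent_class == "nontargeting_control") & (rel.treatment == "vehicle")]
    assert (ctrl["value"] == 1.0).all()
    ctrl_drug = rel[(rel.reagent_class == "nontargeting_control") & (rel.treatment == "drug")]
    assert np.allclose(ctrl_drug["value"], rel.attrs["r_control_drug"])


def test_median_of_two_replicate_plates_is_their_mean(design):
    wells = _two_arm_screen([1000], [1000], 800, 800)
    # second replicate pair with a different siRNA-drug ratio: 0.2 and 0.4
    wells += [
        _well("v2", "A01", "siControl", "", "nontargeting_control", "vehicle", 1000),
        _well("d2", "A01", "siControl", "", "nontargeting_control", "drug", 1000),
        _well("v2", "B01", "pool_G1", "G1", "pool", "vehicle", 800),
        _well("d2", "B01", "pool_G1", "G1", "pool", "drug", 400),
    ]
    # per-plate drug ratios 0.8 and 0.4 -> median of two = mean = 0.6
    scores = b.score_screen(wells, design)
    assert scores.iloc[0].r_sirna_drug == pytest.approx(0.6)


def test_bliss_null_screen_has_unit_cdi_everywhere(design):
    truth = b.SimTruth.random(10, n_synergy=0, noise_cv=0.0, seed=3)
    wells, _ = b.simulate_screen(None, truth, design)
    scores = b.score_screen(wells, design)
    assert np.all(np.abs(scores["cdi"] - 1.0) < 1e-12)


def test_gene_scores_match_brute_force_oracle(design, noiseless_wells):
    """Independent straight-line recomputation from raw counts on a toy screen."""
    wells, truth = noiseless_wells
    scores = b.score_screen(wells, design).set_index("reagent_id")

    by_plate: dict[str, list] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, []).append(w)
    refs, arms = {}, {}
    for pid, ws in by_plate.items():
        ctrl = sorted(w.cell_count for w in ws if w.reagent_class == "nontargeting_control")
        n = len(ctrl)
        refs[pid] = (ctrl[n // 2] if n % 2 else (ctrl[n // 2 - 1] + ctrl[n // 2]) / 2)
        arms[pid] = ws[0].treatment
    v_refs = sorted(r for p, r in refs.items() if arms[p] == "vehicle")
    d_refs = sorted(r for p, r in refs.items() if arms[p] == "drug")
    med = lambda xs: xs[len(xs) // 2] if len(xs) % 2 else (xs[len(xs) // 2 - 1] + xs[len(xs) // 2]) / 2
    r_cd = med(d_refs) / med(v_refs)

    per = {}
    for w in wells:
        if w.reagent_class != "pool":
            continue
        per.setdefault((w.reagent_id, w.treatment), []).append(w.cell_count / refs[w.plate_id])
    for (rid, arm), vals in per.items():
        expected = med(sorted(vals)) * (r_cd if arm == "drug" else 1.0)
        col = "r_sirna_drug" if arm == "drug" else "r_sirna_vehicle"
        assert scores.loc[rid, col] == pytest.approx(expected, abs=1e-12)
        if arm == "drug":
            rv = scores.loc[rid, "r_sirna_vehicle"]
            assert scores.loc[rid, "cdi"] == pytest.approx(expected / (rv * r_cd), abs=1e-12)


def _rescaled(base, scales):
    return [
        b.WellRecord(w.plate_id, w.well, w.reagent_id, w.gene_symbol,
                     w.reagent_class, w.treatment, w.cell_count * scales[w.plate_id])
        for w in base
    ]


_PLATES = ("pool-vehicle-r1-p1", "pool-vehicle-r2-p1",
           "pool-drug-r1-p1", "pool-drug-r2-p1")


@given(
    scale_v1=st.floats(0.2, 5), scale_v2=st.floats(0.2, 5),
    scale_d1=st.floats(0.2, 5), scale_d2=st.floats(0.2, 5),
)
def test_plate_scale_effect_is_fully_characterised(scale_v1, scale_v2, scale_d1, scale_d2):
    """Per-plate multipliers cancel in CDI and vehicle-arm values exactly.

    Cross-arm values absorb precisely the ratio of arm control medians —
    a uniform multiplier on an arm's plates is indistinguishable from the
    drug effect, so that factor is the complete footprint of plate scale.
    """
    design = b.ScreenDesign()
    truth = b.SimTruth.random(6, n_synergy=2, noise_cv=0.0, seed=11)
    base, _ = b.simulate_screen(None, truth, design)
    base_scores = b.score_screen(base, design)

    scales = dict(zip(_PLATES, (scale_v1, scale_v2, scale_d1, scale_d2)))
    scaled_scores = b.score_screen(_rescaled(base, scales), design)

    for col in ("r_sirna_vehicle", "cdi"):
        np.testing.assert_allclose(scaled_scores[col], base_scores[col], rtol=1e-9)
    # cross-arm values scale by exactly med(drug scales)/med(vehicle scales)
    factor = np.median([scale_d1, scale_d2]) / np.median([scale_v1, scale_v2])
    np.testing.assert_allclose(
        scaled_scores["r_sirna_drug"], base_scores["r_sirna_drug"] * factor, rtol=1e-9
    )
    np.testing.assert_allclose(
        scaled_scores["r_control_drug"], base_scores["r_control_drug"] * factor, rtol=1e-9
    )


@given(
    scale_v1=st.floats(0.2, 5), scale_v2=st.floats(0.2, 5),
    scale_d1=st.floats(0.3, 4.9), global_scale=st.floats(0.1, 10),
)
def test_median_preserving_plate_scales_change_nothing(
    scale_v1, scale_v2, scale_d1, global_scale
):
    """Plate multipliers that keep the cross-arm control median ratio fixed
    (including any global rescale) leave every GeneScore and hit call
    byte-identical."""
    design = b.ScreenDesign()
    truth = b.SimTruth.random(6, n_synergy=2, noise_cv=0.0, seed=11)
    base, _ = b.simulate_screen(None, truth, design)
    base_scores = b.score_screen(base, design)
    from blisscreen.hit_calling import call_primary

    scale_d2 = scale_v1 + scale_v2 - scale_d1  # equal two-plate medians
    if scale_d2 <= 0.05:
        return
    scales = {
        p: s * global_scale
        for p, s in zip(_PLATES, (scale_v1, scale_v2, scale_d1, scale_d2))
    }
    scaled_scores = b.score_screen(_rescaled(base, scales), design)
    for col in ("r_sirna_vehicle", "r_sirna_drug", "r_control_drug", "delta", "cdi"):
        np.testing.assert_allclose(scaled_scores[col], base_scores[col], rtol=1e-9)
    assert call_primary(scaled_scores)["passed"].equals(call_primary(base_scores)["passed"])
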