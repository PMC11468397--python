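import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import circapower as cp
from circapower.protocol import ValidationError
from circapower.qpcr import ZTSeries, collapse_replicates


def standards_from_slope(slope, intercept=30.0, n_steps=6, reps=3):
    rows = []
    for step in range(n_steps):
        log_template = -step * np.log10(5.0)
        for _ in range(reps):
            rows.append({"dilution_step": step, "cq": intercept + slope * log_template})
    return pd.DataFrame(rows)


class TestFitEfficiency:
    def test_perfect_doubling_slope_is_100_percent(self):
        est = cp.fit_efficiency(standards_from_slope(-np.log2(10.0) * np.log10(2) ** 0))
        # slope -1/log10(2) = -3.3219... corresponds to exact doubling
        est = cp.fit_efficiency(standards_from_slope(-1.0 / np.log10(2.0)))
        assert est.efficiency_pct == pytest.approx(100.0, abs=1e-9)
        assert est.acceptable

    @pytest.mark.parametrize(
        "slope, expected_pct, acceptable",
        [(-3.5, 93.07, True), (-2.9, 121.2, False)],
    )
    def test_closed_form_efficiency(self, slope, expected_pct, acceptable):
        est = cp.fit_efficiency(standards_from_slope(slope))
        assert est.efficiency_pct == pytest.approx(expected_pct, abs=0.05)
        assert est.acceptable is acceptable

    def test_round_trip_known_amplification_factor(self):
        # standards simulated from a known factor E: Cq drops by log_E(5) per
        # fivefold dilution step; the fit must recover E
        for factor in (1.85, 2.0, 2.1):
            slope = -1.0 / np.log10(factor)
            est = cp.fit_efficiency(standards_from_slope(slope))
            assert cp.amplification_factor(est.efficiency_pct) == pytest.approx(factor, rel=1e-9)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValidationError):
            cp.fit_efficiency(standards_from_slope(+3.3))

    def test_too_few_dilutions_rejected(self):
        with pytest.raises(ValidationError):
            cp.fit_efficiency(standards_from_slope(-3.3, n_steps=2))


def cq_table(entries):
    """entries: (sample_id, group, zt, gene, cq) tuples, one replicate each."""
    return pd.DataFrame(
        [
            {"sample_id": s, "group": g, "zt": z, "gene": gene, "replicate": 1, "cq": cq}
            for s, g, z, gene, cq in entries
        ]
    )


class TestDualReference:
    def test_single_doubling_gives_factor_two(self):
        table = cq_table(
            [
                ("cal", "control", 0, "Per2", 25.0),
                ("cal", "control", 0, "Actb", 20.0),
                ("cal", "control", 0, "Gapdh", 21.0),
                ("s1", "POI", 0, "Per2", 24.0),
                ("s1", "POI", 0, "Actb", 20.0),
                ("s1", "POI", 0, "Gapdh", 21.0),
            ]
        )
        eff = {"Per2": 2.0, "Actb": 2.0, "Gapdh": 2.0}
        out = cp.relative_expression_dual_ref(table, "Per2", ("Actb", "Gapdh"), eff, ["cal"])
        values = {e.sample_id: e.value for e in out}
        assert values["s1"] == pytest.approx(2.0)
        assert values["cal"] == pytest.approx(1.0)

    def test_opposite_reference_shifts_cancel_geometrically(self):
        table = cq_table(
            [
                ("cal", "control", 0, "Per2", 25.0),
                ("cal", "control", 0, "Actb", 20.0),
                ("cal", "control", 0, "Gapdh", 21.0),
                ("s1", "POI", 0, "Per2", 25.0),
                ("s1", "POI", 0, "Actb", 21.0),   # +1 cycle
                ("s1", "POI", 0, "Gapdh", 20.0),  # -1 cycle
            ]
        )
        eff = {g: 2.0 for g in ("Per2", "Actb", "Gapdh")}
        out = cp.relative_expression_dual_ref(table, "Per2", ("Actb", "Gapdh"), eff, ["cal"])
        assert {e.sample_id: e.value for e in out}["s1"] == pytest.approx(1.0)

    def test_matches_literal_formula_on_random_tables(self):
        rng = np.random.default_rng(4)
        eff = {"T": 1.93, "R1": 2.05, "R2": 1.88}
        entries = []
        samples = [f"s{i}" for i in range(8)]
        for s in samples:
            for gene in eff:
                entries.append((s, "g", 0, gene, float(rng.uniform(18, 30))))
        table = cq_table(entries)
        cal = samples[:2]
        out = cp.relative_expression_dual_ref(table, "T", ("R1", "R2"), eff, cal)

        # independent literal evaluation of the ratio formula
        flat = collapse_replicates(table).set_index(["sample_id", "gene"])["cq"]
        cal_cq = {g: np.mean([flat[(s, g)] for s in cal]) for g in eff}
        for e in out:
            num = eff["T"] ** (cal_cq["T"] - flat[(e.sample_id, "T")])
            den = np.sqrt(
                eff["R1"] ** (cal_cq["R1"] - flat[(e.sample_id, "R1")])
                * eff["R2"] ** (cal_cq["R2"] - flat[(e.sample_id, "R2")])
            )
            assert e.value == pytest.approx(num / den, abs=1e-10)

    def test_reduces_to_ddcq_with_single_ref_at_factor_two(self):
        rng = np.random.default_rng(8)
        entries = []
        for i in range(6):
            entries.append((f"s{i}", "g", 0, "miR", float(rng.uniform(20, 30))))
            entries.append((f"s{i}", "g", 0, "U6", float(rng.uniform(18, 22))))
        table = cq_table(entries)
        dual = cp.relative_expression_dual_ref(
            table, "miR", ("U6",), {"miR": 2.0, "U6": 2.0}, ["s0"]
        )
        dd = cp.ddcq_fold_change(table, "miR", "U6", ["s0"])
        for a, b in zip(dual, dd):
            assert a.value == pytest.approx(b.value, abs=1e-10)

    def test_missing_reference_measurement_names_sample(self):
        table = cq_table(
            [
                ("cal", "g", 0, "T", 25.0),
                ("cal", "g", 0, "R1", 20.0),
                ("cal", "g", 0, "R2", 20.0),
                ("s1", "g", 0, "T", 24.0),
                ("s1", "g", 0, "R1", 20.0),  # R2 missing for s1
            ]
        )
        eff = {g: 2.0 for g in ("T", "R1", "R2")}
        with pytest.raises(ValidationError, match="s1"):
            cp.relative_expression_dual_ref(table, "T", ("R1", "R2"), eff, ["cal"])


class TestDdcq:
    def test_worked_example(self):
        table = cq_table(
            [
                ("cal", "CM", 0, "miR", 26.0),
                ("cal", "CM", 0, "U6", 20.0),
                ("s", "E2-CM", 0, "miR", 24.0),
                ("s", "E2-CM", 0, "U6", 20.0),
            ]
        )
        out = {e.sample_id: e.value for e in cp.ddcq_fold_change(table, "miR", "U6", ["cal"])}
        assert out["s"] == pytest.approx(4.0)  # ddCq = -2
        assert out["cal"] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=20)
    @given(delta=st.floats(-3, 3))
    def test_uniform_target_shift_scales_all_folds(self, delta):
        rng = np.random.default_rng(2)
        entries = []
        for i in range(5):
            entries.append((f"s{i}", "g", 0, "miR", float(rng.uniform(20, 30))))
            entries.append((f"s{i}", "g", 0, "U6", 20.0))
        base = cq_table(entries)
        shifted = base.copy()
        shifted.loc[shifted.gene == "miR", "cq"] += delta
        # the calibrator shifts too, so its fold stays 1 while the
        # sample/calibrator ratio structure is preserved; shifting only
        # the samples' target Cq by +1 must halve every fold instead
        only_samples = base.copy()
        mask = (only_samples.gene == "miR") & (only_samples.sample_id != "s0")
        only_samples.loc[mask, "cq"] += 1.0
        f_base = {e.sample_id: e.value for e in cp.ddcq_fold_change(base, "miR", "U6", ["s0"])}
        f_shift = {
            e.sample_id: e.value
            for e in cp.ddcq_fold_change(only_samples, "miR", "U6", ["s0"])
        }
        for s in f_base:
            if s == "s0":
                continue
            assert f_shift[s] == pytest.approx(f_base[s] / 2.0, rel=1e-9)

    def test_technical_replicates_collapse_to_mean_cq(self):
        table = pd.DataFrame(
            [
                {"sample_id": "cal", "group": "g", "zt": 0, "gene": g, "replicate": r, "cq": cq}
                for g, cqs in {"miR": (25.8, 26.0, 26.2), "U6": (20.0, 20.0, 20.0)}.items()
                for r, cq in enumerate(cqs)
            ]
            + [
                {"sample_id": "s", "group": "g", "zt": 0, "gene": "miR", "replicate": 1, "cq": 25.0},
                {"sample_id": "s", "group": "g", "zt": 0, "gene": "U6", "replicate": 1, "cq": 20.0},
            ]
        )
        out = {e.sample_id: e.value for e in cp.ddcq_fold_change(table, "miR", "U6", ["cal"])}
        assert out["s"] == pytest.approx(2.0)  # mean cal Cq = 26.0


class TestZTSeries:
    def expr(self, zts, reps=3):
        rng = np.random.default_rng(0)
        out = []
        for z in zts:
            for r in range(reps):
                out.append(
                    cp.RelExpression(
                        sample_id=f"z{z}r{r}", gene="Per2", value=float(rng.uniform(0.5, 2)),
                        method="ddcq", reference_genes=("U6",), calibrator="c",
                        group="control", zt=float(z),
                    )
                )
        return out

    def test_wrap_copies_zt0_to_zt24(self):
        series = cp.assemble_zt_series(self.expr((0, 4, 8, 12, 16, 20)), wrap=True)
        assert sorted(series.points) == [0, 4, 8, 12, 16, 20, 24]
        assert series.points[24.0] == series.points[0.0]

    def test_no_wrap_keeps_six_points(self):
        series = cp.assemble_zt_series(self.expr((0, 4, 8, 12, 16, 20)), wrap=False)
        assert len(series.points) == 6

    def test_wrap_is_idempotent(self):
        e = self.expr((0, 4, 8, 12, 16, 20))
        once = cp.assemble_zt_series(e, wrap=True)
        again_input = [
            cp.RelExpression("x", "Per2", v, "ddcq", ("U6",), "c", "control", z)
            for z, vals in once.points.items()
            for v in vals
        ]
        twice = cp.assemble_zt_series(again_input, wrap=True)
        assert twice.points == once.points

    def test_off_grid_zt_rejected(self):
        bad = self.expr((3,))
        with pytest.raises(ValidationError, match="off the sampling grid"):
            cp.assemble_zt_series(bad)


class TestLowess:
    def series(self, values_by_zt):
        return ZTSeries("Per2", "control", {float(z): list(v) for z, v in values_by_zt.items()})

    def test_constant_series_reproduced_exactly(self):
        s = self.series({z: [2.5] for z in (0, 4, 8, 12, 16, 20, 24)})
        sm = cp.lowess_curve(s)
        assert np.allclose(sm.smoothed["value"], 2.5)

    def test_full_span_reproduces_linear_trend(self):
        s = self.series({z: [1.0 + 0.1 * z] for z in (0, 4, 8, 12, 16, 20, 24)})
        sm = cp.lowess_curve(s, span=1.0)
        expected = 1.0 + 0.1 * sm.smoothed["zt"].to_numpy()
        assert np.allclose(sm.smoothed["value"], expected, atol=1e-8)

    def test_smoothing_reduces_noise_against_true_cosine(self):
        rng = np.random.default_rng(6)
        zts = (0, 4, 8, 12, 16, 20, 24)
        truth = {z: 1.0 + 0.5 * np.cos(2 * np.pi * z / 24.0) for z in zts}
        s = self.series({z: truth[z] + rng.normal(0, 0.15, 3) for z in zts})
        sm = cp.lowess_curve(s, span=0.5)
        at_zt = sm.smoothed.set_index("zt")["value"]
        raw_resid = [np.mean(s.points[z]) - truth[z] for z in zts]
        smooth_resid = [at_zt[float(z)] - truth[z] for z in zts]
        assert np.std(smooth_resid) < np.std(raw_resid)

    def test_invalid_span_rejected(self):
        s = self.series({z: [1.0] for z in (0, 4, 8, 12)})
        with pytest.raises(ValidationError):
            cp.lowess_curve(s, span=1.5)

    def test_too_few_points_rejected(self):
        s = self.series({0: [1.0], 4: [1.0], 8: [1.0]})
        with pytest.raises(ValidationError):
            cp.lowess_curve(s)
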