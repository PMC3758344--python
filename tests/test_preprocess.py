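"""Floored log2 transform, replicate averaging, series centering, paired LFC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinarray import (
    SimulationConfig,
    average_replicates,
    basal_profiles,
    center_by_series,
    compute_lfc,
    floor_log2,
    generate,
    net_signal,
)
from kinarray.exceptions import CompletenessError, PairingError
from kinarray.preprocess import SignalMatrix

from conftest import make_experiment


class TestNetSignal:
    def test_subtraction(self):
        assert net_signal(100.0, 30.0) == 70.0

    def test_negative_allowed(self):
        assert net_signal(10.0, 25.0) == -15.0

    def test_zero_background_identity(self):
        assert net_signal(3.7, 0.0) == 3.7

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            net_signal(float("nan"), 0.0)


class TestFloorLog2:
    @pytest.mark.parametrize(
        "net,expected",
        [(8.0, 3.0), (-3.0, math.log2(0.01)), (0.5, -1.0), (0.0, math.log2(0.01))],
    )
    def test_values(self, net, expected):
        assert floor_log2(net) == pytest.approx(expected, abs=1e-12)

    def test_sub_floor_positive_values_pass_through(self):
        # only non-positive nets are floored; (0, 0.01) is left alone
        assert floor_log2(0.005) == pytest.approx(math.log2(0.005))

    def test_invalid_floor(self):
        with pytest.raises(ValueError):
            floor_log2(1.0, floor=0.0)

    @given(
        st.floats(min_value=-1e6, max_value=1e6),
        st.floats(min_value=-1e6, max_value=1e6),
    )
    @settings(deadline=None, max_examples=200)
    def test_monotone_outside_the_floor_gap(self, x, y):
        # flooring only non-positive values leaves a deliberate
        # non-monotone gap on (0, floor); outside it the transform is
        # monotone and equals log2 on positives
        lo, hi = sorted((x, y))
        if not (0 < lo < 0.01 or 0 < hi < 0.01):
            assert floor_log2(lo) <= floor_log2(hi)
        if lo > 0:
            assert floor_log2(lo) == pytest.approx(math.log2(lo))


class TestAverageReplicates:
    def test_mean_of_replicates(self):
        # log2 values 1, 2, 3 across three replicates -> mean 2
        records = [
            ("A", "P1", "c1", 1, "S1", r, "none", 2.0**v + 5.0, 5.0)
            for r, v in [(1, 1), (2, 2), (3, 3)]
        ] + [("B", "P1", "c2", 1, "S1", 1, "none", 2.0**5 + 5.0, 5.0)]
        exp = make_experiment(records)
        mat = average_replicates(exp, "none")
        assert mat.values.loc["A", "P1"] == pytest.approx(2.0)
        # single replicate is its own mean
        assert mat.values.loc["B", "P1"] == pytest.approx(5.0)

    def test_shape_from_synthetic(self):
        exp, _ = generate(
            SimulationConfig(seed=3, n_mutant=1, n_wildtype=2, n_unknown=0,
                             n_normal_skin=0, n_peptides=144, n_signature=5)
        )
        mat = average_replicates(exp, "none")
        assert mat.values.shape == (3, 144)
        assert not mat.values.isna().to_numpy().any()

    def test_missing_cell_is_completeness_error(self):
        records = [
            ("A", "P1", "c1", 1, "S1", 1, "none", 8.0, 0.0),
            ("A", "P2", "c1", 1, "S1", 1, "none", 8.0, 0.0),
            ("B", "P1", "c2", 1, "S1", 1, "none", 8.0, 0.0),
            # B lacks P2
        ]
        exp = make_experiment(records, panel=["P1", "P2"])
        with pytest.raises(CompletenessError, match="P2"):
            average_replicates(exp, "none")


class TestCenterBySeries:
    @staticmethod
    def _sm(index, data):
        return SignalMatrix(pd.DataFrame(data, index=index))

    def test_single_series_mean_subtraction(self):
        out = center_by_series({"S1": self._sm(["A", "B"], {"P1": [4.0, 6.0]})})
        assert out.values["P1"].tolist() == [-1.0, 1.0]

    def test_sample_in_two_series_averaged(self):
        # centered values -1 (S1) and +3 (S2) -> +1
        s1 = self._sm(["A", "B"], {"P1": [4.0, 6.0]})  # A centers to -1
        s2 = self._sm(["A", "C"], {"P1": [8.0, 2.0]})  # A centers to +3
        out = center_by_series({"S1": s1, "S2": s2})
        assert out.values.loc["A", "P1"] == pytest.approx(1.0)

    def test_duplicate_series_idempotent(self):
        s = self._sm(["A", "B", "C"], {"P1": [1.0, 5.0, 6.0]})
        once = center_by_series({"S1": s})
        twice = center_by_series({"S1": s, "S2": self._sm(s.values.index, s.values)})
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_within_series_contrasts_preserved(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(5, 7)),
            index=list("ABCDE"),
            columns=[f"P{j}" for j in range(7)],
        )
        out = center_by_series({"S1": SignalMatrix(df)})
        for a, b in [("A", "B"), ("C", "E")]:
            np.testing.assert_allclose(
                out.values.loc[a] - out.values.loc[b],
                df.loc[a] - df.loc[b],
                atol=1e-12,
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center_by_series({})


class TestComputeLfc:
    def test_chip_then_sample_averaging(self):
        # chip A: without=3.0, with=1.0 (log2); chip B: 4.0 vs 3.0 -> mean(2,1)=1.5
        records = [
            ("A", "P1", "chip1", 1, "S1", 1, "none", 2.0**3, 0.0),
            ("A", "P1", "chip1", 2, "S1", 1, "vemurafenib", 2.0**1, 0.0),
            ("A", "P1", "chip2", 1, "S1", 2, "none", 2.0**4, 0.0),
            ("A", "P1", "chip2", 2, "S1", 2, "vemurafenib", 2.0**3, 0.0),
            ("B", "P1", "chip3", 1, "S1", 1, "none", 2.0**3, 0.0),
            ("B", "P1", "chip3", 2, "S1", 1, "vemurafenib", 2.0**3, 0.0),
        ]
        exp = make_experiment(records)
        prof = compute_lfc(exp, "vemurafenib")
        assert prof.lfc.loc["A", "P1"] == pytest.approx(1.5)
        # identical conditions -> zero LFC
        assert prof.lfc.loc["B", "P1"] == pytest.approx(0.0)

    def test_halving_gives_unit_lfc(self, toy_experiment):
        prof = compute_lfc(toy_experiment, "vemurafenib")
        np.testing.assert_allclose(prof.lfc.to_numpy(), 1.0, atol=1e-12)

    def test_antisymmetric_under_label_swap(self, toy_experiment):
        meas = toy_experiment.measurements.copy()
        swap = {"none": "vemurafenib", "vemurafenib": "none"}
        meas["inhibitor"] = meas["inhibitor"].map(swap)
        swapped = make_experiment(
            list(meas.itertuples(index=False)), panel=toy_experiment.peptide_panel
        )
        prof = compute_lfc(toy_experiment, "vemurafenib")
        prof_swapped = compute_lfc(swapped, "vemurafenib")
        np.testing.assert_allclose(
            prof_swapped.lfc.to_numpy(), -prof.lfc.to_numpy(), atol=1e-12
        )

    def test_noise_free_recovers_depth_exactly(self):
        cfg = SimulationConfig(
            seed=5, replicate_sd=0.0, chip_sd=0.0, series_offset_sd=0.0,
            signature_extra_inhibition_log2=0.0,
            n_mutant=2, n_wildtype=3, n_unknown=0, n_normal_skin=0,
            n_peptides=20, n_signature=5,
        )
        exp, truth = generate(cfg)
        prof = compute_lfc(exp, "vemurafenib")
        expected = truth.attenuation * cfg.base_inhibition_log2
        for sid in prof.sample_ids:
            np.testing.assert_allclose(
                prof.lfc.loc[sid].to_numpy(), expected, atol=1e-9
            )

    def test_unpaired_sample_raises(self):
        records = [
            ("A", "P1", "chip1", 1, "S1", 1, "none", 8.0, 0.0),
            ("A", "P1", "chip1", 2, "S1", 1, "vemurafenib", 4.0, 0.0),
            ("B", "P1", "chip2", 1, "S1", 1, "none", 8.0, 0.0),
        ]
        exp = make_experiment(records)
        with pytest.raises(PairingError):
            compute_lfc(exp, "sunitinib")


def test_basal_pipeline_centers_columns(default_run):
    exp, _ = default_run
    basal = basal_profiles(exp)
    assert basal.provenance == "basal_centered"
    assert basal.values.shape[1] == 144
    # each sample sits in one series and both series are centered per
    # peptide, so the pooled column means vanish
    col_means = np.abs(basal.values.mean(axis=0))
    assert col_means.max() < 1e-9
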