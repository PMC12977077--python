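"""Trial preparation: scaling, ratios, coding, exclusions, assembly."""

import numpy as np
import pandas as pd
import pytest

import aperturepass as ap
from aperturepass.errors import DesignError
from aperturepass.trialprep import prepare_trials, truth_angles_frame


def _rows(widths, condition="randomized", participant="p1", segment="shoulder",
          experiment="real", gseq=1, task="task1", body_visible=None):
    n = len(widths)
    return pd.DataFrame(
        {
            "participant_id": [participant] * n,
            "segment": [segment] * n,
            "experiment": [experiment] * n,
            "task_id": [task] * n,
            "condition": [condition] * n,
            "body_visible": [body_visible] * n,
            "sequence_index_global": [gseq] * n,
            "trial_index_in_sequence": np.arange(1, n + 1),
            "aperture_width_cm": np.asarray(widths, float),
        }
    )


class TestScaling:
    def test_divide_by_group_max(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a"] * 3,
                "segment": ["shoulder"] * 3,
                "alpha_deg": [10.0, 20.0, 40.0],
                "excluded": [False] * 3,
            }
        )
        assert ap.scale_rotation_by_max(df).tolist() == [0.25, 0.5, 1.0]

    def test_single_trial_scales_to_one(self):
        df = pd.DataFrame(
            {"participant_id": ["a"], "segment": ["shoulder"],
             "alpha_deg": [33.0], "excluded": [False]}
        )
        assert ap.scale_rotation_by_max(df).tolist() == [1.0]

    def test_excluded_trial_does_not_set_the_max(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a"] * 3,
                "segment": ["shoulder"] * 3,
                "alpha_deg": [50.0, 20.0, 40.0],
                "excluded": [True, False, False],
            }
        )
        scaled = ap.scale_rotation_by_max(df)
        assert scaled.tolist() == [1.25, 0.5, 1.0]

    def test_all_zero_group_rejected(self):
        df = pd.DataFrame(
            {"participant_id": ["a"] * 2, "segment": ["shoulder"] * 2,
             "alpha_deg": [0.0, 0.0], "excluded": [False, False]}
        )
        with pytest.raises(DesignError):
            ap.scale_rotation_by_max(df)


class TestRatios:
    def test_ratio_arithmetic(self):
        assert ap.compute_ax_ratio(45.0, 40.0) == pytest.approx(1.125)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(DesignError):
            ap.compute_ax_ratio(45.0, 0.0)

    def test_centering_removes_the_mean(self):
        centered, mean = ap.center_ratios([1.0, 1.2, 1.4])
        assert mean == pytest.approx(1.2)
        assert np.allclose(centered, [-0.2, 0.0, 0.2])
        rng = np.random.default_rng(0)
        centered, _ = ap.center_ratios(rng.uniform(0.8, 2.0, 100))
        assert abs(centered.sum()) < 1e-12


class TestOrderEncoding:
    def test_randomized_n_minus_1_rule(self):
        widths5 = 30 + 5 * np.array([2, 7, 6, 8, 4, 3, 1, 5, 9])
        out = ap.encode_order(_rows(widths5))
        labels = out.sort_values("trial_index_in_sequence")["order_label"].tolist()
        assert labels[0] is None
        assert labels[1:4] == ["increasing", "decreasing", "increasing"]
        assert out["first_trial"].sum() == 1

    def test_ordered_plan_reproduced(self):
        out = ap.encode_order(_rows(np.arange(35, 80, 5), condition="ordered"))
        labels = out.sort_values("trial_index_in_sequence")["order_label"]
        assert labels.tolist()[1:] == ["increasing"] * 8

    def test_each_sequence_contributes_eight_labeled_trials(self):
        df = pd.concat(
            [_rows(np.random.default_rng(s).permutation(9) * 5 + 30, gseq=s + 1)
             for s in range(4)],
            ignore_index=True,
        )
        out = ap.encode_order(df)
        assert out["order_label"].notna().sum() == 4 * 8

    def test_duplicate_widths_rejected(self):
        with pytest.raises(DesignError):
            ap.encode_order(_rows([35, 35, 40]))


class TestFactorCoding:
    def test_fatigue_endpoints_and_midpoint(self):
        df = ap.encode_order(_rows(np.arange(35, 80, 5)))
        for gseq, expected in [(1, -1.0), (24, 1.0), (12.5, 0.0)]:
            d = df.copy()
            d["sequence_index_global"] = gseq
            coded = ap.encode_factors(d, {"real": 24})
            assert np.allclose(coded["coded_fatigue"], expected)

    def test_sign_conventions(self):
        df = ap.encode_order(
            _rows(np.arange(35, 80, 5), experiment="virtual",
                  condition="ordered", body_visible=True)
        )
        coded = ap.encode_factors(df, {"virtual": 24})
        assert (coded["coded_environment"] == 1).all()
        assert (coded["coded_condition"] == 1).all()
        assert (coded["coded_bodyvisible"] == 1).all()
        inc = coded[coded["order_label"] == "increasing"]
        assert (inc["coded_order"] == -1).all()

    def test_unknown_level_rejected(self):
        df = ap.encode_order(_rows(np.arange(35, 80, 5), condition="mixed"))
        with pytest.raises(DesignError, match="condition"):
            ap.encode_factors(df, {"real": 15})


class TestExclusions:
    def test_no_flags_removes_first_trials_only(self):
        df = ap.encode_order(_rows(np.arange(35, 80, 5)))
        out, audit = ap.apply_exclusions(df)
        assert audit["first_trial"] == 1
        assert audit["failed"] == 0 and audit["aborted_sequence"] == 0
        assert audit["total"] == audit["included"] + 1

    def test_real_environment_failure_takes_whole_sequence(self):
        df = ap.encode_order(_rows(np.arange(35, 80, 5)))
        df["failed"] = [False] * 4 + [True] + [False] * 4
        df["sequence_aborted"] = True
        out, audit = ap.apply_exclusions(df)
        assert audit["aborted_sequence"] == 9
        assert audit["included"] == 0

    def test_virtual_failure_removes_single_trial(self):
        df = ap.encode_order(
            _rows(np.arange(35, 80, 5), experiment="virtual", body_visible=True)
        )
        df["failed"] = [False] * 4 + [True] + [False] * 4
        df["sequence_aborted"] = False
        out, audit = ap.apply_exclusions(df)
        assert audit["failed"] == 1
        assert audit["first_trial"] == 1
        assert audit["included"] == 7

    def test_row_conservation(self):
        df = ap.encode_order(_rows(np.arange(35, 80, 5)))
        _, audit = ap.apply_exclusions(df)
        assert audit["total"] == sum(
            audit[k] for k in ("included", "first_trial", "failed", "aborted_sequence")
        )


class TestAssembly:
    def _mixed(self):
        parts = [
            _rows(np.arange(35, 80, 5), experiment="real", participant="r1"),
            _rows(np.arange(35, 80, 5), experiment="virtual", participant="v1",
                  body_visible=False, task="task1"),
            _rows(np.arange(35, 80, 5), experiment="virtual", participant="v1",
                  body_visible=True, task="task3", gseq=2),
        ]
        return pd.concat(parts, ignore_index=True)

    def test_combined_drops_body_invisible_virtual_rows(self):
        out = ap.assemble_analysis_dataset(self._mixed(), "combined")
        virtual = out[out["experiment"] == "virtual"]
        assert (virtual["body_visible"] == True).all()  # noqa: E712
        assert (out["experiment"] == "real").sum() == 9

    def test_feedback_keeps_both_visibility_levels(self):
        out = ap.assemble_analysis_dataset(self._mixed(), "feedback")
        assert set(out["body_visible"].unique()) == {False, True}
        assert (out["experiment"] == "virtual").all()

    def test_selections_are_disjoint_partitions(self):
        df = self._mixed().reset_index(names="row_id")
        combined = ap.assemble_analysis_dataset(df, "combined")
        assert combined["row_id"].is_unique

    def test_unknown_analysis_rejected(self):
        with pytest.raises(DesignError):
            ap.assemble_analysis_dataset(self._mixed(), "everything")


class TestPrepareEndToEnd:
    def test_prepared_table_invariants(self, small_exp1):
        angles = truth_angles_frame(small_exp1.trials)
        participants = ap.synthgen.participants_frame(small_exp1.participants, "exp1")
        prepared = prepare_trials(
            angles, small_exp1.trials, participants, "exp1", {"real": 15}
        )
        t = prepared.table
        # every participant x segment reaches the scaled maximum of 1
        gmax = t.groupby(["participant_id", "segment"])["scaled_rotation"].max()
        assert np.allclose(gmax, 1.0)
        # centering per segment
        for seg, grp in t.groupby("segment"):
            assert abs(grp["ax_centered"].mean()) < 1e-9
            assert prepared.centering_means[seg] == pytest.approx(
                grp["ax_ratio"].mean()
            )
        # factor codes on the +-1 grid
        assert set(t["coded_condition"].unique()) <= {-1.0, 1.0}
        assert set(t["coded_order"].unique()) <= {-1.0, 1.0}
        assert t["coded_fatigue"].between(-1, 1).all()
        # pelvis uses hip width
        pelvis = t[t.segment == "pelvis"].iloc[0]
        assert pelvis["ax_ratio"] == pytest.approx(
            pelvis["aperture_width_cm"] / pelvis["hip_width_cm"]
        )
        # row conservation
        assert len(prepared.full) == prepared.audit["total"]
        assert len(t) == prepared.audit["included"]

    def test_order_labels_depend_only_on_width_sequence(self):
        widths = 30 + 5 * np.array([3, 1, 4, 9, 5, 2, 8, 6, 7])
        a = ap.encode_order(_rows(widths))["order_label"].tolist()
        b = ap.encode_order(_rows(widths, participant="zz", gseq=7))["order_label"].tolist()
        assert a == b
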