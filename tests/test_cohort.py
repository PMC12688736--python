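"""Synthetic-cohort generator: calibration, determinism, round trip, validation."""

import numpy as np
import pandas as pd
import pytest

from ncrtfusion import (
    CohortParseError,
    default_config,
    generate_cohort,
    monotone_transition,
    null_config,
    read_cohort,
    write_cohort,
)
from ncrtfusion.cohort import (
    CATEGORICAL_PRE_COUNTS,
    PRE_MEANS,
    PRE_SDS,
    TRG_COUNTS,
)
from ncrtfusion.markers import CATEGORICAL_MARKERS, CONTINUOUS_MARKERS, MARKERS_BY_NAME


class TestDefaultConfig:
    def test_cohort_size_and_trg_mix(self):
        cfg = default_config()
        assert cfg.n_patients == 149
        assert cfg.trg_probabilities == tuple(c / 149 for c in (31, 34, 50, 34))
        assert sum(cfg.trg_probabilities) == pytest.approx(1.0, abs=1e-12)

    def test_pre_marginals_match_published_summaries(self):
        cfg = default_config()
        assert cfg.pre_means["adc_value"] == 0.970
        assert cfg.pre_sds["adc_value"] == 0.251
        assert cfg.pre_means["sagittal_longest_diameter"] == 53.980
        assert cfg.treatment_effects["adc_value"] == pytest.approx(0.253)
        assert cfg.treatment_effects["lymph_node_number"] == pytest.approx(-2.86)

    def test_categorical_pre_frequencies_are_proportions(self):
        cfg = default_config()
        for m, counts in CATEGORICAL_PRE_COUNTS.items():
            freq = cfg.categorical_pre_frequencies[m]
            assert sum(freq) == pytest.approx(1.0)
            np.testing.assert_allclose(freq, np.array(counts) / sum(counts))

    def test_signal_planted_on_features_1_2_5(self):
        cfg = default_config()
        assert cfg.signal_features == (1, 2, 5)
        assert cfg.signal_strength > 0


class TestConfigValidation:
    @pytest.mark.parametrize(
        "mutate, message",
        [
            (lambda c: setattr(c, "trg_probabilities", (0.3, 0.3, 0.3, 0.2)),
             "sum to 1"),
            (lambda c: c.pre_sds.__setitem__("adc_value", 0.0), "SDs > 0"),
            (lambda c: c.paired_correlation.__setitem__("adc_value", 1.5),
             "(-1, 1)"),
            (lambda c: c.transition_matrices.__setitem__(
                "emvi", ((0.5, 0.4), (0.0, 1.0))), "row-stochastic"),
            (lambda c: setattr(c, "signal_strength", -1.0), ">= 0"),
            (lambda c: setattr(c, "signal_features", (1, 9)), "unknown feature"),
        ],
    )
    def test_invalid_config_rejected_with_named_invariant(self, mutate, message):
        cfg = default_config()
        mutate(cfg)
        with pytest.raises(ValueError, match=r".*"):
            cfg.validate()
        try:
            cfg.validate()
        except ValueError as err:
            assert message in str(err)


class TestGenerateCohort:
    def test_cohort_has_149_rows_and_exact_trg_counts(self, default_cohort):
        assert len(default_cohort) == 149
        counts = default_cohort["trg"].value_counts().sort_index()
        assert tuple(counts) == TRG_COUNTS

    def test_deterministic_for_fixed_config_and_seed(self):
        cfg = default_config()
        a = generate_cohort(cfg, seed=42)
        b = generate_cohort(cfg, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        cfg = default_config()
        a = generate_cohort(cfg, seed=1)
        b = generate_cohort(cfg, seed=2)
        assert not a["pre_adc_value"].equals(b["pre_adc_value"])

    def test_pre_adc_mean_close_to_configured(self, default_cohort):
        se = 0.251 / np.sqrt(149)
        assert abs(default_cohort["pre_adc_value"].mean() - 0.970) < 3 * se

    def test_continuous_pre_marginals_calibrated(self):
        """Empirical pre-treatment means stay within 4 SE of their targets."""
        cfg = default_config()
        reps = 200
        sums = {m: 0.0 for m in CONTINUOUS_MARKERS}
        for s in range(reps):
            c = generate_cohort(cfg, seed=1000 + s)
            for m in CONTINUOUS_MARKERS:
                sums[m] += c[f"pre_{m}"].mean()
        for m in CONTINUOUS_MARKERS:
            se = PRE_SDS[m] / np.sqrt(cfg.n_patients)
            assert abs(sums[m] / reps - PRE_MEANS[m]) < 4 * se, m

    def test_floors_respected(self, default_cohort):
        for m in CONTINUOUS_MARKERS:
            floor = MARKERS_BY_NAME[m].floor
            if floor is None:
                continue
            assert (default_cohort[f"pre_{m}"] >= floor).all()
            assert (default_cohort[f"post_{m}"] >= floor).all()

    def test_categorical_values_in_level_sets(self, default_cohort):
        for m in CATEGORICAL_MARKERS:
            levels = MARKERS_BY_NAME[m].levels
            assert default_cohort[f"pre_{m}"].isin(levels).all()
            assert default_cohort[f"post_{m}"].isin(levels).all()

    def test_no_signal_means_no_class_separation(self):
        """With delta=0, class-conditional baseline means differ only by noise."""
        cfg = default_config()
        cfg.signal_strength = 0.0
        diffs = []
        for s in range(50):
            c = generate_cohort(cfg, seed=s)
            resp = c["trg"] <= 1
            diffs.append(
                c.loc[resp, "pre_adc_value"].mean()
                - c.loc[~resp, "pre_adc_value"].mean()
            )
        # mean class difference ~ N(0, sd/sqrt(...)); 50 reps shrink the SE
        assert abs(np.mean(diffs)) < 4 * 0.251 * np.sqrt(1 / 65 + 1 / 84) / np.sqrt(50)

    def test_signal_shift_preserves_overall_mean(self):
        """The planted class contrast is mean-zero by construction."""
        cfg = default_config()
        cfg.signal_strength = 2.0
        means = [generate_cohort(cfg, seed=s)["pre_adc_value"].mean() for s in range(60)]
        se = 0.251 / np.sqrt(149)
        assert abs(np.mean(means) - 0.970) < 4 * se / np.sqrt(60) * 3  # allow var inflation

    def test_post_marginals_follow_transition_matrix(self):
        """Categorical post marginals converge to pre x transition as n grows."""
        cfg = default_config()
        cfg.signal_strength = 0.0
        cfg.n_patients = 6000
        c = generate_cohort(cfg, seed=3)
        for m in ("n_stage", "emvi", "crm"):
            levels = list(MARKERS_BY_NAME[m].levels)
            pre = np.asarray(cfg.categorical_pre_frequencies[m])
            T = np.asarray(cfg.transition_matrices[m])
            expected = pre @ T
            observed = (
                c[f"post_{m}"].value_counts(normalize=True)
                .reindex(levels, fill_value=0.0).to_numpy()
            )
            np.testing.assert_allclose(observed, expected, atol=0.025)

    def test_monotone_transitions_never_worsen(self, default_cohort):
        """Default transitions only improve stage/indicator values."""
        for m in CATEGORICAL_MARKERS:
            assert (default_cohort[f"post_{m}"] <= default_cohort[f"pre_{m}"]).all()


class TestMonotoneTransition:
    def test_reproduces_published_emvi_discordance(self):
        # marginals 35/14 -> 44/5: 9 improvements, none worsen
        T = monotone_transition([35 / 49, 14 / 49], [44 / 49, 5 / 49])
        np.testing.assert_allclose(T[0], [1.0, 0.0])
        np.testing.assert_allclose(T[1], [9 / 14, 5 / 14])

    def test_row_stochastic_and_marginal_consistent(self):
        pre = np.array([0.2, 0.5, 0.3])
        post = np.array([0.6, 0.3, 0.1])
        T = monotone_transition(pre, post)
        np.testing.assert_allclose(T.sum(axis=1), 1.0)
        np.testing.assert_allclose(pre @ T, post, atol=1e-12)
        assert np.allclose(np.triu(T, k=1), 0.0)  # never worsens


class TestCohortIO:
    def test_round_trip_is_lossless(self, tmp_path, default_cohort):
        p = tmp_path / "cohort.csv"
        write_cohort(default_cohort, p, metadata={"seed": 1, "tool": "test"})
        back = read_cohort(p)
        pd.testing.assert_frame_equal(default_cohort, back)

    def test_round_trip_byte_identical(self, tmp_path):
        cfg = default_config()
        for i, p in enumerate([tmp_path / "a.csv", tmp_path / "b.csv"]):
            write_cohort(generate_cohort(cfg, seed=9), p)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_missing_trg_column_named(self, tmp_path, small_cohort):
        p = tmp_path / "bad.csv"
        write_cohort(small_cohort.drop(columns=["trg"]), p)
        with pytest.raises(CohortParseError, match="trg"):
            read_cohort(p)

    def test_unknown_column_rejected(self, tmp_path, small_cohort):
        p = tmp_path / "bad.csv"
        c = small_cohort.copy()
        c["mystery"] = 1
        write_cohort(c, p)
        with pytest.raises(CohortParseError, match="mystery"):
            read_cohort(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(CohortParseError, match="empty"):
            read_cohort(p)

    def test_out_of_range_trg_reports_row(self, tmp_path, small_cohort):
        p = tmp_path / "bad.csv"
        c = small_cohort.copy()
        c.loc[3, "trg"] = 7
        write_cohort(c, p)
        with pytest.raises(CohortParseError, match=r"trg.*\[3\]"):
            read_cohort(p)


class TestNullConfig:
    def test_no_effects_no_signal(self):
        cfg = null_config()
        assert cfg.signal_strength == 0.0
        assert all(v == 0.0 for v in cfg.treatment_effects.values())

    def test_symmetric_exchange_preserves_marginals(self):
        cfg = null_config()
        for m in CATEGORICAL_MARKERS:
            p = np.asarray(cfg.categorical_pre_frequencies[m])
            T = np.asarray(cfg.transition_matrices[m])
            np.testing.assert_allclose(p @ T, p, atol=1e-12)
            # joint symmetry: p_i T_ij == p_j T_ji
            J = p[:, None] * T
            np.testing.assert_allclose(J, J.T, atol=1e-12)
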