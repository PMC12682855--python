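"""Min-max normalization, the composite indicator and quadrant classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pindicator import (
    DEFAULT_ORIENTATIONS,
    classify_quadrants,
    compute_indicator,
    load_table3_fixture,
    minmax_normalize,
)
from pindicator.trial_io import MetricTable, METRIC_COLUMNS


class TestMinmaxNormalize:
    def test_affine_endpoints(self):
        assert minmax_normalize([1, 2, 3]) == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_input_maps_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize([7.0, 7.0, 7.0])
        assert out == pytest.approx([0.5, 0.5, 0.5])

    def test_matches_formula_oracle_on_random_vector(self, rng):
        x = rng.normal(size=26)
        expected = (x - x.min()) / (x.max() - x.min())
        assert minmax_normalize(x) == pytest.approx(expected, abs=1e-15)

    def test_nonfinite_positions_named(self):
        with pytest.raises(ValueError, match="position 1"):
            minmax_normalize([1.0, np.nan, 2.0])

    @settings(deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50),
        a=st.floats(-100, 100),
        b=st.floats(0.01, 100),
    )
    def test_invariant_under_positive_affine_maps(self, values, a, b):
        x = np.asarray(values)
        if np.ptp(x) == 0:
            return
        assert minmax_normalize(a + b * x) == pytest.approx(
            minmax_normalize(x), abs=1e-6
        )


def _table_from_metrics(frame: pd.DataFrame) -> MetricTable:
    """Wrap bare five-metric columns (P- level) into a full MetricTable."""
    data = pd.DataFrame(0.0, index=frame.index, columns=list(METRIC_COLUMNS))
    data["pae_pminus_mean"] = frame["pae"]
    data["prae_pminus_mean"] = frame["prae"]
    data["pue_pminus_mean"] = frame["pue"]
    data["relative_efficiency"] = frame["relative_efficiency"]
    data["apue"] = frame["apue"]
    # give the unused P+ level some spread so normalization stays defined
    data["pae_pplus_mean"] = np.arange(len(frame), dtype=float)
    data["prae_pplus_mean"] = np.arange(len(frame), dtype=float)
    data["pue_pplus_mean"] = np.arange(len(frame), dtype=float)
    return MetricTable(data, platform_label="TEST")


class TestComputeIndicator:
    def test_oriented_extremes_attain_bounds(self, rng):
        n = 8
        frame = pd.DataFrame(
            {
                "pae": rng.uniform(20, 60, n),
                "prae": rng.uniform(0.002, 0.008, n),
                "pue": rng.uniform(20, 80, n),
                "relative_efficiency": rng.uniform(30, 70, n),
                "apue": rng.uniform(10, 90, n),
            },
            index=[f"G{i}" for i in range(n)],
        )
        # best genotype: max in the four ascending metrics, min in PRAE
        frame.loc["G0"] = [100.0, 0.001, 100.0, 99.0, 99.0]
        frame.loc["G1"] = [1.0, 0.02, 1.0, 1.0, 1.0]  # worst in all five
        result = compute_indicator(_table_from_metrics(frame))
        assert result.data.loc["G0", "score"] == pytest.approx(5.0)
        assert result.data.loc["G0", "rank"] == 1
        assert result.data.loc["G1", "score"] == pytest.approx(0.0)
        assert ((result.scores >= 0) & (result.scores <= 5)).all()

    def test_fixture_scores_match_normalize_and_sum_oracle(self, table_alsia):
        result = compute_indicator(table_alsia, condition="P-")
        raw = pd.DataFrame(
            {
                "pae": table_alsia.data["pae_pminus_mean"],
                "prae": table_alsia.data["prae_pminus_mean"],
                "pue": table_alsia.data["pue_pminus_mean"],
                "pre": table_alsia.data["relative_efficiency"],
                "apue": table_alsia.data["apue"],
            }
        )
        # independent normalize-and-sum oracle (brute-force formula)
        def norm(col):
            return (col - col.min()) / (col.max() - col.min())

        expected = (
            norm(raw["pae"])
            + (1 - norm(raw["prae"]))
            + norm(raw["pue"])
            + norm(raw["pre"])
            + norm(raw["apue"])
        )
        assert result.scores.to_numpy() == pytest.approx(expected.to_numpy(), abs=1e-12)

    def test_score_bounds_on_both_platform_fixtures(self, table_4pmi, table_alsia):
        for table in (table_4pmi, table_alsia):
            scores = compute_indicator(table).scores
            assert scores.between(0.0, 5.0).all()

    def test_missing_metric_excludes_genotype_with_warning(self, table_alsia):
        broken = table_alsia.data.copy()
        broken.loc["Rubisko", "apue"] = np.nan
        table = MetricTable(broken, platform_label="ALSIA")
        with pytest.warns(UserWarning, match="Rubisko"):
            result = compute_indicator(table)
        assert "Rubisko" not in result.data.index
        assert result.excluded == ("Rubisko",)
        assert len(result.data) == 25

    def test_row_permutation_permutes_output(self, table_alsia):
        base = compute_indicator(table_alsia)
        shuffled = MetricTable(
            table_alsia.data.sample(frac=1.0, random_state=0), platform_label="ALSIA"
        )
        perm = compute_indicator(shuffled)
        assert base.scores.sort_index().equals(perm.scores.sort_index())

    def test_rank_is_monotone_in_score(self, table_4pmi):
        result = compute_indicator(table_4pmi)
        ordered = result.data.sort_values("score", ascending=False)
        assert (ordered["rank"].diff().dropna() >= 0).all()

    def test_custom_orientation_flips_component(self, table_alsia):
        default = compute_indicator(table_alsia)
        flipped = compute_indicator(table_alsia, orientations={"prae": 1})
        assert flipped.data["prae"].to_numpy() == pytest.approx(
            (1 - default.data["prae"]).to_numpy()
        )

    def test_default_orientations_reward_low_prae(self):
        assert DEFAULT_ORIENTATIONS["prae"] == -1
        assert all(DEFAULT_ORIENTATIONS[m] == 1 for m in
                   ("pae", "pue", "relative_efficiency", "apue"))


class TestClassifyQuadrants:
    def test_identical_genotypes_are_all_er_by_tie_convention(self):
        idx = ["A", "B", "C"]
        result = classify_quadrants(
            pd.Series([5.0] * 3, index=idx), pd.Series([1.0] * 3, index=idx)
        )
        assert (result.classes == "ER").all()

    def test_synthetic_grid_one_genotype_per_class(self):
        idx = ["hh", "hl", "lh", "ll"]
        apue_vals = pd.Series([10.0, 10.0, 1.0, 1.0], index=idx)
        dw = pd.Series([2.0, 0.5, 2.0, 0.5], index=idx)
        result = classify_quadrants(apue_vals, dw)
        assert result.classes.to_dict() == {
            "hh": "ER", "hl": "NER", "lh": "ENR", "ll": "NENR"
        }
        assert sum(result.counts().values()) == 4

    def test_planted_quadrant_structure_recovered(self, rng):
        # well-separated two-cluster structure on both axes
        n = 13
        apue_vals = np.r_[rng.normal(80, 2, n), rng.normal(10, 2, n)]
        dw = np.r_[rng.normal(2.0, 0.05, n), rng.normal(0.4, 0.05, n)]
        rng.shuffle(apue_vals[:0])  # keep pairing: first half high/high
        idx = [f"G{i}" for i in range(2 * n)]
        result = classify_quadrants(
            pd.Series(apue_vals, index=idx), pd.Series(dw, index=idx)
        )
        assert (result.classes.iloc[:n] == "ER").all()
        assert (result.classes.iloc[n:] == "NENR").all()

    def test_mean_vs_median_moves_only_between_threshold_genotypes(self, table_alsia):
        apue_vals = table_alsia.data["apue"]
        dw = table_alsia.data["pue_pminus_mean"]  # any positive per-genotype axis
        mean_cls = classify_quadrants(apue_vals, dw, rule="mean")
        med_cls = classify_quadrants(apue_vals, dw, rule="median")
        lo_a, hi_a = sorted([mean_cls.apue_threshold, med_cls.apue_threshold])
        lo_d, hi_d = sorted([mean_cls.dw_threshold, med_cls.dw_threshold])
        changed = mean_cls.classes[mean_cls.classes != med_cls.classes].index
        for geno in changed:
            in_band = (lo_a <= apue_vals[geno] < hi_a) or (lo_d <= dw[geno] < hi_d)
            assert in_band

    def test_mismatched_genotype_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            classify_quadrants(
                pd.Series([1.0], index=["A"]), pd.Series([1.0], index=["B"])
            )
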