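"""Quintile scoring, index construction and decile binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdi_multiverse.config import (
    CodingVector,
    default_grouping,
    hpdi_coding,
    pdi_coding,
    updi_coding,
)
from pdi_multiverse.index import (
    build_index,
    decile_bins,
    map_items_to_groups,
    quantile_bin,
    quintile_scores,
)


def _rank_oracle(values, n_bins):
    """Independent oracle: hand-computed interpolated percentile
    cutpoints, then 1 + number of cutpoints strictly below the value."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    cuts = []
    for k in range(1, n_bins):
        pos = (k / n_bins) * (n - 1)
        lo = int(np.floor(pos))
        frac = pos - lo
        c = x[lo] if lo == n - 1 else x[lo] + frac * (x[lo + 1] - x[lo])
        cuts.append(c)
    return np.array([1 + sum(c < v for c in cuts) for v in values])


class TestQuantileBin:
    def test_distinct_values_balanced_quintiles(self):
        rng = np.random.default_rng(5)
        vals = rng.permutation(np.linspace(1, 50, 100))
        bins = quantile_bin(vals, 5)
        counts = np.bincount(bins, minlength=6)[1:]
        assert counts.tolist() == [20] * 5

    @pytest.mark.parametrize("n_bins", [5, 10])
    @pytest.mark.parametrize("zero_frac", [0.0, 0.3, 0.6])
    def test_matches_rank_oracle_with_and_without_ties(self, n_bins, zero_frac):
        rng = np.random.default_rng(17)
        n = 1000
        vals = np.exp(rng.normal(0, 0.8, n))
        vals[rng.random(n) < zero_frac] = 0.0
        assert np.array_equal(quantile_bin(vals, n_bins), _rank_oracle(vals, n_bins))

    def test_heavy_ties_take_lowest_applicable_bin(self):
        # 60 zeros + positives 1..40: quintile cutpoints interpolate to
        # (0, 0, 0.4, 20.2) so the attainable scores are exactly {1, 4, 5}
        vals = np.concatenate([np.zeros(60), np.arange(1.0, 41.0)])
        bins = quantile_bin(vals, 5)
        assert (bins[:60] == 1).all()
        counts = dict(zip(*np.unique(bins, return_counts=True)))
        assert counts == {1: 60, 4: 20, 5: 20}

    def test_all_identical_values_fall_in_bin_one(self):
        assert (quantile_bin(np.full(30, 2.5), 5) == 1).all()


class TestMapItems:
    def test_items_summed_into_groups(self, base_config):
        items = pd.DataFrame(
            {"white_potato": [0.5, 0.0], "french_fries": [0.3, 0.2]}
        )
        grouped, unmatched = map_items_to_groups(items, base_config)
        assert grouped["potatoes"].tolist() == [0.8, 0.2]
        assert unmatched == {}

    def test_unmatched_item_excluded_and_logged(self, base_config):
        items = pd.DataFrame({"white_potato": [0.5], "gravy": [0.7]})
        grouped, unmatched = map_items_to_groups(items, base_config)
        assert "gravy" not in grouped.columns
        assert unmatched == {"gravy": 1}

    def test_empty_table_rejected(self, base_config):
        with pytest.raises(ValueError, match="empty"):
            map_items_to_groups(pd.DataFrame(), base_config)


def _toy_scores(config, value):
    return pd.DataFrame({g: [value] for g in config.groups})


class TestQuintileScores:
    def test_reverse_is_complement_of_positive(self):
        rng = np.random.default_rng(3)
        intakes = pd.DataFrame({"fruits": rng.exponential(1.0, 200)})
        pos = CodingVector({"fruits": "positive"}, "p")
        rev = CodingVector({"fruits": "reverse"}, "r")
        sp = quintile_scores(intakes, pos)
        sr = quintile_scores(intakes, rev)
        assert ((sp["fruits"] + sr["fruits"]) == 6).all()

    def test_stratified_scoring_uses_within_stratum_cutpoints(self):
        # women's intakes all below men's: within-stratum scores still
        # span 1..5 in both strata
        vals = np.concatenate([np.linspace(0.1, 1, 100), np.linspace(10, 20, 100)])
        intakes = pd.DataFrame({"fruits": vals})
        stratum = pd.Series(["female"] * 100 + ["male"] * 100)
        s = quintile_scores(
            intakes, CodingVector({"fruits": "positive"}, "p"), stratum=stratum
        )
        assert set(s["fruits"][:100]) == {1, 2, 3, 4, 5}
        assert set(s["fruits"][100:]) == {1, 2, 3, 4, 5}

    def test_small_stratum_rejected(self):
        intakes = pd.DataFrame({"fruits": np.arange(30.0)})
        stratum = pd.Series(["female"] * 25 + ["male"] * 5)
        with pytest.raises(ValueError, match="male"):
            quintile_scores(
                intakes, CodingVector({"fruits": "positive"}, "p"), stratum=stratum
            )

    def test_negative_intake_rejected(self):
        intakes = pd.DataFrame({"fruits": [-0.1] + [1.0] * 30})
        with pytest.raises(ValueError, match="nonnegative"):
            quintile_scores(intakes, CodingVector({"fruits": "positive"}, "p"))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        base=st.lists(st.floats(0, 100, allow_nan=False), min_size=25, max_size=60),
        i=st.integers(0, 24),
        bump=st.floats(0.1, 50),
    )
    def test_score_monotone_in_intake_under_positive_coding(self, base, i, bump):
        intakes = pd.DataFrame({"g": base})
        coding = CodingVector({"g": "positive"}, "p")
        s0 = quintile_scores(intakes, coding)["g"].iloc[i]
        bumped = list(base)
        bumped[i] += bump
        s1 = quintile_scores(pd.DataFrame({"g": bumped}), coding)["g"].iloc[i]
        assert s1 >= s0


class TestBuildIndex:
    def test_theoretical_bounds_18_groups(self, base_config):
        coding = pdi_coding(base_config)
        lo = build_index(_toy_scores(base_config, 1), coding)
        hi = build_index(_toy_scores(base_config, 5), coding)
        assert lo["raw"].iloc[0] == 18 and lo["rescaled"].iloc[0] == 18
        assert hi["raw"].iloc[0] == 90 and hi["rescaled"].iloc[0] == 90

    def test_rescaling_17_groups(self):
        groups = [f"g{i}" for i in range(17)]
        coding = CodingVector({g: "positive" for g in groups}, "c")
        scores = pd.DataFrame({g: [5] for g in groups})  # raw = 85
        out = build_index(scores, coding)
        assert out["raw"].iloc[0] == 85
        assert out["rescaled"].iloc[0] == pytest.approx(90.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(G=st.integers(1, 30))
    def test_rescaled_bounds_for_any_group_count(self, G):
        groups = [f"g{i}" for i in range(G)]
        coding = CodingVector({g: "positive" for g in groups}, "c")
        lo = build_index(pd.DataFrame({g: [1] for g in groups}), coding)
        hi = build_index(pd.DataFrame({g: [5] for g in groups}), coding)
        assert lo["rescaled"].iloc[0] == pytest.approx(18.0)
        assert hi["rescaled"].iloc[0] == pytest.approx(90.0)

    def test_group_mismatch_rejected(self, base_config):
        coding = pdi_coding(base_config)
        scores = _toy_scores(base_config, 3).drop(columns=["fruits"])
        with pytest.raises(ValueError, match="fruits"):
            build_index(scores, coding)

    def test_flipping_one_group_changes_raw_by_complement(self, base_config):
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(
            {g: rng.integers(1, 6, 50) for g in base_config.groups}
        )
        coding = pdi_coding(base_config)
        flipped = coding.flipped("nuts")
        raw0 = build_index(scores, coding)["raw"]
        raw1 = build_index(scores.assign(nuts=6 - scores["nuts"]), flipped)["raw"]
        delta = raw1 - raw0
        assert ((delta == 6 - 2 * scores["nuts"])).all()
        assert delta.isin(range(-4, 5)).all()

    def test_updi_is_hpdi_with_all_plants_flipped(self, base_config):
        h = hpdi_coding(base_config)
        u = updi_coding(base_config)
        for g in base_config.plant_groups:
            assert h.direction[g] != u.direction[g]
        for g in base_config.animal_groups:
            assert h.direction[g] == u.direction[g] == "reverse"


class TestDecileBins:
    def test_balanced_partition_of_distinct_values(self):
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.permutation(np.linspace(18, 90, 100)))
        out = decile_bins(vals)
        assert out["bin"].value_counts().sort_index().tolist() == [10] * 10

    def test_bin_medians_nondecreasing(self, resolved_cohort, base_config):
        from pdi_multiverse.index import group_intake_table

        coding = pdi_coding(base_config)
        intakes = group_intake_table(resolved_cohort, base_config)
        scores = quintile_scores(intakes, coding, stratum=resolved_cohort["gender"])
        idx = build_index(scores, coding)
        out = decile_bins(idx["rescaled"], stratum=resolved_cohort["gender"])
        frame = pd.DataFrame(
            {"bin": out["bin"], "m": out["bin_median"],
             "g": resolved_cohort["gender"].to_numpy()}
        )
        for _, sub in frame.groupby("g"):
            med = sub.drop_duplicates("bin").sort_values("bin")["m"]
            assert med.is_monotonic_increasing

    def test_tied_values_partition_exhaustive_and_matches_oracle(self):
        vals = pd.Series(np.concatenate([np.full(70, 30.0), np.linspace(40, 90, 30)]))
        out = decile_bins(vals)
        assert out["bin"].between(1, 10).all()
        assert np.array_equal(out["bin"].to_numpy(), _rank_oracle(vals.to_numpy(), 10))
        # bin median attached per participant matches the bin's median
        for b, sub in out.groupby("bin"):
            assert (sub["bin_median"] == np.median(vals[out["bin"] == b])).all()
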