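"""Specification families, multiverse runs and group summaries."""

import numpy as np
import pandas as pd
import pytest

from pdi_multiverse.config import (
    default_grouping,
    scaled_grouping,
    hpdi_coding,
    pdi_coding,
)
from pdi_multiverse.index import build_index, group_intake_table, quintile_scores
from pdi_multiverse.multiverse import (
    enumerate_codings,
    leave_one_out_configs,
    recategorization_configs,
    replication_family,
    run_specs,
    summarize_all_groups,
    summarize_group,
)
from pdi_multiverse.survival import fit_cox, hr_per_10_units


class TestFamilies:
    def test_recategorization_has_six_members(self, base_config):
        fam = recategorization_configs(base_config)
        assert [m.label for m in fam.members] == [
            "replication", "model1", "model2", "model3", "model4", "model5",
        ]
        n_groups = {m.label: m.config.n_groups for m in fam.members}
        assert n_groups == {
            "replication": 18, "model1": 17, "model2": 18,
            "model3": 17, "model4": 19, "model5": 18,
        }

    def test_recategorization_requires_potato_group(self, base_config):
        fam = leave_one_out_configs(base_config)
        no_potato = next(m.config for m in fam.members if m.label == "loo_potatoes")
        with pytest.raises(ValueError, match="potatoes"):
            recategorization_configs(no_potato)

    def test_leave_one_out_has_twelve_members_covering_plants(self, base_config):
        fam = leave_one_out_configs(base_config)
        assert len(fam.members) == 12
        omitted = {
            next(iter(set(base_config.groups) - set(m.config.groups)))
            for m in fam.members
        }
        assert omitted == set(base_config.plant_groups)
        for m in fam.members:
            assert m.config.animal_groups == base_config.animal_groups

    def test_agnostic_enumeration_small(self):
        cfg = scaled_grouping(1, 1, 2)
        fam = enumerate_codings(cfg)
        assert [m.label for m in fam.members] == ["00", "01", "10", "11"]

    def test_agnostic_complement_closure(self, base_config):
        fam = enumerate_codings(base_config)
        labels = {m.label for m in fam.members}
        assert len(labels) == 4096
        complement = {
            "".join("1" if b == "0" else "0" for b in lbl) for lbl in labels
        }
        assert complement == labels


@pytest.fixture(scope="module")
def toy_setup(resolved_cohort):
    """A 2-plant-group configuration on the session cohort."""
    return scaled_grouping(1, 1, 2), resolved_cohort


class TestRunSpecs:
    def test_toy_agnostic_run_row_counts(self, toy_setup):
        cfg, resolved = toy_setup
        fam = enumerate_codings(cfg)
        res = run_specs(resolved, fam, forms=("continuous", "deciles"), covariates=())
        for form in ("per10", "extreme_decile"):
            for stratum in ("female", "male", "combined"):
                sub = res[(res["form"] == form) & (res["stratum"] == stratum)]
                assert len(sub) == 4

    def test_replication_family_matches_direct_calls(self, base_config, resolved_cohort):
        fam = replication_family(base_config)
        res = run_specs(
            resolved_cohort, fam, forms=("continuous",), indices=("hpdi",),
            covariates=(),
        )
        row = res[(res["stratum"] == "female") & (res["form"] == "per10")].iloc[0]

        coding = hpdi_coding(base_config)
        intakes = group_intake_table(resolved_cohort, base_config)
        scores = quintile_scores(intakes, coding, stratum=resolved_cohort["gender"])
        data = resolved_cohort.copy()
        data["idx"] = build_index(scores, coding)["rescaled"].to_numpy()
        est = hr_per_10_units(fit_cox(data, "idx", stratum="female"))
        assert row["hr"] == pytest.approx(est.hr, rel=1e-12)
        assert row["p"] == pytest.approx(est.p, rel=1e-12)

    def test_structural_identities_participantwise(self, base_config, resolved_cohort):
        def index_values(config, coding_fn):
            coding = coding_fn(config)
            intakes = group_intake_table(resolved_cohort, config)
            scores = quintile_scores(intakes, coding, stratum=resolved_cohort["gender"])
            return build_index(scores, coding)["rescaled"].to_numpy()

        recat = {m.label: m.config for m in recategorization_configs(base_config).members}
        loo = {m.label: m.config for m in leave_one_out_configs(base_config).members}
        # moving potatoes to healthy cannot change the all-plants-positive index
        assert np.array_equal(
            index_values(recat["replication"], pdi_coding),
            index_values(recat["model2"], pdi_coding),
        )
        # dropping the group and leaving it out are the same configuration
        for fn in (pdi_coding, hpdi_coding):
            assert np.array_equal(
                index_values(recat["model1"], fn),
                index_values(loo["loo_potatoes"], fn),
            )


def _synthetic_agnostic_results(P, beta_fn, stratum="combined", form="per10"):
    rows = []
    for i in range(2**P):
        bits = format(i, f"0{P}b")
        rows.append(
            {
                "family": "agnostic", "label": bits, "coding": bits,
                "index": bits, "stratum": stratum, "form": form,
                "beta": beta_fn(bits), "se": 0.1,
                "hr": np.exp(beta_fn(bits)), "p": 0.5, "converged": True,
            }
        )
    return pd.DataFrame(rows)


class TestSummarizeGroup:
    def test_degenerate_identical_hrs(self):
        cfg = scaled_grouping(2, 1, 2)  # P = 3
        res = _synthetic_agnostic_results(3, lambda bits: 0.05)
        gs = summarize_group(res, cfg.plant_groups[0], cfg)
        assert gs.difference == pytest.approx(0.0)
        assert gs.ratio == pytest.approx(1.0)
        assert gs.n_pairs == 4

    def test_bit_flip_multiplying_hr_by_k_gives_ratio_inverse_k(self):
        cfg = scaled_grouping(2, 1, 2)
        k = 1.25
        g = cfg.plant_groups[1]
        gi = cfg.plant_groups.index(g)

        def beta_fn(bits):
            # reverse coding of g multiplies the HR by k; other bits
            # contribute arbitrary distinct effects
            other = sum(0.07 * (j + 1) * int(b) for j, b in enumerate(bits) if j != gi)
            return other + (np.log(k) if bits[gi] == "0" else 0.0)

        res = _synthetic_agnostic_results(3, beta_fn)
        gs = summarize_group(res, g, cfg)
        assert gs.ratio == pytest.approx(1 / k, rel=1e-12)

    def test_footnote_identity_between_ratio_and_means(self):
        cfg = scaled_grouping(2, 1, 2)
        rng = np.random.default_rng(8)
        betas = {format(i, "03b"): rng.normal(0, 0.1) for i in range(8)}
        res = _synthetic_agnostic_results(3, lambda bits: betas[bits])
        gs = summarize_group(res, cfg.plant_groups[0], cfg)
        assert gs.ratio * gs.mean_hr_reverse == pytest.approx(gs.mean_hr_positive)
        assert gs.difference == pytest.approx(gs.mean_hr_positive - gs.mean_hr_reverse)

    def test_incomplete_family_rejected_naming_missing(self):
        cfg = scaled_grouping(2, 1, 2)
        res = _synthetic_agnostic_results(3, lambda bits: 0.0)
        res = res[res["coding"] != "011"]
        with pytest.raises(ValueError, match="011"):
            summarize_group(res, cfg.plant_groups[0], cfg)

    def test_nonconverged_pairs_dropped_together(self):
        cfg = scaled_grouping(2, 1, 2)
        res = _synthetic_agnostic_results(3, lambda bits: 0.05 * bits.count("1"))
        res.loc[res["coding"] == "111", "converged"] = False
        g = cfg.plant_groups[0]
        gs = summarize_group(res, g, cfg)
        assert gs.n_pairs == 3 and gs.n_dropped_pairs == 1

    def test_summarize_all_groups_table_shape(self):
        cfg = scaled_grouping(2, 1, 2)
        res = _synthetic_agnostic_results(3, lambda bits: 0.02 * int(bits, 2))
        table = summarize_all_groups(res, cfg, strata=("combined",), forms=("per10",))
        assert len(table) == 3
        assert set(table["group"]) == set(cfg.plant_groups)
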