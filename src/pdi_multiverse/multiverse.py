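"""Robustness procedures over index specifications.

Three families of index specifications are enumerated and run against
the same cohort:

* **recategorization** — six configurations probing the potatoes group:
  the replication plus five alternatives (drop the group; move it intact
  to the healthy super-category; merge its items into vegetables; split
  white potato out as a new healthy group; move white potato into
  vegetables) with the index rescaled whenever the group count changes;
* **leave-one-out** — the 12 configurations each omitting one plant
  group;
* **agnostic** — the exhaustive enumeration of every positive/reverse
  coding of the plant groups (2**12 = 4,096 at the default 12), animal
  groups fixed reverse.

For each specification and gender stratum the cohort is rescored from
scratch (with caching of quintile scores, which depend only on a
group's own summed-intake distribution), Cox models are fitted in the
requested exposure forms, and stratum estimates are pooled by
fixed-effects meta-analysis.  The agnostic family is summarised per
food group by splitting the models into those coding the group
positively vs reversely and comparing the two HR distributions:
``difference = exp(mean log HR_pos) - exp(mean log HR_rev)``,
``ratio = exp(mean log HR_pos) / exp(mean log HR_rev)``, and a paired
t-test of log HRs pairing each model with its single-bit-flipped
counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    ANIMAL,
    HEALTHY_PLANT,
    UNHEALTHY_PLANT,
    POTATO_ITEMS,
    CodingVector,
    FoodGroupingConfig,
    STANDARD_CODINGS,
    enumerate_plant_codings,
)
from .index import build_index, decile_bins, group_intake_table, quintile_scores
from .survival import (
    TermEstimate,
    default_covariates,
    add_quintile_covariates,
    extreme_decile_contrast,
    fit_cox,
    hr_per_10_units,
    meta_fixed_effects,
)

__all__ = [
    "SpecMember",
    "SpecFamily",
    "GroupSummary",
    "replication_family",
    "recategorization_configs",
    "leave_one_out_configs",
    "enumerate_codings",
    "run_specs",
    "summarize_group",
    "summarize_all_groups",
]


@dataclass(frozen=True)
class SpecMember:
    """One index specification: a grouping config and, for the agnostic
    family, an explicit coding vector (``None`` means the standard
    PDI/hPDI/uPDI codings derived from the config's super-categories)."""

    config: FoodGroupingConfig
    coding: CodingVector | None
    label: str


@dataclass(frozen=True)
class SpecFamily:
    family: str  # replication | recategorization | leave_one_out | agnostic
    members: tuple[SpecMember, ...]
    base: FoodGroupingConfig

    def to_manifest(self) -> dict:
        return {
            "family": self.family,
            "n_members": len(self.members),
            "base_digest": self.base.digest(),
            "members": [
                {
                    "label": m.label,
                    "config_label": m.config.label,
                    "config_digest": m.config.digest(),
                    "coding": None if m.coding is None else m.coding.to_dict(),
                }
                for m in self.members
            ],
        }


def replication_family(base: FoodGroupingConfig) -> SpecFamily:
    member = SpecMember(config=base, coding=None, label="replication")
    return SpecFamily(family="replication", members=(member,), base=base)


def _require_potatoes(base: FoodGroupingConfig) -> None:
    if "potatoes" not in base.groups:
        raise ValueError("base configuration has no 'potatoes' group")
    items = set(base.items_of("potatoes"))
    missing = [i for i in POTATO_ITEMS if i not in items]
    if missing:
        raise ValueError(f"potatoes group lacks expected items: {missing}")


def recategorization_configs(base: FoodGroupingConfig) -> SpecFamily:
    """The replication plus the five potato-recategorization models."""
    _require_potatoes(base)
    members = [SpecMember(base, None, "replication")]

    # model 1: exclude the potatoes group entirely (its items unmatched)
    groups1 = tuple(g for g in base.groups if g != "potatoes")
    cfg1 = FoodGroupingConfig(
        groups=groups1,
        super_category={g: base.super_category[g] for g in groups1},
        item_map={i: g for i, g in base.item_map.items() if g != "potatoes"},
        label="model1_exclude_potato_group",
    )
    members.append(SpecMember(cfg1, None, "model1"))

    # model 2: potatoes group intact but re-labelled healthy
    sc2 = dict(base.super_category)
    sc2["potatoes"] = HEALTHY_PLANT
    cfg2 = replace(base, super_category=sc2, label="model2_potato_group_in_healthy")
    members.append(SpecMember(cfg2, None, "model2"))

    # model 3: all potato items merged into vegetables
    im3 = dict(cfg1.item_map)
    im3.update({i: "vegetables" for i in POTATO_ITEMS})
    cfg3 = replace(cfg1, item_map=im3, label="model3_potatoes_in_vegetable_group")
    members.append(SpecMember(cfg3, None, "model3"))

    # model 4: white potato as a new single-item healthy group, the
    # remaining items stay as an unhealthy potatoes group
    groups4 = base.groups + ("white_potato",)
    sc4 = dict(base.super_category)
    sc4["white_potato"] = HEALTHY_PLANT
    im4 = dict(base.item_map)
    im4["white_potato"] = "white_potato"
    cfg4 = FoodGroupingConfig(
        groups=groups4, super_category=sc4, item_map=im4,
        label="model4_healthy_and_unhealthy_potatoes",
    )
    members.append(SpecMember(cfg4, None, "model4"))

    # model 5: white potato into vegetables, the rest stay in potatoes
    im5 = dict(base.item_map)
    im5["white_potato"] = "vegetables"
    cfg5 = replace(base, item_map=im5, label="model5_vegetables_and_unhealthy_potatoes")
    members.append(SpecMember(cfg5, None, "model5"))

    return SpecFamily(family="recategorization", members=tuple(members), base=base)


def leave_one_out_configs(base: FoodGroupingConfig) -> SpecFamily:
    """One configuration per plant group, omitting that group (animal
    groups untouched); indices are rescaled to 18-90 as usual."""
    members = []
    for g in base.plant_groups:
        groups = tuple(x for x in base.groups if x != g)
        cfg = FoodGroupingConfig(
            groups=groups,
            super_category={x: base.super_category[x] for x in groups},
            item_map={i: grp for i, grp in base.item_map.items() if grp != g},
            label=f"loo_{g}",
        )
        members.append(SpecMember(cfg, None, f"loo_{g}"))
    return SpecFamily(family="leave_one_out", members=tuple(members), base=base)


def enumerate_codings(base: FoodGroupingConfig) -> SpecFamily:
    """All 2**P plant-group codings (deterministic lexicographic order,
    labels are the direction bit strings)."""
    members = tuple(
        SpecMember(base, coding, coding.label)
        for coding in enumerate_plant_codings(base)
    )
    return SpecFamily(family="agnostic", members=members, base=base)


# ---------------------------------------------------------------------------


def _group_sources(config: FoodGroupingConfig, group: str, columns) -> tuple[str, ...]:
    """Actual intake columns summed into a group (cache key)."""
    srcs = []
    if f"intake_{group}" in columns:
        srcs.append(f"intake_{group}")
    for item in config.items_of(group):
        if f"intake_{item}" in columns:
            srcs.append(f"intake_{item}")
    return tuple(sorted(srcs))


class _ScoreCache:
    """Positive quintile scores per unique group composition.

    A group's quintile score depends only on its own summed intake
    distribution (and the stratification), so compositions shared
    between specifications are scored once.
    """

    def __init__(self, resolved: pd.DataFrame, stratify: bool, min_stratum_size: int):
        self.resolved = resolved
        self.stratum = resolved["gender"] if stratify else None
        self.min_stratum_size = min_stratum_size
        self._cache: dict[tuple[str, ...], np.ndarray] = {}

    def positive_scores(self, config: FoodGroupingConfig) -> pd.DataFrame:
        cols = {}
        todo = []
        for g in config.groups:
            key = _group_sources(config, g, self.resolved.columns)
            if not key:
                raise ValueError(f"no intake columns found for group {g!r}")
            if key in self._cache:
                cols[g] = self._cache[key]
            else:
                todo.append((g, key))
        if todo:
            sub = FoodGroupingConfig(
                groups=tuple(g for g, _ in todo),
                super_category={g: config.super_category[g] for g, _ in todo},
                item_map={
                    i: g
                    for i, g in config.item_map.items()
                    if g in {g_ for g_, _ in todo}
                },
                label="cache_fill",
            )
            intakes = group_intake_table(self.resolved, sub)
            coding = CodingVector(
                direction={g: "positive" for g, _ in todo}, label="positive"
            )
            scored = quintile_scores(
                intakes, coding, stratum=self.stratum,
                min_stratum_size=self.min_stratum_size,
            )
            for g, key in todo:
                arr = scored[g].to_numpy()
                self._cache[key] = arr
                cols[g] = arr
        return pd.DataFrame(cols, index=self.resolved.index)


def _codings_for(member: SpecMember, indices: tuple[str, ...]) -> list[CodingVector]:
    if member.coding is not None:
        return [member.coding]
    return [STANDARD_CODINGS[name](member.config) for name in indices]


def run_specs(
    resolved: pd.DataFrame,
    family: SpecFamily,
    forms: tuple[str, ...] = ("continuous", "deciles"),
    indices: tuple[str, ...] = ("pdi", "hpdi", "updi"),
    strata: tuple[str, ...] = ("female", "male"),
    covariates: str | tuple[str, ...] | list[str] = "default",
    stratify_quantiles: bool = True,
    include_trend: bool = False,
    min_stratum_size: int = 20,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every member specification of a family against a cohort.

    ``resolved`` must have passed eligibility and exposure resolution.
    Returns a long-format frame with one row per member x coding x
    stratum (plus the meta-combined ``"combined"`` stratum) x form,
    where form is ``per10`` (HR per 10 index units), ``extreme_decile``
    (highest vs lowest bin) and optionally ``trend``.  Non-converged
    member fits are flagged, not fatal.
    """
    bad = [f for f in forms if f not in ("continuous", "deciles")]
    if bad:
        raise ValueError(f"unknown forms {bad}")
    if covariates == "default":
        if "energy_q" not in resolved.columns:
            resolved = add_quintile_covariates(resolved)
        covs_by_stratum = {s: default_covariates(s) for s in strata}
    else:
        covs_by_stratum = {s: list(covariates) for s in strata}

    cache = _ScoreCache(resolved, stratify_quantiles, min_stratum_size)
    gender = resolved["gender"]
    rows: list[dict] = []
    iterator = family.members
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc=family.family)

    for member in iterator:
        pos = cache.positive_scores(member.config)
        for coding in _codings_for(member, indices):
            coding.validate_against(member.config)
            scores = pos.copy()
            for g in member.config.groups:
                if not coding.is_positive(g):
                    scores[g] = 6 - scores[g]
            idx = build_index(scores, coding)
            work = resolved.copy()
            work["index_value"] = idx["rescaled"].to_numpy()
            if "deciles" in forms or include_trend:
                db = decile_bins(
                    work["index_value"],
                    stratum=gender if stratify_quantiles else None,
                )
                work["decile_bin"] = db["bin"].to_numpy()
                work["bin_median"] = db["bin_median"].to_numpy()

            index_label = coding.label if member.coding is not None else coding.label
            base_row = {
                "family": family.family,
                "label": member.label,
                "config_label": member.config.label,
                "index": index_label,
                "coding": coding.label,
            }

            def _fit_form(form, col, extract):
                per_stratum = {}
                for s in strata:
                    try:
                        fit = fit_cox(
                            work, col, form=form,
                            covariates=covs_by_stratum[s], stratum=s,
                        )
                        est = extract(fit) if fit.converged else None
                        per_stratum[s] = (fit, est)
                    except ValueError as err:
                        per_stratum[s] = (None, None)
                        rows.append(
                            {**base_row, "stratum": s, "form": _form_name(form),
                             "converged": False, "message": str(err)}
                        )
                for s, (fit, est) in per_stratum.items():
                    if fit is None:
                        continue
                    rows.append(
                        {**base_row, "stratum": s, "form": _form_name(form),
                         "beta": est.beta if est else np.nan,
                         "se": est.se if est else np.nan,
                         "hr": est.hr if est else np.nan,
                         "hr_lcl": est.ci[0] if est else np.nan,
                         "hr_ucl": est.ci[1] if est else np.nan,
                         "p": est.p if est else np.nan,
                         "n": fit.n, "n_events": fit.n_events,
                         "converged": fit.converged, "message": fit.message}
                    )
                ests = [e for _, e in per_stratum.values() if e is not None]
                if len(ests) == len(strata) and len(strata) > 1:
                    meta = meta_fixed_effects(ests)
                    est = TermEstimate(beta=meta.beta, se=meta.se)
                    rows.append(
                        {**base_row, "stratum": "combined", "form": _form_name(form),
                         "beta": est.beta, "se": est.se, "hr": est.hr,
                         "hr_lcl": est.ci[0], "hr_ucl": est.ci[1], "p": est.p,
                         "n": sum(f.n for f, _ in per_stratum.values() if f),
                         "n_events": sum(f.n_events for f, _ in per_stratum.values() if f),
                         "converged": True, "message": ""}
                    )

            if "continuous" in forms:
                _fit_form("continuous", "index_value", hr_per_10_units)
            if "deciles" in forms:
                _fit_form("deciles", "decile_bin", extreme_decile_contrast)
            if include_trend:
                _fit_form(
                    "trend", "bin_median",
                    lambda f: f.term(f.exposure_term),
                )

    out = pd.DataFrame(rows)
    for c in ("beta", "se", "hr", "hr_lcl", "hr_ucl", "p"):
        if c not in out.columns:
            out[c] = np.nan
    out["converged"] = out.get("converged", True)
    if "message" in out.columns:
        out["message"] = out["message"].fillna("")
    return out


def _form_name(form: str) -> str:
    return {"continuous": "per10", "deciles": "extreme_decile", "trend": "trend"}[form]


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """Distributional comparison of HRs between the agnostic models
    coding a food group positively vs reversely."""

    group: str
    stratum: str
    form: str
    mean_hr_positive: float  # exp(mean log HR)
    mean_hr_reverse: float
    spread_positive: tuple[float, float]  # 2.5th/97.5th HR percentiles
    spread_reverse: tuple[float, float]
    median_positive: float
    median_reverse: float
    min_positive: float
    max_positive: float
    min_reverse: float
    max_reverse: float
    difference: float  # exp(mean log pos) - exp(mean log rev)
    ratio: float  # exp(mean log pos) / exp(mean log rev)
    t_statistic: float
    p_paired_t: float
    n_pairs: int
    n_dropped_pairs: int

    def to_row(self) -> dict:
        return {
            "group": self.group, "stratum": self.stratum, "form": self.form,
            "mean_hr_positive": self.mean_hr_positive,
            "spread_lo_positive": self.spread_positive[0],
            "spread_hi_positive": self.spread_positive[1],
            "median_positive": self.median_positive,
            "min_positive": self.min_positive, "max_positive": self.max_positive,
            "mean_hr_reverse": self.mean_hr_reverse,
            "spread_lo_reverse": self.spread_reverse[0],
            "spread_hi_reverse": self.spread_reverse[1],
            "median_reverse": self.median_reverse,
            "min_reverse": self.min_reverse, "max_reverse": self.max_reverse,
            "difference": self.difference, "ratio": self.ratio,
            "t_statistic": self.t_statistic, "p_paired_t": self.p_paired_t,
            "n_pairs": self.n_pairs, "n_dropped_pairs": self.n_dropped_pairs,
        }


def _agnostic_slice(
    results: pd.DataFrame, base: FoodGroupingConfig, stratum: str, form: str
) -> pd.Series:
    sel = results[
        (results["family"] == "agnostic")
        & (results["stratum"] == stratum)
        & (results["form"] == form)
    ]
    if sel.empty:
        raise ValueError(f"no agnostic results for stratum={stratum!r}, form={form!r}")
    P = len(base.plant_groups)
    expected = {format(i, f"0{P}b") for i in range(2**P)}
    got = set(sel["coding"])
    missing = expected - got
    if missing:
        some = sorted(missing)[:5]
        raise ValueError(
            f"agnostic family incomplete: {len(missing)} coding vectors missing "
            f"(e.g. {some})"
        )
    s = sel.set_index("coding")
    if s.index.has_duplicates:
        raise ValueError("duplicate coding vectors in agnostic results")
    beta = s["beta"].where(s["converged"].astype(bool))
    return beta


def summarize_group(
    results: pd.DataFrame,
    group: str,
    base: FoodGroupingConfig,
    stratum: str = "combined",
    form: str = "per10",
) -> GroupSummary:
    """Compare the HR distributions of models coding ``group``
    positively vs reversely within a complete agnostic family.

    The paired t-test pairs every model with its counterpart differing
    only in this group's direction (2**(P-1) pairs); pairs with a
    non-converged member are dropped together and counted.
    """
    plants = base.plant_groups
    if group not in plants:
        raise ValueError(f"{group!r} is not a plant group of the base configuration")
    gi = plants.index(group)
    beta = _agnostic_slice(results, base, stratum, form)
    P = len(plants)

    pos_labels = [lbl for lbl in beta.index if lbl[gi] == "1"]
    diffs, dropped = [], 0
    for lbl in pos_labels:
        partner = lbl[:gi] + "0" + lbl[gi + 1:]
        b1, b0 = beta.loc[lbl], beta.loc[partner]
        if np.isnan(b1) or np.isnan(b0):
            dropped += 1
        else:
            diffs.append(b1 - b0)
    diffs = np.asarray(diffs)
    if diffs.size < 2:
        raise ValueError("fewer than two complete pairs; paired t-test undefined")
    t_stat, p_t = stats.ttest_1samp(diffs, 0.0)

    def side_stats(positive: bool):
        want = "1" if positive else "0"
        b = beta[[lbl[gi] == want for lbl in beta.index]].dropna().to_numpy()
        hr = np.exp(b)
        return (
            float(np.exp(b.mean())),
            (float(np.percentile(hr, 2.5)), float(np.percentile(hr, 97.5))),
            float(np.median(hr)),
            float(hr.min()),
            float(hr.max()),
        )

    mp, sp, medp, minp, maxp = side_stats(True)
    mr, sr, medr, minr, maxr = side_stats(False)
    return GroupSummary(
        group=group, stratum=stratum, form=form,
        mean_hr_positive=mp, mean_hr_reverse=mr,
        spread_positive=sp, spread_reverse=sr,
        median_positive=medp, median_reverse=medr,
        min_positive=minp, max_positive=maxp,
        min_reverse=minr, max_reverse=maxr,
        difference=mp - mr, ratio=mp / mr,
        t_statistic=float(t_stat), p_paired_t=float(p_t),
        n_pairs=int(diffs.size), n_dropped_pairs=int(dropped),
    )


def summarize_all_groups(
    results: pd.DataFrame,
    base: FoodGroupingConfig,
    strata: tuple[str, ...] = ("female", "male", "combined"),
    forms: tuple[str, ...] = ("per10",),
) -> pd.DataFrame:
    """Group summaries for every plant group, as a long-format table."""
    rows = []
    for form in forms:
        for stratum in strata:
            for g in base.plant_groups:
                rows.append(summarize_group(results, g, base, stratum, form).to_row())
    return pd.DataFrame(rows)
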