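"""Quintile scoring and index construction for plant-based diet indices.

Each food group's summed intake is divided into within-cohort quintiles
and scored 1-5; a positively coded group gives higher scores for higher
intake, a reversely coded group the complement ``6 - s``.  The group
scores are summed into a raw index on ``[G, 5G]`` for ``G`` active
groups and linearly rescaled to the canonical 18-90 range (with the
default 18 groups the raw and rescaled indices coincide).  For decile
analyses the index is partitioned into within-cohort decile bins and
each bin is tagged with its median index value (used for the trend
test).

Tie handling (quantile cutpoints are empirical percentiles with linear
interpolation): a value equal to a cutpoint falls in the lower bin, and
when zero inflation duplicates cutpoints the affected participants take
the lowest applicable score.  This makes scoring deterministic under
the heavy ties at zero that FFQ-style group intakes produce.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CodingVector, FoodGroupingConfig

__all__ = [
    "map_items_to_groups",
    "group_intake_table",
    "quintile_scores",
    "build_index",
    "decile_bins",
    "quantile_bin",
]

#: Theoretical bounds of the rescaled index.
INDEX_MIN, INDEX_MAX = 18.0, 90.0


def quantile_bin(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign 1-based quantile-bin labels with the lower-bin tie rule.

    Cutpoints are the ``k/n_bins`` empirical percentiles (linear
    interpolation); a value goes into bin ``1 + #{cutpoints < value}``,
    so values equal to a cutpoint take the lower bin and duplicated
    cutpoints collapse bins downward.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("values contain NaN")
    qs = np.arange(1, n_bins) * (100.0 / n_bins)
    cut = np.percentile(values, qs)
    return 1 + (values[:, None] > cut[None, :]).sum(axis=1)


def map_items_to_groups(
    item_intakes: pd.DataFrame, config: FoodGroupingConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sum item-level intake columns into group-level columns.

    Items without a group under ``config.item_map`` are excluded and
    logged (column name -> number of nonzero records dropped with it).

    Parameters
    ----------
    item_intakes
        One column per food item, one row per participant.
    """
    if item_intakes.shape[1] == 0 or item_intakes.shape[0] == 0:
        raise ValueError("item intake table is empty")
    groups: dict[str, np.ndarray] = {}
    unmatched: dict[str, int] = {}
    for col in item_intakes.columns:
        g = config.item_map.get(col)
        if g is None:
            unmatched[col] = int((item_intakes[col] > 0).sum())
            continue
        vals = item_intakes[col].to_numpy(dtype=float)
        groups[g] = groups.get(g, 0.0) + vals
    out = pd.DataFrame(groups, index=item_intakes.index)
    return out, unmatched


def group_intake_table(
    resolved: pd.DataFrame,
    config: FoodGroupingConfig,
    prefix: str = "intake_",
) -> pd.DataFrame:
    """Build the per-group intake table for a configuration.

    For each group of ``config``, sums the direct group column
    ``<prefix><group>`` (if present) and any mapped item columns
    ``<prefix><item>``.  Raises if a group has no data at all.
    """
    out = {}
    for g in config.groups:
        total = np.zeros(len(resolved))
        found = False
        col = f"{prefix}{g}"
        if col in resolved.columns:
            total = total + resolved[col].to_numpy(dtype=float)
            found = True
        for item in config.items_of(g):
            icol = f"{prefix}{item}"
            if icol in resolved.columns:
                total = total + resolved[icol].to_numpy(dtype=float)
                found = True
        if not found:
            raise ValueError(f"no intake columns found for group {g!r}")
        out[g] = total
    return pd.DataFrame(out, index=resolved.index)


def quintile_scores(
    group_intakes: pd.DataFrame,
    coding: CodingVector,
    stratum: pd.Series | None = None,
    min_stratum_size: int = 20,
) -> pd.DataFrame:
    """Score each group 1-5 by within-stratum intake quintiles.

    Positive direction: 1 for the lowest quintile up to 5 for the
    highest.  Reverse direction: the complement ``6 - s``.  With
    ``stratum`` given (e.g. gender), cutpoints are computed separately
    within each stratum; strata smaller than ``min_stratum_size`` are
    rejected, since quintiles of a handful of values are meaningless.
    """
    if (group_intakes.to_numpy() < 0).any():
        raise ValueError("group intakes must be nonnegative")
    missing = [g for g in coding.direction if g not in group_intakes.columns]
    if missing:
        raise ValueError(f"group intake table lacks coded groups: {missing}")

    scores = pd.DataFrame(index=group_intakes.index, dtype=int)
    if stratum is None:
        strata = [(None, group_intakes.index)]
    else:
        stratum = stratum.loc[group_intakes.index]
        strata = [(k, idx) for k, idx in group_intakes.groupby(stratum).groups.items()]
    for key, idx in strata:
        if len(idx) < min_stratum_size:
            raise ValueError(
                f"stratum {key!r} has {len(idx)} participants, fewer than "
                f"min_stratum_size={min_stratum_size}"
            )
    pos = {p: i for i, p in enumerate(group_intakes.index)}
    for g in coding.direction:
        col = np.empty(len(group_intakes), dtype=int)
        for _, idx in strata:
            vals = group_intakes.loc[idx, g].to_numpy(dtype=float)
            s = quantile_bin(vals, 5)
            if not coding.is_positive(g):
                s = 6 - s
            col[[pos[p] for p in idx]] = s
        scores[g] = col
    return scores


def build_index(scores: pd.DataFrame, coding: CodingVector) -> pd.DataFrame:
    """Sum group scores into the raw index and rescale to 18-90.

    ``raw`` lies in ``[G, 5G]`` for ``G`` active groups;
    ``rescaled = raw * 18 / G`` is the unique linear map through the
    origin sending that interval onto ``[18, 90]``.
    """
    wanted = list(coding.direction)
    missing = [g for g in wanted if g not in scores.columns]
    extra = [g for g in scores.columns if g not in coding.direction]
    if missing or extra:
        raise ValueError(
            f"score matrix / coding vector mismatch (missing={missing}, extra={extra})"
        )
    G = len(wanted)
    raw = scores[wanted].sum(axis=1).astype(float)
    out = pd.DataFrame({"raw": raw, "rescaled": raw * (INDEX_MIN / G)})
    return out


def decile_bins(
    index_values: pd.Series, stratum: pd.Series | None = None
) -> pd.DataFrame:
    """Partition index values into within-stratum decile bins.

    Returns a frame with integer ``bin`` in 1..10 and ``bin_median``,
    the median index value of the participant's bin (bin 1 collects
    values at or below the first decile cutpoint, bin 10 those above the
    ninth).  Ties follow the lower-bin rule of :func:`quantile_bin`, so
    the partition is exhaustive and disjoint even with heavy ties.
    """
    vals = index_values.to_numpy(dtype=float)
    bins = np.empty(len(vals), dtype=int)
    if stratum is None:
        groups = [np.arange(len(vals))]
    else:
        stratum = stratum.loc[index_values.index]
        codes = pd.factorize(stratum)[0]
        groups = [np.flatnonzero(codes == k) for k in range(codes.max() + 1)]
    medians = np.empty(len(vals))
    for loc in groups:
        b = quantile_bin(vals[loc], 10)
        bins[loc] = b
        for k in np.unique(b):
            sel = loc[b == k]
            medians[sel] = np.median(vals[sel])
    return pd.DataFrame({"bin": bins, "bin_median": medians}, index=index_values.index)
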