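"""Publication-style output tables and their export.

Tables are the contract; plots are a thin optional layer over them so
that everything is testable headless.  Exports use a fixed float format
(10 significant digits) and canonical row ordering, so two exports of
the same bundle are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ReportBundle", "build_report", "export", "read_table", "plot_bundle"]

FLOAT_FORMAT = "%.10g"


@dataclass
class ReportBundle:
    """Assembled result tables plus a run manifest.

    * ``volcano`` — one row per specification x stratum x form with its
      HR and p-value (the volcano-plot data).
    * ``distribution`` — agnostic HRs in long form, keyed by food group
      and coding direction (violin-plot data).
    * ``ecdf`` — the same HRs sorted with cumulative fractions.
    * ``decile_medians`` — per index, stratum and bin the median index
      value.
    * ``summaries`` — per-group distributional comparisons.
    * ``manifest`` — seeds, config digests, versions, exclusion counts.
    """

    volcano: pd.DataFrame
    distribution: pd.DataFrame
    ecdf: pd.DataFrame
    decile_medians: pd.DataFrame
    summaries: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _distribution_table(results: pd.DataFrame, plant_groups) -> pd.DataFrame:
    ag = results[(results["family"] == "agnostic") & results["converged"].astype(bool)]
    rows = []
    for _, r in ag.iterrows():
        bits = r["coding"]
        for i, g in enumerate(plant_groups):
            rows.append(
                {
                    "group": g,
                    "direction": "positive" if bits[i] == "1" else "reverse",
                    "stratum": r["stratum"],
                    "form": r["form"],
                    "coding": bits,
                    "hr": r["hr"],
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "direction", "stratum", "form", "coding", "hr"]
    )


def _ecdf_table(distribution: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if distribution.empty:
        return pd.DataFrame(
            columns=["group", "direction", "stratum", "form", "hr", "cum_fraction"]
        )
    keys = ["group", "direction", "stratum", "form"]
    for key, sub in distribution.groupby(keys, sort=True):
        hrs = np.sort(sub["hr"].to_numpy(dtype=float))
        frac = np.arange(1, hrs.size + 1) / hrs.size
        for h, f in zip(hrs, frac):
            rows.append(dict(zip(keys, key)) | {"hr": h, "cum_fraction": f})
    return pd.DataFrame(rows)


def build_report(
    results: pd.DataFrame,
    summaries: pd.DataFrame | None = None,
    decile_medians: pd.DataFrame | None = None,
    plant_groups: tuple[str, ...] = (),
    manifest: dict | None = None,
) -> ReportBundle:
    """Assemble the report tables from a long-format results frame
    (:func:`pdi_multiverse.multiverse.run_specs` output) and optional
    group summaries and decile-median tables."""
    if results.empty:
        raise ValueError("results frame is empty")
    volcano_cols = [
        "family", "label", "index", "coding", "stratum", "form",
        "hr", "hr_lcl", "hr_ucl", "p", "converged",
    ]
    volcano = (
        results.reindex(columns=volcano_cols)
        .sort_values(["family", "label", "index", "stratum", "form"], kind="mergesort")
        .reset_index(drop=True)
    )
    distribution = _distribution_table(results, plant_groups)
    ecdf = _ecdf_table(distribution)
    if summaries is None:
        summaries = pd.DataFrame()
    if decile_medians is None:
        decile_medians = pd.DataFrame(columns=["index", "stratum", "bin", "median"])
    return ReportBundle(
        volcano=volcano,
        distribution=distribution.sort_values(
            ["group", "direction", "stratum", "form", "coding"], kind="mergesort"
        ).reset_index(drop=True),
        ecdf=ecdf,
        decile_medians=decile_medians,
        summaries=summaries,
        manifest=manifest or {},
    )


def decile_median_table(
    resolved: pd.DataFrame, index_values: dict[str, pd.Series], stratify: bool = True
) -> pd.DataFrame:
    """Median index value per decile bin per gender stratum, for each
    named index (the standard replication display)."""
    from .index import decile_bins

    rows = []
    for name, vals in index_values.items():
        stratum = resolved["gender"] if stratify else None
        db = decile_bins(vals, stratum=stratum)
        frame = pd.DataFrame(
            {
                "bin": db["bin"],
                "value": vals,
                "stratum": resolved["gender"] if stratify else "all",
            }
        )
        med = frame.groupby(["stratum", "bin"])["value"].median().reset_index()
        for _, r in med.iterrows():
            rows.append(
                {"index": name, "stratum": r["stratum"], "bin": int(r["bin"]),
                 "median": float(r["value"])}
            )
    return pd.DataFrame(rows)


TABLE_FILES = {
    "volcano": "volcano.csv",
    "distribution": "distribution.csv",
    "ecdf": "ecdf.csv",
    "decile_medians": "decile_medians.csv",
    "summaries": "group_summaries.csv",
}


def export(bundle: ReportBundle, directory) -> list[Path]:
    """Write every table as CSV plus the manifest as JSON.

    File names are fixed and floats use a fixed 10-significant-digit
    format, so exports are deterministic byte-for-byte.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for attr, fname in TABLE_FILES.items():
            path = directory / fname
            getattr(bundle, attr).to_csv(path, index=False, float_format=FLOAT_FORMAT)
            written.append(path)
        mpath = directory / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(mpath)
        return written
    except OSError as err:
        raise OSError(f"failed writing report to {directory}: {err}") from err


def read_table(directory, name: str) -> pd.DataFrame:
    """Read back an exported table by its bundle attribute name."""
    return pd.read_csv(Path(directory) / TABLE_FILES[name])


def plot_bundle(bundle: ReportBundle, directory) -> list[Path]:
    """Optional rendering of the volcano and distribution tables.

    Import of matplotlib is deferred so headless table-only use never
    touches a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    vol = bundle.volcano[bundle.volcano["converged"].astype(bool)]
    if not vol.empty:
        fig, ax = plt.subplots(figsize=(6, 5))
        with np.errstate(divide="ignore"):
            ax.scatter(vol["hr"], -np.log10(vol["p"]), s=6, alpha=0.4)
        ax.axvline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("hazard ratio")
        ax.set_ylabel("-log10 p")
        path = directory / "volcano.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    dist = bundle.distribution
    if not dist.empty:
        groups = sorted(dist["group"].unique())
        fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 5))
        data, labels = [], []
        for g in groups:
            for d in ("positive", "reverse"):
                sub = dist[(dist["group"] == g) & (dist["direction"] == d)]
                data.append(sub["hr"].to_numpy(dtype=float))
                labels.append(f"{g}\n{d}")
        ax.violinplot([x for x in data if x.size], showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, rotation=90, fontsize=6)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_ylabel("hazard ratio")
        fig.tight_layout()
        path = directory / "distribution.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
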