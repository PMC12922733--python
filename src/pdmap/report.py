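"""Group summaries, condition comparisons and report export.

Interface tables from one or more samples are aggregated by cell-type
interaction class and wall orientation; two conditions (root zones,
genotypes) are compared per class with Welch's two-sample t-test and the
star annotation ladder * p<0.01, ** p<0.005, *** p<0.001.  Each interface
counts as one observation, so n is the number of interfaces of that class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: metrics summarised per class by default
DEFAULT_METRICS = ("pct_total_signal", "pct_signal_density", "area_um2", "morans_I")

#: significance ladder: (p threshold, stars), strongest first
STAR_LADDER = ((0.001, "***"), (0.005, "**"), (0.01, "*"))


def stars_for_p(p: float) -> str:
    """Star annotation for a p value under the ladder above."""
    if np.isnan(p):
        return ""
    for thr, s in STAR_LADDER:
        if p < thr:
            return s
    return ""


@dataclass
class ComparisonResult:
    class_key: tuple[str, str]
    metric: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    stars: str


def summarize_classes(
    table: pd.DataFrame, metrics: tuple[str, ...] = DEFAULT_METRICS
) -> pd.DataFrame:
    """n, mean and SD of each metric per (interaction, orientation) class.

    Moran's I summaries skip undefined (NaN) values — interfaces whose
    binary signal is constant carry no spatial information.  SD is NaN for
    n = 1 (ddof 1).
    """
    if len(table) == 0:
        raise ValueError("empty interface table")
    rows = []
    for (inter, orient), grp in table.groupby(
        ["interaction_class", "orientation_class"], sort=True
    ):
        row = dict(interaction_class=inter, orientation_class=orient, n=len(grp))
        for m in metrics:
            vals = grp[m].dropna().to_numpy(dtype=float)
            row[f"{m}_n"] = len(vals)
            row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{m}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    a: pd.DataFrame, b: pd.DataFrame, metric: str
) -> list[ComparisonResult]:
    """Welch's two-sided t-test per class on ``metric`` between two groups.

    Classes missing from either group, or with fewer than two defined
    values in either, are skipped with a warning.
    """
    out = []
    keys_a = set(map(tuple, a[["interaction_class", "orientation_class"]].values))
    keys_b = set(map(tuple, b[["interaction_class", "orientation_class"]].values))
    for key in sorted(keys_a | keys_b):
        in_a = a[
            (a["interaction_class"] == key[0]) & (a["orientation_class"] == key[1])
        ][metric].dropna()
        in_b = b[
            (b["interaction_class"] == key[0]) & (b["orientation_class"] == key[1])
        ][metric].dropna()
        if len(in_a) < 2 or len(in_b) < 2:
            warnings.warn(f"class {key}: too few observations, skipped")
            continue
        if in_a.std(ddof=1) == 0 and in_b.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if in_a.mean() == in_b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(in_a, in_b, equal_var=False)
        out.append(
            ComparisonResult(
                class_key=key,
                metric=metric,
                mean_a=float(in_a.mean()),
                mean_b=float(in_b.mean()),
                n_a=len(in_a),
                n_b=len(in_b),
                t=float(t),
                p=float(p),
                stars=stars_for_p(float(p)),
            )
        )
    return out


def comparisons_frame(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                interaction_class=c.class_key[0],
                orientation_class=c.class_key[1],
                metric=c.metric,
                mean_a=c.mean_a,
                mean_b=c.mean_b,
                n_a=c.n_a,
                n_b=c.n_b,
                t=c.t,
                p=c.p,
                stars=c.stars,
            )
            for c in comparisons
        ]
    )


def export_report(
    summaries: pd.DataFrame,
    comparisons: list[ComparisonResult],
    out_dir: str | Path,
    metrics: tuple[str, ...] = ("pct_total_signal",),
    make_plots: bool = True,
) -> list[Path]:
    """Write summary/comparison CSVs and bar plots with SD error bars.

    File naming is deterministic; re-running on identical input reproduces
    identical CSVs.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    path = out_dir / "class_summary.csv"
    summaries.to_csv(path, index=False, float_format="%.10g")
    written.append(path)

    if comparisons:
        path = out_dir / "comparisons.csv"
        comparisons_frame(comparisons).to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    if make_plots:
        written.extend(_plot_metrics(summaries, comparisons, out_dir, metrics))
    return written


def _plot_metrics(summaries, comparisons, out_dir: Path, metrics) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stars_by_key = {
        (c.class_key, c.metric): c.stars for c in comparisons or []
    }
    written = []
    for metric in metrics:
        mean_col, sd_col = f"{metric}_mean", f"{metric}_sd"
        if mean_col not in summaries.columns:
            continue
        df = summaries.dropna(subset=[mean_col])
        labels = [
            f"{r.interaction_class}\n{r.orientation_class}" for r in df.itertuples()
        ]
        fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(df)), 4))
        xs = np.arange(len(df))
        ax.bar(
            xs,
            df[mean_col],
            yerr=np.nan_to_num(df[sd_col].to_numpy(dtype=float)),
            capsize=3,
            color="#7f9fc4",
        )
        for x, r in zip(xs, df.itertuples()):
            key = ((r.interaction_class, r.orientation_class), metric)
            s = stars_by_key.get(key, "")
            if s:
                y = r.__getattribute__(mean_col) + (
                    0 if np.isnan(r.__getattribute__(sd_col)) else r.__getattribute__(sd_col)
                )
                ax.text(x, y, s, ha="center", va="bottom")
        ax.set_xticks(xs)
        ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=7)
        ax.set_ylabel(metric)
        fig.tight_layout()
        path = out_dir / f"{metric}_by_class.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
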