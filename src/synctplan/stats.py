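"""Statistical comparison of synCT-vs-planCT metric differences and reports.

Paired t-tests on the per-plan metric differences (synCT minus planCT),
mean differences with 95% t-based confidence intervals, and rank-sum
(Mann-Whitney) tests of the differences between tumor-size or -location
groups.  ``build_report`` assembles the CSV tables (organ mean HU, metric
differences by group, gamma pass rates by group) and a whisker plot of the
metric distributions.  No multiple-testing correction is applied; the
report footer says so.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

METRIC_COLUMNS = ("plan_id", "size_class", "location_class", "metric",
                  "synct_value", "planct_value")


def paired_metric_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Attach the paired difference column (synCT - planCT); one row per
    plan x metric."""
    missing = set(METRIC_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"metric table is missing columns: {sorted(missing)}")
    if rows.duplicated(subset=["plan_id", "metric"]).any():
        raise ValueError("metric table has duplicate plan x metric rows")
    out = rows.copy()
    out["difference"] = out["synct_value"] - out["planct_value"]
    return out


def paired_t_test(differences) -> tuple[float, float]:
    """One-sample t on paired differences; (t, p).  Zero variance is flagged."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("paired t-test needs n >= 2 differences")
    if np.allclose(d, d[0]):
        raise ValueError("degenerate paired t-test: differences have zero variance")
    res = sps.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


def mean_ci95(differences) -> tuple[float, float]:
    """Mean and t-based 95% confidence half-width of paired differences."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("confidence interval needs n >= 2")
    se = d.std(ddof=1) / np.sqrt(d.size)
    half = float(sps.t.ppf(0.975, d.size - 1) * se)
    return float(d.mean()), half


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Rank-sum (Mann-Whitney U) test between two groups of differences.

    Exact p for small samples (<= 12 per group, no ties), normal
    approximation with tie correction otherwise.  Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = a.size <= 12 and b.size <= 12
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_difference_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean difference and 95% CI half-width per metric within each tumor
    size/location group (and overall)."""
    rows = []
    groupings = (
        [("all", metrics)]
        + [(f"size:{g}", sub) for g, sub in metrics.groupby("size_class")]
        + [(f"location:{g}", sub) for g, sub in metrics.groupby("location_class")]
    )
    for gname, sub in groupings:
        for metric, msub in sub.groupby("metric"):
            d = msub["difference"].to_numpy(dtype=float)
            row = {"group": gname, "metric": metric, "n": d.size, "flag": ""}
            if d.size >= 2:
                row["mean_diff"], row["ci95_half"] = mean_ci95(d)
                if np.allclose(d, d[0]):
                    row["t_p"] = np.nan
                    row["flag"] = "zero variance: t undefined"
                else:
                    _, row["t_p"] = paired_t_test(d)
            else:
                row["mean_diff"] = float(d.mean()) if d.size else np.nan
                row["ci95_half"] = 0.0
                row["t_p"] = np.nan
                row["flag"] = "single plan"
            rows.append(row)
    return pd.DataFrame(rows)


def between_group_tests(metrics: pd.DataFrame, by: str = "size_class") -> pd.DataFrame:
    """Pairwise rank-sum tests of metric differences between tumor groups."""
    rows = []
    for metric, msub in metrics.groupby("metric"):
        groups = {g: s["difference"].to_numpy(dtype=float)
                  for g, s in msub.groupby(by)}
        names = sorted(groups)
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                if groups[ga].size and groups[gb].size:
                    u, p = wilcoxon_rank_sum(groups[ga], groups[gb])
                    rows.append({"metric": metric, "group_a": ga, "group_b": gb,
                                 "U": u, "p": p})
    return pd.DataFrame(rows)


def build_report(out_dir, metrics: pd.DataFrame | None = None,
                 organ_hu: pd.DataFrame | None = None,
                 gamma_results: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the report bundle: CSV tables plus the metric whisker plot.

    Missing pieces are skipped with a log notice; the report is still
    produced from whatever is available.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if organ_hu is not None and not organ_hu.empty:
        p = out / "organ_mean_hu.csv"
        organ_hu.to_csv(p, index=False, float_format="%.6g")
        artifacts["organ_mean_hu"] = p
    else:
        log.info("report: no organ mean-HU table; omitted")

    if metrics is not None and not metrics.empty:
        p = out / "metric_differences.csv"
        group_difference_table(metrics).to_csv(p, index=False, float_format="%.6g")
        artifacts["metric_differences"] = p
        p = out / "metrics_per_plan.csv"
        metrics.to_csv(p, index=False, float_format="%.6g")
        artifacts["metrics_per_plan"] = p
        artifacts["whisker_plot"] = _whisker_plot(metrics, out / "metric_whisker.png")
    else:
        log.info("report: no metric table; omitted")

    if gamma_results is not None and not gamma_results.empty:
        from .gamma import pass_rate_table

        p = out / "gamma_pass_rates.csv"
        pass_rate_table(gamma_results).to_csv(p, index=False, float_format="%.6g")
        artifacts["gamma_pass_rates"] = p
    else:
        log.info("report: no gamma results; gamma table omitted")

    footer = out / "README.txt"
    footer.write_text(
        "Report tables: per-plan dose-volume metrics, grouped mean differences "
        "with t-based 95% CIs, rank-sum between-group tests, organ mean HU and "
        "gamma pass rates.\nNo multiple-testing correction applied.\n"
    )
    artifacts["footer"] = footer
    return artifacts


def _whisker_plot(metrics: pd.DataFrame, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = sorted(metrics["metric"].unique())
    fig, ax = plt.subplots(figsize=(1.6 * len(names) + 2, 4.0))
    data, labels = [], []
    for m in names:
        sub = metrics[metrics["metric"] == m]
        data.extend([sub["synct_value"].to_numpy(), sub["planct_value"].to_numpy()])
        labels.extend([f"{m}\nsynCT", f"{m}\nplanCT"])
    ax.boxplot(data, tick_labels=labels, whis=(0, 100))
    ax.set_ylabel("metric value")
    ax.set_title("Dose-volume metrics: synCT vs planCT")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
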