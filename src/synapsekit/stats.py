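"""Two-group comparisons of per-cell metrics and batch reporting.

The image-derived metrics (DoR, roundness, roughness, centrosome
distance) are compared between two groups of cells with either Student's
two-sample t-test (pooled variance; Welch's form available via
``welch=True``) or the Mann-Whitney U test (exact for small samples
without ties, normal approximation with tie correction otherwise).
Tests are two-sided and reported per metric without multiple-testing
correction by default; Benjamini-Hochberg adjustment can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "batch_report"]


@dataclass(frozen=True)
class GroupComparison:
    metric_name: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    test: str
    statistic: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


_TESTS = ("t_independent", "mann_whitney")


def _as_group(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"group {name} has {arr.size} values; need >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name} contains non-finite values")
    return arr


def compare_groups(
    a,
    b,
    test: str = "t_independent",
    metric_name: str = "metric",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided two-group test on per-cell values.

    ``t_independent`` is Student's two-sample t with pooled variance
    (``welch=True`` switches to Welch's unequal-variance form).
    ``mann_whitney`` uses the exact null distribution when the smaller
    group has <= 8 values and the data are tie-free, otherwise the normal
    approximation with tie correction.  Degenerate data with zero
    variance in both groups and equal means return statistic 0, p = 1.
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {_TESTS}, got {test!r}")
    a = _as_group(a, "a")
    b = _as_group(b, "b")

    degenerate = np.ptp(np.concatenate([a, b])) == 0
    if test == "t_independent":
        if degenerate:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    else:
        if degenerate:
            stat, p = a.size * b.size / 2.0, 1.0
        else:
            has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
            method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)

    return GroupComparison(
        metric_name=metric_name,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        test=test,
        statistic=float(stat),
        p_value=float(p),
    )


def batch_report(
    data: pd.DataFrame,
    test: str = "t_independent",
    welch: bool = False,
    fdr: bool = False,
    plot_dir=None,
    whiskers: str = "iqr",
):
    """Per-metric group comparisons from a long-format table.

    ``data`` needs columns ``group``, ``metric``, ``value`` (and
    optionally ``cell_id``).  Exactly two groups must be present.  Returns
    a comparisons DataFrame; if ``plot_dir`` is given, writes one
    box-whisker PNG per metric (``whiskers="iqr"``: Tukey 1.5x-IQR
    whiskers, the per-cell convention; ``"minmax"``: whiskers at the data
    range, the per-subject convention).
    """
    required = {"group", "metric", "value"}
    if data is None or len(data) == 0:
        raise ValueError("empty input table")
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"input table missing columns {sorted(missing)}")
    groups = sorted(data["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    ga, gb = groups

    rows = []
    for metric, sub in data.groupby("metric", sort=True):
        vals_a = sub.loc[sub["group"] == ga, "value"].to_numpy()
        vals_b = sub.loc[sub["group"] == gb, "value"].to_numpy()
        rows.append(
            compare_groups(vals_a, vals_b, test=test, metric_name=str(metric),
                           welch=welch).__dict__
        )
    table = pd.DataFrame(rows)
    table.insert(1, "group_a", ga)
    table.insert(2, "group_b", gb)
    if fdr:
        table["p_adjusted"] = _benjamini_hochberg(table["p_value"].to_numpy())

    if plot_dir is not None:
        _write_boxplots(data, ga, gb, plot_dir, whiskers)
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def _write_boxplots(data: pd.DataFrame, ga, gb, plot_dir, whiskers: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    plot_dir = Path(plot_dir)
    plot_dir.mkdir(parents=True, exist_ok=True)
    whis = 1.5 if whiskers == "iqr" else (0, 100)
    for metric, sub in data.groupby("metric", sort=True):
        fig, ax = plt.subplots(figsize=(3.2, 3.6))
        ax.boxplot(
            [sub.loc[sub["group"] == g, "value"] for g in (ga, gb)],
            tick_labels=[str(ga), str(gb)],
            whis=whis,
        )
        ax.set_ylabel(str(metric))
        fig.tight_layout()
        fig.savefig(plot_dir / f"{metric}_boxplot.png", dpi=120)
        plt.close(fig)
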