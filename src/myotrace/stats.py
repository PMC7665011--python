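"""Cohort summarization and control-vs-cancer comparison.

Strips (n) are the unit of analysis, pooled across animals; metrics are
expressed as mean +- SD and compared between groups with the unpaired
(pooled-variance Student) t-test at the 0.05 level. No multiple-testing
correction is applied; the report footnotes this. An unequal-variance
(Welch) variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

ALPHA = 0.05


@dataclass
class Summary:
    mean: float
    sd: float        # sample SD (ddof=1); NaN when n = 1
    n: int
    flags: list = field(default_factory=list)


@dataclass
class GroupComparison:
    metric: str
    control: Summary
    cancer: Summary
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    flags: list = field(default_factory=list)


def summarize(values: Sequence[float]) -> Summary:
    """Arithmetic mean, sample SD (n-1 denominator) and n."""
    x = np.asarray(list(values), float)
    if x.size == 0:
        raise DomainError("cannot summarize an empty sample")
    flags = []
    if x.size == 1:
        sd = float("nan")
        flags.append("sd_undefined_n1")
    else:
        sd = float(np.std(x, ddof=1))
    return Summary(mean=float(np.mean(x)), sd=sd, n=int(x.size), flags=flags)


def unpaired_t(group_a: Sequence[float], group_b: Sequence[float],
               equal_var: bool = True, metric: str = "") -> GroupComparison:
    """Two-sided unpaired t-test between two strip cohorts.

    Pooled-variance (Student) by default, ``df = nA + nB - 2``; Welch via
    ``equal_var=False``. Zero pooled variance is handled explicitly: equal
    means give t = 0, p = 1; unequal means are flagged degenerate.
    """
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size < 2 or b.size < 2:
        raise DomainError("both groups need n >= 2 for a t-test")
    flags = []
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    if equal_var:
        df = a.size + b.size - 2
    else:
        # Welch-Satterthwaite
        va, vb = var_a / a.size, var_b / b.size
        denom = va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1)
        df = (va + vb) ** 2 / denom if denom > 0 else a.size + b.size - 2
    if var_a == 0 and var_b == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t, p = float("nan"), float("nan")
            flags.append("degenerate_zero_variance")
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(metric=metric, control=summarize(a),
                           cancer=summarize(b), t_statistic=t,
                           degrees_of_freedom=float(df), p_value=p,
                           significant=bool(p < ALPHA) if np.isfinite(p) else False,
                           flags=flags)


def compare_cohorts(control_table: pd.DataFrame, cancer_table: pd.DataFrame,
                    metrics: Sequence[str],
                    equal_var: bool = True) -> list:
    """One :class:`GroupComparison` per requested metric column.

    Strips with NaN (flagged/undefined) values are excluded metric-wise and
    n adjusted; a metric absent from either table is reported with a
    ``metric_missing`` flag instead of raising.
    """
    out = []
    for m in metrics:
        if m not in control_table.columns or m not in cancer_table.columns:
            out.append(GroupComparison(
                metric=m, control=Summary(float("nan"), float("nan"), 0),
                cancer=Summary(float("nan"), float("nan"), 0),
                t_statistic=float("nan"), degrees_of_freedom=float("nan"),
                p_value=float("nan"), significant=False,
                flags=["metric_missing"]))
            continue
        a = control_table[m].dropna().to_numpy(float)
        b = cancer_table[m].dropna().to_numpy(float)
        out.append(unpaired_t(a, b, equal_var=equal_var, metric=m))
    return out


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "metric": c.metric,
            "control_mean": c.control.mean, "control_sd": c.control.sd,
            "control_n": c.control.n,
            "cancer_mean": c.cancer.mean, "cancer_sd": c.cancer.sd,
            "cancer_n": c.cancer.n,
            "t_statistic": c.t_statistic, "df": c.degrees_of_freedom,
            "p_value": c.p_value, "significant": c.significant,
            "flags": ";".join(c.flags),
        })
    return pd.DataFrame(rows)


def report(comparisons: Sequence[GroupComparison], out_dir) -> list:
    """Write a delimited comparison table and one bar figure per metric.

    Bars show group mean +- SD with a significance star at p < 0.05.
    Returns the list of written paths.
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise DomainError("need at least one comparison to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    table = out_dir / "comparisons.csv"
    df = comparisons_frame(comparisons)
    with open(table, "w") as fh:
        df.to_csv(fh, index=False)
        fh.write("# note: per-metric unpaired t-tests, no multiple-testing "
                 "correction\n")
    written.append(table)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for c in comparisons:
        fig, ax = plt.subplots(figsize=(3.2, 3.6))
        means = [c.control.mean, c.cancer.mean]
        sds = [c.control.sd, c.cancer.sd]
        ax.bar(["Ctrl", "Cncr"], means,
               yerr=np.nan_to_num(sds), capsize=4,
               color=["lightgrey", "dimgrey"], edgecolor="black")
        ax.set_ylabel(c.metric)
        if c.significant:
            top = max(m + (s if np.isfinite(s) else 0) for m, s in zip(means, sds))
            ax.text(0.5, top * 1.05, "*", ha="center", fontsize=14)
        ax.set_title(f"{c.metric} (p = {c.p_value:.3g})", fontsize=9)
        fig.tight_layout()
        path = out_dir / f"{c.metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
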