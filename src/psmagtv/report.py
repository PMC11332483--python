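"""Aggregation of per-case metrics into a Table-1-style summary.

For each method, medians and interquartile ranges (linear-interpolation
quantiles) of the five evaluation metrics are reported, together with a
two-sided Wilcoxon signed-rank test comparing the method's GTV volumes with
the per-case histopathology volumes at alpha = 0.05. Following the table's
convention, rows whose volumes do NOT differ significantly from
histopathology are starred. Missing metric values (empty GTVs) are dropped
per metric with the count reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import MetricRecord

__all__ = [
    "median_iqr",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "build_summary",
    "render_markdown",
    "METHOD_ORDER",
]

#: canonical report row order
METHOD_ORDER = [
    "Manual",
    "SUV > 2",
    "SUV > 2.5",
    "SUV > 3",
    "SUV > 3.5",
    "SUV > 4",
    "SUV > 4.5",
    "SUVmax20%",
    "SUVmax30%",
    "SUVmax40%",
    "SUVmax50%",
    "Adaptive",
    "Otsu2",
    "Otsu3",
]

#: metric columns summarized per method, in table order
METRIC_COLUMNS = ["volume_ratio", "coverage", "dsc", "fdr", "hd95_mm"]


def median_iqr(values) -> tuple:
    """(median, q1, q3) by linear interpolation; missing values dropped."""
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        raise ValueError("all values are missing; median/IQR undefined")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class WilcoxonResult:
    w: float              # min(W+, W-)
    w_plus: float
    w_minus: float
    p: float              # two-sided
    n_effective: int      # pairs after zero removal
    exact: bool
    degenerate: bool      # all paired differences were zero


def _exact_signed_rank_cdf_counts(n: int) -> np.ndarray:
    """counts[w] = number of sign assignments of ranks 1..n with W+ = w."""
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (classical convention) and ties in |d| get
    average ranks. The p-value is exact — equivalent to enumerating all 2^n
    sign assignments — when n <= 25 and |d| is tie-free; otherwise a normal
    approximation with tie and continuity corrections is used. If every
    difference is zero the test is degenerate and p = 1 is returned flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            w=0.0, w_plus=0.0, w_minus=0.0, p=1.0, n_effective=0, exact=True, degenerate=True
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    tie_free = np.unique(np.abs(d)).size == n
    if n <= 25 and tie_free:
        counts = _exact_signed_rank_cdf_counts(n)
        # symmetric null: two-sided p = 2 * P(W+ <= w)
        p = 2.0 * counts[: int(round(w)) + 1].sum() / 2.0**n
        return WilcoxonResult(
            w=w, w_plus=w_plus, w_minus=w_minus, p=min(1.0, p),
            n_effective=n, exact=True, degenerate=False,
        )

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(
            w=w, w_plus=w_plus, w_minus=w_minus, p=1.0,
            n_effective=n, exact=False, degenerate=True,
        )
    z = (w - mean + 0.5) / np.sqrt(var)  # continuity correction toward the mean
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return WilcoxonResult(
        w=w, w_plus=w_plus, w_minus=w_minus, p=p,
        n_effective=n, exact=False, degenerate=False,
    )


def _order_methods(labels) -> list:
    known = [m for m in METHOD_ORDER if m in labels]
    extra = sorted(set(labels) - set(METHOD_ORDER))
    return known + extra


def build_summary(
    records: list, reference_volumes: dict, alpha: float = 0.05
) -> pd.DataFrame:
    """Build the per-method summary table.

    Parameters
    ----------
    records:
        :class:`MetricRecord` instances covering >= 1 case per method.
    reference_volumes:
        Mapping case_id -> histopathology volume in ml; every case present
        in the records must be covered.
    """
    if not records:
        raise ValueError("no metric records to summarize")
    df = pd.DataFrame(
        {
            "case_id": r.case_id,
            "method_label": r.method_label,
            "dsc": r.dsc,
            "hd95_mm": np.nan if r.hd95_mm is None else r.hd95_mm,
            "coverage": r.coverage,
            "fdr": np.nan if r.fdr is None else r.fdr,
            "volume_ratio": r.volume_ratio,
            "gtv_ml": r.gtv_ml,
        }
        for r in records
    )
    missing_ref = sorted(set(df["case_id"]) - set(reference_volumes))
    if missing_ref:
        raise ValueError(f"no reference volume for case(s): {missing_ref}")

    rows = []
    for method in _order_methods(df["method_label"].unique().tolist()):
        sub = df[df["method_label"] == method].sort_values("case_id")
        row = {"method": method, "n_cases": len(sub)}
        for metric in METRIC_COLUMNS:
            vals = sub[metric].to_numpy()
            n_missing = int(np.isnan(vals).sum())
            med, q1, q3 = median_iqr(vals[~np.isnan(vals)])
            row[f"{metric}_median"] = med
            row[f"{metric}_q1"] = q1
            row[f"{metric}_q3"] = q3
            row[f"{metric}_n_missing"] = n_missing
        ref_ml = np.array([reference_volumes[c] for c in sub["case_id"]])
        wt = wilcoxon_signed_rank(sub["gtv_ml"].to_numpy(), ref_ml)
        row["wilcoxon_w"] = wt.w
        row["wilcoxon_p"] = wt.p
        row["wilcoxon_degenerate"] = wt.degenerate
        row["volume_differs"] = bool(wt.p < alpha) and not wt.degenerate
        rows.append(row)
    return pd.DataFrame(rows)


_PRETTY = {
    "volume_ratio": "GTV/Histopathology volume ratio",
    "coverage": "Lesion coverage ratio",
    "dsc": "DSC",
    "fdr": "FDR",
    "hd95_mm": "HD95% (mm)",
}


def render_markdown(summary: pd.DataFrame) -> str:
    """Render the summary as a Markdown table.

    A star on the method name marks rows whose volumes show no significant
    difference from the histopathology volumes.
    """
    header = "| Method | " + " | ".join(
        f"Median {_PRETTY[m]} (IQR)" for m in METRIC_COLUMNS
    ) + " |"
    sep = "|" + "---|" * (len(METRIC_COLUMNS) + 1)
    lines = [header, sep]
    for _, row in summary.iterrows():
        star = "" if row["volume_differs"] else "*"
        cells = [f"{star}{row['method']}"]
        for m in METRIC_COLUMNS:
            cells.append(
                f"{row[f'{m}_median']:.2f} ({row[f'{m}_q1']:.2f}–{row[f'{m}_q3']:.2f})"
            )
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    lines.append(
        "Stars (*) mark methods whose volumes show no statistically significant "
        "difference from the histopathology volumes (two-sided Wilcoxon "
        "signed-rank, alpha = 0.05)."
    )
    return "\n".join(lines)
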