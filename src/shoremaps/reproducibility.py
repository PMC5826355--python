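"""Test-retest reliability metrics for two-session control data.

With two sessions per subject the within-subject SD is

    sigma_ws = sqrt( sum_i (a_i,tp1 - a_i,tp2)^2 / (2 k) ),

and the reliability metrics are

    ICC      = sigma_bs^2 / (sigma_bs^2 + sigma_ws^2),
    CV_intra = sigma_ws / mu * 100 %     (mu = overall mean),
    CV_inter = mean over sessions of (SD_across_subjects / session mean) * 100 %.

The between-subject SD estimator is the sample SD of the per-subject
two-session means — the simplest companion to the paired sigma_ws above;
ICC values depend on this choice and it is recorded in report metadata.
Acceptability conventions: CV_intra <= 10% and CV_inter < 15%; ICC bands
poor (< 0.4), fair (0.41-0.59), good (0.60-0.74), excellent (> 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["icc", "cv_intra", "cv_inter", "summarize_repro", "ReproReport", "icc_band"]


def _paired(test, retest):
    a = np.asarray(test, dtype=float)
    b = np.asarray(retest, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("test and retest must be 1-D arrays of equal length")
    return a, b


def _sigma_ws(a: np.ndarray, b: np.ndarray) -> float:
    k = len(a)
    return float(np.sqrt(np.sum((a - b) ** 2) / (2.0 * k)))


def icc(test, retest) -> float:
    """Intraclass correlation of paired sessions.

    Degenerate all-equal data (both SDs zero) is defined as 1 and can be
    inspected via :func:`icc_components`."""
    value, *_ = icc_components(test, retest)
    return value


def icc_components(test, retest) -> tuple[float, float, float, bool]:
    """(ICC, sigma_bs, sigma_ws, degenerate_flag)."""
    a, b = _paired(test, retest)
    if len(a) < 2:
        raise ValueError("ICC needs at least two subjects")
    s_ws = _sigma_ws(a, b)
    s_bs = float(np.std((a + b) / 2.0, ddof=1))
    if s_bs == 0 and s_ws == 0:
        return 1.0, 0.0, 0.0, True
    return s_bs**2 / (s_bs**2 + s_ws**2), s_bs, s_ws, False


def cv_intra(test, retest) -> float:
    """Within-subject coefficient of variation in percent."""
    a, b = _paired(test, retest)
    mu = float(np.mean(np.concatenate([a, b])))
    if mu <= 0:
        raise ValueError("overall mean must be positive for CV")
    return _sigma_ws(a, b) / mu * 100.0


def cv_inter(test, retest) -> float:
    """Between-subject coefficient of variation in percent: per-session
    (SD across subjects) / (session mean), averaged over the two
    sessions."""
    a, b = _paired(test, retest)
    if len(a) < 2:
        raise ValueError("CV_inter needs at least two subjects per session")
    out = []
    for sess in (a, b):
        mu = float(np.mean(sess))
        if mu == 0:
            raise ValueError("zero session mean")
        out.append(float(np.std(sess, ddof=1)) / mu * 100.0)
    return float(np.mean(out))


def icc_band(value: float) -> str:
    if value < 0.4:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


@dataclass
class ReproReport:
    """Reliability summary for one index.

    ``scope`` rows: for tract data, ICC and CV_intra pool all connections
    of a loop ((subject, connection) pairs as measurement units) giving a
    single value per loop, while CV_inter is per-connection and
    summarized as mean +- SD; for GM data every metric is per-ROI and
    summarized across ROIs.
    """

    index_name: str
    rows: pd.DataFrame  # scope, unit, icc, cv_intra, cv_inter, flags
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.insert(0, "index", self.index_name)
        return out


def _pivot_sessions(df: pd.DataFrame, unit_cols) -> tuple[np.ndarray, np.ndarray]:
    wide = df.pivot_table(index=unit_cols, columns="session", values="value")
    if wide.shape[1] != 2:
        raise ValueError("test-retest summary requires exactly two sessions")
    if wide.isna().any().any():
        raise ValueError("missing session values for some units")
    return wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()


def summarize_repro(
    table: pd.DataFrame,
    grouping: str = "loop_pooled",
    cv_intra_limit: float = 10.0,
    cv_inter_limit: float = 15.0,
) -> list[ReproReport]:
    """Reliability reports from a control-group measure table.

    ``grouping="loop_pooled"`` applies to connection records: one
    ICC/CV_intra per network loop (connections pooled), CV_inter
    mean +- SD across the loop's connections.  ``grouping="per_unit"``
    applies to ROI records: metrics per region, then mean +- SD across
    regions.
    """
    ctrl = table[table["group"] == "control"]
    if ctrl["session"].nunique() != 2:
        raise ValueError("need exactly two control sessions")
    reports = []
    for index_name, sub in ctrl.groupby("index", sort=True):
        rows = []
        if grouping == "loop_pooled":
            conn = sub[sub["unit_type"] == "connection"].copy()
            conn["loop"] = conn["unit_id"].str.split(":").str[0]
            for loop, loop_df in conn.groupby("loop", sort=True):
                a, b = _pivot_sessions(loop_df, ["subject", "unit_id"])
                icc_v, _, _, degen = icc_components(a, b)
                cvw = cv_intra(a, b)
                inter_per_conn = []
                for _, cdf in loop_df.groupby("unit_id"):
                    ca, cb = _pivot_sessions(cdf, ["subject"])
                    inter_per_conn.append(cv_inter(ca, cb))
                rows.append(
                    {
                        "scope": "loop",
                        "unit": loop,
                        "icc": icc_v,
                        "icc_band": icc_band(icc_v),
                        "icc_degenerate": degen,
                        "cv_intra": cvw,
                        "cv_intra_ok": cvw <= cv_intra_limit,
                        "cv_inter_mean": float(np.mean(inter_per_conn)),
                        "cv_inter_sd": float(np.std(inter_per_conn, ddof=1))
                        if len(inter_per_conn) > 1
                        else 0.0,
                        "cv_inter_ok": float(np.mean(inter_per_conn)) < cv_inter_limit,
                    }
                )
        elif grouping == "per_unit":
            roi = sub[sub["unit_type"] == "roi"]
            for unit, udf in roi.groupby("unit_id", sort=True):
                a, b = _pivot_sessions(udf, ["subject"])
                icc_v, _, _, degen = icc_components(a, b)
                cvw = cv_intra(a, b)
                cvb = cv_inter(a, b)
                rows.append(
                    {
                        "scope": "roi",
                        "unit": unit,
                        "icc": icc_v,
                        "icc_band": icc_band(icc_v),
                        "icc_degenerate": degen,
                        "cv_intra": cvw,
                        "cv_intra_ok": cvw <= cv_intra_limit,
                        "cv_inter_mean": cvb,
                        "cv_inter_sd": 0.0,
                        "cv_inter_ok": cvb < cv_inter_limit,
                    }
                )
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        reports.append(
            ReproReport(
                index_name=index_name,
                rows=pd.DataFrame(rows),
                metadata={
                    "grouping": grouping,
                    "sigma_bs_estimator": "sample SD of per-subject session means",
                    "pooling_unit": "(subject, connection) pair"
                    if grouping == "loop_pooled"
                    else "subject",
                    "cv_intra_limit": cv_intra_limit,
                    "cv_inter_limit": cv_inter_limit,
                },
            )
        )
    return reports
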