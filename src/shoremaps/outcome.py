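"""Clinical-outcome regression with backward elimination.

The motor NIHSS score at the six-month time point is predicted from
baseline information with ordinary least squares.  Model families:

* reference — clinical baseline only: age, stroke size, NIHSS at tp1;
* TBM (tensor-based) — clinical baseline plus the loop means of MD and
  FA at tp1 for one network;
* SBM (propagator-based) — clinical baseline plus the loop means of GFA,
  PA, RTAP, RTPP and MSD at tp1;
* GBM (global microstructural) — all seven index loop means at tp1, no
  clinical variables.

Backward elimination removes, at each step, the predictor with the
largest removal p-value (the partial-F p of dropping it from the current
model, equal to its two-sided t-test p) while that p exceeds ``p_out``
(default 0.10); ties break by design-matrix column order.  The final
model reports R^2 and the adjusted value

    R2_adj = 1 - (1 - R2) (N - 1) / (N - k - 1),

with N the sample size and k the number of retained predictors excluding
the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelResult",
    "loop_mean_predictor",
    "fit_ols",
    "backward_eliminate",
    "adjusted_r2",
    "run_model_families",
    "CLINICAL_PREDICTORS",
    "TBM_INDICES",
    "SBM_INDICES",
    "GBM_INDICES",
]

CLINICAL_PREDICTORS = ("age", "stroke_size", "nihss_tp1")
TBM_INDICES = ("md", "fa")
SBM_INDICES = ("gfa", "pa", "rtap", "rtpp", "msd")
GBM_INDICES = ("gfa", "pa", "rtap", "rtpp", "msd", "fa", "md")


@dataclass(frozen=True)
class ModelSpec:
    """A model family applied to one network's tp1 loop means."""

    family: str  # reference | TBM | SBM | GBM
    network: str | None = None  # CC | CORT | SUBCORT | None for reference
    p_out: float = 0.10

    def predictors(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(clinical variables, index loop means)."""
        if self.family == "reference":
            return CLINICAL_PREDICTORS, ()
        if self.family == "TBM":
            return CLINICAL_PREDICTORS, TBM_INDICES
        if self.family == "SBM":
            return CLINICAL_PREDICTORS, SBM_INDICES
        if self.family == "GBM":
            return (), GBM_INDICES
        raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ModelResult:
    """A fitted (possibly backward-eliminated) linear model."""

    spec: ModelSpec | None
    retained: list[str]
    coefficients: dict[str, float]
    r2: float
    r2_adj: float
    f_pvalue: float
    n: int
    k: int
    intercept_only: bool = False
    predictions: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "family": self.spec.family if self.spec else None,
            "network": self.spec.network if self.spec else None,
            "retained": self.retained,
            "coefficients": self.coefficients,
            "r2": round(self.r2, 6),
            "r2_adj": round(self.r2_adj, 3),
            "f_pvalue": self.f_pvalue,
            "n": self.n,
            "k": self.k,
            "intercept_only": self.intercept_only,
        }
        return d


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """R2 adjusted for the number of retained predictors (excluding the
    intercept); requires N > k + 1."""
    if n <= k + 1:
        raise ValueError(f"need N > k + 1 (got N={n}, k={k})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def loop_mean_predictor(
    table: pd.DataFrame, network: str, index: str, session: int = 1
) -> pd.Series:
    """Per-subject unweighted mean of a network's connection values at one
    session; raises if any connection is missing for some subject."""
    conn = table[
        (table["unit_type"] == "connection")
        & (table["session"] == session)
        & (table["index"] == index)
        & table["unit_id"].str.startswith(f"{network}:")
    ]
    if conn.empty:
        raise ValueError(f"no {network} connections for index {index!r} at session {session}")
    wide = conn.pivot_table(index="subject", columns="unit_id", values="value")
    if wide.isna().any().any():
        missing = [c for c in wide.columns if wide[c].isna().any()]
        raise ValueError(f"missing connections: {missing}")
    return wide.mean(axis=1)


def fit_ols(y: np.ndarray, X: pd.DataFrame):
    """OLS with intercept; returns the statsmodels results object.
    Raises on singular designs and insufficient sample size."""
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(
            f"need N > k + 1 observations (N={len(y)}, k={X.shape[1]})"
        )
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("singular design matrix (exact collinearity)")
    return sm.OLS(y, Xc).fit()


def backward_eliminate(
    y: np.ndarray, X: pd.DataFrame, p_out: float = 0.10, spec: ModelSpec | None = None
) -> ModelResult:
    """Backward elimination on the probability of F-to-remove.

    Iteratively refits after dropping the predictor whose removal p (its
    partial-F/t p-value in the current model) is largest, while that p
    exceeds ``p_out``.  An all-noise design collapses to the
    intercept-only model, which is flagged.
    """
    cols = list(X.columns)
    while cols:
        res = fit_ols(y, X[cols])
        pvals = res.pvalues.drop("const")
        # ties broken by column order: first occurrence of the max wins
        worst = max(cols, key=lambda c: (round(float(pvals[c]), 12)))
        if float(pvals[worst]) > p_out:
            cols.remove(worst)
        else:
            break
    n = len(y)
    if not cols:
        ybar = float(np.mean(y))
        return ModelResult(
            spec=spec,
            retained=[],
            coefficients={"const": ybar},
            r2=0.0,
            r2_adj=0.0,
            f_pvalue=1.0,
            n=n,
            k=0,
            intercept_only=True,
            predictions=pd.DataFrame({"measured": y, "predicted": np.full(n, ybar)}),
        )
    res = fit_ols(y, X[cols])
    k = len(cols)
    r2 = float(res.rsquared)
    return ModelResult(
        spec=spec,
        retained=cols,
        coefficients={name: float(v) for name, v in res.params.items()},
        r2=r2,
        r2_adj=adjusted_r2(r2, n, k),
        f_pvalue=float(res.f_pvalue),
        n=n,
        k=k,
        predictions=pd.DataFrame(
            {"measured": y, "predicted": np.asarray(res.fittedvalues)}
        ),
    )


def run_model_families(
    measures: pd.DataFrame,
    covariates: pd.DataFrame,
    networks: tuple[str, ...] = ("CC", "CORT", "SUBCORT"),
    p_out: float = 0.10,
    outcome_session: int = 3,
) -> dict[tuple[str, str | None], ModelResult]:
    """Fit the full family x network grid on the patient cohort.

    Outcome: NIHSS at the last time point; predictors per
    :class:`ModelSpec`.  Returns 1 (reference) + 3 x (TBM, SBM, GBM)
    = 10 results keyed by (family, network).
    """
    pat_meas = measures[measures["group"] == "patient"]
    pat_cov = covariates[covariates["group"] == "patient"]
    baseline = (
        pat_cov[pat_cov["session"] == 1]
        .set_index("subject")[["age", "stroke_size", "nihss"]]
        .rename(columns={"nihss": "nihss_tp1"})
    )
    outcome = (
        pat_cov[pat_cov["session"] == outcome_session]
        .set_index("subject")["nihss"]
        .rename("nihss_tp3")
    )
    subjects = sorted(outcome.index)
    y = outcome.loc[subjects].to_numpy(dtype=float)

    results: dict[tuple[str, str | None], ModelResult] = {}
    specs = [ModelSpec("reference", None, p_out)] + [
        ModelSpec(fam, net, p_out)
        for fam in ("TBM", "SBM", "GBM")
        for net in networks
    ]
    for spec in specs:
        clinical, indices = spec.predictors()
        cols = {}
        for name in clinical:
            cols[name] = baseline.loc[subjects, name].to_numpy(dtype=float)
        for index in indices:
            lm = loop_mean_predictor(pat_meas, spec.network, index, session=1)
            cols[index] = lm.loc[subjects].to_numpy(dtype=float)
        X = pd.DataFrame(cols, index=subjects)
        results[(spec.family, spec.network)] = backward_eliminate(
            y, X, p_out=p_out, spec=spec
        )
    return results
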