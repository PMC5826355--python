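"""Longitudinal patient-vs-control statistics.

Tract side: percentage absolute changes between time points,

    Delta_tp(i,j) = |v_j - v_i| / v_i * 100,

computed per subject and connection, pooled (averaged) within each motor
loop, then compared between the control change (tp1c-tp2c) and each
patient change (tp1-tp2, tp2-tp3, tp1-tp3) with unpaired t-tests and a
Bonferroni adjustment across indices.  Normality of the percentage values
is checked first with a Kolmogorov-Smirnov test.

Region side: a three-way mixed ANOVA (between: Group; within: time point
and region) and a two-way repeated-measures ANOVA on the patient group,
with Mauchly sphericity tests and Greenhouse-Geisser corrected p-values
where sphericity is rejected.  Significant interactions gate post-hoc
pairwise comparisons (Bonferroni by default, LSD as the liberal
alternative).

All ANOVA sums of squares are computed from cell means of the balanced
design; the decomposition partitions the total SS exactly and is
cross-checked against an independent implementation in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "delta_tp",
    "compare_deltas",
    "group_delta_tests",
    "mixed_anova",
    "rm_anova",
    "posthoc",
    "AnovaResult",
    "AnovaTable",
]


# --------------------------------------------------------------------------
# percentage changes and t-tests

def delta_tp(table: pd.DataFrame, pair: tuple[int, int]) -> pd.DataFrame:
    """Per-subject, per-unit percentage absolute change between sessions.

    The denominator is the earlier time point.  Records with a
    non-positive baseline value are dropped with a log message.
    """
    i, j = pair
    wide = table.pivot_table(
        index=["subject", "group", "unit_type", "unit_id", "index"],
        columns="session",
        values="value",
    )
    if i not in wide.columns or j not in wide.columns:
        raise ValueError(f"sessions {pair} not both present")
    vi, vj = wide[i], wide[j]
    bad = vi <= 0
    if bad.any():
        logger.warning("dropping %d records with non-positive baseline", int(bad.sum()))
    out = ((vj - vi).abs() / vi * 100.0)[~bad].rename("delta_pct").reset_index()
    out["pair"] = f"tp{i}{j}"
    return out


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_deltas(
    control_deltas: np.ndarray,
    patient_deltas: np.ndarray,
    n_indices: int = 7,
    welch: bool = False,
) -> dict:
    """Unpaired two-sided t-test between control and patient percentage
    changes, Bonferroni-adjusted across the index family.

    A Kolmogorov-Smirnov normality check (against a normal with the
    sample moments) is run on each sample and reported alongside.
    """
    a = np.asarray(control_deltas, dtype=float)
    b = np.asarray(patient_deltas, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if np.var(np.concatenate([a, b])) == 0:
        raise ValueError("degenerate zero-variance samples")

    def ks_norm(x):
        sd = np.std(x, ddof=1)
        if sd == 0:
            return 0.0
        return float(stats.kstest(x, "norm", args=(np.mean(x), sd)).pvalue)

    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    p_adj = min(1.0, float(p) * n_indices)
    return {
        "t": float(t),
        "p": float(p),
        "p_adj": p_adj,
        "stars": stars(p_adj),
        "ks_p_control": ks_norm(a),
        "ks_p_patient": ks_norm(b),
        "mean_control": float(a.mean()),
        "mean_patient": float(b.mean()),
    }


def group_delta_tests(
    table: pd.DataFrame,
    n_indices: int = 7,
    patient_pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 3), (1, 3)),
    control_pair: tuple[int, int] = (1, 2),
    welch: bool = False,
) -> pd.DataFrame:
    """The full tract-based comparison: per index and loop, control
    Delta(tp1c, tp2c) vs each patient Delta pair; deltas are averaged
    across the loop's connections per subject before testing."""
    conn = table[table["unit_type"] == "connection"].copy()
    conn["loop"] = conn["unit_id"].str.split(":").str[0]
    ctrl = conn[conn["group"] == "control"]
    pat = conn[conn["group"] == "patient"]
    d_ctrl = delta_tp(ctrl, control_pair)
    d_ctrl["loop"] = d_ctrl["unit_id"].str.split(":").str[0]
    rows = []
    for pair in patient_pairs:
        d_pat = delta_tp(pat, pair)
        d_pat["loop"] = d_pat["unit_id"].str.split(":").str[0]
        for (index_name, loop), sub_p in d_pat.groupby(["index", "loop"], sort=True):
            sub_c = d_ctrl[(d_ctrl["index"] == index_name) & (d_ctrl["loop"] == loop)]
            pooled_c = sub_c.groupby("subject")["delta_pct"].mean().to_numpy()
            pooled_p = sub_p.groupby("subject")["delta_pct"].mean().to_numpy()
            res = compare_deltas(pooled_c, pooled_p, n_indices=n_indices, welch=welch)
            rows.append({"index": index_name, "loop": loop, "pair": f"tp{pair[0]}{pair[1]}", **res})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ANOVA machinery

@dataclass(frozen=True)
class AnovaResult:
    """One effect row of an ANOVA table."""

    effect: str
    ss: float
    df1: int
    df2: int
    f: float
    p: float  # uncorrected
    epsilon: float = 1.0  # Greenhouse-Geisser
    p_gg: float | None = None  # GG-corrected (within effects with df1 > 1)
    mauchly_w: float | None = None
    mauchly_p: float | None = None

    @property
    def p_report(self) -> float:
        """GG-corrected p when sphericity was rejected, else uncorrected."""
        if (
            self.p_gg is not None
            and self.mauchly_p is not None
            and self.mauchly_p < 0.05
        ):
            return self.p_gg
        return self.p


@dataclass
class AnovaTable:
    """ANOVA results together with the data needed for post-hoc tests."""

    design: str  # "mixed" | "rm"
    results: dict[str, AnovaResult]
    data: np.ndarray  # (subjects, A, B)
    groups: np.ndarray | None  # group label per subject (mixed only)
    a_levels: list
    b_levels: list
    error_terms: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __getitem__(self, effect: str) -> AnovaResult:
        return self.results[effect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results.values()])


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows."""
    c = np.zeros((k - 1, k))
    for i in range(1, k):
        c[i - 1, :i] = 1.0
        c[i - 1, i] = -i
        c[i - 1] /= np.linalg.norm(c[i - 1])
    return c


def _gg_mauchly(
    y: np.ndarray, groups: np.ndarray | None, contrast: np.ndarray
) -> tuple[float, float, float]:
    """Greenhouse-Geisser epsilon and Mauchly test for one within effect.

    ``y``: (subjects, cells) flattened within-subject data; ``contrast``:
    orthonormal (p, cells) rows spanning the effect.  The covariance is
    pooled within groups with df = N - G.  A rank-deficient contrast
    covariance (more effect dimensions than error df) yields W = 0 and a
    zero p-value; epsilon still follows from the eigenvalue formula.
    """
    n, _ = y.shape
    if groups is None:
        centered = y - y.mean(axis=0, keepdims=True)
        dof = n - 1
    else:
        centered = y.copy()
        for g in np.unique(groups):
            sel = groups == g
            centered[sel] -= y[sel].mean(axis=0, keepdims=True)
        dof = n - len(np.unique(groups))
    t = centered @ contrast.T  # (subjects, p)
    s_c = t.T @ t / dof
    p = contrast.shape[0]
    eig = np.linalg.eigvalsh(s_c)
    eig = np.clip(eig, 0.0, None)
    tr = eig.sum()
    eps = 1.0 if p == 1 else float(tr**2 / (p * np.sum(eig**2))) if tr > 0 else 1.0
    # Mauchly
    if p == 1:
        return 1.0, 1.0, eps
    det = float(np.prod(eig))
    mean_eig = tr / p
    if det <= 0 or mean_eig <= 0 or p >= dof:
        return 0.0, 0.0, eps
    w = det / mean_eig**p
    rho = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * dof)
    chi2 = -rho * dof * np.log(max(w, 1e-300))
    df_w = p * (p + 1) // 2 - 1
    p_mauchly = float(stats.chi2.sf(chi2, df_w))
    return float(w), p_mauchly, eps


def _f_p(ss1, df1, ss2, df2):
    ms1, ms2 = ss1 / df1, ss2 / df2
    f = ms1 / ms2 if ms2 > 0 else np.inf
    return f, float(stats.f.sf(f, df1, df2))


def _gg_p(f, df1, df2, eps):
    return float(stats.f.sf(f, eps * df1, eps * df2))


def _check_balanced(y: np.ndarray):
    if np.isnan(y).any():
        bad = np.argwhere(np.isnan(y))
        raise ValueError(f"unbalanced design: missing cells at {bad[:5].tolist()}")


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within_a: str = "session",
    within_b: str = "unit_id",
) -> AnovaTable:
    """Three-way mixed ANOVA: one between-subject factor and two
    within-subject (repeated) factors, balanced design required.

    Effects reported: the between main effect, its interactions with each
    within factor and the three-way interaction, plus the within effects;
    each within F is tested against the matching subject-interaction
    error term.  With the emulated design (2 groups x 10 subjects, 2 time
    points, 36 regions) the Group x TP x ROI test has df (35, 630).
    """
    wide = table.pivot_table(
        index=[subject, between], columns=[within_a, within_b], values=dv
    )
    a_levels = sorted(table[within_a].unique())
    b_levels = sorted(table[within_b].unique())
    na, nb = len(a_levels), len(b_levels)
    y = wide.to_numpy(dtype=float)
    _check_balanced(y)
    y = y.reshape(len(wide), na, nb)
    groups = np.asarray([g for _, g in wide.index])
    uniq = np.unique(groups)
    counts = [int(np.sum(groups == g)) for g in uniq]
    if len(set(counts)) != 1:
        raise ValueError(f"unequal group sizes {dict(zip(uniq, counts))}")
    n_per = counts[0]
    ng = len(uniq)
    n_subj = y.shape[0]

    m = y.mean()
    m_g = {g: y[groups == g].mean() for g in uniq}
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ga = {g: y[groups == g].mean(axis=(0, 2)) for g in uniq}
    m_gb = {g: y[groups == g].mean(axis=(0, 1)) for g in uniq}
    m_ab = y.mean(axis=0)
    m_gab = {g: y[groups == g].mean(axis=0) for g in uniq}
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_g = n_per * na * nb * sum((m_g[g] - m) ** 2 for g in uniq)
    ss_sg = na * nb * sum(
        (m_s[i] - m_g[groups[i]]) ** 2 for i in range(n_subj)
    )
    ss_a = n_subj * nb * np.sum((m_a - m) ** 2)
    ss_b = n_subj * na * np.sum((m_b - m) ** 2)
    ss_ga = n_per * nb * sum(
        np.sum((m_ga[g] - m_g[g] - m_a + m) ** 2) for g in uniq
    )
    ss_gb = n_per * na * sum(
        np.sum((m_gb[g] - m_g[g] - m_b + m) ** 2) for g in uniq
    )
    ss_ab = n_subj * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_gab = n_per * sum(
        np.sum(
            (
                m_gab[g]
                - m_ga[g][:, None]
                - m_gb[g][None, :]
                - m_ab
                + m_g[g]
                + m_a[:, None]
                + m_b[None, :]
                - m
            )
            ** 2
        )
        for g in uniq
    )
    ss_as = nb * sum(
        np.sum((m_sa[i] - m_s[i] - m_ga[groups[i]] + m_g[groups[i]]) ** 2)
        for i in range(n_subj)
    )
    ss_bs = na * sum(
        np.sum((m_sb[i] - m_s[i] - m_gb[groups[i]] + m_g[groups[i]]) ** 2)
        for i in range(n_subj)
    )
    ss_total = np.sum((y - m) ** 2)
    ss_abs = ss_total - (
        ss_g + ss_sg + ss_a + ss_b + ss_ga + ss_gb + ss_ab + ss_gab + ss_as + ss_bs
    )

    df_sg = ng * (n_per - 1)
    df_as = (na - 1) * df_sg
    df_bs = (nb - 1) * df_sg
    df_abs = (na - 1) * (nb - 1) * df_sg

    yflat = y.reshape(n_subj, na * nb)
    c_a = _helmert(na)
    c_b = _helmert(nb)
    one_a = np.full((1, na), 1.0 / np.sqrt(na))
    one_b = np.full((1, nb), 1.0 / np.sqrt(nb))
    contrasts = {
        "TP": np.kron(c_a, one_b),
        "ROI": np.kron(one_a, c_b),
        "TP*ROI": np.kron(c_a, c_b),
    }

    results: dict[str, AnovaResult] = {}

    def add(effect, ss, df1, ss_err, df_err, within_key=None):
        f, p = _f_p(ss, df1, ss_err, df_err)
        eps, p_gg, w, p_m = 1.0, None, None, None
        if within_key is not None:
            w, p_m, eps = _gg_mauchly(yflat, groups, contrasts[within_key])
            if df1 > 1:
                p_gg = _gg_p(f, df1, df_err, eps)
        results[effect] = AnovaResult(
            effect, float(ss), df1, df_err, f, p, eps, p_gg, w, p_m
        )

    add("Group", ss_g, ng - 1, ss_sg, df_sg)
    add("TP", ss_a, na - 1, ss_as, df_as, "TP")
    add("Group*TP", ss_ga, (ng - 1) * (na - 1), ss_as, df_as, "TP")
    add("ROI", ss_b, nb - 1, ss_bs, df_bs, "ROI")
    add("Group*ROI", ss_gb, (ng - 1) * (nb - 1), ss_bs, df_bs, "ROI")
    add("TP*ROI", ss_ab, (na - 1) * (nb - 1), ss_abs, df_abs, "TP*ROI")
    add("Group*TP*ROI", ss_gab, (ng - 1) * (na - 1) * (nb - 1), ss_abs, df_abs, "TP*ROI")

    return AnovaTable(
        design="mixed",
        results=results,
        data=y,
        groups=groups,
        a_levels=a_levels,
        b_levels=b_levels,
        error_terms={
            "Subject(Group)": (float(ss_sg), df_sg),
            "TP*Subject(Group)": (float(ss_as), df_as),
            "ROI*Subject(Group)": (float(ss_bs), df_bs),
            "TP*ROI*Subject(Group)": (float(ss_abs), df_abs),
        },
    )


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within_a: str = "session",
    within_b: str = "unit_id",
) -> AnovaTable:
    """Two-way repeated-measures ANOVA (both factors within-subject).

    With 10 subjects, 3 time points and 36 regions the TP x ROI
    interaction has df (70, 630).
    """
    wide = table.pivot_table(index=subject, columns=[within_a, within_b], values=dv)
    a_levels = sorted(table[within_a].unique())
    b_levels = sorted(table[within_b].unique())
    na, nb = len(a_levels), len(b_levels)
    y = wide.to_numpy(dtype=float)
    _check_balanced(y)
    n_subj = y.shape[0]
    y = y.reshape(n_subj, na, nb)

    m = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_s = na * nb * np.sum((m_s - m) ** 2)
    ss_a = n_subj * nb * np.sum((m_a - m) ** 2)
    ss_b = n_subj * na * np.sum((m_b - m) ** 2)
    ss_ab = n_subj * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = nb * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_bs = na * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
    ss_total = np.sum((y - m) ** 2)
    ss_abs = ss_total - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    df_as = (na - 1) * (n_subj - 1)
    df_bs = (nb - 1) * (n_subj - 1)
    df_abs = (na - 1) * (nb - 1) * (n_subj - 1)

    yflat = y.reshape(n_subj, na * nb)
    c_a = _helmert(na)
    c_b = _helmert(nb)
    one_a = np.full((1, na), 1.0 / np.sqrt(na))
    one_b = np.full((1, nb), 1.0 / np.sqrt(nb))
    contrasts = {
        "TP": np.kron(c_a, one_b),
        "ROI": np.kron(one_a, c_b),
        "TP*ROI": np.kron(c_a, c_b),
    }
    results: dict[str, AnovaResult] = {}

    def add(effect, ss, df1, ss_err, df_err, within_key):
        f, p = _f_p(ss, df1, ss_err, df_err)
        w, p_m, eps = _gg_mauchly(yflat, None, contrasts[within_key])
        p_gg = _gg_p(f, df1, df_err, eps) if df1 > 1 else None
        results[effect] = AnovaResult(
            effect, float(ss), df1, df_err, f, p, eps, p_gg, w, p_m
        )

    add("TP", ss_a, na - 1, ss_as, df_as, "TP")
    add("ROI", ss_b, nb - 1, ss_bs, df_bs, "ROI")
    add("TP*ROI", ss_ab, (na - 1) * (nb - 1), ss_abs, df_abs, "TP*ROI")

    return AnovaTable(
        design="rm",
        results=results,
        data=y,
        groups=None,
        a_levels=a_levels,
        b_levels=b_levels,
        error_terms={
            "Subject": (float(ss_s), n_subj - 1),
            "TP*Subject": (float(ss_as), df_as),
            "ROI*Subject": (float(ss_bs), df_bs),
            "TP*ROI*Subject": (float(ss_abs), df_abs),
        },
    )


def posthoc(
    anova: AnovaTable,
    effect: str | None = None,
    method: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise post-hoc comparisons, gated on a significant interaction.

    Mixed design (gate: Group*TP*ROI): unpaired control-vs-patient tests
    per (region, time point); positive sign means patients > controls.
    RM design (gate: TP*ROI): paired tests per (region, tp pair);
    positive sign means the earlier time point is larger.  Bonferroni
    multiplies each raw p by the number of regions (family per time
    comparison); LSD reports raw p.
    """
    if method not in ("bonferroni", "lsd"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    if effect is None:
        effect = "Group*TP*ROI" if anova.design == "mixed" else "TP*ROI"
    gate = anova[effect]
    if gate.p_report >= alpha:
        raise ValueError(
            f"post-hoc refused: interaction {effect} not significant "
            f"(p = {gate.p_report:.3g})"
        )
    y = anova.data
    nb = len(anova.b_levels)
    m = nb if method == "bonferroni" else 1
    rows = []
    if anova.design == "mixed":
        uniq = np.unique(anova.groups)
        if len(uniq) != 2:
            raise ValueError("mixed post-hoc expects two groups")
        g0 = anova.groups == uniq[0]
        g1 = anova.groups == uniq[1]
        for ai, a in enumerate(anova.a_levels):
            for bi, b in enumerate(anova.b_levels):
                x0, x1 = y[g0, ai, bi], y[g1, ai, bi]
                t, p = stats.ttest_ind(x0, x1)
                p_adj = min(1.0, float(p) * m)
                rows.append(
                    {
                        "unit": b,
                        "comparison": f"{uniq[0]} vs {uniq[1]} @ tp{a}",
                        "p_adj": p_adj,
                        "sign": int(np.sign(x1.mean() - x0.mean())),
                        "significant": p_adj < alpha,
                    }
                )
    else:
        pairs = [
            (i, j)
            for i in range(len(anova.a_levels))
            for j in range(i + 1, len(anova.a_levels))
        ]
        for ai, aj in pairs:
            for bi, b in enumerate(anova.b_levels):
                t, p = stats.ttest_rel(y[:, ai, bi], y[:, aj, bi])
                p_adj = min(1.0, float(p) * m)
                rows.append(
                    {
                        "unit": b,
                        "comparison": f"tp{anova.a_levels[ai]} vs tp{anova.a_levels[aj]}",
                        "p_adj": p_adj,
                        "sign": int(np.sign(y[:, ai, bi].mean() - y[:, aj, bi].mean())),
                        "significant": p_adj < alpha,
                    }
                )
    return pd.DataFrame(rows)
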