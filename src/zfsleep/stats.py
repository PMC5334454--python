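"""Statistical machinery shared across the pipeline.

One- and two-way ANOVA (balanced, orthogonal decomposition), Tukey's HSD
with studentized-range p-values, Student's t, the four-parameter logistic
(4PL) curve used both for arousal-threshold dose-response fits and for
ELISA standard-curve calibration, and the extra sum-of-squares F test for
comparing nested curve fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "StatsError",
    "AnovaResult",
    "TukeyResult",
    "FourPLFit",
    "StandardCurve",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "students_t",
    "fourpl",
    "fit_fourpl",
    "extra_ss_f",
    "fit_standard_curve",
    "elisa_concentration",
]


class StatsError(ValueError):
    """Raised on degenerate inputs (empty groups, zero variance, bad fits)."""


@dataclass
class AnovaResult:
    """ANOVA table: one row per effect plus a residual row.

    ``table`` columns: effect, ss, df, ms, F, p.  For balanced designs the
    effect and residual sums of squares add up to the total SS.
    """

    table: pd.DataFrame

    def p(self, effect: str) -> float:
        row = self.table[self.table["effect"] == effect]
        if row.empty:
            raise KeyError(f"no effect {effect!r}")
        return float(row["p"].iloc[0])

    def f(self, effect: str) -> float:
        row = self.table[self.table["effect"] == effect]
        if row.empty:
            raise KeyError(f"no effect {effect!r}")
        return float(row["F"].iloc[0])


def _as_groups(groups) -> list:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, g in enumerate(out):
        if g.size == 0:
            raise StatsError(f"group {i} is empty")
    return out


def one_way_anova(groups) -> AnovaResult:
    """Classical between/within decomposition; p from F(df_between, df_within)."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise StatsError("one-way ANOVA needs at least two groups")
    all_vals = np.concatenate(groups)
    n = all_vals.size
    k = len(groups)
    if n - k < 1:
        raise StatsError("not enough residual degrees of freedom")
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        if ss_between == 0.0:
            f_stat, p = np.nan, np.nan  # flagged undefined
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = ms_b / ms_w
        p = float(sps.f.sf(f_stat, df_b, df_w))
    table = pd.DataFrame(
        [
            {"effect": "group", "ss": ss_between, "df": df_b, "ms": ms_b,
             "F": f_stat, "p": p},
            {"effect": "residual", "ss": ss_within, "df": df_w, "ms": ms_w,
             "F": np.nan, "p": np.nan},
        ]
    )
    return AnovaResult(table)


def two_way_anova(values, factor_a, factor_b,
                  names: tuple = ("A", "B")) -> AnovaResult:
    """Balanced two-factor ANOVA with interaction (orthogonal decomposition).

    The design must be balanced (every cell the same n >= 2); unbalanced
    data are rejected rather than silently choosing a sum-of-squares type.
    """
    values = np.asarray(values, dtype=float).ravel()
    fa = np.asarray(factor_a).ravel()
    fb = np.asarray(factor_b).ravel()
    if not (len(values) == len(fa) == len(fb)):
        raise StatsError("values and factors must have equal length")
    levels_a = list(dict.fromkeys(fa))
    levels_b = list(dict.fromkeys(fb))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise StatsError("each factor needs at least two levels")
    cell_n = {}
    cell_mean = {}
    for a in levels_a:
        for b in levels_b:
            sel = (fa == a) & (fb == b)
            if not sel.any():
                raise StatsError(f"empty cell ({a!r}, {b!r})")
            cell_n[(a, b)] = int(sel.sum())
            cell_mean[(a, b)] = values[sel].mean()
    ns = set(cell_n.values())
    if len(ns) != 1:
        raise StatsError(f"unbalanced design: cell sizes {sorted(ns)}")
    n_cell = ns.pop()
    if n_cell < 2:
        raise StatsError("interaction not estimable: need >= 2 observations per cell")
    grand = values.mean()
    na, nb = len(levels_a), len(levels_b)
    mean_a = {a: values[fa == a].mean() for a in levels_a}
    mean_b = {b: values[fb == b].mean() for b in levels_b}
    ss_a = n_cell * nb * sum((mean_a[a] - grand) ** 2 for a in levels_a)
    ss_b = n_cell * na * sum((mean_b[b] - grand) ** 2 for b in levels_b)
    ss_ab = n_cell * sum(
        (cell_mean[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in levels_a for b in levels_b
    )
    ss_res = 0.0
    for a in levels_a:
        for b in levels_b:
            sel = (fa == a) & (fb == b)
            ss_res += ((values[sel] - cell_mean[(a, b)]) ** 2).sum()
    df_a, df_b_, df_ab = na - 1, nb - 1, (na - 1) * (nb - 1)
    df_res = values.size - na * nb
    ms_res = ss_res / df_res
    rows = []
    for effect, ss, df in [
        (names[0], ss_a, df_a),
        (names[1], ss_b, df_b_),
        (f"{names[0]}:{names[1]}", ss_ab, df_ab),
    ]:
        ms = ss / df
        if ms_res == 0.0:
            f_stat = np.nan if ss == 0.0 else np.inf
            p = np.nan if ss == 0.0 else 0.0
        else:
            f_stat = ms / ms_res
            p = float(sps.f.sf(f_stat, df, df_res))
        rows.append({"effect": effect, "ss": ss, "df": df, "ms": ms,
                     "F": f_stat, "p": p})
    rows.append({"effect": "residual", "ss": ss_res, "df": df_res,
                 "ms": ms_res, "F": np.nan, "p": np.nan})
    return AnovaResult(pd.DataFrame(rows))


@dataclass
class TukeyResult:
    """Pairwise Tukey–Kramer comparisons: mean difference, q, adjusted p."""

    table: pd.DataFrame
    ms_within: float
    df_within: int


def tukey_hsd(groups, labels=None) -> TukeyResult:
    """Tukey's HSD over >= 3 groups.

    q_ij = |m_i - m_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j)); adjusted p
    from the studentized-range distribution with (k, df_within).
    """
    groups = _as_groups(groups)
    k = len(groups)
    if k < 3:
        raise StatsError("Tukey's HSD is applied to three or more groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    n_tot = sum(g.size for g in groups)
    df_w = n_tot - k
    if df_w < 1:
        raise StatsError("no residual degrees of freedom")
    ms_w = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    if ms_w == 0.0:
        raise StatsError("within-group variance is zero")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            se = np.sqrt(ms_w / 2.0 * (1.0 / groups[i].size + 1.0 / groups[j].size))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
            rows.append({"group_i": labels[i], "group_j": labels[j],
                         "mean_diff": diff, "q": q,
                         "p_adj": float(np.clip(p, 0.0, 1.0))})
    return TukeyResult(pd.DataFrame(rows), ms_w, df_w)


def students_t(group1, group2, two_sided: bool = True, welch: bool = False):
    """Two-sample Student's t (pooled variance by default; Welch optional).

    Returns ``(t, df, p)``.
    """
    x = np.asarray(group1, dtype=float).ravel()
    y = np.asarray(group2, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise StatsError("each group needs n >= 2")
    if not welch:
        pooled = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum())
        if pooled == 0.0 and x.mean() != y.mean():
            raise StatsError("zero pooled variance with unequal means")
    res = sps.ttest_ind(
        x, y, equal_var=not welch,
        alternative="two-sided" if two_sided else "greater",
    )
    df = x.size + y.size - 2 if not welch else float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Four-parameter logistic curve (variable-slope log-dose model)
# ---------------------------------------------------------------------------

@dataclass
class FourPLFit:
    """4PL parameters on a log10-dose axis, with fit diagnostics.

    The curve is ``y = bottom + (top - bottom) / (1 + 10**((logec50 - x) * hill))``
    where x is log10(dose).  The convention ``top >= bottom, hill`` free in
    sign is normalized so that increasing curves carry hill > 0 (the
    symmetric parameterization swapping bottom/top and negating hill yields
    an identical curve).
    """

    bottom: float
    top: float
    logec50: float
    hill: float
    rss: float = np.nan
    df: int = 0
    n_points: int = 0

    @property
    def ec50(self) -> float:
        return float(10.0 ** self.logec50)

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        if np.any(dose <= 0):
            raise StatsError("dose must be positive (log-dose model)")
        return fourpl(np.log10(dose), self.bottom, self.top, self.logec50, self.hill)

    def predict_logdose(self, logdose) -> np.ndarray:
        return fourpl(np.asarray(logdose, dtype=float),
                      self.bottom, self.top, self.logec50, self.hill)


def fourpl(logdose, bottom, top, logec50, hill):
    """Evaluate the variable-slope 4PL at log10-dose values."""
    z = (logec50 - np.asarray(logdose, dtype=float)) * hill
    z = np.clip(z, -300.0, 300.0)  # avoid overflow in 10**z
    return bottom + (top - bottom) / (1.0 + 10.0 ** z)


def _fourpl_residuals(theta, logx, y, w):
    return (fourpl(logx, *theta) - y) * w


def fit_fourpl(logdose, y, weights=None) -> FourPLFit:
    """Least-squares 4PL fit with a deterministic multi-start.

    Starts: bottom = min(y), top = max(y), logec50 = median log-dose,
    hill in {+1, -1}; plus hill in {+2, -2} for steeper curves.  The best
    (lowest-RSS) converged start wins; results are deterministic given the
    data.  Raises on non-convergence of every start.
    """
    logx = np.asarray(logdose, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if logx.size != y.size:
        raise StatsError("dose and response lengths differ")
    n = y.size
    if np.unique(logx).size < 5:
        raise StatsError("need at least 5 distinct doses for a 4PL fit")
    w = np.ones(n) if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    lo, hi = float(y.min()), float(y.max())
    med = float(np.median(logx))
    best = None
    failures = []
    for hill0 in (1.0, -1.0, 2.0, -2.0):
        theta0 = np.array([lo, hi, med, hill0])
        try:
            sol = optimize.least_squares(
                _fourpl_residuals, theta0, args=(logx, y, w),
                method="lm" if n >= 4 else "trf", max_nfev=10000,
            )
        except Exception as exc:  # pragma: no cover - optimizer internals
            failures.append(str(exc))
            continue
        rss = float(np.sum((fourpl(logx, *sol.x) - y) ** 2))
        if best is None or rss < best[0] - 1e-14:
            best = (rss, sol)
    if best is None:
        raise StatsError(f"4PL fit failed to converge: {failures}")
    rss, sol = best
    bottom, top, logec50, hill = (float(v) for v in sol.x)
    # (b, t, L, h) and (t, b, L, -h) describe the same curve; normalize so
    # top >= bottom (then hill > 0 iff the curve increases with dose).
    if bottom > top:
        bottom, top, hill = top, bottom, -hill
    df = n - 4
    if df < 1:
        raise StatsError("residual degrees of freedom must be >= 1")
    return FourPLFit(bottom, top, logec50, hill, rss=rss, df=df, n_points=n)


def extra_ss_f(rss_null: float, df_null: int, rss_alt: float, df_alt: int):
    """Extra sum-of-squares F test for nested least-squares models.

    F = ((RSS_null - RSS_alt) / (df_null - df_alt)) / (RSS_alt / df_alt);
    p from F(df_null - df_alt, df_alt).  Returns ``(F, df_num, df_den, p)``.
    """
    if df_alt <= 0:
        raise StatsError("alternative model has no residual degrees of freedom")
    df_num = df_null - df_alt
    if df_num <= 0:
        raise StatsError("models are not nested (df_null must exceed df_alt)")
    if rss_alt <= 0.0:
        f_stat = np.inf if rss_null > rss_alt else 0.0
        return f_stat, df_num, df_alt, 0.0 if f_stat == np.inf else 1.0
    f_stat = ((rss_null - rss_alt) / df_num) / (rss_alt / df_alt)
    f_stat = max(f_stat, 0.0)
    p = float(sps.f.sf(f_stat, df_num, df_alt))
    return float(f_stat), df_num, df_alt, p


# ---------------------------------------------------------------------------
# ELISA standard-curve calibration
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """4PL calibration over (log10 concentration, absorbance) standards.

    ``zero_absorbance`` is the measured absorbance of the 0-concentration
    standard; sample readings beyond it on the low-concentration side clamp
    to exactly 0 (mirroring rounding negative estimates up to zero).
    """

    fit: FourPLFit
    zero_absorbance: float
    concentrations: np.ndarray = field(default_factory=lambda: np.array([]))
    increasing: bool = True  # absorbance vs concentration direction

    def absorbance_at(self, concentration) -> np.ndarray:
        return self.fit.predict(concentration)


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """Fit manufacturer standards to a 4PL; the 0 standard anchors clamping.

    The curve is fitted on log10 concentration over the nonzero standards
    and must be monotone over their range (competitive ELISAs decrease,
    sandwich ELISAs increase; both are accepted).
    """
    conc = np.asarray(concentrations, dtype=float).ravel()
    absb = np.asarray(absorbances, dtype=float).ravel()
    if conc.size != absb.size:
        raise StatsError("standards: concentration/absorbance lengths differ")
    if not np.any(conc == 0.0):
        raise StatsError("standards must include a 0-concentration standard")
    zero_abs = float(absb[conc == 0.0][0])
    pos = conc > 0
    fit = fit_fourpl(np.log10(conc[pos]), absb[pos])
    grid = np.linspace(np.log10(conc[pos].min()), np.log10(conc[pos].max()), 201)
    vals = fit.predict_logdose(grid)
    d = np.diff(vals)
    if np.all(d >= -1e-12):
        increasing = True
    elif np.all(d <= 1e-12):
        increasing = False
    else:
        raise StatsError("fitted standard curve is not monotone over the standards")
    return StandardCurve(fit=fit, zero_absorbance=zero_abs,
                         concentrations=np.sort(conc[pos]), increasing=increasing)


def elisa_concentration(absorbance: float, curve: StandardCurve):
    """Invert the standard curve: absorbance -> concentration.

    Returns ``(concentration, flag)`` with flag in {"ok", "clamped_zero",
    "above_range"}.  Readings beyond the zero standard on the
    low-concentration side return exactly 0.0 with the clamped flag;
    readings beyond the top standard are flagged out of range (the inverted
    value is still returned when invertible, else the top concentration).
    """
    y = float(absorbance)
    f = curve.fit
    top_conc = float(curve.concentrations.max())
    y_top = float(f.predict(top_conc))
    # Low-concentration side is bounded by the zero standard's absorbance.
    if (curve.increasing and y <= curve.zero_absorbance) or (
        not curve.increasing and y >= curve.zero_absorbance
    ):
        return 0.0, "clamped_zero"
    if not (f.bottom < y < f.top):
        # beyond the fitted asymptote on the high-concentration side
        return top_conc, "above_range"
    # closed-form inverse of the 4PL
    ratio = (f.top - f.bottom) / (y - f.bottom) - 1.0
    if ratio <= 0:
        return top_conc, "above_range"
    logc = f.logec50 - np.log10(ratio) / f.hill
    conc = float(10.0 ** logc)
    if (curve.increasing and y > y_top) or (not curve.increasing and y < y_top):
        return conc, "above_range"
    return conc, "ok"
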