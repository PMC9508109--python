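"""Statistical layer: variance-gated post hoc tests and repeated-measures ANOVA.

The comparison scheme mirrors the study's reporting: per kinematic variable
and analysis event, event-window samples from each step condition are
compared against level locomotion (unpaired, one-way MANOVA over the
9-sample window or univariate ANOVA on the window mean); post hoc pairwise
tests are TukeyHSD when a Brown-Forsythe (median-centered) Levene test
finds homogeneous variances and Games-Howell otherwise; the influence of
step height and direction within animals is assessed by repeated-measures
ANOVA (Greenhouse-Geisser corrected). Significance codes follow the
four-star convention: '****' p < 0.0001, '***' < 0.001, '**' < 0.01,
'*' < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.multivariate.manova import MANOVA

SIGNIFICANCE_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_code(p: float) -> str:
    """Star code for a p-value per the four-level convention."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for level, code in SIGNIFICANCE_LEVELS:
        if p < level:
            return code
    return ""


@dataclass
class ComparisonResult:
    """One pairwise comparison with its significance code."""

    variable: str
    event: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    @property
    def code(self) -> str:
        return significance_code(self.p)


def levene_test(groups) -> tuple:
    """Brown-Forsythe (median-centered) Levene test; returns (W, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if all(np.ptp(g) == 0 for g in groups):
        return 0.0, 1.0
    W, p = sps.levene(*groups, center="median")
    return float(W), float(p)


def rm_anova(table: pd.DataFrame, dv: str = "value", subject: str = "individual",
             within=("height", "direction")) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA (step height x direction).

    ``table`` is long-format with one row per (subject, height, direction).
    Individuals missing any cell are dropped (listwise completion).
    Greenhouse-Geisser corrected p-values are reported where available.
    """
    within = list(within)
    need = {dv, subject, *within}
    if not need <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(need)}")
    for w in within:
        if table[w].nunique() < 2:
            raise ValueError(f"factor {w!r} needs >= 2 levels")
    # listwise completion
    counts = table.groupby(subject)[within].apply(
        lambda d: d.drop_duplicates().shape[0])
    full = table.groupby(subject).size()
    n_cells = int(np.prod([table[w].nunique() for w in within]))
    keep = counts[(counts == n_cells) & (full >= n_cells)].index
    data = table[table[subject].isin(keep)]
    if data[subject].nunique() < 2:
        raise ValueError("fewer than 2 complete subjects")
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      detailed=True)
    pcol = next((c for c in ("p_GG_corr", "p-GG-corr", "p_unc", "p-unc")
                 if c in aov.columns), None)
    if pcol is None:
        raise RuntimeError("no p-value column in rm-ANOVA table")
    out = aov.rename(columns={pcol: "p"})
    keep_cols = [c for c in ("Source", "ddof1", "ddof2", "F", "p") if c in out]
    out = out[keep_cols].copy()
    # a zero-variance cell yields 0/0; report F = 0, p = 1 (no effect)
    out["F"] = out["F"].fillna(0.0)
    out["p"] = out["p"].fillna(1.0)
    return out


def posthoc(groups: dict, homogeneous: bool | None = None,
            variable: str = "", event: str = "") -> list:
    """All pairwise comparisons: TukeyHSD if variances are homogeneous,
    Games-Howell otherwise (Levene-gated when ``homogeneous`` is None)."""
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if homogeneous is None:
        _, p_lev = levene_test(arrays)
        homogeneous = p_lev >= 0.05
    results = []
    if homogeneous:
        res = sps.tukey_hsd(*arrays)
        n_total = sum(len(a) for a in arrays)
        df = n_total - len(arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                results.append(ComparisonResult(
                    variable=variable, event=event,
                    group_a=names[i], group_b=names[j], test="tukey_hsd",
                    statistic=float(res.statistic[i, j]), df=float(df),
                    p=float(np.clip(res.pvalue[i, j], 0.0, 1.0))))
    else:
        if any(len(a) < 2 for a in arrays):
            raise ValueError("Games-Howell needs n >= 2 per group")
        long = pd.DataFrame({
            "value": np.concatenate(arrays),
            "group": np.repeat(names, [len(a) for a in arrays])})
        gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        for _, row in gh.iterrows():
            results.append(ComparisonResult(
                variable=variable, event=event,
                group_a=str(row["A"]), group_b=str(row["B"]),
                test="games_howell", statistic=float(row["T"]),
                df=float(row["df"]), p=float(np.clip(row["pval"], 0.0, 1.0))))
    return results


def _manova_p(a: np.ndarray, b: np.ndarray) -> float:
    """Wilks-lambda p of a one-way two-group MANOVA on window samples."""
    Y = np.vstack([a, b])
    df = pd.DataFrame(Y, columns=[f"y{i}" for i in range(Y.shape[1])])
    df["grp"] = ["a"] * len(a) + ["b"] * len(b)
    formula = " + ".join(df.columns[:-1]) + " ~ grp"
    try:
        mv = MANOVA.from_formula(formula, data=df)
        tab = mv.mv_test().results["grp"]["stat"]
        return float(tab.loc["Wilks' lambda", "Pr > F"])
    except (ValueError, np.linalg.LinAlgError):
        # degenerate hypothesis matrix (e.g. numerically identical groups):
        # no detectable multivariate effect
        return 1.0


def condition_vs_level(condition_windows: np.ndarray,
                       level_windows: np.ndarray,
                       variable: str = "", event: str = "",
                       condition: str = "condition",
                       response: str = "multivariate") -> ComparisonResult:
    """Compare one step condition's event windows against level locomotion.

    ``*_windows`` are (n, 9) arrays (event +/- 4 samples per stride).
    ``response="multivariate"`` runs a one-way MANOVA over the window,
    then a Levene-gated post hoc on the window means supplies the pairwise
    statistic and code; ``response="mean"`` skips the MANOVA and compares
    window means directly.
    """
    cond = np.atleast_2d(np.asarray(condition_windows, dtype=float))
    ref = np.atleast_2d(np.asarray(level_windows, dtype=float))
    if ref.size == 0 or cond.size == 0:
        raise ValueError("empty sample set")
    mean_c, mean_r = np.nanmean(cond, axis=1), np.nanmean(ref, axis=1)
    res = posthoc({condition: mean_c, "level": mean_r},
                  variable=variable, event=event)[0]
    if response == "multivariate":
        ok = min(len(cond), len(ref)) > cond.shape[1]
        if ok:
            p_mv = _manova_p(cond, ref)
            # the omnibus MANOVA gates the post hoc comparison
            if p_mv >= 0.05:
                res = ComparisonResult(
                    variable=variable, event=event, group_a=condition,
                    group_b="level", test=res.test + "+manova_ns",
                    statistic=res.statistic, df=res.df, p=max(res.p, p_mv))
    elif response != "mean":
        raise ValueError("response must be 'multivariate' or 'mean'")
    return res


def comparison_table(results: list) -> pd.DataFrame:
    """Long results table with the star coding as a text column."""
    return pd.DataFrame([{
        "variable": r.variable, "event": r.event,
        "group_a": r.group_a, "group_b": r.group_b, "test": r.test,
        "statistic": r.statistic, "df": r.df, "p": r.p, "code": r.code,
    } for r in results])
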