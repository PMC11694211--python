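"""Repeated-measures statistical battery and a-priori power analysis.

Each biomechanical variable is summarised as a subjects x 4-condition table
and run through the decision battery used throughout sports-science RM
designs:

1. Shapiro-Wilk on every condition column (all must pass at ``alpha``);
2. one-way repeated-measures ANOVA if normality holds, else the Friedman
   rank test;
3. pairwise post hoc only when the omnibus test is significant: paired t
   tests with Bonferroni correction after an ANOVA, Wilcoxon signed-rank
   (Pratt zero handling) with the same correction after a Friedman test.

Effect sizes: partial eta squared (ANOVA), Kendall's W (Friedman).

The a-priori power of the within-factor RM-ANOVA uses the noncentral F
distribution with noncentrality ``lambda = f^2 * n * m * eps / (1 - rho)``
and degrees of freedom ``(m-1)*eps`` and ``(n-1)*(m-1)*eps``, where ``f``
is Cohen's effect size, ``m`` the number of repeated measurements, ``rho``
the assumed correlation among them and ``eps`` the nonsphericity
correction (1 = sphericity, the G*Power default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .io import CONDITIONS, FEATURE_COLUMNS, PipelineConfig

__all__ = [
    "PowerQuery",
    "OmnibusResult",
    "PairwiseResult",
    "choose_test",
    "rm_anova",
    "friedman",
    "posthoc",
    "analyze_variable",
    "rmanova_power",
    "min_sample_size",
    "ConditionStudy",
    "StudyResults",
]


class DegenerateDataError(ValueError):
    """The table has no within-cell variance left to test."""


def _as_table(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Coerce to a units x conditions DataFrame (a bare 4-column array gets
    the standard condition labels)."""
    if isinstance(table, np.ndarray):
        if table.ndim != 2:
            raise ValueError("expected a 2-D units x conditions array")
        cols = (list(CONDITIONS) if table.shape[1] == len(CONDITIONS)
                else [f"c{i + 1}" for i in range(table.shape[1])])
        table = pd.DataFrame(table, columns=cols)
    table = table.dropna()
    if table.shape[1] < 2:
        raise ValueError("need at least 2 condition columns")
    if len(table) < 3:
        raise ValueError("need at least 3 units of analysis")
    return table.astype(float)


# ---------------------------------------------------------------------------
# battery components
# ---------------------------------------------------------------------------

def choose_test(table: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> str:
    """Normality gate: ``"rm_anova"`` iff every condition column passes Shapiro-Wilk.

    A zero-variance column is treated as a (degenerate) normality failure.
    """
    table = _as_table(table)
    for col in table.columns:
        x = table[col].to_numpy()
        if np.ptp(x) == 0:
            return "friedman"
        if sps.shapiro(x).pvalue < alpha:
            return "friedman"
    return "rm_anova"


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class OmnibusResult:
    variable: str
    test_used: str              # "rm_anova" | "friedman"
    statistic: float
    df: tuple[float, float] | float
    p_value: float
    effect_size: float          # partial eta^2 (ANOVA) or Kendall's W
    effect_size_name: str
    n_units: int
    posthoc: list[PairwiseResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": self.p_value,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "n": self.n_units,
            "posthoc": [
                {"pair": list(p.pair), "statistic": p.statistic,
                 "p_raw": p.p_raw, "p_adjusted": p.p_adjusted}
                for p in self.posthoc
            ],
        }


def rm_anova(table: pd.DataFrame | np.ndarray, variable: str = "") -> OmnibusResult:
    """One-way repeated-measures ANOVA across the four conditions.

    F on ``(k-1, (k-1)(n-1))`` df; partial eta squared recovered from F via
    ``F*df1 / (F*df1 + df2)`` (identical to SS_cond / (SS_cond + SS_err)).
    """
    table = _as_table(table)
    n, k = table.shape
    arr = table.to_numpy()
    if np.ptp(arr) == 0:
        raise DegenerateDataError("the table is constant: nothing to test")
    resid = arr - arr.mean(1, keepdims=True) - arr.mean(0) + arr.mean()
    ss_cond = n * float(((arr.mean(0) - arr.mean()) ** 2).sum())
    if np.allclose(resid, 0.0):
        if np.isclose(ss_cond, 0.0):
            # identical columns up to a per-subject offset: no condition effect
            return OmnibusResult(
                variable=variable, test_used="rm_anova", statistic=0.0,
                df=(float(k - 1), float((k - 1) * (n - 1))), p_value=1.0,
                effect_size=0.0, effect_size_name="partial_eta_squared",
                n_units=n,
            )
        raise DegenerateDataError("no variance left for the RM-ANOVA error term")
    long = table.reset_index(names="unit").melt(
        id_vars="unit", var_name="condition", value_name="y")
    fit = AnovaRM(long, depvar="y", subject="unit", within=["condition"]).fit()
    row = fit.anova_table.iloc[0]
    F = float(row["F Value"])
    df1, df2 = float(row["Num DF"]), float(row["Den DF"])
    p = float(row["Pr > F"])
    eta_p2 = (F * df1) / (F * df1 + df2) if np.isfinite(F) else np.nan
    return OmnibusResult(
        variable=variable, test_used="rm_anova", statistic=F,
        df=(df1, df2), p_value=p, effect_size=float(eta_p2),
        effect_size_name="partial_eta_squared", n_units=n,
    )


def friedman(table: pd.DataFrame | np.ndarray, variable: str = "") -> OmnibusResult:
    """Friedman rank test across the four conditions (ties mid-ranked).

    Effect size is Kendall's W = chi2 / (n * (k - 1)).
    """
    table = _as_table(table)
    n, k = table.shape
    if k < 3:
        raise ValueError("the Friedman test needs at least 3 conditions")
    cols = [table[c].to_numpy() for c in table.columns]
    arr = table.to_numpy()
    if np.ptp(arr - arr.mean(1, keepdims=True)) == 0:
        # identical columns (up to a per-row constant): statistic is 0
        return OmnibusResult(
            variable=variable, test_used="friedman", statistic=0.0,
            df=float(k - 1), p_value=1.0, effect_size=0.0,
            effect_size_name="kendalls_w", n_units=n,
        )
    stat, p = sps.friedmanchisquare(*cols)
    w = float(stat) / (n * (k - 1))
    return OmnibusResult(
        variable=variable, test_used="friedman", statistic=float(stat),
        df=float(k - 1), p_value=float(p), effect_size=w,
        effect_size_name="kendalls_w", n_units=n,
    )


def posthoc(table: pd.DataFrame | np.ndarray, test_used: str,
            alpha: float = 0.05) -> list[PairwiseResult]:
    """All pairwise comparisons with Bonferroni-adjusted p values.

    Paired t after an ANOVA, Wilcoxon signed-rank (Pratt) after a Friedman
    test; a pair of identical columns gets p = 1 by convention.
    """
    table = _as_table(table)
    pairs = list(combinations(table.columns, 2))
    m = len(pairs)
    out: list[PairwiseResult] = []
    for a, b in pairs:
        x, y = table[a].to_numpy(), table[b].to_numpy()
        if np.ptp(x - y) == 0 and np.all(x == y):
            stat, p = 0.0, 1.0
        elif test_used == "rm_anova":
            res = sps.ttest_rel(x, y)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = sps.wilcoxon(x, y, zero_method="pratt")
            stat, p = float(res.statistic), float(res.pvalue)
        out.append(PairwiseResult(
            pair=(str(a), str(b)), statistic=stat, p_raw=p,
            p_adjusted=min(1.0, p * m),
        ))
    return out


def analyze_variable(table: pd.DataFrame | np.ndarray, variable: str = "",
                     alpha: float = 0.05) -> OmnibusResult:
    """Run the full decision battery on one variable table."""
    table = _as_table(table)
    test = choose_test(table, alpha)
    result = rm_anova(table, variable) if test == "rm_anova" else friedman(table, variable)
    if result.p_value < alpha:
        result.posthoc = posthoc(table, test, alpha)
    return result


# ---------------------------------------------------------------------------
# a-priori power
# ---------------------------------------------------------------------------

@dataclass
class PowerQuery:
    """Inputs of the within-factor RM-ANOVA power computation."""

    f: float = 0.5            # Cohen's effect size
    alpha: float = 0.05
    target_power: float = 0.95
    m: int = 4                # number of repeated measurements
    rho: float = 0.5          # correlation among repeated measures
    epsilon: float = 1.0      # nonsphericity correction

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("effect size f must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target power must be in (0, 1)")
        if self.m < 2:
            raise ValueError("need at least 2 measurements")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")


def rmanova_power(q: PowerQuery, n: int) -> float:
    """Power of the within-factor RM-ANOVA at sample size ``n``.

    ``P[F'(df1, df2, lambda) > F_crit(1-alpha)]`` with
    ``lambda = f^2 n m eps / (1 - rho)``, ``df1 = (m-1) eps`` and
    ``df2 = (n-1)(m-1) eps``.  With ``f = 0`` this reduces to ``alpha``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    lam = q.f ** 2 * n * q.m * q.epsilon / (1.0 - q.rho)
    df1 = (q.m - 1) * q.epsilon
    df2 = (n - 1) * (q.m - 1) * q.epsilon
    fcrit = sps.f.isf(q.alpha, df1, df2)
    if lam == 0:
        return float(q.alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def min_sample_size(q: PowerQuery, n_max: int = 10_000) -> int:
    """Smallest ``n`` whose power reaches ``q.target_power``."""
    for n in range(2, n_max + 1):
        if rmanova_power(q, n) >= q.target_power:
            return n
    raise ValueError(
        f"target power {q.target_power} not attainable below n = {n_max} "
        f"(power there: {rmanova_power(q, n_max):.4f})"
    )


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class ConditionStudy:
    """Comparison of biomechanical variables across the four learning conditions.

    Built from a per-trial feature table (the CSV written by
    :func:`snatchlab.io.write_features`), collapsed to the configured unit
    of analysis — subject means over the three repetitions by default, or
    individual trials.  ``fit()`` runs the decision battery per variable and
    returns a :class:`StudyResults`.

    Examples
    --------
    >>> study = ConditionStudy.from_features(df)          # doctest: +SKIP
    >>> res = study.fit()                                 # doctest: +SKIP
    >>> print(res.summary())                              # doctest: +SKIP
    """

    def __init__(self, tables: dict[str, pd.DataFrame],
                 cfg: PipelineConfig | None = None):
        self.cfg = cfg or PipelineConfig()
        self.tables = {v: _as_table(t) for v, t in tables.items()}

    @classmethod
    def from_features(cls, df: pd.DataFrame,
                      variables: Sequence[str] | None = None,
                      cfg: PipelineConfig | None = None) -> "ConditionStudy":
        """Build the study from a long per-trial feature table.

        ``df`` needs ``subject_id`` and ``condition`` columns plus one
        column per variable; ``variables`` defaults to every recognised
        parameter present.
        """
        cfg = cfg or PipelineConfig()
        variables = list(variables) if variables is not None else [
            c for c in FEATURE_COLUMNS if c in df.columns
        ]
        if not variables:
            raise ValueError("no recognised variable columns in the feature table")
        tables: dict[str, pd.DataFrame] = {}
        for var in variables:
            if cfg.stats_unit == "subject_mean":
                wide = (df.groupby(["subject_id", "condition"])[var].mean()
                          .unstack("condition"))
            else:
                key = df["subject_id"].astype(str) + "/" + df["trial"].astype(str)
                wide = (df.assign(_unit=key)
                          .pivot_table(index="_unit", columns="condition",
                                       values=var, aggfunc="mean"))
            tables[var] = wide.reindex(columns=list(CONDITIONS))
        return cls(tables, cfg)

    def fit(self) -> "StudyResults":
        results = {
            var: analyze_variable(tab, var, self.cfg.alpha)
            for var, tab in self.tables.items()
        }
        return StudyResults(self, results)


class StudyResults:
    """Per-variable omnibus and post-hoc results of a :class:`ConditionStudy`."""

    def __init__(self, model: ConditionStudy, results: dict[str, OmnibusResult]):
        self.model = model
        self.results = results

    def __getitem__(self, variable: str) -> OmnibusResult:
        return self.results[variable]

    def summary(self) -> pd.DataFrame:
        """One row per variable: per-condition mean +/- SD, test, statistic, p, effect size."""
        rows = []
        for var, res in self.results.items():
            tab = self.model.tables[var]
            row: dict[str, object] = {"variable": var}
            for cond in tab.columns:
                row[cond] = f"{tab[cond].mean():.2f} ± {tab[cond].std(ddof=1):.2f}"
            df = res.df
            row["test"] = res.test_used
            row["statistic"] = round(res.statistic, 3)
            row["df"] = (f"({df[0]:g}, {df[1]:g})" if isinstance(df, tuple)
                         else f"{df:g}")
            row["p"] = round(res.p_value, 3)
            row[res.effect_size_name] = round(res.effect_size, 3)
            rows.append(row)
        return pd.DataFrame(rows).set_index("variable")

    def to_json(self, path=None) -> str:
        payload = {var: res.to_dict() for var, res in self.results.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def plot(self, variable: str, ax=None):
        """Per-condition box plot with subject lines for one variable."""
        import matplotlib.pyplot as plt

        tab = self.model.tables[variable]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.boxplot([tab[c].dropna() for c in tab.columns],
                   tick_labels=list(tab.columns))
        xs = np.arange(1, len(tab.columns) + 1)
        for _, row in tab.iterrows():
            ax.plot(xs, row.to_numpy(), color="0.7", lw=0.8, zorder=0)
        res = self.results[variable]
        ax.set_title(f"{variable}  ({res.test_used}, p = {res.p_value:.3f})")
        ax.set_ylabel(variable)
        return ax
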