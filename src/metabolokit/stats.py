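"""Design-driven univariate statistics: method suggestion, hypothesis
tests, post hoc procedures, FDR adjustment, bootstrap and power analysis.

The engine maps a declared study design (two-group / multi-group /
factorial, independent / paired / mixed) to the appropriate parametric
test, its non-parametric alternative and the follow-up procedures, runs
them per feature with complete-case handling, and adjusts p-values across
features by Benjamini-Hochberg.

Welch-family tests are the defaults: they are robust to unequal group
variances, which is the rule rather than the exception in metabolomic
intensities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import FTestAnovaPower, TTestIndPower, TTestPower

from .core_data import Dataset, SUBJECT_COL

__all__ = [
    "DesignSpec",
    "PowerSpec",
    "TestResult",
    "suggest_methods",
    "two_group_test",
    "multi_group_test",
    "repeated_test",
    "factorial_test",
    "post_hoc",
    "adjust_bh",
    "bootstrap_pvalue",
    "power_analysis",
    "test_features",
]

DESIGNS = (
    "two_independent",
    "two_paired",
    "multi_independent",
    "multi_paired",
    "twoway_independent",
    "twoway_paired",
    "twoway_mixed",
)


class StatsError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Declarative study design driving automatic method selection."""

    design: str
    factors: tuple[str, ...] = ()
    subject: str | None = None
    within: tuple[str, ...] = ()  # within-subject factors (factorial designs)

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise StatsError(f"unknown design {self.design!r}; one of {DESIGNS}")
        if isinstance(self.factors, str):
            self.factors = (self.factors,)
        self.factors = tuple(self.factors)
        self.within = tuple(self.within)
        if self.design.startswith("twoway") and len(self.factors) != 2:
            raise StatsError("two-way designs require exactly 2 factors")
        if not self.design.startswith("twoway") and len(self.factors) != 1:
            raise StatsError(f"{self.design} requires exactly 1 factor")
        if self.requires_subject and self.subject is None:
            self.subject = SUBJECT_COL
        if self.design == "twoway_mixed" and len(self.within) != 1:
            # by convention the second factor is within-subject unless stated
            self.within = (self.factors[1],)

    @property
    def requires_subject(self) -> bool:
        return self.design in ("two_paired", "multi_paired", "twoway_paired", "twoway_mixed")


# ---------------------------------------------------------------------------
# method suggestion

_FDR_NOTE = "P-values adjusted for FDR correction using Benjamini-Hochberg procedure"
_FACTORIAL_NOTE = (
    "Post hoc analysis on main effect level and simple main effect level "
    "corresponding to secondary study design structure"
)

_METHOD_TABLE: dict[str, dict] = {
    "two_independent": {
        "methods": [
            ("welch", "Welch's t test", "parametric"),
            ("mannwhitney", "Mann-Whitney U test", "nonparametric"),
            ("student", "t test", "parametric"),
        ],
        "following": [_FDR_NOTE],
    },
    "two_paired": {
        "methods": [
            ("welch", "Welch's t test on difference", "parametric"),
            ("mannwhitney", "Mann-Whitney U test on difference", "nonparametric"),
            ("student", "t test on difference", "parametric"),
        ],
        "following": [_FDR_NOTE],
    },
    "multi_independent": {
        "methods": [
            ("welch_anova", "Welch ANOVA", "parametric"),
            ("kruskal", "Kruskal-Wallis rank sum test", "nonparametric"),
            ("anova", "ANOVA", "parametric"),
        ],
        "following": [
            "Parametric test followed by Games-Howell (or Tukey) post hoc test",
            "Non-parametric test followed by pairwise comparisons using "
            "Dunn's procedure with Bonferroni adjustment",
            _FDR_NOTE,
        ],
    },
    "multi_paired": {
        "methods": [
            ("repeated_anova", "Repeated ANOVA", "parametric"),
            ("friedman", "Friedman test", "nonparametric"),
        ],
        "following": [
            "Parametric test corrected by Greenhouse-Geisser procedure and "
            "followed by Bonferroni post hoc test",
            "Non-parametric test followed by pairwise Wilcoxon signed-rank "
            "tests with Bonferroni correction",
            _FDR_NOTE,
        ],
    },
    "twoway_independent": {
        "methods": [
            ("twoway_anova", "Two-way ANOVA", "parametric"),
            ("twoway_anova_robust", "Two-way ANOVA with robust estimation", "parametric"),
        ],
        "following": [_FACTORIAL_NOTE, _FDR_NOTE],
    },
    "twoway_paired": {
        "methods": [("twoway_rm_anova", "Two-way repeated ANOVA", "parametric")],
        "following": [_FACTORIAL_NOTE, _FDR_NOTE],
    },
    "twoway_mixed": {
        "methods": [("mixed_anova", "Mixed ANOVA", "parametric")],
        "following": [_FACTORIAL_NOTE, _FDR_NOTE],
    },
}


def suggest_methods(design: DesignSpec | str) -> dict:
    """Suggest test methods and follow-up procedures for a study design.

    Returns ``{"methods": [...], "default": key, "following": [...]}``
    where each method entry carries ``key``, ``label`` and ``kind``
    (parametric / nonparametric).  The default is the first parametric
    method (the Welch-family member where available).
    """
    name = design.design if isinstance(design, DesignSpec) else design
    if name not in _METHOD_TABLE:
        raise StatsError(f"unknown design {name!r}")
    row = _METHOD_TABLE[name]
    methods = [
        {"key": k, "label": lbl, "kind": kind} for k, lbl, kind in row["methods"]
    ]
    default = next(m["key"] for m in methods if m["kind"] == "parametric")
    return {"methods": methods, "default": default, "following": list(row["following"])}


# ---------------------------------------------------------------------------
# result container


@dataclass
class TestResult:
    method: str
    statistic: float
    p: float
    df: float | tuple | None = None
    effect: dict = field(default_factory=dict)
    post_hoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# two-group tests


def _clean(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[~np.isnan(a)]


def two_group_test(x, y, method: str = "welch", paired: bool = False) -> TestResult:
    """Two-group comparison (two-sided).

    Paired variants operate on within-subject differences: a one-sample
    t test (or Wilcoxon signed-rank for the rank-based alternative)
    against zero.  The Mann-Whitney test uses the exact null distribution
    when the combined sample size is at most 20 and there are no ties,
    otherwise the normal approximation with tie correction.
    """
    if paired:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if len(x) != len(y):
            raise StatsError("paired test requires equal-length observation vectors")
        ok = ~(np.isnan(x) | np.isnan(y))
        diff = (y - x)[ok]
        if len(diff) < 2:
            raise StatsError("need >= 2 complete pairs")
        if method in ("welch", "student"):
            if np.allclose(diff.std(ddof=1), 0):
                if np.allclose(diff.mean(), 0):
                    return TestResult(method, 0.0, 1.0, len(diff) - 1, {"mean_diff": 0.0})
                warnings.warn("zero-variance differences with nonzero mean; p -> 0")
                return TestResult(method, np.inf, 0.0, len(diff) - 1,
                                  {"mean_diff": float(diff.mean())})
            t, p = sps.ttest_1samp(diff, 0.0)
            return TestResult(method, float(t), float(p), len(diff) - 1,
                              {"mean_diff": float(diff.mean())})
        if method == "mannwhitney":
            if np.allclose(diff, 0):
                return TestResult(method, 0.0, 1.0, None, {"mean_diff": 0.0})
            stat, p = sps.wilcoxon(diff)
            return TestResult(method, float(stat), float(p), None,
                              {"mean_diff": float(np.mean(diff))})
        raise StatsError(f"unknown paired method {method!r}")

    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("need >= 2 observations per group")
    effect = {"mean_diff": float(np.mean(y) - np.mean(x))}
    if np.mean(x) > 0 and np.mean(y) > 0:
        effect["log2FC"] = float(np.log2(np.mean(y) / np.mean(x)))
    if method in ("welch", "student"):
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            if np.mean(x) == np.mean(y):
                return TestResult(method, 0.0, 1.0, len(x) + len(y) - 2, effect)
            warnings.warn("zero variance in both groups with unequal means; p -> 0")
            return TestResult(method, np.inf, 0.0, len(x) + len(y) - 2, effect)
        res = sps.ttest_ind(x, y, equal_var=(method == "student"))
        return TestResult(method, float(res.statistic), float(res.pvalue),
                          float(res.df), effect)
    if method == "mannwhitney":
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        mode = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=mode)
        return TestResult(method, float(res.statistic), float(res.pvalue), None,
                          effect, extra={"mode": mode})
    raise StatsError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# multi-group tests


def _welch_anova_stat(groups):
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    if (v == 0).any():
        raise StatsError("Welch ANOVA requires positive variance in every group")
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    r = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    b = 1 + 2 * (k - 2) / (k ** 2 - 1) * r
    f = a / b
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3 * r)
    return f, df1, df2


def multi_group_test(groups, method: str = "welch_anova") -> TestResult:
    """One-way comparison of three or more independent groups.

    ``welch_anova`` is Welch's heteroscedastic F test; ``anova`` the
    classical one-way ANOVA; ``kruskal`` the Kruskal-Wallis H test with
    tie correction against a chi-square reference.
    """
    groups = [_clean(g) for g in groups]
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise StatsError("need >= 2 observations per group")
    if method == "anova":
        res = sps.f_oneway(*groups)
        k, n = len(groups), sum(len(g) for g in groups)
        return TestResult(method, float(res.statistic), float(res.pvalue), (k - 1, n - k))
    if method == "welch_anova":
        f, df1, df2 = _welch_anova_stat(groups)
        p = sps.f.sf(f, df1, df2)
        return TestResult(method, float(f), float(p), (df1, float(df2)))
    if method == "kruskal":
        res = sps.kruskal(*groups)
        return TestResult(method, float(res.statistic), float(res.pvalue), len(groups) - 1)
    raise StatsError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# repeated measures


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance matrix."""
    k = y.shape[1]
    s = np.cov(y, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    st = c @ s @ c
    eig = np.linalg.eigvalsh(st)
    eig = np.clip(eig, 0, None)
    num = eig.sum() ** 2
    den = (k - 1) * np.sum(eig ** 2)
    if den == 0:
        return 1.0
    return float(min(1.0, num / den))


def repeated_test(blocks, method: str = "repeated_anova") -> TestResult:
    """Within-subject comparison on a complete subject x condition matrix.

    ``repeated_anova`` reports the one-way repeated-measures F with the
    Greenhouse-Geisser epsilon, its sphericity-corrected p-value and the
    uncorrected one; ``friedman`` the rank-based chi-square test.
    """
    y = np.asarray(blocks, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2 or y.shape[0] < 2:
        raise StatsError("need a subjects x conditions matrix, >=2 of each")
    if np.isnan(y).any():
        bad = np.where(np.isnan(y).any(axis=1))[0].tolist()
        raise StatsError(f"incomplete blocks for subject row(s) {bad}")
    n, k = y.shape
    if method == "repeated_anova":
        grand = y.mean()
        ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((y - grand) ** 2)
        ss_err = ss_tot - ss_cond - ss_subj
        df1, df2 = k - 1, (n - 1) * (k - 1)
        ms_err = ss_err / df2
        if ms_err == 0:
            f = 0.0 if ss_cond == 0 else np.inf
            p = 1.0 if ss_cond == 0 else 0.0
            return TestResult(method, f, p, (df1, df2), extra={"epsilon": 1.0, "p_uncorrected": p})
        f = (ss_cond / df1) / ms_err
        eps = 1.0 if k == 2 else _gg_epsilon(y)
        p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
        p_unc = float(sps.f.sf(f, df1, df2))
        return TestResult(method, float(f), p_gg, (eps * df1, eps * df2),
                          extra={"epsilon": eps, "p_uncorrected": p_unc})
    if method == "friedman":
        res = sps.friedmanchisquare(*[y[:, j] for j in range(k)])
        return TestResult(method, float(res.statistic), float(res.pvalue), k - 1)
    raise StatsError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# factorial designs


def _trim_cell(values: np.ndarray, prop: float = 0.2) -> np.ndarray:
    """Symmetric trimming of the lowest/highest ``prop`` fraction."""
    v = np.sort(values)
    g = int(np.floor(prop * len(v)))
    return v[g: len(v) - g] if len(v) - 2 * g >= 1 else v


def factorial_test(
    data: pd.DataFrame,
    dv: str,
    factors: tuple[str, str],
    design: str = "twoway_independent",
    subject: str | None = None,
    robust: bool = False,
    simple_effects_alpha: float = 0.05,
) -> TestResult:
    """Two-way factorial ANOVA with main effects and interaction.

    ``twoway_independent`` uses an OLS fit with Type II sums of squares
    (robust=True first applies 20% symmetric trimming within each cell).
    ``twoway_paired`` and ``twoway_mixed`` delegate to repeated-measures /
    mixed ANOVA.  When the interaction is significant, simple main effects
    of the first factor are tested within each level of the second with
    BH adjustment.
    """
    a, b = factors
    if design == "twoway_independent":
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        d = data[[dv, a, b]].dropna().copy()
        cells = d.groupby([a, b], observed=True)
        levels_a = d[a].unique()
        levels_b = d[b].unique()
        if len(cells) < len(levels_a) * len(levels_b):
            raise StatsError("empty cell in the factorial layout")
        if len(levels_a) < 2 or len(levels_b) < 2:
            raise StatsError("both factors need >= 2 levels")
        if robust:
            parts = [
                g.iloc[np.argsort(g[dv].to_numpy(), kind="stable")].iloc[
                    int(np.floor(0.2 * len(g))): len(g) - int(np.floor(0.2 * len(g)))
                ]
                for _, g in cells
            ]
            d = pd.concat(parts, ignore_index=True)
        d = d.rename(columns={dv: "_y", a: "_a", b: "_b"})
        model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
        table = anova_lm(model, typ=2)
        anova = pd.DataFrame(
            {
                "effect": [a, b, f"{a}:{b}", "residual"],
                "SS": table["sum_sq"].to_numpy(),
                "df": table["df"].to_numpy(),
                "F": table["F"].to_numpy(),
                "p": table["PR(>F)"].to_numpy(),
            }
        )
        inter_p = anova.loc[2, "p"]
        method = "twoway_anova_robust" if robust else "twoway_anova"
    elif design in ("twoway_paired", "twoway_mixed"):
        import pingouin as pg

        if subject is None:
            raise StatsError("paired/mixed factorial designs require subject ids")
        if design == "twoway_paired":
            table = pg.rm_anova(
                data=data, dv=dv, within=[a, b], subject=subject, detailed=True
            )
            eff = table["Source"].tolist()
            anova = pd.DataFrame(
                {
                    "effect": eff,
                    "SS": table["SS"].to_numpy(),
                    "df": table["ddof1"].to_numpy(),
                    "F": table["F"].to_numpy(),
                    "p": table["p-unc"].to_numpy(),
                }
            )
            method = "twoway_rm_anova"
        else:
            table = pg.mixed_anova(
                data=data, dv=dv, within=b, between=a, subject=subject
            )
            anova = pd.DataFrame(
                {
                    "effect": table["Source"].to_numpy(),
                    "SS": table["SS"].to_numpy(),
                    "df": table["DF1"].to_numpy(),
                    "F": table["F"].to_numpy(),
                    "p": table["p-unc"].to_numpy(),
                }
            )
            method = "mixed_anova"
        inter_mask = anova["effect"].astype(str).str.contains(r"\*|Interaction|:")
        inter_p = float(anova.loc[inter_mask, "p"].iloc[0]) if inter_mask.any() else np.nan
    else:
        raise StatsError(f"unknown factorial design {design!r}")

    simple: pd.DataFrame | None = None
    if np.isfinite(inter_p) and inter_p < simple_effects_alpha:
        rows = []
        for lvl in pd.unique(data[b].dropna()):
            sub = data[data[b] == lvl]
            grp = [g[dv].dropna().to_numpy() for _, g in sub.groupby(a, observed=True)]
            grp = [g for g in grp if len(g) >= 2]
            if len(grp) < 2:
                continue
            if len(grp) == 2:
                r = two_group_test(grp[0], grp[1], "welch")
            else:
                r = multi_group_test(grp, "welch_anova")
            rows.append({"within_level": lvl, "effect": a, "statistic": r.statistic, "p": r.p})
        if rows:
            simple = pd.DataFrame(rows)
            simple["p_adj"] = adjust_bh(simple["p"].to_numpy())

    inter_row = anova[anova["effect"].astype(str).str.contains(r"\*|Interaction|:")]
    stat = float(inter_row["F"].iloc[0]) if len(inter_row) else float("nan")
    return TestResult(method, stat, float(inter_p) if np.isfinite(inter_p) else np.nan,
                      None, post_hoc=simple, extra={"anova_table": anova})


# ---------------------------------------------------------------------------
# post hoc procedures


def post_hoc(groups, labels=None, method: str = "games_howell") -> pd.DataFrame:
    """All-pairs follow-up comparisons for >= 3 groups.

    Games-Howell uses per-pair Welch degrees of freedom with the
    studentized-range reference; Tukey assumes equal variances; Dunn
    compares mean ranks with a z reference, tie-corrected, and Bonferroni
    adjustment; ``pairwise_bonferroni`` / ``wilcoxon_bonferroni`` are
    Bonferroni-adjusted pairwise Welch t / signed-rank tests (the latter
    for within-subject conditions, groups given as equal-length vectors).
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 3:
        raise StatsError("post hoc requires >= 3 groups; use two_group_test")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    rows = []

    if method in ("games_howell", "tukey"):
        import pingouin as pg

        clean = [_clean(g) for g in groups]
        df = pd.DataFrame(
            {
                "y": np.concatenate(clean),
                "g": np.concatenate([[labels[i]] * len(g) for i, g in enumerate(clean)]),
            }
        )
        if method == "games_howell":
            t = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        else:
            t = pg.pairwise_tukey(data=df, dv="y", between="g")
        pcol = "pval" if "pval" in t.columns else "p_tukey"
        return pd.DataFrame(
            {
                "group1": t["A"],
                "group2": t["B"],
                "statistic": t["T"].astype(float),
                "p_adj": np.clip(t[pcol].astype(float), 0, 1),
            }
        )

    if method == "dunn_bonferroni":
        clean = [_clean(g) for g in groups]
        pooled = np.concatenate(clean)
        n_tot = len(pooled)
        ranks = sps.rankdata(pooled)
        sizes = [len(g) for g in clean]
        idx = np.cumsum([0] + sizes)
        mean_ranks = [ranks[idx[i]: idx[i + 1]].mean() for i in range(k)]
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (12 * (n_tot - 1))
        var_base = n_tot * (n_tot + 1) / 12 - tie_term
        for i, j in pairs:
            se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * sps.norm.sf(abs(z))
            rows.append((labels[i], labels[j], z, min(1.0, p * m)))
    elif method == "pairwise_bonferroni":
        for i, j in pairs:
            r = two_group_test(groups[i], groups[j], "welch")
            rows.append((labels[i], labels[j], r.statistic, min(1.0, r.p * m)))
    elif method == "wilcoxon_bonferroni":
        if len({len(g) for g in groups}) != 1:
            raise StatsError("wilcoxon_bonferroni expects equal-length condition vectors")
        for i, j in pairs:
            diff = groups[j] - groups[i]
            if np.allclose(diff, 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(groups[i], groups[j])
            rows.append((labels[i], labels[j], float(stat), min(1.0, float(p) * m)))
    else:
        raise StatsError(f"unknown post hoc method {method!r}")
    return pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p_adj"])


# ---------------------------------------------------------------------------
# FDR, bootstrap, power


def adjust_bh(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (pFDR)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_pvalue(x, y, statistic=None, B: int = 1000, seed: int | None = None) -> float:
    """Permutation-style bootstrap p-value for a two-group statistic.

    The group labels are resampled without replacement B times; the
    two-sided p-value is ``(1 + #{|stat*| >= |stat|}) / (B + 1)``.
    """
    if B < 100:
        raise StatsError("B must be >= 100")
    x, y = _clean(x), _clean(y)
    if statistic is None:
        statistic = lambda a, b: np.mean(a) - np.mean(b)  # noqa: E731
    rng = np.random.default_rng(seed)
    obs = abs(statistic(x, y))
    pooled = np.concatenate([x, y])
    n = len(x)
    count = 0
    for _ in range(B):
        perm = rng.permutation(pooled)
        if abs(statistic(perm[:n], perm[n:])) >= obs:
            count += 1
    return (1 + count) / (B + 1)


@dataclass
class PowerSpec:
    """Power-analysis request for the t/F test families.

    ``effect_size`` is Cohen's d for t tests and Cohen's f for ANOVA.
    ``a_priori`` mode solves for the smallest per-group n reaching
    ``power``; ``post_hoc`` mode computes power at the given ``n``.
    """

    mode: str  # a_priori | post_hoc
    family: str = "two_sample_t"  # two_sample_t | paired_t | one_way_anova
    effect_size: float = 0.5
    alpha: float = 0.05
    power: float | None = None
    n: float | None = None
    k_groups: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise StatsError("alpha must be in (0, 1)")
        if self.effect_size < 0:
            raise StatsError("effect size must be >= 0")
        if self.mode not in ("a_priori", "post_hoc"):
            raise StatsError("mode must be a_priori or post_hoc")


def power_analysis(spec: PowerSpec) -> float:
    """Noncentral-distribution power analysis for the supported families."""
    if spec.family == "two_sample_t":
        solver = TTestIndPower()
        kw = {}
    elif spec.family == "paired_t":
        solver = TTestPower()
        kw = {}
    elif spec.family == "one_way_anova":
        solver = FTestAnovaPower()
        kw = {"k_groups": spec.k_groups}
    else:
        raise StatsError(f"unknown test family {spec.family!r}")

    if spec.mode == "post_hoc":
        if spec.n is None:
            raise StatsError("post_hoc power needs n")
        return float(
            solver.power(effect_size=spec.effect_size, nobs=spec.n, alpha=spec.alpha, **kw)
            if spec.family != "two_sample_t"
            else solver.power(effect_size=spec.effect_size, nobs1=spec.n,
                              ratio=1.0, alpha=spec.alpha)
        )
    if spec.power is None:
        raise StatsError("a_priori power needs a target power")
    if spec.effect_size == 0:
        raise StatsError("zero effect size: target power unreachable")
    n = solver.solve_power(
        effect_size=spec.effect_size, alpha=spec.alpha, power=spec.power, **kw
    )
    return int(np.ceil(n - 1e-9))


# ---------------------------------------------------------------------------
# dataset-level driver


def _paired_matrix(d: Dataset, factor: str, subject: str):
    """Pivot biological samples to subject x level intensity blocks."""
    meta = d.sample_meta.loc[d.biological_mask()]
    levels = list(pd.unique(meta[factor].dropna()))
    pivots = {}
    wide_index = None
    for lvl in levels:
        cols = meta.index[meta[factor] == lvl]
        subj = meta.loc[cols, subject]
        if subj.duplicated().any():
            raise StatsError(f"multiple samples per subject at level {lvl!r}")
        sub = d.intensities[cols].T.set_index(subj.to_numpy())
        pivots[lvl] = sub
        wide_index = sub.index if wide_index is None else wide_index.intersection(sub.index)
    return levels, {lvl: pv.loc[wide_index] for lvl, pv in pivots.items()}, wide_index


def test_features(
    d: Dataset,
    design: DesignSpec,
    method: str | None = None,
    fdr: float = 0.05,
    post_hoc_method: str | None = None,
) -> pd.DataFrame:
    """Apply the design's (or an overridden) test to every feature.

    Features are analysed complete-case; p-values are BH-adjusted across
    features.  Features with too few complete observations are reported
    with NA statistics rather than silently dropped.  For multi-group
    designs a long-format post hoc table is attached as
    ``result.attrs["post_hoc"]``.
    """
    suggestion = suggest_methods(design)
    method = method or suggestion["default"]
    meta = d.sample_meta.loc[d.biological_mask()]
    factor = design.factors[0]
    rows = []
    ph_rows = []

    if design.design in ("two_paired", "multi_paired"):
        levels, pivots, subjects = _paired_matrix(d, factor, design.subject)
        if len(subjects) < 2:
            raise StatsError("paired design needs >= 2 complete subject blocks")

    for feat in d.intensities.index:
        row = {"entity_id": feat, "method": method, "statistic": np.nan,
               "df": np.nan, "p": np.nan, "mean_diff": np.nan, "log2FC": np.nan}
        try:
            if design.design == "two_independent":
                lv = list(pd.unique(meta[factor].dropna()))
                if len(lv) != 2:
                    raise StatsError(f"factor {factor!r} must have 2 levels, has {len(lv)}")
                x = d.intensities.loc[feat, meta.index[meta[factor] == lv[0]]]
                y = d.intensities.loc[feat, meta.index[meta[factor] == lv[1]]]
                r = two_group_test(x, y, method)
            elif design.design == "two_paired":
                if len(levels) != 2:
                    raise StatsError(f"factor {factor!r} must have 2 levels, has {len(levels)}")
                x = pivots[levels[0]][feat]
                y = pivots[levels[1]][feat]
                ok = x.notna() & y.notna()
                r = two_group_test(x[ok], y[ok], method, paired=True)
            elif design.design == "multi_independent":
                grp = [
                    d.intensities.loc[feat, meta.index[meta[factor] == lv]].dropna().to_numpy()
                    for lv in pd.unique(meta[factor].dropna())
                ]
                names = list(pd.unique(meta[factor].dropna()))
                r = multi_group_test(grp, method)
                phm = post_hoc_method or (
                    "dunn_bonferroni" if method == "kruskal" else "games_howell"
                )
                try:
                    ph = post_hoc(grp, names, phm)
                    ph.insert(0, "entity_id", feat)
                    ph.insert(1, "procedure", phm)
                    ph_rows.append(ph)
                except StatsError:
                    pass
            elif design.design == "multi_paired":
                block = np.column_stack([pivots[lvl][feat].to_numpy() for lvl in levels])
                block = block[~np.isnan(block).any(axis=1)]
                r = repeated_test(block, method)
                phm = post_hoc_method or (
                    "wilcoxon_bonferroni" if method == "friedman" else "pairwise_bonferroni"
                )
                try:
                    ph = post_hoc([block[:, j] for j in range(block.shape[1])], levels, phm)
                    ph.insert(0, "entity_id", feat)
                    ph.insert(1, "procedure", phm)
                    ph_rows.append(ph)
                except StatsError:
                    pass
            elif design.design.startswith("twoway"):
                a, b = design.factors
                frame = meta[[c for c in {a, b, design.subject} if c in meta.columns]].copy()
                frame["_y"] = d.intensities.loc[feat, meta.index].to_numpy()
                r = factorial_test(
                    frame, "_y", (a, b), design.design,
                    subject=design.subject, robust=(method == "twoway_anova_robust"),
                )
                if r.post_hoc is not None:
                    ph = r.post_hoc.copy()
                    ph.insert(0, "entity_id", feat)
                    ph_rows.append(ph)
            else:  # pragma: no cover - DESIGNS is closed
                raise StatsError(design.design)
        except StatsError as exc:
            row["note"] = str(exc)
            rows.append(row)
            continue
        row.update(
            statistic=r.statistic, p=r.p,
            df=r.df if np.isscalar(r.df) else str(r.df),
            mean_diff=r.effect.get("mean_diff", np.nan),
            log2FC=r.effect.get("log2FC", np.nan),
        )
        rows.append(row)

    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["pFDR"] = np.nan
    if ok.any():
        table.loc[ok, "pFDR"] = adjust_bh(table.loc[ok, "p"].to_numpy())
    table["significant"] = table["pFDR"] < fdr
    table.attrs["post_hoc"] = (
        pd.concat(ph_rows, ignore_index=True) if ph_rows else pd.DataFrame()
    )
    table.attrs["design"] = design.design
    return table
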