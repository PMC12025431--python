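"""Statistical layer for microstate-parameter and behavioral tables.

Covers the comparisons the study design calls for: paired and two-sample
t-tests with Cohen's d, a chi-squared test of group composition, one-way
ANOVA, mixed-design (group x within-class) repeated-measures ANOVA with
Dunn's rank-based post hoc, Bonferroni correction, topographic ANOVA (TANOVA,
a permutation test on global map dissimilarity between group-mean maps), and
ordinary least-squares regression between rates of change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import gmd


class StatsError(ValueError):
    """Raised on degenerate statistical inputs."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float | None = None
    corrected_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise StatsError(f"p value out of range: {self.p}")


@dataclass
class AnovaTable:
    """Mixed-design ANOVA effects: name -> (F, df1, df2, p)."""

    effects: dict[str, tuple[float, int, int, float]]

    def __getitem__(self, name: str) -> tuple[float, int, int, float]:
        return self.effects[name]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise StatsError(f"R^2 out of range: {self.r2}")


GROUPS = ("sham", "sine", "triangular")
STAGES = ("pre", "post")
TASKS = ("two-back", "three-back")


def read_behavior_table(path: str | Path) -> pd.DataFrame:
    """Load and validate the behavioral table.

    Expected columns: participant, group, stage, task, accuracy (fraction),
    rt (ms). (participant, stage, task) rows must be unique.
    """
    sep = "\t" if Path(path).suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"participant", "group", "stage", "task", "accuracy", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise StatsError(f"behavior table missing columns: {sorted(missing)}")
    if not df["group"].isin(GROUPS).all():
        raise StatsError("unknown group name in behavior table")
    if not df["stage"].isin(STAGES).all():
        raise StatsError("unknown stage in behavior table")
    if ((df["accuracy"] < 0) | (df["accuracy"] > 1)).any():
        raise StatsError("accuracy must lie in [0, 1]")
    if (df["rt"] <= 0).any():
        raise StatsError("reaction times must be positive")
    if df.duplicated(["participant", "stage", "task"]).any():
        raise StatsError("duplicate (participant, stage, task) rows")
    return df


# ---------------------------------------------------------------------------
# t-family
# ---------------------------------------------------------------------------

def paired_t(x, y) -> TestResult:
    """Paired t-test with paired Cohen's d = mean(x-y) / sd(x-y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("paired samples must have equal length >= 3")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise StatsError("zero variance of paired differences")
    res = sps.ttest_rel(x, y)
    cohen = float(d.mean() / sd)
    return TestResult(statistic=float(res.statistic), df=float(x.size - 1),
                      p=float(res.pvalue), effect_size=cohen)


def two_sample_t(a, b) -> TestResult:
    """Pooled-variance two-sample t-test with pooled-SD Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs >= 2 observations")
    na, nb = a.size, b.size
    pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / (na + nb - 2))
    if pooled_var == 0:
        raise StatsError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    cohen = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    return TestResult(statistic=float(res.statistic),
                      df=float(na + nb - 2), p=float(res.pvalue),
                      effect_size=cohen)


def chi_squared(table) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise StatsError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise StatsError("zero marginal in contingency table")
    res = sps.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(res.statistic), df=float(res.dof),
                      p=float(res.pvalue))


def one_way_anova(groups) -> TestResult:
    """Classical one-way between-groups ANOVA."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise StatsError(">= 2 groups with >= 2 observations each required")
    if all(g.var(ddof=1) == 0 for g in groups):
        raise StatsError("zero within-group variance")
    res = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(g.size for g in groups) - len(groups)
    return TestResult(statistic=float(res.statistic), df=(df1, df2),
                      p=float(res.pvalue))


# ---------------------------------------------------------------------------
# Mixed-design rmANOVA and post hoc
# ---------------------------------------------------------------------------

def mixed_anova(values: pd.DataFrame, dv: str = "value",
                within: str = "class", subject: str = "participant",
                between: str = "group",
                sphericity_correction: bool = False) -> AnovaTable:
    """Mixed-design ANOVA: between-subject group, within-subject class.

    Requires a balanced within factor (every participant measured on every
    class) and at least two participants per group. No sphericity correction
    by default; pass ``sphericity_correction=True`` for Greenhouse-Geisser.
    """
    import pingouin as pg

    counts = values.groupby([subject])[within].nunique()
    if counts.nunique() != 1:
        raise StatsError("unbalanced within factor: missing cells")
    group_sizes = values.groupby(between)[subject].nunique()
    if (group_sizes < 2).any():
        raise StatsError("singleton group in mixed ANOVA")
    aov = pg.mixed_anova(data=values, dv=dv, within=within, subject=subject,
                         between=between, correction=sphericity_correction)
    effects: dict[str, tuple[float, int, int, float]] = {}
    name_map = {between: "group", within: "class", "Interaction": "interaction"}
    punc = "p_unc" if "p_unc" in aov.columns else "p-unc"
    pgg = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns),
               None)
    for _, row in aov.iterrows():
        name = name_map.get(row["Source"], row["Source"])
        p = row[punc]
        if sphericity_correction and pgg and not pd.isna(row[pgg]):
            p = row[pgg]
        effects[name] = (float(row["F"]), int(row["DF1"]), int(row["DF2"]),
                         float(p))
    return AnovaTable(effects=effects)


def dunn_posthoc(values, groups, adjust: str = "bonferroni"
                 ) -> dict[tuple[str, str], TestResult]:
    """Dunn's rank-based pairwise test with tie-corrected variance.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - sum(t^3 - t)/(12(N-1)))
    * (1/n_i + 1/n_j) ) on pooled mid-ranks; two-sided normal p values,
    optionally Bonferroni-multiplied by the number of pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise StatsError("values/groups length mismatch")
    if np.all(values == values[0]):
        raise StatsError("all values identical")
    ranks = sps.rankdata(values)
    n_total = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    labels = list(dict.fromkeys(groups.tolist()))  # preserve order
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    pairs = list(itertools.combinations(labels, 2))
    out: dict[tuple[str, str], TestResult] = {}
    for g1, g2 in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        corrected = min(1.0, p * len(pairs)) if adjust == "bonferroni" else None
        out[(g1, g2)] = TestResult(statistic=float(z), df=np.inf, p=float(p),
                                   corrected_p=corrected)
    return out


def bonferroni(pvals, m: int | None = None) -> list[float]:
    """Multiply each p by the family size m (default: list length), cap at 1."""
    pvals = list(pvals)
    if m is None:
        m = len(pvals)
    if m < len(pvals):
        raise StatsError("family size m must be >= number of p values")
    return [min(1.0, p * m) for p in pvals]


# ---------------------------------------------------------------------------
# TANOVA
# ---------------------------------------------------------------------------

def tanova(maps_a: np.ndarray, maps_b: np.ndarray, n_perm: int = 500,
           seed: int | np.random.Generator | None = 0) -> TestResult:
    """Topographic ANOVA: permutation test on group-mean map shape.

    The statistic is the polarity-invariant GMD between the GFP-normalized
    mean maps of the two groups; the null distribution reassigns participant
    maps to groups at random (group sizes preserved). The p estimator is
    (1 + #{perm >= observed}) / (1 + n_perm), so identical groups give p = 1
    and p is never exactly 0.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    maps_b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if maps_a.shape[1] != maps_b.shape[1]:
        raise StatsError("channel count mismatch between groups")
    if maps_a.shape[0] < 3 or maps_b.shape[0] < 3:
        raise StatsError(">= 3 participants per group required")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pooled = np.vstack([maps_a, maps_b])
    na = maps_a.shape[0]
    n = pooled.shape[0]
    observed = gmd(maps_a.mean(axis=0), maps_b.mean(axis=0))
    count = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        ga = pooled[perm[:na]].mean(axis=0)
        gb = pooled[perm[na:]].mean(axis=0)
        if gmd(ga, gb) >= observed:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return TestResult(statistic=float(observed), df=float(n_perm), p=float(p))


# ---------------------------------------------------------------------------
# Regression of change rates
# ---------------------------------------------------------------------------

def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the two-sided slope p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError(">= 3 paired points required")
    if np.all(x == x[0]):
        raise StatsError("constant x: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r2=float(res.rvalue**2),
                            p=float(res.pvalue))
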