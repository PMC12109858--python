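"""Assessment analytics: dispersion, correlation, Welch's ANOVA, power.

The module covers the statistical layer of the assessment pipeline:

* per-skill speed/accuracy dispersion (sample variance and SD);
* Pearson correlation between speed and accuracy dispersion, the
  speed-accuracy trade-off statistic;
* Welch's (1951) heteroscedastic one-way ANOVA for response-time
  differences across difficulty levels;
* a-priori power analysis for a two-tailed paired t test via the
  noncentral t distribution;
* Table-style summaries of simulated session logs, and posterior
  calibration metrics against simulated ground truth.

A small packaged CSV (``data/smartick_preassessment.csv``) carries the
published per-skill speed/accuracy dispersion table of the Smartick
pre-assessment, the input from which the trade-off correlations are
reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SkillStats:
    skill_name: str
    speed_variance: float
    speed_sd: float
    accuracy_variance: float
    accuracy_sd: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r plus the regression standard error of estimate.

    ``se`` is the standard error of estimate of the least-squares line
    of y on x, s_y * sqrt((1 - r^2)(n-1)/(n-2)) — a labelled design
    choice, since correlation standard errors can be defined several
    ways.
    """

    r: float
    n: int
    se: float


@dataclass(frozen=True)
class WelchResult:
    F: float
    df1: float
    df2: float
    p_value: float


@dataclass(frozen=True)
class PowerResult:
    N: int
    delta: float
    t_crit: float
    achieved_power: float


def load_preassessment_table() -> pd.DataFrame:
    """The packaged 11-skill pre-assessment dispersion table."""
    with resources.files("edsense.data").joinpath(
            "smartick_preassessment.csv").open() as fh:
        return pd.read_csv(fh)


def per_skill_stats(records: pd.DataFrame) -> list[SkillStats]:
    """Sample variance (n-1 divisor) and SD per skill for the speed and
    accuracy channels.  ``records`` must have columns skill, speed,
    accuracy; skills with fewer than two records are omitted with a
    warning."""
    out: list[SkillStats] = []
    for skill, grp in records.groupby("skill", sort=True):
        if len(grp) < 2:
            warnings.warn(f"skill {skill!r} has < 2 records; omitted")
            continue
        sv = float(grp["speed"].var(ddof=1))
        av = float(grp["accuracy"].var(ddof=1))
        out.append(SkillStats(str(skill), sv, float(np.sqrt(sv)),
                              av, float(np.sqrt(av))))
    return out


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    see = float(np.std(y, ddof=1) * np.sqrt((1 - r * r) * (n - 1) / (n - 2)))
    return CorrelationResult(r, n, see)


def speed_accuracy_correlations(table: pd.DataFrame | None = None,
                                ) -> dict[str, CorrelationResult]:
    """Speed-accuracy trade-off correlations from a dispersion table
    (defaults to the packaged pre-assessment table): Pearson r between
    the speed and accuracy variance columns and between the SD columns."""
    if table is None:
        table = load_preassessment_table()
    return {
        "variance": pearson(table["speed_variance"], table["accuracy_variance"]),
        "sd": pearson(table["speed_sd"], table["accuracy_sd"]),
    }


def welch_anova(groups) -> WelchResult:
    """Welch's heteroscedastic one-way ANOVA.

    With group sizes n_i, means m_i and sample variances s_i^2, the
    weights are w_i = n_i / s_i^2, the weighted grand mean
    m_w = sum(w_i m_i) / sum(w_i), and

        F = [sum(w_i (m_i - m_w)^2) / (k - 1)]
            / [1 + 2(k-2)/(k^2-1) * A],   A = sum((1 - w_i/W)^2 / (n_i - 1))

    with df1 = k-1 and the Satterthwaite-type df2 = (k^2-1) / (3A).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([len(g) for g in groups])
    if (n < 2).any():
        raise ValueError("every group needs at least 2 values")
    s2 = np.array([g.var(ddof=1) for g in groups])
    if (s2 <= 0).any():
        raise ValueError("every group needs positive variance")
    m = np.array([g.mean() for g in groups])
    w = n / s2
    W = w.sum()
    mw = (w * m).sum() / W
    a = (((1 - w / W) ** 2) / (n - 1)).sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    F = num / (1 + 2 * (k - 2) / (k ** 2 - 1) * a)
    df1 = k - 1.0
    df2 = (k ** 2 - 1) / (3 * a)
    p = float(stats.f.sf(F, df1, df2))
    return WelchResult(float(F), df1, float(df2), p)


def _paired_t_power(dz: float, n: int, alpha: float) -> tuple[float, float]:
    df = n - 1
    delta = dz * np.sqrt(n)
    t_crit = float(stats.t.ppf(1 - alpha / 2, df))
    upper = 1 - stats.nct.cdf(t_crit, df, delta)
    lower = stats.nct.cdf(-t_crit, df, delta)   # underflows to nan for huge delta
    power = float(np.nan_to_num(upper) + np.nan_to_num(lower))
    return t_crit, power


def power_paired_t(dz: float, alpha: float = 0.05,
                   target_power: float = 0.95,
                   max_n: int = 1_000_000) -> PowerResult:
    """Smallest N for a two-tailed paired/one-sample t test to reach the
    target power at effect size dz, via the noncentral t distribution
    (noncentrality delta = dz * sqrt(N), df = N - 1)."""
    if dz <= 0:
        raise ValueError("dz must be > 0")
    if not 0 < alpha < 1 or not 0 < target_power < 1:
        raise ValueError("alpha and target_power must lie in (0, 1)")
    for n in range(2, max_n + 1):
        t_crit, power = _paired_t_power(dz, n, alpha)
        if power >= target_power:
            return PowerResult(n, float(dz * np.sqrt(n)), t_crit, power)
    raise ValueError(f"target power not reached by N = {max_n}")


# ---------------------------------------------------------------------------
# session-log analytics
# ---------------------------------------------------------------------------

def _level_of(record: dict, ranks: dict[str, int] | None) -> float:
    if ranks is None:
        return 0.0
    return float(ranks.get(record["skill_id"], 0))


def summarize_sessions(logs, ranks: dict[str, int] | None = None,
                       block: int = 10) -> pd.DataFrame:
    """Per-metric mean/min/max/count table over a collection of session
    logs, mirroring the published sample-dataset summary layout:
    correct / wrong / specific-wrong aggregated per skill level and per
    ``block``-question window, plus special-case occurrences."""
    per_level: dict[str, list[float]] = {"Correct_Answers_Level": [],
                                         "Wrong_Answers_Level": [],
                                         "Specific_Wrong_Level": []}
    per_q: dict[str, list[float]] = {"Correct_Answers_Questions": [],
                                     "Wrong_Answers_Questions": [],
                                     "Specific_Wrong_Questions": []}
    special: list[float] = []
    for log in logs:
        by_skill: dict[str, list[dict]] = {}
        for r in log.records:
            by_skill.setdefault(r["skill_id"], []).append(r)
        for recs in by_skill.values():
            per_level["Correct_Answers_Level"].append(
                sum(r["correct"] for r in recs))
            per_level["Wrong_Answers_Level"].append(
                sum(not r["correct"] for r in recs))
            sw = sum(r["error_case"] not in ("correct", "generic_wrong")
                     for r in recs)
            if sw:
                per_level["Specific_Wrong_Level"].append(sw)
        recs = log.records
        for i in range(0, len(recs), block):
            chunk = recs[i:i + block]
            per_q["Correct_Answers_Questions"].append(
                sum(r["correct"] for r in chunk))
            per_q["Wrong_Answers_Questions"].append(
                sum(not r["correct"] for r in chunk))
            sw = sum(r["error_case"] not in ("correct", "generic_wrong")
                     for r in chunk)
            if sw:
                per_q["Specific_Wrong_Questions"].append(sw)
        cases: dict[str, int] = {}
        for r in recs:
            if r["error_case"] not in ("correct", "generic_wrong"):
                cases[r["error_case"]] = cases.get(r["error_case"], 0) + 1
        special.extend(cases.values())
    rows = []
    for name, vals in {**per_level, **per_q, "Special_Case": special}.items():
        if vals:
            rows.append({"metric": name, "mean": float(np.mean(vals)),
                         "min": float(np.min(vals)), "max": float(np.max(vals)),
                         "count": len(vals)})
        else:
            rows.append({"metric": name, "mean": np.nan, "min": np.nan,
                         "max": np.nan, "count": 0})
    return pd.DataFrame(rows)


def mastery_discrimination(logs) -> dict[str, float]:
    """How well the tracer's posteriors separate true mastery on a
    simulated cohort.

    Pools one (posterior, latent mastery) pair per practice step: the
    posterior after absorbing the step's evidence against the latent
    state that generated the response.  Scoring per step keeps both
    classes represented throughout adaptive sessions, which end with
    everything mastered.  Returns the ranking accuracy (probability a
    randomly chosen mastered-state step outranks an unmastered one,
    i.e. the area under the ROC curve) and the Brier score (mean
    squared error of the posterior as a probability forecast; an
    uninformed 0.5 forecast scores 0.25).
    """
    probs, labels = [], []
    for log in logs:
        for r in log.records:
            if r.get("mastered") is not None:
                probs.append(r["posterior_after"])
                labels.append(bool(r["mastered"]))
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(p) == 0 or y.all() or (~y).all():
        raise ValueError("need both mastered and unmastered observed skills")
    ranks = stats.rankdata(p)
    n1, n0 = int(y.sum()), int((~y).sum())
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    brier = float(np.mean((p - y.astype(float)) ** 2))
    return {"ranking_accuracy": float(auc), "brier": brier,
            "n_pairs": float(len(p))}
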