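"""Biomarker performance evaluation across cervical-neoplasia grades.

Reproduces the evaluation machinery of a cross-sectional methylation-marker
study: Kruskal-Wallis trend across grades, pairwise Mann-Whitney against the
normal group, bootstrap median confidence intervals per grade, and - per
case/control dichotomization scheme - ROC AUC with a DeLong confidence
interval, cutoff selection by Youden's J (or a fixed operating point),
sensitivity/specificity/accuracy with Wilson intervals, and the power of the
two-proportion z-test at the chosen cutoff.

Ties in the AUC count one half; the Mann-Whitney p-value is exact (full
enumeration over labelings) for small samples and a tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError
from .grades import GRADE_ORDER, STANDARD_SCHEMES, DichotomyScheme

EXACT_MW_LIMIT = 8


@dataclass
class EvalConfig:
    """Evaluation parameters.

    ``alpha`` is the two-sided type-1 error used for power and confidence
    intervals; ``significance_p`` is the reporting threshold for trend tests.
    ``positive_rule`` sets whether a value equal to the cutoff counts positive
    (``"ge"``, the default) or not (``"gt"``).
    """

    alpha: float = 0.05
    significance_p: float = 0.01
    bootstrap_reps: int = 2000
    bootstrap_seed: int = 0
    cutoff_criterion: str = "youden"   # or "fixed"
    fixed_cutoff: float | None = None
    positive_rule: str = "ge"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError("alpha: must be in (0, 1)")
        if self.bootstrap_reps < 100:
            raise InputError("bootstrap_reps: must be >= 100")
        if self.cutoff_criterion not in ("youden", "fixed"):
            raise InputError("cutoff_criterion: must be 'youden' or 'fixed'")
        if self.positive_rule not in ("ge", "gt"):
            raise InputError("positive_rule: must be 'ge' or 'gt'")


@dataclass
class RocSummary:
    """Operating characteristics of one dichotomization scheme."""

    scheme: str
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    accuracy: float
    power: float
    n_cases: int
    n_controls: int

    def to_row(self) -> dict:
        d = asdict(self)
        for key in ("auc_ci", "sensitivity_ci", "specificity_ci"):
            lo, hi = d.pop(key)
            d[key + "_lo"], d[key + "_hi"] = lo, hi
        return d


# ---------------------------------------------------------------------------
# nonparametric group comparisons
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H on midranks with tie correction; chi-square p.

    All-identical data yields (H=0, p=1) rather than an error.
    """
    if len(groups) < 2:
        raise InputError("kruskal_wallis: need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise InputError("kruskal_wallis: empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for sample ``a`` with ties counted one half."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _mw_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of C(m+n, m) labelings.

    The two-sided tail is P(|U - mn/2| >= |U_obs - mn/2|); valid under ties.
    """
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    center = m * n / 2.0
    obs = abs(_mann_whitney_u(a, b) - center)
    idx = set(range(m + n))
    hits = 0
    total = 0
    for comb in combinations(range(m + n), m):
        sel = np.fromiter(comb, dtype=int)
        rest = np.fromiter(sorted(idx - set(comb)), dtype=int)
        u = _mann_whitney_u(pooled[sel], pooled[rest])
        if abs(u - center) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact enumeration when both samples have at most 8 observations (correct
    under ties); otherwise scipy's tie- and continuity-corrected normal
    approximation. Returns ``(U, p)`` with U computed for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("mann_whitney: both samples must be non-empty")
    u = _mann_whitney_u(a, b)
    if a.size <= EXACT_MW_LIMIT and b.size <= EXACT_MW_LIMIT:
        return u, _mw_exact_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return u, float(res.pvalue)


def median_ci(values, reps: int = 2000, seed: int = 0,
              level: float = 0.95) -> tuple[float, tuple[float, float] | None]:
    """Sample median with a seeded percentile-bootstrap confidence interval.

    Fewer than 3 values: returns the point estimate with CI ``None``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InputError("median_ci: empty input")
    med = float(np.median(x))
    if x.size < 3:
        return med, None
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, x.size, size=(reps, x.size))
    boots = np.median(x[idx], axis=1)
    lo, hi = np.quantile(boots, [(1 - level) / 2, 1 - (1 - level) / 2])
    return med, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

def dichotomize(results: pd.DataFrame, scheme: DichotomyScheme
                ) -> tuple[np.ndarray, np.ndarray]:
    """Split valid M-index results into values and binary case labels.

    Returns ``(values, labels)`` with label 1 for case grades. Grades outside
    the five canonical categories are an error.
    """
    bad = set(results["grade"].astype(str)) - set(GRADE_ORDER)
    if bad:
        raise InputError(f"grades outside the known categories: {sorted(bad)}")
    if "valid" in results.columns and not results["valid"].all():
        raise InputError("dichotomize expects only valid results; "
                         "filter detection failures first")
    values = results["m_index"].to_numpy(dtype=float)
    labels = results["grade"].astype(str).isin(scheme.case_grades).to_numpy()
    return values, labels.astype(int)


def auc_with_ci(values, labels, alpha: float = 0.05
                ) -> tuple[float, tuple[float, float]]:
    """AUC by the Mann-Whitney identity (ties one half) with a DeLong CI.

    The interval is truncated to [0, 1].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = values[labels == 1]
    controls = values[labels == 0]
    n1, n0 = cases.size, controls.size
    if n1 == 0 or n0 == 0:
        raise InputError("auc_with_ci: need at least one case and one control")
    cmp = (cases[:, None] > controls[None, :]).astype(float)
    cmp += 0.5 * (cases[:, None] == controls[None, :])
    auc = float(cmp.mean())
    # DeLong placements
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    var = 0.0
    if n1 > 1:
        var += float(np.var(v10, ddof=1)) / n1
    if n0 > 1:
        var += float(np.var(v01, ddof=1)) / n0
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def _confusion(values, labels, cutoff, positive_rule):
    pos = values >= cutoff if positive_rule == "ge" else values > cutoff
    tp = int(np.sum(pos & (labels == 1)))
    tn = int(np.sum(~pos & (labels == 0)))
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    return tp, tn, n1, n0


def select_cutoff(values, labels, cfg: EvalConfig | None = None) -> float:
    """Choose an M-index cutoff.

    Criterion ``youden`` maximizes sensitivity + specificity - 1 over the
    observed values (ties broken toward higher specificity, then the larger
    cutoff, making the choice deterministic); ``fixed`` passes
    ``cfg.fixed_cutoff`` through.
    """
    cfg = cfg or EvalConfig()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise InputError("select_cutoff: both arms must be non-empty")
    if cfg.cutoff_criterion == "fixed":
        if cfg.fixed_cutoff is None:
            raise InputError("fixed cutoff criterion requires fixed_cutoff")
        return float(cfg.fixed_cutoff)
    best = None
    for c in np.unique(values):
        tp, tn, n1, n0 = _confusion(values, labels, c, cfg.positive_rule)
        sens, spec = tp / n1, tn / n0
        key = (sens + spec - 1.0, spec, c)
        if best is None or key > best:
            best = key
    return float(best[2])


def diagnostics_at_cutoff(values, labels, cutoff: float,
                          cfg: EvalConfig | None = None) -> dict:
    """Sensitivity, specificity and accuracy at a cutoff with Wilson CIs."""
    cfg = cfg or EvalConfig()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise InputError("diagnostics_at_cutoff: both arms must be non-empty")
    tp, tn, n1, n0 = _confusion(values, labels, cutoff, cfg.positive_rule)
    sens_ci = proportion_confint(tp, n1, alpha=cfg.alpha, method="wilson")
    spec_ci = proportion_confint(tn, n0, alpha=cfg.alpha, method="wilson")
    return {
        "cutoff": float(cutoff),
        "sensitivity": tp / n1,
        "sensitivity_ci": (float(sens_ci[0]), float(sens_ci[1])),
        "specificity": tn / n0,
        "specificity_ci": (float(spec_ci[0]), float(spec_ci[1])),
        "accuracy": (tp + tn) / (n1 + n0),
        "n_cases": n1,
        "n_controls": n0,
    }


def power_at_cutoff(values, labels, cutoff: float, alpha: float = 0.05,
                    positive_rule: str = "ge") -> float:
    """Power of the two-sided two-proportion z-test at the observed rates.

    The test compares positivity rates above the cutoff in cases vs controls
    at the observed arm sizes (pooled-variance null, unpooled alternative,
    normal approximation). Degenerate equal-extreme rates (both 0 or both 1)
    give NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise InputError("power_at_cutoff: both arms must be non-empty")
    tp, tn, n1, n0 = _confusion(values, labels, cutoff, positive_rule)
    p1 = tp / n1
    p0 = 1 - tn / n0
    delta = abs(p1 - p0)
    pbar = (tp + (n0 - tn)) / (n1 + n0)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z = stats.norm.ppf(1 - alpha / 2)
    if se1 == 0.0:
        if delta > 0:
            return 1.0
        return float("nan")
    if se0 == 0.0:
        return 1.0 if delta > 0 else float("nan")
    power = stats.norm.cdf((delta - z * se0) / se1) + stats.norm.cdf(
        (-delta - z * se0) / se1
    )
    return float(power)


# ---------------------------------------------------------------------------
# top-level evaluation
# ---------------------------------------------------------------------------

def evaluate_marker(
    results: pd.DataFrame,
    schemes: tuple[DichotomyScheme, ...] = STANDARD_SCHEMES,
    cfg: EvalConfig | None = None,
) -> dict:
    """Full evaluation of one marker over a cohort of valid QMSP results.

    Runs the grade-trend tests (Kruskal-Wallis across grades, pairwise
    Mann-Whitney against Normal), per-grade median CIs, and for each
    dichotomization scheme the ROC AUC with CI, cutoff selection, operating
    characteristics and power. Detection failures must be filtered out first;
    at least two grades must be present.
    """
    cfg = cfg or EvalConfig()
    valid = results[results["valid"]] if "valid" in results.columns else results
    grades_present = [g for g in GRADE_ORDER
                      if (valid["grade"].astype(str) == g).any()]
    if len(grades_present) < 2:
        raise InputError("evaluate_marker: need at least 2 grades present")

    by_grade = {g: valid.loc[valid["grade"].astype(str) == g, "m_index"]
                  .to_numpy(dtype=float)
                for g in grades_present}
    h, kw_p = kruskal_wallis(list(by_grade.values()))

    pairwise_rows = []
    if "Normal" in by_grade:
        for g in grades_present:
            if g == "Normal":
                continue
            u, p = mann_whitney(by_grade[g], by_grade["Normal"])
            pairwise_rows.append({"grade": g, "vs": "Normal", "U": u, "p_value": p,
                                  "significant": p < cfg.significance_p})
    pairwise = pd.DataFrame(pairwise_rows)

    grade_rows = []
    for g in grades_present:
        med, ci = median_ci(by_grade[g], reps=cfg.bootstrap_reps,
                            seed=cfg.bootstrap_seed, level=1 - cfg.alpha)
        grade_rows.append({
            "grade": g, "n": by_grade[g].size, "median": med,
            "ci_lo": ci[0] if ci else float("nan"),
            "ci_hi": ci[1] if ci else float("nan"),
            "ci_defined": ci is not None,
        })
    grade_summary = pd.DataFrame(grade_rows)

    summaries = []
    for scheme in schemes:
        vals, labels = dichotomize(valid, scheme)
        if not ((labels == 1).any() and (labels == 0).any()):
            continue
        auc, auc_ci = auc_with_ci(vals, labels, alpha=cfg.alpha)
        cutoff = select_cutoff(vals, labels, cfg)
        diag = diagnostics_at_cutoff(vals, labels, cutoff, cfg)
        pw = power_at_cutoff(vals, labels, cutoff, cfg.alpha, cfg.positive_rule)
        summaries.append(RocSummary(
            scheme=scheme.name, auc=auc, auc_ci=auc_ci, cutoff=cutoff,
            sensitivity=diag["sensitivity"], sensitivity_ci=diag["sensitivity_ci"],
            specificity=diag["specificity"], specificity_ci=diag["specificity_ci"],
            accuracy=diag["accuracy"], power=pw,
            n_cases=diag["n_cases"], n_controls=diag["n_controls"],
        ))
    scheme_table = pd.DataFrame([s.to_row() for s in summaries])
    return {
        "kruskal_h": h,
        "kruskal_p": kw_p,
        "pairwise": pairwise,
        "grade_summary": grade_summary,
        "schemes": summaries,
        "scheme_table": scheme_table,
        "config": asdict(cfg),
    }
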