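"""Case-control statistics for bifurcation morphometry.

Mirrors the analysis pattern of a morphometric case-control study:

* group comparisons gated on normality — Shapiro-Wilk per group, then
  one-way ANOVA with a Tukey-Kramer post-hoc for unequal sample sizes when
  every group looks normal, otherwise Kruskal-Wallis with Dunn's multiple
  comparisons (Bonferroni-adjusted);
* tertile coding of continuous predictors (empirical 33.33/66.67th
  percentiles, linear interpolation, boundary ties to the lower tertile);
* univariate and forward-stepwise multivariate binary logistic regression
  for aneurysm presence, reported as odds ratios with Wald 95% CIs;
* ROC analysis with the Youden index picking the optimal cut-off.

All functions take a *cohort frame* — a pandas DataFrame in the morphometry
table dialect (one row per bifurcation, ``aneurysm`` 0/1 outcome column,
undefined values as NaN) — and exclude undefined values pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .geometry import ValidationError
from .pmw import BifurcationMorphometry

ALPHA_LEVEL = 0.05  # significance level used throughout


class InsufficientDataError(ValueError):
    """Too few records (or too little variation) to run a test."""


@dataclass(frozen=True)
class CohortRecord:
    """One bifurcation of one subject, with group/site labels and outcome."""

    subject_id: str
    site: str
    group: str
    aneurysm: int
    morphometry: BifurcationMorphometry

    def __post_init__(self) -> None:
        if self.aneurysm not in (0, 1):
            raise ValidationError(f"aneurysm flag must be 0/1, got {self.aneurysm}")


def cohort_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Flatten cohort records into the morphometry table (NaN = undefined)."""
    rows = []
    for rec in records:
        m = rec.morphometry
        nan = float("nan")
        rows.append({
            "subject_id": rec.subject_id,
            "site": rec.site,
            "group": rec.group,
            "aneurysm": rec.aneurysm,
            "r0_mm": m.radii.r0,
            "r1_mm": m.radii.r1,
            "r2_mm": m.radii.r2,
            "alpha_deg": m.observed.alpha_deg,
            "phi1_obs_deg": m.observed.phi1_obs_deg,
            "phi2_obs_deg": m.observed.phi2_obs_deg,
            "asymmetry_ratio": m.indices.asymmetry_ratio,
            "area_ratio": m.indices.area_ratio,
            "junction_exponent": (
                m.indices.junction_exponent
                if m.indices.junction_exponent is not None else nan),
            "phi1_opt_deg": m.indices.phi1_opt_deg if m.indices.phi1_opt_deg is not None else nan,
            "phi2_opt_deg": m.indices.phi2_opt_deg if m.indices.phi2_opt_deg is not None else nan,
            "total_opt_deg": m.indices.total_opt_deg if m.indices.total_opt_deg is not None else nan,
            "dev_total_deg": m.devs.dev_total_deg if m.devs.dev_total_deg is not None else nan,
            "dev_phi1_deg": m.devs.dev_phi1_deg if m.devs.dev_phi1_deg is not None else nan,
            "dev_phi2_deg": m.devs.dev_phi2_deg if m.devs.dev_phi2_deg is not None else nan,
            "domain_status": m.indices.domain_status.value,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    group_stats: dict  # group -> (n, mean, sd)
    test_used: str  # "anova_tukey" | "kruskal_wallis_mc"
    omnibus_p: float
    posthoc: list = field(default_factory=list)  # [((g1, g2), p), ...]


def _dunn_posthoc(samples: dict[str, np.ndarray]) -> list:
    """Dunn's rank-based multiple comparisons with Bonferroni adjustment."""
    groups = list(samples)
    pooled = np.concatenate([samples[g] for g in groups])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    i = 0
    for g in groups:
        n = len(samples[g])
        mean_ranks[g] = ranks[i:i + n].mean()
        sizes[g] = n
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            g1, g2 = groups[a], groups[b]
            se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            z = (mean_ranks[g1] - mean_ranks[g2]) / se
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
            out.append(((g1, g2), float(p)))
    return out


def _tukey_posthoc(samples: dict[str, np.ndarray]) -> list:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(samples.values()))
    labels = np.concatenate([[g] * len(v) for g, v in samples.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=ALPHA_LEVEL)
    pairs = [(row[0], row[1]) for row in res.summary().data[1:]]
    return [((g1, g2), float(p)) for (g1, g2), p in zip(pairs, res.pvalues)]


def compare_groups(
    frame: pd.DataFrame, parameter: str, grouping: str = "group"
) -> GroupComparison:
    """Omnibus comparison of ``parameter`` across levels of ``grouping``.

    Undefined (NaN) values are excluded per group.  Every group must retain
    at least 3 defined values.  The parametric path (ANOVA + Tukey-Kramer)
    is taken only when every group passes Shapiro-Wilk at p >= 0.05;
    otherwise Kruskal-Wallis with Dunn's Bonferroni post-hoc.  Post-hoc
    p-values are reported only when the omnibus test is significant.
    """
    samples: dict[str, np.ndarray] = {}
    for g, sub in frame.groupby(grouping, sort=True):
        vals = sub[parameter].dropna().to_numpy(dtype=float)
        if len(vals) < 3:
            raise InsufficientDataError(
                f"group {g!r} has only {len(vals)} defined values for {parameter!r}"
            )
        samples[str(g)] = vals
    if len(samples) < 2:
        raise InsufficientDataError(f"need >= 2 groups, got {len(samples)}")

    all_normal = all(
        sps.shapiro(v).pvalue >= ALPHA_LEVEL for v in samples.values()
    )
    if all_normal:
        stat, p = sps.f_oneway(*samples.values())
        test_used = "anova_tukey"
        posthoc = _tukey_posthoc(samples) if p < ALPHA_LEVEL else []
    else:
        stat, p = sps.kruskal(*samples.values())
        test_used = "kruskal_wallis_mc"
        posthoc = _dunn_posthoc(samples) if p < ALPHA_LEVEL else []
    group_stats = {
        g: (len(v), float(np.mean(v)), float(np.std(v, ddof=1)))
        for g, v in samples.items()
    }
    return GroupComparison(
        parameter=parameter,
        group_stats=group_stats,
        test_used=test_used,
        omnibus_p=float(p),
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# tertiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TertileSpec:
    """Empirical tertile boundaries and observed per-tertile value ranges."""

    lower_boundary: float
    upper_boundary: float
    ranges: tuple  # ((min1, max1), (min2, max2), (min3, max3))


def tertile_split(values: Sequence[float]) -> tuple[TertileSpec, np.ndarray]:
    """Split values into tertiles at the 33.33rd/66.67th percentiles.

    Percentiles use linear interpolation between order statistics; a value
    tied with a boundary goes to the lower tertile.  Returns the spec and an
    integer array of assignments in {1, 2, 3}.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(np.unique(vals)) < 3:
        raise InsufficientDataError("need >= 3 distinct defined values for tertiles")
    srt = np.sort(vals)

    def percentile(q: float) -> float:
        # linear interpolation between order statistics; when the virtual
        # index is (numerically) integral take the order statistic itself,
        # so a data value exactly on the boundary resolves downward
        h = (len(srt) - 1) * q
        i, frac = int(math.floor(h)), h - math.floor(h)
        if frac < 1e-9:
            return float(srt[i])
        if frac > 1.0 - 1e-9:
            return float(srt[i + 1])
        return float(srt[i] + frac * (srt[i + 1] - srt[i]))

    lo, hi = percentile(1.0 / 3.0), percentile(2.0 / 3.0)
    if not lo < hi:
        raise InsufficientDataError(
            f"degenerate tertile boundaries ({lo}, {hi}): distribution too discrete"
        )
    assign = np.where(vals <= lo, 1, np.where(vals <= hi, 2, 3))
    ranges = tuple(
        (float(vals[assign == t].min()), float(vals[assign == t].max()))
        if np.any(assign == t) else (math.nan, math.nan)
        for t in (1, 2, 3)
    )
    return TertileSpec(float(lo), float(hi), ranges), assign


def _tertile_assign(values: np.ndarray, spec: TertileSpec) -> np.ndarray:
    return np.where(values <= spec.lower_boundary, 1,
                    np.where(values <= spec.upper_boundary, 2, 3))


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrRow:
    """One odds-ratio row of a logistic model report."""

    predictor: str
    level: str  # "continuous" | "2nd tertile" | "3rd tertile"
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separation: bool = False


@dataclass(frozen=True)
class UnivariateResult:
    predictor: str
    coding: str
    rows: list  # list[OrRow]
    tertiles: Optional[TertileSpec]
    n: int
    min_p: float


def _safe_exp(v: float) -> float:
    with np.errstate(over="ignore"):
        return float(np.exp(v))


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Maximum-likelihood logistic fit; flags quasi/perfect separation."""
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        # huge coefficients with huge SEs mean the MLE ran away
        if np.any(np.abs(res.params.to_numpy()[1:]) > 15):
            separation = True
    except Exception:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit_regularized(alpha=1e-8, disp=0, maxiter=500)
        separation = True
    return res, separation


def _design_for(frame: pd.DataFrame, predictor: str, coding: str,
                tertiles: Optional[TertileSpec] = None
                ) -> tuple[pd.DataFrame, Optional[TertileSpec], list]:
    """Design columns for one predictor; tertile coding uses T1 as reference."""
    x = frame[predictor].to_numpy(dtype=float)
    if coding == "continuous":
        return pd.DataFrame({predictor: x}, index=frame.index), None, [
            (predictor, "continuous")]
    if coding != "tertile":
        raise ValueError(f"unknown coding {coding!r}")
    if tertiles is None:
        tertiles, _ = tertile_split(x)
    assign = _tertile_assign(x, tertiles)
    X = pd.DataFrame({
        f"{predictor}_T2": (assign == 2).astype(float),
        f"{predictor}_T3": (assign == 3).astype(float),
    }, index=frame.index)
    labels = [(f"{predictor}_T2", "2nd tertile"), (f"{predictor}_T3", "3rd tertile")]
    return X, tertiles, labels


def univariate_logistic(
    frame: pd.DataFrame, predictor: str, coding: str = "continuous"
) -> UnivariateResult:
    """Univariate logistic regression of the aneurysm flag on one predictor.

    Continuous coding yields one OR row (odds ratio per unit); tertile
    coding yields two rows (2nd and 3rd tertile vs the 1st as reference).
    """
    data = frame[[predictor, "aneurysm"]].dropna()
    y = data["aneurysm"].to_numpy(dtype=int)
    for cls in (0, 1):
        if int(np.sum(y == cls)) < 10:
            raise InsufficientDataError(
                f"predictor {predictor!r}: outcome class {cls} has "
                f"{int(np.sum(y == cls))} defined records (< 10)"
            )
    if data[predictor].nunique() < 2:
        raise InsufficientDataError(f"predictor {predictor!r} has no variation")
    X, tert, labels = _design_for(data, predictor, coding)
    res, separation = _fit_logit(y, X)
    ci = res.conf_int(alpha=0.05)
    rows = []
    for col, level in labels:
        rows.append(OrRow(
            predictor=predictor,
            level=level,
            odds_ratio=_safe_exp(res.params[col]),
            ci_low=_safe_exp(ci.loc[col, 0]),
            ci_high=_safe_exp(ci.loc[col, 1]),
            p_value=float(res.pvalues[col]),
            separation=separation,
        ))
    return UnivariateResult(
        predictor=predictor, coding=coding, rows=rows, tertiles=tert,
        n=len(data), min_p=float(min(r.p_value for r in rows)),
    )


@dataclass(frozen=True)
class MultivariateResult:
    rows: list  # list[OrRow] for every term of the final model
    included: list  # predictors in order of stepwise entry
    excluded_correlated: list  # (dropped, kept, |r|)
    excluded_entry_p: list  # (predictor, univariate min p)
    n: int


def multivariate_logistic(
    frame: pd.DataFrame,
    candidates: Sequence[tuple[str, str]],
    entry_p: float = 0.1,
    correlation_exclusion_r: float = 0.7,
) -> MultivariateResult:
    """Forward-stepwise multivariate logistic model for aneurysm presence.

    ``candidates`` is a list of ``(predictor, coding)`` pairs.  Candidates
    whose univariate min p-value fails ``entry_p`` are dropped; among pairs
    of candidates with absolute Pearson correlation above
    ``correlation_exclusion_r`` only the one with the smaller univariate p
    is kept.  Remaining candidates enter by stepwise addition (smallest
    likelihood-ratio p first, while below ``entry_p``).
    """
    uni = {p: univariate_logistic(frame, p, coding) for p, coding in candidates}
    kept = [p for p, _ in candidates if uni[p].min_p < entry_p]
    excluded_entry = [(p, uni[p].min_p) for p, _ in candidates if p not in kept]

    # correlation exclusion on the raw (continuous) predictor values
    excluded_corr = []
    surviving = list(kept)
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i], kept[j]
            if a not in surviving or b not in surviving:
                continue
            sub = frame[[a, b]].dropna()
            if len(sub) < 3:
                continue
            r = abs(float(sub[a].corr(sub[b])))
            if r > correlation_exclusion_r:
                drop = a if uni[a].min_p > uni[b].min_p else b
                keep = b if drop == a else a
                surviving.remove(drop)
                excluded_corr.append((drop, keep, r))
    if not surviving:
        raise InsufficientDataError("no candidates survive entry-p/correlation filters")

    coding_of = dict(candidates)
    cols = ["aneurysm"] + surviving
    data = frame[cols].dropna()
    y = data["aneurysm"].to_numpy(dtype=int)

    designs, labels_of = {}, {}
    for p in surviving:
        X, tert, labels = _design_for(data, p, coding_of[p],
                                      tertiles=uni[p].tertiles)
        designs[p] = X
        labels_of[p] = labels

    def fit(preds: list):
        if not preds:
            return None, False
        X = pd.concat([designs[p] for p in preds], axis=1)
        return _fit_logit(y, X)

    # forward stepwise addition by likelihood-ratio p-value
    included: list = []
    current_llf = None
    while True:
        best = None
        res_now, _ = fit(included) if included else (None, False)
        llf_now = res_now.llf if res_now is not None else None
        if llf_now is None:
            # null model log-likelihood
            llf_now = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
        for p in surviving:
            if p in included:
                continue
            res_try, _ = fit(included + [p])
            df = designs[p].shape[1]
            lr = 2.0 * (res_try.llf - llf_now)
            p_lr = float(sps.chi2.sf(max(lr, 0.0), df))
            if best is None or p_lr < best[1]:
                best = (p, p_lr)
        if best is None or best[1] >= entry_p:
            break
        included.append(best[0])
    if not included:
        raise InsufficientDataError("stepwise addition admitted no predictor")

    res, separation = fit(included)
    ci = res.conf_int(alpha=0.05)
    rows = []
    for p in included:
        for col, level in labels_of[p]:
            rows.append(OrRow(
                predictor=p, level=level,
                odds_ratio=_safe_exp(res.params[col]),
                ci_low=_safe_exp(ci.loc[col, 0]),
                ci_high=_safe_exp(ci.loc[col, 1]),
                p_value=float(res.pvalues[col]),
                separation=separation,
            ))
    return MultivariateResult(
        rows=rows, included=included,
        excluded_correlated=excluded_corr, excluded_entry_p=excluded_entry,
        n=len(data),
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    predictor: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    n_cases: int
    n_controls: int


def roc_analysis(frame: pd.DataFrame, predictor: str) -> RocResult:
    """ROC curve for one predictor with the Youden-optimal cut-off.

    The AUC is the tie-corrected rank (Mann-Whitney) statistic, identical to
    the trapezoidal area under the empirical ROC curve.  Candidate cut-offs
    are midpoints between consecutive sorted unique values; a record is
    called positive when the predictor value is >= the cut-off.  The
    reported cut-off maximises Youden's J = sensitivity + specificity - 1,
    ties resolved towards the lowest cut-off.
    """
    data = frame[[predictor, "aneurysm"]].dropna()
    x = data[predictor].to_numpy(dtype=float)
    y = data["aneurysm"].to_numpy(dtype=int)
    cases, controls = x[y == 1], x[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise InsufficientDataError("ROC needs both outcome classes non-empty")

    ranks = sps.rankdata(x)
    auc = (ranks[y == 1].sum() - len(cases) * (len(cases) + 1) / 2.0) / (
        len(cases) * len(controls))

    uniq = np.unique(x)
    cutoffs = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq
    best = None
    for c in cutoffs:
        sens = float(np.mean(cases >= c))
        spec = float(np.mean(controls < c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    j, cutoff, sens, spec = best
    return RocResult(
        predictor=predictor, auc=float(auc), cutoff=cutoff,
        sensitivity=sens, specificity=spec, youden_j=j,
        n_cases=len(cases), n_controls=len(controls),
    )
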