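"""Longitudinal statistics for within-sample culture time courses.

Implements the full battery used on repeated-measures count/PI data:
Shapiro-Wilk normality screening, one-way repeated-measures ANOVA with
Mauchly's sphericity test and Greenhouse-Geisser / Huynh-Feldt epsilons,
post hoc paired comparisons (Bonferroni-adjusted paired t or Tukey HSD)
with Cohen's dz, and the Friedman rank test as a non-parametric
sensitivity analysis.

The ANOVA is computed from first principles (sums-of-squares
decomposition) rather than delegated, so it can be validated against an
independent brute-force oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from evocquant.errors import DegenerateDataError, ValidationError

POSTHOC_METHODS = ("bonferroni_paired_t", "tukey_hsd")


@dataclass(frozen=True)
class RepeatedMeasuresMatrix:
    """Complete n-subjects x k-timepoints outcome matrix."""

    subjects: tuple[str, ...]
    timepoints: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n, k = len(self.subjects), len(self.timepoints)
        if v.shape != (n, k):
            raise ValidationError(
                f"values shape {v.shape} does not match {n} subjects x "
                f"{k} timepoints")
        if n < 2 or k < 2:
            raise ValidationError("need n >= 2 subjects and k >= 2 timepoints")
        if not np.all(np.isfinite(v)):
            raise ValidationError("matrix must be complete (no missing cells)")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def k(self) -> int:
        return len(self.timepoints)


@dataclass(frozen=True)
class RmAnovaResult:
    f_stat: float
    df_time: float
    df_error: float
    ss_time: float
    ss_subject: float
    ss_error: float
    epsilon_gg: float
    epsilon_hf: float
    mauchly_w: float
    mauchly_p: float
    p_uncorrected: float
    p_corrected: float
    eta_p2: float
    correction_applied: bool
    df_time_corrected: float
    df_error_corrected: float
    degenerate: bool = False

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error


@dataclass(frozen=True)
class PairwiseResult:
    day_a: int
    day_b: int
    mean_diff: float
    ci95: tuple[float, float]
    p_raw: float
    p_adjusted: float
    method: str
    cohen_dz: float | None
    flags: tuple[str, ...] = ()


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one outcome at one time point."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValidationError("Shapiro-Wilk needs at least 3 observations")
    if x.size > 5000:
        raise ValidationError("Shapiro-Wilk supports at most 5000 observations")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample: W undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = values.shape[1]
    s = np.cov(values, rowvar=False, ddof=1)
    c = np.eye(k) - np.ones((k, k)) / k
    st = c @ s @ c
    denom = (k - 1) * np.sum(st * st)
    if denom <= 0:
        return 1.0
    return float(np.trace(st) ** 2 / denom)


def _hf_epsilon(eps_gg: float, n: int, k: int) -> float:
    num = n * (k - 1) * eps_gg - 2.0
    den = (k - 1) * (n - 1 - (k - 1) * eps_gg)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def _mauchly(values: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity W with the chi-square approximation."""
    n, k = values.shape
    if k == 2:
        return 1.0, 1.0  # a single difference variance: sphericity trivial
    # Orthonormal contrasts spanning the space orthogonal to the unit vector.
    helmert = np.linalg.qr(
        np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))[0][:, 1:]
    y = values @ helmert
    s = np.cov(y, rowvar=False, ddof=1)
    d = k - 1
    det = np.linalg.det(s)
    tr = np.trace(s)
    if tr <= 0 or det <= 0:
        return 0.0, 0.0 if det <= 0 else 1.0
    w = det / (tr / d) ** d
    w = float(min(w, 1.0))
    # chi-square approximation with the second-order term used by ezANOVA
    f_corr = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * math.log(max(w, 1e-300))
    df = d * (d + 1) // 2 - 1
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f_corr) ** 2))
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(min(max(p1 + w2 * (p2 - p1), 0.0), 1.0))
    return w, p


def rm_anova(data: RepeatedMeasuresMatrix,
             sphericity_alpha: float = 0.05) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with sphericity handling.

    Sums of squares are decomposed into time, subject and error
    (subject x time) components; ``F = MS_time / MS_error`` on
    ``(k-1), (n-1)(k-1)`` degrees of freedom.  When Mauchly's test
    rejects sphericity at ``sphericity_alpha``, the corrected p-value
    uses Huynh-Feldt scaled degrees of freedom; otherwise the
    uncorrected p is reported as corrected.  Effect size is partial
    eta-squared, ``SS_time / (SS_time + SS_error)``.
    """
    v = data.values
    n, k = data.n, data.k
    grand = v.mean()
    col_means = v.mean(axis=0)
    row_means = v.mean(axis=1)
    ss_time = n * float(np.sum((col_means - grand) ** 2))
    ss_subject = k * float(np.sum((row_means - grand) ** 2))
    ss_total = float(np.sum((v - grand) ** 2))
    ss_error = ss_total - ss_time - ss_subject
    ss_error = max(ss_error, 0.0)

    df_time = float(k - 1)
    df_error = float((n - 1) * (k - 1))
    eps_gg = min(1.0, max(_gg_epsilon(v), 1.0 / (k - 1)))
    eps_hf = max(_hf_epsilon(eps_gg, n, k), eps_gg)
    mauchly_w, mauchly_p = _mauchly(v)

    degenerate = ss_error <= 1e-12 * max(ss_total, 1.0)
    if degenerate:
        if ss_time <= 1e-12 * max(ss_total, 1.0):
            f = 0.0
            p_unc = 1.0
        else:
            f = math.inf
            p_unc = 0.0
        eta = 0.0 if ss_time + ss_error == 0 else ss_time / (ss_time + ss_error)
    else:
        f = (ss_time / df_time) / (ss_error / df_error)
        p_unc = float(sps.f.sf(f, df_time, df_error))
        eta = ss_time / (ss_time + ss_error)

    apply_corr = mauchly_p < sphericity_alpha and k > 2
    df_t_c = df_time * eps_hf if apply_corr else df_time
    df_e_c = df_error * eps_hf if apply_corr else df_error
    if degenerate:
        p_corr = p_unc
    elif apply_corr:
        p_corr = float(sps.f.sf(f, df_t_c, df_e_c))
    else:
        p_corr = p_unc

    return RmAnovaResult(
        f_stat=float(f), df_time=df_time, df_error=df_error,
        ss_time=ss_time, ss_subject=ss_subject, ss_error=ss_error,
        epsilon_gg=float(eps_gg), epsilon_hf=float(eps_hf),
        mauchly_w=float(mauchly_w), mauchly_p=float(mauchly_p),
        p_uncorrected=float(p_unc), p_corrected=float(p_corr),
        eta_p2=float(eta), correction_applied=bool(apply_corr),
        df_time_corrected=float(df_t_c), df_error_corrected=float(df_e_c),
        degenerate=bool(degenerate),
    )


def posthoc_pairwise(data: RepeatedMeasuresMatrix,
                     method: str = "bonferroni_paired_t"
                     ) -> list[PairwiseResult]:
    """All pairwise timepoint comparisons with adjustment and effect size.

    ``bonferroni_paired_t``: paired t test per pair, two-sided p multiplied
    by the number of pairs (capped at 1), CI from the per-pair t interval.
    ``tukey_hsd``: studentized-range test on within-subject means using the
    RM-ANOVA error term.  Cohen's dz = mean(diff)/sd(diff) in both cases.
    """
    if method not in POSTHOC_METHODS:
        raise ValidationError(f"method must be one of {POSTHOC_METHODS}")
    v = data.values
    n, k = data.n, data.k
    pairs = list(combinations(range(k), 2))
    n_pairs = len(pairs)

    if method == "tukey_hsd":
        anova = rm_anova(data)
        mse = anova.ss_error / anova.df_error
        df_err = anova.df_error

    results = []
    for a, b in pairs:
        diff = v[:, a] - v[:, b]
        mean_diff = float(diff.mean())
        sd_diff = float(diff.std(ddof=1))
        flags: tuple[str, ...] = ()
        dz: float | None
        if sd_diff == 0:
            dz = None
            flags = ("dz_undefined",)
        else:
            dz = mean_diff / sd_diff

        if method == "bonferroni_paired_t":
            if sd_diff == 0:
                p_raw = 1.0 if mean_diff == 0 else 0.0
                half = 0.0
            else:
                t = mean_diff / (sd_diff / math.sqrt(n))
                p_raw = float(2.0 * sps.t.sf(abs(t), n - 1))
                half = float(sps.t.ppf(0.975, n - 1) * sd_diff / math.sqrt(n))
            p_adj = min(1.0, p_raw * n_pairs)
        else:
            se = math.sqrt(mse / n)
            if se == 0:
                p_raw = 1.0 if mean_diff == 0 else 0.0
                half = 0.0
            else:
                q = abs(mean_diff) / se
                p_raw = float(sps.studentized_range.sf(q, k, df_err))
                half = float(sps.studentized_range.ppf(0.95, k, df_err) * se)
            p_adj = p_raw  # the studentized-range p is family-wise already

        results.append(PairwiseResult(
            day_a=data.timepoints[a], day_b=data.timepoints[b],
            mean_diff=mean_diff, ci95=(mean_diff - half, mean_diff + half),
            p_raw=p_raw, p_adjusted=float(p_adj), method=method,
            cohen_dz=dz, flags=flags))
    return results


def friedman_test(data: RepeatedMeasuresMatrix) -> tuple[float, int, float]:
    """Friedman rank test across timepoints.

    Ranks within each subject (mid-ranks for ties), then
    ``chi2 = 12/(n*k*(k+1)) * sum(R_j^2) - 3*n*(k+1)`` on ``k-1`` degrees
    of freedom.
    """
    v = data.values
    n, k = data.n, data.k
    if k < 3:
        raise ValidationError("Friedman test needs k >= 3 timepoints")
    ranks = np.apply_along_axis(sps.rankdata, 1, v)
    r = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(r * r)) - 3.0 * n * (k + 1)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), df, p


def stats_report(data: RepeatedMeasuresMatrix,
                 posthoc_method: str = "bonferroni_paired_t",
                 sphericity_alpha: float = 0.05) -> dict:
    """Full per-quantity statistics block as a JSON-serialisable dict."""
    normality = []
    for j, day in enumerate(data.timepoints):
        try:
            w, p = normality_check(data.values[:, j])
            normality.append({"day": int(day), "w": w, "p": p})
        except DegenerateDataError:
            normality.append({"day": int(day), "w": None, "p": None,
                              "flag": "constant"})
    anova = rm_anova(data, sphericity_alpha=sphericity_alpha)
    pairwise = posthoc_pairwise(data, method=posthoc_method)
    report = {
        "n_subjects": data.n,
        "timepoints": [int(t) for t in data.timepoints],
        "normality": normality,
        "rm_anova": {
            "f": anova.f_stat, "df_time": anova.df_time,
            "df_error": anova.df_error,
            "epsilon_gg": anova.epsilon_gg, "epsilon_hf": anova.epsilon_hf,
            "mauchly_w": anova.mauchly_w, "mauchly_p": anova.mauchly_p,
            "p_uncorrected": anova.p_uncorrected,
            "p_corrected": anova.p_corrected,
            "correction_applied": anova.correction_applied,
            "df_time_corrected": anova.df_time_corrected,
            "df_error_corrected": anova.df_error_corrected,
            "eta_p2": anova.eta_p2, "degenerate": anova.degenerate,
        },
        "pairwise": [{
            "day_a": r.day_a, "day_b": r.day_b, "mean_diff": r.mean_diff,
            "ci95_low": r.ci95[0], "ci95_high": r.ci95[1],
            "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
            "method": r.method, "cohen_dz": r.cohen_dz,
            "flags": list(r.flags),
        } for r in pairwise],
    }
    if data.k >= 3:
        chi2, df, p = friedman_test(data)
        report["friedman"] = {"chi2": chi2, "df": df, "p": p}
    else:
        report["friedman"] = None
    return report
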