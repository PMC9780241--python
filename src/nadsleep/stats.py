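"""Statistical battery: GG-corrected rm-ANOVA, t-tests, correlations.

Implements the tests used throughout the study's results: repeated-measures
ANOVA (arbitrary balanced within-subject factors, optional between-subject
group factor) with Greenhouse--Geisser sphericity correction and partial
eta-squared; one-sample / dependent / independent t-tests with Cohen's d and
the 95% CI of the tested mean (difference); Pearson correlations with
Fisher-z confidence intervals; Meng--Rosenthal--Rubin's z for comparing two
dependent correlations sharing one variable; median splits; and the region-
count-adjusted significance levels.

The rm-ANOVA uses the multivariate-projection formulation: for each within
effect, the data are projected onto an orthonormal contrast basis of that
effect's space, H and E cross-product matrices are formed in the projected
space (Type III, i.e. the within main effects test the unweighted mean of
group means when group sizes differ), and the sphericity-assumed F is
trace(H)/df1 over trace(E)/df_err.  Greenhouse--Geisser epsilon is computed
from the pooled within-group covariance of the projected scores,
eps = trace(S)^2 / (q * trace(S @ S)).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateInputError, DesignError

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult", "TTestResult", "CorrResult",
    "rm_anova_gg", "ttest", "pearson_ci", "meng_z", "median_split",
    "alpha_for_regions", "wilcoxon_signed_rank",
]


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float              # GG-corrected numerator df
    df2: float              # GG-corrected denominator df
    p: float                # GG-corrected p
    partial_eta_sq: float
    epsilon: float


@dataclass
class TTestResult:
    kind: str
    t: float
    df: int
    p: float
    cohen_d: float
    ci_low: float
    ci_high: float
    mean: float             # tested mean (difference)
    n: int


@dataclass
class CorrResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int


# --------------------------------------------------------------------------
# repeated-measures ANOVA

def _contrast_basis(k: int) -> np.ndarray:
    """Orthonormal basis (k x (k-1)) of the space orthogonal to the mean."""
    c = np.eye(k) - 1.0 / k
    q, r = np.linalg.qr(c)
    return q[:, :k - 1]


def rm_anova_gg(data: pd.DataFrame, dv: str, subject: str,
                within: list[str], between: str | None = None,
                ) -> list[AnovaResult]:
    """Balanced repeated-measures ANOVA with GG correction.

    ``data`` is long-format with one row per subject x within-cell.  Subjects
    with any missing cell (or NaN dv) are dropped listwise with a logged
    count.  Raises DesignError for unbalanced designs (duplicate cells).
    """
    if not within:
        raise DesignError("at least one within-subject factor required")
    cols = [subject] + within + ([between] if between else []) + [dv]
    d = data[cols].copy()
    levels = {f: sorted(pd.unique(d[f])) for f in within}
    n_cells = int(np.prod([len(levels[f]) for f in within]))

    dup = d.duplicated([subject] + within)
    if dup.any():
        raise DesignError("duplicate subject x cell rows; design unbalanced")
    wide = d.pivot_table(index=subject, columns=within, values=dv,
                         aggfunc="first", dropna=False)
    # order columns as the cartesian product of within levels
    order = list(itertools.product(*[levels[f] for f in within]))
    if len(within) == 1:
        order = [lvl for (lvl,) in order]
    wide = wide.reindex(columns=order)
    complete = wide.notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d subjects with incomplete cells",
                    int((~complete).sum()))
    wide = wide[complete]
    if wide.shape[1] != n_cells:
        raise DesignError("missing within-cell combinations")
    subjects = wide.index
    Y = wide.to_numpy(dtype=float)
    n = Y.shape[0]
    if n < 2:
        raise DesignError("need at least two complete subjects")

    if between:
        grp = d.drop_duplicates(subject).set_index(subject)[between]
        g = grp.reindex(subjects)
        if g.isna().any():
            raise DesignError("subjects without a between-group label")
        group_codes, group_levels = pd.factorize(g, sort=True)
        G = len(group_levels)
    else:
        group_codes, G = np.zeros(n, dtype=int), 1
    n_g = np.bincount(group_codes, minlength=G).astype(float)
    df_err_subj = n - G
    if df_err_subj < 1:
        raise DesignError(
            f"no error degrees of freedom ({n} subjects, {G} groups)")

    bases = {f: _contrast_basis(len(levels[f])) for f in within}
    means = {f: np.full((len(levels[f]), 1), 1.0 / len(levels[f]))
             for f in within}

    results: list[AnovaResult] = []

    def projected(effect_set):
        m = np.ones((1, 1))
        for f in within:
            m = np.kron(m, bases[f] if f in effect_set else means[f])
        return Y @ m

    # sums of squares this far below the data's scale are rounding residue
    ss_tol = 1e-12 * float(np.sum(Y * Y)) + 1e-300

    def add_result(name, ss_h, ss_e, q, df_err, eps):
        if ss_e <= ss_tol:
            if ss_h <= ss_tol:
                # no variation at all in this effect's contrast space
                results.append(AnovaResult(name, 0.0, eps * q, eps * df_err,
                                           1.0, 0.0, eps))
                return
            raise DegenerateInputError(f"zero error sum of squares for {name}")
        F = (ss_h / q) / (ss_e / df_err)
        df1, df2 = eps * q, eps * df_err
        p = float(sps.f.sf(F, df1, df2))
        results.append(AnovaResult(name, float(F), float(df1), float(df2), p,
                                   float(ss_h / (ss_h + ss_e)), float(eps)))

    # between-subjects main effect, from subject means
    if between:
        s = projected(frozenset())[:, 0]
        gm = np.array([s[group_codes == j].mean() for j in range(G)])
        grand = (n_g @ gm) / n
        ss_h = float(np.sum(n_g * (gm - grand) ** 2))
        ss_e = float(sum(np.sum((s[group_codes == j] - gm[j]) ** 2)
                         for j in range(G)))
        ss_eb = ss_e
        F = (ss_h / (G - 1)) / (ss_e / df_err_subj)
        p = float(sps.f.sf(F, G - 1, df_err_subj))
        results.append(AnovaResult(between, float(F), float(G - 1),
                                   float(df_err_subj), p,
                                   float(ss_h / (ss_h + ss_eb)), 1.0))

    # within effects and their interactions with the between factor
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            Z = projected(frozenset(combo))
            q = Z.shape[1]
            gm = np.vstack([Z[group_codes == j].mean(axis=0)
                            for j in range(G)])
            E = sum(
                (Z[group_codes == j] - gm[j]).T @ (Z[group_codes == j] - gm[j])
                for j in range(G))
            E = np.atleast_2d(E)
            if q == 1:
                eps = 1.0
            else:
                tr = np.trace(E)
                eps = float(np.clip(tr * tr / (q * np.trace(E @ E)),
                                    1.0 / q, 1.0))
            df_err = q * df_err_subj
            name = " x ".join(combo)
            # Type III within main effect: unweighted mean of group means
            m = gm.mean(axis=0)
            scale = np.sum(1.0 / n_g) / G ** 2
            ss_h = float(m @ m) / scale
            add_result(name, ss_h, float(np.trace(E)), q, df_err, eps)
            if between and G > 1:
                grand_w = (n_g @ gm) / n
                ss_int = float(np.sum(n_g[:, None] * (gm - grand_w) ** 2))
                add_result(f"{name} x {between}", ss_int, float(np.trace(E)),
                           q * (G - 1), df_err, eps)
    return results


# --------------------------------------------------------------------------
# t-tests

def _ks_advisory(x: np.ndarray, label: str) -> None:
    if x.size >= 4 and np.std(x, ddof=1) > 0:
        z = (x - x.mean()) / np.std(x, ddof=1)
        p = sps.kstest(z, "norm").pvalue
        if p < 0.05:
            logger.info("normality advisory (%s): Kolmogorov-Smirnov "
                        "p = %.3g", label, p)


def ttest(kind: str, x, y=None, mu: float = 0.0,
          confidence: float = 0.95) -> TTestResult:
    """Two-sided t-test with Cohen's d and CI of the tested mean (difference).

    ``kind`` is one of ``one_sample``, ``dependent``, ``independent``.  For
    one-sample/dependent tests d is the mean over the SD of the (paired)
    differences; for independent tests it uses the pooled SD.  Zero-variance
    input raises DegenerateInputError.  A Kolmogorov-Smirnov normality check
    is logged as an advisory, never enforced.
    """
    x = np.asarray(x, dtype=float)
    if kind == "one_sample":
        if x.size < 2:
            raise DegenerateInputError("need at least 2 observations")
        diff = x - mu
    elif kind == "dependent":
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise DegenerateInputError("paired samples must match in length")
        if x.size < 2:
            raise DegenerateInputError("need at least 2 pairs")
        diff = x - y
    elif kind == "independent":
        y = np.asarray(y, dtype=float)
        if x.size < 2 or y.size < 2:
            raise DegenerateInputError("need at least 2 per group")
        n1, n2 = x.size, y.size
        v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0:
            raise DegenerateInputError("zero pooled variance")
        _ks_advisory(x, "group 1")
        _ks_advisory(y, "group 2")
        mean = float(x.mean() - y.mean())
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        t = mean / se
        p = 2 * sps.t.sf(abs(t), df)
        crit = sps.t.ppf(0.5 + confidence / 2, df)
        d = mean / np.sqrt(sp2)
        return TTestResult("independent", float(t), df, float(p), float(d),
                           float(mean - crit * se), float(mean + crit * se),
                           mean, n1 + n2)
    else:
        raise ConfigurationError(f"unknown t-test kind {kind!r}")

    sd = np.std(diff, ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance of the (paired) differences")
    _ks_advisory(diff, kind)
    n = diff.size
    mean = float(diff.mean())
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2 * sps.t.sf(abs(t), df)
    crit = sps.t.ppf(0.5 + confidence / 2, df)
    return TTestResult(kind, float(t), df, float(p), float(mean / sd),
                       float(mean - crit * se), float(mean + crit * se),
                       mean, n)


def wilcoxon_signed_rank(x, y=None):
    """Nonparametric fallback used when normality is clearly violated."""
    res = sps.wilcoxon(x, y)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# correlations

def pearson_ci(x, y, confidence: float = 0.95) -> CorrResult:
    """Pearson r with two-sided p (t transform) and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DegenerateInputError("x and y must have equal length")
    if x.size < 4:
        raise DegenerateInputError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant input")
    r, p = sps.pearsonr(x, y)
    n = x.size
    zcrit = sps.norm.ppf(0.5 + confidence / 2)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    return CorrResult(float(r), float(p), float(np.tanh(z - half)),
                      float(np.tanh(z + half)), n)


def meng_z(r_xy1: float, r_xy2: float, r_y1y2: float, n: int,
           ) -> tuple[float, float]:
    """Meng, Rosenthal & Rubin's z for two dependent correlations.

    Tests whether x correlates differently with y1 than with y2, given the
    correlation between y1 and y2, on the same n subjects.  Returns
    ``(z, two-sided p)``.  The adjustment factor f is capped at 1 per the
    original definition.
    """
    for r in (r_xy1, r_xy2, r_y1y2):
        if not -1.0 < r < 1.0:
            raise DegenerateInputError("correlations must lie strictly in "
                                       "(-1, 1)")
    if n < 4:
        raise DegenerateInputError("need n >= 4")
    z1, z2 = np.arctanh(r_xy1), np.arctanh(r_xy2)
    r2bar = (r_xy1 ** 2 + r_xy2 ** 2) / 2.0
    f = min((1.0 - r_y1y2) / (2.0 * (1.0 - r2bar)), 1.0)
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r_y1y2) * h))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# --------------------------------------------------------------------------
# grouping helpers

def median_split(values) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into lower and upper halves by the median.

    Even n gives equal sizes; for odd n the middle observation joins the
    lower half.  Ties at the median are broken by stable input order with a
    logged warning.  Returns ``(lower_idx, upper_idx)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateInputError("need at least 2 values to split")
    order = np.argsort(values, kind="stable")
    cut = (values.size + 1) // 2
    low, high = order[:cut], order[cut:]
    if values[low[-1]] == values[high[0]] if high.size else False:
        logger.warning("ties at the median broken by stable input order")
    return np.sort(low), np.sort(high)


def alpha_for_regions(n_tests: int) -> float:
    """Region-count-adjusted significance level.

    Follows the study's convention: 1 test -> 0.05, 2 regions -> 0.025,
    3 regions -> 0.017, 9 ROIs -> 0.006; any other count falls back to a
    plain Bonferroni 0.05 / n with a logged note.
    """
    if n_tests < 1:
        raise ConfigurationError("number of tests must be >= 1")
    table = {1: 0.05, 2: 0.025, 3: 0.017, 9: 0.006}
    if n_tests in table:
        return table[n_tests]
    logger.info("no registered alpha for %d tests; Bonferroni 0.05/n used",
                n_tests)
    return 0.05 / n_tests
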