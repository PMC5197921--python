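"""Statistical layer: confound residualization, pooled t-tests, partial
correlations and control-referenced Z composites.

All procedures operate on participant-level summaries (window means of
average-day profiles, clinical scores), never on raw samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, InputError


@dataclass
class TestResult:
    """Two-tailed pooled-variance independent t-test result."""

    t: float
    df: int
    p: float
    mean_diff: float
    n1: int
    n2: int


@dataclass
class PartialCorrResult:
    """Partial correlation of two variables given a confound set."""

    r: float
    p: float
    n: int
    controlled: tuple[str, ...] = ()
    window: str | None = None


def _design(confounds: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([np.ones(len(confounds)), confounds.to_numpy(dtype=float)])
    if not np.all(np.isfinite(X)):
        raise InputError("confound columns must be numeric and finite")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = list(confounds.columns)
        bad = []
        for j, name in enumerate(cols):
            Xj = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                bad.append(name)
        raise DataError(f"confound matrix is rank deficient; collinear columns: {bad or cols}")
    return X


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def residualize_confounds(
    values: pd.DataFrame | pd.Series, confounds: pd.DataFrame
) -> pd.DataFrame | pd.Series:
    """Remove linear confound effects from participant-level measures.

    Each measure is regressed (ordinary least squares, pooled across
    groups) on an intercept plus the confound columns; the residuals are
    retained and the measure's grand mean added back, so confound slopes
    are removed while the overall location is preserved.
    """
    squeeze = isinstance(values, pd.Series)
    vals = values.to_frame() if squeeze else values
    if len(vals) < confounds.shape[1] + 2:
        raise InputError("need at least n_confounds + 2 participants to residualize")
    X = _design(confounds)
    out = {}
    for col in vals.columns:
        y = vals[col].to_numpy(dtype=float)
        out[col] = _ols_residuals(y, X) + np.nanmean(y)
    res = pd.DataFrame(out, index=vals.index)
    return res[vals.columns[0]] if squeeze else res


def independent_ttest(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-tailed independent t-test with pooled variance, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InputError("both groups need at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    if sp2 <= 0:
        raise DataError("zero pooled variance; t statistic undefined")
    diff = float(np.mean(x) - np.mean(y))
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(t=float(t), df=df, p=float(p), mean_diff=diff, n1=n1, n2=n2)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    confounds: pd.DataFrame | None = None,
    window: str | None = None,
) -> PartialCorrResult:
    """Pearson correlation of x and y after residualizing both on confounds.

    With an empty confound set this is the plain Pearson correlation.
    Pairs with any missing value are dropped listwise and the remaining n
    reported. The p-value comes from t = r * sqrt((n - k - 2)/(1 - r^2))
    with k confounds, two-tailed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    names: tuple[str, ...] = ()
    if confounds is not None and confounds.shape[1] > 0:
        C = confounds.to_numpy(dtype=float)
        names = tuple(confounds.columns)
        keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
        C = C[keep]
    else:
        C = None
        keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    k = 0 if C is None else C.shape[1]
    n = len(x)
    if n <= k + 2:
        raise InputError(f"partial correlation needs more than {k + 2} complete pairs, got {n}")
    if C is None:
        rx, ry = x - x.mean(), y - y.mean()
    else:
        X = np.column_stack([np.ones(n), C])
        rx = _ols_residuals(x, X)
        ry = _ols_residuals(y, X)
    sx, sy = np.sqrt(np.sum(rx**2)), np.sqrt(np.sum(ry**2))
    # exact linear functions of the confounds leave only rounding noise
    tiny_x = sx <= 1e-10 * max(1.0, float(np.linalg.norm(x)))
    tiny_y = sy <= 1e-10 * max(1.0, float(np.linalg.norm(y)))
    if tiny_x or tiny_y:
        raise DataError("zero residual variance; variable is an exact function of the confounds")
    r = float(np.sum(rx * ry) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    dof = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(r=r, p=p, n=n, controlled=names, window=window)


# ---------------------------------------------------------------------------
# control-referenced Z composites


@dataclass
class DomainZScores:
    """Per-patient composite Z scores over conceptual test domains.

    ``domain_scores`` has one row per patient and one column per domain
    plus ``grand_mean`` (mean z over all tests). ``test_z`` holds the
    per-test standardized scores.
    """

    domain_scores: pd.DataFrame
    test_z: pd.DataFrame
    domains: dict[str, list[str]] = field(default_factory=dict)


def z_composites(
    patient_scores: pd.DataFrame,
    control_scores: pd.DataFrame,
    domain_map: dict[str, list[str]],
    direction_map: dict[str, int] | None = None,
) -> DomainZScores:
    """Standardize patient test scores against the control group.

    Per test, z = direction * (x - mean_control) / sd_control, with
    direction -1 for lower-is-better scores (times, error counts) so every
    z is oriented higher-is-better. Missing raw scores are imputed with the
    group mean before standardization. Domain scores are the mean of their
    tests' z; the grand mean averages over all tests.
    """
    direction_map = direction_map or {}
    tests = [t for tests_ in domain_map.values() for t in tests_]
    seen: list[str] = []
    for t in tests:
        if t not in seen:
            seen.append(t)
    missing = [t for t in seen if t not in patient_scores or t not in control_scores]
    if missing:
        raise InputError(f"scores missing for tests: {missing}")

    patients = patient_scores[seen].astype(float).copy()
    controls = control_scores[seen].astype(float).copy()
    patients = patients.fillna(patients.mean())
    controls = controls.fillna(controls.mean())

    z = pd.DataFrame(index=patients.index, columns=seen, dtype=float)
    for t in seen:
        mu = controls[t].mean()
        sd = controls[t].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DataError(f"control SD is zero for test {t!r}; z score undefined")
        z[t] = direction_map.get(t, 1) * (patients[t] - mu) / sd

    domains = pd.DataFrame(index=patients.index, dtype=float)
    for name, tests_ in domain_map.items():
        domains[name] = z[tests_].mean(axis=1)
    domains["grand_mean"] = z[seen].mean(axis=1)
    return DomainZScores(domain_scores=domains, test_z=z, domains=dict(domain_map))
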