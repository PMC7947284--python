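"""Correlation, mediation, and trial-preprocessing statistics.

The mediation engine estimates the classic three-variable model on
z-standardised data (the binary gender predictor is standardised like any
other column): ``a`` from m ~ x, ``b`` and ``c'`` from y ~ x + m, ``c``
from y ~ x, indirect effect ``ab = a * b`` with a percentile confidence
interval over case-resampled bootstrap replicates (default 10,000).  For
standardised OLS the decomposition c = c' + a*b is exact and is asserted
on every call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class MediationResult:
    """Standardised path estimates and the bootstrap indirect effect."""

    a: float
    b: float
    c: float
    c_prime: float
    se_a: float
    se_b: float
    se_c: float
    se_c_prime: float
    ab: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int
    n: int

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.ci_lower > self.ci_upper:
            raise ValueError("bootstrap CI bounds are inverted")


@dataclass
class PreprocessReport:
    """Counts from the trial-table exclusion filters."""

    participants_dropped: list[str]
    trials_dropped_fast: int
    trials_dropped_slow: int
    rows_retained: int
    response_shift_applied: bool


def masculinity_composite(masculinity, femininity) -> np.ndarray:
    """Masculine-feminine score: masculinity + (-1) * femininity.

    Higher values indicate a more masculine appearance.
    """
    m = np.asarray(masculinity, dtype=float)
    f = np.asarray(femininity, dtype=float)
    if m.shape != f.shape:
        raise ValueError("masculinity and femininity vectors must align")
    return m - f


def correlate(
    machine: pd.DataFrame, ratings: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of machine outputs against trait ratings.

    Rows are joined on index (face_id).  Returns ``(r, p, significant)``
    DataFrames with machine columns as rows and rating columns as columns.
    Zero-variance cells are NaN (undefined), never an error.
    """
    joined = machine.join(ratings, how="inner", lsuffix="_m")
    if len(joined) < 3:
        raise ValueError("need at least 3 paired observations")
    r = pd.DataFrame(index=machine.columns, columns=ratings.columns, dtype=float)
    p = r.copy()
    for mc in machine.columns:
        x = joined[mc + "_m"] if mc + "_m" in joined else joined[mc]
        for rc in ratings.columns:
            y = joined[rc]
            if x.std() == 0 or y.std() == 0:
                r.loc[mc, rc] = np.nan
                p.loc[mc, rc] = np.nan
            else:
                res = sps.pearsonr(x, y)
                r.loc[mc, rc] = res.statistic
                p.loc[mc, rc] = res.pvalue
    return r, p, p < alpha


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant column cannot be standardised")
    return (v - v.mean()) / sd


def mediate(
    x, m, y, n_boot: int = 10000, seed: int = 0, ci_level: float = 0.95
) -> MediationResult:
    """Bootstrap mediation of x -> m -> y with standardised coefficients."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must align")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    xs, ms, ys = _standardize(x), _standardize(m), _standardize(y)

    # point estimates and analytic SEs via OLS
    fit_a = sm.OLS(ms, sm.add_constant(xs)).fit()
    fit_b = sm.OLS(ys, sm.add_constant(np.column_stack([xs, ms]))).fit()
    fit_c = sm.OLS(ys, sm.add_constant(xs)).fit()
    a, se_a = float(fit_a.params[1]), float(fit_a.bse[1])
    c_prime, se_cp = float(fit_b.params[1]), float(fit_b.bse[1])
    b, se_b = float(fit_b.params[2]), float(fit_b.bse[2])
    c, se_c = float(fit_c.params[1]), float(fit_c.bse[1])
    ab = a * b
    # exact decomposition for standardised OLS
    assert abs(c - (c_prime + ab)) < 1e-8, "c = c' + ab identity violated"

    # percentile bootstrap over case resampling, vectorised via correlations
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, bm, by = x[idx], m[idx], y[idx]

    def _cols(u):  # z-standardise each replicate row
        mu = u.mean(axis=1, keepdims=True)
        sd = u.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, np.nan, sd)
        return (u - mu) / sd

    zx, zm, zy = _cols(bx), _cols(bm), _cols(by)
    rxm = np.nanmean(zx * zm, axis=1)
    rxy = np.nanmean(zx * zy, axis=1)
    rmy = np.nanmean(zm * zy, axis=1)
    denom = 1.0 - rxm**2
    boot_ab = rxm * (rmy - rxy * rxm) / denom
    boot_ab = boot_ab[np.isfinite(boot_ab)]
    lo, hi = np.percentile(boot_ab, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])

    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime,
        se_a=se_a, se_b=se_b, se_c=se_c, se_c_prime=se_cp,
        ab=ab, ci_lower=float(lo), ci_upper=float(hi),
        n_boot=n_boot, seed=seed, n=n,
    )


def mediation_table(results: dict[str, MediationResult]) -> pd.DataFrame:
    """Stack MediationResults into a table of standardised path estimates."""
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "mediation": name,
                "a": r.a, "se_a": r.se_a,
                "b": r.b, "se_b": r.se_b,
                "c": r.c, "se_c": r.se_c,
                "c_prime": r.c_prime, "se_c_prime": r.se_c_prime,
                "ab": r.ab, "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                "n": r.n, "n_boot": r.n_boot,
            }
        )
    return pd.DataFrame(rows)


def preprocess_trials(
    trials: pd.DataFrame,
    sd_min: float = 0.4,
    rt_min_ms: float = 50.0,
    rt_max_ms: float = 10000.0,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Apply the trial exclusion filters and the response shift.

    Participants whose response SD across all their trials is below
    ``sd_min`` are removed entirely; among the remaining trials, rows with
    reaction time below ``rt_min_ms`` or above ``rt_max_ms`` are dropped;
    finally 1 is subtracted from every response so the scale runs 0-6.
    The shift is applied only when the table is still on the 1-7 scale
    (minimum response >= 1), which makes the whole step idempotent.
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    sds = trials.groupby("participant_id")["response"].std(ddof=1).fillna(0.0)
    dropped_participants = sorted(sds.index[sds < sd_min])
    kept = trials[~trials["participant_id"].isin(dropped_participants)].copy()

    fast = kept["rt_ms"] < rt_min_ms
    slow = kept["rt_ms"] > rt_max_ms
    out = kept[~(fast | slow)].copy()

    shift = out["response"].min() >= 1
    if shift:
        out["response"] = out["response"] - 1

    report = PreprocessReport(
        participants_dropped=dropped_participants,
        trials_dropped_fast=int(fast.sum()),
        trials_dropped_slow=int(slow.sum()),
        rows_retained=len(out),
        response_shift_applied=bool(shift),
    )
    return out.reset_index(drop=True), report


def fit_trait_contrast(
    trials: pd.DataFrame,
    stimulus_table: pd.DataFrame,
    trait: str,
) -> pd.DataFrame:
    """Thin mixed-model runner for transformed-vs-base rating contrasts.

    Fits ``response ~ face_type + gender + attractiveness`` with a
    participant random intercept via statsmodels MixedLM, one trait at a
    time.  ``stimulus_table`` maps face_id to ``face_type`` (e.g. base vs
    quadrant transform), ``gender``, and mean ``attractiveness``.  This is
    off-the-shelf estimation, not a re-implementation.
    """
    sub = trials[trials["trait"] == trait].merge(stimulus_table, on="face_id")
    if sub["face_type"].nunique() < 2:
        raise ValueError("need at least two face types to contrast")
    model = sm.MixedLM.from_formula(
        "response ~ C(face_type) + C(gender) + attractiveness",
        groups="participant_id",
        data=sub,
    )
    fit = model.fit(reml=True, method="lbfgs")
    return pd.DataFrame(
        {"term": fit.params.index, "estimate": fit.params.values, "se": fit.bse.values}
    )
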