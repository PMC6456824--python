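"""Population cross-effects via linear mixed-effects models.

Two model arms estimate the fixed slope ``b1`` of treatment on outcome:

* raw arm — ``outcome ~ 1 + treatment`` with correlated per-subject random
  intercepts and random slopes, fitted by REML through statsmodels
  ``MixedLM`` (with a diagonal-covariance and then intercept-only fallback
  when the full structure does not converge);
* normalized arm — for within-person z-scored data every subject has mean
  zero, so the model is ``outcome ~ 0 + treatment`` with a per-subject
  random slope and no intercept of any kind.  This one-variance-component
  model profiles to a one-dimensional REML problem in the variance ratio
  ``lambda = var(slope)/var(residual)`` and is solved here directly on
  per-subject sufficient statistics, which makes subject-level bootstrap
  refits cheap.  statsmodels ``MixedLM`` on the same specification is the
  independent cross-check (``engine="statsmodels"``).

p-values use the large-sample normal approximation on ``b1/se``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import LaggedDataset

__all__ = ["ModelFit", "DirectionComparison", "FitError",
           "fit_raw", "fit_normalized", "compare_directions"]


class FitError(RuntimeError):
    """A mixed-model fit could not be carried out."""


@dataclass
class ModelFit:
    direction: str
    normalized: bool
    b1: float
    se: float
    p_value: float
    n_subjects: int
    n_rows: int
    random_effect_variances: dict = field(default_factory=dict)
    converged: bool = True
    diagnostics: str = ""

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "normalized": self.normalized,
            "b1": self.b1,
            "se": self.se,
            "p": self.p_value,
            "n_subjects": self.n_subjects,
            "n_rows": self.n_rows,
            "converged": self.converged,
        }


def _check_dataset(dataset: LaggedDataset, min_rows_per_subject: int = 2) -> pd.DataFrame:
    df = dataset.data.dropna(subset=["treatment", "outcome"])
    counts = df.groupby("subject_id").size()
    df = df[df["subject_id"].isin(counts[counts >= min_rows_per_subject].index)]
    n_sub = df["subject_id"].nunique()
    if n_sub < 2:
        raise FitError(
            f"mixed model needs >=2 subjects with >={min_rows_per_subject} rows "
            f"each; got {n_sub}"
        )
    return df


def _zp(b1: float, se: float) -> float:
    if se <= 0 or not np.isfinite(se):
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(b1 / se)))


# ---------------------------------------------------------------------------
# raw arm: statsmodels MixedLM with a convergence ladder


def fit_raw(dataset: LaggedDataset, random_slope: bool = True) -> ModelFit:
    """REML fit of ``outcome ~ 1 + treatment`` with subject random effects.

    By default both random intercepts and random slopes are estimated with
    an unstructured 2x2 covariance; on non-convergence the ladder falls
    back to a random intercept only.  ``random_slope=False`` requests the
    intercept-only variant directly.
    """
    import statsmodels.formula.api as smf

    df = _check_dataset(dataset)

    # degenerate input: an (almost) exact linear relation leaves the
    # variance components unidentified, so report the OLS solution
    X = np.column_stack([np.ones(len(df)), df["treatment"].to_numpy(float)])
    y = df["outcome"].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if np.var(resid) <= 1e-12 * max(np.var(y), 1e-12):
        return ModelFit(
            direction=dataset.direction, normalized=False,
            b1=float(coef[1]), se=0.0, p_value=0.0,
            n_subjects=df["subject_id"].nunique(), n_rows=len(df),
            random_effect_variances={"residual": float(np.var(resid))},
            converged=True, diagnostics="exact linear relation; OLS solution",
        )

    ladder = ["~treatment", "~1"] if random_slope else ["~1"]
    last_msg = ""
    fallback = None
    for re_formula in ladder:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm("outcome ~ treatment", df, groups="subject_id",
                                 re_formula=re_formula)
                res = md.fit(reml=True)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_msg = f"{re_formula}: {exc}"
                continue
        b1 = float(res.fe_params["treatment"])
        se = float(res.bse_fe["treatment"])
        if not (np.isfinite(b1) and np.isfinite(se) and se >= 0):
            last_msg = f"{re_formula}: non-finite estimates"
            continue
        re_var = {k: float(v) for k, v in res.cov_re.stack().items()} \
            if hasattr(res.cov_re, "stack") else {}
        re_var["residual"] = float(res.scale)
        fit = ModelFit(
            direction=dataset.direction, normalized=False,
            b1=b1, se=se, p_value=_zp(b1, se),
            n_subjects=df["subject_id"].nunique(), n_rows=len(df),
            random_effect_variances=re_var,
            converged=bool(res.converged),
            diagnostics=f"re_formula={re_formula}",
        )
        if res.converged:
            return fit
        fit.diagnostics += "; optimizer did not converge"
        fallback = fallback or fit
        last_msg = f"{re_formula}: not converged"
    if fallback is not None:
        # explicit fit-failure status: estimates are reported but flagged
        return fallback
    raise FitError(f"raw mixed model failed ({last_msg})")


# ---------------------------------------------------------------------------
# normalized arm: profiled REML for the no-intercept random-slope model


def _suffstats(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = df.groupby("subject_id", sort=True)
    x = df["treatment"].to_numpy(float)
    y = df["outcome"].to_numpy(float)
    tmp = pd.DataFrame({
        "sid": df["subject_id"].to_numpy(),
        "xx": x * x, "xy": x * y, "yy": y * y,
    })
    agg = tmp.groupby("sid", sort=True).sum()
    n = g.size().reindex(agg.index).to_numpy(float)
    return (agg["xx"].to_numpy(), agg["xy"].to_numpy(), agg["yy"].to_numpy(), n)


def _profile_reml(sxx, sxy, syy, n, lam_max: float = 200.0):
    """REML estimate for y_ij = b x_ij + u_i x_ij + e_ij, u_i ~ N(0, lam*s2).

    With V_i = s2 (I + lam x_i x_i'), Sherman-Morrison reduces everything
    to the per-subject sums Sxx, Sxy, Syy, so the REML criterion is a
    scalar function of lam.
    """
    N = float(np.sum(n))
    if N <= 1:
        raise FitError("not enough rows for the random-slope model")

    def components(lam):
        w = 1.0 / (1.0 + lam * sxx)
        A = np.sum(w * sxx)
        B = np.sum(w * sxy)
        C = np.sum(syy - lam * w * sxy**2)
        rss = max(C - (B * B) / A if A > 0 else C, 1e-300)
        return w, A, B, rss

    def neg2_reml(lam):
        w, A, _, rss = components(lam)
        if A <= 0:
            return np.inf
        s2 = rss / (N - 1.0)
        return (N - 1.0) * np.log(s2) + np.sum(np.log1p(lam * sxx)) + np.log(A)

    res = optimize.minimize_scalar(neg2_reml, bounds=(0.0, lam_max), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(res.x)
    # the optimum may sit on the lam=0 boundary (no slope heterogeneity)
    if neg2_reml(0.0) <= neg2_reml(lam):
        lam = 0.0
    _, A, B, rss = components(lam)
    s2 = rss / (N - 1.0)
    b1 = B / A
    se = float(np.sqrt(s2 / A))
    return b1, se, lam, s2


def fit_normalized(dataset: LaggedDataset, engine: str = "profile") -> ModelFit:
    """Fit ``outcome ~ 0 + treatment`` with a per-subject random slope.

    Intended for within-person z-scored datasets: the fixed and random
    intercepts are constrained to zero.  ``engine="profile"`` uses the
    closed-form profiled REML; ``engine="statsmodels"`` fits the identical
    specification through ``MixedLM`` and exists as a cross-check.
    """
    df = _check_dataset(dataset)
    n_sub, n_rows = df["subject_id"].nunique(), len(df)

    if engine == "statsmodels":
        import statsmodels.formula.api as smf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("outcome ~ 0 + treatment", df, groups="subject_id",
                             re_formula="0 + treatment")
            res = md.fit(reml=True)
        b1 = float(res.fe_params["treatment"])
        se = float(res.bse_fe["treatment"])
        re_var = {"slope": float(np.asarray(res.cov_re)[0, 0]),
                  "residual": float(res.scale)}
        converged = bool(res.converged)
    elif engine == "profile":
        sxx, sxy, syy, n = _suffstats(df)
        b1, se, lam, s2 = _profile_reml(sxx, sxy, syy, n)
        re_var = {"slope": lam * s2, "residual": s2}
        converged = np.isfinite(se) and se > 0
    else:
        raise ValueError(f"unknown engine {engine!r}")

    if not converged:
        raise FitError("normalized mixed model failed to converge")
    return ModelFit(
        direction=dataset.direction, normalized=True,
        b1=b1, se=se, p_value=_zp(b1, se),
        n_subjects=n_sub, n_rows=n_rows,
        random_effect_variances=re_var,
        converged=True, diagnostics=f"engine={engine}",
    )


# ---------------------------------------------------------------------------
# direction comparison by subject-level bootstrap


@dataclass
class DirectionComparison:
    difference: float
    p_value: float
    boot_mean: float
    boot_sd: float
    n_boot: int
    seed: int
    warning: str = ""


def compare_directions(
    dataset_a: LaggedDataset,
    dataset_b: LaggedDataset,
    n_boot: int = 100,
    seed: int = 0,
    normalized: bool = True,
) -> DirectionComparison:
    """Bootstrap test of ``b1(dataset_a) - b1(dataset_b)`` over subjects.

    Subjects are resampled with replacement (a subject drawn twice counts
    as two independent subjects); both arms are refitted on each replicate
    and the two-sided percentile p-value of the difference is returned.
    For the normalized arm refits use the profiled-REML fitter, so the
    bootstrap is fast; the raw arm refits ``MixedLM`` and is proportionally
    slower.
    """
    warning = ""
    if n_boot < 50:
        warning = f"n_boot={n_boot} < 50: percentile p-value is coarse"

    fit = fit_normalized if normalized else fit_raw
    point = fit(dataset_a).b1 - fit(dataset_b).b1

    ids_a = sorted(dataset_a.data["subject_id"].unique())
    ids_b = sorted(dataset_b.data["subject_id"].unique())
    ids = sorted(set(ids_a) | set(ids_b))
    rng = np.random.default_rng(seed)

    if normalized:
        stats_a = _suffstats(dataset_a.data.dropna(subset=["treatment", "outcome"]))
        stats_b = _suffstats(dataset_b.data.dropna(subset=["treatment", "outcome"]))
        idx_a = {s: i for i, s in enumerate(
            sorted(dataset_a.data.dropna(subset=["treatment", "outcome"])["subject_id"].unique()))}
        idx_b = {s: i for i, s in enumerate(
            sorted(dataset_b.data.dropna(subset=["treatment", "outcome"])["subject_id"].unique()))}
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(ids, size=len(ids), replace=True)
            ia = np.array([idx_a[s] for s in pick if s in idx_a], dtype=int)
            ib = np.array([idx_b[s] for s in pick if s in idx_b], dtype=int)
            ba, *_ = _profile_reml(*(arr[ia] for arr in stats_a[:3]), stats_a[3][ia])
            bb, *_ = _profile_reml(*(arr[ib] for arr in stats_b[:3]), stats_b[3][ib])
            diffs[b] = ba - bb
    else:
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(ids, size=len(ids), replace=True)
            diffs[b] = (_refit_resampled(dataset_a, pick, fit)
                        - _refit_resampled(dataset_b, pick, fit))

    p = _percentile_p(diffs)
    return DirectionComparison(
        difference=float(point), p_value=p,
        boot_mean=float(np.mean(diffs)), boot_sd=float(np.std(diffs, ddof=1)),
        n_boot=n_boot, seed=seed, warning=warning,
    )


def _refit_resampled(dataset: LaggedDataset, pick, fit_fn) -> float:
    parts = []
    for k, s in enumerate(pick):
        block = dataset.data[dataset.data["subject_id"] == s]
        if len(block):
            block = block.copy()
            block["subject_id"] = f"{s}__{k}"
            parts.append(block)
    data = pd.concat(parts, ignore_index=True)
    resampled = LaggedDataset(dataset.direction, dataset.history_depth, data,
                              dataset.confounder_columns)
    return fit_fn(resampled).b1


def _percentile_p(diffs: np.ndarray) -> float:
    n = len(diffs)
    lo = (np.sum(diffs <= 0.0) + 1) / (n + 1)
    hi = (np.sum(diffs >= 0.0) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))
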