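"""Calibration pipeline: outlier elimination, cross-validation, treatment grid.

The procedure mirrors routine NIR calibration practice:

1. pretreat the per-sample absorbance matrix with a candidate treatment;
2. remove spectral outliers by the GH ("global H") criterion — squared
   Mahalanobis distance in the retained PCA score space divided by the
   number of components, threshold 3 — and chemical outliers by the
   T criterion — cross-validated standardized residual |y − ŷ|/SECV ≥ 2.5;
3. select the factor count by grouped cross-validation (default six
   subsets) minimizing SECV;
4. report SEC, RSQ, SECV, RPD and the range of applicability;
5. rank candidate treatments by (lowest SECV, highest RSQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .errors import ConfigurationError, DataError
from .mpls import MPLSModel, fit_mpls, pca_describe, predict
from .preprocess import FittedTreatment, MathTreatment, apply_treatment
from .spectra import SpectraSet

DEFAULT_VARIANCE_TARGET = 0.996
DEFAULT_N_FACTORS_MAX = 16


@dataclass(frozen=True)
class OutlierConfig:
    """Thresholds for spectral (H) and chemical (T) outlier elimination."""

    h_threshold: float = 3.0
    t_threshold: float = 2.5
    max_passes: int = 2

    def __post_init__(self) -> None:
        if self.h_threshold <= 0 or self.t_threshold <= 0:
            raise ConfigurationError("outlier thresholds must be > 0")
        if self.max_passes < 1:
            raise ConfigurationError("max_passes must be >= 1")


@dataclass
class OutlierRemoval:
    sample_id: object
    criterion: str   # "H" or "T"
    value: float
    pass_number: int


@dataclass
class OutlierReport:
    removals: list = field(default_factory=list)
    n_passes: int = 0
    aborted: bool = False

    @property
    def n_removed(self) -> int:
        return len(self.removals)

    def removed_ids(self) -> list:
        return [r.sample_id for r in self.removals]


def gh_distances(scores: np.ndarray, n_components: int) -> np.ndarray:
    """GH distance of each sample in the leading PCA score space.

    Squared Mahalanobis distance under the scores' own covariance, divided
    by ``n_components``; over a centred calibration set the mean GH is
    (n−1)/n ≈ 1.
    """
    scores = np.asarray(scores, float)
    if n_components < 1:
        raise ConfigurationError("n_components must be >= 1")
    if scores.shape[0] <= n_components:
        raise DataError("need more samples than score components for GH")
    S = scores[:, :n_components]
    Sc = S - S.mean(axis=0)
    cov = Sc.T @ Sc / (S.shape[0] - 1)
    try:
        cho = sla.cho_factor(cov)
    except sla.LinAlgError as exc:
        raise DataError(
            "singular score covariance; try fewer components"
        ) from exc
    d2 = np.einsum("ij,ij->i", Sc, sla.cho_solve(cho, Sc.T).T)
    return d2 / n_components


@dataclass
class CVResult:
    secv_by_factors: np.ndarray   # index k = SECV using k factors (0..kmax)
    n_factors: int                # argmin, ties broken toward fewer factors
    y_cv: np.ndarray              # held-out predictions at the chosen factor count
    folds: list                   # list of index arrays, one per group
    predictions: np.ndarray       # (n, kmax+1) held-out predictions per factor count

    @property
    def secv(self) -> float:
        return float(self.secv_by_factors[self.n_factors])


def make_folds(n: int, n_groups: int, rng: np.random.Generator) -> list:
    """Seeded random partition into near-equal groups."""
    if n_groups < 2:
        raise ConfigurationError("cross-validation needs at least 2 groups")
    if n < n_groups:
        raise DataError(f"cannot split {n} samples into {n_groups} groups")
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_groups)]


def cross_validate(X: np.ndarray, y: np.ndarray, n_groups: int = 6,
                   n_factors_max: int | None = None,
                   standardize_residuals: bool = True,
                   rng=None, folds: list | None = None) -> CVResult:
    """Grouped cross-validation of MPLS over every factor count.

    SECV(k) = sqrt(Σ held-out residuals² / n); the chosen factor count is
    the argmin with exact ties resolved toward fewer factors.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    if folds is None:
        rng = np.random.default_rng(rng)
        folds = make_folds(n, n_groups, rng)
    if min(len(f) for f in folds) < 1:
        raise DataError("empty cross-validation fold")
    min_train = n - max(len(f) for f in folds)
    if n_factors_max is None:
        n_factors_max = min(DEFAULT_N_FACTORS_MAX, max(1, min_train // 3))
    kmax = min(n_factors_max, min_train - 2, X.shape[1])
    if kmax < 1:
        raise DataError("not enough samples per training fold for even one factor")

    preds = np.empty((n, kmax + 1))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        model = fit_mpls(X[train], y[train], kmax, standardize_residuals)
        for k in range(kmax + 1):
            preds[fold, k] = predict(model, X[fold], n_factors=min(k, model.n_factors_available))
    secv = np.sqrt(np.mean((y[:, None] - preds) ** 2, axis=0))
    chosen = int(np.argmin(secv))
    return CVResult(secv_by_factors=secv, n_factors=chosen,
                    y_cv=preds[:, chosen], folds=list(folds), predictions=preds)


def remove_outliers(X: np.ndarray, y: np.ndarray, config: OutlierConfig | None = None,
                    sample_ids=None, n_groups: int = 6,
                    n_factors_max: int | None = None,
                    standardize_residuals: bool = True,
                    variance_target: float = DEFAULT_VARIANCE_TARGET,
                    gh_max_components: int = 10,
                    rng=None):
    """Iteratively drop spectral (GH) and chemical (T) outliers.

    Per pass: drop samples with GH > h_threshold in the PCA score space at
    the variance target, then cross-validate and drop samples with
    T = |y − ŷ_cv| / SECV ≥ t_threshold.  Stops when a pass removes nothing
    or ``max_passes`` is reached; aborts (flagged) rather than trimming the
    set below what a refit needs.

    The GH score space is capped at ``gh_max_components`` components:
    smooth NIR spectra concentrate their variance in a handful of
    components, and letting dozens of near-noise components into the
    distance both dilutes GH (it divides by the component count) and makes
    the covariance unstable.

    Returns ``(X_kept, y_kept, kept_indices, report)``.
    """
    config = config or OutlierConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    ids = list(sample_ids) if sample_ids is not None else list(range(n))
    rng = np.random.default_rng(rng)
    keep = np.arange(n)
    report = OutlierReport()
    min_keep = 8  # a refit needs at least a few samples beyond the factor count

    for pass_number in range(1, config.max_passes + 1):
        removed_this_pass = 0
        # spectral criterion
        pca = pca_describe(X[keep], variance_target)
        ncomp = min(pca.n_components, len(keep) - 2, gh_max_components)
        gh = gh_distances(pca.scores, ncomp)
        bad = np.flatnonzero(gh > config.h_threshold)
        if len(keep) - len(bad) < min_keep:
            report.aborted = True
            report.n_passes = pass_number
            return X[keep], y[keep], keep, report
        for i in bad:
            report.removals.append(OutlierRemoval(ids[keep[i]], "H", float(gh[i]), pass_number))
        removed_this_pass += len(bad)
        keep = np.delete(keep, bad)
        # chemical criterion
        cv = cross_validate(X[keep], y[keep], n_groups=n_groups,
                            n_factors_max=n_factors_max,
                            standardize_residuals=standardize_residuals, rng=rng)
        if cv.secv > 1e-12:
            t_vals = np.abs(y[keep] - cv.y_cv) / cv.secv
            bad = np.flatnonzero(t_vals >= config.t_threshold)
            if len(keep) - len(bad) < min_keep:
                report.aborted = True
                report.n_passes = pass_number
                return X[keep], y[keep], keep, report
            for i in bad:
                report.removals.append(
                    OutlierRemoval(ids[keep[i]], "T", float(t_vals[i]), pass_number))
            removed_this_pass += len(bad)
            keep = np.delete(keep, bad)
        report.n_passes = pass_number
        if removed_this_pass == 0:
            break
    return X[keep], y[keep], keep, report


@dataclass
class CalibrationResult:
    """Statistics block of one calibrated treatment (one table row)."""

    constituent: str
    treatment: str
    n_retained: int
    mean: float
    sd: float
    range_min: float
    range_max: float
    sec: float
    rsq: float
    secv: float
    rpd: float
    n_factors: int
    outlier_report: OutlierReport | None = None

    def to_row(self) -> dict:
        return {
            "constituent": self.constituent,
            "math_treatment": self.treatment,
            "N": self.n_retained,
            "mean": self.mean,
            "SD": self.sd,
            "range_min": self.range_min,
            "range_max": self.range_max,
            "SEC": self.sec,
            "RSQ": self.rsq,
            "SECV": self.secv,
            "RPD": self.rpd,
            "n_factors": self.n_factors,
            "n_outliers_removed": (self.outlier_report.n_removed
                                   if self.outlier_report else 0),
        }


def calibration_stats(y_ref: np.ndarray, y_fit: np.ndarray, y_cv: np.ndarray,
                      n_factors: int) -> dict:
    """SEC, RSQ, SECV, SD, RPD and the range of applicability.

    SEC uses the n − k − 1 denominator, SECV the plain n; RPD = SD/SECV
    with the reference values' sample SD; the applicability range is
    mean ± 3·SD widened to include the observed extremes.
    """
    y_ref = np.asarray(y_ref, float)
    y_fit = np.asarray(y_fit, float)
    y_cv = np.asarray(y_cv, float)
    n = len(y_ref)
    if n <= n_factors + 1:
        raise DataError("need n > n_factors + 1 for calibration statistics")
    sd = float(np.std(y_ref, ddof=1))
    if sd < 1e-300:
        raise DataError("reference values have zero variance")
    sec = float(np.sqrt(np.sum((y_ref - y_fit) ** 2) / (n - n_factors - 1)))
    if np.std(y_fit) < 1e-300:
        rsq = 0.0  # constant (zero-factor) fit carries no correlation
    else:
        rsq = float(np.corrcoef(y_ref, y_fit)[0, 1] ** 2)
    secv = float(np.sqrt(np.mean((y_ref - y_cv) ** 2)))
    rpd = float(sd / secv) if secv > 0 else float("inf")
    mean = float(np.mean(y_ref))
    lo = min(mean - 3 * sd, float(np.min(y_ref)))
    hi = max(mean + 3 * sd, float(np.max(y_ref)))
    return {"mean": mean, "sd": sd, "range_min": lo, "range_max": hi,
            "sec": sec, "rsq": rsq, "secv": secv, "rpd": rpd}


DEFAULT_CODES = ((0, 0, 1, 1), (1, 4, 4, 1), (2, 4, 4, 1), (2, 8, 6, 1), (2, 10, 10, 1))


def default_treatment_grid() -> list:
    """The 25-candidate grid: 5 scatter options x 5 derivative codes."""
    from .preprocess import SCATTER_OPTIONS
    return [MathTreatment(sc, code) for sc in SCATTER_OPTIONS for code in DEFAULT_CODES]


@dataclass
class CalibrationOutcome:
    """Everything produced while calibrating one treatment."""

    result: CalibrationResult
    model: MPLSModel
    fitted_treatment: FittedTreatment
    cv: CVResult
    kept_indices: np.ndarray
    error: str | None = None


def calibrate_treatment(s: SpectraSet, y: np.ndarray, treatment: MathTreatment,
                        constituent: str = "", outlier_config: OutlierConfig | None = None,
                        n_groups: int = 6, n_factors_max: int | None = None,
                        standardize_residuals: bool = True,
                        rng=None) -> CalibrationOutcome:
    """Run pretreatment, outlier removal, CV and the final fit for one treatment."""
    rng = np.random.default_rng(rng)
    treated, fitted_t = apply_treatment(s, treatment)
    X = treated.values
    y = np.asarray(y, float).ravel()
    Xk, yk, keep, report = remove_outliers(
        X, y, outlier_config, sample_ids=s.sample_ids, n_groups=n_groups,
        n_factors_max=n_factors_max, standardize_residuals=standardize_residuals, rng=rng)
    cv = cross_validate(Xk, yk, n_groups=n_groups, n_factors_max=n_factors_max,
                        standardize_residuals=standardize_residuals, rng=rng)
    kmax_fit = max(cv.n_factors, 1)
    model = fit_mpls(Xk, yk, kmax_fit, standardize_residuals)
    model.n_factors_selected = min(cv.n_factors, model.n_factors_available)
    model.constituent = constituent
    model.sample_ids = [s.sample_ids[i] for i in keep]
    model.treatment_label = treatment.label
    y_fit = model.fitted_values[:, model.n_factors_selected]
    stats = calibration_stats(yk, y_fit, cv.y_cv, model.n_factors_selected)
    result = CalibrationResult(
        constituent=constituent, treatment=treatment.label, n_retained=len(yk),
        n_factors=model.n_factors_selected, outlier_report=report, **stats)
    return CalibrationOutcome(result=result, model=model, fitted_treatment=fitted_t,
                              cv=cv, kept_indices=keep)


def grid_search(s: SpectraSet, y: np.ndarray, treatments: list,
                constituent: str = "", outlier_config: OutlierConfig | None = None,
                n_groups: int = 6, n_factors_max: int | None = None,
                standardize_residuals: bool = True, seed: int | None = None):
    """Calibrate every treatment and rank by (SECV asc, RSQ desc, order).

    Returns ``(ranked outcomes, failures)`` where failures is a list of
    (treatment, message).  Raises :class:`DataError` if every treatment
    fails.
    """
    if not treatments:
        raise ConfigurationError("treatment grid is empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(treatments))
    outcomes, failures = [], []
    for order, (treatment, child) in enumerate(zip(treatments, children)):
        try:
            out = calibrate_treatment(
                s, y, treatment, constituent=constituent, outlier_config=outlier_config,
                n_groups=n_groups, n_factors_max=n_factors_max,
                standardize_residuals=standardize_residuals,
                rng=np.random.default_rng(child))
        except (DataError, ConfigurationError) as exc:
            failures.append((treatment, str(exc)))
            continue
        outcomes.append((order, out))
    if not outcomes:
        raise DataError(
            "all treatments failed: " + "; ".join(f"{t.label}: {m}" for t, m in failures))
    outcomes.sort(key=lambda pair: (pair[1].result.secv, -pair[1].result.rsq, pair[0]))
    return [out for _, out in outcomes], failures
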