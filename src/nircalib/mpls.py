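"""Modified partial least squares (MPLS) regression, PLS1 variant.

Ordinary PLS1 extracts factors by projecting the centred spectra onto the
covariance direction with the response and deflating both.  The "modified"
variant additionally standardizes the spectral residuals after each
factor: every wavelength column of the deflated matrix is divided by its
residual standard deviation before the next factor is extracted, so later
factors weight all wavelengths equally regardless of how much variance the
earlier factors left behind.  Only the spectral (X) residuals are scaled;
the response residual is left alone.

Prediction replays the exact fit recursion — centring, per-factor score
projection, deflation and residual scaling — so a model is a full record
of its per-factor artifacts, serializable to JSON.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

_SD_GUARD = 1e-12


@dataclass
class MPLSModel:
    x_center: np.ndarray
    y_center: float
    weights: list            # per-factor unit weight vectors (standardized space)
    loadings: list           # per-factor x-loading vectors
    y_loadings: list         # per-factor score-regression scalars q_k
    scalings: list           # per-factor residual-SD column scalings
    n_factors_max: int       # requested
    n_factors_available: int  # actually extracted (may stop early on rank deficiency)
    standardize_residuals: bool
    rank_deficient: bool = False
    n_factors_selected: int | None = None
    fitted_values: np.ndarray | None = None  # (n, available+1); column k = k-factor fit
    constituent: str | None = None
    sample_ids: list | None = None
    treatment_label: str | None = None

    def to_dict(self) -> dict:
        return {
            "x_center": self.x_center.tolist(),
            "y_center": float(self.y_center),
            "weights": [w.tolist() for w in self.weights],
            "loadings": [p.tolist() for p in self.loadings],
            "y_loadings": [float(q) for q in self.y_loadings],
            "scalings": [s.tolist() for s in self.scalings],
            "n_factors_max": self.n_factors_max,
            "n_factors_available": self.n_factors_available,
            "standardize_residuals": self.standardize_residuals,
            "rank_deficient": self.rank_deficient,
            "n_factors_selected": self.n_factors_selected,
            "constituent": self.constituent,
            "sample_ids": self.sample_ids,
            "treatment_label": self.treatment_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MPLSModel":
        return cls(
            x_center=np.asarray(d["x_center"], float),
            y_center=float(d["y_center"]),
            weights=[np.asarray(w, float) for w in d["weights"]],
            loadings=[np.asarray(p, float) for p in d["loadings"]],
            y_loadings=[float(q) for q in d["y_loadings"]],
            scalings=[np.asarray(s, float) for s in d["scalings"]],
            n_factors_max=int(d["n_factors_max"]),
            n_factors_available=int(d["n_factors_available"]),
            standardize_residuals=bool(d["standardize_residuals"]),
            rank_deficient=bool(d["rank_deficient"]),
            n_factors_selected=d.get("n_factors_selected"),
            constituent=d.get("constituent"),
            sample_ids=d.get("sample_ids"),
            treatment_label=d.get("treatment_label"),
        )


def fit_mpls(X: np.ndarray, y: np.ndarray, n_factors_max: int,
             standardize_residuals: bool = True) -> MPLSModel:
    """Fit an MPLS (or plain PLS1 when standardization is off) model.

    Factor extraction per step k on the working residuals (Xw, yw):
    weight w ∝ Xwᵀyw (unit norm), scores t = Xw w, loading p = Xwᵀt/(tᵀt),
    y-regression q = ywᵀt/(tᵀt); deflate Xw ← Xw − t pᵀ, yw ← yw − q t;
    then (if standardizing) divide each column of Xw by its residual SD
    (SD < 1e-12 → scale 1).  Stops early, flagged ``rank_deficient``, if
    the weight or score norm vanishes.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise DataError("X row count must match length of y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DataError("X and y must be free of NaN/inf")
    if n < n_factors_max + 2:
        raise DataError(f"need at least n_factors_max + 2 = {n_factors_max + 2} samples, got {n}")

    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xw = X - x_center
    yw = y - y_center

    weights, loadings, qs, scalings = [], [], [], []
    fitted = [np.full(n, y_center)]
    rank_deficient = False
    for _ in range(n_factors_max):
        w = Xw.T @ yw
        nw = np.linalg.norm(w)
        if nw < _SD_GUARD:
            rank_deficient = True
            break
        w = w / nw
        t = Xw @ w
        tt = float(t @ t)
        if tt < _SD_GUARD ** 2:
            rank_deficient = True
            break
        pvec = Xw.T @ t / tt
        q = float(yw @ t / tt)
        Xw = Xw - np.outer(t, pvec)
        yw = yw - q * t
        if standardize_residuals:
            sd = Xw.std(axis=0, ddof=1)
            scale = np.where(sd < _SD_GUARD, 1.0, sd)
            Xw = Xw / scale
        else:
            scale = np.ones(p)
        weights.append(w)
        loadings.append(pvec)
        qs.append(q)
        scalings.append(scale)
        fitted.append(y - yw)

    return MPLSModel(
        x_center=x_center,
        y_center=y_center,
        weights=weights,
        loadings=loadings,
        y_loadings=qs,
        scalings=scalings,
        n_factors_max=n_factors_max,
        n_factors_available=len(weights),
        standardize_residuals=standardize_residuals,
        rank_deficient=rank_deficient,
        fitted_values=np.column_stack(fitted),
    )


def predict(model: MPLSModel, X_new: np.ndarray, n_factors: int | None = None) -> np.ndarray:
    """Predict by replaying the fit recursion on new (identically pretreated) spectra."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.x_center.size:
        raise DataError(
            f"channel count mismatch: model has {model.x_center.size}, input has {X_new.shape[1]}"
        )
    if n_factors is None:
        n_factors = (model.n_factors_selected
                     if model.n_factors_selected is not None
                     else model.n_factors_available)
    if n_factors > model.n_factors_max:
        raise DataError(f"n_factors={n_factors} exceeds n_factors_max={model.n_factors_max}")
    k_use = min(n_factors, model.n_factors_available)
    Xw = X_new - model.x_center
    yhat = np.full(X_new.shape[0], model.y_center)
    for k in range(k_use):
        t = Xw @ model.weights[k]
        yhat = yhat + model.y_loadings[k] * t
        Xw = Xw - np.outer(t, model.loadings[k])
        Xw = Xw / model.scalings[k]
    return yhat


@dataclass
class PCAResult:
    n_components: int
    explained: np.ndarray    # fraction of variance per component
    scores: np.ndarray
    loadings: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained)


def pca_describe(X: np.ndarray, variance_target: float = 0.996) -> PCAResult:
    """Mean-centred SVD description of a spectra matrix.

    ``n_components`` is the smallest k whose cumulative explained variance
    reaches ``variance_target`` (default 99.6%).
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("PCA needs at least two spectra")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total < 1e-300:
        raise DataError("PCA of an all-identical spectra set is degenerate")
    explained = s ** 2 / total
    n_components = int(np.searchsorted(np.cumsum(explained), variance_target - 1e-12) + 1)
    n_components = min(n_components, len(s))
    return PCAResult(
        n_components=n_components,
        explained=explained,
        scores=U * s,
        loadings=Vt,
    )
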