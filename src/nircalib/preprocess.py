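"""Scatter corrections and derivative/smoothing math treatments.

A treatment is a scatter correction (none, SNV, MSC, Detrend or SNV-DT)
followed by a four-digit code ``d,g,s1,s2``: derivative order, derivative
gap in channels, first smoothing window and second smoothing window
(window 1 = no smoothing).  The code ``0,0,1,1`` is the identity.

Conventions, stated because the code digits alone do not pin them down:

* spectrum standard deviations use the n−1 denominator;
* the gap derivative is the forward difference ``y[i] = x[i+g] − x[i]``
  applied ``d`` times, each application shortening the spectrum by ``g``;
* smoothing is a running mean over the window (not Savitzky–Golay);
* wavelengths are relabelled to the midpoint of each window, and edges
  shrink the valid range rather than padding;
* MSC regresses each spectrum on a reference spectrum (default: the mean
  of the set it was fitted on) and returns ``(x − a)/b``; the reference is
  kept so new spectra are corrected against the calibration reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .spectra import ABSORBANCE, SpectraSet

SCATTER_OPTIONS = ("none", "snv", "msc", "detrend", "snv-dt")

_DISPLAY = {
    "none": "None",
    "snv": "SNV only",
    "msc": "Standard MSC",
    "detrend": "Detrend only",
    "snv-dt": "SNV-DT",
}

_ALIASES = {
    "none": "none", "raw": "none",
    "snv": "snv", "snv only": "snv", "standard normal variate": "snv",
    "standard normal variant": "snv",
    "msc": "msc", "standard msc": "msc", "multiplicative scatter correction": "msc",
    "multiplicative dispersion correction": "msc",
    "detrend": "detrend", "detrend only": "detrend", "dt": "detrend",
    "snv-dt": "snv-dt", "snv dt": "snv-dt", "snv-detrend": "snv-dt", "snvdt": "snv-dt",
}


@dataclass(frozen=True)
class MathTreatment:
    """Scatter correction plus derivative/gap/smoothing code."""

    scatter: str = "none"
    code: tuple = (0, 0, 1, 1)

    def __post_init__(self) -> None:
        if self.scatter not in SCATTER_OPTIONS:
            raise ConfigurationError(
                f"scatter must be one of {SCATTER_OPTIONS}, got {self.scatter!r}"
            )
        object.__setattr__(self, "code", tuple(int(c) for c in self.code))
        validate_code(self.code)

    @property
    def label(self) -> str:
        d, g, s1, s2 = self.code
        return f"{_DISPLAY[self.scatter]} {d},{g},{s1},{s2}"


def validate_code(code) -> None:
    if len(code) != 4:
        raise ConfigurationError("math code needs exactly four digits (d, g, s1, s2)")
    d, g, s1, s2 = code
    if min(d, g) < 0 or min(s1, s2) < 1:
        raise ConfigurationError(f"invalid math code {code}: need d,g >= 0 and s1,s2 >= 1")
    if d >= 1 and g < 1:
        raise ConfigurationError(f"invalid math code {code}: a derivative needs gap g >= 1")


def parse_treatment(text: str) -> MathTreatment:
    """Parse a display string such as ``"SNV only 0,0,1,1"`` (case-insensitive)."""
    t = text.strip().lower()
    m = re.match(r"^(.*?)[\s,]*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)$", t)
    if m:
        name, code = m.group(1).strip(), tuple(int(m.group(i)) for i in range(2, 6))
    else:
        name, code = t, (0, 0, 1, 1)
    if name not in _ALIASES:
        raise ConfigurationError(f"unrecognized treatment {text!r}")
    return MathTreatment(_ALIASES[name], code)


# ---------------------------------------------------------------------------
# scatter corrections (all operate on rows of a 2-D matrix)

def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: z-score each spectrum (n−1 denominator)."""
    x = np.atleast_2d(np.asarray(values, float))
    if x.shape[1] < 2:
        raise DataError("SNV needs at least two channels")
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd < 1e-300) or not np.all(np.isfinite(sd)):
        raise DataError("SNV is undefined for a constant (zero-SD) spectrum")
    out = (x - x.mean(axis=1, keepdims=True)) / sd
    return out if np.asarray(values).ndim == 2 else out[0]


def msc_reference(values: np.ndarray) -> np.ndarray:
    """Mean spectrum of a set, the default MSC reference."""
    x = np.asarray(values, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DataError("fitting an MSC reference needs at least two spectra")
    return x.mean(axis=0)


def msc(values: np.ndarray, reference: np.ndarray | None = None):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is fitted as ``x ≈ a + b*ref`` by ordinary least squares
    over channels and replaced by ``(x − a)/b``.  Returns
    ``(corrected, reference, a, b)``.
    """
    x = np.atleast_2d(np.asarray(values, float))
    ref = msc_reference(x) if reference is None else np.asarray(reference, float)
    if ref.shape != (x.shape[1],):
        raise DataError("MSC reference length must match the channel count")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom < 1e-300:
        raise DataError("MSC reference spectrum is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < 1e-12):
        raise DataError("degenerate MSC fit: slope |b| < 1e-12 for some spectrum")
    a = x.mean(axis=1) - b * ref.mean()
    corrected = (x - a[:, None]) / b[:, None]
    if np.asarray(values).ndim == 1:
        return corrected[0], ref, a[0], b[0]
    return corrected, ref, a, b


def detrend(values: np.ndarray, wavelengths: np.ndarray, order: int = 2) -> np.ndarray:
    """Subtract the least-squares polynomial of given order in wavelength."""
    x = np.atleast_2d(np.asarray(values, float))
    wl = np.asarray(wavelengths, float)
    if x.shape[1] <= order:
        raise DataError(f"detrend of order {order} needs more than {order} channels")
    # centred/scaled basis for conditioning; residuals are basis-invariant
    z = (wl - wl.mean()) / (wl.std() if wl.std() > 0 else 1.0)
    V = np.vander(z, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, x.T, rcond=None)
    out = x - (V @ coef).T
    return out if np.asarray(values).ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# derivative / smoothing code

def moving_average(values: np.ndarray, wavelengths: np.ndarray, window: int):
    """Running mean over ``window`` points; shrinks the grid by window−1."""
    if window < 1:
        raise ConfigurationError("smoothing window must be >= 1")
    x = np.atleast_2d(np.asarray(values, float))
    wl = np.asarray(wavelengths, float)
    if window == 1:
        return (x if np.asarray(values).ndim == 2 else x[0]), wl.copy()
    if x.shape[1] < window:
        raise DataError(f"smoothing window {window} exceeds {x.shape[1]} channels")
    kernel = np.ones(window) / window
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, x)
    wl_out = np.convolve(wl, kernel, mode="valid")
    return (out if np.asarray(values).ndim == 2 else out[0]), wl_out


def gap_derivative(values: np.ndarray, wavelengths: np.ndarray, gap: int):
    """Forward gap difference ``y[i] = x[i+g] − x[i]``; midpoint wavelengths."""
    if gap < 1:
        raise ConfigurationError("derivative gap must be >= 1")
    x = np.atleast_2d(np.asarray(values, float))
    wl = np.asarray(wavelengths, float)
    if x.shape[1] <= gap:
        raise DataError(f"gap {gap} leaves no channels from {x.shape[1]}")
    out = x[:, gap:] - x[:, :-gap]
    wl_out = 0.5 * (wl[gap:] + wl[:-gap])
    return (out if np.asarray(values).ndim == 2 else out[0]), wl_out


def apply_math_code(values: np.ndarray, wavelengths: np.ndarray, code):
    """Apply smoothing(s1) → d gap derivatives → smoothing(s2).

    Output channel count is ``n − d·g − (s1−1) − (s2−1)``; fewer than two
    remaining channels is an error.
    """
    validate_code(code)
    d, g, s1, s2 = (int(c) for c in code)
    n = np.atleast_2d(values).shape[1]
    remaining = n - d * g - (s1 - 1) - (s2 - 1)
    if remaining < 2:
        raise DataError(f"math code {tuple(code)} leaves {remaining} channels from {n}")
    x, wl = moving_average(values, wavelengths, s1)
    for _ in range(d):
        x, wl = gap_derivative(x, wl, g)
    x, wl = moving_average(x, wl, s2)
    return x, wl


# ---------------------------------------------------------------------------
# full treatment on a SpectraSet

@dataclass
class FittedTreatment:
    """A treatment bound to its fitted state (the MSC reference spectrum).

    Validation spectra must be corrected against the calibration reference,
    so the reference learned at fit time is stored and replayed by
    :meth:`transform`.
    """

    treatment: MathTreatment
    detrend_order: int = 2
    msc_ref: np.ndarray | None = None

    def transform(self, s: SpectraSet) -> SpectraSet:
        if s.mode != ABSORBANCE:
            raise DataError("treatments apply to absorbance spectra; convert first")
        x, wl = s.values, s.wavelengths
        scatter = self.treatment.scatter
        if scatter == "snv":
            x = snv(x)
        elif scatter == "msc":
            if self.msc_ref is None:
                raise DataError("MSC treatment has no fitted reference; use apply_treatment")
            x, _, _, _ = msc(x, self.msc_ref)
        elif scatter == "detrend":
            x = detrend(x, wl, self.detrend_order)
        elif scatter == "snv-dt":
            x = detrend(snv(x), wl, self.detrend_order)
        x, wl = apply_math_code(x, wl, self.treatment.code)
        return s.with_values(x, wl)


def apply_treatment(s: SpectraSet, treatment: MathTreatment, *,
                    msc_ref: np.ndarray | None = None, detrend_order: int = 2):
    """Fit-and-apply a treatment; returns ``(treated set, FittedTreatment)``.

    For MSC the reference defaults to the mean spectrum of ``s`` and is
    recorded in the returned :class:`FittedTreatment`.
    """
    ref = msc_ref
    if treatment.scatter == "msc" and ref is None:
        if s.mode != ABSORBANCE:
            raise DataError("treatments apply to absorbance spectra; convert first")
        ref = msc_reference(s.values)
    fitted = FittedTreatment(treatment=treatment, detrend_order=detrend_order, msc_ref=ref)
    return fitted.transform(s), fitted
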