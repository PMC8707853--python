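"""External validation statistics, descriptive tables and group comparison.

External validation compares NIR predictions with reference chemistry on
samples the calibration never saw.  With residuals e = y_ref − y_pred:

* bias = mean(e)
* RMSE = SEP = sqrt(Σe²/n)                (uncorrected, denominator n)
* SEP(C) = sqrt(Σ(e − bias)²/(n − 1))      (bias-corrected)
* paired t = bias / (SEP(C)/√n), df = n − 1, two-sided

so SEP² = bias² + SEP(C)²·(n−1)/n holds as an identity.  The validation
verdict is "no difference" between methods when p > 0.05.

"Mean residual" is reported as the mean absolute residual (the signed
mean is the bias and is reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError


@dataclass
class ValidationResult:
    constituent: str
    n: int
    bias: float
    mean_residual: float   # mean absolute residual
    rmse: float
    sep: float
    sep_c: float
    t_statistic: float
    p_value: float
    no_difference: bool    # True when the paired test does not reject at alpha=0.05

    def to_dict(self) -> dict:
        return {
            "constituent": self.constituent,
            "n": self.n,
            "bias": self.bias,
            "mean_residual": self.mean_residual,
            "rmse": self.rmse,
            "SEP": self.sep,
            "SEP_C": self.sep_c,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "no_difference": self.no_difference,
        }


def external_validate(y_ref, y_pred, constituent: str = "", alpha: float = 0.05) -> ValidationResult:
    """Validation statistics and the paired Student's t comparison."""
    y_ref = np.asarray(y_ref, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    n = len(y_ref)
    if len(y_pred) != n:
        raise DataError("reference and prediction vectors must have equal length")
    if n < 3:
        raise DataError("external validation needs at least 3 samples")
    e = y_ref - y_pred
    bias = float(np.mean(e))
    mean_abs = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e ** 2)))
    sep_c = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    if sep_c < 1e-300:
        if abs(bias) < 1e-300:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.inf) * np.sign(bias), 0.0
    else:
        t = bias / (sep_c / np.sqrt(n))
        p = float(2 * sps.t.sf(abs(t), df=n - 1))
    return ValidationResult(
        constituent=constituent, n=n, bias=bias, mean_residual=mean_abs,
        rmse=rmse, sep=rmse, sep_c=sep_c, t_statistic=float(t), p_value=float(p),
        no_difference=bool(p > alpha),
    )


def describe(values, labels=None) -> pd.DataFrame:
    """Mean, sample SD (n−1), min, max and n per group plus the overall row."""
    values = np.asarray(values, float).ravel()
    if values.size == 0:
        raise DataError("describe needs at least one value")
    if labels is None:
        labels = ["all"] * values.size
    labels = np.asarray(labels, dtype=object)
    rows = []
    group_names = list(dict.fromkeys(labels))
    for g in group_names:
        v = values[labels == g]
        rows.append((g, len(v), float(np.mean(v)),
                     float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                     float(np.min(v)), float(np.max(v))))
    if len(group_names) > 1:
        rows.append(("overall", len(values), float(np.mean(values)),
                     float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                     float(np.min(values)), float(np.max(values))))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "SD", "min", "max"]).set_index("group")


def compare_groups(values, labels):
    """Kruskal–Wallis rank test across groups; ``(H, p)``.

    With every value identical the test is undefined and (0, 1) is
    returned by convention.
    """
    values = np.asarray(values, float).ravel()
    labels = np.asarray(labels, dtype=object)
    groups = [values[labels == g] for g in dict.fromkeys(labels)]
    if len(groups) < 2:
        raise DataError("group comparison needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise DataError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)
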