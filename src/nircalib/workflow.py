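"""End-to-end helpers: serializable calibration bundles and prediction.

A :class:`CalibrationBundle` packages everything needed to apply a
calibration to new spectra: the fitted treatment (including the MSC
reference learned on the calibration set), the MPLS model, the expected
raw wavelength grid and the calibration statistics.  JSON serialization
keeps full float precision (Python's repr round-trips doubles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .calibrate import CalibrationOutcome
from .errors import DataError
from .mpls import MPLSModel, predict
from .preprocess import FittedTreatment, MathTreatment
from .spectra import ABSORBANCE, REFLECTANCE, SpectraSet, average_replicates, to_absorbance


@dataclass
class CalibrationBundle:
    constituent: str
    wavelengths: np.ndarray          # raw grid the treatment expects
    fitted_treatment: FittedTreatment
    model: MPLSModel
    stats: dict                      # the CalibrationResult row
    provenance: dict                 # seed, retained ids, grid size, ...

    def to_dict(self) -> dict:
        return {
            "constituent": self.constituent,
            "wavelengths": self.wavelengths.tolist(),
            "treatment": {
                "scatter": self.fitted_treatment.treatment.scatter,
                "code": list(self.fitted_treatment.treatment.code),
                "detrend_order": self.fitted_treatment.detrend_order,
                "msc_ref": (None if self.fitted_treatment.msc_ref is None
                            else self.fitted_treatment.msc_ref.tolist()),
            },
            "model": self.model.to_dict(),
            "stats": self.stats,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationBundle":
        t = d["treatment"]
        fitted = FittedTreatment(
            treatment=MathTreatment(t["scatter"], tuple(t["code"])),
            detrend_order=int(t["detrend_order"]),
            msc_ref=None if t["msc_ref"] is None else np.asarray(t["msc_ref"], float),
        )
        return cls(
            constituent=d["constituent"],
            wavelengths=np.asarray(d["wavelengths"], float),
            fitted_treatment=fitted,
            model=MPLSModel.from_dict(d["model"]),
            stats=d["stats"],
            provenance=d.get("provenance", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CalibrationBundle":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def bundle_from_outcome(outcome: CalibrationOutcome, wavelengths: np.ndarray,
                        provenance: dict | None = None) -> CalibrationBundle:
    return CalibrationBundle(
        constituent=outcome.result.constituent,
        wavelengths=np.asarray(wavelengths, float),
        fitted_treatment=outcome.fitted_treatment,
        model=outcome.model,
        stats=outcome.result.to_row(),
        provenance=provenance or {},
    )


def prepare_sample_matrix(s: SpectraSet) -> SpectraSet:
    """Convert to absorbance if needed and average replicates if present."""
    if s.mode == REFLECTANCE:
        s = to_absorbance(s)
    if s.replicate_ids is not None:
        s = average_replicates(s)
    return s


def predict_spectra(bundle: CalibrationBundle, s: SpectraSet) -> np.ndarray:
    """Predict the bundle's constituent for new spectra.

    Input may be reflectance and/or contain replicates; it is converted and
    averaged, checked against the calibration wavelength grid, pretreated
    with the stored fitted treatment, and passed through the MPLS model at
    the selected factor count.
    """
    s = prepare_sample_matrix(s)
    if s.n_channels != bundle.wavelengths.size or not np.allclose(
            s.wavelengths, bundle.wavelengths, rtol=0, atol=1e-6):
        raise DataError("spectra are not on the calibration wavelength grid")
    treated = bundle.fitted_treatment.transform(s)
    return predict(bundle.model, treated.values)
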