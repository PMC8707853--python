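"""Synthetic NIR spectra of potato tubers with known composition.

Emulates the structure of a two-cultivar diffuse-reflectance study:
reference values (dry matter %, reducing sugars g/100 g) are drawn from
per-cultivar truncated normals, and each sample's latent absorbance
spectrum is a Beer–Lambert-style mixture of Gaussian absorption bands
tied to moisture (100 − dry matter), dry matter and reducing sugars,
plus a per-sample linear baseline.  Each replicate scan perturbs the
latent spectrum with a multiplicative scatter factor, a replicate-level
offset and independent per-channel noise.

The defaults mirror the study conditions: 89 samples (Kennebec 48,
Agria 41) x 6 replicates on a 900–1698 nm grid at 6 nm steps (134
channels), split 70/19 into calibration and validation groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .spectra import ABSORBANCE, SpectraSet

_MAX_REJECTION_ROUNDS = 10_000


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band of a constituent.

    ``amplitude`` is absorbance per unit concentration at the band centre;
    ``width`` is the Gaussian sigma in nm.
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ConfigurationError("band width must be > 0")
        if not np.isfinite(self.amplitude):
            raise ConfigurationError("band amplitude must be finite")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wavelengths - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class CultivarSpec:
    """Truncated-normal parameters of one cultivar population."""

    label: str
    n: int
    dry_matter: tuple[float, float, float, float]  # mean, sd, min, max
    reducing_sugars: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("cultivar n must be >= 1")
        for name in ("dry_matter", "reducing_sugars"):
            mean, sd, lo, hi = getattr(self, name)
            if sd < 0:
                raise ConfigurationError(f"{self.label}/{name}: SD must be >= 0")
            if not lo < hi:
                raise ConfigurationError(f"{self.label}/{name}: require min < max, got [{lo}, {hi}]")


def _default_bands() -> dict:
    # Plausible NIR assignments: water overtone/combination bands dominate the
    # intact-tuber spectrum; carbohydrate and sugar features are weak shoulders.
    return {
        "moisture": [
            ComponentBand(970.0, 35.0, 0.004),
            ComponentBand(1190.0, 40.0, 0.006),
            ComponentBand(1450.0, 45.0, 0.012),
        ],
        "dry_matter": [
            ComponentBand(1200.0, 30.0, 0.010),
            ComponentBand(1580.0, 40.0, 0.008),
        ],
        "reducing_sugars": [
            ComponentBand(1430.0, 25.0, 0.30),
            ComponentBand(1690.0, 30.0, 0.225),
        ],
    }


def _default_cultivars() -> list:
    return [
        CultivarSpec("Kennebec", 48, (19.88, 1.63, 16.00, 22.10), (0.23, 0.09, 0.15, 0.49)),
        CultivarSpec("Agria", 41, (20.19, 1.04, 17.30, 22.20), (0.15, 0.04, 0.10, 0.37)),
    ]


@dataclass
class SyntheticConfig:
    """Full description of a simulated acquisition campaign.

    Noise fields are in absorbance units except ``scatter_slope_sd``
    (dimensionless multiplicative scatter per replicate) and
    ``baseline_slope_sd`` (absorbance per nm).
    """

    wavelength_start: float = 900.0
    wavelength_end: float = 1700.0
    wavelength_step: float = 6.0
    n_replicates: int = 6
    cultivar_specs: list = field(default_factory=_default_cultivars)
    component_bands: dict = field(default_factory=_default_bands)
    baseline_offset_sd: float = 0.02
    baseline_slope_sd: float = 2e-5
    scatter_slope_sd: float = 0.05
    replicate_noise_sd: float = 0.01
    channel_noise_sd: float = 0.055
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength_step <= 0:
            raise ConfigurationError("wavelength_step must be > 0")
        if self.wavelength_grid().size < 2:
            raise ConfigurationError("wavelength grid must have at least 2 channels")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for name in ("baseline_offset_sd", "baseline_slope_sd", "scatter_slope_sd",
                     "replicate_noise_sd", "channel_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.cultivar_specs:
            raise ConfigurationError("at least one cultivar spec is required")

    @property
    def n_samples(self) -> int:
        return sum(c.n for c in self.cultivar_specs)

    def wavelength_grid(self) -> np.ndarray:
        """Grid start + k*step for every k with the value <= end."""
        n = int(np.floor((self.wavelength_end - self.wavelength_start) / self.wavelength_step + 1e-9)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    def to_dict(self) -> dict:
        return {
            "wavelength_start": self.wavelength_start,
            "wavelength_end": self.wavelength_end,
            "wavelength_step": self.wavelength_step,
            "n_replicates": self.n_replicates,
            "cultivar_specs": [
                {"label": c.label, "n": c.n, "dry_matter": list(c.dry_matter),
                 "reducing_sugars": list(c.reducing_sugars)}
                for c in self.cultivar_specs
            ],
            "component_bands": {
                k: [{"center": b.center, "width": b.width, "amplitude": b.amplitude} for b in v]
                for k, v in self.component_bands.items()
            },
            "baseline_offset_sd": self.baseline_offset_sd,
            "baseline_slope_sd": self.baseline_slope_sd,
            "scatter_slope_sd": self.scatter_slope_sd,
            "replicate_noise_sd": self.replicate_noise_sd,
            "channel_noise_sd": self.channel_noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "cultivar_specs" in d:
            d["cultivar_specs"] = [
                CultivarSpec(c["label"], c["n"], tuple(c["dry_matter"]), tuple(c["reducing_sugars"]))
                for c in d["cultivar_specs"]
            ]
        if "component_bands" in d:
            d["component_bands"] = {
                k: [ComponentBand(b["center"], b["width"], b["amplitude"]) for b in v]
                for k, v in d["component_bands"].items()
            }
        return cls(**d)


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def truncated_normal(mean: float, sd: float, lo: float, hi: float, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw by rejection: resample out-of-bounds values until all land in [lo, hi].

    With sd = 0 every draw is exactly the mean (which must lie in bounds).
    """
    if not lo < hi:
        raise ConfigurationError(f"truncation bounds require min < max, got [{lo}, {hi}]")
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ConfigurationError(f"degenerate mean {mean} outside bounds [{lo}, {hi}]")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(_MAX_REJECTION_ROUNDS):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ConfigurationError(
        f"rejection sampling did not converge for N({mean}, {sd}) on [{lo}, {hi}]"
    )


def generate_reference(config: SyntheticConfig, rng_state=None) -> pd.DataFrame:
    """Draw per-sample reference chemistry from the cultivar populations.

    Returns a DataFrame indexed by sample id with columns
    ``cultivar, dry_matter, reducing_sugars``.
    """
    rng = _as_rng(config.seed if rng_state is None else rng_state)
    rows = []
    counter = 0
    for spec in config.cultivar_specs:
        dm = truncated_normal(*spec.dry_matter, spec.n, rng)
        rs = truncated_normal(*spec.reducing_sugars, spec.n, rng)
        for i in range(spec.n):
            counter += 1
            rows.append((f"S{counter:03d}", spec.label, dm[i], rs[i]))
    df = pd.DataFrame(rows, columns=["sample_id", "cultivar", "dry_matter", "reducing_sugars"])
    return df.set_index("sample_id")


def _constituent_concentration(name: str, refs: pd.DataFrame, sample_id: str) -> float:
    if name == "moisture":
        return 100.0 - float(refs.loc[sample_id, "dry_matter"])
    if name not in refs.columns:
        raise DataError(f"component_bands refers to unknown constituent {name!r}")
    return float(refs.loc[sample_id, name])


def latent_spectrum(config: SyntheticConfig, refs: pd.DataFrame, sample_id: str,
                    baseline_offset: float = 0.0, baseline_slope: float = 0.0) -> np.ndarray:
    """Noise-free absorbance of one sample: band mixture plus linear baseline."""
    wl = config.wavelength_grid()
    spec = np.full(wl.shape, baseline_offset) + baseline_slope * wl
    for name, bands in config.component_bands.items():
        conc = _constituent_concentration(name, refs, sample_id)
        for band in bands:
            spec += conc * band.profile(wl)
    return spec


def generate_spectra(config: SyntheticConfig, refs: pd.DataFrame, rng_state=None) -> SpectraSet:
    """Simulate replicate absorbance spectra for every sample in ``refs``."""
    rng = _as_rng(config.seed if rng_state is None else rng_state)
    wl = config.wavelength_grid()
    sample_ids = list(refs.index)
    n = len(sample_ids)
    if n == 0:
        raise DataError("reference table is empty")
    rows = []
    out_ids, out_reps, out_cults = [], [], []
    has_cult = "cultivar" in refs.columns
    for sid in sample_ids:
        offset = rng.normal(0.0, config.baseline_offset_sd)
        slope = rng.normal(0.0, config.baseline_slope_sd)
        latent = latent_spectrum(config, refs, sid, offset, slope)
        for rep in range(1, config.n_replicates + 1):
            scatter = 1.0 + rng.normal(0.0, config.scatter_slope_sd)
            rep_offset = rng.normal(0.0, config.replicate_noise_sd)
            noise = rng.normal(0.0, config.channel_noise_sd, wl.size)
            rows.append(scatter * latent + rep_offset + noise)
            out_ids.append(sid)
            out_reps.append(rep)
            if has_cult:
                out_cults.append(str(refs.loc[sid, "cultivar"]))
    return SpectraSet(
        wavelengths=wl,
        values=np.vstack(rows),
        sample_ids=out_ids,
        mode=ABSORBANCE,
        replicate_ids=out_reps,
        cultivars=out_cults if has_cult else None,
    )


def split_calibration_validation(sample_ids, n_cal: int, n_val: int, rng_state=None):
    """Random disjoint exhaustive partition of ``sample_ids`` into (cal, val)."""
    ids = list(sample_ids)
    if n_cal + n_val != len(ids):
        raise ConfigurationError(
            f"n_cal + n_val = {n_cal + n_val} does not match {len(ids)} samples"
        )
    rng = _as_rng(rng_state)
    perm = rng.permutation(len(ids))
    cal = [ids[i] for i in sorted(perm[:n_cal])]
    val = [ids[i] for i in sorted(perm[n_cal:])]
    return cal, val
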