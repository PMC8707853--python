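"""Spectra and reference-table containers with CSV round-trip I/O.

The working unit of NIR chemometrics is pseudo-absorbance ``log10(1/R)``
computed from diffuse reflectance ``R``.  A :class:`SpectraSet` holds a
wavelengths-by-samples matrix in either mode, together with sample /
replicate / cultivar metadata; the reference chemistry (dry matter in %,
reducing sugars in g/100 g) travels in a plain :class:`pandas.DataFrame`
indexed by sample id.

The pipeline convention is: convert to absorbance first, then average
replicates.  Averaging in reflectance and converting afterwards gives a
different answer (Jensen's inequality), so :func:`average_replicates`
refuses to operate on reflectance data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

REFLECTANCE = "reflectance"
ABSORBANCE = "absorbance"

_WL_PREFIX = "wl_"


@dataclass
class SpectraSet:
    """A set of spectra on a common wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm, one entry per channel.
    values
        ``(n_spectra, n_channels)`` matrix of reflectance or absorbance.
    sample_ids
        One id per row; repeated ids denote replicates of the same sample.
    mode
        ``"reflectance"`` or ``"absorbance"``.
    replicate_ids
        Optional per-row replicate index; ``None`` once replicates are
        averaged.
    cultivars
        Optional per-row cultivar label.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list
    mode: str = ABSORBANCE
    replicate_ids: list | None = None
    cultivars: list | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise DataError("a SpectraSet needs at least two wavelength channels")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DataError("wavelengths must be strictly increasing")
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D (spectra x channels) matrix")
        if self.values.shape[1] != self.wavelengths.size:
            raise DataError(
                f"value matrix has {self.values.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} channels"
            )
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) != self.values.shape[0]:
            raise DataError("sample_ids length must match the number of rows")
        if self.mode not in (REFLECTANCE, ABSORBANCE):
            raise DataError(f"mode must be reflectance or absorbance, got {self.mode!r}")
        for name in ("replicate_ids", "cultivars"):
            meta = getattr(self, name)
            if meta is not None:
                meta = list(meta)
                if len(meta) != self.values.shape[0]:
                    raise DataError(f"{name} length must match the number of rows")
                setattr(self, name, meta)

    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    def with_values(self, values: np.ndarray, wavelengths: np.ndarray | None = None) -> "SpectraSet":
        """Return a copy with a new value matrix (and optionally a new grid)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            wavelengths=self.wavelengths if wavelengths is None else np.asarray(wavelengths, float),
        )


def to_absorbance(s: SpectraSet) -> SpectraSet:
    """Convert reflectance to absorbance ``log10(1/R)``.

    Raises :class:`DataError` naming the first offending cell if any
    reflectance is non-positive.
    """
    if s.mode != REFLECTANCE:
        raise DataError("to_absorbance expects a reflectance-mode SpectraSet")
    bad = np.argwhere(s.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"non-positive reflectance {s.values[i, j]!r} for sample "
            f"{s.sample_ids[i]!r} at wavelength {s.wavelengths[j]:g} nm"
        )
    out = replace(s, values=np.log10(1.0 / s.values))
    out.mode = ABSORBANCE
    return out


def average_replicates(s: SpectraSet) -> SpectraSet:
    """Average replicate rows into one spectrum per sample id.

    Only defined in absorbance mode: averaging reflectance and converting
    afterwards is not the same operation (log is concave), and the pipeline
    fixes the order convert-then-average.
    """
    if s.replicate_ids is None:
        raise DataError("average_replicates requires replicate ids")
    if s.mode != ABSORBANCE:
        raise DataError("replicates are averaged in absorbance space; convert first")
    order: list = []
    seen: dict = {}
    for sid in s.sample_ids:
        if sid not in seen:
            seen[sid] = len(order)
            order.append(sid)
    means = np.empty((len(order), s.n_channels))
    cultivars = [None] * len(order) if s.cultivars is not None else None
    ids_arr = np.asarray(s.sample_ids, dtype=object)
    for sid, k in seen.items():
        mask = ids_arr == sid
        if not mask.any():  # pragma: no cover - unreachable by construction
            raise DataError(f"sample {sid!r} has zero replicates")
        means[k] = s.values[mask].mean(axis=0)
        if cultivars is not None:
            labels = {s.cultivars[i] for i in np.flatnonzero(mask)}
            if len(labels) > 1:
                raise DataError(f"sample {sid!r} has inconsistent cultivar labels {labels}")
            cultivars[k] = labels.pop()
    return SpectraSet(
        wavelengths=s.wavelengths.copy(),
        values=means,
        sample_ids=order,
        mode=ABSORBANCE,
        replicate_ids=None,
        cultivars=cultivars,
    )


def _wl_column(w: float) -> str:
    if float(w).is_integer():
        return f"{_WL_PREFIX}{int(w):04d}"
    return f"{_WL_PREFIX}{w:.6g}"


def write_spectra(s: SpectraSet, path) -> None:
    """Write a SpectraSet to CSV (mode recorded on a leading ``#`` line)."""
    cols: dict = {"sample_id": s.sample_ids}
    if s.replicate_ids is not None:
        cols["replicate"] = s.replicate_ids
    if s.cultivars is not None:
        cols["cultivar"] = s.cultivars
    meta = pd.DataFrame(cols)
    wl_block = pd.DataFrame(s.values, columns=[_wl_column(w) for w in s.wavelengths])
    df = pd.concat([meta, wl_block], axis=1)
    with open(path, "w") as fh:
        fh.write(f"# mode={s.mode}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_spectra(path) -> SpectraSet:
    """Read a SpectraSet written by :func:`write_spectra`.

    Raises :class:`ParseError` with the offending line for ragged rows,
    non-numeric cells or out-of-order wavelength columns.
    """
    with open(path) as fh:
        first = fh.readline()
        mode = ABSORBANCE
        skip = 0
        if first.startswith("#"):
            skip = 1
            for token in first.lstrip("#").strip().split(","):
                if token.strip().startswith("mode="):
                    mode = token.strip().split("=", 1)[1]
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    wl_cols = [c for c in df.columns if c.startswith(_WL_PREFIX)]
    if len(wl_cols) < 2:
        raise ParseError(f"{path}: no '{_WL_PREFIX}*' wavelength columns found in header")
    try:
        wavelengths = np.array([float(c[len(_WL_PREFIX):]) for c in wl_cols])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed wavelength column name: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise ParseError(f"{path}: wavelength columns are not strictly increasing")
    for col in wl_cols:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(coerced.isna() & df[col].notna())
            row = int(bad[0]) if bad.size else int(np.flatnonzero(df[col].isna())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col} "
                f"at line {row + 2 + skip}"
            )
    values = df[wl_cols].to_numpy(dtype=float)
    return SpectraSet(
        wavelengths=wavelengths,
        values=values,
        sample_ids=df["sample_id"].astype(str).tolist(),
        mode=mode,
        replicate_ids=df["replicate"].tolist() if "replicate" in df.columns else None,
        cultivars=df["cultivar"].astype(str).tolist() if "cultivar" in df.columns else None,
    )


def write_reference(refs: pd.DataFrame, path) -> None:
    """Write a reference table (index = sample_id) to CSV."""
    refs.to_csv(path, index_label="sample_id", float_format="%.17g")


def read_reference(path) -> pd.DataFrame:
    """Read a reference table CSV into a DataFrame indexed by sample id.

    Constituent columns must be finite and non-negative; duplicate sample ids
    are rejected.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate sample ids in reference table: {sorted(set(dup))}")
    df = df.set_index("sample_id")
    for col in df.columns:
        if col == "cultivar":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col} "
                f"at line {row + 2}"
            )
        arr = vals.to_numpy(float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise DataError(f"reference column {col!r} must be finite and >= 0")
        df[col] = arr
    return df


def match_reference(s: SpectraSet, refs: pd.DataFrame, constituent: str) -> np.ndarray:
    """Return the constituent vector aligned to ``s.sample_ids``.

    Raises :class:`DataError` listing every spectra sample missing from the
    reference table.
    """
    if constituent not in refs.columns:
        raise DataError(f"constituent {constituent!r} not in reference table columns {list(refs.columns)}")
    missing = sorted(set(s.sample_ids) - set(refs.index))
    if missing:
        raise DataError(f"reference table is missing samples: {missing}")
    return refs.loc[s.sample_ids, constituent].to_numpy(dtype=float)
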