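"""Canopy reflectance spectra: containers, validation, I/O, resampling.

Every downstream operation (index evaluation, contour scans, PLSR) consumes
spectra on the canonical 1-nm integer grid covering 350-2500 nm (2151 bands),
the native output range of field spectroradiometers used for proximal canopy
sensing.  Spectra arriving on an instrument's raw sampling grid (e.g. 1.4 nm
in the VNIR and 2.2 nm in the SWIR) are linearly interpolated onto the
canonical grid; replicate scans of a plot are averaged pointwise before any
index is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WL_MIN = 350
WL_MAX = 2500
#: canonical integer-nanometre wavelength grid (2151 bands)
GRID = np.arange(WL_MIN, WL_MAX + 1)
N_BANDS = GRID.size

META_COLUMNS = ["plot_id", "genotype", "treatment", "year", "replicate"]
LONG_COLUMNS = META_COLUMNS + ["wavelength_nm", "reflectance"]


class SpectraFormatError(ValueError):
    """Raised for malformed spectra files or inconsistent inputs."""


@dataclass
class Spectrum:
    """A single plot-level reflectance spectrum with its design metadata."""

    plot_id: str
    genotype: str
    treatment: str
    year: str
    replicate: int
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise SpectraFormatError("wavelengths and reflectance length mismatch")
        if self.wavelengths.size < 2:
            raise SpectraFormatError("a spectrum needs at least two samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectraFormatError("non-finite reflectance values")
        if self.reflectance.min() < 0 or self.reflectance.max() > 1:
            raise SpectraFormatError("reflectance must lie in [0, 1]")

    @property
    def is_canonical(self) -> bool:
        return self.wavelengths.size == N_BANDS and np.array_equal(
            self.wavelengths, GRID
        )

    def value_at(self, wavelength_nm: int) -> float:
        """Reflectance at an exact integer wavelength on the canonical grid."""
        if not self.is_canonical:
            raise SpectraFormatError("value_at requires a canonical spectrum")
        return float(self.reflectance[int(wavelength_nm) - WL_MIN])


def resample_to_grid(spectrum: Spectrum) -> Spectrum:
    """Linearly interpolate a spectrum onto the canonical 1-nm grid.

    The input must cover [350, 2500] nm entirely; no extrapolation is
    performed.  A spectrum already on the canonical grid is returned
    unchanged (idempotence).
    """
    if spectrum.is_canonical:
        return spectrum
    wl = spectrum.wavelengths
    if wl[0] > WL_MIN or wl[-1] < WL_MAX:
        raise SpectraFormatError(
            f"input covers [{wl[0]:g}, {wl[-1]:g}] nm; full coverage of "
            f"[{WL_MIN}, {WL_MAX}] nm is required"
        )
    values = np.interp(GRID.astype(float), wl, spectrum.reflectance)
    return replace(spectrum, wavelengths=GRID.astype(float), reflectance=values)


def average_scans(scans: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate scans of one plot."""
    if len(scans) == 0:
        raise SpectraFormatError("average_scans needs at least one spectrum")
    first = scans[0]
    for s in scans[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise SpectraFormatError("scans are on different wavelength grids")
    mean = np.mean([s.reflectance for s in scans], axis=0)
    return replace(first, reflectance=mean)


@dataclass
class SpectraSet:
    """A collection of canonical spectra stored as a dense plot x band matrix.

    ``meta`` holds one row per plot (plot_id, genotype, treatment, year,
    replicate) in the same order as the rows of ``values``.
    """

    meta: pd.DataFrame
    values: np.ndarray
    provenance: str = ""
    wavelengths: np.ndarray = field(default_factory=lambda: GRID.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.wavelengths.size:
            raise SpectraFormatError("values must be (n_plots, n_bands)")
        if len(self.meta) != self.values.shape[0]:
            raise SpectraFormatError("meta rows and value rows differ")
        ids = self.meta["plot_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:3]
            raise SpectraFormatError(f"duplicate plot_ids: {list(dupes)}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def plot_ids(self) -> list[str]:
        return list(self.meta["plot_id"])

    def spectrum(self, plot_id: str) -> Spectrum:
        rows = self.meta.index[self.meta["plot_id"] == plot_id]
        if len(rows) == 0:
            raise KeyError(plot_id)
        row = self.meta.loc[rows[0]]
        return Spectrum(
            plot_id=str(row["plot_id"]),
            genotype=str(row["genotype"]),
            treatment=str(row["treatment"]),
            year=str(row["year"]),
            replicate=int(row["replicate"]),
            wavelengths=self.wavelengths.astype(float),
            reflectance=self.values[rows[0]].copy(),
        )

    def band(self, wavelength_nm: int) -> np.ndarray:
        """Column of reflectance values at an exact grid wavelength."""
        idx = int(wavelength_nm) - WL_MIN
        if idx < 0 or idx >= self.wavelengths.size:
            raise KeyError(f"{wavelength_nm} nm is outside the canonical grid")
        return self.values[:, idx]

    def subset(self, mask: np.ndarray | pd.Series) -> "SpectraSet":
        mask = np.asarray(mask, dtype=bool)
        return SpectraSet(
            meta=self.meta.loc[mask].reset_index(drop=True),
            values=self.values[mask],
            provenance=self.provenance,
            wavelengths=self.wavelengths,
        )

    @classmethod
    def from_spectra(cls, spectra: Iterable[Spectrum], provenance: str = "") -> "SpectraSet":
        spectra = [resample_to_grid(s) for s in spectra]
        if not spectra:
            raise SpectraFormatError("empty spectra collection")
        meta = pd.DataFrame(
            {
                "plot_id": [s.plot_id for s in spectra],
                "genotype": [s.genotype for s in spectra],
                "treatment": [s.treatment for s in spectra],
                "year": [s.year for s in spectra],
                "replicate": [s.replicate for s in spectra],
            }
        )
        values = np.vstack([s.reflectance for s in spectra])
        return cls(meta=meta, values=values, provenance=provenance)

    # ------------------------------------------------------------------ I/O

    def to_long_frame(self) -> pd.DataFrame:
        n, p = self.values.shape
        frame = self.meta.loc[self.meta.index.repeat(p)].reset_index(drop=True)
        frame["wavelength_nm"] = np.tile(self.wavelengths.astype(int), n)
        frame["reflectance"] = self.values.ravel()
        return frame

    def write_csv(self, path: str | Path, dialect: str = "long") -> None:
        path = Path(path)
        if dialect == "long":
            self.to_long_frame().to_csv(path, index=False)
        elif dialect == "wide":
            wide = self.meta.copy()
            cols = {f"w{int(w):04d}": self.values[:, i] for i, w in enumerate(self.wavelengths)}
            wide = pd.concat([wide, pd.DataFrame(cols, index=wide.index)], axis=1)
            wide.to_csv(path, index=False)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def _fail_rows(frame: pd.DataFrame, bad: pd.Series, message: str) -> None:
    if bad.any():
        rows = list(frame.index[bad][:5] + 2)  # +2: header line and 1-based
        raise SpectraFormatError(f"{message} (file rows {rows})")


def read_spectra(path: str | Path, dialect: str = "long") -> SpectraSet:
    """Read a spectra table and return a validated canonical SpectraSet.

    Long dialect: columns plot_id, genotype, treatment, year, replicate,
    wavelength_nm, reflectance.  Wide dialect: the key columns followed by
    one column per band named ``w0350`` ... ``w2500``.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if dialect == "wide":
        band_cols = [c for c in frame.columns if c.startswith("w") and c[1:].isdigit()]
        missing = [c for c in META_COLUMNS if c not in frame.columns]
        if missing:
            raise SpectraFormatError(f"missing key columns: {missing}")
        wavelengths = np.array(sorted(int(c[1:]) for c in band_cols))
        long_rows = frame.melt(
            id_vars=META_COLUMNS,
            value_vars=band_cols,
            var_name="wavelength_nm",
            value_name="reflectance",
        )
        long_rows["wavelength_nm"] = long_rows["wavelength_nm"].str[1:].astype(int)
        frame = long_rows
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise SpectraFormatError(f"missing columns: {missing}")

    refl = pd.to_numeric(frame["reflectance"], errors="coerce")
    _fail_rows(frame, refl.isna(), "non-numeric or missing reflectance")
    _fail_rows(frame, (refl < 0) | (refl > 1), "reflectance outside [0, 1]")
    wl = pd.to_numeric(frame["wavelength_nm"], errors="coerce")
    _fail_rows(frame, wl.isna(), "non-numeric wavelength")
    _fail_rows(frame, (wl < WL_MIN) | (wl > WL_MAX), "wavelength outside [350, 2500] nm")
    _fail_rows(
        frame,
        frame.duplicated(subset=["plot_id", "wavelength_nm"], keep=False)
        & frame.duplicated(subset=["plot_id", "wavelength_nm"]),
        "duplicate (plot_id, wavelength) rows",
    )
    frame = frame.assign(reflectance=refl, wavelength_nm=wl)

    spectra = []
    for plot_id, grp in frame.groupby("plot_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        first = grp.iloc[0]
        spectra.append(
            Spectrum(
                plot_id=str(plot_id),
                genotype=str(first["genotype"]),
                treatment=str(first["treatment"]),
                year=str(first["year"]),
                replicate=int(first["replicate"]),
                wavelengths=grp["wavelength_nm"].to_numpy(),
                reflectance=grp["reflectance"].to_numpy(),
            )
        )
    return SpectraSet.from_spectra(spectra, provenance=str(path))
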