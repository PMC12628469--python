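"""Band-based optical indices from tissue reflectance spectra.

The TIVITA-style tissue parameters (NIR perfusion index, StO2, organ
hemoglobin index OHI, tissue water index TWI) are summaries of a reflectance
curve measured between 500 and 1000 nm.  Here each index is computed as a
two-band contrast on the absorbance curve

    A(lambda) = -log10 R(lambda)
    c = (A_signal - A_reference) / (A_signal + A_reference)

where ``A_signal`` and ``A_reference`` are band means of ``A``, and the
contrast ``c`` is affinely rescaled and clamped into [0, 1].  The shipped
default band definitions are documented approximations chosen so that
hemoglobin absorption raises OHI and water absorption raises TWI; they are
fully overridable through configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    EmptyBandError,
    EmptyROIError,
    GridMismatchError,
    InvalidSpectrumError,
)

__all__ = [
    "Spectrum",
    "WavelengthBand",
    "IndexDefinition",
    "HSIIndexSet",
    "INDEX_NAMES",
    "default_index_definitions",
    "absorbance",
    "band_mean",
    "compute_index",
    "compute_index_set",
    "roi_mean_spectrum",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "index_definitions_from_config",
]

WAVELENGTH_MIN = 500.0
WAVELENGTH_MAX = 1000.0

INDEX_NAMES = ("NIR", "StO2", "OHI", "TWI")


@dataclass(frozen=True)
class Spectrum:
    """A reflectance curve on a strictly increasing wavelength grid in nm.

    Reflectance values are fractions in (0, 1]; wavelengths live in the
    device range [500, 1000] nm.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)
        if wl.ndim != 1 or rf.ndim != 1 or wl.size != rf.size:
            raise InvalidSpectrumError(
                "wavelengths and reflectance must be 1-D arrays of equal length"
            )
        if wl.size == 0:
            raise InvalidSpectrumError("spectrum must contain at least one grid point")
        if np.any(np.diff(wl) <= 0):
            raise InvalidSpectrumError("wavelength grid must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise InvalidSpectrumError(
                f"wavelengths must lie within [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm"
            )
        if np.any(rf <= 0.0) or np.any(rf > 1.0):
            raise InvalidSpectrumError("reflectance values must lie in (0, 1]")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class WavelengthBand:
    """Inclusive wavelength interval [lo_nm, hi_nm] within the device range."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not (WAVELENGTH_MIN <= self.lo_nm < self.hi_nm <= WAVELENGTH_MAX):
            raise ConfigError(
                f"band [{self.lo_nm}, {self.hi_nm}] must satisfy "
                f"{WAVELENGTH_MIN:g} <= lo < hi <= {WAVELENGTH_MAX:g}"
            )

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.lo_nm) & (wavelengths <= self.hi_nm)


@dataclass(frozen=True)
class IndexDefinition:
    """A two-band contrast index: signal band vs reference band plus rescaling bounds."""

    name: str
    signal_band: WavelengthBand
    reference_band: WavelengthBand
    contrast_lo: float = -1.0
    contrast_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in INDEX_NAMES:
            raise ConfigError(f"index name must be one of {INDEX_NAMES}, got {self.name!r}")
        if not self.contrast_lo < self.contrast_hi:
            raise ConfigError("contrast_lo must be strictly below contrast_hi")


@dataclass(frozen=True)
class HSIIndexSet:
    """The four derived tissue indices, each a unitless value in [0, 1]."""

    nir: float
    sto2: float
    ohi: float
    twi: float

    def __post_init__(self) -> None:
        for fname in ("nir", "sto2", "ohi", "twi"):
            v = getattr(self, fname)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigError(f"index {fname} must be finite and in [0, 1], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {"nir": self.nir, "sto2": self.sto2, "ohi": self.ohi, "twi": self.twi}


def default_index_definitions() -> dict[str, IndexDefinition]:
    """Shipped default band definitions (documented approximations).

    The exact vendor band formulas are not public; these bands are chosen so
    that hemoglobin absorption (Soret/Q bands below 650 nm) drives OHI up and
    the 970 nm water overtone drives TWI up, which is the qualitative behaviour
    the downstream score relies on.
    """
    return {
        "NIR": IndexDefinition(
            "NIR", WavelengthBand(825, 925), WavelengthBand(655, 735)
        ),
        "StO2": IndexDefinition(
            "StO2", WavelengthBand(570, 590), WavelengthBand(740, 780)
        ),
        "OHI": IndexDefinition(
            "OHI", WavelengthBand(500, 650), WavelengthBand(700, 800)
        ),
        "TWI": IndexDefinition(
            "TWI", WavelengthBand(880, 1000), WavelengthBand(700, 880)
        ),
    }


def absorbance(s: Spectrum) -> np.ndarray:
    """Per-wavelength absorbance A = -log10(R) on the spectrum's grid.

    All values are >= 0 because reflectance is constrained to (0, 1].
    """
    return -np.log10(s.reflectance)


def band_mean(
    wavelengths: np.ndarray, values: np.ndarray, band: WavelengthBand
) -> float:
    """Arithmetic mean of ``values`` at grid points falling inside ``band``.

    Band membership is decided on the stored grid (inclusive bounds, no
    interpolation) for determinism.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = band.mask(wavelengths)
    if not mask.any():
        raise EmptyBandError(
            f"band [{band.lo_nm}, {band.hi_nm}] nm contains no grid point"
        )
    return float(values[mask].mean())


def compute_index(s: Spectrum, d: IndexDefinition) -> float:
    """Two-band absorbance contrast, rescaled and clamped into [0, 1].

    The contrast c = (A_sig - A_ref) / (A_sig + A_ref) is 0 for a flat
    spectrum and strictly increases with added signal-band absorbance, until
    the clamp saturates.  A fully reflective tissue (zero absorbance in both
    bands) is assigned c = 0 by convention.
    """
    a = absorbance(s)
    a_sig = band_mean(s.wavelengths, a, d.signal_band)
    a_ref = band_mean(s.wavelengths, a, d.reference_band)
    denom = a_sig + a_ref
    c = 0.0 if denom == 0.0 else (a_sig - a_ref) / denom
    scaled = (c - d.contrast_lo) / (d.contrast_hi - d.contrast_lo)
    return float(np.clip(scaled, 0.0, 1.0))


def compute_index_set(
    s: Spectrum, defs: Iterable[IndexDefinition] | Mapping[str, IndexDefinition]
) -> HSIIndexSet:
    """Compute all four tissue indices; ``defs`` must cover NIR, StO2, OHI, TWI exactly."""
    if isinstance(defs, Mapping):
        defs = defs.values()
    by_name: dict[str, IndexDefinition] = {}
    for d in defs:
        if d.name in by_name:
            raise ConfigError(f"duplicate index definition for {d.name}")
        by_name[d.name] = d
    missing = set(INDEX_NAMES) - set(by_name)
    if missing:
        raise ConfigError(f"missing index definitions: {sorted(missing)}")
    return HSIIndexSet(
        nir=compute_index(s, by_name["NIR"]),
        sto2=compute_index(s, by_name["StO2"]),
        ohi=compute_index(s, by_name["OHI"]),
        twi=compute_index(s, by_name["TWI"]),
    )


def roi_mean_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    """Mean reflectance across ROI pixels sharing one wavelength grid."""
    if len(spectra) == 0:
        raise EmptyROIError("ROI aggregate requires at least one spectrum")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != grid.shape or not np.array_equal(s.wavelengths, grid):
            raise GridMismatchError("all ROI spectra must share one wavelength grid")
    mean_r = np.mean([s.reflectance for s in spectra], axis=0)
    return Spectrum(grid.copy(), mean_r)


# ---------------------------------------------------------------------------
# I/O and configuration


def read_spectrum_csv(path) -> Spectrum:
    """Read a per-ROI spectrum CSV with header ``wavelength_nm,reflectance``."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "reflectance"}
    if not required.issubset(df.columns):
        raise InvalidSpectrumError(
            f"spectrum CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return Spectrum(df["wavelength_nm"].to_numpy(float), df["reflectance"].to_numpy(float))


def write_spectrum_csv(s: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": s.wavelengths, "reflectance": s.reflectance}
    ).to_csv(path, index=False)


def index_definitions_from_config(cfg: Mapping) -> dict[str, IndexDefinition]:
    """Build index definitions from a parsed config mapping.

    Expected shape (under the config key ``index_definitions``)::

        - name: OHI
          signal_band: [500, 650]
          reference_band: [700, 800]
          contrast_bounds: [-1, 1]

    Indices not listed fall back to the shipped defaults.
    """
    defs = default_index_definitions()
    entries = cfg.get("index_definitions", []) if isinstance(cfg, Mapping) else []
    for entry in entries:
        try:
            name = entry["name"]
            sig = entry["signal_band"]
            ref = entry["reference_band"]
            lo, hi = entry.get("contrast_bounds", (-1.0, 1.0))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed index definition entry: {entry!r}") from exc
        defs[name] = IndexDefinition(
            name,
            WavelengthBand(float(sig[0]), float(sig[1])),
            WavelengthBand(float(ref[0]), float(ref[1])),
            float(lo),
            float(hi),
        )
    return defs
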