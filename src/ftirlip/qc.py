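"""Per-spectrum quality test.

Each recorded spectrum is admitted to analysis only if it passes three
criteria: a minimum signal level, a noise ceiling and a water-vapor ceiling.
The instrument vendor's formulas are proprietary, so the three statistics are
reimplemented here explicitly (windows follow common OPUS practice):

* ``max_absorbance`` — maximum absorbance in the 2100–1600 cm^-1 window
  (covers the ester carbonyl and amide bands); must exceed 0.35.
* ``noise`` — root-mean-square of the first difference of the absorbance in
  the signal-free 2100–2000 cm^-1 window, scaled by 1/sqrt(2) so that for
  iid noise of standard deviation sigma the statistic estimates sigma; must
  be below 1.5e-5.
* ``water_vapor`` — peak-to-peak amplitude of the first difference in the
  1847–1837 cm^-1 window, where rotational water-vapor lines sit on an
  otherwise flat region; must be below 3e-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectraSet

logger = logging.getLogger(__name__)

ABSORBANCE_WINDOW = (2100.0, 1600.0)
NOISE_WINDOW = (2100.0, 2000.0)
WATER_VAPOR_WINDOW = (1847.0, 1837.0)


@dataclass(frozen=True)
class QualityThresholds:
    """Admission thresholds for the spectral quality test."""

    min_max_absorbance: float = 0.35
    max_noise: float = 1.5e-5
    max_water_vapor: float = 3e-4

    def __post_init__(self) -> None:
        for name in ("min_max_absorbance", "max_noise", "max_water_vapor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _window_values(spectrum: Spectrum, window: tuple[float, float],
                   name: str) -> np.ndarray:
    high, low = max(window), min(window)
    wn = spectrum.wavenumbers
    if wn.max() < high or wn.min() > low:
        raise ValueError(
            f"{name} window {high}-{low} cm^-1 is outside the grid "
            f"({wn.max():g}-{wn.min():g} cm^-1)")
    mask = (wn <= high) & (wn >= low)
    # orientation-invariant: evaluate on a descending sub-grid either way
    return spectrum.absorbance[mask]


def quality_statistics(spectrum: Spectrum) -> dict[str, float]:
    """The three quality statistics of one spectrum."""
    signal = _window_values(spectrum, ABSORBANCE_WINDOW, "absorbance")
    noise_vals = _window_values(spectrum, NOISE_WINDOW, "noise")
    vapor_vals = _window_values(spectrum, WATER_VAPOR_WINDOW, "water vapor")
    d_noise = np.diff(noise_vals)
    d_vapor = np.diff(vapor_vals)
    return {
        "max_absorbance": float(np.max(signal)),
        "noise": float(np.sqrt(np.mean(d_noise ** 2)) / np.sqrt(2.0)),
        "water_vapor": float(np.ptp(d_vapor)),
    }


def quality_test(spectrum: Spectrum,
                 thresholds: QualityThresholds = QualityThresholds()
                 ) -> dict[str, object]:
    """Quality-report entry: the three statistics, pass flag and reasons."""
    stats = quality_statistics(spectrum)
    reasons = []
    if not stats["max_absorbance"] > thresholds.min_max_absorbance:
        reasons.append("absorbance")
    if not stats["noise"] < thresholds.max_noise:
        reasons.append("noise")
    if not stats["water_vapor"] < thresholds.max_water_vapor:
        reasons.append("water_vapor")
    entry = dict(stats)
    entry["pass"] = not reasons
    entry["failure_reasons"] = ";".join(reasons)
    entry["spectrum_id"] = spectrum.metadata.get("spectrum_id", "")
    return entry


def filter_set(spectra: SpectraSet,
               thresholds: QualityThresholds = QualityThresholds()
               ) -> tuple[SpectraSet, pd.DataFrame]:
    """Apply the quality test to every spectrum.

    Returns the surviving subset (input order preserved) and the full
    per-spectrum report.  An empty surviving set is allowed, with a warning.
    """
    entries = [quality_test(s, thresholds) for s in spectra]
    report = pd.DataFrame(entries)
    keep = report["pass"].to_numpy(bool)
    if not keep.any():
        logger.warning("quality test removed all %d spectra", len(spectra))
    passing = spectra.select(keep)
    return passing, report
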