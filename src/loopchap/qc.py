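"""Biophysical QC computations around the main analyses.

Covers three small quantitative procedures: estimating oligomer subunit
counts from a size-exclusion chromatography (SEC) peak and its full width
at half maximum; converting circular-dichroism ellipticity to mean residue
ellipticity (MRE); and locating a tryptophan fluorescence emission maximum.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import LoopchapError


@dataclass(frozen=True)
class SECChromatogram:
    elution_volume: np.ndarray  # mL, strictly increasing
    a280: np.ndarray
    column_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.elution_volume, dtype=float)
        a = np.asarray(self.a280, dtype=float)
        object.__setattr__(self, "elution_volume", v)
        object.__setattr__(self, "a280", a)
        if v.size < 10 or a.shape != v.shape:
            raise LoopchapError("chromatogram needs >= 10 matched points")
        if not np.all(np.diff(v) > 0):
            raise LoopchapError("elution volumes must be strictly increasing")


@dataclass(frozen=True)
class SECCalibration:
    """log10(MW) vs elution volume line fitted to column standards."""

    standards: tuple  # ((volume_mL, mw_Da), ...)
    slope: float
    intercept: float

    @classmethod
    def from_standards(cls, standards: Sequence[tuple[float, float]]
                       ) -> "SECCalibration":
        standards = tuple((float(v), float(mw)) for v, mw in standards)
        if len(standards) < 3:
            raise LoopchapError("calibration needs >= 3 standards")
        vols = np.array([s[0] for s in standards])
        logmw = np.log10([s[1] for s in standards])
        res = stats.linregress(vols, logmw)
        if res.slope >= 0:
            raise LoopchapError(
                "calibration slope must be negative (larger species elute first)"
            )
        return cls(standards=standards, slope=float(res.slope),
                   intercept=float(res.intercept))

    def mw_at(self, volume: float) -> float:
        return float(10 ** (self.intercept + self.slope * volume))

    def volume_of(self, mw: float) -> float:
        return float((np.log10(mw) - self.intercept) / self.slope)


@dataclass(frozen=True)
class OligomerEstimate:
    peak_volume: float
    fwhm_volumes: tuple[float, float]
    subunits_peak: int
    subunits_range: tuple[int, int]
    monomer_mw: float
    mw_peak: float  # unrounded MW at the peak


def _half_crossing(v, a, i_peak, half, direction):
    """Volume where the signal crosses ``half``, walking from the peak."""
    idx = range(i_peak, -1, -1) if direction < 0 else range(i_peak, len(v))
    prev = i_peak
    for i in idx:
        if a[i] < half:
            v0, v1 = v[i], v[prev]
            a0, a1 = a[i], a[prev]
            return float(v0 + (half - a0) * (v1 - v0) / (a1 - a0))
        prev = i
    raise LoopchapError("FWHM crossing outside the chromatogram")


def estimate_subunits(
    chrom: SECChromatogram,
    cal: SECCalibration,
    monomer_mw: float,
    peak_window: tuple[float, float] | None = None,
) -> OligomerEstimate:
    """Subunit count from the SEC peak maximum, range from the FWHM.

    The peak is the signal maximum inside ``peak_window``; half-height
    crossings are located by linear interpolation.  Volumes are converted
    to molecular weight via the calibration and to subunit counts by
    rounding MW/monomer_mw (floored at 1).  The earlier (low-volume) FWHM
    edge maps to the *larger* count since the calibration slope is negative.
    """
    v, a = chrom.elution_volume, chrom.a280
    mask = np.ones_like(v, dtype=bool)
    if peak_window is not None:
        lo, hi = peak_window
        mask = (v >= lo) & (v <= hi)
        if not mask.any():
            raise LoopchapError("peak window contains no chromatogram points")
    i_peak = int(np.flatnonzero(mask)[np.argmax(a[mask])])
    peak_height = a[i_peak]
    if peak_height <= 0:
        raise LoopchapError("no positive peak in window")
    half = peak_height / 2.0
    v_lo = _half_crossing(v, a, i_peak, half, -1)
    v_hi = _half_crossing(v, a, i_peak, half, +1)

    def count(volume):
        return max(1, round(cal.mw_at(volume) / monomer_mw))

    mw_peak = cal.mw_at(v[i_peak])
    n_lo, n_hi = count(v_hi), count(v_lo)  # high volume -> small species
    n_peak = max(1, round(mw_peak / monomer_mw))
    lo_count, hi_count = min(n_lo, n_hi, n_peak), max(n_lo, n_hi, n_peak)
    return OligomerEstimate(
        peak_volume=float(v[i_peak]),
        fwhm_volumes=(v_lo, v_hi),
        subunits_peak=n_peak,
        subunits_range=(lo_count, hi_count),
        monomer_mw=float(monomer_mw),
        mw_peak=mw_peak,
    )


def cd_to_mre(
    ellipticity_mdeg: Sequence[float],
    conc_molar: float,
    path_cm: float,
    n_residues: int,
    blank_mdeg: Sequence[float] | None = None,
    n_bonds: int | None = None,
) -> np.ndarray:
    """Convert CD ellipticity (mdeg) to mean residue ellipticity.

    MRE(λ) = θ(λ) / (10 · path · conc · n_bonds) in deg·cm²·dmol⁻¹, with
    n_bonds defaulting to n_residues − 1 peptide bonds (conventions differ;
    pass ``n_bonds`` to override).  ``blank_mdeg`` is subtracted first.
    """
    if conc_molar <= 0 or path_cm <= 0:
        raise LoopchapError("concentration and path length must be > 0")
    if n_residues < 2:
        raise LoopchapError("n_residues must be >= 2")
    theta = np.asarray(ellipticity_mdeg, dtype=float)
    if blank_mdeg is not None:
        theta = theta - np.asarray(blank_mdeg, dtype=float)
    bonds = n_bonds if n_bonds is not None else n_residues - 1
    return theta / (10.0 * path_cm * conc_molar * bonds)


def emission_max(
    wavelengths: Sequence[float],
    intensity: Sequence[float],
    smooth_window: int = 5,
) -> float:
    """Wavelength of the fluorescence emission maximum, to 1 nm.

    A centered moving average of ``smooth_window`` points suppresses
    shot noise before the argmax.  A flat spectrum (no unique maximum)
    is an error.
    """
    wl = np.asarray(wavelengths, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if wl.size < 20:
        raise LoopchapError("emission spectrum needs >= 20 points")
    if np.ptp(y) == 0:
        raise LoopchapError("flat spectrum: no unique emission maximum")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
        # edge bins see a partial kernel; exclude them from the argmax
        half = smooth_window // 2
        y = y[half:-half] if half else y
        wl = wl[half:-half] if half else wl
    return float(round(wl[int(np.argmax(y))]))
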