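"""Radiocarbon calibration against an IntCal-format curve.

Probability-method calibration: for a conventional age m ± σ and a curve
(μ(θ), σ_c(θ)) on a calendar grid, the posterior over calendar age θ is

    p(θ) ∝ exp(-(m - μ(θ))² / (2(σ² + σ_c(θ)²)))

evaluated on a 1-year grid spanning the curve and normalized.  Reported
ranges are highest-posterior-density unions at 95.4% (2σ) mass, endpoints
rounded outward to the nearest 10 years, matching the precision radiocarbon
chronologies are conventionally reported at.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

TWO_SIGMA = 0.954


@dataclass
class CalCurve:
    cal_bp: np.ndarray      # calendar grid, strictly increasing
    c14_bp: np.ndarray      # curve mean μ(θ)
    error: np.ndarray       # curve error σ_c(θ) > 0

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_bp = np.asarray(self.c14_bp, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError("calendar grid must be strictly monotonic")
        if np.any(self.error <= 0):
            raise ValueError("curve errors must be > 0")

    def interp(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = np.interp(theta, self.cal_bp, self.c14_bp)
        sc = np.interp(theta, self.cal_bp, self.error)
        return mu, sc


@dataclass
class CalibratedDate:
    mean: float
    sigma: float
    grid: np.ndarray
    density: np.ndarray                       # sums to 1 on the grid
    ranges: list[tuple[float, float]]         # [older, younger] cal BP, old->young


def read_calcurve(path) -> CalCurve:
    """Read cal-age / 14C-age / error columns from an IntCal-style CSV."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 3:
        df = pd.read_csv(path, comment="#", sep=r"\s+|,", engine="python")
    cols = df.columns[:3]
    df = df[cols].astype(float).sort_values(cols[0])
    return CalCurve(df[cols[0]].values, df[cols[1]].values, df[cols[2]].values)


def identity_curve(lo: float = 0.0, hi: float = 10_000.0, error: float = 0.1) -> CalCurve:
    """Synthetic curve with μ(θ) = θ, used for analytic checks and tests."""
    grid = np.arange(lo, hi + 1.0)
    return CalCurve(grid, grid.copy(), np.full_like(grid, error))


def calibrate(mean: float, sigma: float, curve: CalCurve) -> CalibratedDate:
    """Calibrate a conventional 14C age; 2σ HPD ranges, outward-rounded."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not curve.c14_bp.min() - 10 * sigma <= mean <= curve.c14_bp.max() + 10 * sigma:
        raise ValueError("radiocarbon age outside the calibration curve support")
    grid = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + 1.0)
    mu, sc = curve.interp(grid)
    var = sigma * sigma + sc * sc
    logd = -((mean - mu) ** 2) / (2 * var) - 0.5 * np.log(var)
    logd -= logd.max()
    dens = np.exp(logd)
    dens /= dens.sum()
    ranges = hpd_ranges(grid, dens, TWO_SIGMA)
    ranges = [(_round_out_older(a), _round_out_younger(b)) for a, b in ranges]
    return CalibratedDate(mean, sigma, grid, dens, ranges)


def hpd_ranges(grid: np.ndarray, dens: np.ndarray, mass: float) -> list[tuple[float, float]]:
    """Smallest union of grid intervals holding >= ``mass`` probability.

    Returned as [older, younger] pairs ordered old -> young.
    """
    order = np.argsort(dens)[::-1]
    csum = np.cumsum(dens[order])
    k = int(np.searchsorted(csum, mass)) + 1
    inside = np.zeros(len(grid), dtype=bool)
    inside[order[:k]] = True
    ranges: list[tuple[float, float]] = []
    i = 0
    n = len(grid)
    while i < n:
        if inside[i]:
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            ranges.append((float(grid[j]), float(grid[i])))  # (older, younger)
            i = j + 1
        else:
            i += 1
    ranges.sort(key=lambda r: -r[0])
    return ranges


def _round_out_older(x: float) -> float:
    return float(np.ceil(x / 10.0) * 10.0)


def _round_out_younger(x: float) -> float:
    return float(np.floor(x / 10.0) * 10.0)
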