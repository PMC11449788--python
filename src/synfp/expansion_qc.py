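"""Expansion quality control from AZ-PSD line profiles.

In expanded tissue the peak-to-peak distance between the presynaptic active
zone (AZ) and the postsynaptic density (PSD), read off intensity profiles
drawn perpendicularly across side-view synapses, acts as a local ruler for
the expansion factor.  This module measures that distance per profile,
aggregates it per animal and batch, and turns the per-animal mean (relative
to its batch mean) into the dimensionless correction factor used to
normalize every length-derived quantity downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProfileTrace",
    "ExpansionSummary",
    "MeasurementError",
    "measure_az_psd",
    "summarize_expansion",
    "macroscopic_expansion_factor",
]


class MeasurementError(RuntimeError):
    """Raised when a profile does not yield two resolvable peaks."""


@dataclass
class ProfileTrace:
    """Intensity samples along a line crossing a side-view synapse.

    ``positions`` are nm along the line and must be strictly increasing;
    at least 20 samples are required for a stable polynomial fit.
    """

    positions: np.ndarray
    intensities: np.ndarray
    synapse_id: str = ""
    animal: str = ""
    batch: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.size != self.intensities.size:
            raise ValueError("positions and intensities differ in length")
        if self.positions.size < 20:
            raise ValueError("profile needs at least 20 samples")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class ExpansionSummary:
    """Per-animal AZ-PSD means, batch means and correction factors."""

    animal_means: pd.Series
    batch_means: pd.Series
    correction_factors: pd.Series
    animal_batch: pd.Series = field(default_factory=pd.Series)


def _poly_local_maxima(coeffs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Interior local maxima of a fitted polynomial on [lo, hi]."""
    deriv = np.polyder(coeffs)
    roots = np.roots(deriv)
    real = roots[np.abs(roots.imag) < 1e-8].real
    real = real[(real > lo) & (real < hi)]
    if real.size == 0:
        return real
    second = np.polyval(np.polyder(deriv), real)
    return np.sort(real[second < 0])


def _quadratic_refine(x: np.ndarray, y: np.ndarray, x0: float, halfwidth: int = 3) -> float:
    """Refine a peak position by fitting a parabola to samples around x0.

    The window is centered on the highest raw sample near x0 so that, for a
    symmetric peak sampled on-grid, the parabola vertex is exact.
    """
    i = int(np.argmin(np.abs(x - x0)))
    lo0 = max(0, i - halfwidth)
    hi0 = min(x.size, i + halfwidth + 1)
    i = lo0 + int(np.argmax(y[lo0:hi0]))
    lo = max(0, i - halfwidth)
    hi = min(x.size, i + halfwidth + 1)
    if hi - lo < 3:
        return x0
    a, b, c = np.polyfit(x[lo:hi], y[lo:hi], 2)
    if a >= 0:  # not concave — keep the initial estimate
        return x0
    vertex = -b / (2 * a)
    if not (x[lo] <= vertex <= x[hi - 1]):
        return x0
    return float(vertex)


def measure_az_psd(trace: ProfileTrace, fit_degree: int = 8) -> float:
    """AZ-PSD peak-to-peak distance (nm) from one line profile.

    A polynomial of ``fit_degree`` is fitted through the intensity samples
    and its interior local maxima are located; the two highest are taken as
    the AZ and PSD peaks (they dominate the profile by construction).  Each
    peak position is then refined by a local quadratic fit to the raw
    samples, which removes the residual bias of the global polynomial.  If
    the polynomial yields fewer than two maxima, the two highest separated
    raw local maxima are used instead; fewer than two of those raises
    :class:`MeasurementError` so the trace can be flagged and excluded.

    The measurement is invariant to adding a constant baseline and to
    uniform intensity scaling.
    """
    x, y = trace.positions, trace.intensities
    coeffs = np.polyfit(x, y, fit_degree)
    maxima = _poly_local_maxima(coeffs, x[0], x[-1])

    # dominance check against the raw trace: the secondary peak must carry
    # real signal, not polynomial ringing on the baseline
    if maxima.size >= 2:
        raw = np.interp(maxima, x, y) - y.min()
        keep = raw >= 0.2 * raw.max()
        maxima = maxima[keep]

    if maxima.size >= 2:
        heights = np.polyval(coeffs, maxima)
        top2 = maxima[np.argsort(heights)[-2:]]
    else:
        # fallback: raw local maxima, separated by at least 3 samples
        interior = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
        if interior.size < 2:
            raise MeasurementError("fewer than two peaks in profile")
        order = interior[np.argsort(y[interior])[::-1]]
        picked = [order[0]]
        for idx in order[1:]:
            if abs(idx - picked[0]) >= 3:
                picked.append(idx)
                break
        if len(picked) < 2:
            raise MeasurementError("fewer than two separated peaks in profile")
        top2 = x[np.array(picked)]

    refined = [_quadratic_refine(x, y, float(p)) for p in top2]
    return float(abs(refined[1] - refined[0]))


def summarize_expansion(distances: pd.DataFrame) -> ExpansionSummary:
    """Aggregate AZ-PSD distances into per-animal correction factors.

    ``distances`` needs columns ``distance_nm``, ``animal``, ``batch``.
    Batch means are computed as the mean of the member animals' means, so a
    heavily sampled animal does not dominate its batch.  The correction
    factor of an animal is its mean divided by its batch mean; normalized
    distances of a batch therefore average to 1 across animals.
    """
    req = {"distance_nm", "animal", "batch"}
    if not req.issubset(distances.columns):
        raise ValueError(f"distance table needs columns {sorted(req)}")
    if distances.empty or distances.groupby("animal").size().min() < 1:
        raise ValueError("every animal needs at least one distance")

    animal_means = distances.groupby("animal")["distance_nm"].mean()
    animal_batch = distances.groupby("animal")["batch"].first()
    batch_means = animal_means.groupby(animal_batch).mean()
    factors = animal_means / animal_batch.map(batch_means)
    return ExpansionSummary(animal_means, batch_means, factors, animal_batch)


def macroscopic_expansion_factor(pre_length: float, post_length: float) -> float:
    """Linear expansion factor from pre-/post-expansion gel measurements."""
    if pre_length <= 0 or post_length <= 0:
        raise ValueError("lengths must be positive")
    return post_length / pre_length
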