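"""Features of binned nanoparticle size distributions.

Nanoparticle tracking instruments report particle concentration per size
bin (10-1000 nm for plasma EV work). This module reduces such a binned
distribution to the summary features used to compare plasma preparations
and transport modes: total concentration (trapezoidal AUC),
concentration-weighted mean/SD/skewness of size, mode and median size,
and the dilution-corrected total particle volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SizeDistribution",
    "DistributionFeatures",
    "distribution_features",
    "original_particle_volume",
    "average_dilutions",
    "read_size_distribution",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Binned particle concentration vs diameter for one sample.

    ``bin_centers`` are diameters in nm (strictly increasing, within
    [10, 1000]); ``concentration`` is particles/mL per bin; the
    ``dilution_factor`` is the factor the plasma was diluted by before
    measurement (>= 1).
    """

    bin_centers: np.ndarray
    concentration: np.ndarray
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))
        object.__setattr__(self, "concentration", np.asarray(self.concentration, dtype=float))
        if len(self.bin_centers) != len(self.concentration):
            raise ValueError("bin_centers and concentration must have equal length")
        if len(self.bin_centers) < 3:
            raise ValueError("a size distribution needs at least 3 bins")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if self.bin_centers[0] < 10 - 1e-9 or self.bin_centers[-1] > 1000 + 1e-9:
            raise ValueError("bin centers must lie within 10-1000 nm")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be nonnegative")
        if not np.any(self.concentration > 0):
            raise ValueError("at least one bin must have positive concentration")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class DistributionFeatures:
    """Summary features of one size distribution."""

    auc: float  # particles/mL (trapezoidal integral over size)
    mean_size: float  # nm
    sd_size: float  # nm
    mode_size: float  # nm
    median_size: float  # nm
    skewness: float  # dimensionless (standardized third central moment)
    original_particle_volume: float  # nm^3/mL, dilution-corrected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: [v] for k, v in self.__dict__.items()})


def distribution_features(dist: SizeDistribution) -> DistributionFeatures:
    """All summary features of a binned size distribution.

    AUC uses the trapezoidal rule over bin centers; mean, SD and skewness
    are concentration-weighted moments of the bin centers; the mode is the
    bin center of maximal concentration; the median is interpolated
    linearly within the bin where the cumulative weight crosses half of
    the total.
    """
    s = dist.bin_centers
    c = dist.concentration
    auc = float(np.trapezoid(c, s))
    w = c / c.sum()
    mean = float(np.sum(w * s))
    var = float(np.sum(w * (s - mean) ** 2))
    sd = float(np.sqrt(var))
    skew = 0.0 if sd == 0 else float(np.sum(w * (s - mean) ** 3) / sd**3)
    mode = float(s[int(np.argmax(c))])
    median = _weighted_median(s, c)
    return DistributionFeatures(
        auc=auc,
        mean_size=mean,
        sd_size=sd,
        mode_size=mode,
        median_size=median,
        skewness=skew,
        original_particle_volume=original_particle_volume(dist),
    )


def _weighted_median(sizes: np.ndarray, weights: np.ndarray) -> float:
    """Grouped-data median: linear interpolation within the bin where the
    cumulative weight crosses half the total.

    Bin boundaries are the midpoints between consecutive centers (end bins
    extended symmetrically); inside the crossing bin the cumulative weight
    is taken to rise linearly, so a symmetric distribution's median equals
    its central bin center.
    """
    cum = np.cumsum(weights)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half))
    mids = (sizes[:-1] + sizes[1:]) / 2.0
    lower = np.concatenate(([sizes[0] - (mids[0] - sizes[0])], mids))
    upper = np.concatenate((mids, [sizes[-1] + (sizes[-1] - mids[-1])]))
    below = cum[i - 1] if i > 0 else 0.0
    frac = (half - below) / weights[i]
    return float(lower[i] + frac * (upper[i] - lower[i]))


def original_particle_volume(dist: SizeDistribution) -> float:
    """Total spherical particle volume, corrected by the dilution factor.

    ``sum_i c_i * (4/3) pi (d_i/2)^3 * dilution``, in nm^3 per mL of the
    original (undiluted) plasma.
    """
    radii = dist.bin_centers / 2.0
    volume = np.sum(dist.concentration * (4.0 / 3.0) * np.pi * radii**3)
    return float(volume * dist.dilution_factor)


def average_dilutions(dists: Sequence[SizeDistribution]) -> SizeDistribution:
    """Combine several dilution measurements of the same sample.

    Each distribution's concentrations are first brought back to the
    original plasma scale (multiplied by its dilution factor), then the
    bins are averaged with weights proportional to each measurement's
    total counts, so dilutions that traced more particles dominate.
    The result has ``dilution_factor = 1`` (already corrected).
    """
    if not dists:
        raise ValueError("need at least one distribution")
    grid = dists[0].bin_centers
    for d in dists[1:]:
        if not np.array_equal(d.bin_centers, grid):
            raise ValueError("all dilution measurements must share one bin grid")
    corrected = np.stack([d.concentration * d.dilution_factor for d in dists])
    weights = corrected.sum(axis=1)
    avg = (corrected * weights[:, None]).sum(axis=0) / weights.sum()
    return SizeDistribution(bin_centers=grid, concentration=avg, dilution_factor=1.0)


def read_size_distribution(path, dilution_factor: float = 1.0) -> SizeDistribution:
    """Read a distribution CSV with header ``size_nm,concentration``."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["size_nm", "concentration"]:
        raise ValueError("distribution CSV must have columns size_nm,concentration")
    return SizeDistribution(
        bin_centers=df["size_nm"].to_numpy(),
        concentration=df["concentration"].to_numpy(),
        dilution_factor=dilution_factor,
    )
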