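"""Net tow volumes and normalized biovolume size spectra (NBSS).

The theoretical volume filtered by a plankton net is opening area times
tow speed times tow duration.  The NBSS bins the biovolume of living
objects into log2-spaced size classes, normalizing each class by its
width (mm^3) and the sampled volume (m^3), giving an abundance-per-size
analogue; the ratio of two nets' spectra over shared size classes
measures their relative sampling efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class NetTowSpec:
    """Net opening radius (m), tow speed (m/s) and tow duration (s)."""

    net_radius: float
    tow_speed: float
    tow_duration: float

    def __post_init__(self):
        if min(self.net_radius, self.tow_speed, self.tow_duration) <= 0:
            raise ValueError("net radius, speed and duration must be positive")


def theoretical_volume(spec: NetTowSpec) -> float:
    """Volume filtered (m^3) = opening area × tow speed × tow duration."""
    return np.pi * spec.net_radius ** 2 * spec.tow_speed * spec.tow_duration


@dataclass
class PlanktonSample:
    """Imaged-object biovolumes (mm^3) with living flags for one net tow."""

    biovolumes: np.ndarray
    living: np.ndarray
    volume_sampled: float         # m^3
    net_id: str = "NET"

    def __post_init__(self):
        self.biovolumes = np.asarray(self.biovolumes, dtype=float)
        self.living = np.asarray(self.living, dtype=bool)
        if len(self.biovolumes) == 0:
            raise ValueError("sample must contain at least one object")
        if (self.biovolumes <= 0).any():
            raise ValueError("biovolumes must be positive")
        if self.volume_sampled <= 0:
            raise ValueError("volume_sampled must be positive")


@dataclass
class NbssSpectrum:
    """Normalized biovolume per log2 size class (mm^3 · mm^-3 · m^-3)."""

    bin_low: np.ndarray           # mm^3
    bin_high: np.ndarray
    nbss: np.ndarray
    counts: np.ndarray
    net_id: str = "NET"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_low": self.bin_low, "bin_high": self.bin_high,
                             "nbss": self.nbss, "count": self.counts})


def log2_bins(min_size: float, max_size: float) -> np.ndarray:
    """log2-spaced bin edges anchored at 2^0 mm^3, covering [min, max]."""
    lo = int(np.floor(np.log2(min_size)))
    hi = int(np.ceil(np.log2(max_size)))
    if 2.0 ** hi <= max_size:
        hi += 1
    return 2.0 ** np.arange(lo, hi + 1)


def compute_nbss(sample: PlanktonSample,
                 bins: Optional[np.ndarray] = None) -> NbssSpectrum:
    """NBSS of the living objects of one sample.

    Per bin: summed biovolume of living objects divided by the bin width
    (mm^3) and the sampled volume (m^3).  Non-living objects are excluded;
    a living object falling outside the bin coverage raises.
    """
    bv = sample.biovolumes[sample.living]
    if bins is None:
        bins = log2_bins(bv.min(), bv.max())
    bins = np.asarray(bins, dtype=float)
    if (np.diff(bins) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    outside = (bv < bins[0]) | (bv >= bins[-1])
    if outside.any():
        raise ValueError(f"{int(outside.sum())} living object(s) outside bin "
                         f"coverage, e.g. biovolume {bv[outside][0]:g} mm^3")
    idx = np.digitize(bv, bins) - 1
    nb = len(bins) - 1
    total = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    np.add.at(total, idx, bv)
    np.add.at(counts, idx, 1)
    width = np.diff(bins)
    return NbssSpectrum(bin_low=bins[:-1], bin_high=bins[1:],
                        nbss=total / width / sample.volume_sampled,
                        counts=counts, net_id=sample.net_id)


def nbss_slope(spectrum: NbssSpectrum, min_count: int = 5) -> float:
    """Log-log least-squares slope of the spectrum over well-filled bins.

    Bins with fewer than ``min_count`` objects are excluded: sparsely
    populated large-size classes otherwise bias the fit.  For biovolumes
    drawn from a power law pdf ∝ s^k, the expected NBSS slope is k + 1.
    """
    keep = spectrum.counts >= min_count
    if keep.sum() < 2:
        raise ValueError("need at least two well-filled size classes to fit")
    centers = np.sqrt(spectrum.bin_low * spectrum.bin_high)
    fit = sstats.linregress(np.log10(centers[keep]), np.log10(spectrum.nbss[keep]))
    return float(fit.slope)


def net_efficiency(spectrum_a: NbssSpectrum,
                   spectrum_b: NbssSpectrum) -> tuple[float, float]:
    """Mean ± SD of the per-size-class ratio a/b over shared classes.

    The spectra must be on identical bins; classes where either spectrum
    is empty are excluded.  Returns (mean ratio, SD of ratio).
    """
    if (len(spectrum_a.bin_low) != len(spectrum_b.bin_low)
            or not np.allclose(spectrum_a.bin_low, spectrum_b.bin_low)):
        raise ValueError("spectra must share identical bins")
    shared = (spectrum_a.nbss > 0) & (spectrum_b.nbss > 0)
    if not shared.any():
        raise ValueError("no shared non-empty size class")
    ratio = spectrum_a.nbss[shared] / spectrum_b.nbss[shared]
    sd = float(ratio.std(ddof=1)) if len(ratio) > 1 else 0.0
    return float(ratio.mean()), sd
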