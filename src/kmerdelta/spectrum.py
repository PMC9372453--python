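"""Genome-size estimation, copy-number scaling and geometric binning.

The multiplicity axis of a k-mer spectrum is sample specific: it scales
with sequencing depth.  Dividing multiplicities by the monoploid-peak
multiplicity ``c`` (the coverage of k-mers present on only one of a
diploid's two genome copies) converts them to genomic copy numbers, on
which samples are comparable: heterozygous k-mers sit at 1, homozygous
at 2, a repeat present in N copies per diploid genome at N.

Copy numbers are then pooled into geometric bins whose upper limit is
10% above the lower limit, ``(0.5*1.1^i, 0.5*1.1^(i+1)]``, shared by
all samples.  Scaled values at or below 0.5 are discarded as likely
contaminants or sequencing errors.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np

from .kmerset import Spectrum

__all__ = [
    "MBP_PER_PG",
    "BinScheme",
    "BinnedSpectrum",
    "GenomeSizeEstimate",
    "find_monoploid_peak",
    "estimate_genome_size",
    "mbp_to_pg_1c",
    "scale_and_bin",
    "binned_genome_size",
    "range_summary",
    "DEFAULT_RANGE_BREAKPOINTS",
]

#: 1 pg of double-stranded DNA corresponds to 978 Mbp.
MBP_PER_PG = 978.0

DEFAULT_RANGE_BREAKPOINTS = (10.0, 100.0, 1_000.0, 10_000.0, 100_000.0, 1_000_000.0)


@dataclasses.dataclass(frozen=True)
class BinScheme:
    """Geometric copy-number bins ``(lower_origin*growth^i, lower_origin*growth^(i+1)]``."""

    lower_origin: float = 0.5
    growth: float = 1.10

    def __post_init__(self) -> None:
        if self.lower_origin <= 0:
            raise ValueError("lower_origin must be positive")
        if self.growth <= 1:
            raise ValueError("growth must exceed 1")

    def lower(self, i: int) -> float:
        return self.lower_origin * self.growth**i

    def upper(self, i: int) -> float:
        return self.lower_origin * self.growth ** (i + 1)

    def bounds(self, i: int) -> tuple[float, float]:
        return self.lower(i), self.upper(i)

    def representative(self, i: int, kind: str = "geometric") -> float:
        """Expected copy number of k-mers in bin i.

        ``geometric`` (default) is the geometric mean of the bounds,
        consistent with the geometric bin growth; ``midpoint`` is the
        arithmetic midpoint (differs by < 0.12% at 10% growth).
        """
        lo, hi = self.bounds(i)
        if kind == "geometric":
            return math.sqrt(lo * hi)
        if kind == "midpoint":
            return 0.5 * (lo + hi)
        raise ValueError(f"unknown representative kind {kind!r}")

    def index(self, value: float):
        """Bin index for a scaled multiplicity, or None if discarded (<= origin)."""
        if value <= 0:
            raise ValueError(f"scaled multiplicity must be positive, got {value}")
        if value <= self.lower_origin:
            return None
        i = self.index_array(np.asarray([value], dtype=float))[0]
        return int(i)

    def index_array(self, values: np.ndarray) -> np.ndarray:
        """Vectorized bin indices; caller must pre-filter values <= origin."""
        values = np.asarray(values, dtype=float)
        x = np.log(values / self.lower_origin) / np.log(self.growth)
        idx = np.ceil(x - 1e-9).astype(np.int64) - 1
        idx = np.maximum(idx, 0)
        # one-step correction for floating-point boundary error; a value
        # within 1e-12 (relative) of a bound is treated as exactly on it,
        # and bounds are upper-inclusive
        eps = 1e-12
        upper = self.lower_origin * self.growth ** (idx + 1)
        idx = np.where(values > upper * (1 + eps), idx + 1, idx)
        lower = self.lower_origin * self.growth**idx
        idx = np.where((idx > 0) & (values <= lower * (1 + eps)), idx - 1, idx)
        return idx

    def compatible(self, other: "BinScheme") -> bool:
        return math.isclose(self.lower_origin, other.lower_origin) and math.isclose(
            self.growth, other.growth
        )


@dataclasses.dataclass(frozen=True, eq=False)
class BinnedSpectrum:
    """Per-bin distinct-k-mer counts on the genomic copy-number scale."""

    scheme: BinScheme
    counts: dict[int, int]  # bin index -> distinct k-mers
    c: float  # monoploid coverage used for scaling

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("monoploid coverage must be positive")
        clean = {int(i): int(n) for i, n in sorted(self.counts.items())}
        if any(i < 0 for i in clean):
            raise ValueError("bin indices must be >= 0")
        if any(n < 0 for n in clean.values()):
            raise ValueError("bin counts must be >= 0")
        object.__setattr__(self, "counts", clean)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinnedSpectrum):
            return NotImplemented
        return (
            self.scheme.compatible(other.scheme)
            and self.counts == other.counts
        )

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total_kmers(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def max_bin(self) -> int:
        return max(self.counts) if self.counts else -1

    def genome_size(self, representative: str = "geometric") -> float:
        return binned_genome_size(self, representative=representative)


@dataclasses.dataclass(frozen=True)
class GenomeSizeEstimate:
    """Diploid (2C) genome size in bp, with picogram conversion."""

    gs_2c: float  # base pairs per diploid genome

    def __post_init__(self) -> None:
        if self.gs_2c < 0:
            raise ValueError("genome size must be >= 0")

    @property
    def gs_2c_mbp(self) -> float:
        return self.gs_2c / 1e6

    @property
    def gs_1c_pg(self) -> float:
        return self.gs_2c / (2 * MBP_PER_PG * 1e6)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def find_monoploid_peak(
    s: Spectrum,
    search_min: float,
    search_max: float,
    *,
    smooth_window: int = 3,
    refine: bool = True,
) -> float:
    """Locate the monoploid ('haploid') peak multiplicity of a spectrum.

    The counts are smoothed with a moving average, the error trough
    (first local minimum from multiplicity 1) is found, and the tallest
    local maximum after the trough within ``[search_min, search_max]``
    is returned, with parabolic refinement to sub-integer resolution.
    Ties break toward lower multiplicity.  Model-based fitters give
    better estimates on real data; a known coverage should be passed
    straight to the scaling functions instead.

    Raises ValueError when no local maximum exists in range (e.g. a
    monotonically decreasing pure-error spectrum), in which case the
    coverage must be supplied manually.
    """
    if not s.counts:
        raise ValueError("cannot locate a peak in an empty spectrum")
    if search_min >= search_max:
        raise ValueError("search_min must be below search_max")
    top = int(min(s.max_multiplicity, math.ceil(search_max) + 2))
    dense = np.zeros(top + 2, dtype=float)  # index = multiplicity, 0 unused
    for m, n in s.counts.items():
        if m <= top + 1:
            dense[m] = n
    padded = dense.copy()
    padded[0] = padded[1]  # nearest-neighbour boundary: multiplicity 0 is not observable
    y = _smooth(padded, smooth_window)
    # error trough: first local minimum scanning up from m=1
    trough = 1
    for m in range(2, top):
        if y[m] <= y[m - 1] and y[m] <= y[m + 1]:
            trough = m
            break
        if y[m] > y[m - 1]:  # counts rising from the start: no error component
            trough = m - 1
            break
    lo = max(int(math.ceil(search_min)), trough, 1)
    hi = min(int(math.floor(search_max)), top)
    best_m, best_y = None, -np.inf
    for m in range(max(lo, 2), hi + 1):
        if m + 1 >= dense.size:
            break
        if y[m] >= y[m - 1] and y[m] >= y[m + 1] and y[m] > best_y:
            best_m, best_y = m, y[m]
    if best_m is None:
        raise ValueError(
            "no local maximum found in the search range; "
            "supply the monoploid coverage manually"
        )
    # smoothing flattens narrow peaks into plateaus: snap to the raw maximum
    # among the plateau neighbourhood (ties toward lower multiplicity)
    window = dense[best_m - 1 : best_m + 2]
    best_m += int(np.argmax(window)) - 1
    peak = float(best_m)
    if refine:
        # centroid of the raw counts in a symmetric window around the mode:
        # for a sampling (Poisson-like) peak this tracks the mean coverage,
        # which an integer mode understates by up to half a multiplicity unit
        half = max(1, int(round(0.4 * best_m)))
        lo_w = max(best_m - half, trough + 1, 1)
        hi_w = min(best_m + half, dense.size - 1)
        half = min(best_m - lo_w, hi_w - best_m)
        if half >= 1:
            mm = np.arange(best_m - half, best_m + half + 1)
            weights = dense[mm[0] : mm[-1] + 1]
            total = weights.sum()
            if total > 0:
                peak = float((mm * weights).sum() / total)
    return peak


def estimate_genome_size(s: Spectrum, c: float) -> GenomeSizeEstimate:
    """Estimate 2C genome size from an uncropped spectrum.

    Multiplicities below half the monoploid coverage (largely the
    contamination/error peak) are discarded; the remaining
    multiplicity*count products are summed and divided by ``c``.
    Organellar k-mers should already have been subtracted.
    """
    if c <= 0:
        raise ValueError("monoploid coverage must be positive")
    total = sum(m * n for m, n in s.counts.items() if m >= c / 2)
    if total == 0:
        warnings.warn("spectrum empty after multiplicity cutoff; genome size is 0")
    return GenomeSizeEstimate(gs_2c=total / c)


def mbp_to_pg_1c(gs_2c_mbp: float) -> float:
    """Convert a diploid (2C) genome size in Mbp to 1C picograms (1 pg = 978 Mbp)."""
    if gs_2c_mbp < 0:
        raise ValueError("genome size must be >= 0")
    return gs_2c_mbp / 2 / MBP_PER_PG


def scale_and_bin(
    s: Spectrum, c: float, scheme: BinScheme | None = None
) -> BinnedSpectrum:
    """Scale a spectrum's multiplicities by 1/c and pool them into bins.

    Scaled values at or below the scheme origin (default 0.5) are
    discarded.  The highest occupied bin is determined by the
    highest-copy-number k-mer observed.
    """
    if c <= 0:
        raise ValueError("monoploid coverage must be positive")
    scheme = scheme or BinScheme()
    m, n = s.arrays()
    scaled = m.astype(float) / c
    keep = scaled > scheme.lower_origin
    if not keep.any():
        return BinnedSpectrum(scheme, {}, c)
    idx = scheme.index_array(scaled[keep])
    kept_n = n[keep]
    binned = np.bincount(idx, weights=kept_n.astype(float)).astype(np.int64)
    counts = {int(i): int(v) for i, v in enumerate(binned) if v > 0}
    return BinnedSpectrum(scheme, counts, c)


def binned_genome_size(b: BinnedSpectrum, representative: str = "geometric") -> float:
    """Genome size implied by a binned spectrum: sum of count * expected copy number."""
    return float(
        sum(
            n * b.scheme.representative(i, representative)
            for i, n in b.counts.items()
        )
    )


def range_summary(
    b: BinnedSpectrum,
    breakpoints: Sequence[float] = DEFAULT_RANGE_BREAKPOINTS,
    representative: str = "geometric",
) -> dict[tuple[float, float], float]:
    """Aggregate binned mass into coarse half-open copy-number ranges.

    Each geometric bin is assigned to the range containing its
    representative copy number, so the ranges partition the binned mass
    exactly and their values sum to ``binned_genome_size(b)``.
    """
    bp = [float(x) for x in breakpoints]
    if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    edges = [0.0] + bp + [math.inf]
    ranges = list(zip(edges[:-1], edges[1:]))
    out = {r: 0.0 for r in ranges}
    for i, n in b.counts.items():
        r_i = b.scheme.representative(i, representative)
        for lo, hi in ranges:
            if lo < r_i <= hi:
                out[(lo, hi)] += n * r_i
                break
    return out
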