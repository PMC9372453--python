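"""Pairwise and cohort genome comparisons on the copy-number-bin scale.

Three complementary views are provided:

* difference graphs — per-bin k-mer count differences weighted by the
  bin's expected copy number, giving base-pair contributions to the
  total genome size difference; the cumulative form shows which
  repetitiveness classes drive it (identity-free);
* joint k-mer spectra — a full outer join of two k-mer dumps on the
  k-mer column, tallied over pairs of copy-number bins; off-diagonal
  mass marks copy-number divergence (identity-aware);
* distance matrices and a one-way ANOVA/permutation check for cohorts.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kmerset import KmerDump
from .spectrum import BinScheme, BinnedSpectrum, GenomeSizeEstimate

__all__ = [
    "ABSENT",
    "DiffGraph",
    "JointSpectrum",
    "DistanceMatrix",
    "AnovaResult",
    "PermutationResult",
    "diff_graph",
    "total_gs_difference",
    "joint_spectrum",
    "joint_marginals",
    "distance_matrix",
    "anova_partition",
    "permutation_check",
]

#: Reserved bin index for k-mers missing from (or discarded on) one axis
#: of a joint spectrum.
ABSENT = -1


@dataclasses.dataclass(frozen=True, eq=False)
class DiffGraph:
    """Per-bin and cumulative k-mer differences between two samples (A - B)."""

    scheme: BinScheme
    bins: np.ndarray  # occupied bin indices, ascending
    count_diff: np.ndarray  # distinct-k-mer count difference per bin
    bp_diff: np.ndarray  # count_diff * representative copy number
    cumulative_bp: np.ndarray

    @property
    def total_bp(self) -> float:
        return float(self.cumulative_bp[-1]) if self.cumulative_bp.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        lower = np.array([self.scheme.lower(int(i)) for i in self.bins])
        upper = np.array([self.scheme.upper(int(i)) for i in self.bins])
        rep = np.array([self.scheme.representative(int(i)) for i in self.bins])
        return pd.DataFrame(
            {
                "bin_index": self.bins,
                "lower": lower,
                "upper": upper,
                "representative_cn": rep,
                "count_diff": self.count_diff,
                "bp_diff": self.bp_diff,
                "cumulative_bp": self.cumulative_bp,
            }
        )


def diff_graph(
    a: BinnedSpectrum, b: BinnedSpectrum, representative: str = "geometric"
) -> DiffGraph:
    """Difference graph of two binned spectra sharing one bin scheme.

    Per-bin differences over the union of occupied bins are multiplied
    by the expected copy number of k-mers in each bin; summing the
    products gives the total genome size difference (analogous to
    computing a genome size from a single spectrum).
    """
    if not a.scheme.compatible(b.scheme):
        raise ValueError("binned spectra use different bin schemes")
    bins = sorted(set(a.counts) | set(b.counts))
    bins_arr = np.asarray(bins, dtype=np.int64)
    cdiff = np.array(
        [a.counts.get(i, 0) - b.counts.get(i, 0) for i in bins], dtype=np.int64
    )
    rep = np.array([a.scheme.representative(i, representative) for i in bins])
    bp = cdiff * rep
    return DiffGraph(a.scheme, bins_arr, cdiff, bp, np.cumsum(bp))


def total_gs_difference(a, b) -> float:
    """Genome-size difference A - B; accepts estimates or plain numbers."""
    va = a.gs_2c if isinstance(a, GenomeSizeEstimate) else float(a)
    vb = b.gs_2c if isinstance(b, GenomeSizeEstimate) else float(b)
    return va - vb


@dataclasses.dataclass(frozen=True, eq=False)
class JointSpectrum:
    """K-mer counts over pairs of copy-number bins for two samples.

    Cell ``(i_a, i_b)`` counts the joined k-mers binned at ``i_a`` in
    sample A and ``i_b`` in sample B; the reserved index ``ABSENT``
    (-1) marks k-mers missing from one dump or discarded by the
    scaled-multiplicity cutoff on that axis.
    """

    scheme: BinScheme
    cells: dict[tuple[int, int], int]
    c_a: float
    c_b: float
    k: int
    label_a: str = "A"
    label_b: str = "B"

    @property
    def total_kmers(self) -> int:
        return int(sum(self.cells.values()))

    def to_table(self) -> pd.DataFrame:
        """Three-column table: count, bin in sample A (reference), bin in sample B."""
        rows = sorted(self.cells.items())
        return pd.DataFrame(
            {
                "count": [n for _, n in rows],
                "bin_a": [ij[0] for ij, _ in rows],
                "bin_b": [ij[1] for ij, _ in rows],
            }
        )

    def to_matrix(self) -> pd.DataFrame:
        """Dense matrix, rows = sample A bins, columns = sample B bins."""
        if not self.cells:
            return pd.DataFrame()
        rows = sorted({i for i, _ in self.cells})
        cols = sorted({j for _, j in self.cells})
        mat = pd.DataFrame(0, index=rows, columns=cols, dtype=np.int64)
        for (i, j), n in self.cells.items():
            mat.loc[i, j] = n
        return mat


def _scaled_bin_indices(
    counts: np.ndarray, present: np.ndarray, c: float, scheme: BinScheme
) -> np.ndarray:
    """Per-k-mer bin index with ABSENT for missing or discarded entries."""
    scaled = counts.astype(float) / c
    idx = np.full(counts.size, ABSENT, dtype=np.int64)
    keep = present & (scaled > scheme.lower_origin)
    if keep.any():
        idx[keep] = scheme.index_array(scaled[keep])
    return idx


def joint_spectrum(
    a: KmerDump,
    b: KmerDump,
    c_a: float,
    c_b: float,
    scheme: BinScheme | None = None,
    *,
    join: str = "outer",
    label_a: str = "A",
    label_b: str = "B",
) -> JointSpectrum:
    """Joint k-mer spectrum of two dumps (join on the k-mer column).

    ``join='outer'`` (default) keeps k-mers present in either dump, so
    presence/absence variation shows up against the ABSENT index;
    ``join='inner'`` restricts to k-mers surviving the cutoff on both
    axes.
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if c_a <= 0 or c_b <= 0:
        raise ValueError("monoploid coverages must be positive")
    if join not in ("outer", "inner"):
        raise ValueError(f"join must be 'outer' or 'inner', got {join!r}")
    scheme = scheme or BinScheme()
    union = np.union1d(a.codes, b.codes)
    ia = np.searchsorted(a.codes, union)
    in_a = np.zeros(union.size, dtype=bool)
    if a.codes.size:
        iac = np.minimum(ia, a.codes.size - 1)
        in_a = (ia < a.codes.size) & (a.codes[iac] == union)
    ib = np.searchsorted(b.codes, union)
    in_b = np.zeros(union.size, dtype=bool)
    if b.codes.size:
        ibc = np.minimum(ib, b.codes.size - 1)
        in_b = (ib < b.codes.size) & (b.codes[ibc] == union)
    m_a = np.zeros(union.size, dtype=np.int64)
    m_b = np.zeros(union.size, dtype=np.int64)
    if a.codes.size:
        m_a[in_a] = a.counts[ia[in_a]]
    if b.codes.size:
        m_b[in_b] = b.counts[ib[in_b]]
    bins_a = _scaled_bin_indices(m_a, in_a, c_a, scheme)
    bins_b = _scaled_bin_indices(m_b, in_b, c_b, scheme)
    if join == "inner":
        keep = (bins_a != ABSENT) & (bins_b != ABSENT)
    else:
        keep = (bins_a != ABSENT) | (bins_b != ABSENT)
    bins_a, bins_b = bins_a[keep], bins_b[keep]
    cells: dict[tuple[int, int], int] = {}
    if bins_a.size:
        width = int(max(bins_a.max(), bins_b.max())) + 2
        key = (bins_a + 1) * width + (bins_b + 1)
        uniq, counts = np.unique(key, return_counts=True)
        for kk, n in zip(uniq.tolist(), counts.tolist()):
            cells[(kk // width - 1, kk % width - 1)] = int(n)
    return JointSpectrum(scheme, cells, c_a, c_b, a.k, label_a, label_b)


def joint_marginals(j: JointSpectrum) -> tuple[BinnedSpectrum, BinnedSpectrum]:
    """Axis marginals of a joint spectrum as per-sample binned spectra.

    Summing over the partner axis (including its ABSENT class) and
    dropping this axis's own ABSENT class reproduces each sample's
    binned spectrum restricted to k-mers surviving the per-axis discard.
    """
    marg_a: dict[int, int] = {}
    marg_b: dict[int, int] = {}
    for (i, jj), n in j.cells.items():
        if i != ABSENT:
            marg_a[i] = marg_a.get(i, 0) + n
        if jj != ABSENT:
            marg_b[jj] = marg_b.get(jj, 0) + n
    return (
        BinnedSpectrum(j.scheme, marg_a, j.c_a),
        BinnedSpectrum(j.scheme, marg_b, j.c_b),
    )


@dataclasses.dataclass(frozen=True, eq=False)
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def distance_matrix(
    samples: Sequence[BinnedSpectrum],
    metric: str = "manhattan",
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise sample distances from per-bin k-mer counts.

    ``manhattan``: sum of absolute per-bin count differences.
    ``gower``: Gower's coefficient for quantitative variables — the
    mean over occupied bins of absolute difference divided by the
    across-cohort count range for that bin (zero-range bins skipped);
    values lie in [0, 1].
    """
    if len(samples) < 2:
        raise ValueError("at least two samples are required")
    scheme = samples[0].scheme
    for s in samples[1:]:
        if not s.scheme.compatible(scheme):
            raise ValueError("samples use different bin schemes")
    if labels is None:
        labels = [f"S{i}" for i in range(len(samples))]
    labels = [str(x) for x in labels]
    if len(labels) != len(samples):
        raise ValueError("labels and samples differ in length")
    bins = sorted(set().union(*(s.counts.keys() for s in samples)))
    mat = np.array(
        [[s.counts.get(i, 0) for i in bins] for s in samples], dtype=float
    )
    n = len(samples)
    d = np.zeros((n, n))
    if metric == "manhattan":
        for i in range(n):
            for jj in range(i + 1, n):
                d[i, jj] = d[jj, i] = np.abs(mat[i] - mat[jj]).sum()
    elif metric == "gower":
        rng = mat.max(axis=0) - mat.min(axis=0)
        use = rng > 0
        for i in range(n):
            for jj in range(i + 1, n):
                if use.any():
                    d[i, jj] = d[jj, i] = float(
                        np.mean(np.abs(mat[i, use] - mat[jj, use]) / rng[use])
                    )
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels, d)


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    variance_explained: float  # SS_between / SS_total
    p: float


def anova_partition(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA with the explained-variance fraction."""
    y = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    if y.size != g.size:
        raise ValueError("values and groups differ in length")
    labels = sorted(set(g.tolist()))
    if len(labels) < 2:
        raise ValueError("at least two groups are required")
    n = y.size
    df_between = len(labels) - 1
    df_within = n - len(labels)
    if df_within < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = 0.0
    for lab in labels:
        sub = y[g == lab]
        ss_between += sub.size * (sub.mean() - grand) ** 2
    ss_within = ss_total - ss_between
    if ss_total == 0:
        return AnovaResult(0.0, df_between, df_within, 0.0, 1.0)
    if ss_within <= 0:
        F = np.inf
        p = 0.0
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), df_between, df_within, ss_between / ss_total, p)


class PermutationResult(NamedTuple):
    observed: AnovaResult
    f_exceedance: float  # (1 + #{perm F >= observed}) / (1 + n_perm)
    ve_exceedance: float
    f_q95: float  # one-sided 95% quantile of the permutation F distribution
    ve_q95: float
    f_perm: np.ndarray
    ve_perm: np.ndarray


def permutation_check(
    values: Sequence[float],
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation null check for the one-way ANOVA.

    Group labels are shuffled uniformly at random ``n_perm`` times; the
    observed F and explained-variance fraction are compared with the
    permutation distribution.  Exceedance fractions use the add-one
    rule (1 + #{perm >= obs}) / (1 + n_perm), so they never reach zero.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    observed = anova_partition(values, groups)
    rng = np.random.default_rng(seed)
    g = np.asarray([str(x) for x in groups])
    f_perm = np.empty(n_perm)
    ve_perm = np.empty(n_perm)
    for i in range(n_perm):
        res = anova_partition(values, rng.permutation(g))
        f_perm[i] = res.F
        ve_perm[i] = res.variance_explained
    f_exc = (1 + int((f_perm >= observed.F).sum())) / (1 + n_perm)
    ve_exc = (1 + int((ve_perm >= observed.variance_explained).sum())) / (1 + n_perm)
    return PermutationResult(
        observed,
        f_exc,
        ve_exc,
        float(np.quantile(f_perm, 0.95)),
        float(np.quantile(ve_perm, 0.95)),
        f_perm,
        ve_perm,
    )
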