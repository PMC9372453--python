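"""Attribution of genome-size differences to specific repeat groups.

Repeat families (e.g. read superclusters from graph-based clustering,
or consensus sequences) are reduced to the k-mers unique to each
family.  Restricting a sample's k-mer dump to such a set and applying
the whole-genome size arithmetic to the subset yields that family's
base-pair contribution to the sample's genome, and differencing two
samples attributes genome-size differences to families.  Because only
family-unique k-mers are used, contributions are underestimates.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .kmerset import KmerDump, RepeatKmerDB, intersect, spectrum_of
from .spectrum import BinScheme, estimate_genome_size
from .compare import JointSpectrum, joint_spectrum

__all__ = [
    "RepeatContribution",
    "repeat_contribution",
    "explained_fraction",
    "repeat_joint_spectrum",
    "contribution_report",
]


@dataclasses.dataclass(frozen=True)
class RepeatContribution:
    """One repeat group's bp contribution to one sample's 2C genome size."""

    group: str
    bp: float
    genome_proportion: float | None = None  # bp / whole-genome 2C estimate


def repeat_contribution(
    sample: KmerDump,
    db: RepeatKmerDB,
    c: float,
    genome_size_2c: float | None = None,
) -> dict[str, RepeatContribution]:
    """Per-group genome-size contributions for one sample.

    For each group the sample dump is restricted to the group's unique
    k-mers and the genome-size arithmetic is applied to the subset,
    with the same multiplicity >= c/2 contamination cutoff as the
    whole-genome estimator.  An empty or absent group contributes 0.
    """
    if sample.k != db.k:
        raise ValueError(f"k mismatch: {sample.k} vs {db.k}")
    if c <= 0:
        raise ValueError("monoploid coverage must be positive")
    out: dict[str, RepeatContribution] = {}
    for label, codes in db.groups.items():
        sub = intersect(sample, codes)
        kept = sub.counts[sub.counts >= c / 2]
        bp = float(kept.sum()) / c
        prop = bp / genome_size_2c if genome_size_2c else None
        out[label] = RepeatContribution(label, bp, prop)
    return out


def explained_fraction(
    pair_diff_bp: float, repeat_diffs: Mapping[str, float]
) -> float:
    """Fraction of a pairwise genome-size difference explained by repeats.

    Sum of per-group bp differences divided by the total pair
    difference; may exceed 1 when the non-repeat fraction changes in
    the opposite direction.
    """
    if pair_diff_bp == 0:
        raise ValueError(
            "explained fraction undefined for a zero genome-size difference"
        )
    return float(sum(repeat_diffs.values())) / pair_diff_bp


def repeat_joint_spectrum(
    sample: KmerDump,
    reference: KmerDump,
    group_kmers,
    c_s: float,
    c_r: float,
    scheme: BinScheme | None = None,
    *,
    join: str = "outer",
) -> JointSpectrum:
    """Joint spectrum restricted to one repeat group's k-mer set.

    Axis A is the sample, axis B the reference individual; a satellite
    with differing copy number shows as a compact off-diagonal cluster.
    """
    sub_s = intersect(sample, group_kmers)
    sub_r = intersect(reference, group_kmers)
    return joint_spectrum(sub_s, sub_r, c_s, c_r, scheme, join=join)


def contribution_report(
    samples: Mapping[str, tuple[KmerDump, float]],
    db: RepeatKmerDB,
) -> pd.DataFrame:
    """Tidy per-(group, sample) contribution table.

    ``samples`` maps a sample name to its (dump, monoploid coverage).
    Columns: group, sample, bp, mbp, genome_proportion.
    """
    rows = []
    for name, (dump, c) in samples.items():
        gs = estimate_genome_size(spectrum_of(dump), c).gs_2c
        contrib = repeat_contribution(dump, db, c, genome_size_2c=gs or None)
        for label, rc in contrib.items():
            rows.append(
                {
                    "group": label,
                    "sample": name,
                    "bp": rc.bp,
                    "mbp": rc.bp / 1e6,
                    "genome_proportion": rc.genome_proportion,
                }
            )
    return pd.DataFrame(rows)
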