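"""File formats: FASTA/FASTQ, k-mer dumps and histograms, result tables.

Dump files follow the KMC/Jellyfish text-dump dialect: one
``KMER<TAB>COUNT`` record per line, sorted ascending by k-mer, no
header.  Histogram files are ``MULTIPLICITY<TAB>COUNT`` lines in
ascending multiplicity; zero-count rows are accepted on read and
omitted on write.  Result tables are TSV with a header line; leading
``#`` comment lines carry the run configuration and are skipped on
read.  All writers are atomic (write to a temp file, then rename).
"""

from __future__ import annotations

import gzip
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .kmerset import KmerDump, Spectrum, decode_codes, encode_kmers
from .spectrum import BinnedSpectrum, BinScheme
from .compare import DiffGraph, DistanceMatrix, JointSpectrum

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_dump",
    "write_dump",
    "read_histogram",
    "write_histogram",
    "read_binned_spectrum",
    "write_binned_spectrum",
    "write_diff_graph",
    "write_joint_table",
    "write_joint_matrix",
    "write_distance_matrix",
    "write_genome_size_report",
]


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _atomic_write(path, render) -> None:
    """Write via a sibling temp file and rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            render(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sequence_format(path) -> str:
    name = os.fspath(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (plain or gzip) as (id, sequence) pairs.

    The format is taken from the file extension; FASTQ qualities are
    ignored.
    """
    fmt = _sequence_format(path)
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    def render(fh):
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    _atomic_write(path, render)


def write_fastq(path, records: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    def render(fh):
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")

    _atomic_write(path, render)


def write_dump(path, dump: KmerDump) -> None:
    kmers = decode_codes(dump.codes, dump.k)

    def render(fh):
        counts = dump.counts
        for i, km in enumerate(kmers):
            fh.write(f"{km}\t{counts[i]}\n")

    _atomic_write(path, render)


def read_dump(path, k: int | None = None) -> KmerDump:
    kmers: list[str] = []
    counts: list[int] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            km, cnt = line.split("\t")
            kmers.append(km)
            counts.append(int(cnt))
    if not kmers:
        if k is None:
            raise ValueError("cannot infer k from an empty dump file; pass k")
        return KmerDump.empty(k)
    k_obs = len(kmers[0])
    if k is not None and k != k_obs:
        raise ValueError(f"dump contains {k_obs}-mers, expected {k}-mers")
    codes = np.empty(len(kmers), dtype=np.uint64)
    for i, km in enumerate(kmers):
        codes[i] = encode_kmers([km], k_obs, canonical=False)[0]
    counts_arr = np.asarray(counts, dtype=np.int64)
    min_count = int(counts_arr.min())
    return KmerDump(k_obs, codes, counts_arr, min_count)


def write_histogram(path, s: Spectrum) -> None:
    def render(fh):
        for m in sorted(s.counts):
            n = s.counts[m]
            if n > 0:
                fh.write(f"{m}\t{n}\n")

    _atomic_write(path, render)


def read_histogram(path, k: int = 21) -> Spectrum:
    counts: dict[int, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m, n = line.split("\t")
            if int(n) != 0:
                counts[int(m)] = int(n)
    return Spectrum(k, counts)


def _write_frame(path, frame: pd.DataFrame, comments: Sequence[str] = ()) -> None:
    def render(fh):
        for c in comments:
            fh.write(f"# {c}\n")
        frame.to_csv(fh, sep="\t", index=False)

    _atomic_write(path, render)


def write_binned_spectrum(path, b: BinnedSpectrum, comments: Sequence[str] = ()) -> None:
    rows = sorted(b.counts.items())
    frame = pd.DataFrame(
        {
            "bin_index": [i for i, _ in rows],
            "lower_bound": [b.scheme.lower(i) for i, _ in rows],
            "upper_bound": [b.scheme.upper(i) for i, _ in rows],
            "representative_cn": [b.scheme.representative(i) for i, _ in rows],
            "kmer_count": [n for _, n in rows],
        }
    )
    _write_frame(path, frame, comments)


def read_binned_spectrum(path, c: float = 1.0) -> BinnedSpectrum:
    frame = pd.read_csv(path, sep="\t", comment="#")
    counts = dict(
        zip(frame["bin_index"].astype(int), frame["kmer_count"].astype(int))
    )
    if len(frame) >= 1:
        i0 = int(frame["bin_index"].iloc[0])
        lo0 = float(frame["lower_bound"].iloc[0])
        up0 = float(frame["upper_bound"].iloc[0])
        growth = up0 / lo0
        origin = lo0 / growth**i0
        scheme = BinScheme(origin, growth)
    else:
        scheme = BinScheme()
    return BinnedSpectrum(scheme, counts, c)


def write_diff_graph(path, d: DiffGraph, comments: Sequence[str] = ()) -> None:
    _write_frame(path, d.to_frame(), comments)


def write_joint_table(path, j: JointSpectrum, comments: Sequence[str] = ()) -> None:
    """Three-column joint-spectrum table (count, bin_a, bin_b); absent = -1."""
    _write_frame(path, j.to_table(), comments)


def write_joint_matrix(path, j: JointSpectrum, comments: Sequence[str] = ()) -> None:
    """Dense joint-spectrum matrix (rows = sample A bins, cols = sample B)."""

    def render(fh):
        for c in comments:
            fh.write(f"# {c}\n")
        j.to_matrix().to_csv(fh, sep="\t", index_label="bin_a")

    _atomic_write(path, render)


def write_distance_matrix(
    path, d: DistanceMatrix, fmt: str = "tsv", comments: Sequence[str] = ()
) -> None:
    """Square distance matrix as labelled TSV or PHYLIP square format."""
    if fmt == "tsv":
        def render(fh):
            for c in comments:
                fh.write(f"# {c}\n")
            d.to_frame().to_csv(fh, sep="\t", index_label="sample")

        _atomic_write(path, render)
    elif fmt == "phylip":
        def render(fh):
            fh.write(f"{len(d.labels)}\n")
            for i, lab in enumerate(d.labels):
                row = " ".join(f"{v:.6f}" for v in d.values[i])
                fh.write(f"{lab[:10]:<10} {row}\n")

        _atomic_write(path, render)
    else:
        raise ValueError(f"unknown distance matrix format {fmt!r}")


def write_genome_size_report(path, rows: Sequence[dict], comments: Sequence[str] = ()) -> None:
    """Genome-size report: sample, coverage, gs_2c_bp, gs_2c_mbp, gs_1c_pg."""
    frame = pd.DataFrame(
        rows, columns=["sample", "coverage", "gs_2c_bp", "gs_2c_mbp", "gs_1c_pg"]
    )
    frame["gs_2c_mbp"] = frame["gs_2c_mbp"].round(2)
    frame["gs_1c_pg"] = frame["gs_1c_pg"].round(2)
    _write_frame(path, frame, comments)
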