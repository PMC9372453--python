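"""Canonical k-mer counting and set algebra over k-mer dumps.

A *k-mer dump* is the identity-aware representation of a sequencing
dataset: a sorted table of canonical k-mers and their multiplicities,
as produced by counters such as KMC or Jellyfish in text-dump mode.
A *k-mer spectrum* is the identity-free tally of those multiplicities.

K-mers are held internally as 2-bit-packed ``uint64`` codes (A=0, C=1,
G=2, T=3, first base most significant), so ascending code order equals
lexicographic string order for a fixed k and set operations reduce to
sorted-array merges.  The canonical form of a k-mer is the
lexicographic minimum of the k-mer and its reverse complement.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "KmerDump",
    "Spectrum",
    "RepeatKmerDB",
    "canonicalize",
    "count_kmers",
    "count_reference_kmers",
    "subtract",
    "intersect",
    "unique_to_group",
    "spectrum_of",
]

# base -> 2-bit code, 255 marks ambiguous symbols
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case
_DECODE_BYTES = b"ACGT"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Collapse raw window codes into a counted pair once this many windows
# have accumulated, to bound peak memory during large counts.
_FLUSH_WINDOWS = 48_000_000


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)):
        raise ValueError(f"k must be an integer, got {k!r}")
    if k < 1 or k > 31 or k % 2 == 0:
        raise ValueError(f"k must be odd and in 1..31, got {k}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _encode_bases(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """Codes of every window of k consecutive unambiguous bases in `seq`."""
    b = _encode_bases(seq)
    n = b.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = b == 255
    ok = None
    if invalid.any():
        csum = np.concatenate(([0], np.cumsum(invalid)))
        ok = (csum[k:] - csum[:-k]) == 0
        if not ok.any():
            return np.empty(0, dtype=np.uint64)
    bb = np.where(invalid, 0, b).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    if canonical:
        rev = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            col = bb[j : j + n]
            fwd = fwd * four + col
            rev = rev + (col << np.uint64(2 * j))
        mask = np.uint64((1 << (2 * k)) - 1)
        fwd = np.minimum(fwd, mask - rev)
    else:
        for j in range(k):
            fwd = fwd * four + bb[j : j + n]
    if ok is not None:
        fwd = fwd[ok]
    return fwd


def encode_kmers(kmers: Iterable[str], k: int, canonical: bool = True) -> np.ndarray:
    """Encode k-mer strings to sorted unique uint64 codes."""
    codes = []
    for km in kmers:
        if len(km) != k:
            raise ValueError(f"k-mer {km!r} has length {len(km)}, expected {k}")
        w = _window_codes(km, k, canonical=canonical)
        if w.size != 1:
            raise ValueError(f"k-mer {km!r} contains an ambiguous base")
        codes.append(w[0])
    if not codes:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.asarray(codes, dtype=np.uint64))


def decode_codes(codes: np.ndarray, k: int) -> list[str]:
    codes = np.asarray(codes, dtype=np.uint64)
    if codes.size == 0:
        return []
    letters = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k):
        letters[:, k - 1 - j] = (
            (codes >> np.uint64(2 * j)) & np.uint64(3)
        ).astype(np.uint8)
    lut = np.frombuffer(_DECODE_BYTES, dtype=np.uint8)
    raw = lut[letters].tobytes()
    return [raw[i : i + k].decode("ascii") for i in range(0, len(raw), k)]


def _iter_sequences(sequences) -> Iterator[str]:
    """Yield plain strings from strings, SeqRecords, Seqs, or (id, seq) pairs."""
    if isinstance(sequences, str):
        sequences = [sequences]
    for item in sequences:
        if isinstance(item, str):
            yield item
        elif isinstance(item, tuple) and len(item) == 2:
            yield str(item[1])
        elif hasattr(item, "seq"):  # Bio.SeqRecord.SeqRecord
            yield str(item.seq)
        else:
            yield str(item)


@dataclasses.dataclass(frozen=True, eq=False)
class KmerDump:
    """Sorted table of canonical k-mers (as uint64 codes) and multiplicities."""

    k: int
    codes: np.ndarray  # uint64, strictly increasing
    counts: np.ndarray  # int64, >= 1
    min_count: int = 1

    def __post_init__(self) -> None:
        _check_k(self.k)
        object.__setattr__(self, "codes", np.asarray(self.codes, dtype=np.uint64))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must have equal length")
        if self.codes.size > 1 and not np.all(np.diff(self.codes.astype(np.int64)) > 0):
            # cast safe: codes < 2**62 for k <= 31
            raise ValueError("dump codes must be strictly increasing")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("multiplicities must be >= 1")

    def __len__(self) -> int:
        return int(self.codes.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, KmerDump):
            return NotImplemented
        return (
            self.k == other.k
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.counts, other.counts)
        )

    @property
    def total_observations(self) -> int:
        """Sum of multiplicities (number of counted windows)."""
        return int(self.counts.sum())

    def kmers(self) -> list[str]:
        return decode_codes(self.codes, self.k)

    def items(self) -> Iterator[tuple[str, int]]:
        counts = self.counts
        for i, km in enumerate(self.kmers()):
            yield km, int(counts[i])

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    def get(self, kmer: str, default: int = 0) -> int:
        code = encode_kmers([kmer], self.k)
        idx = np.searchsorted(self.codes, code[0])
        if idx < self.codes.size and self.codes[idx] == code[0]:
            return int(self.counts[idx])
        return default

    @classmethod
    def from_dict(cls, k: int, mapping: Mapping[str, int], min_count: int = 1) -> "KmerDump":
        kmers = list(mapping)
        codes = []
        counts = []
        for km in kmers:
            c = encode_kmers([km], k)[0]
            codes.append(c)
            counts.append(int(mapping[km]))
        if not codes:
            return cls(k, np.empty(0, np.uint64), np.empty(0, np.int64), min_count)
        codes_arr = np.asarray(codes, dtype=np.uint64)
        counts_arr = np.asarray(counts, dtype=np.int64)
        order = np.argsort(codes_arr)
        codes_arr, counts_arr = codes_arr[order], counts_arr[order]
        if np.any(np.diff(codes_arr.astype(np.int64)) == 0):
            raise ValueError("duplicate k-mers after canonicalization")
        return cls(k, codes_arr, counts_arr, min_count)

    @classmethod
    def empty(cls, k: int, min_count: int = 1) -> "KmerDump":
        return cls(k, np.empty(0, np.uint64), np.empty(0, np.int64), min_count)


@dataclasses.dataclass(frozen=True, eq=False)
class Spectrum:
    """K-mer spectrum: distinct-k-mer count per multiplicity level."""

    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        _check_k(self.k)
        clean: dict[int, int] = {}
        for m in sorted(self.counts):
            n = int(self.counts[m])
            if m < 1:
                raise ValueError(f"multiplicity must be >= 1, got {m}")
            if n < 0:
                raise ValueError(f"count must be >= 0, got {n}")
            clean[int(m)] = n
        object.__setattr__(self, "counts", clean)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return self.k == other.k and self.counts == other.counts

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))
        n = np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))
        return m, n

    @property
    def distinct_kmers(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def total_observations(self) -> int:
        return int(sum(m * n for m, n in self.counts.items()))

    @property
    def max_multiplicity(self) -> int:
        return max(self.counts) if self.counts else 0


@dataclasses.dataclass(frozen=True, eq=False)
class RepeatKmerDB:
    """Per-group sets of k-mers unique to each repeat group (globally disjoint)."""

    k: int
    groups: dict[str, np.ndarray]  # label -> sorted uint64 codes

    def __post_init__(self) -> None:
        _check_k(self.k)
        clean = {
            str(lab): np.asarray(codes, dtype=np.uint64)
            for lab, codes in self.groups.items()
        }
        object.__setattr__(self, "groups", clean)

    def labels(self) -> list[str]:
        return list(self.groups)

    def kmers(self, label: str) -> list[str]:
        return decode_codes(self.groups[label], self.k)

    def size(self, label: str) -> int:
        return int(self.groups[label].size)


def _merge_counted(pairs: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    codes = np.concatenate([p[0] for p in pairs])
    weights = np.concatenate([p[1] for p in pairs])
    uniq, inv = np.unique(codes, return_inverse=True)
    summed = np.bincount(inv, weights=weights.astype(np.float64))
    return uniq, summed.astype(np.int64)


def count_kmers(
    sequences,
    k: int = 21,
    min_count: int = 2,
    *,
    canonical: bool = True,
) -> KmerDump:
    """Count canonical k-mers over a collection of sequences.

    Every window of k consecutive unambiguous bases contributes one
    observation to its canonical form; windows containing non-ACGT
    symbols are skipped.  Entries with multiplicity below ``min_count``
    are removed (the counter default of 2 drops most sequencing-error
    k-mers from read data).
    """
    _check_k(k)
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    raw: list[np.ndarray] = []
    counted: list[tuple[np.ndarray, np.ndarray]] = []
    pending = 0
    # short sequences (reads) are batched into large N-joined buffers:
    # windows spanning the separator contain an ambiguous symbol and are
    # skipped, so batching is exact and avoids per-read overhead
    buffer: list[str] = []
    buffered = 0

    def _flush_buffer():
        nonlocal buffered, pending
        if buffer:
            w = _window_codes("N".join(buffer), k, canonical=canonical)
            if w.size:
                raw.append(w)
                pending += w.size
            buffer.clear()
            buffered = 0

    for seq in _iter_sequences(sequences):
        buffer.append(seq)
        buffered += len(seq)
        if buffered >= 4_000_000:
            _flush_buffer()
        if pending >= _FLUSH_WINDOWS:
            u, c = np.unique(np.concatenate(raw), return_counts=True)
            counted.append((u, c.astype(np.int64)))
            raw, pending = [], 0
    _flush_buffer()
    if raw:
        u, c = np.unique(np.concatenate(raw), return_counts=True)
        counted.append((u, c.astype(np.int64)))
    if not counted:
        return KmerDump.empty(k, min_count)
    codes, counts = counted[0] if len(counted) == 1 else _merge_counted(counted)
    if min_count > 1:
        keep = counts >= min_count
        codes, counts = codes[keep], counts[keep]
    return KmerDump(k, codes, counts, min_count)


def count_reference_kmers(sequences, k: int = 21, *, canonical: bool = True) -> KmerDump:
    """Count k-mers of an assembly, keeping multiplicity-1 entries.

    Assemblies represent each locus once, so unlike read data their
    singleton k-mers are genuine; this mirrors running a counter with
    its minimum-count filter disabled.
    """
    return count_kmers(sequences, k, min_count=1, canonical=canonical)


def _membership(codes: np.ndarray, sorted_other: np.ndarray) -> np.ndarray:
    """Boolean mask of which `codes` occur in the sorted array `sorted_other`."""
    if sorted_other.size == 0 or codes.size == 0:
        return np.zeros(codes.size, dtype=bool)
    idx = np.searchsorted(sorted_other, codes)
    idx_c = np.minimum(idx, sorted_other.size - 1)
    return (idx < sorted_other.size) & (sorted_other[idx_c] == codes)


def subtract(a: KmerDump, b: KmerDump) -> KmerDump:
    """Entries of `a` whose k-mer is absent from `b` (e.g. organelle removal)."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    mask = ~_membership(a.codes, b.codes)
    return KmerDump(a.k, a.codes[mask], a.counts[mask], a.min_count)


def _as_code_array(keys, k: int) -> np.ndarray:
    if isinstance(keys, KmerDump):
        if keys.k != k:
            raise ValueError(f"k mismatch: {keys.k} vs {k}")
        return keys.codes
    if isinstance(keys, np.ndarray):
        return np.unique(keys.astype(np.uint64))
    keys = list(keys)
    if keys and isinstance(keys[0], str):
        return encode_kmers(keys, k)
    return np.unique(np.asarray(keys, dtype=np.uint64))


def intersect(a: KmerDump, keys) -> KmerDump:
    """Entries of `a` restricted to a key set (strings, codes, or another dump)."""
    code_keys = _as_code_array(keys, a.k)
    mask = _membership(a.codes, code_keys)
    return KmerDump(a.k, a.codes[mask], a.counts[mask], a.min_count)


def unique_to_group(groups, k: int = 21) -> RepeatKmerDB:
    """Per-group k-mer sets restricted to k-mers found in no other group.

    ``groups`` maps a label to a sequence collection (one repeat family
    each).  K-mers shared between any two groups are dropped from both,
    so the resulting sets are globally pairwise disjoint.
    """
    if isinstance(groups, Mapping):
        pairs = list(groups.items())
    else:
        pairs = list(groups)
    labels = [str(lab) for lab, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    if not pairs:
        raise ValueError("at least one group is required")
    per_group: dict[str, np.ndarray] = {}
    for lab, seqs in pairs:
        per_group[str(lab)] = count_reference_kmers(seqs, k).codes
    all_codes = np.concatenate(list(per_group.values())) if per_group else np.empty(0, np.uint64)
    uniq, occurrences = np.unique(all_codes, return_counts=True)
    shared = uniq[occurrences > 1]
    out = {
        lab: codes[~_membership(codes, shared)] for lab, codes in per_group.items()
    }
    return RepeatKmerDB(k, out)


def spectrum_of(a: KmerDump) -> Spectrum:
    """Tally a dump's multiplicities into a k-mer spectrum."""
    if len(a) == 0:
        return Spectrum(a.k, {})
    m, n = np.unique(a.counts, return_counts=True)
    return Spectrum(a.k, dict(zip(m.tolist(), n.tolist())))
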