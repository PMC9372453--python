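"""Synthetic diploid genomes, organelle contaminants and shotgun reads.

The generator emulates the genome architecture the k-mer pipeline is
designed to resolve: a diploid with two haplotypes differing by i.i.d.
substitutions (heterozygosity), a head-to-tail satellite array, a
dispersed transposable-element family with per-copy divergence, a
high-copy tandem rDNA-like block, and an organellar molecule sequenced
at a much higher relative depth.  Reads are fixed-length with uniform
start positions and substitution errors only — k-mer identity methods
never inspect alignments, so indel realism adds nothing here.

Every simulation is driven by an explicit integer seed and emits an
exact ground-truth table, so every pipeline stage can be verified
without external data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .kmerset import KmerDump, count_reference_kmers

__all__ = [
    "GenomeSpec",
    "ReadSpec",
    "FamilyTruth",
    "TruthTable",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_reads",
    "make_pair",
    "planted_difference",
    "expected_monoploid_multiplicity",
]

_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

_READ_CHUNK = 200_000


def _decode(arr: np.ndarray) -> str:
    return _LUT[arr].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _decode(rng.integers(0, 4, length, dtype=np.uint8))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability `rate`."""
    if rate <= 0:
        return seq
    arr = _encode(seq).copy()
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        arr[mask] = (arr[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return _decode(arr)


@dataclasses.dataclass(frozen=True)
class GenomeSpec:
    """Architecture of a simulated diploid genome.

    Defaults are a desk-scale rendering of a heterozygous plant genome:
    1 Mbp of single-copy sequence, 0.5% heterozygosity, a 145-nt
    satellite at 1,500 copies per haplotype (~3,000 per 2C genome), a
    5-kb TE family at 30 dispersed copies with 2% per-copy divergence,
    a 10-kb rDNA-like unit at 20 tandem copies, and a 150-kb organelle
    sequenced at 20x the nuclear per-haplotype depth.
    """

    unique_len: int = 1_000_000
    heterozygosity: float = 0.005  # per-site substitution prob between haplotypes
    satellite: tuple[int, int] = (145, 1_500)  # (monomer bp, copies per haplotype)
    te: tuple[int, int, float] = (5_000, 30, 0.02)  # (bp, copies, divergence)
    rdna: tuple[int, int] = (10_000, 20)  # (unit bp, tandem copies)
    organelle: tuple[int, float] = (150_000, 20.0)  # (bp, relative depth)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.heterozygosity < 1:
            raise ValueError("heterozygosity must be in [0, 1)")
        for name, length in (
            ("unique_len", self.unique_len),
            ("satellite monomer", self.satellite[0]),
            ("te element", self.te[0]),
            ("rdna unit", self.rdna[0]),
            ("organelle", self.organelle[0]),
        ):
            if length <= 21:
                raise ValueError(f"{name} length must exceed the k-mer length")
        for name, copies in (
            ("satellite", self.satellite[1]),
            ("te", self.te[1]),
            ("rdna", self.rdna[1]),
        ):
            if copies < 0:
                raise ValueError(f"{name} copies must be >= 0")


@dataclasses.dataclass(frozen=True)
class ReadSpec:
    """Shotgun read simulation parameters (coverage is per haplotype)."""

    coverage: float = 30.0
    read_length: int = 150
    error_rate: float = 0.002
    paired: bool = False  # cosmetic for k-mer counting; /1 and /2 name suffixes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")
        if self.read_length < 1:
            raise ValueError("read length must be positive")


@dataclasses.dataclass(frozen=True)
class FamilyTruth:
    """Ground truth for one repeat family (as placed on haplotype A)."""

    name: str
    unit_length: int
    copies_per_haplotype: int
    bp_per_haplotype: int
    kmer_codes: np.ndarray  # distinct canonical 21-mer codes within family copies

    @property
    def distinct_kmers(self) -> int:
        return int(self.kmer_codes.size)


@dataclasses.dataclass(frozen=True)
class TruthTable:
    size_1c: int  # bp of haplotype A
    size_2c: int  # bp of both haplotypes
    heterozygosity: float
    families: dict[str, FamilyTruth]
    seed: int


@dataclasses.dataclass(frozen=True)
class SimulatedGenome:
    haplotype_a: str
    haplotype_b: str
    organelle: str
    organelle_depth: float  # relative to per-haplotype nuclear depth
    truth: TruthTable
    spec: GenomeSpec


@dataclasses.dataclass(frozen=True)
class _Components:
    """Shared raw material for one genome or a related pair."""

    unique: str
    monomer: str
    te_instances: tuple[str, ...]
    te_positions: tuple[int, ...]  # insertion points in the unique sequence
    rdna_unit: str
    organelle: str


def _build_components(spec: GenomeSpec, sat_max: int, te_max: int, rdna_max: int) -> _Components:
    ss = np.random.SeedSequence(spec.seed)
    (s_unique, s_monomer, s_te, s_tepos, s_rdna, s_org, _s_het) = ss.spawn(7)
    rng_unique = np.random.default_rng(s_unique)
    unique = _random_sequence(rng_unique, spec.unique_len)
    monomer = _random_sequence(np.random.default_rng(s_monomer), spec.satellite[0])
    te_rng = np.random.default_rng(s_te)
    element = _random_sequence(te_rng, spec.te[0])
    te_instances = tuple(
        _mutate(element, spec.te[2], te_rng) for _ in range(te_max)
    )
    pos_rng = np.random.default_rng(s_tepos)
    te_positions = tuple(
        sorted(pos_rng.integers(0, spec.unique_len + 1, te_max).tolist())
    )
    rdna_unit = _random_sequence(np.random.default_rng(s_rdna), spec.rdna[0])
    organelle = _random_sequence(np.random.default_rng(s_org), spec.organelle[0])
    return _Components(unique, monomer, te_instances, te_positions, rdna_unit, organelle)


def _family_kmers(segments: Sequence[str], k: int = 21) -> np.ndarray:
    dump = count_reference_kmers(list(segments), k)
    return dump.codes


def _assemble(
    spec: GenomeSpec,
    comp: _Components,
    sat_copies: int,
    te_copies: int,
    rdna_copies: int,
    het_seed: np.random.SeedSequence,
) -> SimulatedGenome:
    pieces = []
    prev = 0
    for pos, inst in zip(comp.te_positions[:te_copies], comp.te_instances[:te_copies]):
        pieces.append(comp.unique[prev:pos])
        pieces.append(inst)
        prev = pos
    pieces.append(comp.unique[prev:])
    sat_array = comp.monomer * sat_copies
    rdna_array = comp.rdna_unit * rdna_copies
    hap_a = "".join(pieces) + sat_array + rdna_array
    hap_b = _mutate(hap_a, spec.heterozygosity, np.random.default_rng(het_seed))
    families = {
        "satellite": FamilyTruth(
            "satellite",
            spec.satellite[0],
            sat_copies,
            len(sat_array),
            _family_kmers([sat_array]) if sat_array else np.empty(0, np.uint64),
        ),
        "te": FamilyTruth(
            "te",
            spec.te[0],
            te_copies,
            spec.te[0] * te_copies,
            _family_kmers(comp.te_instances[:te_copies])
            if te_copies
            else np.empty(0, np.uint64),
        ),
        "rdna": FamilyTruth(
            "rdna",
            spec.rdna[0],
            rdna_copies,
            len(rdna_array),
            _family_kmers([rdna_array]) if rdna_array else np.empty(0, np.uint64),
        ),
    }
    truth = TruthTable(
        size_1c=len(hap_a),
        size_2c=len(hap_a) + len(hap_b),
        heterozygosity=spec.heterozygosity,
        families=families,
        seed=spec.seed,
    )
    return SimulatedGenome(
        hap_a, hap_b, comp.organelle, spec.organelle[1], truth, spec
    )


def simulate_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Simulate one diploid genome plus organelle, with exact ground truth.

    Haplotype B is haplotype A with i.i.d. substitutions at the
    heterozygosity rate; repeat families are planted as specified.
    Identical specs (including seed) yield byte-identical genomes.
    """
    comp = _build_components(
        spec, spec.satellite[1], spec.te[1], spec.rdna[1]
    )
    het_seed = np.random.SeedSequence(spec.seed).spawn(7)[6]
    return _assemble(
        spec, comp, spec.satellite[1], spec.te[1], spec.rdna[1], het_seed
    )


def make_pair(
    spec: GenomeSpec, delta: Mapping[str, int]
) -> tuple[SimulatedGenome, SimulatedGenome]:
    """Two related diploid genomes differing only by planted repeat-copy edits.

    ``delta`` maps family name ('satellite', 'te', 'rdna') to a change
    in copies per haplotype applied to the second genome.  Shared
    repeat copies are identical between the genomes; each genome draws
    its own heterozygous substitutions.
    """
    base = {"satellite": spec.satellite[1], "te": spec.te[1], "rdna": spec.rdna[1]}
    for fam, d in delta.items():
        if fam not in base:
            raise ValueError(f"unknown repeat family {fam!r}")
        if base[fam] + d < 0:
            raise ValueError(
                f"cannot remove {-d} copies of {fam!r}: only {base[fam]} exist"
            )
    edited = {fam: base[fam] + int(delta.get(fam, 0)) for fam in base}
    comp = _build_components(
        spec,
        max(base["satellite"], edited["satellite"]),
        max(base["te"], edited["te"]),
        max(base["rdna"], edited["rdna"]),
    )
    seeds = np.random.SeedSequence(spec.seed).spawn(9)
    g1 = _assemble(spec, comp, base["satellite"], base["te"], base["rdna"], seeds[6])
    g2 = _assemble(
        spec, comp, edited["satellite"], edited["te"], edited["rdna"], seeds[8]
    )
    return g1, g2


def planted_difference(g1: SimulatedGenome, g2: SimulatedGenome) -> dict[str, float]:
    """Per-family planted 2C bp difference (genome 2 minus genome 1)."""
    out = {}
    for fam in g1.truth.families:
        f1, f2 = g1.truth.families[fam], g2.truth.families[fam]
        out[fam] = 2.0 * (f2.bp_per_haplotype - f1.bp_per_haplotype)
    return out


def _reads_from(
    seq: str, depth: float, read_spec: ReadSpec, rng: np.random.Generator, prefix: str
) -> tuple[list[str], list[str]]:
    L = read_spec.read_length
    if L > len(seq):
        raise ValueError(
            f"read length {L} exceeds template length {len(seq)}"
        )
    n_reads = int(round(depth * len(seq) / L))
    names: list[str] = []
    seqs: list[str] = []
    arr = _encode(seq)
    offsets = np.arange(L)
    done = 0
    while done < n_reads:
        chunk = min(_READ_CHUNK, n_reads - done)
        starts = rng.integers(0, len(seq) - L + 1, chunk)
        mat = arr[starts[:, None] + offsets]
        if read_spec.error_rate > 0:
            mask = rng.random(mat.shape) < read_spec.error_rate
            n_err = int(mask.sum())
            if n_err:
                mat[mask] = (mat[mask] + rng.integers(1, 4, n_err, dtype=np.uint8)) % 4
        raw = _LUT[mat].tobytes()
        for i in range(chunk):
            seqs.append(raw[i * L : (i + 1) * L].decode("ascii"))
            names.append(f"{prefix}_{done + i}")
        done += chunk
    if read_spec.paired:
        names = [
            f"{nm}/{1 + (i % 2)}" for i, nm in enumerate(names)
        ]
    return names, seqs


def simulate_reads(
    genome: SimulatedGenome | str | Sequence[str],
    spec: ReadSpec,
    *,
    include_organelle: bool = True,
) -> list[tuple[str, str]]:
    """Draw substitution-error shotgun reads as (name, sequence) pairs.

    For a :class:`SimulatedGenome`, both haplotypes are sampled at the
    per-haplotype coverage and the organelle at its relative depth
    multiplier.  Plain sequences are sampled at ``spec.coverage``.
    Identical specs yield identical reads.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    names: list[str] = []
    seqs: list[str] = []
    if isinstance(genome, SimulatedGenome):
        sources = [
            ("hapA", genome.haplotype_a, spec.coverage),
            ("hapB", genome.haplotype_b, spec.coverage),
        ]
        if include_organelle and genome.organelle_depth > 0:
            sources.append(
                ("org", genome.organelle, spec.coverage * genome.organelle_depth)
            )
    elif isinstance(genome, str):
        sources = [("seq", genome, spec.coverage)]
    else:
        sources = [(f"seq{i}", s, spec.coverage) for i, s in enumerate(genome)]
    for prefix, seq, depth in sources:
        nm, sq = _reads_from(seq, depth, spec, rng, prefix)
        names.extend(nm)
        seqs.extend(sq)
    return list(zip(names, seqs))


def expected_monoploid_multiplicity(spec: ReadSpec, k: int = 21) -> float:
    """Expected multiplicity of an error-free single-copy (heterozygous) k-mer.

    A read of length L covers L - k + 1 of the L genomic k-mer starts
    it spans, and a window survives only if all k bases are error-free.
    """
    L = spec.read_length
    if L < k:
        return 0.0
    return spec.coverage * (L - k + 1) / L * (1 - spec.error_rate) ** k
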