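"""Fidelity metrics and synthetic fixtures.

The Bray-Curtis (BC) dissimilarity,

    D(X, Y) = sum_k |x_k - y_k| / sum_k (x_k + y_k),

measures how far apart two non-negative vectors are: 0 for
proportionally identical vectors, 1 for disjoint support.  Vectors are
normalized to proportions before comparison, because every quantity the
metric is applied to here (community compositions, error-type triples,
per-window coverage) is proportional by nature; on normalized input the
formula reduces to ``0.5 * sum |x - y|``.

The fixture generator builds synthetic communities in three complexity
presets — LC (2 genomes, one dominant), MC (9 genomes in 5 abundance
levels, two dominant) and HC (11 genomes, equal abundance) — so the
entire pipeline is testable without downloading reference genomes or
sequencing runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional

import numpy as np
from scipy.spatial.distance import braycurtis
from scipy.stats import pearsonr

from .composition import CommunityComposition
from .coverage_model import CoverageProfile, DEFAULT_INTERVAL_SIZE
from .seq_io import AlignmentRecord, GenomeDB
from .simulator import READ_ID_PREFIX, SimulatedRead

__all__ = [
    "AbundanceVector",
    "Fixture",
    "bc_distance",
    "coverage_compare",
    "make_fixture",
    "oracle_alignments",
    "true_alignments",
    "PRESET_ABUNDANCES",
]


@dataclass
class AbundanceVector:
    """Labelled non-negative vector (a composition, error triple, ...)."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values differ in length")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and non-negative")
        if not np.any(self.values > 0):
            raise ValueError("at least one value must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "AbundanceVector":
        return cls(tuple(mapping.keys()), np.array(list(mapping.values())))


def _coerce(x) -> AbundanceVector:
    if isinstance(x, AbundanceVector):
        return x
    if isinstance(x, CommunityComposition):
        return AbundanceVector.from_mapping(x.entries)
    if isinstance(x, Mapping):
        return AbundanceVector.from_mapping(x)
    values = np.asarray(x, dtype=float)
    return AbundanceVector(tuple(range(len(values))), values)


def bc_distance(x, y) -> float:
    """Bray-Curtis dissimilarity between two abundance vectors.

    Inputs may be :class:`AbundanceVector`, compositions, mappings or
    plain sequences.  Labelled inputs are aligned by label (and must
    carry the same label set); both vectors are normalized to sum 1
    before the distance is taken.
    """
    xv, yv = _coerce(x), _coerce(y)
    if len(xv.labels) != len(yv.labels):
        raise ValueError(
            f"dimension mismatch: {len(xv.labels)} vs {len(yv.labels)}"
        )
    if xv.labels != yv.labels:
        if set(xv.labels) != set(yv.labels):
            raise ValueError("vectors carry different label sets")
        order = {lab: i for i, lab in enumerate(yv.labels)}
        yvals = np.empty_like(yv.values)
        for i, lab in enumerate(xv.labels):
            yvals[i] = yv.values[order[lab]]
    else:
        yvals = yv.values
    a = xv.values / xv.values.sum()
    b = yvals / yvals.sum()
    return float(braycurtis(a, b))


def coverage_compare(
    a: CoverageProfile,
    b: CoverageProfile,
    first_n_intervals: Optional[int] = None,
) -> tuple[float, float]:
    """(BC distance, Pearson r) between two coverage profiles.

    BC is computed on normalized weights; Pearson r on the raw weights
    (normalization cancels under Pearson anyway).  Profiles must share
    the genome and interval size.
    """
    if a.genome_id != b.genome_id:
        raise ValueError(
            f"profiles cover different genomes: {a.genome_id!r} vs {b.genome_id!r}"
        )
    if a.interval_size != b.interval_size or a.n_intervals != b.n_intervals:
        raise ValueError("profiles have different interval structure")
    n = first_n_intervals if first_n_intervals is not None else a.n_intervals
    if n > a.n_intervals:
        raise ValueError(f"only {a.n_intervals} intervals available")
    wa, wb = a.weights[:n], b.weights[:n]
    bc = bc_distance(wa, wb)
    r = float(pearsonr(wa, wb).statistic)
    return bc, r


# ---------------------------------------------------------------------------
# Synthetic fixtures

#: complexity presets: relative abundances of the community members
PRESET_ABUNDANCES = {
    # two species, one dominant
    "LC": (0.9, 0.1),
    # nine species in five abundance levels, two dominant
    "MC": (0.25, 0.25, 0.12, 0.12, 0.08, 0.08, 0.04, 0.04, 0.02),
    # eleven species, equal abundance
    "HC": tuple([1.0 / 11.0] * 11),
}


class Fixture(NamedTuple):
    db: GenomeDB
    composition: CommunityComposition
    profiles: Optional[dict[str, CoverageProfile]]


def make_fixture(
    preset: Optional[str] = None,
    n_genomes: Optional[int] = None,
    genome_length: int = 100_000,
    gc: float = 0.5,
    seed: int = 0,
    bias: bool = False,
    bias_amplitude: float = 0.8,
    bias_period: int = 20,
    interval_size: int = DEFAULT_INTERVAL_SIZE,
) -> Fixture:
    """Deterministic synthetic community: i.i.d. genomes at the requested
    GC content plus a composition (preset or uniform over ``n_genomes``).

    With ``bias=True`` each genome also gets a sinusoidal coverage
    profile, ``w_i = 1 + A sin(2 pi i / period)``, handy for bias
    round-trip tests.
    """
    if preset is not None:
        if preset not in PRESET_ABUNDANCES:
            raise ValueError(f"unknown preset {preset!r}; use LC, MC or HC")
        abundances = PRESET_ABUNDANCES[preset]
    elif n_genomes is not None:
        if n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        abundances = tuple([1.0 / n_genomes] * n_genomes)
    else:
        raise ValueError("give either a preset or n_genomes")
    if genome_length < 1_000:
        raise ValueError("genome_length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    if not 0.0 < bias_amplitude < 1.0:
        raise ValueError("bias_amplitude must be in (0, 1)")

    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    entries = {}
    for i in range(len(abundances)):
        draws = rng.choice(alphabet, size=genome_length, p=p)
        entries[f"g{i + 1:02d}"] = draws.tobytes().decode("ascii")
    db = GenomeDB(entries)
    comp = CommunityComposition(
        dict(zip(entries, abundances)), provenance="given"
    )

    profiles = None
    if bias:
        n_int = -(-genome_length // interval_size)
        idx = np.arange(n_int)
        profiles = {
            g: CoverageProfile(
                genome_id=g,
                genome_length=genome_length,
                weights=1.0
                + bias_amplitude * np.sin(2 * np.pi * (idx + shift) / bias_period),
                interval_size=interval_size,
            )
            for shift, g in enumerate(entries)
        }
    return Fixture(db, comp, profiles)


# ---------------------------------------------------------------------------
# Provenance-based alignments (stand-ins for a real mapper in closed loops)


def _parse_provenance(read_id: str):
    core, _, mate = read_id.partition("/")
    fields = core.split("|")
    if len(fields) != 6 or fields[0] != READ_ID_PREFIX:
        raise ValueError(f"read id {read_id!r} carries no simulation provenance")
    _, gid, lo, hi, strand, _serial = fields
    return gid, int(lo), int(hi), strand


def oracle_alignments(
    reads: Iterable,
) -> Iterator[AlignmentRecord]:
    """Perfect-match alignments at each read's true origin.

    Accepts :class:`SimulatedRead` objects or any record with a
    provenance-bearing ``read_id`` and ``sequence``.  The alignment is
    all-M at the recorded coordinates (MD = read length, NM = injected
    substitution count when known) — the closed-loop replacement for
    running a mapper when only *where* the read belongs matters.
    """
    for read in reads:
        gid, lo, hi, strand = _parse_provenance(read.read_id)
        n = len(read.sequence)
        nm = read.n_sub if isinstance(read, SimulatedRead) else 0
        yield AlignmentRecord(
            read_id=read.read_id,
            genome_id=gid,
            start=lo,
            cigar=[("M", n)],
            md=str(n),
            nm=nm,
            is_mapped=True,
            sequence=read.sequence,
        )


def true_alignments(
    reads: Iterable[SimulatedRead],
) -> Iterator[AlignmentRecord]:
    """Exact alignments reconstructed from each read's edit list.

    CIGAR, MD and NM reflect every injected error, so re-estimating an
    error model from these alignments closes the loop on the simulator.
    Alignments are emitted in read orientation (the reference is the
    oriented template), which is the frame the error model itself is
    defined in; error counting never consults the start coordinate.
    """
    for read in reads:
        cigar: list[tuple[str, int]] = []
        md_parts: list[str] = []
        match_run = 0  # MD: matches since last mismatch/deletion

        def push_cigar(op: str, n: int) -> None:
            if n == 0:
                return
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + n)
            else:
                cigar.append((op, n))

        t = 0  # template offset
        c = 0  # read offset
        in_del = False
        for op, et, ec, ref_base, read_base in read.edits:
            matches = et - t
            if matches:
                push_cigar("M", matches)
                match_run += matches
                t += matches
                c += matches
                in_del = False
            if op == "S":
                push_cigar("M", 1)
                md_parts.append(f"{match_run}{ref_base}")
                match_run = 0
                t += 1
                c += 1
                in_del = False
            elif op == "I":
                push_cigar("I", 1)
                c += 1
                in_del = False
            else:  # deletion
                push_cigar("D", 1)
                if in_del:
                    md_parts[-1] += ref_base
                else:
                    md_parts.append(f"{match_run}^{ref_base}")
                    match_run = 0
                in_del = True
                t += 1
        tail = len(read.sequence) - c
        if tail:
            push_cigar("M", tail)
            match_run += tail
        md_parts.append(str(match_run))
        yield AlignmentRecord(
            read_id=read.read_id,
            genome_id=read.genome_id,
            start=read.start,
            cigar=cigar,
            md="".join(md_parts),
            nm=read.n_ins + read.n_del + read.n_sub,
            is_mapped=True,
            sequence=read.sequence,
        )
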