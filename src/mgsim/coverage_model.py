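"""Sequencing coverage bias: estimation and biased position sampling.

Each genome is divided into fixed-width intervals (100 bp by default).
A mapped read adds one count to the interval containing its leftmost
coordinate, and every interval starts from a pseudo-count (0.1) so that
unobserved intervals keep a small sampling probability.  During
simulation a read start is drawn by first picking an interval with
probability proportional to its weight, then a position uniformly within
the interval; the start is clamped so the read fits inside the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .seq_io import AlignmentRecord, GenomeDB

__all__ = [
    "CoverageProfile",
    "estimate_coverage",
    "sample_position",
    "sample_positions",
    "write_bias_table",
    "read_bias_table",
]

DEFAULT_INTERVAL_SIZE = 100
DEFAULT_PSEUDO = 0.1


@dataclass
class CoverageProfile:
    """Per-interval sampling weights for one genome.

    A profile is keyed to the genome (and genome length) it was
    estimated from; applying it elsewhere is an error, not a rescale.
    """

    genome_id: str
    genome_length: int
    weights: np.ndarray
    interval_size: int = DEFAULT_INTERVAL_SIZE
    pseudo: float = DEFAULT_PSEUDO

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        expected = -(-self.genome_length // self.interval_size)  # ceil
        if len(self.weights) != expected:
            raise ValueError(
                f"{self.genome_id}: {len(self.weights)} intervals for a "
                f"{self.genome_length}-bp genome at interval size "
                f"{self.interval_size} (expected {expected})"
            )
        if np.any(self.weights <= 0):
            raise ValueError(f"{self.genome_id}: non-positive interval weight")

    @property
    def n_intervals(self) -> int:
        return len(self.weights)

    def probabilities(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def estimate_coverage(
    alignments: Iterable[AlignmentRecord],
    db: GenomeDB,
    interval_size: int = DEFAULT_INTERVAL_SIZE,
    pseudo: float = DEFAULT_PSEUDO,
) -> dict[str, CoverageProfile]:
    """Bin mapped reads by start coordinate into per-genome profiles.

    Every genome in the database gets a profile; genomes without hits
    keep the pseudo-count floor in every interval.
    """
    weights = {
        g: np.full(-(-db.size(g) // interval_size), pseudo) for g in db
    }
    for rec in alignments:
        if not rec.is_mapped or rec.genome_id is None:
            continue
        if rec.genome_id not in weights:
            raise KeyError(f"alignment references unknown genome {rec.genome_id!r}")
        if not 0 <= rec.start < db.size(rec.genome_id):
            raise ValueError(
                f"read {rec.read_id!r}: start {rec.start} outside genome "
                f"{rec.genome_id!r}"
            )
        weights[rec.genome_id][rec.start // interval_size] += 1.0
    return {
        g: CoverageProfile(
            genome_id=g,
            genome_length=db.size(g),
            weights=w,
            interval_size=interval_size,
            pseudo=pseudo,
        )
        for g, w in weights.items()
    }


def sample_positions(
    profile: CoverageProfile,
    read_lengths: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized biased start sampling for a batch of reads.

    Each start is drawn interval-proportionally, uniform within the
    interval, then clamped so that ``start + read_length`` stays inside
    the genome.
    """
    read_lengths = np.asarray(read_lengths)
    if np.any(read_lengths > profile.genome_length):
        raise ValueError(
            f"read longer than genome {profile.genome_id!r} "
            f"({profile.genome_length} bp)"
        )
    k = len(read_lengths)
    intervals = rng.choice(profile.n_intervals, size=k, p=profile.probabilities())
    offsets = rng.integers(0, profile.interval_size, size=k)
    starts = intervals * profile.interval_size + offsets
    return np.minimum(starts, profile.genome_length - read_lengths)


def sample_position(
    profile: CoverageProfile, read_length: int, rng: np.random.Generator
) -> int:
    """Draw one 0-based start coordinate under the coverage bias."""
    return int(sample_positions(profile, np.array([read_length]), rng)[0])


# ---------------------------------------------------------------------------
# Bias tables: TSV genome_id <TAB> interval_index <TAB> weight


def write_bias_table(profiles: dict[str, CoverageProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("# genome_id\tinterval_index\tweight\n")
        for g, prof in profiles.items():
            fh.write(
                f"#meta\t{g}\t{prof.genome_length}\t{prof.interval_size}"
                f"\t{prof.pseudo!r}\n"
            )
        for g, prof in profiles.items():
            for i, w in enumerate(prof.weights):
                fh.write(f"{g}\t{i}\t{float(w)!r}\n")


def read_bias_table(path) -> dict[str, CoverageProfile]:
    meta: dict[str, tuple[int, int, float]] = {}
    rows: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#meta\t"):
                _, g, length, isz, pseudo = line.split("\t")
                meta[g] = (int(length), int(isz), float(pseudo))
                continue
            if line.startswith("#"):
                continue
            g, idx, w = line.split("\t")
            rows.setdefault(g, {})[int(idx)] = float(w)
    profiles = {}
    for g, by_idx in rows.items():
        if g not in meta:
            raise ValueError(f"bias table lacks a #meta line for genome {g!r}")
        length, isz, pseudo = meta[g]
        weights = np.array([by_idx[i] for i in sorted(by_idx)])
        profiles[g] = CoverageProfile(
            genome_id=g,
            genome_length=length,
            weights=weights,
            interval_size=isz,
            pseudo=pseudo,
        )
    return profiles
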