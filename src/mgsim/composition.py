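"""Community-composition estimation from read-to-genome alignments.

A read mapping to a single genome adds one count to it.  A read mapping
to several genomes is shared between them with weights proportional to
the *per-base* density of uniquely assigned reads,

    w_i = (m_i / s_i) / sum_j (m_j / s_j),

where ``m_i`` is the unique-read count of genome ``i`` (plus a small
pseudo-count, 0.001 by default, so that genomes without unique evidence
still receive mass) and ``s_i`` its size in bases.  The weighting is
computed in two passes — unique counts first, then multi-mapped sharing
against those fixed counts — so the result does not depend on the order
reads appear in the alignment file.

Genomes whose final weighted count exceeds a threshold (10 reads by
default, strict comparison) form the candidate list; their counts are
renormalized into relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .seq_io import AlignmentRecord, GenomeDB, read_composition_table

__all__ = [
    "CommunityComposition",
    "ReadAssignmentCounts",
    "EmptyCompositionError",
    "group_hits",
    "assign_reads",
    "candidate_filter",
    "estimate_composition",
]

DEFAULT_PSEUDO_COUNT = 0.001
DEFAULT_MIN_READS = 10


class EmptyCompositionError(ValueError):
    """No genome passed the candidate threshold."""


@dataclass
class CommunityComposition:
    """Genome -> relative abundance, normalized to sum 1."""

    entries: dict[str, float]
    provenance: str = "given"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("composition has no entries")
        total = 0.0
        for gid, a in self.entries.items():
            if a < 0:
                raise ValueError(f"negative abundance for {gid!r}")
            total += a
        if total <= 0:
            raise ValueError("composition has zero total abundance")
        if abs(total - 1.0) > 1e-9:
            self.entries = {g: a / total for g, a in self.entries.items()}

    @classmethod
    def from_table(
        cls, path, db: GenomeDB | None = None, provenance: str = "given"
    ) -> "CommunityComposition":
        table = read_composition_table(path)
        if db is not None:
            missing = [g for g in table if g not in db]
            if missing:
                raise KeyError(
                    f"composition genomes absent from the database: {missing}"
                )
        return cls(table, provenance=provenance)

    def abundance(self, genome_id: str) -> float:
        return self.entries[genome_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ReadAssignmentCounts:
    """Weighted read counts per genome after multi-map sharing.

    Every genome of the database appears, floored at the pseudo-count;
    total count minus the pseudo-count mass equals the number of assigned
    reads (each read distributes total weight 1).
    """

    counts: dict[str, float]
    pseudo_count: float = DEFAULT_PSEUDO_COUNT
    n_reads_processed: int = 0


def group_hits(
    alignments: Iterable[AlignmentRecord],
) -> Iterator[tuple[str, frozenset[str]]]:
    """Collapse alignment records into (read_id, set of genomes hit).

    Multiple hits of one read to the same genome count once; reads with
    only unmapped records are dropped.  The whole stream is buffered
    because mappers are not required to group records by read.
    """
    hits: dict[str, set[str]] = {}
    for rec in alignments:
        if not rec.is_mapped or rec.genome_id is None:
            continue
        hits.setdefault(rec.read_id, set()).add(rec.genome_id)
    for read_id, genomes in hits.items():
        yield read_id, frozenset(genomes)


def assign_reads(
    hits: Iterable[tuple[str, frozenset[str]]],
    db: GenomeDB,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> ReadAssignmentCounts:
    """Two-pass weighted assignment of reads to genomes.

    Pass 1 counts uniquely mapping reads (a read whose hits all fall on
    one genome is unique even if it hits several positions there).
    Pass 2 shares each multi-mapping read across its ``n`` genomes with
    weight ``(m_i/s_i) / sum_j (m_j/s_j)`` where ``m_i`` is the pass-1
    count plus the pseudo-count.  Per-read weights sum to 1.
    """
    hit_list = list(hits)
    for _, genomes in hit_list:
        for g in genomes:
            if g not in db:
                raise KeyError(f"alignment references unknown genome {g!r}")

    unique: dict[str, int] = {g: 0 for g in db}
    multi: list[frozenset[str]] = []
    for _, genomes in hit_list:
        if len(genomes) == 1:
            (g,) = genomes
            unique[g] += 1
        else:
            multi.append(genomes)

    m = {g: unique[g] + pseudo_count for g in db}
    counts = dict(m)
    for genomes in multi:
        dens = {g: m[g] / db.size(g) for g in genomes}
        total = sum(dens.values())
        for g in genomes:
            counts[g] += dens[g] / total

    return ReadAssignmentCounts(
        counts=counts,
        pseudo_count=pseudo_count,
        n_reads_processed=len(hit_list),
    )


def candidate_filter(
    counts: ReadAssignmentCounts, min_reads: float = DEFAULT_MIN_READS
) -> CommunityComposition:
    """Keep genomes with weighted count strictly above the threshold and
    renormalize their counts into relative abundances."""
    if not counts.counts:
        raise ValueError("empty read-assignment counts")
    kept = {g: c for g, c in counts.counts.items() if c > min_reads}
    if not kept:
        raise EmptyCompositionError(
            f"no genome exceeded the candidate threshold of {min_reads} reads; "
            "consider lowering --min-reads"
        )
    total = sum(kept.values())
    return CommunityComposition(
        {g: c / total for g, c in kept.items()}, provenance="estimated"
    )


def estimate_composition(
    alignments: Iterable[AlignmentRecord],
    db: GenomeDB,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    min_reads: float = DEFAULT_MIN_READS,
) -> CommunityComposition:
    """Full pipeline: group hits, share multi-mapped reads, filter, normalize."""
    counts = assign_reads(group_hits(alignments), db, pseudo_count=pseudo_count)
    return candidate_filter(counts, min_reads=min_reads)
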