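"""Platform error models: per-cycle quality distributions, error-type
proportions and substitution matrices.

The error rate of a simulated base is driven entirely by its PHRED
quality score ``q`` through ``p = 10**(-q/10)``.  Quality scores at each
sequencing cycle follow an *explicit* empirical distribution (a full
histogram per cycle), not a per-cycle mean, because real per-cycle
quality distributions are skewed and multi-modal.  Conditional on an
error happening, its type (insertion / deletion / substitution) follows
a platform-specific triple, and a substitution replaces the template
base according to a 4x4 substitution matrix.

The substitution matrix is stored as a *joint* distribution over the 12
ordered (original base, substituted base) pairs — its off-diagonal
entries sum to 1.  During simulation the row of the actual template base
is renormalized into a conditional distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .seq_io import MAX_PHRED, AlignmentRecord, ReadRecord

__all__ = [
    "BASE_ORDER",
    "QualityDistribution",
    "ErrorTypeProportions",
    "SubstitutionMatrix",
    "ErrorModel",
    "ErrorCounts",
    "EstimationError",
    "quality_to_error_prob",
    "estimate_quality_distribution",
    "count_error_types",
    "finalize_model",
    "estimate_error_model",
    "save_model",
    "load_model",
    "DEFAULT_PROPORTIONS",
    "DEFAULT_SUBMAT",
]

N_SCORES = MAX_PHRED + 1
BASE_ORDER = "ATCG"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

#: error probability for each PHRED score 0..62
ERROR_PROB = 10.0 ** (-np.arange(N_SCORES) / 10.0)


class EstimationError(ValueError):
    """Model estimation received unusable input."""


def quality_to_error_prob(phred):
    """PHRED -> error probability, ``p = 10**(-phred/10)``.

    Accepts a scalar or an array; negative scores are a domain error.
    """
    arr = np.asarray(phred)
    if np.any(arr < 0):
        raise ValueError(f"negative PHRED score: {phred}")
    p = 10.0 ** (-arr / 10.0)
    return float(p) if np.isscalar(phred) or arr.ndim == 0 else p


# ---------------------------------------------------------------------------
# Quality distributions


@dataclass
class QualityDistribution:
    """Per-cycle empirical distributions of PHRED scores.

    ``probs[c, q]`` is the probability of score ``q`` at 0-based cycle
    ``c``.  Cycles beyond the estimation depth reuse the last estimated
    cycle, so a model estimated from 100-cycle data can still drive
    longer simulated reads.
    """

    probs: np.ndarray  # (n_cycles, N_SCORES)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_SCORES:
            raise ValueError(
                f"quality distribution must be (n_cycles, {N_SCORES})"
            )
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-cycle quality distributions must sum to 1")
        self._cdf = np.cumsum(self.probs, axis=1)

    @property
    def n_cycles(self) -> int:
        return self.probs.shape[0]

    def row(self, cycle: int) -> np.ndarray:
        return self.probs[min(cycle, self.n_cycles - 1)]

    def cdf_rows(self, n: int) -> np.ndarray:
        """CDF rows for cycles 0..n-1, repeating the last estimated cycle."""
        idx = np.minimum(np.arange(n), self.n_cycles - 1)
        return self._cdf[idx]

    def mean_error_prob(self, n: int) -> np.ndarray:
        """Expected per-base error probability for cycles 0..n-1."""
        idx = np.minimum(np.arange(n), self.n_cycles - 1)
        return self.probs[idx] @ ERROR_PROB

    @classmethod
    def point_mass(cls, score: int, n_cycles: int) -> "QualityDistribution":
        probs = np.zeros((n_cycles, N_SCORES))
        probs[:, score] = 1.0
        return cls(probs)


def estimate_quality_distribution(
    reads: Iterable[ReadRecord],
) -> QualityDistribution:
    """Empirical per-cycle score histograms from a stream of reads.

    ``dist[c][q]`` = (# reads with score q at cycle c) / (# reads covering
    cycle c).  Cycles covered by no read (possible only interior to the
    matrix after ragged input) borrow the nearest earlier estimated cycle.
    """
    counts = np.zeros((0, N_SCORES), dtype=np.int64)
    n = 0
    for read in reads:
        if read.qualities is None:
            raise EstimationError(f"read {read.read_id!r} has no qualities")
        q = np.asarray(read.qualities, dtype=np.int64)
        if len(q) > counts.shape[0]:
            grown = np.zeros((len(q), N_SCORES), dtype=np.int64)
            grown[: counts.shape[0]] = counts
            counts = grown
        np.add.at(counts, (np.arange(len(q)), q), 1)
        n += 1
    if n == 0 or counts.shape[0] == 0:
        raise EstimationError("no reads with qualities to estimate from")

    coverage = counts.sum(axis=1)
    probs = np.zeros_like(counts, dtype=float)
    last = None
    for c in range(counts.shape[0]):
        if coverage[c] > 0:
            probs[c] = counts[c] / coverage[c]
            last = c
        elif last is not None:
            probs[c] = probs[last]
        else:
            raise EstimationError("first cycle has no coverage")
    return QualityDistribution(probs)


# ---------------------------------------------------------------------------
# Error-type proportions and substitution matrices


@dataclass(frozen=True)
class ErrorTypeProportions:
    """Fractions of insertion, deletion and substitution errors."""

    p_ins: float
    p_del: float
    p_sub: float

    def __post_init__(self) -> None:
        for p in (self.p_ins, self.p_del, self.p_sub):
            if p < 0:
                raise ValueError("error-type proportions must be >= 0")
        if abs(self.p_ins + self.p_del + self.p_sub - 1.0) > 1e-9:
            raise ValueError("error-type proportions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_ins, self.p_del, self.p_sub)


#: default (insertion, deletion, substitution) proportions per platform
DEFAULT_PROPORTIONS = {
    "illumina": ErrorTypeProportions(0.01, 0.005, 0.985),
    "454": ErrorTypeProportions(0.2, 0.15, 0.65),
}


@dataclass
class SubstitutionMatrix:
    """Joint probabilities of (original base, substituted base) pairs.

    Rows and columns are indexed A, T, C, G; the row is the original
    (template) base.  The diagonal is zero and the 12 off-diagonal
    entries sum to 1.  ``conditional()`` renormalizes each row for use
    during simulation.
    """

    joint: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        if self.joint.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if np.any(self.joint < 0):
            raise ValueError("substitution probabilities must be >= 0")
        if np.any(np.diag(self.joint) != 0):
            raise ValueError("substitution matrix diagonal must be zero")
        if abs(self.joint.sum() - 1.0) > 1e-4:
            raise ValueError("off-diagonal entries must sum to 1")

    def conditional(self) -> np.ndarray:
        """Row-normalized matrix: P(substituted base | original base).

        A row with zero mass falls back to uniform over the three other
        bases.
        """
        cond = self.joint.copy()
        sums = cond.sum(axis=1)
        for i in range(4):
            if sums[i] > 0:
                cond[i] /= sums[i]
            else:
                cond[i] = 1.0 / 3.0
                cond[i, i] = 0.0
        return cond


#: 454 substitution-error proportions estimated from pyrosequencing data
#: (rows/cols A, T, C, G; row = original base).  The 12 entries sum to 1.
_SUBMAT_454 = np.array(
    [
        [0.0, 0.06474, 0.05735, 0.12439],
        [0.05378, 0.0, 0.13480, 0.06577],
        [0.05298, 0.11709, 0.0, 0.06752],
        [0.12384, 0.06784, 0.06990, 0.0],
    ]
)

#: Illumina fallback: a neutral joint matrix, uniform over the 12
#: substitution pairs.  It is NOT estimated from sequencing data — when a
#: real substitution profile matters, estimate one with
#: ``estimate_error_model`` and it will replace this default.
_SUBMAT_UNIFORM = np.full((4, 4), 1.0 / 12.0)
np.fill_diagonal(_SUBMAT_UNIFORM, 0.0)

DEFAULT_SUBMAT = {
    "454": SubstitutionMatrix(_SUBMAT_454),
    "illumina": SubstitutionMatrix(_SUBMAT_UNIFORM.copy()),
}

#: FASTQ ASCII offsets conventionally paired with each platform here
PLATFORM_OFFSET = {"illumina": 64, "454": 33}


@dataclass
class ErrorModel:
    """Everything needed to corrupt a perfect read realistically."""

    platform: str
    qdist: QualityDistribution
    props: ErrorTypeProportions
    submat: SubstitutionMatrix
    quality_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.platform not in ("illumina", "454"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.quality_offset is None:
            self.quality_offset = PLATFORM_OFFSET[self.platform]
        if self.quality_offset not in (33, 64):
            raise ValueError("quality offset must be 33 or 64")

    @classmethod
    def platform_default(
        cls, platform: str, n_cycles: int = 150, quality_offset: int | None = None
    ) -> "ErrorModel":
        """Runnable default model for a platform.

        Error-type proportions and the substitution matrix are the
        platform defaults.  The quality profile is synthetic (no default
        histogram is shipped with real provenance): per-cycle discretized
        normal with the mean declining linearly from 34 at the first
        cycle to 20 at the last, sd 3 — a generic quality decay shape.
        """
        means = np.linspace(34.0, 20.0, n_cycles)
        scores = np.arange(N_SCORES)
        z = (scores[None, :] - means[:, None]) / 3.0
        probs = np.exp(-0.5 * z * z)
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(
            platform=platform,
            qdist=QualityDistribution(probs),
            props=DEFAULT_PROPORTIONS[platform],
            submat=DEFAULT_SUBMAT[platform],
            quality_offset=quality_offset,
        )

    def expected_errors_per_read(self, read_length: int) -> float:
        """Model-implied expected number of injected errors in one read.

        Given the cycle's score ``q`` the base errs with probability
        ``p(q)``; a deletion re-attempts the cycle, so the error count at
        one cycle has expectation ``p/(1 - p*p_del)``.  That correction
        is averaged over the score distribution (it is convex in ``p``,
        so applying it to the mean score would bias low).
        """
        per_score = ERROR_PROB / (1.0 - ERROR_PROB * self.props.p_del)
        idx = np.minimum(np.arange(read_length), self.qdist.n_cycles - 1)
        return float(np.sum(self.qdist.probs[idx] @ per_score))


# ---------------------------------------------------------------------------
# Error counting from alignments

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


@dataclass
class ErrorCounts:
    """Raw error-event counts harvested from alignments."""

    ins: int = 0
    dels: int = 0
    subs: int = 0
    pairs: np.ndarray = None  # (4, 4) original x substituted

    def __post_init__(self) -> None:
        if self.pairs is None:
            self.pairs = np.zeros((4, 4), dtype=np.int64)


def _match_columns(rec: AlignmentRecord) -> list[int]:
    """Query positions of the M/=/X alignment columns, in reference order."""
    cols: list[int] = []
    qpos = 0
    for op, n in rec.cigar:
        if op in "M=X":
            cols.extend(range(qpos, qpos + n))
            qpos += n
        elif op in "IS":
            qpos += n
        # D, N, H, P consume no query
    return cols


def count_error_types(
    alignments: Iterable[AlignmentRecord],
) -> ErrorCounts:
    """Count insertions, deletions and substitutions from CIGAR + MD.

    Insertion/deletion bases come from the CIGAR I/D operations;
    substitutions come from walking the MD string against the matched
    columns, pairing the MD reference base with the read base at that
    column.  Soft-clipped bases are excluded (they are not aligned
    evidence).  Records without an MD tag contribute indel counts only.
    """
    out = ErrorCounts()
    for rec in alignments:
        if not rec.is_mapped or not rec.cigar:
            continue
        for op, n in rec.cigar:
            if op == "I":
                out.ins += n
            elif op == "D":
                out.dels += n
        if rec.md is None:
            continue

        cols = _match_columns(rec)
        ptr = 0
        consumed = "".join(m.group(0) for m in _MD_TOKEN.finditer(rec.md))
        if consumed != rec.md:
            raise ValueError(f"read {rec.read_id!r}: malformed MD string {rec.md!r}")
        for m in _MD_TOKEN.finditer(rec.md):
            if m.group(1) is not None:  # run of matches
                ptr += int(m.group(1))
            elif m.group(2) is not None:  # deletion, ^bases — counted via CIGAR
                continue
            else:  # mismatch: MD letter is the reference base
                if ptr >= len(cols):
                    raise ValueError(
                        f"read {rec.read_id!r}: MD string {rec.md!r} walks past "
                        f"the {len(cols)} aligned columns of CIGAR {rec.cigar}"
                    )
                out.subs += 1
                ref_base = m.group(3).upper()
                if rec.sequence is not None:
                    read_base = rec.sequence[cols[ptr]]
                    if ref_base in _BASE_INDEX and read_base in _BASE_INDEX:
                        out.pairs[_BASE_INDEX[ref_base], _BASE_INDEX[read_base]] += 1
                ptr += 1
        if ptr > len(cols):
            raise ValueError(
                f"read {rec.read_id!r}: MD/CIGAR inconsistency "
                f"({ptr} columns walked, {len(cols)} aligned)"
            )
    return out


def finalize_model(
    counts: ErrorCounts,
    qdist: QualityDistribution,
    platform: str,
    quality_offset: int | None = None,
) -> ErrorModel:
    """Assemble a model from harvested counts, falling back to platform
    defaults where there is no evidence (no errors observed at all, or no
    identifiable substitution pairs)."""
    total = counts.ins + counts.dels + counts.subs
    if total > 0:
        props = ErrorTypeProportions(
            counts.ins / total, counts.dels / total, counts.subs / total
        )
    else:
        props = DEFAULT_PROPORTIONS[platform]

    pair_total = counts.pairs.sum()
    if counts.subs > 0 and pair_total > 0:
        submat = SubstitutionMatrix(counts.pairs / pair_total)
    else:
        submat = DEFAULT_SUBMAT[platform]

    return ErrorModel(
        platform=platform,
        qdist=qdist,
        props=props,
        submat=submat,
        quality_offset=quality_offset,
    )


def estimate_error_model(
    reads: Iterable[ReadRecord],
    alignments: Iterable[AlignmentRecord],
    platform: str,
    quality_offset: int | None = None,
) -> ErrorModel:
    """Estimate the full error model from FASTQ reads plus their alignments."""
    qdist = estimate_quality_distribution(reads)
    counts = count_error_types(alignments)
    return finalize_model(counts, qdist, platform, quality_offset=quality_offset)


# ---------------------------------------------------------------------------
# Model files: a human-diffable sectioned text format, bit-exact on reload


def save_model(model: ErrorModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("[meta]\n")
        fh.write(f"platform\t{model.platform}\n")
        fh.write(f"quality_offset\t{model.quality_offset}\n")
        fh.write("[proportions]\n")
        fh.write(f"insertion\t{float(model.props.p_ins)!r}\n")
        fh.write(f"deletion\t{float(model.props.p_del)!r}\n")
        fh.write(f"substitution\t{float(model.props.p_sub)!r}\n")
        fh.write("[submatrix]\n")
        for i, base in enumerate(BASE_ORDER):
            row = "\t".join(repr(float(v)) for v in model.submat.joint[i])
            fh.write(f"{base}\t{row}\n")
        fh.write("[quality]\n")
        for c in range(model.qdist.n_cycles):
            row = model.qdist.probs[c]
            pairs = " ".join(
                f"{q}:{float(row[q])!r}" for q in np.nonzero(row)[0]
            )
            fh.write(f"{c}\t{pairs}\n")


def load_model(path) -> ErrorModel:
    sections: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                current = line.strip("[]")
                sections[current] = []
            else:
                sections[current].append(line)

    meta = dict(line.split("\t") for line in sections["meta"])
    props_raw = dict(line.split("\t") for line in sections["proportions"])
    props = ErrorTypeProportions(
        float(props_raw["insertion"]),
        float(props_raw["deletion"]),
        float(props_raw["substitution"]),
    )
    joint = np.zeros((4, 4))
    for line in sections["submatrix"]:
        fields = line.split("\t")
        joint[_BASE_INDEX[fields[0]]] = [float(v) for v in fields[1:]]
    rows = {}
    for line in sections["quality"]:
        cycle_s, _, rest = line.partition("\t")
        row = np.zeros(N_SCORES)
        if rest:
            for pair in rest.split(" "):
                q, _, p = pair.partition(":")
                row[int(q)] = float(p)
        rows[int(cycle_s)] = row
    probs = np.vstack([rows[c] for c in sorted(rows)])
    return ErrorModel(
        platform=meta["platform"],
        qdist=QualityDistribution(probs),
        props=props,
        submat=SubstitutionMatrix(joint),
        quality_offset=int(meta["quality_offset"]),
    )
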