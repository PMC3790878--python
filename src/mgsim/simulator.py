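"""Shotgun-read simulation: allocation, position/length/strand sampling,
quality-driven error injection and FASTQ output.

The simulation of one community proceeds genome by genome.  Read counts
per genome are multinomial with probabilities proportional to abundance
x genome size (a twice-as-large genome at equal cell abundance sheds
twice the reads).  Each read gets a start position (uniform, or biased
by a :class:`~mgsim.coverage_model.CoverageProfile`), a length from the
configured length model, and a strand with probability 1/2 each.

Errors are injected per cycle: the cycle's PHRED score ``q`` is drawn
from the model's explicit per-cycle distribution, the base errs with
probability ``10**(-q/10)``, and an erring base is an insertion,
deletion or substitution according to the model's proportions.  A
substitution replaces the template base via the renormalized row of the
substitution matrix; an insertion emits a uniform random base without
consuming template; a deletion skips one template base and re-attempts
the cycle.  Output length therefore always equals the requested read
length; the template window is over-fetched by ``max(10, 0.2 x length)``
bases to absorb deletions, and a read that still exhausts its template
is regenerated at a fresh position.

Everything is driven by one seeded generator with a fixed draw order
(allocation, then per-genome length/position/strand batches, then
per-read cycle draws), so a given (inputs, seed) pair yields
byte-identical FASTQ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .composition import CommunityComposition
from .coverage_model import CoverageProfile, sample_positions
from .error_model import ERROR_PROB, ErrorModel
from .seq_io import GenomeDB, revcomp

__all__ = [
    "LengthModel",
    "SimulationConfig",
    "SimulatedRead",
    "TemplateExhausted",
    "allocate_reads",
    "sample_length",
    "extract_fragment",
    "inject_errors",
    "simulate",
    "write_simulated_fastq",
    "PERFECT_QUALITY",
    "READ_ID_PREFIX",
]

logger = logging.getLogger(__name__)

#: quality reported for every base of an error-free read
PERFECT_QUALITY = 40

READ_ID_PREFIX = "MGSIM"

_BASES = "ACGT"


class TemplateExhausted(RuntimeError):
    """Deletions consumed the template past its safety margin."""


# ---------------------------------------------------------------------------
# Length models


@dataclass
class LengthModel:
    """Read-length distribution: fixed, truncated normal, or explicit."""

    kind: str
    length: int = 0
    mean: float = 0.0
    sd: float = 0.0
    min_length: int = 1
    max_length_: int = 0
    support: Optional[np.ndarray] = None
    probs: Optional[np.ndarray] = None

    @classmethod
    def fixed(cls, length: int) -> "LengthModel":
        if length < 1:
            raise ValueError("read length must be >= 1")
        return cls(kind="fixed", length=length)

    @classmethod
    def normal(
        cls, mean: float, sd: float, min_length: int = 1, max_length: int = 0
    ) -> "LengthModel":
        if min_length < 1:
            raise ValueError("minimum length must be >= 1")
        if not max_length:
            max_length = int(round(mean + 6 * sd))
        return cls(
            kind="normal",
            mean=mean,
            sd=sd,
            min_length=min_length,
            max_length_=max_length,
        )

    @classmethod
    def explicit(cls, lengths, probs) -> "LengthModel":
        support = np.asarray(lengths, dtype=np.int64)
        p = np.asarray(probs, dtype=float)
        if len(support) == 0:
            raise ValueError("explicit length model has empty support")
        if np.any(support < 1):
            raise ValueError("lengths must be >= 1")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("explicit length probabilities must sum to 1")
        return cls(kind="explicit", support=support, probs=p)

    @property
    def max_length(self) -> int:
        if self.kind == "fixed":
            return self.length
        if self.kind == "normal":
            return self.max_length_
        return int(self.support.max())

    def sample_batch(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.length, dtype=np.int64)
        if self.kind == "normal":
            draws = np.rint(rng.normal(self.mean, self.sd, size=n)).astype(np.int64)
            return np.clip(draws, self.min_length, self.max_length_)
        idx = rng.choice(len(self.support), size=n, p=self.probs)
        return self.support[idx]


def sample_length(model: LengthModel, rng: np.random.Generator) -> int:
    """Draw one read length from the model."""
    return int(model.sample_batch(1, rng)[0])


# ---------------------------------------------------------------------------
# Configuration and read records


@dataclass
class SimulationConfig:
    """Knobs of one simulation run."""

    total_reads: int
    seed: int = 0
    paired: bool = False
    insert_mean: float = 0.0
    insert_sd: float = 0.0
    length_model: LengthModel = field(default_factory=lambda: LengthModel.fixed(100))
    bias: Optional[dict[str, CoverageProfile]] = None

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if self.paired:
            if self.total_reads % 2:
                raise ValueError("paired mode needs an even total read count")
            if self.insert_mean < 2 * self.length_model.max_length:
                raise ValueError(
                    "insert mean must be at least twice the maximum read length"
                )


@dataclass
class SimulatedRead:
    """A simulated read together with its full provenance.

    ``start``/``end`` delimit the reference bases the read actually
    covers (0-based, half-open, leftmost-based for both strands).
    ``edits`` lists the injected errors as ``(op, template_offset,
    cycle, ref_base, read_base)`` in template order, which is enough to
    reconstruct the true alignment exactly.
    """

    read_id: str
    sequence: str
    qualities: np.ndarray
    genome_id: str
    start: int
    end: int
    strand: str
    n_ins: int = 0
    n_del: int = 0
    n_sub: int = 0
    edits: list = field(default_factory=list)
    mate: Optional[int] = None  # 1 or 2 for paired reads


# ---------------------------------------------------------------------------
# Elementary operations


def allocate_reads(
    comp: CommunityComposition,
    db: GenomeDB,
    total_reads: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Multinomial split of the read budget across genomes.

    Expected counts are proportional to abundance x genome size; the
    realized counts are one multinomial draw and always sum exactly to
    ``total_reads``.
    """
    genomes = list(comp)
    for g in genomes:
        if g not in db:
            raise KeyError(f"composition genome {g!r} absent from the database")
    mass = np.array([comp.abundance(g) * db.size(g) for g in genomes], dtype=float)
    if mass.sum() <= 0:
        raise ValueError("zero total expected read mass")
    counts = rng.multinomial(total_reads, mass / mass.sum())
    return dict(zip(genomes, (int(c) for c in counts)))


def extract_fragment(
    db: GenomeDB, genome_id: str, start: int, length: int, strand: str = "+"
) -> str:
    """Exact template substring, reverse-complemented on the minus strand."""
    size = db.size(genome_id)
    if start < 0 or length < 0 or start + length > size:
        raise ValueError(
            f"fragment [{start}, {start + length}) outside genome "
            f"{genome_id!r} of size {size}"
        )
    frag = db.entries[genome_id][start : start + length]
    return revcomp(frag) if strand == "-" else frag


@dataclass
class InjectionResult:
    sequence: str
    qualities: np.ndarray
    n_ins: int
    n_del: int
    n_sub: int
    edits: list
    template_consumed: int


class _ErrorEngine:
    """Cached arrays for fast repeated error injection under one model."""

    def __init__(self, model: ErrorModel):
        self.model = model
        self.p_ins = model.props.p_ins
        self.p_del = model.props.p_del
        cond = model.submat.conditional()
        self.cond_cdf = np.cumsum(cond, axis=1)
        self.base_index = {b: i for i, b in enumerate("ATCG")}
        self._cdf_cache: dict[int, np.ndarray] = {}

    def _cdf_rows(self, n: int) -> np.ndarray:
        rows = self._cdf_cache.get(n)
        if rows is None:
            rows = self.model.qdist.cdf_rows(n)
            self._cdf_cache[n] = rows
        return rows

    def draw_qualities(self, length: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(length)
        return (self._cdf_rows(length) <= u[:, None]).sum(axis=1)

    def substitute(self, base: str, rng: np.random.Generator) -> str:
        if base == "N":
            return _BASES[rng.integers(4)]
        row = self.cond_cdf[self.base_index[base]]
        r = rng.random()
        return "ATCG"[int(np.searchsorted(row, r, side="right"))]

    def corrupt(
        self, template: str, length: int, rng: np.random.Generator
    ) -> InjectionResult:
        quals = self.draw_qualities(length, rng)
        perr = ERROR_PROB[quals]
        err = rng.random(length) < perr

        if not err.any():
            if len(template) < length:
                raise TemplateExhausted
            return InjectionResult(template[:length], quals, 0, 0, 0, [], length)

        out: list[str] = []
        edits: list = []
        n_ins = n_del = n_sub = 0
        t = 0
        c = 0
        fresh = True  # whether the precomputed indicator is still valid
        tlen = len(template)
        while c < length:
            if t >= tlen:
                raise TemplateExhausted
            is_err = err[c] if fresh else (rng.random() < perr[c])
            if not is_err:
                out.append(template[t])
                t += 1
                c += 1
                fresh = True
                continue
            r = rng.random()
            if r < self.p_ins:
                base = _BASES[rng.integers(4)]
                out.append(base)
                edits.append(("I", t, c, None, base))
                n_ins += 1
                c += 1
                fresh = True
            elif r < self.p_ins + self.p_del:
                edits.append(("D", t, c, template[t], None))
                n_del += 1
                t += 1
                fresh = False  # re-attempt this cycle
            else:
                orig = template[t]
                new = self.substitute(orig, rng)
                out.append(new)
                edits.append(("S", t, c, orig, new))
                n_sub += 1
                t += 1
                c += 1
                fresh = True
        return InjectionResult(
            "".join(out), quals, n_ins, n_del, n_sub, edits, t
        )


def inject_errors(
    template: str,
    model: ErrorModel,
    rng: np.random.Generator,
    length: Optional[int] = None,
) -> InjectionResult:
    """Corrupt a template into a read of ``length`` bases (default: the
    whole template) under the error model.  Raises
    :class:`TemplateExhausted` if deletions run past the template end."""
    if length is None:
        length = len(template)
    return _ErrorEngine(model).corrupt(template, length, rng)


# ---------------------------------------------------------------------------
# The main loop


def _safety_margin(length: int) -> int:
    return max(10, math.ceil(0.2 * length))


def _make_read(
    db: GenomeDB,
    genome_id: str,
    genome: str,
    pos: int,
    length: int,
    strand: str,
    engine: Optional[_ErrorEngine],
    rng: np.random.Generator,
    serial: int,
    mate: Optional[int],
) -> SimulatedRead:
    """Build one read at a clamped leftmost position ``pos``."""
    size = len(genome)
    if engine is None:
        frag = genome[pos : pos + length]
        seq = revcomp(frag) if strand == "-" else frag
        quals = np.full(length, PERFECT_QUALITY, dtype=np.int64)
        lo, hi = pos, pos + length
        n_ins = n_del = n_sub = 0
        edits: list = []
    else:
        margin = _safety_margin(length)
        if strand == "+":
            template = genome[pos : min(size, pos + length + margin)]
        else:
            template = revcomp(genome[max(0, pos - margin) : pos + length])
        res = engine.corrupt(template, length, rng)
        seq, quals = res.sequence, res.qualities
        n_ins, n_del, n_sub, edits = res.n_ins, res.n_del, res.n_sub, res.edits
        t = res.template_consumed
        if strand == "+":
            lo, hi = pos, pos + t
        else:
            lo, hi = pos + length - t, pos + length
    suffix = f"/{mate}" if mate else ""
    read_id = (
        f"{READ_ID_PREFIX}|{genome_id}|{lo}|{hi}|{strand}|{serial}{suffix}"
    )
    return SimulatedRead(
        read_id=read_id,
        sequence=seq,
        qualities=quals,
        genome_id=genome_id,
        start=lo,
        end=hi,
        strand=strand,
        n_ins=n_ins,
        n_del=n_del,
        n_sub=n_sub,
        edits=edits,
        mate=mate,
    )


def _sample_starts(
    size: int,
    lengths: np.ndarray,
    profile: Optional[CoverageProfile],
    rng: np.random.Generator,
) -> np.ndarray:
    """Leftmost start positions: pure uniform without a profile, else
    interval-biased."""
    if profile is None:
        return rng.integers(0, size - lengths + 1)
    return sample_positions(profile, lengths, rng)


def simulate(
    comp: CommunityComposition,
    db: GenomeDB,
    model: Optional[ErrorModel],
    config: SimulationConfig,
) -> Iterator[SimulatedRead]:
    """Simulate a metagenome; yields exactly ``config.total_reads`` reads.

    ``model=None`` produces error-free reads with a constant quality of
    ``PERFECT_QUALITY``.  In paired mode each fragment yields two reads
    (mate 2 on the opposite strand of mate 1), and ``total_reads`` counts
    both mates.
    """
    lm = config.length_model
    for g in comp:
        if db.size(g) < lm.max_length:
            raise ValueError(
                f"genome {g!r} ({db.size(g)} bp) is shorter than the maximum "
                f"read length {lm.max_length}"
            )
        if config.paired and db.size(g) < config.insert_mean:
            raise ValueError(
                f"genome {g!r} is shorter than the mean insert size"
            )
    if config.bias:
        for g in comp:
            prof = config.bias.get(g)
            if prof is not None and prof.genome_length != db.size(g):
                raise ValueError(
                    f"coverage profile for {g!r} was estimated on a "
                    f"{prof.genome_length}-bp sequence, not {db.size(g)} bp"
                )

    rng = np.random.default_rng(config.seed)
    engine = _ErrorEngine(model) if model is not None else None
    n_units = config.total_reads // 2 if config.paired else config.total_reads
    counts = allocate_reads(comp, db, n_units, rng)

    serial = 0
    regenerated = 0
    for g, n in counts.items():
        if n == 0:
            continue
        genome = db.entries[g]
        size = len(genome)
        profile = config.bias.get(g) if config.bias else None
        if not config.paired:
            lengths = lm.sample_batch(n, rng)
            starts = _sample_starts(size, lengths, profile, rng)
            strands = rng.random(n) < 0.5
            for i in range(n):
                strand = "-" if strands[i] else "+"
                pos, length = int(starts[i]), int(lengths[i])
                for _attempt in range(100):
                    try:
                        read = _make_read(
                            db, g, genome, pos, length, strand,
                            engine, rng, serial, None,
                        )
                        break
                    except TemplateExhausted:
                        regenerated += 1
                        pos = int(
                            _sample_starts(
                                size, np.array([length]), profile, rng
                            )[0]
                        )
                else:  # pragma: no cover - would need a pathological model
                    raise RuntimeError("could not place read after 100 attempts")
                serial += 1
                yield read
        else:
            len1 = lm.sample_batch(n, rng)
            len2 = lm.sample_batch(n, rng)
            frags = np.rint(
                rng.normal(config.insert_mean, config.insert_sd, size=n)
            ).astype(np.int64)
            frags = np.clip(frags, np.maximum(len1, len2), size)
            starts = _sample_starts(size, frags, profile, rng)
            strands = rng.random(n) < 0.5
            for i in range(n):
                fpos, flen = int(starts[i]), int(frags[i])
                l1, l2 = int(len1[i]), int(len2[i])
                sigma = "-" if strands[i] else "+"
                if sigma == "+":
                    spec = ((fpos, l1, "+", 1), (fpos + flen - l2, l2, "-", 2))
                else:
                    spec = ((fpos + flen - l1, l1, "-", 1), (fpos, l2, "+", 2))
                for pos, length, strand, mate in spec:
                    for _attempt in range(100):
                        try:
                            read = _make_read(
                                db, g, genome, pos, length, strand,
                                engine, rng, serial, mate,
                            )
                            break
                        except TemplateExhausted:
                            regenerated += 1
                            pos = max(0, min(pos, size - length))
                            # fresh attempt at the same locus cannot help if
                            # the margin is truly exhausted; re-draw nearby
                            pos = int(
                                _sample_starts(
                                    size, np.array([length]), None, rng
                                )[0]
                            )
                    else:  # pragma: no cover
                        raise RuntimeError(
                            "could not place read after 100 attempts"
                        )
                    yield read
                serial += 1
    if regenerated:
        logger.info("regenerated %d reads whose templates were exhausted",
                    regenerated)


def write_simulated_fastq(
    reads,
    path,
    quality_offset: int = 33,
    path2=None,
) -> int:
    """Write simulated reads to FASTQ (two files when ``path2`` is given:
    mate 1 to ``path``, mate 2 to ``path2``).  Returns the read count."""
    if quality_offset not in (33, 64):
        raise ValueError("quality offset must be 33 or 64")
    n = 0
    fh2 = open(path2, "w") if path2 is not None else None
    try:
        with open(path, "w") as fh1:
            for read in reads:
                q = np.asarray(read.qualities) + quality_offset
                if q.min() < 33 or q.max() > 126:
                    raise ValueError(
                        f"read {read.read_id!r}: quality outside printable "
                        f"ASCII at offset {quality_offset}"
                    )
                record = (
                    f"@{read.read_id}\n{read.sequence}\n+\n"
                    f"{q.astype(np.uint8).tobytes().decode('ascii')}\n"
                )
                target = fh2 if (fh2 is not None and read.mate == 2) else fh1
                target.write(record)
                n += 1
    finally:
        if fh2 is not None:
            fh2.close()
    return n
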