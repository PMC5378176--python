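"""PWM motif scanning and positional hit densities around peak centers.

Scoring is standard log-odds: for a position-probability matrix ``p`` (rows
A,C,G,T after pseudocount regularisation) and background frequencies ``b``,
the score of a window starting at ``i`` is ``sum_j log2(p[base(i+j), j] /
b[base(i+j)])``. Both strands are scanned; a reverse-strand hit is reported
at the forward-strand coordinate of the window it occupies. Windows
containing N are skipped.

The positional-density operation aggregates hit start positions over many
peaks into 50-bp sliding windows (1-bp step) relative to the peak center,
as used for hotspot-motif enrichment plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, PeakSet

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# complement of codes A,C,G,T -> T,G,C,A
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)

__all__ = ["PWM", "MotifHit", "PositionalDensity", "encode", "decode",
           "score_sequence", "scan", "positional_hit_density",
           "randomized_control", "motif_containing_count"]


def encode(seq: str | np.ndarray) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    if isinstance(seq, np.ndarray):
        if seq.dtype == np.uint8:
            return seq
        seq = "".join(seq.tolist())
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


@dataclass
class PWM:
    """Position probability matrix with log-odds scoring threshold.

    ``matrix`` has shape (4, w) with rows A, C, G, T; each column sums to 1
    after the pseudocount is applied. ``threshold`` is an absolute log-odds
    value; when None it defaults to ``threshold_fraction`` of the maximal
    attainable score.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01
    threshold: float | None = None
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError("PWM matrix must have shape (4, w)")
        colsums = m.sum(axis=0)
        if np.any(colsums <= 0):
            raise ValueError("PWM columns must have positive mass")
        m = m / colsums  # accept counts or probabilities
        m = (m + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        self.matrix = m
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise AssertionError("PWM columns not normalized")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return self.threshold_fraction * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    @classmethod
    def from_consensus(
        cls, consensus: str, name: str = "", p: float = 0.85, **kwargs
    ) -> "PWM":
        """A PWM putting probability ``p`` on each consensus base."""
        w = len(consensus)
        m = np.full((4, w), (1.0 - p) / 3.0)
        for j, base in enumerate(consensus.upper()):
            m[BASES.index(base), j] = p
        return cls(name=name or consensus, matrix=m, **kwargs)

    @classmethod
    def from_text(cls, path: str | Path, name: str | None = None, **kwargs) -> "PWM":
        """Parse a plain-text matrix: 4 rows labelled A/C/G/T (or JASPAR-style
        ``A [ 1 2 3 ]``); values may be counts, which are normalized."""
        rows: dict[str, list[float]] = {}
        header = None
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    header = line[1:].split()[0]
                    continue
                label = line[0].upper()
                if label not in BASES:
                    raise ValueError(f"unrecognized PWM row label in {line!r}")
                body = line[1:].replace(":", " ").replace("[", " ").replace("]", " ")
                rows[label] = [float(x) for x in body.split()]
        if set(rows) != set(BASES):
            raise ValueError(f"PWM file {path} must contain rows A, C, G, T")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"PWM rows in {path} have unequal lengths")
        m = np.array([rows[b] for b in BASES])
        return cls(name=name or header or Path(path).stem, matrix=m, **kwargs)


@dataclass(frozen=True)
class MotifHit:
    """A motif match: forward-coordinate start of the window and its score."""

    start: int
    strand: str
    score: float


@dataclass
class PositionalDensity:
    """Aggregated motif-hit counts per sliding-window offset.

    ``offsets`` are window start positions relative to peak centers; with
    window w, step 1 and extent E the vector has 2E - w + 2 entries.
    """

    window: int
    step: int
    extent: int
    offsets: np.ndarray
    counts: np.ndarray
    n_peaks: int
    total_hits: int

    def peak_offset(self) -> int:
        """Offset of the maximal window (midpoint convention: window start)."""
        return int(self.offsets[int(np.argmax(self.counts))])


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score for every window start; NaN where the window has an N."""
    w = log_odds.shape[1]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    safe = np.where(codes < 4, codes, 0)
    scores = np.zeros(n)
    for j in range(w):
        scores += log_odds[safe[j : j + n], j]
    has_n = codes >= 4
    if has_n.any():
        bad = np.convolve(has_n.astype(int), np.ones(w, dtype=int), mode="valid") > 0
        scores[bad] = np.nan
    return scores


def scan(
    pwm: PWM, seq: str | np.ndarray, threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scan both strands; returns (starts, strands, scores) arrays.

    Starts are forward-strand window start positions. Reverse-strand scores
    use the reverse complement of the window.
    """
    codes = encode(seq)
    thr = pwm.effective_threshold if threshold is None else threshold
    lo = pwm.log_odds
    # scoring the reverse complement of each window == scoring the window
    # with the complemented, position-reversed matrix
    lo_rc = lo[::-1, ::-1]
    fwd = _window_scores(codes, lo)
    rev = _window_scores(codes, lo_rc)
    starts, strands, scores = [], [], []
    with np.errstate(invalid="ignore"):
        fwd_hit = np.nan_to_num(fwd, nan=-np.inf) >= thr
        rev_hit = np.nan_to_num(rev, nan=-np.inf) >= thr
    for i in np.flatnonzero(fwd_hit):
        starts.append(i), strands.append("+"), scores.append(fwd[i])
    for i in np.flatnonzero(rev_hit):
        starts.append(i), strands.append("-"), scores.append(rev[i])
    order = np.lexsort((np.array(strands, dtype="U1"), np.array(starts, dtype=int))) \
        if starts else np.empty(0, dtype=int)
    return (
        np.array(starts, dtype=int)[order],
        np.array(strands, dtype="U1")[order],
        np.array(scores)[order],
    )


def score_sequence(
    pwm: PWM, seq: str | np.ndarray, threshold: float | None = None
) -> list[MotifHit]:
    """Hits of ``pwm`` in ``seq`` on both strands, sorted by start."""
    starts, strands, scores = scan(pwm, seq, threshold=threshold)
    return [MotifHit(int(p), s, float(sc)) for p, s, sc in zip(starts, strands, scores)]


def _get_chrom_seq(genome, chrom: str) -> np.ndarray:
    """Coerce one chromosome of a genome-like object to uint8 codes."""
    obj = genome[chrom]
    if isinstance(obj, np.ndarray):
        return encode(obj)
    return encode(str(obj))


def positional_hit_density(
    peaks: PeakSet,
    genome,
    pwm: PWM,
    window: int = 50,
    step: int = 1,
    extent: int = 1000,
    threshold: float | None = None,
) -> PositionalDensity:
    """Motif-hit density in sliding windows around peak centers.

    For each peak, hits whose (forward) start offset from the center lies in
    ``[-extent, extent]`` are histogrammed; hit counts are then summed in
    windows of ``window`` bp advanced by ``step`` bp. Peaks whose scan window
    exceeds chromosome bounds are skipped with a logged warning.
    """
    if step != 1:
        raise NotImplementedError("only step=1 densities are supported")
    w = pwm.width
    hist = np.zeros(2 * extent + 1, dtype=int)
    n_used = 0
    chrom_cache: dict[str, np.ndarray] = {}
    for iv in peaks:
        if iv.chrom not in chrom_cache:
            chrom_cache[iv.chrom] = _get_chrom_seq(genome, iv.chrom)
        seq = chrom_cache[iv.chrom]
        c = iv.center
        lo, hi = c - extent, c + extent + w  # window starts in [lo, hi - w]
        if lo < 0 or hi > seq.size:
            logger.warning(
                "peak %s:%d-%d window exceeds chromosome bounds; skipped",
                iv.chrom, iv.start, iv.end,
            )
            continue
        starts, _, _ = scan(pwm, seq[lo:hi], threshold=threshold)
        hist[starts] += 1  # starts are offsets from lo, i.e. offset + extent
        n_used += 1
    kernel = np.ones(window, dtype=int)
    counts = np.convolve(hist, kernel, mode="valid")
    offsets = np.arange(-extent, extent - window + 2)
    assert counts.size == offsets.size == 2 * extent - window + 2
    return PositionalDensity(
        window=window, step=step, extent=extent,
        offsets=offsets, counts=counts,
        n_peaks=n_used, total_hits=int(hist.sum()),
    )


def motif_containing_count(peaks: PeakSet, genome, pwm: PWM,
                           threshold: float | None = None) -> int:
    """Number of peaks with >= 1 hit anywhere inside the peak interval."""
    n = 0
    chrom_cache: dict[str, np.ndarray] = {}
    for iv in peaks:
        if iv.chrom not in chrom_cache:
            chrom_cache[iv.chrom] = _get_chrom_seq(genome, iv.chrom)
        seq = chrom_cache[iv.chrom][iv.start : iv.end]
        starts, _, _ = scan(pwm, seq, threshold=threshold)
        if starts.size:
            n += 1
    return n


def randomized_control(
    peaks: PeakSet,
    chrom_sizes: Mapping[str, int],
    seed: int,
    genome=None,
    pwm: PWM | None = None,
    threshold: float | None = None,
) -> tuple[PeakSet, int | None]:
    """Shuffle peaks to uniform random positions (same chromosome, same
    length) and optionally count motif-containing peaks in the shuffle.

    Deterministic under ``seed``. Returns ``(shuffled_set, count)``; the
    count is None unless ``genome`` and ``pwm`` are supplied.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for iv in peaks:
        size = chrom_sizes[iv.chrom]
        if iv.length > size:
            raise ValueError(
                f"peak length {iv.length} exceeds chromosome {iv.chrom} ({size} bp)"
            )
        new_start = int(rng.integers(0, size - iv.length + 1))
        shuffled.append(
            GenomicInterval(iv.chrom, new_start, new_start + iv.length,
                            name=iv.name, score=iv.score, strand=iv.strand)
        )
    out = peaks.with_intervals(shuffled)
    count = None
    if genome is not None and pwm is not None:
        count = motif_containing_count(out, genome, pwm, threshold=threshold)
    return out, count
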