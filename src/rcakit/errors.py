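"""Sequencing error-rate measurement and Phred conversions.

The error rate of a read set is defined as the number of substitution
mismatches against a known reference, divided by the total mapped read
length; insertions and deletions are excluded from the numerator.  Reads
overlapping known germline variants are removed first, as are reads below
a mapping-quality threshold, and at most a fixed number of mutually
non-overlapping reads is retained before counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignedRead",
    "ErrorRateResult",
    "NoUsableReadsError",
    "compute_error_rate",
    "phred_from_rate",
    "phred_exact",
]


class NoUsableReadsError(ValueError):
    """Raised when filtering leaves no reads to measure an error rate on."""


@dataclass(frozen=True)
class AlignedRead:
    """A read with a gapless alignment to a reference.

    ``start`` is 0-based; the read covers ``[start, start + len(seq))`` on
    ``chrom``.  Indels observed during alignment are carried as counts only
    (they do not contribute mismatches, matching the substitution-only
    error definition).
    """

    chrom: str
    start: int
    seq: str
    mapq: int = 60
    n_insertions: int = 0
    n_deletions: int = 0

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass(frozen=True)
class ErrorRateResult:
    error_rate: float
    phred: int
    n_reads_used: int
    n_bases: int


def phred_exact(e: float) -> float:
    """Unrounded Phred quality -10*log10(e) for an error probability e."""
    if not 0.0 < e <= 1.0:
        raise ValueError(f"error probability must be in (0, 1], got {e}")
    return -10.0 * math.log10(e)


def phred_from_rate(e: float, *, zero_cap: int | None = None) -> int:
    """Integer Phred quality, truncated: Q = floor(-10*log10(e)).

    ``e = 0`` has no finite Phred value; pass ``zero_cap`` (e.g. 60) to
    request an explicit cap instead of an error.
    """
    if e == 0:
        if zero_cap is not None:
            return int(zero_cap)
        raise ValueError("Phred quality of a zero error rate is undefined; pass zero_cap")
    return int(math.floor(phred_exact(e)))


def _mask_by_chrom(germline_mask: Iterable[tuple[str, int]]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for chrom, pos in germline_mask:
        by.setdefault(chrom, []).append(pos)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in by.items()}


def _overlaps_mask(read: AlignedRead, mask: dict[str, np.ndarray]) -> bool:
    pos = mask.get(read.chrom)
    if pos is None or len(pos) == 0:
        return False
    i = np.searchsorted(pos, read.start, side="left")
    return bool(i < len(pos) and pos[i] < read.end)


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def encode_bases(seq: str) -> np.ndarray:
    """Map a base string to uint8 codes (A,C,G,T -> 0..3; other -> 255)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _count_substitutions(read: AlignedRead, reference: Mapping[str, str]) -> int:
    ref = reference[read.chrom]
    if read.end > len(ref):
        raise ValueError(
            f"read [{read.start}, {read.end}) exceeds reference {read.chrom} "
            f"of length {len(ref)}"
        )
    a = encode_bases(read.seq)
    b = encode_bases(ref[read.start:read.end])
    valid = (a != 255) & (b != 255)
    return int(np.count_nonzero((a != b) & valid))


def compute_error_rate(
    reads: Sequence[AlignedRead],
    reference: Mapping[str, str],
    germline_mask: Iterable[tuple[str, int]] = (),
    mapq_min: int = 60,
    subsample: int = 400_000,
    seed: int | np.random.Generator | None = None,
) -> ErrorRateResult:
    """Measure the per-base substitution error rate of aligned reads.

    Filtering order: drop reads with ``mapq < mapq_min``; drop reads
    overlapping any germline-mask position; greedily keep a maximal set of
    mutually non-overlapping reads (ties in genomic order broken by a
    seeded shuffle); if more than ``subsample`` remain, keep a seeded
    random subset of that size.  The rate is total substitutions divided
    by total aligned bases; indels never enter the numerator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mask = _mask_by_chrom(germline_mask)

    kept = [r for r in reads if r.mapq >= mapq_min and not _overlaps_mask(r, mask)]
    if not kept:
        raise NoUsableReadsError("no reads remain after MAPQ and germline filtering")

    # Non-overlapping sweep: random priority among reads at the same start,
    # then a left-to-right greedy pass per chromosome.
    priority = rng.permutation(len(kept))
    order = sorted(range(len(kept)), key=lambda i: (kept[i].chrom, kept[i].start, priority[i]))
    chosen: list[AlignedRead] = []
    last_end: dict[str, int] = {}
    for i in order:
        r = kept[i]
        if r.start >= last_end.get(r.chrom, -1):
            chosen.append(r)
            last_end[r.chrom] = r.end
    if len(chosen) > subsample:
        idx = rng.choice(len(chosen), size=subsample, replace=False)
        chosen = [chosen[i] for i in sorted(idx)]
    if not chosen:
        raise NoUsableReadsError("no non-overlapping reads available")

    n_sub = sum(_count_substitutions(r, reference) for r in chosen)
    n_bases = sum(len(r.seq) for r in chosen)
    rate = n_sub / n_bases
    return ErrorRateResult(
        error_rate=rate,
        phred=phred_from_rate(rate, zero_cap=60),
        n_reads_used=len(chosen),
        n_bases=n_bases,
    )
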