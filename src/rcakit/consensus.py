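"""Consensus calling for rolling-circle concatemer reads.

A concatemer carries several error-bearing copies (subreads) of one
template fragment.  Because the generator's error model is
substitution-only, subreads are column-aligned to template coordinates
and the consensus base at each column is a plurality vote over subreads.
Reads with fewer than three repeats carry too little redundancy and are
rejected.  After consensus, residual backbone sequence is trimmed from
both ends and reads mapping to the same genomic coordinates within
+/-1 bp are merged into a single representative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import encode_bases
from .synth import BASES, ConcatemerRead

__all__ = [
    "ConsensusRead",
    "call_consensus",
    "trim_backbone",
    "deduplicate",
    "consensus_error_theory",
]

#: Consensus base qualities are capped here (Phred scale).
MAX_CONSENSUS_QUAL = 60
MIN_CONSENSUS_QUAL = 2


@dataclass(frozen=True)
class ConsensusRead:
    """Error-reduced consensus of one concatemer's subreads.

    ``coords`` are 0-based half-open genomic coordinates of the insert;
    ``qual`` is the per-base aggregated Phred quality.
    """

    template_id: str
    seq: str
    qual: tuple[int, ...]
    n_repeats: int
    coords: tuple[str, int, int]
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("seq and qual must have equal length")


def call_consensus(read: ConcatemerRead, min_repeats: int = 3) -> ConsensusRead | None:
    """Plurality-vote consensus over a concatemer's subread stack.

    Returns ``None`` (rejection) when the read has fewer than
    ``min_repeats`` subreads.  Per column, the consensus base is the one
    observed in most subreads; plurality ties are broken by the highest
    summed subread quality, then by the template base if it is among the
    tied candidates, then by the alphabetically smallest base.  The
    consensus quality of a column is the summed quality of agreeing
    subreads minus that of disagreeing subreads, floored at
    ``MIN_CONSENSUS_QUAL`` and capped at ``MAX_CONSENSUS_QUAL``.
    """
    if read.n_repeats < min_repeats:
        return None
    L = len(read.template_seq)
    X = np.stack([encode_bases(s) for s in read.subreads])  # (r, L)
    if np.any(X == 255):
        raise ValueError("subreads contain non-ACGT characters")
    Q = np.asarray(read.subread_quals, dtype=np.int64)  # (r, L)

    counts = np.stack([(X == b).sum(axis=0) for b in range(4)])  # (4, L)
    qsum = np.stack([np.where(X == b, Q, 0).sum(axis=0) for b in range(4)])  # (4, L)

    tied = counts == counts.max(axis=0)  # plurality candidates
    q_masked = np.where(tied, qsum, -1)
    tied &= q_masked == q_masked.max(axis=0)  # quality tie-break

    tmpl = encode_bases(read.template_seq)
    cols = np.arange(L)
    prefer_tmpl = tied[tmpl, cols]
    # argmax over the remaining tie mask picks the smallest base index,
    # which is alphabetical order for "ACGT".
    chosen = np.where(prefer_tmpl, tmpl, tied.argmax(axis=0))

    q_agree = qsum[chosen, cols]
    q_total = Q.sum(axis=0)
    qual = np.clip(q_agree - (q_total - q_agree), MIN_CONSENSUS_QUAL, MAX_CONSENSUS_QUAL)

    return ConsensusRead(
        template_id=read.template_id,
        seq="".join(BASES[c] for c in chosen),
        qual=tuple(int(q) for q in qual),
        n_repeats=read.n_repeats,
        coords=read.template_coords,
        timestamp=read.timestamp,
    )


def trim_backbone(
    consensus: ConsensusRead,
    backbone_seq: str,
    max_mismatch_frac: float = 0.10,
    min_overlap: int = 5,
) -> ConsensusRead | None:
    """Remove residual backbone from the 5' and 3' ends of a consensus read.

    The read's prefix is compared against the backbone's tail and the
    read's suffix against the backbone's head (the orientations adjacent
    to the insert in the concatemer).  The maximal end-anchored match with
    at most ``max_mismatch_frac`` mismatches is removed; matches shorter
    than ``min_overlap`` are ignored so that inserts that merely share a
    base or two with the backbone are untouched.  Returns ``None`` when
    trimming would empty the read.  Coordinates refer to the insert and
    are unchanged.
    """
    if not backbone_seq:
        return consensus
    bb = encode_bases(backbone_seq)
    seq = encode_bases(consensus.seq)
    k5 = 0
    kmax = min(len(seq), len(bb))
    for k in range(kmax, min_overlap - 1, -1):
        if np.count_nonzero(seq[:k] != bb[len(bb) - k :]) <= max_mismatch_frac * k:
            k5 = k
            break
    k3 = 0
    for k in range(kmax, min_overlap - 1, -1):
        if np.count_nonzero(seq[len(seq) - k :] != bb[:k]) <= max_mismatch_frac * k:
            k3 = k
            break
    if k5 + k3 >= len(seq):
        return None
    if k5 == 0 and k3 == 0:
        return consensus
    new_seq = consensus.seq[k5 : len(consensus.seq) - k3]
    new_qual = consensus.qual[k5 : len(consensus.qual) - k3]
    return replace(consensus, seq=new_seq, qual=new_qual)


def deduplicate(reads: Sequence[ConsensusRead], tol: int = 1) -> list[ConsensusRead]:
    """Merge consensus reads mapping to the same coordinates within ``tol`` bp.

    Reads whose starts and ends both agree within ``tol`` are clustered by
    single linkage; each cluster is represented by its member with the
    most repeats (ties: earliest timestamp).  Output is sorted by
    coordinates, so the operation is deterministic and idempotent.
    """
    n = len(reads)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (reads[i].coords[0], reads[i].coords[1], reads[i].coords[2]))
    for a in range(n):
        i = order[a]
        ci = reads[i].coords
        for b in range(a + 1, n):
            j = order[b]
            cj = reads[j].coords
            if cj[0] != ci[0] or cj[1] - ci[1] > tol:
                break
            if abs(cj[2] - ci[2]) <= tol:
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    reps = [
        min(members, key=lambda i: (-reads[i].n_repeats, reads[i].timestamp, i))
        for members in clusters.values()
    ]
    return sorted((reads[i] for i in reps), key=lambda r: r.coords)


def consensus_error_theory(e: float, r: int) -> float:
    """Exact per-column consensus error probability for ``r`` subreads.

    Enumerates every multinomial outcome of ``r`` iid subread bases under
    the uniform-3-alternative substitution model (correct with probability
    1-e, each specific wrong base with probability e/3) and applies the
    plurality rule with equal-quality tie-breaking toward the template
    base.  A column is miscalled exactly when some single wrong base
    outnumbers the correct base.
    """
    if not 0.0 <= e < 1.0:
        raise ValueError("e must be in [0, 1)")
    if r < 1:
        raise ValueError("r must be >= 1")
    if e == 0.0:
        return 0.0
    p_err = 0.0
    log_fact = [math.lgamma(k + 1) for k in range(r + 1)]
    for c0 in range(r + 1):
        rem = r - c0
        for c1 in range(rem + 1):
            for c2 in range(rem - c1 + 1):
                c3 = rem - c1 - c2
                if max(c1, c2, c3) <= c0:
                    continue  # template base wins (ties included)
                logp = (
                    log_fact[r]
                    - log_fact[c0]
                    - log_fact[c1]
                    - log_fact[c2]
                    - log_fact[c3]
                    + c0 * math.log(1 - e)
                    + rem * math.log(e / 3.0)
                )
                p_err += math.exp(logp)
    return p_err
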