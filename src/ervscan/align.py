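"""Deterministic seed-and-extend local alignment.

The detection pipeline needs two alignment steps: reads against a short
LTR query, and junction flanks against the host genome.  Both are served
by the same machinery: an exact k-mer index over the reference and
ungapped X-less extension along each seeded diagonal (the maximal-scoring
segment on a diagonal is found exactly with a Kadane scan, so no score
drop-off heuristic is needed).  The error model upstream is
substitution-only, which makes ungapped extension exact for the data this
package aligns; an external gapped aligner can be plugged in through
:class:`Aligner`.

All coordinates are 0-based half-open.  For reverse-strand alignments the
query interval is reported in the coordinates of the query as given (not
of its reverse complement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from ._seq import kmer_codes, revcomp


@dataclass(frozen=True)
class AlignParams:
    """Scoring and seeding parameters for the built-in aligner."""

    k: int = 14                 # seed length
    match: int = 1
    mismatch: int = -4
    min_score: int = 18         # minimum segment score to report
    min_aligned: int = 20       # minimum aligned length (bp)
    min_identity: float = 0.9
    max_seed_hits: int = 64     # k-mers with more reference hits are skipped
    near_margin: int = 0        # second locus within this score of best => multi-mapping


@dataclass(frozen=True)
class LocalAlignment:
    chrom: str | None
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str          # '+' or '-'
    score: int
    n_mismatch: int
    n_best_loci: int = 1

    @property
    def is_unique(self) -> bool:
        return self.n_best_loci == 1


class Aligner(Protocol):
    """Anything that maps an encoded query onto a reference."""

    def align(self, query: np.ndarray) -> LocalAlignment | None: ...


def _best_segment(scores: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment (Kadane, leftmost on ties).

    Returns (start, stop, score) with stop exclusive; score may be <= 0
    for all-mismatch input.
    """
    prefix = np.concatenate(([0], np.cumsum(scores)))
    prefix_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - prefix_min
    j = int(np.argmax(gains))
    i = int(np.argmin(prefix[: j + 1]))
    return i, j + 1, int(gains[j])


def _extend_diagonal(
    query: np.ndarray, ref: np.ndarray, diag: int, params: AlignParams
) -> tuple[int, int, int, int] | None:
    """Best ungapped segment on one diagonal: (q_start, q_end, score, n_mm)."""
    q_lo = max(0, -diag)
    q_hi = min(query.shape[0], ref.shape[0] - diag)
    if q_hi - q_lo < params.min_aligned:
        return None
    qseg = query[q_lo:q_hi]
    rseg = ref[q_lo + diag : q_hi + diag]
    match = (qseg == rseg) & (qseg != 4) & (rseg != 4)
    scores = np.where(match, params.match, params.mismatch)
    i, j, score = _best_segment(scores)
    length = j - i
    if score < params.min_score or length < params.min_aligned:
        return None
    n_match = int(match[i:j].sum())
    if n_match / length < params.min_identity:
        return None
    return q_lo + i, q_lo + j, score, length - n_match


class KmerIndex:
    """Sorted exact k-mer index over one or more reference sequences.

    Multiple chromosomes are concatenated with an N spacer so no k-mer
    spans a boundary; positions are translated back on lookup.
    """

    def __init__(self, chroms: dict[str, np.ndarray], k: int = 14):
        self.k = int(k)
        self.names = list(chroms)
        spacer = np.full(self.k, 4, dtype=np.uint8)
        parts: list[np.ndarray] = []
        offsets: list[int] = []
        pos = 0
        for name in self.names:
            seq = np.ascontiguousarray(chroms[name], dtype=np.uint8)
            offsets.append(pos)
            parts.append(seq)
            parts.append(spacer)
            pos += seq.shape[0] + self.k
        self.concat = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray([chroms[n].shape[0] for n in self.names], dtype=np.int64)
        kmers, valid = kmer_codes(self.concat, self.k)
        idx = np.nonzero(valid)[0]
        order = np.argsort(kmers[idx], kind="stable")
        self.sorted_kmers = kmers[idx][order]
        self.sorted_pos = idx[order].astype(np.int64)

    def chrom_of(self, concat_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map concatenated positions to (chrom index, within-chrom position)."""
        ci = np.searchsorted(self.offsets, concat_pos, side="right") - 1
        return ci, concat_pos - self.offsets[ci]

    def seed_hits(
        self, qkmers: np.ndarray, valid: np.ndarray, max_hits: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """All (query offset, concat reference position) seed pairs."""
        lo = np.searchsorted(self.sorted_kmers, qkmers, side="left")
        hi = np.searchsorted(self.sorted_kmers, qkmers, side="right")
        counts = hi - lo
        take = valid & (counts > 0) & (counts <= max_hits)
        sel = np.nonzero(take)[0]
        if sel.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        c = counts[sel]
        cum = np.concatenate(([0], np.cumsum(c)))
        flat = np.arange(cum[-1]) - np.repeat(cum[:-1], c) + np.repeat(lo[sel], c)
        return np.repeat(sel, c), self.sorted_pos[flat]

class SeedExtendAligner:
    """Built-in :class:`Aligner`: exact seeds, exact ungapped extension."""

    def __init__(self, chroms: dict[str, np.ndarray], params: AlignParams | None = None):
        self.params = params or AlignParams()
        for name, seq in chroms.items():
            if seq.shape[0] == 0:
                raise ValueError(f"empty reference sequence {name!r}")
        self.index = KmerIndex(chroms, k=self.params.k)

    def _candidates(self, query: np.ndarray, strand: str) -> list[LocalAlignment]:
        p = self.params
        qk, valid = kmer_codes(query, p.k)
        q_off, r_pos = self.index.seed_hits(qk, valid, p.max_seed_hits)
        if q_off.shape[0] == 0:
            return []
        diags = np.unique(r_pos - q_off)
        out = []
        qlen = query.shape[0]
        for d in diags:
            res = _extend_diagonal(query, self.index.concat, int(d), p)
            if res is None:
                continue
            qs, qe, score, n_mm = res
            ci, rs = self.index.chrom_of(np.asarray([qs + d]))
            chrom = self.index.names[int(ci[0])]
            ref_start = int(rs[0])
            if strand == "-":
                qs, qe = qlen - qe, qlen - qs
            out.append(
                LocalAlignment(
                    chrom=chrom,
                    ref_start=ref_start,
                    ref_end=ref_start + (qe - qs),
                    query_start=qs,
                    query_end=qe,
                    strand=strand,
                    score=score,
                    n_mismatch=n_mm,
                )
            )
        return out

    def align(self, query: np.ndarray) -> LocalAlignment | None:
        cands = self._candidates(query, "+") + self._candidates(revcomp(query), "-")
        if not cands:
            return None
        best_score = max(c.score for c in cands)
        # group near-best candidates into loci by reference-interval overlap
        near = [c for c in cands if c.score >= best_score - self.params.near_margin]
        near.sort(key=lambda c: (c.chrom, c.ref_start, c.ref_end, c.strand))
        loci: list[list[LocalAlignment]] = []
        for c in near:
            if loci and loci[-1][0].chrom == c.chrom and c.ref_start < max(x.ref_end for x in loci[-1]):
                loci[-1].append(c)
            else:
                loci.append([c])
        n_loci = len(loci)
        ranked = sorted(cands, key=lambda c: (-c.score, c.chrom, c.ref_start, c.strand))
        best = ranked[0]
        return LocalAlignment(
            chrom=best.chrom,
            ref_start=best.ref_start,
            ref_end=best.ref_end,
            query_start=best.query_start,
            query_end=best.query_end,
            strand=best.strand,
            score=best.score,
            n_mismatch=best.n_mismatch,
            n_best_loci=n_loci,
        )
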