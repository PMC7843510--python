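"""Seeded local alignment of reads against viral circles and host scaffolds.

A self-contained BLASTN-like search: exact k-mer seeding, window selection
by diagonal clustering, then optimal local (Smith–Waterman/Gotoh) alignment
of the read against each candidate window.  Scoring is match +1,
mismatch −2, gap open −5, gap extend −2 — close in effect to BLASTN
defaults at the high identities of 150 bp resequencing reads; bit-exact
BLASTN reproduction is a non-goal.

Circular targets are indexed on their doubled sequence so seeds (and
alignments) spanning the origin are found; reported coordinates are
reduced modulo the circle size into ``1..size``.

Significance uses the ungapped Karlin–Altschul model
``E = K·m·n·exp(−λ·score)`` with λ root-found for the +1/−2 scoring at
uniform base composition and the standard tabulated K for that scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from skbio.alignment import pair_align

from .core_io import CircularSequence, GenomeScaffold, reverse_complement

#: seed length for read mapping; 150 bp reads at <=1% substitution error
#: almost always contain an exact 15-mer in every 20 nt window
DEFAULT_K = 15

MATCH = 1
MISMATCH = -2
GAP_OPEN = 5
GAP_EXTEND = 2

#: standard tabulated Karlin-Altschul K for +1/-2 ungapped nucleotide scoring
KA_K = 0.621


@dataclass(frozen=True)
class LocalHit:
    """One local alignment of a read segment to a target.

    ``read_interval`` is 1-based inclusive on the read *as sequenced*.
    ``target_interval`` is 1-based inclusive on the target; start > end on
    minus-strand hits (the ``strand`` field is authoritative: a plus-strand
    hit wrapping a circle origin also has start > end).
    """

    read_id: str
    read_interval: tuple[int, int]
    target_id: str
    target_interval: tuple[int, int]
    strand: str
    matched_length: int
    identity: float
    score: float
    evalue: float
    # per-column (read_pos0, target_pos0) pairs in doubled-text coordinates;
    # used to project junction offsets through the alignment (himscan)
    columns: tuple[tuple[int, int], ...] = field(
        default=(), repr=False, compare=False
    )


class KmerIndex:
    """Exact k-mer lookup over a set of circles and/or scaffolds."""

    def __init__(
        self,
        targets: Sequence[CircularSequence | GenomeScaffold],
        k: int = DEFAULT_K,
    ) -> None:
        if k < 8:
            raise ValueError(f"k must be >= 8, got {k}")
        self.k = k
        self.texts: dict[str, str] = {}
        self.sizes: dict[str, int] = {}
        self.circular: dict[str, bool] = {}
        for t in targets:
            if isinstance(t, CircularSequence):
                tid, seq, circ = t.circle_id, t.residues, True
            else:
                tid, seq, circ = t.scaffold_id, t.residues, False
            if k > len(seq):
                raise ValueError(
                    f"k={k} exceeds length of target {tid} ({len(seq)})"
                )
            self.sizes[tid] = len(seq)
            self.circular[tid] = circ
            # doubled text lets seeds and extensions span the origin
            self.texts[tid] = seq + seq if circ else seq
        self.total_length = sum(self.sizes.values())
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, text in self.texts.items():
            n_pos = self.sizes[tid] if self.circular[tid] else len(text) - k + 1
            for pos in range(n_pos):
                kmer = text[pos : pos + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((tid, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


@lru_cache(maxsize=None)
def karlin_lambda(match: int = MATCH, mismatch: int = MISMATCH) -> float:
    """λ solving Σ p_i p_j exp(λ s_ij) = 1 at uniform base composition."""
    p_match, p_mismatch = 0.25, 0.75

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * match)
            + p_mismatch * math.exp(lam * mismatch)
            - 1.0
        )

    return brentq(f, 1e-9, 10.0)


def estimate_evalue(score: float, read_len: int, database_len: int) -> float:
    """Karlin–Altschul expectation ``E = K·m·n·exp(−λ·score)``.

    Monotone decreasing in score, linear in both sequence-space sizes.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    lam = karlin_lambda()
    return KA_K * read_len * database_len * math.exp(-lam * score)


def _alignment_identity(
    q: str, t: str, path, q_off: int, t_off: int
) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Fraction identical columns and per-column coordinate pairs."""
    qa, ta = path.to_aligned((q, t))
    matches = 0
    cols: list[tuple[int, int]] = []
    qi, ti = int(path.ranges[0][0]), int(path.ranges[1][0])
    for cq, ct in zip(qa, ta):
        if cq != "-" and ct != "-":
            cols.append((q_off + qi, t_off + ti))
            if cq == ct and cq != "N":
                matches += 1
        if cq != "-":
            qi += 1
        if ct != "-":
            ti += 1
    n_cols = len(qa)
    return (matches / n_cols if n_cols else 0.0), tuple(cols)


def _cluster_diagonals(diags: list[int], gap: int = 20) -> list[tuple[int, int]]:
    """Group sorted diagonals into (min, max) clusters separated by > gap."""
    diags = sorted(diags)
    clusters = []
    lo = hi = diags[0]
    for d in diags[1:]:
        if d - hi <= gap:
            hi = d
        else:
            clusters.append((lo, hi))
            lo = hi = d
    clusters.append((lo, hi))
    return clusters


def find_local_hits(
    read_id: str,
    sequence: str,
    index: KmerIndex,
    min_len: int = 20,
    min_identity: float = 0.95,
    max_evalue: float = 1e-5,
    keep_columns: bool = False,
) -> list[LocalHit]:
    """All retained local hits of one read against an indexed target set.

    Both strands are searched by also querying the reverse complement.
    Overlapping hits to the same target locus are merged keeping the best
    score.  Retained hits satisfy ``matched_length >= min_len``,
    ``identity >= min_identity`` and ``evalue <= max_evalue``.
    """
    if len(sequence) < min_len:
        return []
    k = index.k
    read_len = len(sequence)
    hits: list[LocalHit] = []
    for strand in "+-":
        seq = sequence if strand == "+" else reverse_complement(sequence)
        seeds: dict[str, list[int]] = {}
        for i in range(read_len - k + 1):
            for tid, pos in index.lookup(seq[i : i + k]):
                seeds.setdefault(tid, []).append(pos - i)
        for tid, diags in seeds.items():
            text = index.texts[tid]
            for lo, hi in _cluster_diagonals(diags):
                win_start = max(0, lo - 10)
                win_end = min(len(text), hi + read_len + 10)
                window = text[win_start:win_end]
                score, paths, _ = pair_align(
                    seq,
                    window,
                    mode="local",
                    sub_score=(MATCH, MISMATCH),
                    gap_cost=(GAP_OPEN, GAP_EXTEND),
                    atol=0,
                )
                if not paths or score <= 0:
                    continue
                path = paths[0]
                (qs, qe), (ts, te) = (
                    (int(a), int(b)) for a, b in path.ranges
                )  # 0-based half-open
                matched_length = qe - qs
                if matched_length < min_len:
                    continue
                identity, cols = _alignment_identity(
                    seq, window, path, 0, win_start
                )
                if identity < min_identity:
                    continue
                ev = estimate_evalue(score, read_len, index.total_length)
                if ev > max_evalue:
                    continue
                hits.append(
                    _build_hit(
                        read_id,
                        read_len,
                        strand,
                        tid,
                        index,
                        qs,
                        qe,
                        win_start + ts,
                        win_start + te,
                        matched_length,
                        identity,
                        float(score),
                        ev,
                        cols if keep_columns else (),
                    )
                )
    return _merge_hits(hits)


def _build_hit(
    read_id: str,
    read_len: int,
    strand: str,
    tid: str,
    index: KmerIndex,
    qs: int,
    qe: int,
    ts: int,
    te: int,
    matched_length: int,
    identity: float,
    score: float,
    evalue: float,
    columns: tuple[tuple[int, int], ...],
) -> LocalHit:
    # read interval on the as-sequenced read, 1-based inclusive
    if strand == "+":
        r_int = (qs + 1, qe)
    else:
        r_int = (read_len - qe + 1, read_len - qs)
    size = index.sizes[tid]
    lo1 = (ts % size) + 1 if index.circular[tid] else ts + 1
    hi1 = ((te - 1) % size) + 1 if index.circular[tid] else te
    t_int = (lo1, hi1) if strand == "+" else (hi1, lo1)
    return LocalHit(
        read_id=read_id,
        read_interval=r_int,
        target_id=tid,
        target_interval=t_int,
        strand=strand,
        matched_length=matched_length,
        identity=identity,
        score=score,
        evalue=evalue,
        columns=columns,
    )


def _merge_hits(hits: list[LocalHit]) -> list[LocalHit]:
    """Drop duplicates of the same locus, keeping the best score.

    Hits from adjacent seed clusters can describe the same alignment; two
    hits of one read to one target/strand whose read intervals overlap are
    considered one locus.
    """
    hits = sorted(hits, key=lambda h: (-h.score, h.target_id, h.read_interval))
    kept: list[LocalHit] = []
    for h in hits:
        dup = False
        for g in kept:
            if (
                g.target_id == h.target_id
                and g.strand == h.strand
                and h.read_interval[0] <= g.read_interval[1]
                and g.read_interval[0] <= h.read_interval[1]
                and _target_near(g, h)
            ):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def _target_near(a: LocalHit, b: LocalHit, slack: int = 400) -> bool:
    sa = sorted(a.target_interval)
    sb = sorted(b.target_interval)
    return sa[0] <= sb[1] + slack and sb[0] <= sa[1] + slack


def best_hits(hits: Sequence[LocalHit]) -> tuple[LocalHit | None, bool]:
    """Best-scoring hit and whether it is ambiguous (tied with another locus)."""
    if not hits:
        return None, False
    ranked = sorted(hits, key=lambda h: -h.score)
    best = ranked[0]
    ambiguous = len(ranked) > 1 and ranked[1].score == best.score
    return best, ambiguous


def hits_to_rows(hits: Iterable[LocalHit]) -> list[dict]:
    """Flatten hits for a tab-separated export."""
    return [
        {
            "read_id": h.read_id,
            "read_start": h.read_interval[0],
            "read_end": h.read_interval[1],
            "target_id": h.target_id,
            "target_start": h.target_interval[0],
            "target_end": h.target_interval[1],
            "strand": h.strand,
            "matched_length": h.matched_length,
            "identity": round(h.identity, 4),
            "score": h.score,
            "evalue": h.evalue,
        }
        for h in hits
    ]
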