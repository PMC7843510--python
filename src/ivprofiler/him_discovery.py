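"""Host integration motif (HIM) discovery and cross-virus prediction.

A conserved-broken circle linearises at a fixed junction *pair*; the
segment between the two junctions is excised during integration.  The HIM
is the excised segment plus short flanks, bounded by two pairs of
reverse-complementary repeats (11 nt and 6 nt in DsIV).  This module

* locates the conserved junction pair from a CBC's chimeric reads,
* computes the deletion length (two printed conventions exist, differing
  by one: the canonical output is the exclusive count
  ``downstream.left − upstream.left``; ``inclusive=True`` adds one),
* extracts the HIM region and enumerates all maximal reverse-complementary
  repeat pairs near the two junctions, and
* scans other virus segment sets for candidate HIMs by local alignment,
  projecting the query's junctions through each retained alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chimera_detection import ChimericRead
from .core_io import (
    BetweenBaseJunction,
    CircularSequence,
    circular_subsequence,
    reverse_complement,
)
from .integration_stats import paired_junction_counts, conserved_ratio
from .read_mapping import KmerIndex, LocalHit, find_local_hits

HIMSCAN_K = 8  # seeds must survive the 80% identity retention floor
DEFAULT_FLANK = 25
DEFAULT_MIN_REPEAT = 5
DEFAULT_MAX_GAP = 25


@dataclass(frozen=True)
class RepeatPair:
    """A reverse-complementary repeat pair flanking the two junctions.

    ``right_seq == reverse_complement(left_seq)`` always.  Positions are
    1-based starts; relative to the HIM region when produced by
    :func:`find_reverse_complement_repeat_pairs`, on the circle when part
    of a :class:`HimModel`.
    """

    left_seq: str
    right_seq: str
    left_position: int
    right_position: int

    def __post_init__(self) -> None:
        if self.right_seq != reverse_complement(self.left_seq):
            raise ValueError("repeat pair is not reverse-complementary")

    @property
    def length(self) -> int:
        return len(self.left_seq)


@dataclass(frozen=True)
class ConservedJunctionPair:
    upstream: BetweenBaseJunction
    downstream: BetweenBaseJunction
    upstream_support: int
    downstream_support: int


@dataclass(frozen=True)
class HimModel:
    circle_id: str
    upstream_junction: BetweenBaseJunction
    downstream_junction: BetweenBaseJunction
    deletion_length: int
    repeat_pairs: tuple[RepeatPair, ...]
    him_region: str
    flank: int


@dataclass(frozen=True)
class CrossVirusHit:
    query_circle_id: str
    subject_segment_id: str
    subject_accession: str | None
    identity: float
    alignment_length: int
    evalue: float
    upstream_junction: BetweenBaseJunction
    downstream_junction: BetweenBaseJunction
    putative_deletion: int


def detect_conserved_junction_pair(
    chimeras: Sequence[ChimericRead],
) -> ConservedJunctionPair:
    """The two modal virus junctions of a CBC, one per integrated-arc end.

    Reads anchoring the arc's right end support the upstream junction;
    reads anchoring its left end support the downstream junction.  A
    circle whose reads all anchor one end cannot yield a pair.
    """
    if not chimeras:
        raise ValueError("no chimeric reads")
    by_side = paired_junction_counts(chimeras)
    if not by_side["right_end"] or not by_side["left_end"]:
        raise ValueError(
            "single-ended evidence: junctions observed for only one arc end"
        )
    _, up = conserved_ratio(by_side["right_end"])
    _, down = conserved_ratio(by_side["left_end"])
    return ConservedJunctionPair(
        upstream=up,
        downstream=down,
        upstream_support=by_side["right_end"][up],
        downstream_support=by_side["left_end"][down],
    )


def deletion_length(
    upstream: BetweenBaseJunction,
    downstream: BetweenBaseJunction,
    circle_size: int,
    inclusive: bool = False,
) -> int:
    """Length of the excised stretch between the two junctions.

    Canonical (exclusive) convention: ``downstream.left − upstream.left``,
    wrapping modulo the circle size; identical junctions give 0.
    ``inclusive=True`` counts one more, the other printed convention.
    """
    if upstream.target_id != downstream.target_id:
        raise ValueError("junctions lie on different circles")
    base = (downstream.left_position - upstream.left_position) % circle_size
    return base + 1 if inclusive else base


def extract_him_region(
    circle: CircularSequence,
    upstream: BetweenBaseJunction,
    downstream: BetweenBaseJunction,
    flank: int = DEFAULT_FLANK,
) -> str:
    """Excised segment plus ``flank`` nt on each side, wrap-aware."""
    if flank >= circle.size / 2:
        raise ValueError(
            f"flank {flank} too large for circle of size {circle.size}"
        )
    deletion = deletion_length(upstream, downstream, circle.size)
    start = (upstream.left_position + 1 - flank - 1) % circle.size + 1
    return circular_subsequence(circle, start, deletion + 2 * flank)


def find_reverse_complement_repeat_pairs(
    him_region: str,
    upstream_offset: int,
    downstream_offset: int,
    min_len: int = DEFAULT_MIN_REPEAT,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[RepeatPair]:
    """All maximal reverse-complementary substring pairs near the junctions.

    ``upstream_offset``/``downstream_offset`` are between-base offsets in
    the region (number of residues before each junction).  The left member
    must lie within ``max_gap`` of the upstream junction, the right member
    within ``max_gap`` of the downstream junction; a pair is maximal when
    it cannot be extended in either direction.  Longest first.
    """
    w1_lo = max(0, upstream_offset - max_gap)
    w1_hi = min(len(him_region), upstream_offset + max_gap)
    w2_lo = max(0, downstream_offset - max_gap)
    w2_hi = min(len(him_region), downstream_offset + max_gap)
    w1 = him_region[w1_lo:w1_hi]
    w2 = him_region[w2_lo:w2_hi]
    rc2 = reverse_complement(w2)
    n, m = len(w1), len(rc2)
    pairs: list[RepeatPair] = []
    for i0 in range(n):
        for j0 in range(m):
            # start of a maximal run only
            if i0 > 0 and j0 > 0 and w1[i0 - 1] == rc2[j0 - 1]:
                continue
            if w1[i0] != rc2[j0]:
                continue
            length = 1
            while (
                i0 + length < n
                and j0 + length < m
                and w1[i0 + length] == rc2[j0 + length]
            ):
                length += 1
            if length < min_len:
                continue
            left_start0 = w1_lo + i0
            right_start0 = w2_lo + (len(w2) - j0 - length)
            left_seq = him_region[left_start0 : left_start0 + length]
            pairs.append(
                RepeatPair(
                    left_seq=left_seq,
                    right_seq=reverse_complement(left_seq),
                    left_position=left_start0 + 1,
                    right_position=right_start0 + 1,
                )
            )
    pairs.sort(key=lambda p: (-p.length, p.left_position, p.right_position))
    return pairs


def build_him_model(
    circle: CircularSequence,
    upstream: BetweenBaseJunction,
    downstream: BetweenBaseJunction,
    flank: int = DEFAULT_FLANK,
    min_repeat: int = DEFAULT_MIN_REPEAT,
    max_gap: int = DEFAULT_MAX_GAP,
) -> HimModel:
    """Assemble the HIM model of one circle from its junction pair."""
    deletion = deletion_length(upstream, downstream, circle.size)
    region = extract_him_region(circle, upstream, downstream, flank)
    region_pairs = find_reverse_complement_repeat_pairs(
        region, flank, flank + deletion, min_len=min_repeat, max_gap=max_gap
    )
    region_start0 = (upstream.left_position - flank) % circle.size  # 0-based
    circle_pairs = tuple(
        RepeatPair(
            left_seq=p.left_seq,
            right_seq=p.right_seq,
            left_position=(region_start0 + p.left_position - 1) % circle.size
            + 1,
            right_position=(region_start0 + p.right_position - 1) % circle.size
            + 1,
        )
        for p in region_pairs
    )
    return HimModel(
        circle_id=circle.circle_id,
        upstream_junction=upstream,
        downstream_junction=downstream,
        deletion_length=deletion,
        repeat_pairs=circle_pairs,
        him_region=region,
        flank=flank,
    )


def _project_offset(
    hit: LocalHit, query_len: int, offset: int
) -> int | None:
    """Project a between-base query offset through a hit's alignment.

    Returns the 0-based target position of the residue just right of the
    junction in strand-oriented coordinates, or None when the alignment
    does not cover the junction.
    """
    if hit.strand == "-":
        offset = query_len - offset
    for q0, t0 in hit.columns:
        if q0 >= offset:
            return t0
    return None


def predict_him_cross_virus(
    queries: Sequence[HimModel],
    subjects: Sequence[CircularSequence],
    min_identity: float = 0.80,
    min_len: int = 16,
    max_evalue: float = 10.0,
    k: int = HIMSCAN_K,
) -> list[CrossVirusHit]:
    """Scan other virus segments for candidate HIMs.

    Each query HIM region is searched against every subject with the local
    aligner; hits passing identity > 80%, length > 15 and E < 10 whose
    alignment covers both query junctions are reported with the predicted
    subject junction pair (raw alignment-image coordinates) and the
    putative deletion between them.
    """
    if not subjects:
        return []
    index = KmerIndex(subjects, k=k)
    accessions = {s.circle_id: s.accession for s in subjects}
    results: list[CrossVirusHit] = []
    for model in queries:
        region = model.him_region
        up_off = model.flank
        down_off = model.flank + model.deletion_length
        hits = find_local_hits(
            f"{model.circle_id}_him",
            region,
            index,
            min_len=min_len,
            min_identity=min_identity,
            max_evalue=max_evalue,
            keep_columns=True,
        )
        for hit in hits:
            size = index.sizes[hit.target_id]
            up_t = _project_offset(hit, len(region), up_off)
            down_t = _project_offset(hit, len(region), down_off)
            if up_t is None or down_t is None:
                continue
            if hit.strand == "-":
                up_t, down_t = down_t, up_t
            up_j = BetweenBaseJunction.on_circle(hit.target_id, up_t, size)
            down_j = BetweenBaseJunction.on_circle(hit.target_id, down_t, size)
            results.append(
                CrossVirusHit(
                    query_circle_id=model.circle_id,
                    subject_segment_id=hit.target_id,
                    subject_accession=accessions.get(hit.target_id),
                    identity=hit.identity,
                    alignment_length=hit.matched_length,
                    evalue=hit.evalue,
                    upstream_junction=up_j,
                    downstream_junction=down_j,
                    putative_deletion=deletion_length(up_j, down_j, size),
                )
            )
    results.sort(
        key=lambda h: (h.query_circle_id, h.evalue, h.subject_segment_id)
    )
    return results


def him_rows(models: Sequence[HimModel]) -> list[dict]:
    rows = []
    for m in models:
        rows.append(
            {
                "circle_id": m.circle_id,
                "upstream": (
                    f"{m.upstream_junction.left_position}-"
                    f"{m.upstream_junction.right_position}"
                ),
                "downstream": (
                    f"{m.downstream_junction.left_position}-"
                    f"{m.downstream_junction.right_position}"
                ),
                "deletion_length": m.deletion_length,
                "repeat_pairs": ";".join(
                    f"{p.left_seq}@{p.left_position}/"
                    f"{p.right_seq}@{p.right_position}"
                    for p in m.repeat_pairs
                ),
            }
        )
    return rows


def cross_virus_rows(hits: Sequence[CrossVirusHit]) -> list[dict]:
    rows = []
    for h in hits:
        rows.append(
            {
                "query_circle": h.query_circle_id,
                "subject_segment": h.subject_segment_id,
                "accession": h.subject_accession or "",
                "identity": round(h.identity, 4),
                "length": h.alignment_length,
                "evalue": h.evalue,
                "upstream": (
                    f"{h.upstream_junction.left_position}-"
                    f"{h.upstream_junction.right_position}"
                ),
                "downstream": (
                    f"{h.downstream_junction.left_position}-"
                    f"{h.downstream_junction.right_position}"
                ),
                "putative_deletion": h.putative_deletion,
            }
        )
    return rows
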