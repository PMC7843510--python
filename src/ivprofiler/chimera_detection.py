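"""Chimeric-read calling, junction inference, and breakpoint overlaps.

A qualified chimeric read carries a viral-circle hit on one end and a host
hit on the other end, each covering at least 20 nt of the read, with the
two matched lengths summing to more than 140 bp.  From an accepted read we
infer

* the *virus junction* — the between-base circle position at which the
  circle was linearised, read off the circle hit's boundary that faces the
  host side of the read (strand-aware), and
* the *host insertion* — the between-base scaffold position, read off the
  host hit's boundary that faces the virus side.

When integration used microhomology, the two hits share a few read bases
in the middle of the read; that intersection is the breakpoint *overlap*.
Each junction is reported from its own hit's inner boundary, so a k-base
overlap leaves both junction coordinates at the true breakpoints while the
overlap itself is recovered as the interval intersection.

The ``junction_side`` of a call records which end of the integrated arc
the read anchors: ``right_end`` means the arc ends just before the
junction (the upstream junction of a conserved break), ``left_end`` means
the arc begins just after it (the downstream junction).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import BetweenBaseJunction
from .read_mapping import LocalHit, best_hits

#: enumerated reasons a circle-hit-bearing read is not called chimeric
REJECTION_REASONS = (
    "no_host_hit",
    "ambiguous",
    "too_short_side",
    "sum_below_threshold",
    "same_side",
    "nested",
)


@dataclass(frozen=True)
class ChimericRead:
    read_id: str
    virus_hit: LocalHit
    host_hit: LocalHit
    virus_junction: BetweenBaseJunction
    host_insertion: BetweenBaseJunction
    junction_side: str  # 'left_end' | 'right_end' of the integrated arc
    overlap_interval: tuple[int, int] | None
    overlap_sequence: str

    @property
    def circle_id(self) -> str:
        return self.virus_hit.target_id

    @property
    def scaffold_id(self) -> str:
        return self.host_hit.target_id


@dataclass(frozen=True)
class OverlapClass:
    """Reads of one circle sharing a virus junction and overlap sequence."""

    circle_id: str
    virus_junction: BetweenBaseJunction
    overlap_sequence: str
    supporting_read_count: int


def _reaches_left(interval: tuple[int, int], slack: int) -> bool:
    return interval[0] <= 1 + slack


def _reaches_right(interval: tuple[int, int], length: int, slack: int) -> bool:
    return interval[1] >= length - slack


def _contains(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[0] and b[1] <= a[1]


def call_chimeric_read(
    read_id: str,
    read_sequence: str,
    circle_hits: Sequence[LocalHit],
    host_hits: Sequence[LocalHit],
    circle_sizes: dict[str, int],
    min_side: int = 20,
    min_sum: int = 141,
    end_slack: int = 5,
) -> tuple[ChimericRead | None, str | None]:
    """Apply the chimeric-read filters to one read.

    Returns ``(call, None)`` on acceptance or ``(None, reason)`` with a
    reason from :data:`REJECTION_REASONS`.  ``min_sum=141`` implements the
    strict reading of "more than 140 bp".
    """
    if not circle_hits:
        raise ValueError("call_chimeric_read requires at least one circle hit")
    virus, v_ambig = best_hits(circle_hits)
    if not host_hits:
        return None, "no_host_hit"
    host, h_ambig = best_hits(host_hits)
    if v_ambig or h_ambig:
        return None, "ambiguous"
    if virus.matched_length < min_side or host.matched_length < min_side:
        return None, "too_short_side"
    if virus.matched_length + host.matched_length < min_sum:
        return None, "sum_below_threshold"

    length = len(read_sequence)
    v_int, h_int = virus.read_interval, host.read_interval
    if _contains(v_int, h_int) or _contains(h_int, v_int):
        return None, "nested"
    v_left = _reaches_left(v_int, end_slack)
    v_right = _reaches_right(v_int, length, end_slack)
    h_left = _reaches_left(h_int, end_slack)
    h_right = _reaches_right(h_int, length, end_slack)
    virus_on_left = v_left and h_right and h_int[0] > v_int[0]
    virus_on_right = v_right and h_left and v_int[0] > h_int[0]
    if not (virus_on_left or virus_on_right):
        return None, "same_side"

    virus_junction, host_insertion, side = infer_junctions(
        virus, host, circle_sizes[virus.target_id]
    )
    overlap_interval, overlap_sequence = compute_overlap(
        virus, host, read_sequence
    )
    return (
        ChimericRead(
            read_id=read_id,
            virus_hit=virus,
            host_hit=host,
            virus_junction=virus_junction,
            host_insertion=host_insertion,
            junction_side=side,
            overlap_interval=overlap_interval,
            overlap_sequence=overlap_sequence,
        ),
        None,
    )


def infer_junctions(
    virus: LocalHit,
    host: LocalHit,
    circle_size: int,
) -> tuple[BetweenBaseJunction, BetweenBaseJunction, str]:
    """Infer circle linearisation junction and host insertion site.

    Each junction is the between-base position at the hit's boundary that
    faces the other hit, taken strand-aware from the hit's own target
    coordinates.  Also classifies which end of the integrated arc the read
    anchors (``left_end``/``right_end``).
    """
    virus_on_left = virus.read_interval[0] <= host.read_interval[0]

    ti = virus.target_interval
    if virus_on_left:
        inner = ti[1]  # target coordinate at the virus hit's right read end
        if virus.strand == "+":
            vj = BetweenBaseJunction.on_circle(virus.target_id, inner, circle_size)
            side = "right_end"  # arc occupies ...inner
        else:
            vj = BetweenBaseJunction.on_circle(
                virus.target_id, inner - 1, circle_size
            )
            side = "left_end"  # arc occupies inner...
    else:
        inner = ti[0]
        if virus.strand == "+":
            vj = BetweenBaseJunction.on_circle(
                virus.target_id, inner - 1, circle_size
            )
            side = "left_end"
        else:
            vj = BetweenBaseJunction.on_circle(virus.target_id, inner, circle_size)
            side = "right_end"

    hi = host.target_interval
    if virus_on_left:  # host hit on the right; its inner boundary is its start
        inner_h = hi[0]
        if host.strand == "+":
            hj = BetweenBaseJunction(host.target_id, inner_h - 1, inner_h)
        else:
            hj = BetweenBaseJunction(host.target_id, inner_h, inner_h + 1)
    else:
        inner_h = hi[1]
        if host.strand == "+":
            hj = BetweenBaseJunction(host.target_id, inner_h, inner_h + 1)
        else:
            hj = BetweenBaseJunction(host.target_id, inner_h - 1, inner_h)
    return vj, hj, side


def compute_overlap(
    virus: LocalHit, host: LocalHit, read_sequence: str
) -> tuple[tuple[int, int] | None, str]:
    """Intersection of the two hits' read intervals and its sequence."""
    lo = max(virus.read_interval[0], host.read_interval[0])
    hi = min(virus.read_interval[1], host.read_interval[1])
    if lo > hi:
        return None, ""
    return (lo, hi), read_sequence[lo - 1 : hi]


def tabulate_overlaps(
    chimeras: Iterable[ChimericRead], circle_id: str
) -> list[OverlapClass]:
    """Group one circle's chimeric reads by (virus junction, overlap sequence).

    Class counts sum to the circle's chimeric-read total; classes are
    returned by descending support, ties by junction then sequence.
    """
    counts: Counter[tuple[BetweenBaseJunction, str]] = Counter()
    for c in chimeras:
        if c.circle_id != circle_id:
            raise ValueError(
                f"read {c.read_id} belongs to {c.circle_id}, not {circle_id}"
            )
        counts[(c.virus_junction, c.overlap_sequence)] += 1
    return [
        OverlapClass(circle_id, junction, seq, n)
        for (junction, seq), n in sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
        )
    ]


def chimera_rows(chimeras: Iterable[ChimericRead]) -> list[dict]:
    """Flatten calls for the chimeric-read TSV export."""
    rows = []
    for c in chimeras:
        rows.append(
            {
                "read_id": c.read_id,
                "circle_id": c.circle_id,
                "circle_junction": (
                    f"{c.virus_junction.left_position}-"
                    f"{c.virus_junction.right_position}"
                ),
                "junction_side": c.junction_side,
                "scaffold_id": c.scaffold_id,
                "host_insertion": (
                    f"{c.host_insertion.left_position}-"
                    f"{c.host_insertion.right_position}"
                ),
                "strands": f"{c.virus_hit.strand}/{c.host_hit.strand}",
                "virus_len": c.virus_hit.matched_length,
                "host_len": c.host_hit.matched_length,
                "overlap_sequence": c.overlap_sequence,
            }
        )
    return rows
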