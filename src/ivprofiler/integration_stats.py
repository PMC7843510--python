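"""Per-circle integration statistics and circle classification.

Implements the per-circle bookkeeping used to decide, for each viral
circle, whether it persists only episomally or also chromosomally, and —
for integrated circles — whether it linearises at one conserved junction
pair (conserved-broken circle, CBC) or at effectively random positions
(random-broken circle, RBC):

* depth  ``x = related_reads × read_length / circle_size``
* percent integrated  ``% = (chimeric_reads / 2) / x × 100``
  (each integrated copy produces two junctions, hence the halving)
* form: ``integrated`` iff percent ≥ 1% (threshold configurable)
* conserved ratio: reads at the circle's modal junction / total chimeric
  reads; for the break-mode call the modal support of each arc end is
  pooled, because one conserved junction *pair* shows up as two junction
  coordinates — one per end of the integrated arc — while a single random
  linearisation yields the same coordinate at both ends.
* break mode: CBC iff ratio > 0.5 (strict), RBC otherwise; circles with
  fewer than ``min_reads`` chimeric reads are left ``undetermined``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from .chimera_detection import ChimericRead
from .core_io import BetweenBaseJunction

DEFAULT_READ_LENGTH = 150
DEFAULT_PERCENT_THRESHOLD = 1.0
DEFAULT_MIN_MODE_READS = 4


@dataclass(frozen=True)
class CircleProfile:
    circle_id: str
    circle_size: int
    related_read_count: int
    chimeric_read_count: int
    depth: float
    percent_integrated: float
    form: str  # 'non_integrated' | 'integrated'
    conserved_ratio: float | None
    break_mode: str  # 'CBC' | 'RBC' | 'undetermined'
    majority_junction: tuple[BetweenBaseJunction, ...] | None


def compute_depth(
    related_read_count: int,
    circle_size: int,
    read_length: int = DEFAULT_READ_LENGTH,
) -> float:
    """Coverage estimate: every related read contributes one full read length."""
    if circle_size <= 0:
        raise ValueError("circle_size must be positive")
    if related_read_count < 0:
        raise ValueError("related_read_count must be non-negative")
    return related_read_count * read_length / circle_size


def percent_integrated(chimeric_read_count: int, depth: float) -> float:
    """Percent of a circle's copies that are chromosomally integrated."""
    if chimeric_read_count == 0:
        return 0.0
    if depth <= 0:
        raise ValueError(
            f"inconsistent input: {chimeric_read_count} chimeric reads "
            "but zero depth"
        )
    return (chimeric_read_count / 2) / depth * 100.0


def classify_form(
    percent: float, threshold: float = DEFAULT_PERCENT_THRESHOLD
) -> str:
    """``integrated`` iff the percent reaches the threshold (boundary included)."""
    if percent < 0:
        raise ValueError("percent must be non-negative")
    return "integrated" if percent >= threshold else "non_integrated"


def _junction_sort_key(j: Hashable):
    if isinstance(j, BetweenBaseJunction):
        return (j.target_id, j.left_position)
    if isinstance(j, tuple):
        return tuple(_junction_sort_key(x) for x in j)
    return (str(j),)


def conserved_ratio(
    junction_counts: Mapping[Hashable, int],
) -> tuple[float, Hashable]:
    """Modal fraction of a junction count table.

    Returns ``(modal count / total, modal key)``; ties break toward the
    smallest circle coordinate.  Empty input raises (the circle is then
    reported ``undetermined`` upstream).
    """
    if not junction_counts:
        raise ValueError("no junctions observed")
    total = sum(junction_counts.values())
    best = min(
        junction_counts.items(), key=lambda kv: (-kv[1], _junction_sort_key(kv[0]))
    )
    return best[1] / total, best[0]


def paired_junction_counts(
    chimeras: Iterable[ChimericRead],
) -> dict[str, Counter[BetweenBaseJunction]]:
    """Junction support split by which arc end the read anchors."""
    by_side: dict[str, Counter[BetweenBaseJunction]] = {
        "right_end": Counter(),
        "left_end": Counter(),
    }
    for c in chimeras:
        by_side[c.junction_side][c.virus_junction] += 1
    return by_side


def _support_within(
    counts: Counter, junction: BetweenBaseJunction, tol: int
) -> int:
    if tol <= 0:
        return counts[junction]
    return sum(
        n
        for j, n in counts.items()
        if j.target_id == junction.target_id
        and abs(j.left_position - junction.left_position) <= tol
    )


def paired_conserved_ratio(
    chimeras: Sequence[ChimericRead],
    junction_tol: int = 0,
) -> tuple[float, tuple[BetweenBaseJunction, ...]]:
    """Conserved ratio pooled over the two arc ends.

    The modal junction of each arc end is found independently and their
    supports are summed: a conserved junction *pair* contributes both its
    upstream (right_end) and downstream (left_end) coordinates, whereas
    scattered random breaks leave both modal supports small.  If the two
    modal junctions coincide (single linearisation point, no deletion) the
    read set is counted once.  ``junction_tol`` merges junctions within
    ±tol nt of the modal one into its support, absorbing residual
    microhomology ambiguity (0 = exact matching).
    """
    if not chimeras:
        raise ValueError("no chimeric reads")
    by_side = paired_junction_counts(chimeras)
    total = len(chimeras)
    modal: dict[str, tuple[int, BetweenBaseJunction] | None] = {}
    for side, counts in by_side.items():
        if counts:
            ratio, junction = conserved_ratio(counts)
            modal[side] = (_support_within(counts, junction, junction_tol), junction)
        else:
            modal[side] = None
    up, down = modal["right_end"], modal["left_end"]
    if up and down:
        if up[1] == down[1]:
            support = up[0] + down[0]
            majority: tuple[BetweenBaseJunction, ...] = (up[1],)
        else:
            support = up[0] + down[0]
            majority = (up[1], down[1])
    else:
        present = up or down
        support = present[0]
        majority = (present[1],)
    return support / total, majority


def classify_break_mode(
    ratio: float,
    total_chimeric: int,
    min_reads: int = DEFAULT_MIN_MODE_READS,
) -> str:
    """CBC iff ratio > 0.5 strictly; below ``min_reads`` no call is made."""
    if total_chimeric < min_reads:
        return "undetermined"
    return "CBC" if ratio > 0.5 else "RBC"


def profile_circle(
    circle_id: str,
    circle_size: int,
    related_read_count: int,
    chimeras: Sequence[ChimericRead],
    read_length: int = DEFAULT_READ_LENGTH,
    percent_threshold: float = DEFAULT_PERCENT_THRESHOLD,
    min_mode_reads: int = DEFAULT_MIN_MODE_READS,
    junction_tol: int = 0,
) -> CircleProfile:
    """Assemble the full per-circle profile from mapped evidence."""
    depth = compute_depth(related_read_count, circle_size, read_length)
    n_chim = len(chimeras)
    pct = percent_integrated(n_chim, depth) if n_chim else 0.0
    form = classify_form(pct, percent_threshold)
    if chimeras:
        ratio, majority = paired_conserved_ratio(chimeras, junction_tol)
        mode = classify_break_mode(ratio, n_chim, min_mode_reads)
    else:
        ratio, majority, mode = None, None, "undetermined"
    return CircleProfile(
        circle_id=circle_id,
        circle_size=circle_size,
        related_read_count=related_read_count,
        chimeric_read_count=n_chim,
        depth=depth,
        percent_integrated=pct,
        form=form,
        conserved_ratio=ratio,
        break_mode=mode,
        majority_junction=majority,
    )


def profile_rows(profiles: Iterable[CircleProfile]) -> list[dict]:
    rows = []
    for p in profiles:
        rows.append(
            {
                "circle_id": p.circle_id,
                "circle_size": p.circle_size,
                "related_reads": p.related_read_count,
                "chimeric_reads": p.chimeric_read_count,
                "depth": round(p.depth, 3),
                "percent_integrated": round(p.percent_integrated, 3),
                "form": p.form,
                "conserved_ratio": (
                    round(p.conserved_ratio, 4)
                    if p.conserved_ratio is not None
                    else ""
                ),
                "break_mode": p.break_mode,
                "majority_junction": (
                    ";".join(
                        f"{j.left_position}-{j.right_position}"
                        for j in p.majority_junction
                    )
                    if p.majority_junction
                    else ""
                ),
            }
        )
    return rows
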