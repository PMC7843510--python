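"""End-to-end orchestration: map → call chimeras → profile → HIM models.

The two-pass search mirrors the study design: every read is first
screened against the circle set, and only circle-related reads are mapped
against the host genome.  Per-circle statistics, break-mode calls, HIM
models for conserved-broken circles, and breakpoint-overlap tables are
assembled from the accepted chimeric reads.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .chimera_detection import (
    ChimericRead,
    OverlapClass,
    call_chimeric_read,
    chimera_rows,
    tabulate_overlaps,
)
from .core_io import CircularSequence, GenomeScaffold, SequencingRead
from .him_discovery import (
    HimModel,
    build_him_model,
    detect_conserved_junction_pair,
    him_rows,
)
from .integration_stats import CircleProfile, profile_circle, profile_rows
from .read_mapping import DEFAULT_K, KmerIndex, find_local_hits

logger = logging.getLogger("ivprofiler")


@dataclass
class ProfileParams:
    k: int = DEFAULT_K
    min_len: int = 20
    min_identity: float = 0.95
    evalue_circle: float = 1e-5
    evalue_host: float = 1e-5
    min_sum: int = 141
    end_slack: int = 5
    percent_threshold: float = 1.0
    min_mode_reads: int = 4
    read_length: int = 150
    him_flank: int = 25
    junction_tol: int = 0
    dedup: bool = False


@dataclass
class ProfileResult:
    profiles: list[CircleProfile]
    chimeras: list[ChimericRead]
    rejections: Counter
    related_counts: dict[str, int]
    him_models: dict[str, HimModel]
    overlap_classes: dict[str, list[OverlapClass]]
    n_reads: int
    n_circle_hit_reads: int

    def chimeras_of(self, circle_id: str) -> list[ChimericRead]:
        return [c for c in self.chimeras if c.circle_id == circle_id]

    def profile_of(self, circle_id: str) -> CircleProfile:
        for p in self.profiles:
            if p.circle_id == circle_id:
                return p
        raise KeyError(circle_id)

    def tables(self) -> dict[str, pd.DataFrame]:
        overlap_rows = [
            {
                "circle_id": oc.circle_id,
                "virus_junction": (
                    f"{oc.virus_junction.left_position}-"
                    f"{oc.virus_junction.right_position}"
                ),
                "overlap_sequence": oc.overlap_sequence,
                "overlap_length": len(oc.overlap_sequence),
                "read_count": oc.supporting_read_count,
            }
            for classes in self.overlap_classes.values()
            for oc in classes
        ]
        return {
            "circle_profiles": pd.DataFrame(profile_rows(self.profiles)),
            "chimeric_reads": pd.DataFrame(chimera_rows(self.chimeras)),
            "him_models": pd.DataFrame(him_rows(list(self.him_models.values()))),
            "overlap_classes": pd.DataFrame(overlap_rows),
        }


def profile_reads(
    circles: Sequence[CircularSequence],
    host_scaffolds: Sequence[GenomeScaffold],
    reads: Sequence[SequencingRead],
    params: ProfileParams | None = None,
) -> ProfileResult:
    """Run the full analysis over an in-memory read set."""
    params = params or ProfileParams()
    circle_index = KmerIndex(circles, k=params.k)
    host_index = KmerIndex(host_scaffolds, k=params.k)
    circle_sizes = {c.circle_id: c.size for c in circles}

    if params.dedup:
        seen: set[tuple[int, str]] = set()
        unique = []
        for read in reads:
            key = (read.mate, read.residues)
            if key not in seen:
                seen.add(key)
                unique.append(read)
        reads = unique

    related: Counter = Counter()
    rejections: Counter = Counter()
    chimeras: list[ChimericRead] = []
    n_circle_hit = 0
    for read in reads:
        key = f"{read.read_id}/{read.mate}"
        circle_hits = find_local_hits(
            key,
            read.residues,
            circle_index,
            min_len=params.min_len,
            min_identity=params.min_identity,
            max_evalue=params.evalue_circle,
        )
        if not circle_hits:
            continue
        n_circle_hit += 1
        best_circle = max(circle_hits, key=lambda h: h.score).target_id
        related[best_circle] += 1
        host_hits = find_local_hits(
            key,
            read.residues,
            host_index,
            min_len=params.min_len,
            min_identity=params.min_identity,
            max_evalue=params.evalue_host,
        )
        call, reason = call_chimeric_read(
            key,
            read.residues,
            circle_hits,
            host_hits,
            circle_sizes,
            min_side=params.min_len,
            min_sum=params.min_sum,
            end_slack=params.end_slack,
        )
        if call is not None:
            chimeras.append(call)
        else:
            rejections[reason] += 1

    by_circle: dict[str, list[ChimericRead]] = defaultdict(list)
    for c in chimeras:
        by_circle[c.circle_id].append(c)

    profiles: list[CircleProfile] = []
    him_models: dict[str, HimModel] = {}
    overlap_classes: dict[str, list[OverlapClass]] = {}
    for circle in circles:
        cid = circle.circle_id
        prof = profile_circle(
            cid,
            circle.size,
            related[cid],
            by_circle.get(cid, []),
            read_length=params.read_length,
            percent_threshold=params.percent_threshold,
            min_mode_reads=params.min_mode_reads,
            junction_tol=params.junction_tol,
        )
        profiles.append(prof)
        if by_circle.get(cid):
            overlap_classes[cid] = tabulate_overlaps(by_circle[cid], cid)
        if prof.break_mode == "CBC":
            try:
                pair = detect_conserved_junction_pair(by_circle[cid])
            except ValueError:
                logger.warning("circle %s: CBC with single-ended evidence", cid)
                continue
            him_models[cid] = build_him_model(
                circle,
                pair.upstream,
                pair.downstream,
                flank=params.him_flank,
            )

    logger.info(
        "reads=%d circle_hit_reads=%d chimeric=%d rejected=%s "
        "integrated=%d CBC=%d",
        len(reads),
        n_circle_hit,
        len(chimeras),
        dict(rejections),
        sum(p.form == "integrated" for p in profiles),
        sum(p.break_mode == "CBC" for p in profiles),
    )
    return ProfileResult(
        profiles=profiles,
        chimeras=chimeras,
        rejections=rejections,
        related_counts=dict(related),
        him_models=him_models,
        overlap_classes=overlap_classes,
        n_reads=len(reads),
        n_circle_hit_reads=n_circle_hit,
    )
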