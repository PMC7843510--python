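"""Chimeric-read filters, junction inference, and overlap tabulation."""

from __future__ import annotations

import random
from collections import Counter

import pandas as pd
import pytest

from ivprofiler.chimera_detection import (
    ChimericRead,
    call_chimeric_read,
    compute_overlap,
    infer_junctions,
    tabulate_overlaps,
)
from ivprofiler.core_io import BetweenBaseJunction
from ivprofiler.read_mapping import LocalHit


def make_hit(
    read_interval,
    target_id,
    target_interval,
    strand,
    score=None,
    read_id="r",
):
    length = read_interval[1] - read_interval[0] + 1
    return LocalHit(
        read_id=read_id,
        read_interval=read_interval,
        target_id=target_id,
        target_interval=target_interval,
        strand=strand,
        matched_length=length,
        identity=1.0,
        score=score if score is not None else float(length),
        evalue=1e-20,
    )


READ_150 = ("ACGT" * 38)[:150]
SIZES = {"DsIV-15": 4024, "circ": 4000}


class TestWorkedExample:
    """The published junction-inference example, reproduced end to end."""

    def test_minus_minus_example(self):
        virus = make_hit((1, 51), "DsIV-15", (2048, 1988), "-")
        host = make_hit((50, 150), "scaffold_206", (80256, 80156), "-")
        call, reason = call_chimeric_read(
            "r", READ_150, [virus], [host], SIZES
        )
        assert reason is None
        assert call.virus_junction == BetweenBaseJunction("DsIV-15", 1987, 1988)
        assert call.host_insertion == BetweenBaseJunction(
            "scaffold_206", 80256, 80257
        )
        assert call.overlap_interval == (50, 51)
        assert len(call.overlap_sequence) == 2

    def test_plus_strand_zero_overlap(self):
        virus = make_hit((1, 75), "circ", (101, 175), "+")
        host = make_hit((76, 150), "scaf", (5000, 5074), "+")
        vj, hj, side = infer_junctions(virus, host, SIZES["circ"])
        assert vj == BetweenBaseJunction("circ", 175, 176)
        assert hj == BetweenBaseJunction("scaf", 4999, 5000)
        assert side == "right_end"
        assert compute_overlap(virus, host, READ_150) == (None, "")

    def test_virus_on_right_plus_strand(self):
        host = make_hit((1, 75), "scaf", (5000, 5074), "+")
        virus = make_hit((76, 150), "circ", (200, 274), "+")
        vj, hj, side = infer_junctions(virus, host, SIZES["circ"])
        assert vj == BetweenBaseJunction("circ", 199, 200)
        assert hj == BetweenBaseJunction("scaf", 5074, 5075)
        assert side == "left_end"

    def test_junction_wraps_circle_origin(self):
        virus = make_hit((1, 60), "circ", (3941, 4000), "+")
        host = make_hit((61, 150), "scaf", (100, 189), "+")
        vj, _, side = infer_junctions(virus, host, SIZES["circ"])
        assert (vj.left_position, vj.right_position) == (4000, 1)
        assert side == "right_end"


class TestFilters:
    def test_short_virus_side_rejected(self):
        virus = make_hit((1, 19), "circ", (101, 119), "+")
        host = make_hit((25, 150), "scaf", (1000, 1125), "+")
        _, reason = call_chimeric_read("r", READ_150, [virus], [host], SIZES)
        assert reason == "too_short_side"

    def test_sum_rule_is_strictly_more_than_140(self):
        virus = make_hit((1, 60), "circ", (101, 160), "+")
        host = make_hit((81, 150), "scaf", (1000, 1069), "+")
        _, reason = call_chimeric_read("r", READ_150, [virus], [host], SIZES)
        assert reason == "sum_below_threshold"  # 60 + 70 = 130
        virus = make_hit((1, 70), "circ", (101, 170), "+")
        host = make_hit((75, 150), "scaf", (1000, 1075), "+")
        call, reason = call_chimeric_read("r", READ_150, [virus], [host], SIZES)
        assert call is not None  # 70 + 76 = 146 > 140

    def test_same_side_rejected(self):
        virus = make_hit((1, 80), "circ", (101, 180), "+")
        host = make_hit((2, 81), "scaf", (1000, 1079), "+")
        _, reason = call_chimeric_read("r", READ_150, [virus], [host], SIZES)
        assert reason == "same_side"

    def test_nested_rejected(self):
        virus = make_hit((1, 150), "circ", (101, 250), "+")
        host = make_hit((30, 140), "scaf", (1000, 1110), "+")
        _, reason = call_chimeric_read("r", READ_150, [virus], [host], SIZES)
        assert reason == "nested"

    def test_equal_score_hits_ambiguous(self):
        virus1 = make_hit((1, 75), "circ", (101, 175), "+")
        virus2 = make_hit((1, 75), "circ", (901, 975), "+")
        host = make_hit((76, 150), "scaf", (1000, 1074), "+")
        _, reason = call_chimeric_read(
            "r", READ_150, [virus1, virus2], [host], SIZES
        )
        assert reason == "ambiguous"

    def test_no_host_hit_reason(self):
        virus = make_hit((1, 75), "circ", (101, 175), "+")
        _, reason = call_chimeric_read("r", READ_150, [virus], [], SIZES)
        assert reason == "no_host_hit"

    def test_filter_matches_enumeration_oracle(self):
        """Accept/reject over exhaustive end-anchored interval pairs."""
        step = 7
        for v_end in range(20, 150, step):
            for h_start in range(2, 149, step):
                virus = make_hit((1, v_end), "circ", (101, 100 + v_end), "+")
                host = make_hit((h_start, 150), "scaf", (1000, 1150 - h_start), "+")
                call, reason = call_chimeric_read(
                    "r", READ_150, [virus], [host], SIZES
                )
                v_len = v_end
                h_len = 150 - h_start + 1
                expect_accept = (
                    v_len >= 20
                    and h_len >= 20
                    and v_len + h_len >= 141
                    and not (h_start <= 1)  # host would contain virus end
                    and not (v_end >= 150)
                )
                assert (call is not None) == expect_accept, (
                    v_end,
                    h_start,
                    reason,
                )


class TestOverlaps:
    def _chimera(self, junction_left, overlap_seq, read_id="r"):
        virus = make_hit((1, 75), "circ", (101, 175), "+", read_id=read_id)
        host = make_hit((76, 150), "scaf", (1000, 1074), "+", read_id=read_id)
        return ChimericRead(
            read_id=read_id,
            virus_hit=virus,
            host_hit=host,
            virus_junction=BetweenBaseJunction.on_circle(
                "circ", junction_left, 4000
            ),
            host_insertion=BetweenBaseJunction("scaf", 999, 1000),
            junction_side="right_end",
            overlap_interval=None,
            overlap_sequence=overlap_seq,
        )

    def test_counts_and_order(self):
        chimeras = [
            self._chimera(175, "AC"),
            self._chimera(175, "AC"),
            self._chimera(175, "AC"),
            self._chimera(175, "GG"),
        ]
        classes = tabulate_overlaps(chimeras, "circ")
        assert [c.supporting_read_count for c in classes] == [3, 1]
        assert sum(c.supporting_read_count for c in classes) == 4

    def test_matches_independent_groupby_on_fixture(self):
        rng = random.Random(3)
        chimeras = [
            self._chimera(
                rng.choice([175, 320, 990]),
                rng.choice(["", "A", "AC", "ACG"]),
                read_id=f"r{i}",
            )
            for i in range(50)
        ]
        classes = tabulate_overlaps(chimeras, "circ")
        df = pd.DataFrame(
            {
                "j": [c.virus_junction.left_position for c in chimeras],
                "o": [c.overlap_sequence for c in chimeras],
            }
        )
        oracle = df.groupby(["j", "o"]).size()
        got = {
            (c.virus_junction.left_position, c.overlap_sequence): c.supporting_read_count
            for c in classes
        }
        assert got == oracle.to_dict()
        assert sum(got.values()) == 50

    def test_rejects_foreign_circle(self):
        with pytest.raises(ValueError):
            tabulate_overlaps([self._chimera(175, "AC")], "other")


class TestPlantedOverlapRecovery:
    def test_microhomology_lengths_recovered_on_error_free_reads(self):
        """Planted k-base overlaps come back as k-length overlap sequences."""
        from ivprofiler.pipeline import profile_reads
        from ivprofiler.synthetic_data import SimulationConfig, simulate_scene

        cfg = SimulationConfig(
            seed=23,
            host_scaffold_lengths=(12_000,),
            circle_count=1,
            circle_size_range=(1_500, 1_600),
            him_circle_count=1,
            conserved_circle_count=1,
            random_circle_count=0,
            events_per_circle=4,
            episomal_coverage=10.0,
            host_coverage=12.0,
            substitution_rate=0.0,
            microhomology_weights={0: 0.2, 2: 0.4, 5: 0.4},
        )
        scene = simulate_scene(cfg)
        result = profile_reads(
            scene.circles, scene.host_scaffolds, scene.reads
        )
        truth_k = {
            (e.scaffold_id, e.host_insertion.left_position): (
                e.microhomology_length,
                e.microhomology_side,
            )
            for e in scene.events
        }
        checked = 0
        for c in result.chimeras:
            key = (c.scaffold_id, c.host_insertion.left_position)
            if key not in truth_k:
                continue
            k, side = truth_k[key]
            # the overlap appears on the junction matching the rewritten side
            expected_side = (
                "right_end" if side == "right" else "left_end"
            ) if side else None
            if side is None or c.junction_side != expected_side:
                assert len(c.overlap_sequence) == 0
            else:
                assert len(c.overlap_sequence) == k
                checked += 1
        assert checked >= 5
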