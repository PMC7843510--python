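"""Generator contracts: determinism, planting fidelity, truth completeness."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ivprofiler.core_io import (
    circular_subsequence,
    read_fasta,
    reverse_complement,
)
from ivprofiler.synthetic_data import (
    SimulationConfig,
    default_event_plan,
    generate_circle_set,
    generate_host_genome,
    simulate_integrations,
    simulate_reads,
    simulate_scene,
    write_scene,
)

CFG = dict(
    host_scaffold_lengths=(20_000,),
    circle_count=3,
    circle_size_range=(1_500, 2_500),
    him_circle_count=2,
    conserved_circle_count=1,
    random_circle_count=1,
    events_per_circle=3,
    episomal_coverage=8.0,
    host_coverage=6.0,
)


def _config(seed=3, **over):
    return SimulationConfig(seed=seed, **{**CFG, **over})


class TestConfigValidation:
    def test_zero_length_scaffold_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            _config(host_scaffold_lengths=(0,))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _config(microhomology_weights={0: 0.5, 1: 0.2})

    def test_conserved_circles_need_hims(self):
        with pytest.raises(ValueError):
            _config(him_circle_count=0, conserved_circle_count=1)


class TestHostGenome:
    def test_deterministic_given_seed(self, tmp_path):
        a = generate_host_genome(_config())
        b = generate_host_genome(_config())
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        from ivprofiler.core_io import write_fasta

        write_fasta([(s.scaffold_id, s.residues) for s in a], pa)
        write_fasta([(s.scaffold_id, s.residues) for s in b], pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_total_length_bookkeeping(self):
        scaffolds = generate_host_genome(
            _config(host_scaffold_lengths=(50_000, 50_000))
        )
        assert sum(s.length for s in scaffolds) == 100_000

    def test_gc_fraction_binomial_bound(self):
        (s,) = generate_host_genome(_config(host_scaffold_lengths=(100_000,)))
        gc = sum(c in "GC" for c in s.residues) / s.length
        # 0.5 +/- > 12 sd for n = 1e5 — fails only on a broken generator
        assert 0.48 <= gc <= 0.52


class TestCircleSet:
    def test_planted_repeats_and_coordinates_match_spec(self):
        circles, specs = generate_circle_set(_config())
        assert len(specs) == 2
        for cid, spec in specs.items():
            circle = next(c for c in circles if c.circle_id == cid)
            u = spec.upstream_junction.left_position
            d = spec.downstream_junction.left_position
            assert d - u == spec.deletion_length
            # direct string-search oracle against the planted coordinates
            seq = circle.residues
            assert seq[spec.inner_left_start - 1 :].startswith(spec.inner_repeat)
            assert seq[spec.outer_left_start - 1 :].startswith(spec.outer_repeat)
            assert seq[spec.outer_right_start - 1 :].startswith(
                reverse_complement(spec.outer_repeat)
            )
            assert seq[spec.inner_right_start - 1 :].startswith(
                reverse_complement(spec.inner_repeat)
            )
            assert spec.inner_left_start == u - 5
            assert spec.outer_left_start == u + 1
            assert spec.inner_right_start == d + 1
            assert 32 <= spec.deletion_length <= 311

    def test_downstream_border_is_reverse_complement_of_outer(self):
        circles, specs = generate_circle_set(_config())
        for cid, spec in specs.items():
            circle = next(c for c in circles if c.circle_id == cid)
            down = circular_subsequence(
                circle, spec.outer_right_start, len(spec.outer_repeat)
            )
            assert down == reverse_complement(spec.outer_repeat)

    def test_non_him_circle_has_no_spec(self):
        circles, specs = generate_circle_set(_config())
        assert "circle_03" not in specs

    def test_oversized_repeat_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            generate_circle_set(
                _config(outer_repeat_length=40, deletion_range=(32, 60))
            )


class TestIntegrations:
    def test_zero_events_leaves_host_untouched(self):
        cfg = _config()
        host = generate_host_genome(cfg)
        circles, specs = generate_circle_set(cfg)
        mosaic = simulate_integrations(host, circles, specs, cfg, event_plan=[])
        assert [s.residues for s in mosaic.mosaic_scaffolds] == [
            s.residues for s in host
        ]
        assert mosaic.events == []

    def test_conserved_arc_length_excludes_deletion(self):
        cfg = _config()
        host = generate_host_genome(cfg)
        circles, specs = generate_circle_set(cfg)
        mosaic = simulate_integrations(
            host, circles, specs, cfg, event_plan=[("circle_01", "conserved")]
        )
        (event,) = mosaic.events
        spec = specs["circle_01"]
        circle = circles[0]
        grown = sum(s.length for s in mosaic.mosaic_scaffolds) - sum(
            s.length for s in mosaic.host_scaffolds
        )
        assert grown == circle.size - spec.deletion_length - event.microhomology_length

    def test_conserved_without_him_rejected(self):
        cfg = _config()
        host = generate_host_genome(cfg)
        circles, specs = generate_circle_set(cfg)
        with pytest.raises(ValueError, match="no HIM"):
            simulate_integrations(
                host, circles, specs, cfg, event_plan=[("circle_03", "conserved")]
            )

    def test_truth_set_matches_mosaic_boundaries(self):
        """Every virus-host boundary in the mosaic has exactly one truth
        record and the planted microhomology is present verbatim."""
        cfg = _config(seed=9)
        host = generate_host_genome(cfg)
        circles, specs = generate_circle_set(cfg)
        plan = default_event_plan(cfg, circles)
        mosaic = simulate_integrations(host, circles, specs, cfg, plan)
        by_id = {c.circle_id: c for c in circles}
        host_ref = {s.scaffold_id: s.residues for s in mosaic.host_scaffolds}
        mosaic_seq = {s.scaffold_id: s.residues for s in mosaic.mosaic_scaffolds}
        assert len(mosaic.events) == len(plan)
        for e in mosaic.events:
            circle = by_id[e.circle_id]
            if e.mode == "conserved":
                spec = specs[e.circle_id]
                arc_start = spec.downstream_junction.left_position % circle.size + 1
                arc_len = circle.size - spec.deletion_length
            else:
                arc_start = e.circle_break.left_position % circle.size + 1
                arc_len = circle.size
            arc = circular_subsequence(circle, arc_start, arc_len)
            p0 = e.host_insertion.left_position
            k = e.microhomology_length
            ref = host_ref[e.scaffold_id]
            # the arc, flanked by host sequence, occurs in the mosaic
            k_l = k if e.microhomology_side == "left" else 0
            k_r = k if e.microhomology_side == "right" else 0
            context = (
                ref[p0 - k_l - 10 : p0 - k_l] + arc + ref[p0 + k_r : p0 + k_r + 10]
            )
            assert context in mosaic_seq[e.scaffold_id]
            if k and e.microhomology_side == "right":
                assert ref[p0 : p0 + k] == arc[-k:]
            if k and e.microhomology_side == "left":
                assert ref[p0 - k : p0] == arc[:k]

    def test_conserved_events_share_one_junction_pair(self):
        cfg = _config(events_per_circle=4)
        scene = simulate_scene(cfg)
        conserved = [e for e in scene.events if e.mode == "conserved"]
        assert len({e.circle_break for e in conserved}) == 1
        random_breaks = [
            e.circle_break for e in scene.events if e.mode == "random"
        ]
        assert len(set(random_breaks)) >= len(random_breaks) - 1


class TestReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = _config(substitution_rate=0.0)
        scene = simulate_scene(cfg)
        texts = {
            s.scaffold_id: s.residues for s in scene.mosaic_scaffolds
        } | {c.circle_id: c.residues + c.residues for c in scene.circles}
        for read, origin in list(zip(scene.reads, scene.origins))[:200]:
            frag = texts[origin.template_id][origin.start : origin.end]
            if origin.strand == "-":
                frag = reverse_complement(frag)
            assert read.residues == frag

    def test_expected_pair_count_arithmetic(self):
        cfg = _config(substitution_rate=0.0)
        host = generate_host_genome(cfg)
        reads, origins = simulate_reads(host, [], cfg)
        expected_pairs = round(20_000 * cfg.host_coverage / (2 * 150))
        assert len(reads) == 2 * expected_pairs
        assert len(origins) == len(reads)

    def test_zero_coverage_gives_empty_set(self):
        cfg = _config(host_coverage=0.0)
        host = generate_host_genome(cfg)
        reads, _ = simulate_reads(host, [], cfg)
        assert reads == []

    def test_substitution_rate_within_binomial_bound(self):
        cfg = _config(substitution_rate=0.01, host_coverage=8.0)
        host = generate_host_genome(cfg)
        reads, origins = simulate_reads(host, [], cfg)
        text = host[0].residues
        mismatches = bases = 0
        for read, origin in zip(reads, origins):
            frag = text[origin.start : origin.end]
            if origin.strand == "-":
                frag = reverse_complement(frag)
            mismatches += sum(a != b for a, b in zip(read.residues, frag))
            bases += read.length
        assert bases >= 1e5
        rate = mismatches / bases
        sd = math.sqrt(0.01 * 0.99 / bases)
        assert abs(rate - 0.01) < 3 * sd


class TestSceneOutputs:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for name in ("a", "b"):
            write_scene(simulate_scene(_config(seed=21)), tmp_path / name)
        for fname in (
            "host.fasta",
            "circles.fasta",
            "mosaic.fasta",
            "reads_R1.fastq",
            "reads_R2.fastq",
            "truth_events.tsv",
            "truth.json",
        ):
            assert (tmp_path / "a" / fname).read_bytes() == (
                tmp_path / "b" / fname
            ).read_bytes()

    def test_written_files_parse_back(self, tmp_path):
        scene = simulate_scene(_config(seed=5))
        paths = write_scene(scene, tmp_path / "scene")
        assert len(read_fasta(paths["circles"])) == 3
        host = read_fasta(paths["host"])
        assert [h[0] for h in host] == ["scaffold_001"]
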