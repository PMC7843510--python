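"""Synthetic parasitized-genome scenes with machine-readable truth.

Generates, deterministically from a seed: a host genome of random
scaffolds; a set of viral circles, some carrying a planted host
integration motif (HIM); a mosaic "parasitized" genome holding episomal
and integrated circle copies; 150 bp paired-end reads with substitution
errors; and the truth records every downstream stage is scored against.

Planted HIM layout (1-based circle coordinates, junctions ``u–u+1`` and
``d–d+1``, deletion ``d−u``)::

    ... [inner 6nt] | u | [outer 11nt] ... core ... [rc(outer)] [spacer 3nt] | d | [rc(inner)] ...
        retained arc              excised on conserved integration             retained arc

The outer reverse-complementary pair sits just inside the excised
segment, the inner pair just outside it on the retained arc; a 3 nt
spacer before the downstream junction plus resampled neighbour bases
keep each planted pair exactly maximal.  This layout supports the full
32–311 nt deletion range (two 11+6 pairs cannot both fit inside a 32 nt
deletion).

Conserved integrations linearise at the HIM junction pair and excise the
internal segment; random integrations linearise the full circle at a
uniform position with no deletion (an assumption — whether random breaks
also delete sequence is unobserved).  Breakpoint microhomology of k bases
is created by rewriting k host bases at one flank of the insertion point
to equal the arc's terminal k bases; the rewritten scaffolds are the
emitted host reference, so the overlap is recoverable by mapping and all
truth coordinates stay valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    BetweenBaseJunction,
    CircularSequence,
    GenomeScaffold,
    SequencingRead,
    circular_subsequence,
    reverse_complement,
    write_fasta,
    write_fastq,
)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: default microhomology length distribution (weights over 0..10 nt)
DEFAULT_MICROHOMOLOGY_WEIGHTS: dict[int, float] = {
    0: 0.25,
    1: 0.15,
    2: 0.15,
    3: 0.12,
    4: 0.10,
    5: 0.08,
    6: 0.06,
    7: 0.04,
    8: 0.03,
    9: 0.01,
    10: 0.01,
}


@dataclass(frozen=True)
class HimSpec:
    """Truth record of a planted HIM."""

    circle_id: str
    upstream_junction: BetweenBaseJunction
    downstream_junction: BetweenBaseJunction
    deletion_length: int
    outer_repeat: str
    inner_repeat: str
    # 1-based starts of the four planted repeat copies on the circle
    inner_left_start: int = 0
    outer_left_start: int = 0
    outer_right_start: int = 0
    inner_right_start: int = 0

    def __post_init__(self) -> None:
        if len(self.outer_repeat) < 5 or len(self.inner_repeat) < 5:
            raise ValueError("repeat lengths must be >= 5")


@dataclass(frozen=True)
class IntegrationEventTruth:
    circle_id: str
    mode: str  # 'conserved' | 'random'
    circle_break: BetweenBaseJunction
    excised_interval: tuple[int, int] | None
    scaffold_id: str
    host_insertion: BetweenBaseJunction
    microhomology_length: int
    microhomology_side: str | None  # 'left' | 'right' | None
    # junction supported by reads anchoring each end of the integrated arc
    left_end_junction: BetweenBaseJunction = None  # type: ignore[assignment]
    right_end_junction: BetweenBaseJunction = None  # type: ignore[assignment]


@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    mate: int
    template_id: str
    template_kind: str  # 'mosaic' | 'episome'
    start: int  # 0-based on the template
    end: int
    strand: str


@dataclass
class SimulationConfig:
    """All knobs of one synthetic scene; ``seed`` is mandatory.

    Defaults describe the standard test scene: 5 × 50 kb host scaffolds,
    8 circles of 3–6 kb of which 3 carry HIMs, 2 conserved and 3 random
    integrated circles with 5 events each, 30× episomal circle coverage,
    15× host coverage, 150 bp paired reads at 0.1% substitution error.
    """

    seed: int
    host_scaffold_lengths: tuple[int, ...] = (50_000,) * 5
    circle_count: int = 8
    circle_size_range: tuple[int, int] = (3_000, 6_000)
    him_circle_count: int = 3
    conserved_circle_count: int = 2
    random_circle_count: int = 3
    events_per_circle: int = 5
    deletion_range: tuple[int, int] = (32, 311)
    outer_repeat_length: int = 11
    inner_repeat_length: int = 6
    episomal_coverage: float = 30.0
    host_coverage: float = 15.0
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    substitution_rate: float = 0.001
    microhomology_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MICROHOMOLOGY_WEIGHTS)
    )
    min_event_spacing: int = 600
    host_edge_margin: int = 300

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.host_scaffold_lengths):
            raise ValueError("zero-length scaffold requested")
        if self.circle_size_range[0] < 1_000:
            raise ValueError("circle sizes must be >= 1 kb")
        if self.him_circle_count > self.circle_count:
            raise ValueError("more HIM circles than circles")
        if self.conserved_circle_count > self.him_circle_count:
            raise ValueError("conserved circles must carry a HIM")
        if (
            self.conserved_circle_count + self.random_circle_count
            > self.circle_count
        ):
            raise ValueError("more integrated circles than circles")
        total = sum(self.microhomology_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(
                f"microhomology weights must sum to 1, got {total}"
            )
        if min(self.microhomology_weights) < 0 or any(
            w < 0 for w in self.microhomology_weights.values()
        ):
            raise ValueError("negative microhomology weight")
        for name in ("events_per_circle", "read_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def generate_host_genome(config: SimulationConfig) -> list[GenomeScaffold]:
    """I.i.d. uniform A/C/G/T scaffolds of the configured lengths."""
    rng = _rng(config, 0)
    return [
        GenomeScaffold(f"scaffold_{i + 1:03d}", _random_seq(rng, length))
        for i, length in enumerate(config.host_scaffold_lengths)
    ]


_HARDEN_HORIZON = 18


def _harden_walk(
    rng: np.random.Generator,
    chars: list[str],
    start_idx: int,
    step: int,
    partners_a: list[str | None],
    partners_b: list[str | None],
    cum_b0: int,
) -> None:
    """Resample host bases so junction-crossing extensions never score > 0.

    Walks outward from a junction comparing each host base with up to two
    extension partners (the circle continuation for the virus hit, the arc
    continuation for the other junction's host hit) under match +1 /
    mismatch -2 scoring; whenever a match would lift a running score to
    >= 0 the base is resampled to mismatch both partners.
    """
    cum_a, cum_b = 0, cum_b0
    for i, (pa, pb) in enumerate(zip(partners_a, partners_b)):
        idx = start_idx + step * i
        if idx < 0 or idx >= len(chars):
            break
        base = chars[idx]
        need = (pa is not None and base == pa and cum_a + 1 >= 0) or (
            pb is not None and base == pb and cum_b + 1 >= 0
        )
        if need:
            avoid = {x for x in (pa, pb) if x is not None}
            choices = [b for b in "ACGT" if b not in avoid]
            base = choices[rng.integers(0, len(choices))]
            chars[idx] = base
        cum_a += 1 if base == pa else -2
        cum_b += 1 if base == pb else -2
        if cum_a < -40 and cum_b < -40:
            break


def _harden_junction_flanks(
    rng: np.random.Generator,
    chars: list[str],
    p0: int,
    k_left: int,
    k_right: int,
    arc: str,
    circle: CircularSequence,
    arc_start_pos: int,
    arc_end_pos: int,
    horizon: int = _HARDEN_HORIZON,
) -> None:
    size = circle.size

    def circ_base(pos1: int) -> str:
        return circular_subsequence(circle, (pos1 - 1) % size + 1, 1)

    def arc_base(idx: int) -> str | None:
        return arc[idx] if -len(arc) <= idx < len(arc) else None

    # right of the cut: virus forward extension at the right junction vs
    # the circle past the arc end; host-hit right extension at the left
    # junction vs the arc continuation (offset past any rewritten stretch)
    partners_a = [circ_base(arc_end_pos + 1 + i) for i in range(horizon)]
    partners_b = [arc_base(k_left + k_right + i) for i in range(horizon)]
    cum_b0 = 0
    for j in range(k_right):  # fixed rewritten prefix, not resampleable
        cum_b0 += 1 if arc[-k_right + j] == arc_base(k_left + j) else -2
    _harden_walk(rng, chars, p0 + k_right, 1, partners_a, partners_b, cum_b0)

    # left of the cut: virus backward extension at the left junction vs
    # the circle before the arc start; host-hit left extension at the
    # right junction vs the arc read backwards from its right end
    partners_a = [circ_base(arc_start_pos - 1 - i) for i in range(horizon)]
    partners_b = [
        arc_base(-(k_right + k_left + 1 + i)) for i in range(horizon)
    ]
    cum_b0 = 0
    for j in range(k_left):
        cum_b0 += (
            1 if arc[k_left - 1 - j] == arc_base(-(k_right + 1 + j)) else -2
        )
    _harden_walk(
        rng, chars, p0 - k_left - 1, -1, partners_a, partners_b, cum_b0
    )


def _resample_not_complement(
    rng: np.random.Generator, partner: str
) -> str:
    """A base whose pairing with ``partner`` cannot extend a revcomp match."""
    choices = [b for b in "ACGT" if b != _COMP[partner]]
    return choices[rng.integers(0, len(choices))]


def generate_circle_set(
    config: SimulationConfig,
) -> tuple[list[CircularSequence], dict[str, HimSpec]]:
    """Random circles, the first ``him_circle_count`` with a planted HIM."""
    rng = _rng(config, 1)
    spacer_len = 3
    olen, ilen = config.outer_repeat_length, config.inner_repeat_length
    d_lo, d_hi = config.deletion_range
    if 2 * olen + spacer_len > d_lo:
        d_lo_eff = 2 * olen + spacer_len
        if d_lo_eff > d_hi:
            raise ValueError(
                f"outer repeat of {olen} nt does not fit any deletion "
                f"window in {config.deletion_range}"
            )
    else:
        d_lo_eff = d_lo
    circles: list[CircularSequence] = []
    specs: dict[str, HimSpec] = {}
    for i in range(config.circle_count):
        cid = f"circle_{i + 1:02d}"
        size = int(
            rng.integers(config.circle_size_range[0], config.circle_size_range[1] + 1)
        )
        seq = list(_random_seq(rng, size))
        if i < config.him_circle_count:
            deletion = int(rng.integers(d_lo_eff, d_hi + 1))
            # keep the planted region away from the origin; wrap handling is
            # exercised by coordinate arithmetic, not by planting across it
            u = int(rng.integers(ilen + 50, size - deletion - ilen - 50))
            d = u + deletion
            outer = _random_seq(rng, olen)
            inner = _random_seq(rng, ilen)
            seq[u - ilen : u] = inner  # 1-based [u-ilen+1, u]
            seq[u : u + olen] = outer  # 1-based [u+1, u+olen]
            seq[d - spacer_len - olen : d - spacer_len] = reverse_complement(
                outer
            )
            seq[d : d + ilen] = reverse_complement(inner)
            spacer = list(_random_seq(rng, spacer_len))
            # neighbour constraints keep planted pairs exactly maximal
            if _COMP[spacer[-1]] == outer[0]:
                spacer[-1] = _resample_not_complement(rng, outer[0])
            if _COMP[spacer[0]] == inner[-1]:
                spacer[0] = _resample_not_complement(rng, inner[-1])
            seq[d - spacer_len : d] = spacer
            if _COMP[seq[d + ilen]] == seq[u - ilen - 1]:
                seq[u - ilen - 1] = _resample_not_complement(rng, seq[d + ilen])
            if _COMP[seq[d - spacer_len - olen - 1]] == seq[u + olen]:
                seq[u + olen] = _resample_not_complement(
                    rng, seq[d - spacer_len - olen - 1]
                )
            circle = CircularSequence(cid, "".join(seq))
            specs[cid] = HimSpec(
                circle_id=cid,
                upstream_junction=BetweenBaseJunction(cid, u, u + 1),
                downstream_junction=BetweenBaseJunction(cid, d, d + 1),
                deletion_length=deletion,
                outer_repeat=outer,
                inner_repeat=inner,
                inner_left_start=u - ilen + 1,
                outer_left_start=u + 1,
                outer_right_start=d - spacer_len - olen + 1,
                inner_right_start=d + 1,
            )
        else:
            circle = CircularSequence(cid, "".join(seq))
        circles.append(circle)
    return circles, specs


@dataclass
class MosaicGenome:
    host_scaffolds: list[GenomeScaffold]  # reference (microhomology rewrites applied)
    mosaic_scaffolds: list[GenomeScaffold]
    events: list[IntegrationEventTruth]


def default_event_plan(
    config: SimulationConfig, circles: Sequence[CircularSequence]
) -> list[tuple[str, str]]:
    """(circle_id, mode) with one entry per integration event."""
    plan: list[tuple[str, str]] = []
    conserved = [c.circle_id for c in circles[: config.conserved_circle_count]]
    non_him = [c.circle_id for c in circles[config.him_circle_count :]]
    random_ids = non_him[: config.random_circle_count]
    for cid in conserved:
        plan += [(cid, "conserved")] * config.events_per_circle
    for cid in random_ids:
        plan += [(cid, "random")] * config.events_per_circle
    return plan


def simulate_integrations(
    host_scaffolds: Sequence[GenomeScaffold],
    circles: Sequence[CircularSequence],
    him_specs: Mapping[str, HimSpec],
    config: SimulationConfig,
    event_plan: Sequence[tuple[str, str]] | None = None,
) -> MosaicGenome:
    """Insert circle copies into the host, returning mosaic + truth.

    Conserved events linearise at the circle's HIM junction pair and
    excise the internal segment; random events linearise the whole circle
    at a uniform position.  Insertion points are uniform over scaffolds
    (length-weighted), kept ``min_event_spacing`` apart.
    """
    rng = _rng(config, 2)
    if event_plan is None:
        event_plan = default_event_plan(config, circles)
    by_id = {c.circle_id: c for c in circles}
    host_chars = {s.scaffold_id: list(s.residues) for s in host_scaffolds}
    lengths = np.array([s.length for s in host_scaffolds], dtype=float)
    probs = lengths / lengths.sum()
    used: dict[str, list[int]] = {s.scaffold_id: [] for s in host_scaffolds}
    mh_lengths = np.array(sorted(config.microhomology_weights))
    mh_weights = np.array(
        [config.microhomology_weights[k] for k in mh_lengths]
    )

    events: list[IntegrationEventTruth] = []
    # (scaffold_id, cut_lo, cut_hi, arc)
    insertions: dict[str, list[tuple[int, int, str]]] = {
        s.scaffold_id: [] for s in host_scaffolds
    }
    for circle_id, mode in event_plan:
        circle = by_id[circle_id]
        size = circle.size
        if mode == "conserved":
            spec = him_specs.get(circle_id)
            if spec is None:
                raise ValueError(
                    f"conserved integration requested for {circle_id} "
                    "which has no HIM"
                )
            u = spec.upstream_junction.left_position
            d = spec.downstream_junction.left_position
            arc = circular_subsequence(
                circle, d % size + 1, size - spec.deletion_length
            )
            circle_break = spec.upstream_junction
            excised: tuple[int, int] | None = (u + 1, d)
            left_j = spec.downstream_junction
            right_j = spec.upstream_junction
        elif mode == "random":
            b = int(rng.integers(1, size + 1))
            arc = circular_subsequence(circle, b % size + 1, size)
            circle_break = BetweenBaseJunction.on_circle(circle_id, b, size)
            excised = None
            left_j = right_j = circle_break
        else:
            raise ValueError(f"unknown integration mode {mode!r}")

        # pick an insertion point respecting spacing
        for _ in range(1000):
            si = int(rng.choice(len(host_scaffolds), p=probs))
            sid = host_scaffolds[si].scaffold_id
            length = host_scaffolds[si].length
            p0 = int(
                rng.integers(
                    config.host_edge_margin, length - config.host_edge_margin
                )
            )
            if all(
                abs(p0 - q) >= config.min_event_spacing for q in used[sid]
            ):
                break
        else:  # pragma: no cover - config pathology
            raise RuntimeError("could not place events with required spacing")
        used[sid].append(p0)

        k = int(rng.choice(mh_lengths, p=mh_weights))
        side = None
        cut_lo, cut_hi = p0, p0
        chars = host_chars[sid]
        k_left = k_right = 0
        if k > 0:
            side = "left" if rng.random() < 0.5 else "right"
            # a rewrite whose terminal base coincides with the opposite arc
            # terminus would plant an unintended 1-base overlap at the other
            # junction; prefer the side where that cannot happen
            left_contaminates = arc[k - 1] == arc[-1]
            right_contaminates = arc[-k] == arc[0]
            if side == "left" and left_contaminates and not right_contaminates:
                side = "right"
            elif side == "right" and right_contaminates and not left_contaminates:
                side = "left"
            if side == "right":
                k_right = k
                chars[p0 : p0 + k] = arc[-k:]
                cut_hi = p0 + k
            else:
                k_left = k
                chars[p0 - k : p0] = arc[:k]
                cut_lo = p0 - k
        # The planted microhomology length must be exact, not a lower
        # bound: coincidental identities between host flanks and the
        # circle (or arc) continuation would let a +1/-2 local alignment
        # extend past the junction and blur the truth coordinates.
        # Resample flank bases so every such extension scores <= -1.
        arc_end_pos = circle_break.left_position  # 1-based, both modes
        arc_start_pos = (
            (excised[1] if excised else circle_break.left_position) % size + 1
        )
        _harden_junction_flanks(
            rng, chars, p0, k_left, k_right, arc, circle,
            arc_start_pos, arc_end_pos,
        )
        insertions[sid].append((cut_lo, cut_hi, arc))
        events.append(
            IntegrationEventTruth(
                circle_id=circle_id,
                mode=mode,
                circle_break=circle_break,
                excised_interval=excised,
                scaffold_id=sid,
                host_insertion=BetweenBaseJunction(sid, p0, p0 + 1),
                microhomology_length=k,
                microhomology_side=side,
                left_end_junction=left_j,
                right_end_junction=right_j,
            )
        )

    new_host = [
        GenomeScaffold(s.scaffold_id, "".join(host_chars[s.scaffold_id]))
        for s in host_scaffolds
    ]
    mosaic: list[GenomeScaffold] = []
    for s in new_host:
        cuts = sorted(insertions[s.scaffold_id])
        pieces: list[str] = []
        prev = 0
        for cut_lo, cut_hi, arc in cuts:
            pieces.append(s.residues[prev:cut_lo])
            pieces.append(arc)
            prev = cut_hi
        pieces.append(s.residues[prev:])
        mosaic.append(GenomeScaffold(s.scaffold_id, "".join(pieces)))
    return MosaicGenome(
        host_scaffolds=new_host, mosaic_scaffolds=mosaic, events=events
    )


def simulate_reads(
    mosaic_scaffolds: Sequence[GenomeScaffold],
    episomal_circles: Sequence[CircularSequence],
    config: SimulationConfig,
) -> tuple[list[SequencingRead], list[ReadOrigin]]:
    """Paired 150 bp reads over the mosaic genome and episomal circles.

    Fragment starts are uniform (circles sampled with wraparound); insert
    sizes are normal; substitution errors are applied per base at the
    configured rate.  Expected pair count per template is
    ``round(L × coverage / (2 × read_length))``.
    """
    rng = _rng(config, 3)
    rl = config.read_length
    reads: list[SequencingRead] = []
    origins: list[ReadOrigin] = []
    counter = 0

    templates: list[tuple[str, str, str, float]] = [
        (s.scaffold_id, s.residues, "mosaic", config.host_coverage)
        for s in mosaic_scaffolds
    ] + [
        (c.circle_id, c.residues, "episome", config.episomal_coverage)
        for c in episomal_circles
    ]
    for tid, seq, kind, coverage in templates:
        length = len(seq)
        circular = kind == "episome"
        if rl > length:
            raise ValueError(
                f"read length {rl} exceeds template {tid} ({length})"
            )
        n_pairs = round(length * coverage / (2 * rl))
        text = seq + seq if circular else seq
        for _ in range(n_pairs):
            insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            insert = max(rl, min(insert, length))
            start = int(
                rng.integers(0, length if circular else length - insert + 1)
            )
            frag = text[start : start + insert]
            fwd = frag[:rl]
            rev = reverse_complement(frag[-rl:])
            counter += 1
            rid = f"sim{counter:07d}"
            flip = bool(rng.random() < 0.5)
            mates = [
                (1, rev if flip else fwd),
                (2, fwd if flip else rev),
            ]
            for mate, mseq in mates:
                mseq = _apply_errors(rng, mseq, config.substitution_rate)
                reads.append(SequencingRead(rid, mate, mseq))
                is_fwd = (mate == 1) != flip
                origins.append(
                    ReadOrigin(
                        read_id=rid,
                        mate=mate,
                        template_id=tid,
                        template_kind=kind,
                        start=start if is_fwd else start + insert - rl,
                        end=start + rl if is_fwd else start + insert,
                        strand="+" if is_fwd else "-",
                    )
                )
    return reads, origins


def _apply_errors(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


@dataclass
class SyntheticScene:
    """Everything one simulated experiment produced, truth included."""

    config: SimulationConfig
    host_scaffolds: list[GenomeScaffold]
    circles: list[CircularSequence]
    him_specs: dict[str, HimSpec]
    mosaic_scaffolds: list[GenomeScaffold]
    events: list[IntegrationEventTruth]
    reads: list[SequencingRead]
    origins: list[ReadOrigin]

    @property
    def integrated_circle_ids(self) -> set[str]:
        return {e.circle_id for e in self.events}


def simulate_scene(
    config: SimulationConfig,
    event_plan: Sequence[tuple[str, str]] | None = None,
) -> SyntheticScene:
    """Run the full generator: host → circles → integrations → reads."""
    host = generate_host_genome(config)
    circles, specs = generate_circle_set(config)
    mosaic = simulate_integrations(host, circles, specs, config, event_plan)
    reads, origins = simulate_reads(
        mosaic.mosaic_scaffolds, circles, config
    )
    return SyntheticScene(
        config=config,
        host_scaffolds=mosaic.host_scaffolds,
        circles=circles,
        him_specs=specs,
        mosaic_scaffolds=mosaic.mosaic_scaffolds,
        events=mosaic.events,
        reads=reads,
        origins=origins,
    )


def write_scene(scene: SyntheticScene, outdir: str | Path) -> dict[str, Path]:
    """Write a scene to disk: FASTA/FASTQ inputs plus truth TSV and JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "host": outdir / "host.fasta",
        "circles": outdir / "circles.fasta",
        "mosaic": outdir / "mosaic.fasta",
        "reads_1": outdir / "reads_R1.fastq",
        "reads_2": outdir / "reads_R2.fastq",
        "truth_tsv": outdir / "truth_events.tsv",
        "truth_json": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    write_fasta(
        [(s.scaffold_id, s.residues) for s in scene.host_scaffolds],
        paths["host"],
    )
    write_fasta(
        [(c.circle_id, c.residues) for c in scene.circles], paths["circles"]
    )
    write_fasta(
        [(s.scaffold_id, s.residues) for s in scene.mosaic_scaffolds],
        paths["mosaic"],
    )
    write_fastq([r for r in scene.reads if r.mate == 1], paths["reads_1"])
    write_fastq([r for r in scene.reads if r.mate == 2], paths["reads_2"])

    lines = [
        "circle_id\tmode\tcircle_break\texcised\tscaffold_id\t"
        "host_insertion\tmicrohomology"
    ]
    for e in scene.events:
        excised = (
            f"{e.excised_interval[0]}..{e.excised_interval[1]}"
            if e.excised_interval
            else "."
        )
        lines.append(
            f"{e.circle_id}\t{e.mode}\t"
            f"{e.circle_break.left_position}-{e.circle_break.right_position}\t"
            f"{excised}\t{e.scaffold_id}\t"
            f"{e.host_insertion.left_position}-"
            f"{e.host_insertion.right_position}\t{e.microhomology_length}"
        )
    paths["truth_tsv"].write_text("\n".join(lines) + "\n")

    def _junction(j: BetweenBaseJunction | None):
        if j is None:
            return None
        return {
            "target_id": j.target_id,
            "left": j.left_position,
            "right": j.right_position,
        }

    truth = {
        "him_specs": [
            {
                "circle_id": s.circle_id,
                "upstream": _junction(s.upstream_junction),
                "downstream": _junction(s.downstream_junction),
                "deletion_length": s.deletion_length,
                "outer_repeat": s.outer_repeat,
                "inner_repeat": s.inner_repeat,
            }
            for s in scene.him_specs.values()
        ],
        "events": [
            {
                "circle_id": e.circle_id,
                "mode": e.mode,
                "circle_break": _junction(e.circle_break),
                "excised_interval": e.excised_interval,
                "scaffold_id": e.scaffold_id,
                "host_insertion": _junction(e.host_insertion),
                "microhomology_length": e.microhomology_length,
                "microhomology_side": e.microhomology_side,
            }
            for e in scene.events
        ],
    }
    paths["truth_json"].write_text(json.dumps(truth, indent=1))
    cfg = asdict(scene.config)
    cfg["host_scaffold_lengths"] = list(cfg["host_scaffold_lengths"])
    paths["config"].write_text(json.dumps(cfg, indent=1, default=str))
    return paths
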