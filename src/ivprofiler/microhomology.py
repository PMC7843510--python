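"""Permutation test for microhomology enrichment at integration breakpoints.

An explicitly optional extra beyond the core profiling: the observed mean
breakpoint-overlap length across accepted chimeric reads is compared with
a null distribution obtained by re-drawing each read's host insertion
point uniformly over the host genome and recomputing how far the virus
side's junction-adjacent bases happen to match the host flank there.
One-sided: enrichment means the observed mean exceeds the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chimera_detection import ChimericRead
from .core_io import GenomeScaffold


@dataclass(frozen=True)
class EnrichmentResult:
    observed_mean_overlap: float
    null_mean_overlap: float
    p_value: float
    n_reads: int
    n_permutations: int


def _virus_end_bases(chimera: ChimericRead, read_bases: str, k: int = 10) -> str:
    """The k read bases at the virus hit's junction-facing end, oriented
    so index 0 is the base adjacent to the junction moving away from it."""
    v = chimera.virus_hit.read_interval
    h = chimera.host_hit.read_interval
    if v[0] <= h[0]:  # virus left: junction faces right
        seg = read_bases[max(0, v[1] - k) : v[1]]
        return seg[::-1]
    seg = read_bases[v[0] - 1 : v[0] - 1 + k]
    return seg


def microhomology_enrichment(
    chimeras: Sequence[ChimericRead],
    read_sequences: dict[str, str],
    host_scaffolds: Sequence[GenomeScaffold],
    n_permutations: int = 10_000,
    max_overlap: int = 10,
    seed: int = 0,
) -> EnrichmentResult:
    """One-sided permutation test of mean breakpoint-overlap length.

    ``read_sequences`` maps the chimeras' read ids to their residues.
    """
    if not chimeras:
        raise ValueError("no chimeric reads")
    rng = np.random.default_rng(seed)
    observed = float(
        np.mean([len(c.overlap_sequence) for c in chimeras])
    )
    ends = []
    for c in chimeras:
        seq = read_sequences[c.read_id]
        ends.append(_virus_end_bases(c, seq, k=max_overlap))
    texts = [s.residues for s in host_scaffolds]
    lengths = np.array([len(t) for t in texts], dtype=float)
    probs = lengths / lengths.sum()

    null_means = np.empty(n_permutations)
    n = len(ends)
    for p in range(n_permutations):
        total = 0
        scaf_idx = rng.choice(len(texts), size=n, p=probs)
        for end, si in zip(ends, scaf_idx):
            text = texts[si]
            pos = rng.integers(0, len(text) - max_overlap)
            # walk outward from the random insertion point; a match means
            # the base could be attributed to either source
            strand_seg = text[pos : pos + max_overlap]
            m = 0
            for a, b in zip(end, strand_seg):
                if a == b:
                    m += 1
                else:
                    break
            total += m
        null_means[p] = total / n
    p_value = float((np.sum(null_means >= observed) + 1) / (n_permutations + 1))
    return EnrichmentResult(
        observed_mean_overlap=observed,
        null_mean_overlap=float(null_means.mean()),
        p_value=p_value,
        n_reads=n,
        n_permutations=n_permutations,
    )
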