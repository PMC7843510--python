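#!/usr/bin/env python
"""Step 3 — HIM structure of conserved-broken circles and cross-virus scan.

From the conserved-broken circles found in step 2, re-derives each HIM
model (junction pair, deletion length, reverse-complementary boundary
repeat pairs) directly from the circle sequences, then scans the whole
circle set for homologous motifs (identity > 80%, aligned length > 15,
E < 10) the way candidate HIMs are predicted in other virus segment
sets.  Writes junction/repeat and candidate tables under results/him/.
"""

import argparse
from pathlib import Path

import pandas as pd

from ivprofiler.core_io import BetweenBaseJunction, CircularSequence, read_fasta
from ivprofiler.him_discovery import (
    build_him_model,
    cross_virus_rows,
    him_rows,
    predict_him_cross_virus,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scene", type=Path, default=Path("results/scene"))
    parser.add_argument("--profile", type=Path, default=Path("results/profile"))
    parser.add_argument("--out", type=Path, default=Path("results/him"))
    args = parser.parse_args()

    circles = {
        n: CircularSequence(n, s)
        for n, s in read_fasta(args.scene / "circles.fasta")
    }
    him_table = pd.read_csv(args.profile / "him_models.tsv", sep="\t")
    models = []
    for _, row in him_table.iterrows():
        circle = circles[row["circle_id"]]
        up = int(str(row["upstream"]).split("-")[0])
        down = int(str(row["downstream"]).split("-")[0])
        models.append(
            build_him_model(
                circle,
                BetweenBaseJunction.on_circle(circle.circle_id, up, circle.size),
                BetweenBaseJunction.on_circle(circle.circle_id, down, circle.size),
            )
        )
    hits = predict_him_cross_virus(models, list(circles.values()))

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(him_rows(models)).to_csv(
        args.out / "him_models.tsv", sep="\t", index=False
    )
    pd.DataFrame(cross_virus_rows(hits)).to_csv(
        args.out / "him_candidates.tsv", sep="\t", index=False
    )
    for m in models:
        pairs = ", ".join(
            f"{p.left_seq}/{p.right_seq} ({p.length} nt)"
            for p in m.repeat_pairs[:2]
        )
        print(
            f"{m.circle_id}: junctions "
            f"{m.upstream_junction.left_position}-"
            f"{m.upstream_junction.right_position} / "
            f"{m.downstream_junction.left_position}-"
            f"{m.downstream_junction.right_position}, "
            f"deletion {m.deletion_length} nt, boundary repeats: {pairs}"
        )
    non_self = [
        h for h in hits if h.query_circle_id != h.subject_segment_id
    ]
    print(
        f"cross-virus scan: {len(hits)} hits "
        f"({len(non_self)} non-self) -> {args.out}"
    )


if __name__ == "__main__":
    main()
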