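"""Published reference tables for DsIV and related ichnovirus circles.

The profiling study of *Diadegma semiclausum* ichnovirus (DsIV) in
parasitized *Plutella xylostella* hemocytes reported, for each of the 47
DsIV circles, the number of chimeric reads recovered from ~1.84 billion
resequencing reads, plus the conserved junction pairs of the four
conserved-broken circles (CBCs) and the candidate HIM junction pairs
predicted in *Hyposoter fugitivus* IV and *Tranosema rostrale* IV.  These
small published tables are inputs for arithmetic cross-checks of the
statistics implemented here; the full sequencing dataset is not.
"""

from __future__ import annotations

from .core_io import BetweenBaseJunction

#: chimeric-read count per DsIV circle (reported genome-wide profile)
DSIV_CHIMERIC_READ_COUNTS: dict[str, int] = {
    "DsIV-01": 0, "DsIV-02": 8, "DsIV-03": 3, "DsIV-04": 12,
    "DsIV-05": 10, "DsIV-06": 17, "DsIV-07": 36, "DsIV-08": 5,
    "DsIV-09": 17, "DsIV-10": 12, "DsIV-11": 9, "DsIV-12": 5,
    "DsIV-13": 1, "DsIV-14": 7, "DsIV-15": 541, "DsIV-16": 3,
    "DsIV-17": 33, "DsIV-18": 14, "DsIV-19": 24, "DsIV-20": 0,
    "DsIV-21": 69, "DsIV-22": 6, "DsIV-23": 17, "DsIV-24": 28,
    "DsIV-25": 14, "DsIV-26": 25, "DsIV-27": 1, "DsIV-28": 21,
    "DsIV-29": 15, "DsIV-30": 18, "DsIV-31": 21, "DsIV-32": 1,
    "DsIV-33": 129, "DsIV-34": 9, "DsIV-35": 31, "DsIV-36": 23,
    "DsIV-37": 0, "DsIV-38": 47, "DsIV-39": 13, "DsIV-40": 42,
    "DsIV-41": 35, "DsIV-42": 48, "DsIV-43": 3, "DsIV-44": 17,
    "DsIV-45": 13, "DsIV-46": 15, "DsIV-47": 17,
}

#: the four conserved-broken DsIV circles
DSIV_CBC_IDS = ("DsIV-15", "DsIV-33", "DsIV-38", "DsIV-40")

#: reported chimeric reads attributed to the 17 low-count circles for which
#: no integration model could be called
DSIV_UNCLASSIFIED_CHIMERIC_READS = 109

#: conserved junction pairs of the CBCs:
#: circle -> (size, accession, upstream junction, downstream junction)
DSIV_CBC_JUNCTIONS: dict[
    str, tuple[int, str, BetweenBaseJunction, BetweenBaseJunction]
] = {
    "DsIV-15": (
        4024, "KF156228.1",
        BetweenBaseJunction("DsIV-15", 1943, 1944),
        BetweenBaseJunction("DsIV-15", 1997, 1998),
    ),
    "DsIV-33": (
        5277, "KF156246.1",
        BetweenBaseJunction("DsIV-33", 1058, 1059),
        BetweenBaseJunction("DsIV-33", 1090, 1091),
    ),
    "DsIV-38": (
        4756, "KF156251.1",
        BetweenBaseJunction("DsIV-38", 2391, 2392),
        BetweenBaseJunction("DsIV-38", 2702, 2703),
    ),
    "DsIV-40": (
        5127, "KF156253.1",
        BetweenBaseJunction("DsIV-40", 373, 374),
        BetweenBaseJunction("DsIV-40", 449, 450),
    ),
}

#: reported deletion lengths for the CBCs (exclusive convention)
DSIV_CBC_DELETIONS: dict[str, int] = {
    "DsIV-15": 54,
    "DsIV-33": 32,
    "DsIV-38": 311,
    "DsIV-40": 76,
}

#: the HIM boundary reverse-complementary repeat pairs of DsIV
DSIV_HIM_OUTER_REPEAT = ("CCGTACGCTCT", "AGAGCGTACGG")  # 11 nt
DSIV_HIM_INNER_REPEAT = ("ACTGTA", "TACAGT")  # 6 nt

#: candidate HIMs predicted in other ichnoviruses:
#: (virus, circle, accession, upstream junction, downstream junction,
#:  putative deletion — inclusive convention)
PREDICTED_HIM_JUNCTIONS: list[
    tuple[str, str, str, BetweenBaseJunction, BetweenBaseJunction, int]
] = [
    ("HfIV", "C5", "AB291183.1",
     BetweenBaseJunction("HfIV-C5", 920, 921),
     BetweenBaseJunction("HfIV-C5", 952, 953), 33),
    ("HfIV", "D1", "AB291196.1",
     BetweenBaseJunction("HfIV-D1", 854, 855),
     BetweenBaseJunction("HfIV-D1", 886, 887), 33),
    ("HfIV", "D2", "AB291197.1",
     BetweenBaseJunction("HfIV-D2", 1768, 1769),
     BetweenBaseJunction("HfIV-D2", 1800, 1801), 33),
    ("HfIV", "D4", "AB291199.1",
     BetweenBaseJunction("HfIV-D4", 4556, 4557),
     BetweenBaseJunction("HfIV-D4", 4600, 4601), 45),
    ("HfIV", "D6", "AB291200.1",
     BetweenBaseJunction("HfIV-D6", 364, 365),
     BetweenBaseJunction("HfIV-D6", 441, 442), 78),
    ("TrIV", "F1", "AF421353.1",
     BetweenBaseJunction("TrIV-F1", 2194, 2195),
     BetweenBaseJunction("TrIV-F1", 2226, 2227), 33),
    ("TrIV", "G5", "AB291163.1",
     BetweenBaseJunction("TrIV-G5", 5094, 5095),
     BetweenBaseJunction("TrIV-G5", 6874, 6875), 1781),
    ("TrIV", "C1", "AY940454.1",
     BetweenBaseJunction("TrIV-C1", 1456, 1457),
     BetweenBaseJunction("TrIV-C1", 1487, 1488), 32),
]

#: the worked junction-inference example from the published analysis:
#: read bases 1-51 map to DsIV-15 positions 2048-1988 (minus strand),
#: bases 50-150 to scaffold_206 positions 80256-80156 (minus strand);
#: the circle is linearised at 1987-1988 and inserts at 80256-80257
WORKED_EXAMPLE = {
    "read_length": 150,
    "circle_id": "DsIV-15",
    "circle_size": 4024,
    "virus_read_interval": (1, 51),
    "virus_target_interval": (2048, 1988),
    "virus_strand": "-",
    "scaffold_id": "scaffold_206",
    "host_read_interval": (50, 150),
    "host_target_interval": (80256, 80156),
    "host_strand": "-",
    "expected_virus_junction": (1987, 1988),
    "expected_host_insertion": (80256, 80257),
}
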