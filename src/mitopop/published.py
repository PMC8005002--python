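"""Worked-example inputs: printed classification counts from a published
mitogenome survey of 10-11th century Carpathian Basin cemeteries.

The study classified each maternal lineage into one of four
phylogeographic regions and reported per-cemetery percentage tables, and
reduced haplogroups to 34 major classes to report frequency contrasts
between the commoner (n = 182) and elite (n = 112) population pools.
The integer counts below are recovered from those printed percentages by
unique-integer inversion at the stated sample sizes; they serve as inputs
for reproducing the printed tables with this package's summary routines.

Only aggregate counts are constrained by the printed numbers; where a
reported total spans several haplogroup classes (e.g. the east Eurasian
block), the split across classes is a representative choice whose sum
matches the published aggregate.
"""

from __future__ import annotations

from .core import Population, RegionClass, Sample

W = RegionClass.WEST_EURASIA
E = RegionClass.EAST_EURASIA
U = RegionClass.EURASIA
C = RegionClass.CAUCASUS_MIDDLE_EAST

#: Per-population region counts (west excludes the Caucasus-Middle East
#: subclass, which the study carves out of the western lineages).
REGION_COUNTS: dict[str, dict[RegionClass, int]] = {
    "ConqC": {W: 96, E: 23, U: 52, C: 11},  # merged commoners, n = 182
    "Homokmegy-Szekes": {W: 16, E: 5, U: 13, C: 0},  # n = 34
    "Puspokladany-Eperjesvolgy": {W: 17, E: 6, U: 4, C: 4},  # n = 31
    "Sarretudvari-Hizofold": {W: 23, E: 4, U: 11, C: 1},  # n = 39
    "Ibrany-Esbohalom": {W: 12, E: 2, U: 7, C: 5},  # n = 26
    "Magyarhomorog-Konyadomb": {W: 16, E: 0, U: 9, C: 1},  # commoner part, n = 26
    "Vors-Papkert-B": {W: 19, E: 2, U: 6, C: 1},  # n = 28
}

#: Major-class counts for the merged commoner pool (n = 182).  Reported
#: classes carry their inverted counts; the remainder is filler in common
#: west-Eurasian classes so the east Eurasian aggregate (14 lineages,
#: 7.69%) is exact.
COMMONER_MAJOR_COUNTS: dict[str, int] = {
    "H": 61,   # 33.52%
    "T2": 12,  # 6.59%
    "N": 7,    # 3.85%
    "T1": 5,   # 2.75%
    "X": 1,    # 0.55%
    "C": 8,    # east block: C + D notable, single B; sums to 14 (7.69%)
    "D": 5,
    "B": 1,
    "U5": 42,  # filler (unreported split)
    "J": 40,   # filler (unreported split)
}

#: Major-class counts for the elite pool (n = 112); east block (A, B, C,
#: D, F, G, Y) sums to 22 lineages (19.64%).
ELITE_MAJOR_COUNTS: dict[str, int] = {
    "N": 13,   # 11.61%
    "T1": 13,  # 11.61%
    "H": 22,   # 19.64%
    "X": 5,    # 4.46%
    "T2": 2,   # 1.79%
    "A": 4,
    "B": 3,
    "C": 5,
    "D": 6,
    "F": 2,
    "G": 1,
    "Y": 1,
    "U4": 20,  # filler (unreported split)
    "J": 15,   # filler (unreported split)
}

#: A terminal sub-haplogroup representative per major class, used to
#: materialize count vectors as Sample collections.
REPRESENTATIVE_TERMINAL: dict[str, str] = {
    "A": "A12a", "B": "B4c1", "C": "C4a1", "D": "D4e4", "F": "F1b1",
    "G": "G2a", "H": "H1a", "HV": "HV0", "I": "I1a", "J": "J1c",
    "K": "K1a", "L": "L3e", "M": "M7a", "N": "N9a", "N1a": "N1a1a1a1a",
    "N1b": "N1b1", "R": "R2", "T": "T3", "T1": "T1a1", "T2": "T2b",
    "U": "U9a", "U1": "U1a", "U2": "U2e", "U3": "U3a", "U4": "U4a",
    "U5": "U5a1", "U6": "U6a", "U7": "U7a", "U8": "U8b", "V": "V7a",
    "W": "W6", "X": "X2b", "Y": "Y1a", "Z": "Z1a",
}

#: Closest published pairwise Fst of the merged commoner pool, against a
#: pooled European Medieval group.
CONQC_EUROPEAN_MEDIEVAL_FST = 0.0098


def population_from_major_counts(name: str, counts: dict[str, int]) -> Population:
    """Materialize a major-class count vector as a Population of samples
    carrying representative terminal sub-haplogroups."""
    samples = []
    i = 0
    for major, k in counts.items():
        label = REPRESENTATIVE_TERMINAL[major]
        for _ in range(k):
            samples.append(Sample(f"{name}_{i:03d}", name, name, label))
            i += 1
    return Population(name=name, samples=samples)
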