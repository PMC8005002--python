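"""Phylogeographic region assignment and per-population summaries.

Each maternal lineage is assigned one of four regions — west Eurasia, east
Eurasia, pan-Eurasia, Caucasus-Middle East — from its nearest matches in a
region-annotated reference panel, either by sequence distance (Hamming over
pairwise-complete positions) or by haplogroup-nomenclature proximity
(longest shared segment-prefix).  When the nearest set spans more than one
region the lineage is called generically Eurasian: a lineage whose closest
relatives sit on both sides of the continent is, operationally, widespread.

Summaries report per-region counts and percentages per cemetery or
population, and major-haplogroup frequency tables feed the ordination
stage.  Percentages use round-half-away-from-zero at a stated number of
decimals so printed tables are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .core import (
    MISSING_CHARS,
    HaplotypeSignature,
    Population,
    RegionClass,
    Sample,
)
from .haplogroups import MajorHgScheme, parse_haplogroup, reduce_to_major, terminal_sub_hg


def round_half_away(value: float, decimals: int) -> float:
    """Round with ties going away from zero (the convention of printed tables).

    Python's builtin ``round`` is banker's rounding; printed percentage
    tables in this field are not.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RegionSummary:
    """Per-region lineage counts and percentages for one population."""

    name: str
    counts: dict[RegionClass, int]
    percentages: dict[RegionClass, float]
    n: int


@dataclass
class MajorHgFrequencyTable:
    """Populations x major-class matrix of relative frequencies.

    ``frequencies`` rows are populations, columns the scheme's classes (in
    scheme order, zero-count classes included); each row sums to 1.
    ``sample_sizes`` maps population name to n.
    """

    frequencies: pd.DataFrame
    sample_sizes: dict[str, int]


def _hamming_pairwise_complete(a: str, b: str) -> int:
    """Differences over positions resolved (A/C/G/T) in both sequences."""
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x not in MISSING_CHARS and y not in MISSING_CHARS
    )


def _shared_prefix_depth(label_a: str, label_b: str) -> int:
    """Number of leading nomenclature blocks two haplogroup labels share."""
    pa = parse_haplogroup(label_a)
    pb = parse_haplogroup(label_b)
    depth = 0
    for x, y in zip(pa, pb):
        if x != y:
            break
        depth += 1
    return depth


def _looks_like_sequence(text: str) -> bool:
    return len(text) > 0 and set(text.upper()) <= set("ACGTN-")


def assign_region(
    query: str | HaplotypeSignature,
    panel: list[tuple[str, RegionClass]],
) -> RegionClass:
    """Region of the nearest reference-panel entries.

    Two comparison modes, chosen by the shape of ``query``:

    * **sequence mode** — ``query`` is a nucleotide string (or a
      :class:`HaplotypeSignature` resolvable against sequence panel
      entries is not supported; pass the raw sequence): nearest = minimum
      Hamming distance over pairwise-complete positions.
    * **label mode** — ``query`` is a haplogroup label; nearest = longest
      shared nomenclature prefix.

    If all nearest entries agree on a region that region is returned; an
    equidistant tie across regions yields the generic
    :attr:`RegionClass.EURASIA`.
    """
    if not panel:
        raise ValueError("reference panel is empty")
    if isinstance(query, HaplotypeSignature):
        raise TypeError(
            "pass the raw sequence for sequence-mode region assignment; a bare "
            "signature does not locate its missing positions"
        )

    sequence_mode = _looks_like_sequence(query)
    panel_is_sequence = all(_looks_like_sequence(key) for key, _ in panel)
    if sequence_mode and not panel_is_sequence:
        # Single-letter haplogroups like "A" or "T" also look like sequences;
        # fall back to label mode when the panel is label-keyed.
        if len(query) <= 2:
            sequence_mode = False
        else:
            raise ValueError("query is a sequence but the panel is label-keyed")
    if not sequence_mode and panel_is_sequence and len(panel[0][0]) > 2:
        raise ValueError("query is a haplogroup label but the panel is sequence-keyed")

    if sequence_mode:
        scores = [(-_hamming_pairwise_complete(query, key), region) for key, region in panel]
    else:
        scores = [(_shared_prefix_depth(query, key), region) for key, region in panel]
    best = max(score for score, _ in scores)
    nearest_regions = {region for score, region in scores if score == best}
    if len(nearest_regions) == 1:
        return next(iter(nearest_regions))
    return RegionClass.EURASIA


def annotate_regions(
    samples: list[Sample], panel: list[tuple[str, RegionClass]], mode: str = "auto"
) -> list[Sample]:
    """Assign a region to every sample lacking one, from its haplogroup
    (label mode) or sequence (sequence mode, when ``mode='sequence'``)."""
    out = []
    for s in samples:
        if s.region is not None:
            out.append(s)
            continue
        if mode == "sequence":
            if s.sequence is None:
                raise ValueError(f"sample {s.sample_id!r} has no sequence for region assignment")
            region = assign_region(s.sequence, panel)
        else:
            region = assign_region(s.haplogroup, panel)
        out.append(Sample(s.sample_id, s.site, s.population, s.haplogroup, s.sequence, region))
    return out


def region_summary(
    pop: Population,
    rounding_decimals: int = 1,
    merge_caucasus_into_west: bool = False,
) -> RegionSummary:
    """Four-region distribution of a population's maternal lineages.

    Every sample must carry a region annotation.  Percentages are
    ``round(100 * count / n, rounding_decimals)`` with half-away-from-zero.
    With ``merge_caucasus_into_west`` the Caucasus-Middle East class is
    folded into west Eurasia (a 3-way view); by default it is carved out as
    its own category.
    """
    counts = {region: 0 for region in RegionClass}
    for s in pop.samples:
        if s.region is None:
            raise ValueError(f"sample {s.sample_id!r} has no region annotation")
        counts[s.region] += 1
    if merge_caucasus_into_west:
        counts[RegionClass.WEST_EURASIA] += counts.pop(RegionClass.CAUCASUS_MIDDLE_EAST)
    n = pop.n
    percentages = {
        region: round_half_away(100 * c / n, rounding_decimals) for region, c in counts.items()
    }
    return RegionSummary(name=pop.name, counts=counts, percentages=percentages, n=n)


def region_summary_from_counts(
    name: str,
    counts: dict[RegionClass, int],
    rounding_decimals: int = 1,
) -> RegionSummary:
    """Region summary directly from classification counts (no Sample objects).

    Convenience for reproducing published per-cemetery tables where only
    the counts are known.
    """
    counts = {region: counts.get(region, 0) for region in RegionClass}
    n = sum(counts.values())
    if n <= 0:
        raise ValueError("counts must sum to a positive total")
    percentages = {
        region: round_half_away(100 * c / n, rounding_decimals) for region, c in counts.items()
    }
    return RegionSummary(name=name, counts=counts, percentages=percentages, n=n)


def major_hg_frequencies(
    pops: list[Population], scheme: MajorHgScheme | None = None
) -> MajorHgFrequencyTable:
    """Relative major-class frequencies per population.

    Every sample's haplogroup is reduced to its major class; frequency is
    count / n.  Classes absent from a population appear as 0 so all rows
    share the scheme's column order.
    """
    scheme = scheme or MajorHgScheme()
    rows = {}
    sizes = {}
    for pop in pops:
        counts = dict.fromkeys(scheme.classes, 0)
        for s in pop.samples:
            counts[reduce_to_major(terminal_sub_hg(s), scheme)] += 1
        rows[pop.name] = {c: counts[c] / pop.n for c in scheme.classes}
        sizes[pop.name] = pop.n
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(scheme.classes))
    return MajorHgFrequencyTable(frequencies=table, sample_sizes=sizes)


def east_eurasian_ratio(
    pop: Population, scheme: MajorHgScheme | None = None, rounding_decimals: int = 2
) -> float:
    """Percentage of lineages whose major class is east Eurasian.

    100 x the summed frequency over the scheme's east set, rounded
    half-away-from-zero to ``rounding_decimals`` (default 2).
    """
    scheme = scheme or MajorHgScheme()
    table = major_hg_frequencies([pop], scheme)
    total = sum(table.frequencies.loc[pop.name, c] for c in scheme.east_set)
    return round_half_away(100 * total, rounding_decimals)
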