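"""Core domain types and file I/O for mitogenome datasets.

All coordinates are 1-based and inclusive, following mtDNA community
convention (rCRS positions).  Sequences are assumed pre-aligned to a common
reference coordinate system: every per-sample consensus has the same length
as the reference and position *i* in the sample corresponds to position *i*
in the reference.  No alignment is performed here.

The sequence alphabet is ``{A, C, G, T, N, -}``.  IUPAC ambiguity codes are
collapsed to ``N`` on input: the expected upstream producers emit consensus
calls where an ambiguous base carries no usable information for
pairwise-difference statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mitopop")

#: Characters accepted in a normalized sequence.
SEQUENCE_ALPHABET = frozenset("ACGTN-")

#: Characters treated as missing data.
MISSING_CHARS = frozenset("N-")

#: Resolved nucleotide states.
RESOLVED_CHARS = frozenset("ACGT")


class RegionClass(Enum):
    """Phylogeographic region of a maternal lineage.

    Exactly four categories are distinguished: east Eurasia, west Eurasia,
    a generic pan-Eurasian class for lineages widespread across the
    continent, and Caucasus-Middle East.
    """

    WEST_EURASIA = "west_eurasia"
    EAST_EURASIA = "east_eurasia"
    EURASIA = "eurasia"
    CAUCASUS_MIDDLE_EAST = "caucasus_middle_east"

    @classmethod
    def parse(cls, text: str) -> "RegionClass":
        """Parse a region label from free text (TSV cells, config files).

        Accepts the canonical snake_case values plus common human spellings
        such as ``"east Eurasia"`` or ``"Caucasus-Middle East"``.
        """
        key = (
            text.strip()
            .lower()
            .replace("–", "-")  # en dash
            .replace("—", "-")
            .replace("-", " ")
            .replace("_", " ")
        )
        key = " ".join(key.split())
        mapping = {
            "west eurasia": cls.WEST_EURASIA,
            "west eurasian": cls.WEST_EURASIA,
            "east eurasia": cls.EAST_EURASIA,
            "east eurasian": cls.EAST_EURASIA,
            "eurasia": cls.EURASIA,
            "eurasian": cls.EURASIA,
            "caucasus middle east": cls.CAUCASUS_MIDDLE_EAST,
        }
        if key not in mapping:
            raise ValueError(
                f"unknown phylogeographic region {text!r}; expected one of "
                f"{sorted(m.value for m in cls)}"
            )
        return mapping[key]


@dataclass
class Sample:
    """One sequenced individual.

    Parameters
    ----------
    sample_id:
        Unique identifier within a dataset.
    site:
        Cemetery / sampling-site name.
    population:
        Analysis group the sample is pooled into (e.g. ``"ConqC"``).
    haplogroup:
        Deepest determined haplogroup label (the terminal sub-haplogroup),
        e.g. ``"N1a1a1a1a"``.  May be empty only if no haplogroup-based
        operation is invoked on the sample.
    sequence:
        Optional consensus sequence in reference coordinates, over
        ``{A,C,G,T,N,-}``.
    region:
        Optional phylogeographic region annotation.
    """

    sample_id: str
    site: str
    population: str
    haplogroup: str
    sequence: str | None = None
    region: RegionClass | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass
class Population:
    """A named, ordered collection of samples."""

    name: str
    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("population name must be non-empty")
        if len(self.samples) < 1:
            raise ValueError(f"population {self.name!r} must contain at least one sample")

    @property
    def n(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class HaplotypeSignature:
    """Canonical variant set of a sequence relative to the reference.

    ``variants`` is a tuple of ``(position, derived_state)`` pairs sorted by
    position (1-based); ``n_missing`` counts positions where the sample is
    ``N`` or gap.  Positions are unique and never overlap with missing
    positions.
    """

    variants: tuple[tuple[int, str], ...]
    n_missing: int = 0

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.variants]
        if positions != sorted(set(positions)):
            raise ValueError("variant positions must be strictly increasing and unique")

    @property
    def variant_positions(self) -> frozenset[int]:
        return frozenset(p for p, _ in self.variants)


def normalize_sequence(raw: str) -> str:
    """Upper-case a sequence and collapse non-``{A,C,G,T,N,-}`` characters to N."""
    seq = raw.upper()
    if set(seq) <= SEQUENCE_ALPHABET:
        return seq
    return "".join(c if c in SEQUENCE_ALPHABET else "N" for c in seq)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs, order preserved.

    Sequences are upper-cased; characters outside ``{A,C,G,T,N,-}`` (e.g.
    IUPAC ambiguity codes) are mapped to ``N``.  Record ids are preserved
    verbatim (up to the first whitespace, FASTA convention).

    Raises
    ------
    ValueError
        On malformed FASTA (naming the offending line), duplicate ids, or
        empty records.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, line {lineno} does not start a record: "
                    f"{line.strip()[:50]!r}"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")

    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with fixed line wrapping."""
    with open(path, "w", encoding="utf-8") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


_MANDATORY_COLUMNS = ("sample_id", "site", "population", "haplogroup")


def read_metadata(path: str | Path) -> list[Sample]:
    """Read a per-sample metadata TSV into Samples.

    The file must carry a header row with at least the columns
    ``sample_id``, ``site``, ``population`` and ``haplogroup``.  Optional
    columns ``region`` and ``period`` are parsed when present.  Rows with an
    empty haplogroup cell are loaded with ``haplogroup=""`` and reported via
    the package logger so haplogroup-based stages can refuse them later.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: metadata is missing mandatory column(s): {', '.join(missing)}")

    samples: list[Sample] = []
    seen: set[str] = set()
    n_missing_hg = 0
    for idx, row in table.iterrows():
        sample_id = row["sample_id"].strip()
        if not sample_id:
            raise ValueError(f"{path}: row {idx + 2} has an empty sample_id")
        if sample_id in seen:
            raise ValueError(f"{path}: duplicate sample_id {sample_id!r} (row {idx + 2})")
        seen.add(sample_id)
        haplogroup = row["haplogroup"].strip()
        if not haplogroup:
            n_missing_hg += 1
            logger.warning("%s: row %d (%s) has no haplogroup", path, idx + 2, sample_id)
        region: RegionClass | None = None
        if "region" in table.columns and row["region"].strip():
            try:
                region = RegionClass.parse(row["region"])
            except ValueError as exc:
                raise ValueError(f"{path}: row {idx + 2} ({sample_id}): {exc}") from exc
        samples.append(
            Sample(
                sample_id=sample_id,
                site=row["site"].strip(),
                population=row["population"].strip(),
                haplogroup=haplogroup,
                region=region,
            )
        )
    logger.info(
        "%s: loaded %d samples (%d without haplogroup)", path, len(samples), n_missing_hg
    )
    return samples


def write_metadata(samples: Iterable[Sample], path: str | Path) -> None:
    """Write Samples as a metadata TSV (inverse of :func:`read_metadata`)."""
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "site": s.site,
                "population": s.population,
                "haplogroup": s.haplogroup,
                "region": s.region.value if s.region is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_sequences(
    samples: TypingSequence[Sample], fasta_records: Iterable[tuple[str, str]]
) -> list[Sample]:
    """Attach FASTA sequences to samples by id; error on ids without sequence."""
    by_id = dict(fasta_records)
    out = []
    for s in samples:
        if s.sample_id not in by_id:
            raise ValueError(f"no sequence found for sample {s.sample_id!r}")
        out.append(
            Sample(s.sample_id, s.site, s.population, s.haplogroup, by_id[s.sample_id], s.region)
        )
    return out


def missing_fraction(sequence: str) -> float:
    """Fraction of positions that are N or gap."""
    n_missing = sum(1 for c in sequence if c in MISSING_CHARS)
    return n_missing / len(sequence)


def filter_by_missingness(
    samples: TypingSequence[Sample], max_missing_fraction: float = 0.05
) -> tuple[list[Sample], list[Sample]]:
    """Partition samples into (kept, excluded) by sequence missingness.

    A sample is excluded iff its fraction of N/gap positions strictly
    exceeds ``max_missing_fraction`` (default 5%); a sample sitting exactly
    on the threshold is kept.  Both partitions preserve input order.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    kept: list[Sample] = []
    excluded: list[Sample] = []
    for s in samples:
        if s.sequence is None:
            raise ValueError(f"sample {s.sample_id!r} has no sequence")
        if missing_fraction(s.sequence) > max_missing_fraction:
            excluded.append(s)
        else:
            kept.append(s)
    if excluded:
        logger.info(
            "missingness filter (> %.1f%%): excluded %d of %d sequences",
            100 * max_missing_fraction,
            len(excluded),
            len(samples),
        )
    return kept, excluded


def haplotype_signature(sequence: str, reference: str) -> HaplotypeSignature:
    """Canonical variant set of ``sequence`` against ``reference``.

    Every position where the sample carries a resolved base (A/C/G/T)
    differing from the reference becomes a ``(position, state)`` variant;
    positions where the sample is N or gap are counted in ``n_missing`` and
    never appear as variants.  Positions are 1-based.
    """
    if len(sequence) != len(reference):
        raise ValueError(
            f"sequence length {len(sequence)} does not match reference length {len(reference)}"
        )
    variants: list[tuple[int, str]] = []
    n_missing = 0
    for pos0, (s, r) in enumerate(zip(sequence, reference)):
        if s in MISSING_CHARS:
            n_missing += 1
        elif s != r:
            variants.append((pos0 + 1, s))
    return HaplotypeSignature(variants=tuple(variants), n_missing=n_missing)
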