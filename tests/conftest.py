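"""Shared fixtures: small synthetic references and sample builders."""

from __future__ import annotations

import pytest

from mitopop.core import Population, Sample


@pytest.fixture
def reference() -> str:
    # deterministic 120-bp toy reference
    return ("ACGT" * 30)[:120]


def mutate(seq: str, pos: int, base: str) -> str:
    """Return seq with the 1-based position set to base."""
    chars = list(seq)
    chars[pos - 1] = base
    return "".join(chars)


def make_sample(sample_id: str, sequence: str | None = None, *, site: str = "site1",
                population: str = "Pop", haplogroup: str = "H", region=None) -> Sample:
    return Sample(sample_id=sample_id, site=site, population=population,
                  haplogroup=haplogroup, sequence=sequence, region=region)


def make_population(name: str, haplogroups: list[str] | None = None,
                    sequences: list[str] | None = None) -> Population:
    if haplogroups is None:
        haplogroups = ["H"] * len(sequences)
    if sequences is None:
        sequences = [None] * len(haplogroups)
    samples = [
        Sample(sample_id=f"{name}_{i}", site=name, population=name,
               haplogroup=hg, sequence=seq)
        for i, (hg, seq) in enumerate(zip(haplogroups, sequences))
    ]
    return Population(name=name, samples=samples)
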