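"""Screening for identical mitochondrial haplotypes within and between sites.

Two individuals sharing an identical mitogenome haplotype are candidates
for direct maternal kinship (though identity alone is not evidence of close
family relation — the mitogenome is a single locus).  Identity is judged at
sequence level, not haplogroup level: two samples pair iff their variant
sets against the reference are identical AND neither is missing (N/gap) at
any position where the other carries a variant.  The second clause is a
conservative guard: a sample blind at a site cannot vouch for matching a
variant there.  Missing data at positions where neither sample carries a
variant is tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import MISSING_CHARS, Sample, haplotype_signature


class PairScope(Enum):
    WITHIN_SITE = "within_site"
    BETWEEN_SITE = "between_site"


@dataclass(frozen=True)
class HaplotypePair:
    """An unordered pair of samples with identical haplotypes.

    Canonical order: ``sample_id_a < sample_id_b``.
    """

    sample_id_a: str
    sample_id_b: str
    site_a: str
    site_b: str
    scope: PairScope

    def __post_init__(self) -> None:
        if self.sample_id_a == self.sample_id_b:
            raise ValueError("a sample cannot pair with itself")
        if self.sample_id_a > self.sample_id_b:
            raise ValueError("pair must be in canonical id order")


def _identical_haplotypes(
    seq_a: str, seq_b: str, reference: str, mask: frozenset[int]
) -> bool:
    sig_a = haplotype_signature(seq_a, reference)
    sig_b = haplotype_signature(seq_b, reference)
    va = {(p, s) for p, s in sig_a.variants if p not in mask}
    vb = {(p, s) for p, s in sig_b.variants if p not in mask}
    if va != vb:
        return False
    # missing-data guard: neither sample may be blind where the other varies
    for pos, _ in va | vb:
        if seq_a[pos - 1] in MISSING_CHARS or seq_b[pos - 1] in MISSING_CHARS:
            return False
    return True


def find_identical_pairs(
    samples: Sequence[Sample],
    reference: str,
    position_mask: Sequence[int] = (),
) -> list[HaplotypePair]:
    """All unordered pairs of samples with identical haplotypes.

    ``position_mask`` optionally lists 1-based positions ignored during
    comparison (e.g. hypervariable indel hotspots); default empty.  Pairs
    are partitioned by scope: within-site when both samples come from the
    same site, between-site otherwise.  Output order is canonical
    (sorted by id pair), independent of input order.
    """
    mask = frozenset(position_mask)
    for s in samples:
        if s.sequence is None:
            raise ValueError(f"sample {s.sample_id!r} has no sequence")
        if len(s.sequence) != len(reference):
            raise ValueError(
                f"sample {s.sample_id!r}: sequence length {len(s.sequence)} "
                f"!= reference length {len(reference)}"
            )

    pairs: list[HaplotypePair] = []
    ordered = sorted(samples, key=lambda s: s.sample_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if _identical_haplotypes(a.sequence, b.sequence, reference, mask):
                scope = PairScope.WITHIN_SITE if a.site == b.site else PairScope.BETWEEN_SITE
                pairs.append(
                    HaplotypePair(a.sample_id, b.sample_id, a.site, b.site, scope)
                )
    return pairs


def pairs_to_table(pairs: Sequence[HaplotypePair]) -> pd.DataFrame:
    """Pairs as a DataFrame (id_a, id_b, site_a, site_b, scope)."""
    return pd.DataFrame(
        [
            {
                "id_a": p.sample_id_a,
                "id_b": p.sample_id_b,
                "site_a": p.site_a,
                "site_b": p.site_b,
                "scope": p.scope.value,
            }
            for p in pairs
        ],
        columns=["id_a", "id_b", "site_a", "site_b", "scope"],
    )


def write_pairs(pairs: Sequence[HaplotypePair], path: str | Path) -> None:
    pairs_to_table(pairs).to_csv(path, sep="\t", index=False)
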