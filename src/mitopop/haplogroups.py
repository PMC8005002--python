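"""Mitochondrial haplogroup nomenclature: parsing, major-class reduction,
and east/west Eurasian classification.

Haplogroup labels follow Phylotree-style nomenclature: a leading letter
block naming the top-level clade (``H``, ``HV``, ``U``...) followed by
alternating digit and lower-case letter blocks refining the clade
(``U5a2``, ``N1a1a1a1a``).  Every cut at a block boundary names an ancestor
clade, which is what prefix-based reduction and matching exploit.

The default major-haplogroup scheme reduces labels to 34 coarse classes
(A, B, C, D, F, G, H, HV, I, J, K, L, M, N, N1a, N1b, R, T, T1, T2, U,
U1-U8, V, W, X, Y, Z) — the dimensionality used for haplogroup-frequency
ordination of ancient Eurasian populations.  Matching is by nomenclature
segments, never raw characters, so ``HV0`` reduces to ``HV`` and not ``H``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import yaml

from .core import Sample

#: The 34 default major-haplogroup classes.
DEFAULT_MAJOR_CLASSES: tuple[str, ...] = (
    "A", "B", "C", "D", "F", "G", "H", "HV", "I", "J", "K", "L", "M", "N",
    "N1a", "N1b", "R", "T", "T1", "T2", "U", "U1", "U2", "U3", "U4", "U5",
    "U6", "U7", "U8", "V", "W", "X", "Y", "Z",
)

#: Major classes treated as east Eurasian by default.  A-G and Y are the
#: classically east Eurasian clades among the 34; Z is included as it is
#: conventionally east Eurasian.  M, despite an eastern centre of gravity,
#: is deliberately NOT in the default set (it also harbours widespread
#: western sub-clades); override the scheme if a different convention is
#: needed.
DEFAULT_EAST_SET: frozenset[str] = frozenset({"A", "B", "C", "D", "F", "G", "Y", "Z"})

_TOKEN_RE = re.compile(r"[A-Za-z]+|[0-9]+")


@dataclass(frozen=True)
class MajorHgScheme:
    """A major-haplogroup reduction scheme.

    ``classes`` is the ordered list of major-class labels; ``east_set`` the
    subset flagged east Eurasian.
    """

    classes: tuple[str, ...] = DEFAULT_MAJOR_CLASSES
    east_set: frozenset[str] = DEFAULT_EAST_SET

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("scheme must define at least one major class")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("major classes must be unique")
        extra = set(self.east_set) - set(self.classes)
        if extra:
            raise ValueError(f"east_set entries not among classes: {sorted(extra)}")

    @classmethod
    def from_config(cls, path: str | Path) -> "MajorHgScheme":
        """Load a scheme from a YAML config with keys ``classes`` and ``east``."""
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ValueError(f"{path}: scheme config must be a mapping")
        classes = tuple(str(c) for c in cfg.get("classes", DEFAULT_MAJOR_CLASSES))
        east = frozenset(str(c) for c in cfg.get("east", sorted(DEFAULT_EAST_SET)))
        return cls(classes=classes, east_set=east)


def _tokenize(label: str) -> list[str]:
    """Split a haplogroup label into nomenclature blocks, normalizing case.

    Suffix annotations (anything from the first non-alphanumeric character,
    e.g. ``"U5b+16189"`` or ``"H5*"``) are truncated before tokenizing — Hg
    callers commonly emit such decorations.
    """
    label = label.strip()
    m = re.match(r"[A-Za-z0-9]*", label)
    core = m.group(0) if m else ""
    if not core:
        raise ValueError(f"cannot parse haplogroup label {label!r}")
    tokens = _TOKEN_RE.findall(core)
    if "".join(tokens) != core or not tokens[0][0].isalpha():
        raise ValueError(f"cannot parse haplogroup label {label!r}")
    # alternation check: blocks must alternate alpha/digit
    for prev, cur in zip(tokens, tokens[1:]):
        if prev[0].isdigit() == cur[0].isdigit():
            raise ValueError(f"cannot parse haplogroup label {label!r}")
    out = []
    for i, tok in enumerate(tokens):
        if tok[0].isdigit():
            out.append(tok)
        elif i == 0:
            out.append(tok.upper())
        else:
            out.append(tok.lower())
    return out


def normalize_label(label: str) -> str:
    """Canonical form of a label: decorations stripped, case normalized."""
    return "".join(_tokenize(label))


def parse_haplogroup(label: str) -> list[str]:
    """Expand a haplogroup label into its ordered list of nested prefixes.

    ``"U5a2"`` yields ``["U", "U5", "U5a", "U5a2"]`` — every ancestor clade
    named by cutting at a block boundary, shortest first.
    """
    tokens = _tokenize(label)
    prefixes = []
    acc = ""
    for tok in tokens:
        acc += tok
        prefixes.append(acc)
    return prefixes


def reduce_to_major(label: str, scheme: MajorHgScheme | None = None) -> str:
    """Reduce a haplogroup label to its major class under ``scheme``.

    Returns the longest scheme class that is a segment-prefix of the label
    (``"N1a1a1a1a"`` → ``"N1a"``, ``"HV0"`` → ``"HV"``).  Raises if no class
    matches, forcing an explicit scheme extension rather than silent
    bucketing.
    """
    scheme = scheme or MajorHgScheme()
    prefixes = parse_haplogroup(label)
    matches = [p for p in prefixes if p in set(scheme.classes)]
    if not matches:
        raise ValueError(
            f"haplogroup {label!r} is not reducible under the scheme "
            f"(no class among its prefixes {prefixes})"
        )
    return max(matches, key=len)


def is_east_eurasian(major: str, scheme: MajorHgScheme | None = None) -> bool:
    """Whether a major class belongs to the scheme's east Eurasian set."""
    scheme = scheme or MajorHgScheme()
    if major not in scheme.classes:
        raise ValueError(f"unknown major haplogroup class {major!r}")
    return major in scheme.east_set


def terminal_sub_hg(sample: Sample) -> str:
    """The sample's terminal sub-haplogroup (deepest determined level).

    Returns the full label in canonical form; the deepest level is the unit
    of sub-haplogroup sharing statistics.
    """
    if not sample.haplogroup:
        raise ValueError(f"sample {sample.sample_id!r} has no haplogroup assigned")
    return normalize_label(sample.haplogroup)
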