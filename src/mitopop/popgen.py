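"""Population-comparison statistics for mitogenome datasets.

Three complementary distance notions between populations:

* **Phi-ST / Fst** — sequence-based.  An AMOVA decomposition of molecular
  variance for two groups, using the count of pairwise nucleotide
  differences (over positions resolved in both sequences) as the squared
  inter-individual distance.  With sums of squares

  .. math::

      SS_{tot} = \\frac{1}{N}\\sum_{i<j} \\delta^2_{ij}, \\qquad
      SS_{w} = \\sum_g \\frac{1}{n_g} \\sum_{i<j \\in g} \\delta^2_{ij},

  the within component is :math:`\\sigma^2_w = SS_w/(N-G)` and the among
  component :math:`\\sigma^2_a = (MS_{a} - \\sigma^2_w)/n'` with the usual
  AMOVA coefficient :math:`n' = (N - \\sum_g n_g^2/N)/(G-1)`;
  :math:`\\Phi_{ST} = \\sigma^2_a / (\\sigma^2_a + \\sigma^2_w)`.
  Significance comes from permuting individuals between the two groups.
  Slatkin's linearization :math:`F_{ST}/(1-F_{ST})` — proportional to
  divergence time under a simple demographic model — feeds classical MDS.

* **SHD (shared haplogroup distance)** — haplogroup-based.  One minus the
  overlap of the two populations' terminal sub-haplogroup frequency
  distributions, :math:`SHD = 1 - \\sum_h \\min(f_A(h), f_B(h))`.  Small
  values indicate shared ancestry or past admixture.

* **Major-haplogroup PCA** — frequency-profile ordination over the coarse
  major classes (column-centered, unscaled, via SVD).

No substitution-model correction (gamma, Tamura-Nei) is applied to the
pairwise distances; raw mismatch counts are the substrate throughout.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Population
from .haplogroups import MajorHgScheme, is_east_eurasian, reduce_to_major, terminal_sub_hg
from .phylogeo import MajorHgFrequencyTable

# ---------------------------------------------------------------------------
# containers


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix between populations."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        if list(frame.index) != list(frame.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls(labels=tuple(frame.index), values=frame.to_numpy(dtype=float))


@dataclass
class FstResult:
    """A pairwise Phi-ST estimate with its permutation p-value."""

    fst: float
    linearized: float
    p_value: float
    n_permutations: int


@dataclass
class OrdinationResult:
    """Low-dimensional coordinates from PCA or classical MDS.

    ``explained`` holds per-axis variance fractions for PCA and raw
    eigenvalues (descending) for MDS.
    """

    coordinates: pd.DataFrame
    explained: np.ndarray
    method: str


# ---------------------------------------------------------------------------
# sequence distances and AMOVA Phi-ST

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i


def encode_sequences(sequences: list[str]) -> np.ndarray:
    """Encode sequences as a (n, L) uint8 matrix; A..T -> 0..3, missing -> 255."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have differing lengths: {sorted(lengths)}")
    buf = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return _ENCODE[buf].reshape(len(sequences), -1)


def _pairwise_sq_distances(matrix: np.ndarray) -> np.ndarray:
    """All-pairs mismatch counts over pairwise-complete positions."""
    n = matrix.shape[0]
    resolved = matrix != 255
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = resolved[i] & resolved[i + 1 :]
        diff = (matrix[i] != matrix[i + 1 :]) & both
        counts = diff.sum(axis=1)
        out[i, i + 1 :] = counts
        out[i + 1 :, i] = counts
    return out


def pairwise_difference_matrix(pop_a: Population, pop_b: Population) -> np.ndarray:
    """Counts of nucleotide differences between every sample of A and of B.

    A position contributes only when both sequences are resolved (A/C/G/T)
    there — pairwise-complete deletion of missing sites.
    """
    seqs = [s.sequence for s in list(pop_a) + list(pop_b)]
    if any(s is None for s in seqs):
        raise ValueError("every sample needs a sequence")
    full = _pairwise_sq_distances(encode_sequences(seqs))
    return full[: pop_a.n, pop_a.n :]


def _phi_st_from_sq(sq: np.ndarray, n_a: int, n_b: int) -> float:
    """Two-group AMOVA Phi-ST from a pooled squared-distance matrix."""
    n_total = n_a + n_b
    iu = np.triu_indices(n_total, k=1)
    ss_total = sq[iu].sum() / n_total
    iu_a = np.triu_indices(n_a, k=1)
    iu_b = np.triu_indices(n_b, k=1)
    ss_within = sq[:n_a, :n_a][iu_a].sum() / n_a + sq[n_a:, n_a:][iu_b].sum() / n_b
    ss_among = ss_total - ss_within
    sigma_w = ss_within / (n_total - 2)
    n_prime = n_total - (n_a**2 + n_b**2) / n_total  # (N - sum n_g^2 / N) / (G - 1)
    sigma_a = (ss_among - sigma_w) / n_prime  # MS_among = SS_among / (G - 1)
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return sigma_a / denom


def _pooled_sq(pop_a: Population, pop_b: Population) -> np.ndarray:
    for pop in (pop_a, pop_b):
        if pop.n < 2:
            raise ValueError(f"population {pop.name!r} needs at least 2 sequences")
        if any(s.sequence is None for s in pop):
            raise ValueError(f"population {pop.name!r} has samples without sequences")
    seqs = [s.sequence for s in list(pop_a) + list(pop_b)]
    return _pairwise_sq_distances(encode_sequences(seqs))


def phi_st(pop_a: Population, pop_b: Population) -> float:
    """AMOVA-based pairwise Phi-ST between two populations.

    May be slightly negative by estimation noise; values are not clamped.
    """
    return _phi_st_from_sq(_pooled_sq(pop_a, pop_b), pop_a.n, pop_b.n)


def slatkin_linearize(fst: float) -> float:
    """Slatkin's linearization fst / (1 - fst).

    Negative estimates pass through unchanged (the transform is monotone
    and near-identity around zero); fst = 1 yields +inf with a warning.
    """
    if fst >= 1:
        warnings.warn("fst >= 1: linearized value is infinite", stacklevel=2)
        return float("inf")
    return fst / (1.0 - fst)


def fst_permutation_test(
    pop_a: Population,
    pop_b: Population,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> FstResult:
    """Phi-ST with a permutation p-value.

    Individuals are shuffled between the two groups holding group sizes
    fixed; ``p = (1 + #{permuted Phi-ST >= observed}) / (1 + n_permutations)``
    (add-one estimator, so p is never exactly 0).  Deterministic given the
    seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sq = _pooled_sq(pop_a, pop_b)
    n_a, n_b = pop_a.n, pop_b.n
    observed = _phi_st_from_sq(sq, n_a, n_b)
    if not sq.any():
        warnings.warn(
            "all pooled sequences are identical; permutation test is degenerate (p = 1)",
            stacklevel=2,
        )
        return FstResult(fst=observed, linearized=slatkin_linearize(max(observed, 0.0)),
                         p_value=1.0, n_permutations=n_permutations)
    rng = np.random.default_rng(seed)
    n_total = n_a + n_b
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        shuffled = sq[np.ix_(perm, perm)]
        if _phi_st_from_sq(shuffled, n_a, n_b) >= observed:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return FstResult(
        fst=observed,
        linearized=slatkin_linearize(observed) if observed < 1 else float("inf"),
        p_value=p,
        n_permutations=n_permutations,
    )


def phi_st_matrix(
    pops: list[Population],
    linearize: bool = False,
    clamp_negative: bool | None = None,
) -> DistanceMatrix:
    """Pairwise Phi-ST matrix over a set of populations.

    With ``linearize`` the Slatkin transform is applied entry-wise;
    negative estimates are then clamped to 0 first (default when
    linearizing), since fst/(1-fst) of a negative estimate has no
    interpretation as a divergence-time proxy.  Without linearization
    negative estimates are retained.
    """
    if clamp_negative is None:
        clamp_negative = linearize
    names = [p.name for p in pops]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique")
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fst = phi_st(pops[i], pops[j])
            if clamp_negative:
                fst = max(fst, 0.0)
            values[i, j] = values[j, i] = slatkin_linearize(fst) if linearize else fst
    return DistanceMatrix(labels=tuple(names), values=values)


# ---------------------------------------------------------------------------
# shared haplogroup distance


def terminal_frequencies(pop: Population) -> dict[str, float]:
    """Relative frequencies of terminal sub-haplogroups in a population."""
    counts = Counter(terminal_sub_hg(s) for s in pop)
    return {hg: c / pop.n for hg, c in counts.items()}


def shd(pop_a: Population, pop_b: Population) -> float:
    """Shared haplogroup distance between two populations.

    ``1 - sum_h min(f_A(h), f_B(h))`` over terminal sub-haplogroups h: one
    minus the overlap of the two frequency distributions.  Symmetric, in
    [0, 1]; 0 for identical profiles, 1 for disjoint terminal sub-Hg sets.
    """
    fa = terminal_frequencies(pop_a)
    fb = terminal_frequencies(pop_b)
    shared = sum(min(fa[h], fb[h]) for h in fa.keys() & fb.keys())
    return 1.0 - shared


def shd_matrix(pops: list[Population]) -> DistanceMatrix:
    """Pairwise SHD matrix over a set of populations."""
    names = [p.name for p in pops]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique")
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = shd(pops[i], pops[j])
    return DistanceMatrix(labels=tuple(names), values=values)


@dataclass(frozen=True)
class SharedHg:
    """One terminal sub-haplogroup present in both compared populations."""

    haplogroup: str
    freq_a: float
    freq_b: float
    east_eurasian: bool


def shared_hg_report(
    pop_a: Population, pop_b: Population, scheme: MajorHgScheme | None = None
) -> list[SharedHg]:
    """Terminal sub-haplogroups shared by both populations.

    Each entry carries its frequency in either population and an east
    Eurasian flag derived from the major-class reduction under the scheme's
    (configurable) east set.
    """
    scheme = scheme or MajorHgScheme()
    fa = terminal_frequencies(pop_a)
    fb = terminal_frequencies(pop_b)
    report = []
    for hg in sorted(fa.keys() & fb.keys()):
        east = is_east_eurasian(reduce_to_major(hg, scheme), scheme)
        report.append(SharedHg(haplogroup=hg, freq_a=fa[hg], freq_b=fb[hg], east_eurasian=east))
    return report


# ---------------------------------------------------------------------------
# ordination


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: each axis's largest-|.| loading positive."""
    for j in range(loadings.shape[0]):
        pivot = np.argmax(np.abs(loadings[j]))
        if loadings[j, pivot] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1


def pca(freq_table: MajorHgFrequencyTable | pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Principal component analysis of a haplogroup-frequency table.

    Columns (classes) are centered but not scaled — frequencies already
    share a scale, and rare classes should not be inflated.  Scores come
    from the SVD of the centered matrix; ``explained`` is the variance
    fraction per retained axis.  Axis signs follow a fixed convention
    (largest-magnitude loading positive) so runs are reproducible.
    """
    frame = freq_table.frequencies if isinstance(freq_table, MajorHgFrequencyTable) else freq_table
    x = frame.to_numpy(dtype=float)
    n_pops, n_classes = x.shape
    if n_pops < 2:
        raise ValueError("PCA needs at least 2 populations")
    if not 1 <= k <= min(n_pops - 1, n_classes):
        raise ValueError(
            f"k={k} out of range; must be within [1, {min(n_pops - 1, n_classes)}]"
        )
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].copy()
    _fix_signs(loadings, scores)
    total = float((s**2).sum())
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    coords = pd.DataFrame(
        scores, index=frame.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coordinates=coords, explained=explained, method="pca")


def classical_mds(dist: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical (Torgerson) multidimensional scaling / PCoA.

    Double-centers ``-1/2 J D^2 J``, eigendecomposes, and keeps the top-k
    nonnegative eigenvalues; coordinates scale as
    ``sqrt(eigenvalue) * eigenvector``.  Negative eigenvalues (the input
    not being Euclidean-realizable) are dropped with a warning listing
    their magnitudes.  On Euclidean-realizable input the embedding
    reproduces all pairwise distances exactly once k reaches the intrinsic
    dimension.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = dist.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = max(1e-9, 1e-12 * max(abs(eigval[0]), 1.0))
    negative = eigval[eigval < -tol]
    if negative.size:
        warnings.warn(
            "dropping negative MDS eigenvalues (input not Euclidean): "
            + ", ".join(f"{abs(v):.6g}" for v in negative),
            stacklevel=2,
        )
    nonneg = np.where(eigval >= -tol)[0]
    if eigval[nonneg].max(initial=-1.0) <= tol:
        raise ValueError("all MDS eigenvalues are non-positive; no embedding exists")
    keep = nonneg[: min(k, nonneg.size)]
    vals = np.clip(eigval[keep], 0.0, None)
    coords_arr = eigvec[:, keep] * np.sqrt(vals)
    axes = coords_arr.T.copy()
    scores = coords_arr.copy()
    _fix_signs(axes, scores)
    coords = pd.DataFrame(
        scores, index=list(dist.labels), columns=[f"Dim{i + 1}" for i in range(len(keep))]
    )
    return OrdinationResult(coordinates=coords, explained=vals, method="mds")
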