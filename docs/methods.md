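# Methods

This note documents the models and procedures implemented in `mitopop`,
the assumptions behind them, and the numerical and design choices a
maintainer would want to know about.

## Scope and data model

The package operates downstream of consensus calling: its inputs are
whole-mitogenome consensus sequences already projected onto a common
reference coordinate system (one FASTA record per sample, all of
reference length), plus a per-sample metadata table (sample id, site,
population, terminal haplogroup, optional region). Coordinates are
1-based and inclusive, the mtDNA community convention (rCRS positions).
No alignment, read mapping, damage handling or haplogroup calling is
performed; the haplogroup string is an input.

IUPAC ambiguity codes are collapsed to `N` on load: consensus pipelines
emit ambiguous calls where coverage or damage leaves the base unusable
for difference counting, and treating them as missing is the
conservative choice. Sequences with more than 5% missing positions
(strictly greater; a sequence exactly at the threshold is kept) are
excluded before any distance computation.

## Haplogroup nomenclature

Labels follow the alternating letter/digit block convention
(`N1a1a1a1a`, `U5a2`, `HV0`). Parsing is by blocks, never raw
characters, so every cut at a block boundary names an ancestor clade and
`HV0` can never be mistaken for a sub-clade of `H`. Trailing
decorations emitted by haplogroup callers (`*`, `+16189`, primes) are
truncated at the first non-alphanumeric character.

Reduction to major haplogroups uses a 34-class scheme (A, B, C, D, F, G,
H, HV, I, J, K, L, M, N, N1a, N1b, R, T, T1, T2, U, U1-U8, V, W, X, Y,
Z), taking the longest class that is a block-prefix of the label. A
label matching no class raises an error rather than being silently
bucketed, forcing an explicit scheme extension. The default east
Eurasian flag set is {A, B, C, D, F, G, Y, Z}: A-G and Y are the
classically east Eurasian clades among the 34, and Z is conventionally
east Eurasian. M is deliberately not flagged east by default — although
its centre of gravity is eastern, it harbours widespread western
sub-clades and the commoner/elite contrast treats it with the western
classes; the scheme (classes and east set) is user-overridable through a
YAML config precisely because this convention is contestable.

## Phylogeographic region assignment

Each lineage is assigned one of four regions — west Eurasia, east
Eurasia, pan-Eurasia, Caucasus-Middle East — from its nearest matches in
a region-annotated reference panel. Two comparison modes are exposed:
sequence mode (minimum Hamming distance over positions resolved in both
sequences) and label mode (longest shared nomenclature prefix); sequence
mode is the default where sequences are available, since haplogroup
labels saturate at the resolution of the assignment. When the nearest
set spans more than one region, the lineage is called generically
Eurasian: operationally, a lineage whose closest relatives sit on both
sides of the continent is widespread. The same tie rule applies to
nearest-neighbour lookups on median-joining networks.

Per-population region summaries are reported 4-way by default, carving
Caucasus-Middle East out of the western lineages; a 3-way view folding
it back into west Eurasia is available. Percentages round
half-away-from-zero (1 decimal for region summaries, 2 for
major-haplogroup frequencies) — the convention needed to reproduce
printed percentage tables bit-for-bit; Python's banker's rounding would
differ on exact ties.

## Kinship screening

Two samples are reported as an identical-haplotype pair iff their
variant sets against the reference are identical and neither is missing
(N or gap) at any position where the other carries a variant. The guard
is conservative: a sample that is blind at a site cannot vouch for
matching a variant there, while missingness at positions where neither
sample varies is tolerated. Identity is sequence-level, not
haplogroup-level — two samples in the same terminal sub-haplogroup can
still carry different private variants. An optional position mask
excludes hypervariable hotspots (e.g. poly-C indel regions) from the
comparison; it defaults to empty. Mitogenome identity is a single
non-recombining locus: a shared haplotype is compatible with, but never
proof of, close maternal kinship.

## Pairwise Phi-ST / Fst

Sequence-based population differentiation is the two-group AMOVA
Phi-ST. The squared inter-individual distance is the count of
nucleotide differences over pairwise-complete positions (no gamma or
Tamura-Nei correction; raw mismatch counts). With

    SS_total  = (1/N) * sum_{i<j} d2_ij          (all N individuals)
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d2_ij

the variance components are sigma2_w = SS_within / (N - G) and
sigma2_a = (MS_among - sigma2_w) / n' with
n' = (N - sum_g n_g^2 / N)/(G - 1), and
Phi_ST = sigma2_a / (sigma2_a + sigma2_w). Estimates may be slightly
negative by sampling noise and are retained unclamped in distance
matrices; before Slatkin linearization fst/(1 - fst) they are clamped to
zero, since the linearized value is a divergence-time proxy and a
negative estimate has no such interpretation. Significance comes from
permuting individuals between the two groups with sizes held fixed,
using the add-one estimator p = (1 + hits)/(1 + n_permutations) so p is
never exactly zero; the default is 100,000 permutations so p < 1e-5 is
resolvable. If the pooled sequences are all identical the test is
degenerate and p = 1 is returned with a warning. Permutation streams
are seeded per population pair.

## Shared haplogroup distance (SHD)

SHD between populations A and B is one minus the overlap of their
terminal sub-haplogroup frequency distributions:

    SHD = 1 - sum_h min(f_A(h), f_B(h))

Symmetric, in [0, 1], zero for identical profiles and one for disjoint
terminal sub-haplogroup sets; 1 - SHD equals one minus the total
variation distance between the two distributions. The sum-of-minima
form is this package's explicit definition of "frequency of identical
terminal sub-haplogroups"; published SHD figures computed with other
overlap conventions can differ in the second decimal (an SHD of 0.85
has been glossed as a 14% rather than 15% common gene pool), so exact
cross-tool comparisons should verify the formula in use.

Note that the plug-in estimator sum_h min(f̂_A, f̂_B) is biased
downward by roughly E|f̂_A(h) - f̂_B(h)|/2 per shared haplogroup
(~0.7 percentage points per shared class at n = 500 and f = 0.07); at
realistic sample sizes this bias is well inside the multinomial noise
band, and the recovery experiments below quantify it empirically.

## Ordination

PCA operates on the populations x 34 major-class frequency matrix:
columns are centered but not scaled (frequencies already share a scale,
and scaling would inflate rare classes), scores come from the SVD, and
per-axis explained variance fractions are reported. Classical
(Torgerson) MDS double-centers -1/2 J D^2 J, eigendecomposes, and keeps
the top-k nonnegative eigenvalues with coordinates
sqrt(eigenvalue) * eigenvector; negative eigenvalues (non-Euclidean
input, common for linearized-Fst matrices) are dropped with a warning
listing their magnitudes, and an error is raised if no positive
eigenvalue exists. Both fix axis signs by making each axis's
largest-magnitude loading (or coordinate) positive, so repeated runs are
bit-identical.

## Median-joining networks

Haplotypes are first condensed: identical sequences (under the kinship
identity rule) are grouped with multiplicities, and only columns that
are variable among classes and resolved in every sample are retained —
character states are restricted to {A, C, G, T}. Since the identity
relation is not transitive under missing data, grouping is greedy in
input order against each class's representative, which is deterministic
and documented rather than hidden.

Construction then iterates: (1) the epsilon-relaxed minimum spanning
network (a link is kept iff its weight is within epsilon of the minimax
path cost between its endpoints; epsilon defaults to 0, the conservative
standard); (2) quasi-medians of every triplet with at least two of its
three links present (majority state per column; columns where all three
states differ spawn each of the three); (3) the candidate median that
most reduces total network length is added and the spanning network
recomputed, until no candidate reduces it; (4) inferred nodes of degree
<= 2 whose removal changes no observed-pair shortest path are pruned.
All tie-breaks are lexicographic. A cap (default 10,000) on quasi-median
candidates guards against the exponential closure of pathological
inputs; exceeding it is a hard error, not silent truncation. Mutation
weighting is uniform (no transition/transversion weighting); both
epsilon and the cap are configurable.

One structural subtlety: recomputing the spanning network after a
median insertion can legitimately drop a long link between two observed
haplotypes, and their shortest path through the final network can then
exceed their path in the observed-only spanning network. This is
inherent to the construction (the canonical three-haplotype example —
pairwise distance 2, disjoint variants — resolves to a pure median star
of total length 3, containing none of the original weight-2 links), so
the guaranteed invariants are the ones tested: total length never
exceeds the observed spanning network's, every surviving link is a
spanning link of the surviving node set, path lengths respect the
Hamming metric, and medians come from the quasi-median closure.

## Synthetic data

The generators produce data with exactly the structure the statistics
assume, so parameter recovery is checkable against closed forms.

* `simulate_shared_pair(s, n, config)` builds two haplogroup profiles
  whose terminal-haplogroup distributions have sum-of-minima overlap
  exactly `s`: a shared block of haplogroups with matched frequencies
  totalling `s` (two classes by default) and disjoint private blocks
  totalling `1 - s` each (three classes per side). Profile-level SHD is
  exactly `1 - s`; sample-level SHD fluctuates with multinomial noise
  of order sqrt(s(1-s)/n).
* `simulate_divergent_demes(k, within, between, n, config)` gives each
  deme a founder carrying `between` deme-private variants and each
  individual Poisson(`within`) private variants. Expected pairwise
  differences are 2*within (within demes) and 2*between + 2*within
  (between demes), so sigma2_a = between, sigma2_w = within and the
  expected Phi-ST is between/(between + within); `within = 0` yields
  exactly 1 and `between = 0` fluctuates around 0.

Every mutation hits a previously unused position (infinite-sites
approximation), which is what makes distances additive and the
expectations exact. The default reference length is 2,000 (hundreds of
free positions at these rates; full 16,569-scale generation is a flag
away), the default private-mutation rate is 1 per lineage — the order
of private variation seen between mitogenomes within a terminal
sub-haplogroup. Not emulated, deliberately: transition/transversion
bias, mutational hotspots, rate heterogeneity, ancient-DNA damage, and
coalescent genealogy within demes. Passing recovery tests therefore
demonstrates correctness of the estimators under their own model
assumptions, not robustness to real-data artefacts.

The recovery experiments run at study scale: the shared-fraction design
uses s = 0.14 (the shared-gene-pool magnitude reported for the
commoner/elite comparison) with n = 500 per population and 200
replicates; the Phi-ST design uses between = 10, within = 1 (expected
0.909) at 20 + 20 individuals. The worked-example summaries run on the
published per-cemetery classification counts (n = 26-182), recovered
from the printed percentages by unique-integer inversion; where a
printed aggregate spans several classes, the split is a representative
choice whose sum matches the aggregate.

## Known limitations

* SHD treats terminal sub-haplogroups as atoms: two populations fixed
  for sister clades one mutation apart have SHD 1, the same as two
  populations from different continents.
* The AMOVA here is strictly two-group; hierarchical designs (groups of
  populations) are out of scope.
* Region assignment quality is bounded by the reference panel; the
  package ships no curated panel and makes no claim about panel
  completeness.
* The permutation test assumes exchangeability of individuals under the
  null; structured missingness that correlates with population would
  violate it.
* Median-joining networks are exponential in the worst case; the
  candidate cap makes failure explicit rather than slow.
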