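"""Median-joining haplotype networks.

The median-joining construction connects observed haplotypes through an
epsilon-relaxed minimum-spanning network (MSN) and augments it with
inferred intermediate sequences ("median vectors"): consensus-like
haplotypes that shorten the network, standing in for unsampled or extinct
lineages.  The resulting graph supports phylogeographic placement — a
query lineage inherits the region of its nearest annotated neighbours.

Construction, given condensed haplotypes (identical sequences grouped,
invariant columns dropped):

1. Build the epsilon-relaxed MSN: a link (u, v) is included iff its weight
   (Hamming distance) is within epsilon of the minimax-path cost between u
   and v, i.e. ``d(u, v) <= sigma(u, v) + epsilon``.  With epsilon = 0 this
   is the classical MSN, the union of all minimum spanning trees.
2. For every triplet of nodes with at least two of its three links in the
   current network, generate quasi-median candidates: per column, the
   majority state; columns where all three states differ spawn every
   combination of the three observed states.
3. Add the candidate median vector that most reduces the total network
   length (sum of link weights of the recomputed MSN); repeat 1-3 until no
   candidate reduces the length.
4. Prune obsolete median vectors: inferred nodes of degree <= 2 whose
   removal changes no shortest-path distance between observed haplotypes.

All tie-breaks are lexicographic, so the network is deterministic given
the input order.  Character states are restricted to {A, C, G, T}; columns
with missing data in any sample are excluded from the condensed alignment
before network building.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .core import MISSING_CHARS, RegionClass, Sample

#: Default cap on quasi-median candidates per construction (the closure is
#: finite but can explode exponentially on pathological inputs).
DEFAULT_MEDIAN_CAP = 10_000


@dataclass
class HaplotypeClass:
    """A condensed haplotype: one distinct sequence and its carriers."""

    states: tuple[str, ...]  # one state per retained column
    members: tuple[str, ...]  # sample ids
    representative_id: str

    @property
    def multiplicity(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    """A median-joining network over condensed haplotypes.

    ``graph`` is an undirected networkx graph whose nodes carry attributes
    ``kind`` ("observed" | "median"), ``states`` (tuple of characters over
    the condensed columns), ``multiplicity`` and ``members``; edges carry
    ``weight`` (Hamming distance of endpoint states) and ``positions``
    (the 1-based reference positions that mutate along the edge).
    """

    graph: nx.Graph
    columns: tuple[int, ...]  # 1-based reference positions of the retained columns
    epsilon: int = 0

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def total_length(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def _hamming(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def condense_haplotypes(
    samples: list[Sample], reference: str
) -> tuple[list[HaplotypeClass], tuple[int, ...]]:
    """Group samples into haplotype classes and drop uninformative columns.

    Columns retained are those variable among the classes and resolved
    (A/C/G/T) in *every* sample; missing positions are excluded before
    network building.  Grouping uses the same identity rule as kinship
    screening: a sample joins the first class whose representative it
    matches (identical variant sets, neither blind at the other's variant
    sites).  Returns the classes and the 1-based positions of the retained
    columns.
    """
    from .kinship import _identical_haplotypes  # same identity relation

    for s in samples:
        if s.sequence is None:
            raise ValueError(f"sample {s.sample_id!r} has no sequence")
        if len(s.sequence) != len(reference):
            raise ValueError(f"sample {s.sample_id!r}: sequence/reference length mismatch")

    groups: list[list[Sample]] = []
    for s in samples:
        for group in groups:
            if _identical_haplotypes(
                s.sequence, group[0].sequence, reference, frozenset()
            ):
                group.append(s)
                break
        else:
            groups.append([s])

    length = len(reference)
    # columns resolved everywhere...
    resolved = [
        all(s.sequence[i] not in MISSING_CHARS for s in samples) for i in range(length)
    ]
    # ...and variable across group representatives
    columns = []
    for i in range(length):
        if not resolved[i]:
            continue
        states = {g[0].sequence[i] for g in groups}
        if len(states) > 1:
            columns.append(i + 1)

    classes = [
        HaplotypeClass(
            states=tuple(g[0].sequence[c - 1] for c in columns),
            members=tuple(s.sample_id for s in g),
            representative_id=g[0].sample_id,
        )
        for g in groups
    ]
    return classes, tuple(columns)


def _minimax_costs(seqs: list[tuple[str, ...]]) -> list[list[int]]:
    """sigma(u, v): the minimax-path (MST connection) cost between all pairs."""
    n = len(seqs)
    sigma = [[_hamming(seqs[i], seqs[j]) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            sik = sigma[i][k]
            row = sigma[i]
            rowk = sigma[k]
            for j in range(n):
                alt = sik if sik > rowk[j] else rowk[j]
                if alt < row[j]:
                    row[j] = alt
    return sigma


def _msn_links(seqs: list[tuple[str, ...]], epsilon: int) -> list[tuple[int, int, int]]:
    """Links of the epsilon-relaxed minimum spanning network as (i, j, weight)."""
    n = len(seqs)
    sigma = _minimax_costs(seqs)
    links = []
    for i in range(n):
        for j in range(i + 1, n):
            d = _hamming(seqs[i], seqs[j])
            if d <= sigma[i][j] + epsilon:
                links.append((i, j, d))
    # reproducible order: by (weight, smaller index, larger index)
    links.sort(key=lambda t: (t[2], t[0], t[1]))
    return links


def _msn_total_length(seqs: list[tuple[str, ...]], epsilon: int) -> int:
    return sum(w for _, _, w in _msn_links(seqs, epsilon))


def _quasi_medians(
    u: tuple[str, ...], v: tuple[str, ...], w: tuple[str, ...], cap: int
) -> list[tuple[str, ...]]:
    """Quasi-median sequences of a triplet: majority state per column;
    three-state columns spawn all combinations of the observed states."""
    fixed: list[str | None] = []
    open_columns: list[tuple[int, tuple[str, str, str]]] = []
    for idx, states in enumerate(zip(u, v, w)):
        a, b, c = states
        if a == b or a == c:
            fixed.append(a)
        elif b == c:
            fixed.append(b)
        else:
            fixed.append(None)
            open_columns.append((idx, states))
    n_combos = 3 ** len(open_columns)
    if n_combos > cap:
        raise RuntimeError(
            f"quasi-median explosion: {n_combos} candidates from one triplet "
            f"exceeds the cap of {cap}"
        )
    medians = []
    for combo in itertools.product(*(states for _, states in open_columns)):
        seq = list(fixed)
        for (idx, _), state in zip(open_columns, combo):
            seq[idx] = state
        medians.append(tuple(seq))  # type: ignore[arg-type]
    return medians


def build_mj_network(
    haplotypes: list[HaplotypeClass],
    columns: tuple[int, ...],
    epsilon: int = 0,
    median_cap: int = DEFAULT_MEDIAN_CAP,
) -> HaplotypeNetwork:
    """Median-joining network over condensed haplotype classes.

    Observed nodes are named ``H1..Hk`` (input order), inferred median
    vectors ``mv1..``.  See the module docstring for the construction.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if len(haplotypes) < 2:
        raise ValueError("need at least 2 haplotype classes to build a network")

    seqs: list[tuple[str, ...]] = [h.states for h in haplotypes]
    n_observed = len(seqs)
    seen: set[tuple[str, ...]] = set(seqs)

    while True:
        links = _msn_links(seqs, epsilon)
        total = sum(w for _, _, w in links)
        adjacency: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
        for i, j, _ in links:
            adjacency[i].add(j)
            adjacency[j].add(i)

        candidates: set[tuple[str, ...]] = set()
        for a in range(len(seqs)):
            for b in range(a + 1, len(seqs)):
                for c in range(b + 1, len(seqs)):
                    n_links = (
                        (b in adjacency[a]) + (c in adjacency[a]) + (c in adjacency[b])
                    )
                    if n_links < 2:
                        continue
                    for m in _quasi_medians(seqs[a], seqs[b], seqs[c], median_cap):
                        if m not in seen:
                            candidates.add(m)
                    if len(candidates) > median_cap:
                        raise RuntimeError(
                            f"quasi-median closure exceeds the cap of {median_cap} candidates"
                        )

        best_seq: tuple[str, ...] | None = None
        best_total = total
        for cand in sorted(candidates):
            cand_total = _msn_total_length(seqs + [cand], epsilon)
            if cand_total < best_total or (
                cand_total == best_total and best_seq is not None and cand < best_seq
            ):
                best_total = cand_total
                best_seq = cand
        if best_seq is None or best_total >= total:
            break
        seqs.append(best_seq)
        seen.add(best_seq)

    # assemble the graph from the final MSN
    names = [f"H{i + 1}" for i in range(n_observed)] + [
        f"mv{i + 1}" for i in range(len(seqs) - n_observed)
    ]
    graph = nx.Graph()
    for idx, name in enumerate(names):
        if idx < n_observed:
            h = haplotypes[idx]
            graph.add_node(
                name,
                kind="observed",
                states=seqs[idx],
                multiplicity=h.multiplicity,
                members=h.members,
            )
        else:
            graph.add_node(name, kind="median", states=seqs[idx], multiplicity=0, members=())
    for i, j, weight in _msn_links(seqs, epsilon):
        positions = tuple(
            columns[k] for k, (x, y) in enumerate(zip(seqs[i], seqs[j])) if x != y
        )
        graph.add_edge(names[i], names[j], weight=weight, positions=positions)

    _prune_obsolete_medians(graph)
    return HaplotypeNetwork(graph=graph, columns=columns, epsilon=epsilon)


def _prune_obsolete_medians(graph: nx.Graph) -> None:
    """Remove median vectors of degree <= 2 that support no shortest path
    between observed nodes."""
    observed = [n for n, d in graph.nodes(data=True) if d["kind"] == "observed"]
    changed = True
    while changed:
        changed = False
        for node in sorted(n for n, d in graph.nodes(data=True) if d["kind"] == "median"):
            if graph.degree(node) > 2:
                continue
            trial = graph.copy()
            trial.remove_node(node)
            if not all(nx.has_path(trial, u, v) for u, v in itertools.combinations(observed, 2)):
                continue
            before = dict(nx.all_pairs_dijkstra_path_length(graph, weight="weight"))
            after = dict(nx.all_pairs_dijkstra_path_length(trial, weight="weight"))
            if all(
                after[u][v] <= before[u][v]
                for u, v in itertools.combinations(observed, 2)
            ):
                graph.remove_node(node)
                changed = True
                break


def network_nearest_regions(
    network: HaplotypeNetwork,
    query: str,
    annotations: dict[str, RegionClass],
) -> RegionClass:
    """Region of the annotated observed node(s) nearest to ``query``.

    Nearness is cumulative edge weight (Dijkstra).  A query that is itself
    annotated returns its own region.  An equidistant tie across different
    regions yields the generic :attr:`RegionClass.EURASIA`.
    ``annotations`` maps observed node names (or member sample ids) to
    regions.
    """
    graph = network.graph
    if query not in graph:
        raise ValueError(f"query node {query!r} is not in the network")

    node_region: dict[str, RegionClass] = {}
    for node, data in graph.nodes(data=True):
        if data["kind"] != "observed":
            continue
        if node in annotations:
            node_region[node] = annotations[node]
        else:
            member_regions = {
                annotations[m] for m in data["members"] if m in annotations
            }
            if len(member_regions) == 1:
                node_region[node] = next(iter(member_regions))
            elif len(member_regions) > 1:
                node_region[node] = RegionClass.EURASIA
    if not node_region:
        raise ValueError("no annotated observed nodes in the network")

    if query in node_region:
        return node_region[query]

    lengths = nx.single_source_dijkstra_path_length(graph, query, weight="weight")
    reachable = {n: d for n, d in lengths.items() if n in node_region and n != query}
    if not reachable:
        raise ValueError("no annotated observed node is reachable from the query")
    best = min(reachable.values())
    regions = {node_region[n] for n, d in reachable.items() if d == best}
    if len(regions) == 1:
        return next(iter(regions))
    return RegionClass.EURASIA


def network_edge_table(network: HaplotypeNetwork):
    """Edge list as (node_a, node_b, weight, positions) rows."""
    import pandas as pd

    rows = [
        {
            "node_a": u,
            "node_b": v,
            "weight": d["weight"],
            "positions": ",".join(str(p) for p in d["positions"]),
        }
        for u, v, d in sorted(network.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "positions"])


def network_node_table(network: HaplotypeNetwork):
    """Node list as (node, kind, multiplicity, members) rows."""
    import pandas as pd

    rows = [
        {
            "node": n,
            "kind": d["kind"],
            "multiplicity": d["multiplicity"],
            "members": ",".join(d["members"]),
        }
        for n, d in sorted(network.graph.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=["node", "kind", "multiplicity", "members"])


def write_network(network: HaplotypeNetwork, prefix: str) -> None:
    """Write edge-list TSV, node-table TSV and GML exports of the network."""
    network_edge_table(network).to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)
    network_node_table(network).to_csv(f"{prefix}.nodes.tsv", sep="\t", index=False)
    export = nx.Graph()
    for n, d in network.graph.nodes(data=True):
        export.add_node(
            n,
            kind=d["kind"],
            multiplicity=d["multiplicity"],
            members=",".join(d["members"]),
            states="".join(d["states"]),
        )
    for u, v, d in network.graph.edges(data=True):
        export.add_edge(u, v, weight=d["weight"], positions=",".join(map(str, d["positions"])))
    nx.write_gml(export, f"{prefix}.gml")
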