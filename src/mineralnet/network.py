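"""Bipartite mineral–element chemistry networks.

A network has mineral nodes and element nodes; each mineral is joined by an
unweighted edge to every element in its ideal formula (chalcopyrite CuFeS2
has exactly three edges, to Cu, Fe and S).  Networks may be restricted to
the minerals containing at least one *focal* element and/or to minerals
whose maximum known age meets an age threshold in Ga, which yields the
time-sliced "network at >T Ga" views.

Community structure is found with the Louvain modularity heuristic applied
to the bipartite graph directly (mineral and element nodes are partitioned
together); the reported modularity is independently recomputable Newman
modularity, and community ids are canonicalized by descending size so runs
are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd

from .elements import MineralRecord

__all__ = [
    "BipartiteNetwork",
    "CommunityPartition",
    "DEFAULT_LOUVAIN_SEED",
    "DEFAULT_LOUVAIN_RESOLUTION",
    "build_network",
    "is_fully_connected",
    "detect_communities",
    "count_minerals_with_elements",
    "containment_fraction",
    "export_network",
    "import_graphml",
]

#: arbitrary fixed constant so community detection is reproducible by default
DEFAULT_LOUVAIN_SEED: int = 7140
DEFAULT_LOUVAIN_RESOLUTION: float = 1.0


@dataclass(frozen=True)
class BipartiteNetwork:
    """An immutable bipartite mineral–element graph with provenance."""

    element_nodes: frozenset[str]
    mineral_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (mineral id, element symbol)
    mineral_ages: dict[str, float | None]
    age_threshold_ga: float | None = None
    focal_elements: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for mineral, element in self.edges:
            if mineral not in self.mineral_nodes or element not in self.element_nodes:
                raise ValueError(f"edge ({mineral!r}, {element!r}) has a missing endpoint")
        touched_m = {m for m, _ in self.edges}
        touched_e = {e for _, e in self.edges}
        if touched_m != set(self.mineral_nodes) or touched_e != set(self.element_nodes):
            raise ValueError("orphan nodes: every node must have degree >= 1")

    @property
    def n_nodes(self) -> int:
        return len(self.element_nodes) + len(self.mineral_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        """Unipartite view: one Graph holding both node types."""
        g = nx.Graph()
        for e in sorted(self.element_nodes):
            g.add_node(e, node_type="element")
        for m in sorted(self.mineral_nodes):
            age = self.mineral_ages.get(m)
            if age is None:
                g.add_node(m, node_type="mineral")
            else:
                g.add_node(m, node_type="mineral", max_age_ga=float(age))
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class CommunityPartition:
    """A node → community assignment with its (recomputable) modularity."""

    assignment: dict[str, int]
    modularity: float
    seed: int
    resolution: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


def build_network(
    minerals: Iterable[MineralRecord],
    focal_elements: Iterable[str] | None = None,
    min_age_ga: float | None = None,
    strict_age: bool = False,
) -> BipartiteNetwork:
    """Build the bipartite network of the selected minerals.

    A mineral is included iff it contains at least one focal element (all
    minerals qualify when ``focal_elements`` is None) and, when an age
    threshold is given, its maximum known age meets it (``>=`` by default;
    ``strict_age=True`` switches to ``>``).  Minerals without an age are
    excluded from any thresholded network.  Element nodes are exactly the
    constituent elements of the included minerals.
    """
    focal = frozenset(focal_elements) if focal_elements is not None else None
    included: list[MineralRecord] = []
    for m in minerals:
        if focal is not None and not (m.elements & focal):
            continue
        if min_age_ga is not None:
            if m.max_age_ga is None:
                continue
            if strict_age and not m.max_age_ga > min_age_ga:
                continue
            if not strict_age and not m.max_age_ga >= min_age_ga:
                continue
        included.append(m)
    if focal is not None and not included:
        warnings.warn(
            f"no minerals match focal elements {sorted(focal)}; network is empty",
            stacklevel=2,
        )
    edges = frozenset((m.name, e) for m in included for e in m.elements)
    return BipartiteNetwork(
        element_nodes=frozenset(e for _, e in edges),
        mineral_nodes=frozenset(m.name for m in included),
        edges=edges,
        mineral_ages={m.name: m.max_age_ga for m in included},
        age_threshold_ga=min_age_ga,
        focal_elements=focal,
    )


def is_fully_connected(network: BipartiteNetwork) -> bool:
    """True iff one connected component spans all nodes."""
    if network.n_nodes == 0:
        raise ValueError("connectivity is undefined for an empty network")
    return nx.is_connected(network.to_networkx())


def _canonicalize(communities: list[set[str]]) -> dict[str, int]:
    """Relabel communities by descending size, ties by smallest member."""
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {node: i for i, comm in enumerate(ordered) for node in comm}


def detect_communities(
    network: BipartiteNetwork,
    seed: int = DEFAULT_LOUVAIN_SEED,
    resolution: float = DEFAULT_LOUVAIN_RESOLUTION,
) -> CommunityPartition:
    """Louvain communities on the (unweighted) bipartite graph.

    Deterministic for a given seed.  Disconnected networks are allowed; a
    single-node network gets the trivial partition with a warning.
    """
    g = network.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    if g.number_of_nodes() == 1:
        warnings.warn("single-node network: trivial partition", stacklevel=2)
        return CommunityPartition(
            assignment={next(iter(g.nodes)): 0}, modularity=0.0, seed=seed, resolution=resolution
        )
    communities = nx.community.louvain_communities(g, resolution=resolution, seed=seed)
    modularity = nx.community.modularity(g, communities)
    return CommunityPartition(
        assignment=_canonicalize([set(c) for c in communities]),
        modularity=float(modularity),
        seed=seed,
        resolution=resolution,
    )


def count_minerals_with_elements(
    minerals: Iterable[MineralRecord], required: Iterable[str]
) -> int:
    """Number of minerals whose element set contains every required element."""
    req = frozenset(required)
    if not req:
        raise ValueError("required element set must be non-empty")
    return sum(1 for m in minerals if req <= m.elements)


def containment_fraction(
    minerals: Iterable[MineralRecord], of_element: str, containing: str
) -> float:
    """Fraction of ``of_element``-containing minerals that also contain
    ``containing`` (e.g. the share of C minerals that carry H)."""
    have = [m for m in minerals if of_element in m.elements]
    if not have:
        raise KeyError(f"element {of_element!r} not present in any mineral")
    return sum(1 for m in have if containing in m.elements) / len(have)


def export_network(
    network: BipartiteNetwork,
    path: str | Path,
    partition: CommunityPartition | None = None,
    format: Literal["graphml", "edgelist"] = "graphml",
) -> Path:
    """Write the network to GraphML (with node attributes) or edge-list TSV.

    GraphML nodes carry ``node_type``, ``max_age_ga`` (dated minerals) and,
    when a partition is given, ``community``.  The edge list has columns
    ``mineral_id`` and ``element_symbol``.
    """
    path = Path(path)
    if format == "graphml":
        g = network.to_networkx()
        if partition is not None:
            nx.set_node_attributes(g, partition.assignment, "community")
        nx.write_graphml(g, path)
    elif format == "edgelist":
        df = pd.DataFrame(sorted(network.edges), columns=["mineral_id", "element_symbol"])
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def import_graphml(path: str | Path) -> BipartiteNetwork:
    """Reconstruct a :class:`BipartiteNetwork` from an exported GraphML file."""
    g = nx.read_graphml(path)
    elements = frozenset(n for n, d in g.nodes(data=True) if d.get("node_type") == "element")
    minerals = frozenset(n for n, d in g.nodes(data=True) if d.get("node_type") == "mineral")
    if elements | minerals != set(g.nodes):
        raise ValueError("GraphML file lacks node_type attributes")
    edges = frozenset((a, b) if a in minerals else (b, a) for a, b in g.edges())
    ages = {
        n: (float(d["max_age_ga"]) if "max_age_ga" in d else None)
        for n, d in g.nodes(data=True)
        if n in minerals
    }
    return BipartiteNetwork(
        element_nodes=elements, mineral_nodes=minerals, edges=edges, mineral_ages=ages
    )
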