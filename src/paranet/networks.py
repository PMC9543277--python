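"""Per-cell potential networks and their complexity metrics.

For each grid cell, the *potential network* is the bipartite graph whose
edges are the globally documented parasite-host interactions between
species both present in that cell ("potential" because co-occurrence plus
a documented interaction somewhere does not guarantee local parasitism).

The complexity statistic is linkage density: the number of interactions
divided by the number of species in the network.  A species is in the
network only if it is incident to at least one edge — a host that
co-occurs with no documented parasite of its own contributes nothing.
Under this convention the minimum over non-empty networks is 0.5 (one
parasite, one host, one interaction) and a complete 2x2 network scores
1.0.  Note that "linkage density" for *weighted* networks in the
bipartite-network literature is a different (marginal-weighted) quantity;
the binary ratio interactions/species is what is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .grid import Grid
from .interactions import InteractionTable
from .ranges import PresenceMatrix

TOPOLOGY_CLASSES = ("empty", "one_to_one", "one_to_many", "many_to_one", "many_to_many")


class UndefinedMetricError(ValueError):
    """Metric requested on an empty network."""


@dataclass(frozen=True)
class CellNetwork:
    """The potential bipartite network of one grid cell."""

    cell_id: str
    edges: frozenset[tuple[str, str]]

    @property
    def parasite_nodes(self) -> set[str]:
        return {p for p, _ in self.edges}

    @property
    def host_nodes(self) -> set[str]:
        return {h for _, h in self.edges}

    @property
    def n_interactions(self) -> int:
        return len(self.edges)

    @property
    def n_species(self) -> int:
        # a species acting as both parasite and host is counted once
        return len(self.parasite_nodes | self.host_nodes)

    def graph(self) -> nx.Graph:
        """The network as a bipartite networkx graph (for diagnostics)."""
        g = nx.Graph()
        g.add_nodes_from(self.parasite_nodes, bipartite="parasite")
        g.add_nodes_from(self.host_nodes, bipartite="host")
        g.add_edges_from(self.edges)
        return g


def cell_network(
    cell_id: str, presence: PresenceMatrix, table: InteractionTable
) -> CellNetwork:
    """Filter the global edge list to species co-present in one cell."""
    if cell_id not in presence._cell_index:
        raise KeyError(f"unknown cell_id {cell_id!r}")
    local = presence.species_in_cell(cell_id)
    edges = frozenset(
        (p, h) for p, h in table.edges if p in local and h in local
    )
    return CellNetwork(cell_id, edges)


def linkage_density(net: CellNetwork) -> float:
    """Interactions divided by species; undefined for an empty network."""
    if net.n_interactions == 0:
        raise UndefinedMetricError(
            f"linkage density undefined for empty network in cell {net.cell_id!r}"
        )
    return net.n_interactions / net.n_species


def classify_topology(net: CellNetwork) -> str:
    """Classify by whole-network parasite/host node counts.

    one_to_one: 1 parasite, 1 host; one_to_many: 1 parasite, several hosts;
    many_to_one: several parasites, 1 host; many_to_many: several of both.
    Classification is at whole-network level (two disjoint 1-1 pairs make
    a many_to_many network); see component_topologies for the per-component
    breakdown.
    """
    p, h = len(net.parasite_nodes), len(net.host_nodes)
    if p == 0 or h == 0:
        return "empty"
    if p == 1:
        return "one_to_one" if h == 1 else "one_to_many"
    return "many_to_one" if h == 1 else "many_to_many"


def component_topologies(net: CellNetwork) -> list[str]:
    """Topology class of each connected component (secondary diagnostic)."""
    if not net.edges:
        return []
    g = net.graph()
    out = []
    for comp in nx.connected_components(g):
        sub = CellNetwork(
            net.cell_id,
            frozenset((p, h) for p, h in net.edges if p in comp and h in comp),
        )
        out.append(classify_topology(sub))
    return out


def complexity_table(
    grid: Grid,
    presence: PresenceMatrix,
    table: InteractionTable,
    all_bird_presence: PresenceMatrix | None = None,
) -> pd.DataFrame:
    """One row per grid cell with network metrics; the regression input.

    Columns: cell_id, linkage_density (NaN where the network is empty —
    never coerced to 0), linkage_density_1dp, parasite_richness,
    host_richness, optional total_bird_richness, topology_class,
    n_interactions, n_species.  Richness counts species *present* in the
    cell (whether or not they enter the network), restricted to species
    appearing in the interaction table.
    """
    parasites = sorted(table.parasite_ids & set(presence.species_ids))
    hosts = sorted(table.host_ids & set(presence.species_ids))
    from .ranges import richness  # local import to avoid cycle

    p_rich = richness(presence, parasites)
    h_rich = richness(presence, hosts)
    rows = []
    for cell in grid.cells:
        net = cell_network(cell.cell_id, presence, table)
        ld = linkage_density(net) if net.n_interactions else np.nan
        rows.append(
            {
                "cell_id": cell.cell_id,
                "linkage_density": ld,
                "linkage_density_1dp": round(ld, 1) if np.isfinite(ld) else np.nan,
                "parasite_richness": int(p_rich[cell.cell_id]),
                "host_richness": int(h_rich[cell.cell_id]),
                "topology_class": classify_topology(net),
                "n_interactions": net.n_interactions,
                "n_species": net.n_species,
            }
        )
    df = pd.DataFrame(rows)
    if all_bird_presence is not None:
        total = richness(all_bird_presence, all_bird_presence.species_ids)
        df["total_bird_richness"] = df["cell_id"].map(total).astype(int)
    return df
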