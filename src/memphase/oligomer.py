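"""Peptide oligomer detection and size distributions.

At high surface densities chance contacts are frequent, so clustering is not
simple single-linkage on a distance cutoff.  A 0.6 nm neighborhood graph
between backbone beads of distinct peptides feeds three rules: (i) two
peptides establish a cluster if at least three of each peptide's backbone
beads are neighbors of the other's; (ii) a peptide joins a cluster if at
least three of its beads contact at least three distinct cluster beads
(pooled across cluster members); (iii) clusters sharing peptides merge.
Side-by-side oligomers therefore count while weakly bound T-shaped encounters
do not.  Size distributions are reported as the fraction of all peptides in
clusters of each order, not as cluster counts, which would visually inflate
low orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import SeriesStats, corrected_bootstrap
from .trajio import Frame
from .energetics import neighbor_pairs

__all__ = [
    "ClusterSet",
    "OligomerDistribution",
    "backbone_contact_graph",
    "find_clusters",
    "size_distribution",
]


@dataclass
class ClusterSet:
    """Partition of the frame's peptides into oligomers (singletons included)."""

    clusters: list[frozenset[int]]
    time: float = 0.0

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters overlap; not a partition")
            seen |= c

    def order_of(self, peptide_id: int) -> int:
        for c in self.clusters:
            if peptide_id in c:
                return len(c)
        raise KeyError(peptide_id)

    def peptides(self) -> set[int]:
        return set().union(*self.clusters) if self.clusters else set()


def backbone_contact_graph(frame: Frame, cutoff: float = 0.6) -> nx.Graph:
    """Bead-level adjacency between backbone beads of distinct peptides.

    Nodes are bead indices annotated with their peptide molecule id; edges
    connect beads of different peptides within ``cutoff`` (minimum image).
    """
    classes = frame.classes()
    pep = np.flatnonzero(classes == "peptide")
    bb = pep[frame.names[pep] == "BB"]
    g = nx.Graph()
    for i in bb:
        g.add_node(int(i), peptide=int(frame.molecule_ids[i]))
    if len(bb) == 0:
        return g
    ii, jj = neighbor_pairs(frame, bb, bb, cutoff)
    for a, b in zip(ii, jj):
        if frame.molecule_ids[a] != frame.molecule_ids[b]:
            g.add_edge(int(a), int(b))
    return g


def _contact_counts(g: nx.Graph, beads_a: list[int], beads_b: set[int]
                    ) -> tuple[int, int]:
    """(#beads of A touching B, #distinct beads of B touched)."""
    touching = 0
    touched: set[int] = set()
    for bead in beads_a:
        nb = set(g.adj[bead]) & beads_b
        if nb:
            touching += 1
            touched |= nb
    return touching, len(touched)


def find_clusters(g: nx.Graph, frame: Frame, min_contacts: int = 3,
                  pooled_rule: bool = True) -> ClusterSet:
    """Partition peptides into clusters under the three contact rules.

    Seeds come from peptide pairs with >= ``min_contacts`` contacting beads
    on *each* side (rule i, which automatically excludes peptides shorter
    than three backbone beads); unseeded peptides then accrete onto clusters
    when >= 3 of their beads touch >= 3 distinct cluster beads (rule ii,
    cluster beads pooled across members; set ``pooled_rule`` False for the
    looser per-bead-count-only reading), iterating to a fixed point in
    ascending molecule-id order for determinism; clusters sharing peptides
    merge (rule iii).  Everything else is a singleton.
    """
    beads_of: dict[int, list[int]] = {}
    for bead, data in g.nodes(data=True):
        beads_of.setdefault(data["peptide"], []).append(bead)
    classes = frame.classes()
    pep_idx = np.flatnonzero(classes == "peptide")
    all_peptides = sorted(int(m) for m in np.unique(frame.molecule_ids[pep_idx]))
    for p in all_peptides:
        beads_of.setdefault(p, [])

    # rule (i): pairwise seeds, merged by rule (iii) via connected components
    seed_graph = nx.Graph()
    seed_graph.add_nodes_from(all_peptides)
    pairs_checked: set[tuple[int, int]] = set()
    for a, b in g.edges:
        pa, pb = g.nodes[a]["peptide"], g.nodes[b]["peptide"]
        key = (min(pa, pb), max(pa, pb))
        if key in pairs_checked:
            continue
        pairs_checked.add(key)
        na, _ = _contact_counts(g, beads_of[pa], set(beads_of[pb]))
        nb, _ = _contact_counts(g, beads_of[pb], set(beads_of[pa]))
        if na >= min_contacts and nb >= min_contacts:
            seed_graph.add_edge(pa, pb)

    clusters = [set(c) for c in nx.connected_components(seed_graph) if len(c) > 1]
    in_cluster = set().union(*clusters) if clusters else set()

    # rule (ii): accrete remaining peptides until a fixed point
    changed = True
    while changed:
        changed = False
        for p in all_peptides:
            if p in in_cluster:
                continue
            for c in clusters:
                cluster_beads = set()
                for q in c:
                    cluster_beads.update(beads_of[q])
                touching, touched = _contact_counts(g, beads_of[p], cluster_beads)
                ok = (touching >= min_contacts and
                      (touched >= min_contacts or not pooled_rule))
                if ok:
                    c.add(p)
                    in_cluster.add(p)
                    changed = True
                    break
        if changed:
            # rule (iii) again: accretion may have bridged clusters
            merge = nx.Graph()
            for ci, c in enumerate(clusters):
                merge.add_node(ci)
            for p in in_cluster:
                owners = [ci for ci, c in enumerate(clusters) if p in c]
                for a, b in zip(owners, owners[1:]):
                    merge.add_edge(a, b)
            clusters = [set().union(*(clusters[ci] for ci in comp))
                        for comp in nx.connected_components(merge)]

    singles = [frozenset({p}) for p in all_peptides if p not in in_cluster]
    return ClusterSet(clusters=[frozenset(c) for c in clusters] + singles,
                      time=frame.time)


@dataclass
class OligomerDistribution:
    """Time-averaged fraction of all peptides per oligomer order."""

    table: pd.DataFrame           # order, fraction, ci_low, ci_high
    per_frame: pd.DataFrame       # frame, order, fraction
    stats: dict[int, SeriesStats]


def size_distribution(clustersets: Sequence[ClusterSet], n_boot: int = 1000,
                      level: float = 0.95, seed: int = 0) -> OligomerDistribution:
    """Fraction of peptides in clusters of each order, averaged over frames.

    Per frame, fraction(k) = k * (#order-k clusters) / N_peptides, which sums
    to 1 exactly.  CIs per order come from the corrected bootstrap over the
    per-frame fraction series (orders absent from a frame contribute 0).
    """
    if len(clustersets) == 0:
        raise ValueError("need at least one frame")
    orders_seen: set[int] = set()
    frame_fracs: list[dict[int, float]] = []
    for cs in clustersets:
        n_pep = len(cs.peptides())
        fr: dict[int, float] = {}
        if n_pep:
            for c in cs.clusters:
                k = len(c)
                fr[k] = fr.get(k, 0.0) + k / n_pep
        frame_fracs.append(fr)
        orders_seen |= set(fr)

    rows, summary, stats = [], [], {}
    for k in sorted(orders_seen):
        series = np.array([fr.get(k, 0.0) for fr in frame_fracs])
        for t, v in enumerate(series):
            rows.append({"frame": t, "order": k, "fraction": v})
        if len(series) >= 8 and not np.all(series == series[0]):
            st = corrected_bootstrap(series, n_boot=n_boot, level=level,
                                     seed=seed + k)
            stats[k] = st
            summary.append({"order": k, "fraction": st.mean,
                            "ci_low": st.ci_low, "ci_high": st.ci_high})
        else:
            summary.append({"order": k, "fraction": float(series.mean()),
                            "ci_low": np.nan, "ci_high": np.nan})
    return OligomerDistribution(table=pd.DataFrame(summary),
                                per_frame=pd.DataFrame(rows), stats=stats)
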