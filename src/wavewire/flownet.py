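"""Cross-genotype wave-flow network.

Nodes are the expression waves of each genotype; a directed edge from a WT
wave to a mutant wave carries the number of dynamic transcripts the two
waves share, and is displayed only when that count reaches 10% of the WT
(source) wave size — ``weight >= ceil(sensitivity * size(source))``, so a
10-member wave needs exactly one shared transcript.  Each node also records
its specificity: the fraction of its members that are not dynamic at all in
the other genotype (the "inner ring").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .waves import WaveSet

DEFAULT_SENSITIVITY = 0.10


@dataclass
class FlowNetwork:
    """Thresholded bipartite flow between two WaveSets (source -> target)."""

    graph: nx.DiGraph
    shared_counts: pd.DataFrame   # source wave x target wave, unthresholded
    sensitivity: float
    source_genotype: str
    target_genotype: str

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v in self.graph.edges()}


def _node_id(genotype: str, wave: int) -> str:
    return f"{genotype}:{wave}"


def build_flow(source_waves: WaveSet, source_calls: pd.DataFrame,
               target_waves: WaveSet, target_calls: pd.DataFrame,
               sensitivity: float = DEFAULT_SENSITIVITY) -> FlowNetwork:
    """Build the thresholded flow network between two genotypes' waves.

    ``source_calls`` / ``target_calls`` are the dynamic-call tables of the
    respective genotypes (boolean ``dynamic`` column indexed by feature) over
    the same feature universe; they supply the specificity denominator
    (members not dynamic in the other genotype).
    """
    univ_s = set(source_calls.index)
    univ_t = set(target_calls.index)
    if not (univ_s & univ_t):
        raise ValueError("source and target feature universes are disjoint")

    g = nx.DiGraph()
    src_members = {w: set(source_waves.members(w)) for w in range(source_waves.n_waves)}
    tgt_members = {w: set(target_waves.members(w)) for w in range(target_waves.n_waves)}
    dyn_t = set(target_calls.index[target_calls["dynamic"]])
    dyn_s = set(source_calls.index[source_calls["dynamic"]])

    for w, members in src_members.items():
        spec = (len(members - dyn_t) / len(members)) if members else 0.0
        g.add_node(_node_id(source_waves.genotype, w),
                   genotype=source_waves.genotype, wave=w,
                   name=source_waves.names.get(w, str(w)),
                   size=len(members), specificity=spec)
    for w, members in tgt_members.items():
        spec = (len(members - dyn_s) / len(members)) if members else 0.0
        g.add_node(_node_id(target_waves.genotype, w),
                   genotype=target_waves.genotype, wave=w,
                   name=target_waves.names.get(w, str(w)),
                   size=len(members), specificity=spec)

    shared = pd.DataFrame(0, index=sorted(src_members), columns=sorted(tgt_members))
    for sw, sm in src_members.items():
        threshold = max(1, math.ceil(sensitivity * len(sm)))
        for tw, tm in tgt_members.items():
            weight = len(sm & tm)
            shared.loc[sw, tw] = weight
            if weight >= threshold and weight > 0:
                g.add_edge(_node_id(source_waves.genotype, sw),
                           _node_id(target_waves.genotype, tw), weight=weight)
    return FlowNetwork(graph=g, shared_counts=shared, sensitivity=sensitivity,
                       source_genotype=source_waves.genotype,
                       target_genotype=target_waves.genotype)


def flow_summary(net: FlowNetwork) -> pd.DataFrame:
    """Per-node degree, total incident flow, retained-flow fraction and
    specificity, recomputed from the thresholded edge list."""
    rows = []
    for node, data in net.graph.nodes(data=True):
        degree = net.graph.degree(node)
        flow = sum(d["weight"] for _, _, d in net.graph.in_edges(node, data=True))
        flow += sum(d["weight"] for _, _, d in net.graph.out_edges(node, data=True))
        size = data["size"]
        rows.append({
            "node": node,
            "genotype": data["genotype"],
            "wave": data["wave"],
            "name": data["name"],
            "size": size,
            "degree": degree,
            "total_flow": flow,
            "retained_flow": (flow / size) if size else float("nan"),
            "specificity": data["specificity"],
        })
    return pd.DataFrame(rows).set_index("node")
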