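"""Tracklet relinking by min-cost max-flow over a gated endpoint graph.

Tracking produces per-identity fragments (tracklets) whenever a fish is
lost to occlusion or a body-fit veto.  Fragments belonging to one fish
are reconnected by building a directed graph with a source S, a sink E
and a node pair (T_i, T_i') per tracklet, where a unit-capacity edge
T_i' -> T_j exists iff tracklet j starts after tracklet i ends, the
frame gap is below ``max_interf`` and the endpoint head distance below
``max_interd``.  A candidate link costs exp(D) * exp(-V): D the
Euclidean distance between the J_1 endpoints, V the von Mises similarity
of the endpoint head orientations (k = 4).  Body geometry is deliberately
excluded — a few frames of undulation change it too much to be a
reliable cue.

Solving the flow at total flow f, with every tracklet forced to carry
flow, selects the cheapest set of ``n_tracklets - f`` links that chain
the tracklets into f trajectories.  Because links never go backward in
time the link graph is a DAG and the forced-flow problem reduces to a
minimum-cost bipartite matching between tracklet tails and heads, solved
here by successive shortest augmenting paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import FishPose
from .tracking import TrackerState, von_mises_similarity

__all__ = [
    "Tracklet",
    "build_link_graph",
    "solve_mcmf",
    "relink",
    "tracklets_from_trackers",
]


@dataclass
class Tracklet:
    """A contiguous fragment of one fish's trajectory."""

    id: int
    poses: list[FishPose]  # ordered by frame, contiguous

    @property
    def st(self) -> int:
        return self.poses[0].frame

    @property
    def ed(self) -> int:
        return self.poses[-1].frame

    def head_in(self):
        p = self.poses[0]
        return p.J[0], float(p.theta[0])

    def head_out(self):
        p = self.poses[-1]
        return p.J[0], float(p.theta[0])

    def endpoint_before(self, frame: int):
        """Endpoint state for a successor starting at ``frame``.

        Normally the tracklet's last pose.  A terminated tracker's
        trailing coasted (extrapolated) frames may overlap a successor
        that spawned while it was still coasting; those frames are
        provisional, so the endpoint is then the pose just before the
        successor starts — provided every pose from ``frame`` on is
        coasted.  Returns (J_1, theta_1, effective end frame) or None.
        """
        if frame > self.ed:
            p = self.poses[-1]
            return p.J[0], float(p.theta[0]), self.ed
        if frame <= self.st:
            return None
        by_frame = {p.frame: p for p in self.poses}
        if any(not by_frame[f].coasted for f in range(frame, self.ed + 1)):
            return None
        p = by_frame[frame - 1]
        return p.J[0], float(p.theta[0]), frame - 1


def tracklets_from_trackers(trackers: list[TrackerState]) -> list[Tracklet]:
    out = []
    for tr in trackers:
        if not tr.history:
            continue
        poses = [tr.history[f] for f in sorted(tr.history)]
        out.append(Tracklet(id=tr.id, poses=poses))
    return out


def build_link_graph(
    tracklets: list[Tracklet],
    max_interf: int = 6,
    max_interd: float = 80.0,
    k: float = 4.0,
) -> nx.DiGraph:
    """Gated tracklet-endpoint digraph with unit capacities.

    Nodes: ``"S"``, ``"E"`` and ``("T", i)`` / ``("T'", i)`` per
    tracklet.  Structural edges (S->T_i, T_i->T_i', T_i'->E) carry zero
    cost; candidate link edges T_i'->T_j carry cost exp(D)*exp(-V) and
    store the pair (D, V) for auditability, with the cost only
    exponentiated lazily from them.
    """
    g = nx.DiGraph(max_interf=max_interf, max_interd=max_interd, k=k)
    g.add_node("S")
    g.add_node("E")
    for idx, t in enumerate(tracklets):
        g.add_edge("S", ("T", idx), cap=1, cst=0.0)
        g.add_edge(("T", idx), ("T'", idx), cap=1, cst=0.0)
        g.add_edge(("T'", idx), "E", cap=1, cst=0.0)
    for i, ti in enumerate(tracklets):
        for j, tj in enumerate(tracklets):
            if i == j:
                continue
            end = ti.endpoint_before(tj.st)
            if end is None:
                continue
            Ji, thi, ed_eff = end
            gap = tj.st - ed_eff
            if gap <= 0 or gap >= max_interf:
                continue
            Jj, thj = tj.head_in()
            D = float(np.linalg.norm(np.asarray(Jj) - np.asarray(Ji)))
            if D >= max_interd:
                continue
            V = von_mises_similarity(thj, thi, k)
            g.add_edge(("T'", i), ("T", j), cap=1, cst=float(np.exp(D - V)),
                       D=D, V=V, gap=gap)
    return g


def _link_edges(graph: nx.DiGraph):
    return [
        (u[1], v[1], d)
        for u, v, d in graph.edges(data=True)
        if isinstance(u, tuple) and u[0] == "T'" and isinstance(v, tuple) and v[0] == "T"
    ]


def _min_cost_matching(edges, n_links: int):
    """Cheapest matching of exactly ``n_links`` link edges.

    Successive shortest augmenting paths with Bellman–Ford (costs are
    nonnegative but reduced costs along residual edges may not be) on the
    bipartite graph tail-side i -> head-side j.  After k augmentations
    the flow is the minimum-cost matching of cardinality k, so stopping
    at ``n_links`` gives the optimum for that cardinality.  Returns
    (chosen (i, j) pairs, total cost) or None when infeasible.
    """
    tails = sorted({e[0] for e in edges})
    heads = sorted({e[1] for e in edges})
    cost = {(i, j): d["cst"] for i, j, d in edges}
    # residual graph over nodes: "src", "snk", ("t", i), ("h", j)
    match_t: dict = {}
    match_h: dict = {}
    total = 0.0
    for _ in range(n_links):
        # Bellman-Ford shortest augmenting path from src to snk
        dist = {"src": 0.0}
        parent = {}
        nodes = ["src", "snk"] + [("t", i) for i in tails] + [("h", j) for j in heads]
        for _round in range(len(nodes)):
            improved = False

            def relax(u, v, w):
                nonlocal improved
                if u in dist and dist[u] + w < dist.get(v, np.inf) - 1e-15:
                    dist[v] = dist[u] + w
                    parent[v] = u
                    improved = True

            for i in tails:
                if i not in match_t:
                    relax("src", ("t", i), 0.0)
            for (i, j), w in cost.items():
                if match_t.get(i) != j:
                    relax(("t", i), ("h", j), w)  # forward edge
                else:
                    relax(("h", j), ("t", i), -w)  # residual edge
            for j in heads:
                if j not in match_h:
                    relax(("h", j), "snk", 0.0)
            if not improved:
                break
        if "snk" not in dist:
            return None  # matching of this size is infeasible
        # trace back and augment
        v = "snk"
        path = []
        while v != "src":
            u = parent[v]
            path.append((u, v))
            v = u
        for u, v in path:
            if isinstance(u, tuple) and u[0] == "t" and isinstance(v, tuple) and v[0] == "h":
                match_t[u[1]] = v[1]
                match_h[v[1]] = u[1]
            elif isinstance(u, tuple) and u[0] == "h" and isinstance(v, tuple) and v[0] == "t":
                # residual traversal un-matches the pair
                if match_t.get(v[1]) == u[1]:
                    del match_t[v[1]]
                    del match_h[u[1]]
        total = sum(cost[(i, j)] for i, j in match_t.items())
    chosen = sorted(match_t.items())
    return chosen, total


@dataclass
class FlowSolution:
    flow: int
    links: list[tuple[int, int]]
    total_cost: float
    feasible: bool = True


def solve_mcmf(graph: nx.DiGraph, flow: int) -> FlowSolution:
    """Minimum-cost flow of value ``flow`` with every tracklet covered.

    ``flow`` is the number of resulting trajectories; covering all n
    tracklets with ``flow`` unit paths requires exactly ``n - flow``
    link edges forming vertex-disjoint chains, i.e. a matching in the
    gated link graph.  Structural edges cost nothing, so the flow cost
    equals the summed link costs.
    """
    n = sum(1 for u in graph.nodes if isinstance(u, tuple) and u[0] == "T")
    if flow > n or flow < 0:
        return FlowSolution(flow, [], np.inf, feasible=False)
    n_links = n - flow
    edges = _link_edges(graph)
    res = _min_cost_matching(edges, n_links)
    if res is None:
        return FlowSolution(flow, [], np.inf, feasible=False)
    links, total = res
    return FlowSolution(flow, links, total)


def relink(
    tracklets: list[Tracklet],
    max_interf: int = 6,
    max_interd: float = 80.0,
    k: float = 4.0,
    n_fish: int | None = None,
    cost_ceiling: float = np.inf,
) -> tuple[list[Tracklet], list[dict]]:
    """Chain tracklets into maximal trajectories.

    With ``n_fish`` given, the flow is solved at that value (or the
    smallest feasible flow above it).  Otherwise feasible flows are
    enumerated and the largest number of links whose solution uses only
    edges cheaper than ``cost_ceiling`` wins — i.e. link as much as
    possible, then as cheaply as possible.  Each merged trajectory keeps
    the id of its earliest tracklet.  Returns the trajectories and a link
    audit (one record per accepted link).
    """
    if not tracklets:
        return [], []
    graph = build_link_graph(tracklets, max_interf, max_interd, k)
    n = len(tracklets)
    if n_fish is not None:
        flow = max(min(n_fish, n), 0)
        sol = solve_mcmf(graph, flow)
        while not sol.feasible and flow < n:
            flow += 1
            sol = solve_mcmf(graph, flow)
    else:
        sol = FlowSolution(n, [], 0.0)
        for flow in range(n - 1, -1, -1):
            cand = solve_mcmf(graph, flow)
            if not cand.feasible:
                break
            if cand.links and max(
                graph.edges[("T'", i), ("T", j)]["cst"] for i, j in cand.links
            ) >= cost_ceiling:
                break
            sol = cand

    succ = dict(sol.links)
    has_pred = {j for _, j in sol.links}
    audit = []
    for i, j in sorted(sol.links):
        d = graph.edges[("T'", i), ("T", j)]
        audit.append({
            "from_id": tracklets[i].id, "to_id": tracklets[j].id,
            "gap": d["gap"], "D": d["D"], "V": d["V"], "cost": d["cst"],
        })

    merged: list[Tracklet] = []
    for idx, t in enumerate(tracklets):
        if idx in has_pred:
            continue
        poses = list(t.poses)
        cur = idx
        while cur in succ:
            cur = succ[cur]
            poses.extend(tracklets[cur].poses)
        merged.append(Tracklet(id=t.id, poses=poses))
    merged.sort(key=lambda t: (t.st, t.id))
    return merged, audit
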