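"""Key-node (master-regulator) search on signed signaling networks.

Given a directed network whose edges are labelled ``activate`` or
``inhibit`` and a set of regulated genes with observed directions, the
analysis asks: which molecule reaches every regulated gene within a bounded
number of regulation steps (default 4 hierarchical levels)?  A node covering
the whole query set is a "common denominator" — a putative master regulator.

Sign propagation follows the product rule along a path (an even number of
inhibitions nets out to activation).  Sign consistency of a candidate is the
fraction of covered genes for which at least one shortest path predicts the
observed direction, under the better of the two assumed regulator states
(active-up or active-down).  It annotates the ranking; it does not filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

SIGNS = {"activate": 1, "inhibit": -1}
DEFAULT_MAX_DEPTH = 4


class NetworkParseError(ValueError):
    """Raised on malformed network files, with the offending line number."""


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def load_network(path) -> nx.MultiDiGraph:
    """Parse a three-column SIF-like TSV (source, interaction, target).

    Interaction must be ``activate`` or ``inhibit``.  Duplicate identical
    edges are collapsed; self-loops are dropped with a warning.  Parallel
    edges with opposite signs are kept.
    """
    G = nx.MultiDiGraph()
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            source, interaction, target = (p.strip() for p in parts)
            if interaction not in SIGNS:
                raise NetworkParseError(
                    f"{path}:{lineno}: unknown interaction {interaction!r} "
                    f"(expected 'activate' or 'inhibit')"
                )
            G.add_node(source)
            G.add_node(target)
            if source == target:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, source)
                continue
            key = (source, target, interaction)
            if key in seen:
                continue
            seen.add(key)
            G.add_edge(source, target, sign=interaction)
    return G


def write_network(G: nx.MultiDiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(G.edges(data=True)):
            fh.write(f"{u}\t{data['sign']}\t{v}\n")


# ---------------------------------------------------------------------------
# reachability and signs
# ---------------------------------------------------------------------------

def bounded_reach(
    G: nx.DiGraph, source, max_depth: int = DEFAULT_MAX_DEPTH, include_cycle_to_source: bool = True
) -> dict:
    """Shortest directed depths from ``source``, truncated at ``max_depth`` edges.

    The source itself appears only if it lies on a directed cycle of length
    <= max_depth (paths must use at least one edge; a gene does not cover
    itself at depth 0).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if source not in G:
        raise ValueError(f"unknown source node {source!r}")
    depths = dict(nx.single_source_shortest_path_length(G, source, cutoff=max_depth))
    depths.pop(source, None)
    if include_cycle_to_source:
        best = None
        for succ in G.successors(source):
            if succ == source:
                continue
            back = nx.single_source_shortest_path_length(G, succ, cutoff=max_depth - 1)
            if source in back:
                cand = 1 + back[source]
                best = cand if best is None else min(best, cand)
        if best is not None:
            depths[source] = best
    return depths


def path_sign(edge_signs: Iterable[str]) -> str:
    """Net sign of a regulation path: odd number of inhibitions inhibits."""
    product = 1
    n = 0
    for s in edge_signs:
        product *= SIGNS[s]
        n += 1
    if n == 0:
        raise ValueError("empty path has no sign")
    return "net_activate" if product == 1 else "net_inhibit"


def shortest_path_signs(G: nx.MultiDiGraph, source, depths: Mapping) -> dict:
    """Net signs achievable along shortest paths from ``source``.

    Dynamic program over BFS layers: a node at depth k inherits the sign
    sets of its depth-(k-1) predecessors combined with each parallel edge
    sign.  Returns node -> subset of {+1, -1}.  The source-as-target cycle
    case is not covered (no layer structure) and is left out.
    """
    signs = {source: {1}}
    order = sorted((d, n) for n, d in depths.items() if n != source)
    by_depth: dict[int, list] = {}
    for d, n in order:
        by_depth.setdefault(d, []).append(n)
    for d in sorted(by_depth):
        for node in by_depth[d]:
            acc = set()
            for pred in G.predecessors(node):
                pred_depth = 0 if pred == source else depths.get(pred)
                if pred_depth != d - 1 or pred not in signs:
                    continue
                edge_signs = {SIGNS[data["sign"]] for data in G[pred][node].values()}
                for s in signs[pred]:
                    for es in edge_signs:
                        acc.add(s * es)
            if acc:
                signs[node] = acc
    signs.pop(source, None)
    return signs


# ---------------------------------------------------------------------------
# key-node search
# ---------------------------------------------------------------------------

@dataclass
class KeyNodeResult:
    """One candidate regulator's coverage of the query gene set."""

    node: str
    coverage: float
    n_query: int
    covered: dict = field(default_factory=dict)  # gene -> shortest depth
    mean_depth: float = float("nan")
    max_depth: int = 0
    sign_consistency: float = float("nan")
    assumed_state: str = "active_up"

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "coverage": self.coverage,
            "n_covered": len(self.covered),
            "n_query": self.n_query,
            "mean_depth": self.mean_depth,
            "max_depth": self.max_depth,
            "sign_consistency": self.sign_consistency,
            "assumed_state": self.assumed_state,
        }


def evaluate_candidate(
    G: nx.MultiDiGraph, node, query: Mapping[str, str], max_depth: int = DEFAULT_MAX_DEPTH
) -> KeyNodeResult:
    """Coverage, depth statistics and sign consistency for one candidate."""
    depths = bounded_reach(G, node, max_depth)
    covered = {g: depths[g] for g in query if g in depths}
    n_query = len(query)
    result = KeyNodeResult(str(node), len(covered) / n_query, n_query, covered)
    if covered:
        dvals = list(covered.values())
        result.mean_depth = sum(dvals) / len(dvals)
        result.max_depth = max(dvals)
        signs = shortest_path_signs(G, node, depths)
        # genes covered only via a cycle back to the candidate itself carry
        # no layered sign information; they are excluded from the denominator
        scoreable = [g for g in covered if g in signs]
        best = (float("nan"), "active_up")
        if scoreable:
            for state, label in ((1, "active_up"), (-1, "active_down")):
                ok = 0
                for g in scoreable:
                    want = 1 if query[g] == "up" else -1
                    if any(state * s == want for s in signs[g]):
                        ok += 1
                frac = ok / len(scoreable)
                if best[0] != best[0] or frac > best[0]:  # NaN-safe max
                    best = (frac, label)
        result.sign_consistency, result.assumed_state = best
    return result


def find_key_nodes(
    G: nx.MultiDiGraph,
    query: Mapping[str, str],
    max_depth: int = DEFAULT_MAX_DEPTH,
    require_full_coverage: bool = True,
) -> list[KeyNodeResult]:
    """Rank every network node as a candidate upstream master regulator.

    ``query`` maps gene node ids to observed directions ('up'/'down').
    Genes absent from the network are reported via the log and excluded.
    Ranking: coverage desc, then max depth asc, then mean depth asc, then
    node id.  With ``require_full_coverage`` only common denominators
    (coverage 1.0) are returned.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    bad = {d for d in query.values()} - {"up", "down"}
    if bad:
        raise ValueError(f"unknown query directions: {sorted(bad)}")
    mapped = {g: d for g, d in query.items() if g in G}
    unmapped = sorted(set(query) - set(mapped))
    if unmapped:
        logger.warning("%d query gene(s) not in network: %s", len(unmapped), unmapped)
    if not mapped:
        raise ValueError("no query genes could be mapped to network nodes")

    results = [evaluate_candidate(G, node, mapped, max_depth) for node in G.nodes]
    results = [r for r in results if r.covered]
    results.sort(key=lambda r: (-r.coverage, r.max_depth, r.mean_depth, r.node))
    if require_full_coverage:
        results = [r for r in results if r.coverage == 1.0]
        if not results:
            logger.info(
                "no node covers all %d mapped query genes within %d steps",
                len(mapped), max_depth,
            )
    return results


class KeyNodeFinder:
    """Thin object wrapper: fit a network once, rank several query sets.

    Follows the fit/attribute convention (``network_`` after ``fit``) so it
    slots into the same workflow style as the estimator stages, though the
    search itself is not a predictor.
    """

    def __init__(self, max_depth: int = DEFAULT_MAX_DEPTH, require_full_coverage: bool = True):
        self.max_depth = max_depth
        self.require_full_coverage = require_full_coverage

    def fit(self, network: nx.MultiDiGraph):
        if not isinstance(network, nx.MultiDiGraph):
            network = nx.MultiDiGraph(network)
        self.network_ = network
        return self

    def rank(self, query: Mapping[str, str]) -> list[KeyNodeResult]:
        return find_key_nodes(
            self.network_, query, self.max_depth, self.require_full_coverage
        )
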