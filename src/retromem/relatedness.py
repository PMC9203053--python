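"""Semantic-relatedness metrics over free-association networks and word embeddings.

An :class:`AssociationNetwork` is a directed weighted graph whose edge weight
is associative strength (AS): the empirical probability that the destination
word is produced in free association to the source word.  Because the weights
are free-association probabilities, every edge weight lies in (0, 1] and the
outgoing weights of a node sum to at most 1.

Five network metrics plus embedding cosine similarity are provided:

* direct AS lookup in the forward (a→b) or backward (b→a) direction,
* backward mediator strength — cumulative strength of two-step routes
  new→mediator→base,
* weighted path length — shortest path under edge weights 1−AS, clamped to a
  cap (default 6) when no path exists,
* bounded spreading activation — activation propagated up to ``max_steps``
  along per-node renormalized out-weights, summing the weight products of all
  walks that end at the destination,
* cosine similarity between embedding vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "AssociationNetwork",
    "EmbeddingTable",
    "RelatednessProfile",
    "load_association_tsv",
    "load_embeddings",
    "as_lookup",
    "backward_mediator_strength",
    "weighted_path_length",
    "spreading_activation",
    "cosine_similarity",
    "profile",
]

DEFAULT_PATH_CAP = 6.0


class MissingWordError(KeyError):
    """Raised when a queried word is absent from a resource."""

    def __init__(self, word: str, resource: str = "association network"):
        super().__init__(word)
        self.word = word
        self.resource = resource

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"word {self.word!r} not found in {self.resource}"


class AssociationNetwork:
    """Directed weighted free-association graph.

    Parameters
    ----------
    edges
        Iterable of ``(source, target, strength)`` triples.  Words are
        case-folded.  Strengths must lie in (0, 1]; self-loops are rejected;
        the outgoing strengths of a node may sum to at most 1 (+ tolerance).
    """

    _SUM_TOL = 1e-6

    def __init__(self, edges: Iterable[tuple[str, str, float]]):
        g = nx.DiGraph()
        for src, dst, w in edges:
            src, dst, w = str(src).casefold(), str(dst).casefold(), float(w)
            if src == dst:
                raise ValueError(f"self-loop {src!r} not allowed")
            if not 0.0 < w <= 1.0:
                raise ValueError(
                    f"associative strength must be in (0, 1], got {w} for {src}->{dst}"
                )
            if g.has_edge(src, dst):
                raise ValueError(f"duplicate edge {src}->{dst}")
            g.add_edge(src, dst, weight=w)
        for node in g:
            out = g.out_degree(node, weight="weight")
            if out > 1.0 + self._SUM_TOL:
                raise ValueError(
                    f"outgoing strengths of {node!r} sum to {out:.6f} > 1"
                )
        self._g = g

    # -- container protocol -------------------------------------------------
    def __contains__(self, word: str) -> bool:
        return str(word).casefold() in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self._g.edges(data=True)]

    def strength(self, src: str, dst: str) -> float:
        """Direct AS src→dst; 0 when no edge exists (norms are sparse)."""
        src, dst = str(src).casefold(), str(dst).casefold()
        for w in (src, dst):
            if w not in self._g:
                raise MissingWordError(w)
        d = self._g.get_edge_data(src, dst)
        return d["weight"] if d is not None else 0.0

    def successors(self, word: str) -> list[tuple[str, float]]:
        word = str(word).casefold()
        if word not in self._g:
            raise MissingWordError(word)
        return [(v, d["weight"]) for v, d in self._g[word].items()]

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying networkx digraph (read-only by convention)."""
        return self._g


class EmbeddingTable:
    """Word → fixed-dimension embedding vector mapping."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        self._vecs: dict[str, np.ndarray] = {}
        dim = None
        for word, vec in vectors.items():
            v = np.asarray(vec, dtype=float)
            if v.ndim != 1:
                raise ValueError(f"vector for {word!r} is not 1-D")
            if dim is None:
                dim = v.size
            elif v.size != dim:
                raise ValueError(
                    f"vector for {word!r} has dimension {v.size}, expected {dim}"
                )
            self._vecs[str(word).casefold()] = v
        self.dim = dim or 0

    def __contains__(self, word: str) -> bool:
        return str(word).casefold() in self._vecs

    def __len__(self) -> int:
        return len(self._vecs)

    def vector(self, word: str) -> np.ndarray:
        key = str(word).casefold()
        if key not in self._vecs:
            raise MissingWordError(key, "embedding table")
        return self._vecs[key]


@dataclass
class RelatednessProfile:
    """Bundle of all relatedness metrics for one word pair.

    Fields that could not be computed (word missing from the resource) are
    ``None`` — missingness is represented, never silently zero.
    """

    pair: tuple[str, str]
    as_backward: float | None = None
    as_forward: float | None = None
    mediator_strength: float | None = None
    weighted_path_length: float | None = None
    spreading_activation: float | None = None
    cosine: float | None = None


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_association_tsv(path) -> AssociationNetwork:
    """Read a 3-column ``source<TAB>target<TAB>strength`` TSV.

    UTF-8; lines starting with ``#`` and blank lines are skipped; words are
    case-folded on load.
    """
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            edges.append((parts[0], parts[1], float(parts[2])))
    return AssociationNetwork(edges)


def load_embeddings(path) -> EmbeddingTable:
    """Read word-per-line text vectors (``word v1 v2 ...``).

    An optional first header line of two integers ``n d`` is auto-detected
    and skipped.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        parts = first.split()
        if len(parts) == 2 and all(p.lstrip("+-").isdigit() for p in parts):
            pass  # header line: vocabulary size and dimension
        elif parts:
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return EmbeddingTable(vectors)


# ---------------------------------------------------------------------------
# network metrics
# ---------------------------------------------------------------------------

def as_lookup(
    network: AssociationNetwork, src: str, dst: str, direction: str = "backward"
) -> float:
    """Direct associative strength between two words.

    ``forward`` reads the edge src→dst; ``backward`` reads dst→src (the
    probability that the *source* word is produced in response to the
    destination word, the direction used for cue←Δcue lookups).  Absent edges
    are 0; absent words raise :class:`MissingWordError`.
    """
    if direction == "forward":
        return network.strength(src, dst)
    if direction == "backward":
        return network.strength(dst, src)
    raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")


def backward_mediator_strength(
    network: AssociationNetwork,
    base: str,
    new: str,
    aggregate: str = "sum",
) -> float:
    """Cumulative strength of two-step routes new→mediator→base.

    Sums AS(new→m)·AS(m→base) over every mediator m distinct from both
    endpoints; the direct edge new→base is excluded.  ``aggregate='max'``
    returns the single strongest route instead of the sum.
    """
    base_f, new_f = str(base).casefold(), str(new).casefold()
    for w in (base_f, new_f):
        if w not in network:
            raise MissingWordError(w)
    contributions = [
        w1 * network.strength(m, base_f)
        for m, w1 in network.successors(new_f)
        if m not in (base_f, new_f)
    ]
    contributions = [c for c in contributions if c > 0.0]
    if not contributions:
        return 0.0
    return max(contributions) if aggregate == "max" else float(sum(contributions))


def weighted_path_length(
    network: AssociationNetwork,
    src: str,
    dst: str,
    cap: float = DEFAULT_PATH_CAP,
    path_criterion: str = "weight",
    clamp_finite: bool = True,
) -> float:
    """Shortest-path length under edge weights 1−AS, clamped to ``cap``.

    ``path_criterion='weight'`` minimizes the summed 1−AS weights (Dijkstra);
    ``'hops'`` takes a hop-shortest path and sums its 1−AS weights.
    Unreachable destinations return ``cap``; with ``clamp_finite`` (default)
    finite lengths exceeding the cap are clamped too.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    src_f, dst_f = str(src).casefold(), str(dst).casefold()
    for w in (src_f, dst_f):
        if w not in network:
            raise MissingWordError(w)
    if src_f == dst_f:
        return 0.0
    g = network.graph
    try:
        if path_criterion == "weight":
            length = nx.dijkstra_path_length(
                g, src_f, dst_f, weight=lambda u, v, d: 1.0 - d["weight"]
            )
        elif path_criterion == "hops":
            path = nx.shortest_path(g, src_f, dst_f)
            length = sum(
                1.0 - g[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
            )
        else:
            raise ValueError(f"unknown path criterion {path_criterion!r}")
    except nx.NetworkXNoPath:
        return float(cap)
    if clamp_finite and length > cap:
        return float(cap)
    return float(length)


def spreading_activation(
    network: AssociationNetwork,
    src: str,
    dst: str,
    max_steps: int = 3,
    allow_revisits: bool = True,
) -> float:
    """Activation reaching ``dst`` within ``max_steps`` from ``src``.

    Each node's outgoing AS values are renormalized once to sum to 1 (a
    static transition matrix).  Activation starts at the source and advances
    along all edges step by step; every directed walk of length ≤ max_steps
    ending at the destination contributes the product of its renormalized
    weights, and contributions are accumulated across steps.  With
    ``allow_revisits=False`` walks may not revisit a node (simple paths only).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    src_f, dst_f = str(src).casefold(), str(dst).casefold()
    for w in (src_f, dst_f):
        if w not in network:
            raise MissingWordError(w)

    def renorm(node: str) -> list[tuple[str, float]]:
        succ = network.successors(node)
        total = sum(w for _, w in succ)
        if total <= 0:
            return []  # zero out-degree propagates nothing
        return [(v, w / total) for v, w in succ]

    total_activation = 0.0
    if allow_revisits:
        # frontier: node -> summed walk-product mass at the current step
        frontier: dict[str, float] = {src_f: 1.0}
        for _ in range(max_steps):
            nxt: dict[str, float] = {}
            for node, mass in frontier.items():
                for v, p in renorm(node):
                    nxt[v] = nxt.get(v, 0.0) + mass * p
            total_activation += nxt.get(dst_f, 0.0)
            frontier = nxt
            if not frontier:
                break
    else:
        stack = [(src_f, 1.0, {src_f}, 0)]
        while stack:
            node, mass, visited, depth = stack.pop()
            if depth == max_steps:
                continue
            for v, p in renorm(node):
                if v in visited:
                    continue
                if v == dst_f:
                    total_activation += mass * p
                stack.append((v, mass * p, visited | {v}, depth + 1))
    return total_activation


def cosine_similarity(vecs: EmbeddingTable, a: str, b: str) -> float:
    """Cosine of the angle between two embedding vectors, in [−1, 1]."""
    va, vb = vecs.vector(a), vecs.vector(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        zero = a if na == 0.0 else b
        raise ValueError(f"zero-norm vector for {zero!r}")
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))


def profile(
    network: AssociationNetwork | None,
    vecs: EmbeddingTable | None,
    pair: tuple[str, str],
    cap: float = DEFAULT_PATH_CAP,
    max_steps: int = 3,
) -> RelatednessProfile:
    """All relatedness metrics for one (base word, new word) pair.

    Metrics whose resource lacks a word are left ``None``.  The convention
    follows the cue←Δcue usage: ``pair = (base, new)``; backward AS reads
    new→base, forward AS reads base→new, path length and spreading
    activation run new→base.
    """
    base, new = pair
    prof = RelatednessProfile(pair=(str(base).casefold(), str(new).casefold()))
    if network is not None and base in network and new in network:
        prof.as_backward = as_lookup(network, base, new, "backward")
        prof.as_forward = as_lookup(network, base, new, "forward")
        prof.mediator_strength = backward_mediator_strength(network, base, new)
        prof.weighted_path_length = weighted_path_length(network, new, base, cap=cap)
        prof.spreading_activation = spreading_activation(
            network, new, base, max_steps=max_steps
        )
    if vecs is not None and base in vecs and new in vecs:
        try:
            prof.cosine = cosine_similarity(vecs, base, new)
        except ValueError:
            prof.cosine = None
    return prof
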