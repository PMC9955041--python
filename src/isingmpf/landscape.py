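"""Downstream analytics on a fitted landscape.

Top-k topography over the exact distribution, Hamming graphs of the most
probable configurations, probability-weighted hierarchical clustering into
groups, local (focal) neighbourhoods with single-flip "move tables", exact
conditional prediction of unknown answers, and the side-by-side comparison
of inferred couplings with surface-level Pearson correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    IsingParameters,
    config_to_index,
    enumerate_distribution,
    index_to_config,
    pair_index_arrays,
)
from .mpf import flip_sets
from .partial import MAX_MISSING, completion_weights

logger = logging.getLogger(__name__)


@dataclass
class ConfigurationNode:
    state: int
    probability: float
    observed_entities: list = field(default_factory=list)


def top_k(
    params: IsingParameters, k: int, observed: dict[int, list] | None = None
) -> tuple[list[ConfigurationNode], float]:
    """The k most probable configurations (descending; ties by state index).

    ``observed`` optionally maps state indices to entity ids occupying them.
    Returns the nodes and their cumulative probability mass.
    """
    dist = enumerate_distribution(params)
    if k > len(dist.probs):
        raise ValueError(f"k={k} exceeds the 2^n = {len(dist.probs)} states")
    order = np.argsort(-dist.probs, kind="stable")[:k]
    observed = observed or {}
    nodes = [
        ConfigurationNode(
            state=int(i),
            probability=float(dist.probs[i]),
            observed_entities=list(observed.get(int(i), [])),
        )
        for i in order
    ]
    return nodes, float(sum(nd.probability for nd in nodes))


def build_graph(nodes: list[ConfigurationNode]) -> nx.Graph:
    """Hamming-1 graph over the given nodes.

    Edge weight is the product of the endpoint probabilities (the convention
    used to scale edges when the graph is drawn).
    """
    g = nx.Graph()
    for nd in nodes:
        g.add_node(
            nd.state,
            probability=nd.probability,
            entities=",".join(map(str, nd.observed_entities)),
        )
    states = [nd.state for nd in nodes]
    probs = {nd.state: nd.probability for nd in nodes}
    for i, si in enumerate(states):
        for sj in states[i + 1 :]:
            if (si ^ sj).bit_count() == 1:
                g.add_edge(si, sj, weight=probs[si] * probs[sj])
    return g


def _hamming_matrix(states: np.ndarray, n: int) -> np.ndarray:
    configs = np.array([index_to_config(s, n) for s in states], dtype=np.int8)
    eq = configs[:, None, :] != configs[None, :, :]
    return eq.sum(axis=2).astype(float)


def cluster_configurations(
    nodes: list[ConfigurationNode], n_groups: int, n: int | None = None
) -> np.ndarray:
    """Probability-weighted average-linkage clustering on Hamming distances.

    Each node carries its probability mass as a case weight, so merging
    decisions are driven by where the probability sits, not by node counts.
    Deterministic: ties in the merge queue break toward the smaller pair of
    cluster indices.  Returns integer labels, 0..n_groups-1, numbered by
    first-seen node order.
    """
    k = len(nodes)
    if k < n_groups:
        raise ValueError(f"{k} nodes cannot form {n_groups} groups")
    if n is None:
        n = max(max(nd.state for nd in nodes).bit_length(), 1)
    D = _hamming_matrix(np.array([nd.state for nd in nodes]), n)
    mass = np.array([nd.probability for nd in nodes], dtype=float)
    active = list(range(k))
    members: dict[int, list[int]] = {i: [i] for i in range(k)}
    m = {i: mass[i] for i in range(k)}
    dist = {
        (i, j): D[i, j] for idx, i in enumerate(active) for j in active[idx + 1 :]
    }
    nxt = k
    while len(active) > n_groups:
        (ci, cj) = min(dist, key=lambda p: (dist[p], p))
        # weighted-average linkage update
        for other in active:
            if other in (ci, cj):
                continue
            dio = dist[tuple(sorted((ci, other)))]
            djo = dist[tuple(sorted((cj, other)))]
            dnew = (m[ci] * dio + m[cj] * djo) / (m[ci] + m[cj])
            dist[tuple(sorted((nxt, other)))] = dnew
        members[nxt] = members.pop(ci) + members.pop(cj)
        m[nxt] = m.pop(ci) + m.pop(cj)
        active = [a for a in active if a not in (ci, cj)] + [nxt]
        dist = {p: d for p, d in dist.items() if ci not in p and cj not in p}
        nxt += 1
    labels = np.empty(k, dtype=int)
    # label clusters by their first-seen member for permutation stability
    for lab, cid in enumerate(sorted(active, key=lambda c: min(members[c]))):
        labels[members[cid]] = lab
    return labels


def focal_neighborhood(
    params: IsingParameters,
    focal: np.ndarray,
    radius: int = 2,
    top: int = 49,
) -> tuple[nx.Graph, pd.DataFrame]:
    """The focal configuration, its most probable nearby configurations, and
    the single-flip move table.

    The graph holds the focal node plus the ``top`` highest-probability
    states within Hamming distance ``radius``.  The move table lists, for
    each radius-1 neighbour, its share of the total radius-1 probability —
    the relative likelihood of each single-answer "reformation".
    """
    if radius not in (1, 2):
        raise ValueError("radius must be 1 or 2")
    focal = np.asarray(focal)
    n = params.n
    dist = enumerate_distribution(params)

    sets = flip_sets(n, radius)
    cand = np.tile(focal, (len(sets), 1))
    for r, T in enumerate(sets):
        cand[r, list(T)] *= -1
    idx = np.array([config_to_index(c) for c in cand])
    probs = dist.probs[idx]

    order = np.argsort(-probs, kind="stable")[:top]
    nodes = [
        ConfigurationNode(state=int(config_to_index(focal)),
                          probability=float(dist.probs[config_to_index(focal)]))
    ] + [
        ConfigurationNode(state=int(idx[r]), probability=float(probs[r]))
        for r in order
    ]
    graph = build_graph(nodes)

    single = [r for r, T in enumerate(sets) if len(T) == 1]
    p1 = probs[single]
    shares = p1 / p1.sum()
    move_table = pd.DataFrame(
        {
            "question": [sets[r][0] for r in single],
            "flipped_to": [int(-focal[sets[r][0]]) for r in single],
            "probability": p1,
            "move_share": shares,
        }
    ).sort_values("move_share", ascending=False, ignore_index=True)
    return graph, move_table


def conditional_predict(
    params: IsingParameters, values: np.ndarray, max_missing: int = MAX_MISSING
) -> pd.DataFrame:
    """Ranked table of exact conditional probabilities over the completions.

    One row per assignment of the unknown questions, highest belief first;
    the same machinery that weights completions inside the partial-data
    objective, presented as degrees of belief.
    """
    values = np.asarray(values, dtype=float)
    cset = completion_weights(params, values, weight=1.0, max_missing=max_missing)
    miss = np.where(np.isnan(values))[0]
    rows = []
    for comp, w in zip(cset.completions, cset.weights):
        row = {f"q{q}": int(comp[q]) for q in miss}
        row["probability"] = float(w)
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values("probability", ascending=False, ignore_index=True)
    )


def logic_summary(
    params: IsingParameters, obs=None, top: int = 15
) -> dict[str, pd.DataFrame]:
    """Inferred landscape logic vs surface-level correlations.

    Returns two edge lists: the ``top`` strongest couplings |J_ab| with the
    local fields, and (when data is given) the ``top`` strongest pairwise
    Pearson correlations computed pairwise-complete over known answers,
    with the per-question observed means.  Constant columns have no defined
    correlation and are excluded with a logged note.
    """
    n = params.n
    rows, cols = pair_index_arrays(n)
    order = np.argsort(-np.abs(params.couplings), kind="stable")[:top]
    couplings = pd.DataFrame(
        {
            "a": rows[order],
            "b": cols[order],
            "J": params.couplings[order],
        }
    )
    fields = pd.DataFrame({"question": np.arange(n), "h": params.fields})
    out = {"couplings": couplings, "fields": fields}

    if obs is not None:
        values = obs.values if hasattr(obs, "values") else np.asarray(obs, dtype=float)
        df = pd.DataFrame(np.asarray(values, dtype=float))
        known_std = df.std(skipna=True)
        constant = [int(c) for c in df.columns if not known_std[c] > 0]
        if constant:
            logger.info(
                "excluding constant question(s) %s from the correlation table",
                constant,
            )
        corr = df.corr()  # pairwise-complete by construction
        recs = []
        for a, b in zip(rows, cols):
            if a in constant or b in constant:
                continue
            r = corr.iloc[a, b]
            if np.isfinite(r):
                recs.append({"a": int(a), "b": int(b), "r": float(r)})
        corr_df = (
            pd.DataFrame(recs)
            .sort_values("r", key=np.abs, ascending=False, ignore_index=True)
            .head(top)
        )
        out["correlations"] = corr_df
        out["means"] = pd.DataFrame(
            {"question": np.arange(values.shape[1]), "mean": df.mean(skipna=True).to_numpy()}
        )
    return out


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT export with probability node attributes (layout is left
    to external tools)."""
    with open(path, "w") as fh:
        fh.write("graph landscape {\n")
        for node, attrs in graph.nodes(data=True):
            fh.write(
                f'  "{node}" [probability="{attrs.get("probability", 0):.6g}"];\n'
            )
        for u, v, attrs in graph.edges(data=True):
            fh.write(f'  "{u}" -- "{v}" [weight="{attrs.get("weight", 0):.6g}"];\n')
        fh.write("}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
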