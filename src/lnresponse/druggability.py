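"""Mechanistic circuit propagation and in-silico target inhibition.

A circuit is an acyclic signed digraph from receptor nodes (indegree 0) to
a single effector node (outdegree 0); each node is annotated with member
genes.  Per sample, gene expression is rank-scaled across samples into
(0, 1), node values are gene means, and the signal propagates in
topological order:

    S_r = v_r                                   (receptors)
    S_n = v_n * (1 - prod_a (1 - S_a)) * prod_i (1 - S_i)

over activating parents ``a`` and inhibiting parents ``i``; the circuit
activity is the effector signal.  Target inhibition multiplies target-gene
expression by 0.1; perturbed values are re-scaled against the empirical
distribution of the unperturbed cohort, so the knock-down propagates into
(0, 1) space.  A patient's response score for a target set is the summed
absolute change of circuit activities, and a favorable responder scores at
or above the cohort mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CircuitGraph", "compute_node_values", "propagate",
    "simulate_inhibition", "response_score", "favorable_rate",
]


@dataclass
class CircuitGraph:
    """Signed directed receptor->effector circuit with gene-annotated nodes."""

    name: str
    graph: nx.DiGraph

    @classmethod
    def from_tables(cls, name: str,
                    nodes: Sequence[Tuple[str, Sequence[str]]],
                    edges: Sequence[Tuple[str, str, int]]) -> "CircuitGraph":
        g = nx.DiGraph()
        for node, genes in nodes:
            genes = tuple(genes)
            if not genes:
                raise ValueError(f"node {node!r} has no genes")
            g.add_node(node, genes=genes)
        for u, v, sign in edges:
            if sign not in (-1, 1):
                raise ValueError("edge sign must be +1 or -1")
            g.add_edge(u, v, sign=int(sign))
        circ = cls(name=name, graph=g)
        circ.validate()
        return circ

    def validate(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"circuit {self.name!r} contains a cycle: {cycle}")
        receptors = [n for n in g if g.in_degree(n) == 0]
        effectors = [n for n in g if g.out_degree(n) == 0]
        if not receptors:
            raise ValueError("circuit has no receptor (zero-indegree) node")
        if len(effectors) != 1:
            raise ValueError("circuit must have exactly one effector node")
        effector = effectors[0]
        reaches = set(nx.ancestors(g, effector)) | {effector}
        if set(g) - reaches:
            raise ValueError("every node must lie on a receptor->effector path")
        for n, data in g.nodes(data=True):
            data.setdefault("genes", ())
            data["role"] = ("receptor" if g.in_degree(n) == 0 else
                            "effector" if n == effector else "intermediate")

    @property
    def effector(self) -> str:
        return next(n for n in self.graph if self.graph.out_degree(n) == 0)

    @property
    def receptors(self) -> List[str]:
        return [n for n in self.graph if self.graph.in_degree(n) == 0]

    def genes(self) -> List[str]:
        out: List[str] = []
        for _, data in self.graph.nodes(data=True):
            out.extend(data["genes"])
        return sorted(set(out))


# ---------------------------------------------------------------------------
# node values

def _rank_scale(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Scale values into (0, 1) by their mid-rank within the reference.

    For a value present in the reference this reproduces the average rank
    divided by (n + 1); perturbed values fall where they would insert.
    """
    ref = np.sort(reference)
    n = ref.size
    less = np.searchsorted(ref, values, side="left")
    leq = np.searchsorted(ref, values, side="right")
    return (less + (leq - less + 1) / 2.0) / (n + 1.0)


def compute_node_values(expr: pd.DataFrame, circuit: CircuitGraph,
                        reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Node values per sample: mean of the member genes' rank-scaled values.

    ``expr`` is genes x samples on a positive scale.  ``reference``
    (default: ``expr`` itself) supplies the per-gene distribution the
    scaling is anchored to; pass the unperturbed matrix when scoring an
    inhibited one.  Returns nodes x samples values in (0, 1).
    """
    reference = expr if reference is None else reference
    rows = {}
    for node, data in circuit.graph.nodes(data=True):
        present = [g for g in data["genes"] if g in expr.index]
        missing = set(data["genes"]) - set(present)
        if not present:
            raise ValueError(f"node {node!r} has no measured genes")
        if missing:
            warnings.warn(f"node {node!r}: dropping unmeasured genes "
                          f"{sorted(missing)}")
        scaled = np.vstack([
            _rank_scale(expr.loc[g].to_numpy(float),
                        reference.loc[g].to_numpy(float))
            for g in present])
        rows[node] = scaled.mean(axis=0)
    return pd.DataFrame(rows, index=expr.columns).T


# ---------------------------------------------------------------------------
# propagation

def propagate(circuit: CircuitGraph, node_values) -> pd.Series | pd.DataFrame:
    """Propagate receptor signals to the effector in topological order.

    ``node_values`` is a mapping node -> value in [0, 1] (or a nodes x
    samples DataFrame).  Returns the signal per node (Series for a single
    sample, DataFrame for many); the circuit activity is the effector row.
    """
    g = circuit.graph
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"cycle detected: {cycle}")
    if isinstance(node_values, pd.DataFrame):
        v = {n: node_values.loc[n].to_numpy(float) for n in g}
        columns = node_values.columns
    else:
        v = {n: np.asarray(float(node_values[n])) for n in g}
        columns = None
    S: Dict[str, np.ndarray] = {}
    for n in nx.topological_sort(g):
        parents = list(g.predecessors(n))
        if not parents:
            S[n] = v[n]
            continue
        act = [S[p] for p in parents if g.edges[p, n]["sign"] > 0]
        inh = [S[p] for p in parents if g.edges[p, n]["sign"] < 0]
        activation = 1.0 - np.prod([1.0 - a for a in act], axis=0) \
            if act else np.zeros_like(v[n])
        inhibition = np.prod([1.0 - i for i in inh], axis=0) if inh else 1.0
        S[n] = v[n] * activation * inhibition
    if columns is not None:
        return pd.DataFrame(S, index=columns).T
    return pd.Series({k: float(val) for k, val in S.items()})


def simulate_inhibition(expr: pd.DataFrame, targets: Iterable[str],
                        factor: float = 0.1) -> pd.DataFrame:
    """Multiply target-gene expression by ``factor`` (positive scale)."""
    targets = list(targets)
    if not targets:
        raise ValueError("target list is empty")
    present = [g for g in targets if g in expr.index]
    missing = sorted(set(targets) - set(present))
    if not present:
        raise ValueError(f"no target gene found in the matrix: {missing}")
    out = expr.copy()
    out.loc[present] = out.loc[present] * factor
    return out


def response_score(expr: pd.DataFrame, circuits: Sequence[CircuitGraph],
                   targets: Iterable[str], factor: float = 0.1,
                   per_node: bool = False) -> pd.DataFrame:
    """Per-patient response score for inhibiting a target gene set.

    Activities are propagated on node values computed before and after the
    inhibition (perturbed values rank-scaled against the unperturbed
    cohort); the score is the summed absolute activity change over
    circuits (or over all nodes with ``per_node=True``).
    """
    perturbed = simulate_inhibition(expr, targets, factor)
    target_set = set(targets)
    total = np.zeros(expr.shape[1])
    touched = False
    for circ in circuits:
        if not target_set & set(circ.genes()):
            continue
        touched = True
        before = propagate(circ, compute_node_values(expr, circ))
        after = propagate(circ, compute_node_values(perturbed, circ,
                                                    reference=expr))
        if per_node:
            total += np.abs(after.to_numpy() - before.to_numpy()).sum(axis=0)
        else:
            total += np.abs(after.loc[circ.effector].to_numpy()
                            - before.loc[circ.effector].to_numpy())
    if not touched:
        warnings.warn("no circuit contains any target gene; scores are 0")
    return pd.DataFrame({"score": total}, index=expr.columns)


def favorable_rate(scores: pd.Series, group: Sequence | None = None,
                   cohort: Sequence | None = None) -> float:
    """Fraction of the group scoring at or above the cohort-mean score.

    ``cohort`` selects the patients defining the mean (default: all);
    ``group`` selects the patients whose rate is reported (default: the
    cohort).  The threshold is inclusive (score >= mean is favorable).
    """
    scores = pd.Series(scores)
    pool = scores if cohort is None else scores.loc[list(cohort)]
    if pool.empty:
        raise ValueError("empty cohort")
    grp = pool if group is None else scores.loc[list(group)]
    if grp.empty:
        raise ValueError("empty group")
    return float((grp >= pool.mean()).mean())
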