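"""Partial-correlation network over the final regression model.

A sparse Gaussian graphical model is estimated over the outcome and the
retained predictors with the graphical LASSO (L1-penalized inverse
covariance, penalty chosen by cross-validated log-likelihood on a
log-spaced grid).  Partial correlations are read off the precision
matrix P as r_ij = -p_ij / sqrt(p_ii * p_jj); edges below |r| = 0.10 are
pruned for parsimony.  Outcome-to-feature edges carry the absolute
standardized stepwise coefficient as the node-strength annotation, and
2-D coordinates come from a seeded Fruchterman-Reingold spring layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import GraphicalLassoCV

from .stepwise import StepwiseModel

log = logging.getLogger(__name__)

__all__ = ["NetworkModel", "fit_glasso_network", "layout_network", "partial_correlations"]

EDGE_THRESHOLD = 0.10


@dataclass(frozen=True)
class NetworkModel:
    nodes: tuple[str, ...]
    node_weights: dict[str, float]  # |standardized beta|; outcome weight = 1
    outcome: str
    edges: tuple[tuple[str, str, float], ...]  # (u, v, partial correlation)
    threshold: float
    penalty: float
    layout: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, weight=self.node_weights.get(node, 0.0))
        for u, v, r in self.edges:
            g.add_edge(u, v, partial_correlation=r, weight=abs(r))
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": u, "target": v, "partial_correlation": r} for u, v, r in self.edges],
            columns=["source", "target", "partial_correlation"],
        )


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def fit_glasso_network(
    data: pd.DataFrame,
    outcome: str,
    stepwise_model: StepwiseModel | None = None,
    threshold: float = EDGE_THRESHOLD,
    n_alphas: int = 20,
    cv: int = 5,
) -> NetworkModel:
    """Estimate the pruned partial-correlation network.

    ``data`` holds standardized columns for the outcome and the model
    variables (>= 3 columns).  The penalty grid has ``n_alphas``
    log-spaced values selected by ``cv``-fold cross-validated
    log-likelihood; a non-positive-definite fit falls back to a stronger
    penalty with a warning.
    """
    if data.shape[1] < 3:
        raise ValueError("network estimation needs at least 3 variables")
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} missing from data")
    X = data.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    model = GraphicalLassoCV(alphas=n_alphas, cv=cv, max_iter=500)
    try:
        model.fit(X)
        precision = model.precision_
        penalty = float(model.alpha_)
    except FloatingPointError:  # pragma: no cover - degenerate input fallback
        log.warning("graphical lasso failed to converge; refitting with strong penalty")
        model = GraphicalLassoCV(alphas=np.logspace(-0.5, 0.5, 5), cv=cv, max_iter=500)
        model.fit(X)
        precision = model.precision_
        penalty = float(model.alpha_)

    pc = partial_correlations(precision)
    cols = list(data.columns)
    edges = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(pc[i, j])
            if abs(r) >= threshold:
                edges.append((cols[i], cols[j], r))

    weights = {outcome: 1.0}
    if stepwise_model is not None:
        for term in stepwise_model.terms:
            weights[term.name] = abs(term.beta)
    for c in cols:
        weights.setdefault(c, 0.0)

    return NetworkModel(
        nodes=tuple(cols),
        node_weights=weights,
        outcome=outcome,
        edges=tuple(edges),
        threshold=threshold,
        penalty=penalty,
    )


def layout_network(network: NetworkModel, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Deterministic 2-D Fruchterman-Reingold coordinates.

    Stronger edges pull nodes together (spring weight = |partial
    correlation|); a single node is placed at the origin by convention.
    """
    g = network.to_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty network")
    if g.number_of_nodes() == 1:
        return {next(iter(g.nodes)): (0.0, 0.0)}
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    return {node: (float(xy[0]), float(xy[1])) for node, xy in pos.items()}
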