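"""Partial-correlation connectivity over a fixed 11-node DMN/FPN parcellation.

Per-subject functional connectivity is summarized as the partial correlation
between every pair of node time series, i.e. the correlation of each pair
conditioned on all remaining nodes, obtained from the normalized negative
inverse of the sample covariance matrix.  Edges are vectorized in a single
canonical order (upper triangle, row-major over the atlas node order) and each
edge is labelled with the network pair it connects: within the default mode
network (DMN), within the frontoparietal network (FPN), or between the two.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NODE_LABELS",
    "DEFAULT_NODE_NETWORKS",
    "EdgeVector",
    "edge_keys",
    "classify_edges",
    "partial_correlation",
    "partial_correlation_from_precision",
    "cohort_edge_table",
]

# 4 DMN nodes + 7 FPN nodes -> 55 pairwise edges.  The left posterior
# temporal region of the frontoparietal atlas is deliberately absent: the
# analysed parcellation has exactly 11 nodes.
DEFAULT_NODE_LABELS: tuple[str, ...] = (
    "F_DMN",
    "M_DMN",
    "L_DMN",
    "R_DMN",
    "L_dorsolateral_prefrontal",
    "R_dorsolateral_prefrontal",
    "L_parietal",
    "R_parietal",
    "L_frontal_pole",
    "R_frontal_pole",
    "R_posterior_temporal",
)

DEFAULT_NODE_NETWORKS: dict[str, str] = {
    "F_DMN": "DMN",
    "M_DMN": "DMN",
    "L_DMN": "DMN",
    "R_DMN": "DMN",
    "L_dorsolateral_prefrontal": "FPN",
    "R_dorsolateral_prefrontal": "FPN",
    "L_parietal": "FPN",
    "R_parietal": "FPN",
    "L_frontal_pole": "FPN",
    "R_frontal_pole": "FPN",
    "R_posterior_temporal": "FPN",
}


def edge_keys(node_labels: Sequence[str] = DEFAULT_NODE_LABELS) -> list[tuple[str, str]]:
    """Canonical edge ordering: upper triangle, row-major, i < j."""
    return list(itertools.combinations(node_labels, 2))


def classify_edges(
    keys: Sequence[tuple[str, str]],
    node_networks: dict[str, str] | None = None,
) -> list[str]:
    """Map each (node_i, node_j) edge to its network-pair class.

    Both endpoints in the DMN -> ``"DMN<->DMN"``; both in the FPN (either
    hemisphere) -> ``"FPN<->FPN"``; one of each -> ``"FPN<->DMN"``.
    """
    networks = DEFAULT_NODE_NETWORKS if node_networks is None else node_networks
    labels = []
    for a, b in keys:
        for node in (a, b):
            if node not in networks:
                raise KeyError(f"node {node!r} missing from the network label table")
        na, nb = networks[a], networks[b]
        if na == nb:
            labels.append(f"{na}<->{na}")
        else:
            labels.append("FPN<->DMN")
    return labels


@dataclass
class EdgeVector:
    """Vectorized partial-correlation connectome for one subject."""

    values: np.ndarray
    edge_keys: list[tuple[str, str]]
    network_pair: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_nodes = (1 + np.sqrt(1 + 8 * self.values.size)) / 2
        if not float(n_nodes).is_integer():
            raise ValueError("edge vector length is not n*(n-1)/2 for integer n")
        if len(self.edge_keys) != self.values.size:
            raise ValueError("edge_keys length does not match values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("edge values must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.values, index=[f"{a}__{b}" for a, b in self.edge_keys], name=self.subject_id
        )


def partial_correlation_from_precision(precision: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a precision matrix.

    rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj), unit diagonal.
    """
    omega = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def partial_correlation(
    node_series,
    node_labels: Sequence[str] | None = None,
    shrinkage: bool = False,
    subject_id: str = "",
) -> EdgeVector:
    """Estimate the per-subject partial-correlation edge vector.

    Parameters
    ----------
    node_series
        T x N array (or a ``NodeTimeSeriesMatrix`` with ``.values`` /
        ``.node_labels``) of cleaned node signals.
    shrinkage
        Use a Ledoit-Wolf shrunk covariance instead of the empirical one.
        Required when the empirical covariance is singular (e.g. T <= N).
    """
    if hasattr(node_series, "values") and hasattr(node_series, "node_labels"):
        if node_labels is None:
            node_labels = list(node_series.node_labels)
        if not subject_id:
            subject_id = getattr(node_series, "subject_id", "")
        node_series = node_series.values
    X = np.asarray(node_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("node series must be a T x N matrix")
    T, N = X.shape
    if node_labels is None:
        node_labels = [f"node{i}" for i in range(N)]
    if len(node_labels) != N:
        raise ValueError("node_labels length does not match the number of columns")

    if shrinkage:
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf(assume_centered=False).fit(X).covariance_
    else:
        if T <= N:
            raise ValueError(
                f"T={T} <= N={N}: empirical covariance is singular; "
                "enable shrinkage (shrinkage=True)"
            )
        cov = np.cov(X, rowvar=False)

    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or logdet < N * np.log(np.finfo(float).tiny) / 2:
        raise np.linalg.LinAlgError(
            "sample covariance is singular; enable shrinkage (shrinkage=True)"
        )
    try:
        omega = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - slogdet guards first
        raise np.linalg.LinAlgError(
            "sample covariance could not be inverted; enable shrinkage"
        ) from exc

    rho = partial_correlation_from_precision(omega)
    iu = np.triu_indices(N, k=1)
    keys = edge_keys(node_labels)
    try:
        pairs = classify_edges(keys)
    except KeyError:
        pairs = ["unknown"] * len(keys)
    return EdgeVector(values=rho[iu], edge_keys=keys, network_pair=pairs, subject_id=subject_id)


def cohort_edge_table(edge_vectors: Sequence[EdgeVector]) -> pd.DataFrame:
    """Stack per-subject edge vectors into a subjects x edges DataFrame."""
    if not edge_vectors:
        return pd.DataFrame()
    first = edge_vectors[0]
    for ev in edge_vectors[1:]:
        if ev.edge_keys != first.edge_keys:
            raise ValueError("edge vectors have inconsistent edge orderings")
    df = pd.DataFrame([ev.as_series() for ev in edge_vectors])
    df.index.name = "subject_id"
    return df
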