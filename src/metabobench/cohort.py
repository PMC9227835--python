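"""Cohort-style analysis on a raw feature table.

Mirrors a typical population-cohort metabolomics workflow: raw
intensities are log-transformed and standardized to mean 0 / SD 1 per
metabolite; each method is run against a continuous (age) or binary
(sex) trait, optionally adjusting for specimen batch; method
agreement is summarized as the seven regions of a three-set Venn
partition; and metabolite relatedness is summarized as a thresholded
Spearman correlation network with per-method selection annotations,
exportable as a force-layout JSON edge list or GraphML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .methods import (
    DEFAULT_FDR_Q,
    MethodOutput,
    bh_select,
    bonferroni_select,
    lasso_fit,
    spls_fit,
    splsda_fit,
    univariate_scan,
)
from .simdata import FeatureTable

__all__ = [
    "NetworkEdges",
    "preprocess_table",
    "run_cohort_methods",
    "venn_counts",
    "spearman_network",
    "export_network",
]


def preprocess_table(table: FeatureTable) -> np.ndarray:
    """Natural log then per-column z-score; columns end with mean 0, SD 1.

    Raises on nonpositive intensities (naming the offending sample and
    metabolite) and on zero-variance metabolites, which cannot be
    standardized.
    """
    x = np.asarray(table.intensities, dtype=float)
    bad = np.argwhere(x <= 0)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"nonpositive intensity for sample {table.sample_ids[i]!r}, "
            f"metabolite {table.metabolite_ids[j]!r}: {x[i, j]!r}"
        )
    logged = np.log(x)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=0)
    zero_var = np.flatnonzero(sd < 1e-12)
    if len(zero_var):
        raise ValueError(
            f"zero-variance metabolite {table.metabolite_ids[zero_var[0]]!r}: "
            "cannot standardize"
        )
    return (logged - mean) / sd


def _batch_dummies(batch: Sequence) -> np.ndarray:
    return pd.get_dummies(pd.Series(batch), drop_first=True).to_numpy(dtype=float)


def run_cohort_methods(
    Z: np.ndarray,
    outcome: np.ndarray,
    batch: Optional[Sequence] = None,
    q: float = DEFAULT_FDR_Q,
    alpha: float = 0.05,
    seed: int = 0,
    lasso_options: Optional[dict] = None,
    spls_options: Optional[dict] = None,
) -> Dict[str, MethodOutput]:
    """Bonferroni, FDR, LASSO, and SPLS(-DA) on a standardized matrix.

    Binary outcomes (exactly two levels, coded 0/1) route to SPLSDA and
    logistic LASSO; continuous outcomes to SPLS and linear LASSO.  When
    a batch factor is supplied it enters all models as an unpenalized
    indicator covariate.
    """
    Z = np.asarray(Z, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if len(outcome) != Z.shape[0]:
        raise ValueError("outcome length does not match the number of samples")
    binary = set(np.unique(outcome)).issubset({0.0, 1.0})
    outcome_type = "binary" if binary else "continuous"
    cov = _batch_dummies(batch) if batch is not None else None

    pvals, coef = univariate_scan(Z, outcome, outcome_type, adjust_covariates=cov)
    out: Dict[str, MethodOutput] = {
        "bonferroni": MethodOutput(
            "bonferroni", np.abs(coef), bonferroni_select(pvals, alpha),
            {"alpha": alpha}, pvals,
        ),
        "fdr": MethodOutput("fdr", np.abs(coef), bh_select(pvals, q), {"q": q}, pvals),
        "lasso": lasso_fit(
            Z, outcome, outcome_type, adjust_covariates=cov, seed=seed,
            **(lasso_options or {}),
        ),
    }
    if binary:
        out["spls"] = splsda_fit(Z, outcome, seed=seed, **(spls_options or {}))
    else:
        out["spls"] = spls_fit(Z, outcome, seed=seed, **(spls_options or {}))
    return out


def venn_counts(sets: Dict[str, Iterable[int]]) -> Dict[str, int]:
    """Counts of the 7 regions of a three-set Venn partition.

    Keys are '&'-joined sorted method names (e.g. 'fdr', 'fdr&lasso',
    'fdr&lasso&spls'); counts sum to the size of the union.
    """
    if len(sets) != 3:
        raise ValueError("venn_counts requires exactly three named sets")
    names = sorted(sets)
    s = {n: set(map(int, sets[n])) for n in names}
    a, b, c = (s[n] for n in names)
    regions = {
        names[0]: a - b - c,
        names[1]: b - a - c,
        names[2]: c - a - b,
        f"{names[0]}&{names[1]}": (a & b) - c,
        f"{names[0]}&{names[2]}": (a & c) - b,
        f"{names[1]}&{names[2]}": (b & c) - a,
        f"{names[0]}&{names[1]}&{names[2]}": a & b & c,
    }
    return {k: len(v) for k, v in regions.items()}


@dataclass
class NetworkEdges:
    """Thresholded Spearman correlation network with selection annotations."""

    edges: list  # (metabolite_i, metabolite_j, rho), i < j
    threshold: float
    node_annotations: Dict[str, set] = field(default_factory=dict)
    node_ids: list = field(default_factory=list)


def spearman_network(
    Z: np.ndarray,
    threshold: float = 0.75,
    metabolite_ids: Optional[Sequence[str]] = None,
    annotations: Optional[Dict[str, Iterable[int]]] = None,
) -> NetworkEdges:
    """Edges between metabolite pairs with Spearman rho above the threshold.

    The default +0.75 cut keeps strongly positively correlated pairs
    (signed rho, not |rho|).  ``annotations`` maps method name to the
    selected index set; the resulting node annotation records which
    methods selected each metabolite.
    """
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if n < 3:
        raise ValueError("Spearman network requires at least 3 samples")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    ids = list(metabolite_ids) if metabolite_ids is not None else [f"met{j+1:04d}" for j in range(m)]
    if m == 1:
        rho = np.ones((1, 1))
    else:
        rho = stats.spearmanr(Z).statistic
        rho = np.atleast_2d(rho)
    iu, ju = np.triu_indices(m, k=1)
    keep = rho[iu, ju] > threshold
    edges = [(ids[i], ids[j], float(rho[i, j])) for i, j in zip(iu[keep], ju[keep])]
    node_ann: Dict[str, set] = {mid: set() for mid in ids}
    for method, sel in (annotations or {}).items():
        for j in sel:
            node_ann[ids[int(j)]].add(method)
    return NetworkEdges(edges=edges, threshold=float(threshold),
                        node_annotations=node_ann, node_ids=ids)


def _to_graph(net: NetworkEdges) -> nx.Graph:
    g = nx.Graph()
    connected = {i for e in net.edges for i in e[:2]}
    for node in sorted(connected):
        g.add_node(node, methods=",".join(sorted(net.node_annotations.get(node, set()))))
    for i, j, rho in net.edges:
        g.add_edge(i, j, rho=float(rho))
    return g


def export_network(net: NetworkEdges, path: str | Path) -> tuple[Path, Path]:
    """Write the network as force-layout JSON and as GraphML.

    ``path`` is a stem; '<stem>.json' and '<stem>.graphml' are written.
    Only nodes participating in at least one edge are exported.
    """
    path = Path(path)
    g = _to_graph(net)
    payload = {
        "nodes": [
            {"id": n, "methods": sorted(net.node_annotations.get(n, set()))}
            for n in g.nodes
        ],
        "links": [
            {"source": i, "target": j, "rho": float(d["rho"])} for i, j, d in g.edges(data=True)
        ],
    }
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=2))
    graphml_path = path.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    return json_path, graphml_path
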