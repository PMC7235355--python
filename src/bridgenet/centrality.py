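"""Expected influence and bridge expected influence centrality.

Expected influence (EI) is the signed sum of a node's edge weights —
unlike strength it keeps the direction of associations, which matters in
comorbidity networks where negative edges occur. One-step and two-step
variants:

    EI1(i) = Σ_j W_ij
    EI2(i) = EI1(i) + Σ_j W_ij · EI1(j)

Bridge EI restricts the one-step sum to edges crossing a community
partition (e.g., eating-disorder items vs autism-trait items), quantifying
how strongly a node connects the two symptom clusters:

    BEI1(i) = Σ_{j: comm(j) ≠ comm(i)} W_ij
    BEI2(i) = BEI1(i) + Σ_{j≠i} W_ij · BEI1(j)

The two-step sums include the back-edge through the node itself inside the
neighbor's one-step term (the purely additive reading of "secondary
influence via immediate neighbors"); see the methods note for why, and for
the exclusion variant this choice was preferred over.

Z-scored columns (mean 0, sample sd 1 across nodes, within metric) are
reported alongside raw values for comparability.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .network import NetworkModel


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if not np.allclose(np.diag(W), 0, atol=1e-12):
        raise ValueError("W must have zero diagonal")
    return W


def expected_influence(W: np.ndarray, steps: int = 1) -> np.ndarray:
    """Signed expected influence, one- or two-step."""
    W = _check_weights(W)
    ei1 = W.sum(axis=1)
    if steps == 1:
        return ei1
    if steps == 2:
        return ei1 + W @ ei1
    raise ValueError("steps must be 1 or 2")


def bridge_expected_influence(
    W: np.ndarray, communities: Sequence[str], steps: int = 1
) -> np.ndarray:
    """Expected influence restricted to cross-community edges."""
    W = _check_weights(W)
    communities = list(communities)
    if len(communities) != W.shape[0]:
        raise ValueError("one community label per node required")
    if any(c is None or c == "" for c in communities):
        raise ValueError("unlabeled node(s)")
    if len(set(communities)) < 2:
        raise ValueError("need at least 2 communities for bridge centrality")
    labels = np.asarray(communities)
    cross = labels[:, None] != labels[None, :]
    bei1 = (W * cross).sum(axis=1)
    if steps == 1:
        return bei1
    if steps == 2:
        return bei1 + W @ bei1
    raise ValueError("steps must be 1 or 2")


def zscore(values: np.ndarray) -> np.ndarray:
    """(v − mean)/sd with the sample (n−1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; z-scores undefined (report raw values)")
    return (v - v.mean()) / sd


def centrality_table(model: NetworkModel) -> pd.DataFrame:
    """Per-node EI1/EI2 and bridge EI1/EI2, raw and z-scored.

    Falls back to NaN z-columns when a metric is constant across nodes
    (z-scores undefined; raw values remain authoritative).
    """
    W = model.W
    cols = {
        "ei1": expected_influence(W, 1),
        "ei2": expected_influence(W, 2),
        "bridge_ei1": bridge_expected_influence(W, model.communities, 1),
        "bridge_ei2": bridge_expected_influence(W, model.communities, 2),
    }
    out = pd.DataFrame(
        {"item": model.items, "community": model.communities, **cols}
    )
    for name, v in cols.items():
        try:
            out[f"z_{name}"] = zscore(v)
        except ValueError:
            out[f"z_{name}"] = np.nan
    return out


def rank_nodes(table: pd.DataFrame, metric: str = "ei1", k: int | None = None) -> list[str]:
    """Top-k item ids by descending metric; ties broken by item_id."""
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}")
    if k is None:
        k = len(table)
    order = table.sort_values(
        by=[metric, "item"], ascending=[False, True], kind="mergesort"
    )
    return order["item"].head(k).tolist()
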