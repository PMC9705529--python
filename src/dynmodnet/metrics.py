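"""Dynamic modular network metrics.

All metrics derive from either the partition ensemble of a trial or its
connectivity stack:

* **flexibility** — per node, the ratio F = S/T of the number of
  consecutive-window module changes S to the number of time windows T,
  averaged over detection repetitions.  Bounded by (T-1)/T.
* **module allegiance** — P[i, j], the fraction of (repetition, window)
  observations in which nodes i and j share a module; pooling over both
  repetitions and windows uses every observation the ensemble provides.
* **recruitment** — a node's mean allegiance with the other nodes of its
  own large-scale system; system value = mean over its nodes.
* **integration** — mean allegiance between the nodes of two different
  systems (pairwise form), or the mean of the pairwise values over all
  unordered pairs of the four reported systems (overall form).
* **node-to-system density** — mean connectivity weight between one node
  and all nodes of a target system, across windows.

System-level summaries cover the named systems only; "Others" nodes
participate in the underlying graphs but are excluded here.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import SystemMap
from .community import PartitionEnsemble
from .connectivity import ConnectivityStack

#: Systems entering the overall-integration average.
INTEGRATION_SYSTEMS: tuple[str, ...] = ("SMN", "DMN", "VN", "ATN")


class MetricError(ValueError):
    pass


def flexibility(labels: np.ndarray) -> np.ndarray:
    """Per-node flexibility F = S/T of one node-by-layer partition."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise MetricError("flexibility undefined for T<2")
    T = labels.shape[1]
    s = (labels[:, 1:] != labels[:, :-1]).sum(axis=1)
    return s / T


def ensemble_flexibility(ens: PartitionEnsemble) -> np.ndarray:
    """Per-node flexibility averaged over the ensemble's repetitions."""
    if ens.n_layers < 2:
        raise MetricError("flexibility undefined for T<2")
    per_rep = (ens.labels[:, :, 1:] != ens.labels[:, :, :-1]).sum(axis=2) / ens.n_layers
    return per_rep.mean(axis=0)


def allegiance(ens: PartitionEnsemble) -> np.ndarray:
    """Module-allegiance matrix pooled over repetitions and layers.

    P[i, j] = (# of (repetition, layer) observations with shared label) / (R*T).
    """
    R, N, T = ens.labels.shape
    if R < 1:
        raise MetricError("empty ensemble")
    P = np.zeros((N, N))
    for r in range(R):
        lab = ens.labels[r]                      # (N, T)
        P += (lab[:, None, :] == lab[None, :, :]).sum(axis=2)
    P /= R * T
    np.fill_diagonal(P, 1.0)
    return P


def layer_allegiance(ens: PartitionEnsemble, layer: int) -> np.ndarray:
    """Allegiance restricted to a single layer (pooled over repetitions only)."""
    lab = ens.labels[:, :, layer]                # (R, N)
    P = (lab[:, :, None] == lab[:, None, :]).mean(axis=0)
    np.fill_diagonal(P, 1.0)
    return P


def _mean_allegiance(
    P: np.ndarray, nodes_a: Sequence[int], nodes_b: Sequence[int], exclude_same: bool
) -> float:
    a = np.fromiter(nodes_a, dtype=int)
    b = np.fromiter(nodes_b, dtype=int)
    sub = P[np.ix_(a, b)]
    if exclude_same:
        mask = a[:, None] != b[None, :]
        if not mask.any():
            raise MetricError("no node pairs left after excluding self-pairs")
        return float(sub[mask].mean())
    return float(sub.mean())


def recruitment(
    P: np.ndarray, system_map: SystemMap, system: str, per_node: bool = False
) -> float | np.ndarray:
    """Within-system co-occurrence probability.

    Node form: mean of P[i, j] over same-system partners j != i.
    System form (default): mean of the node values.
    """
    nodes = sorted(system_map.members(system))
    if len(nodes) < 2:
        raise MetricError(f"recruitment undefined for singleton system {system!r}")
    idx = np.array(nodes)
    sub = P[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.nan)
    node_vals = np.nanmean(sub, axis=1)
    return node_vals if per_node else float(node_vals.mean())


def integration(P: np.ndarray, system_map: SystemMap, system_a: str, system_b: str) -> float:
    """Pairwise integration: mean allegiance between two disjoint systems."""
    if system_a == system_b:
        raise MetricError("pairwise integration requires two different systems")
    nodes_a = sorted(system_map.members(system_a))
    nodes_b = sorted(system_map.members(system_b))
    if not nodes_a or not nodes_b:
        raise MetricError("both systems must be non-empty")
    if set(nodes_a) & set(nodes_b):
        raise MetricError("systems overlap")
    return _mean_allegiance(P, nodes_a, nodes_b, exclude_same=False)


def overall_integration(
    P: np.ndarray,
    system_map: SystemMap,
    systems: Iterable[str] = INTEGRATION_SYSTEMS,
) -> float:
    """Mean pairwise integration over all unordered pairs of the named systems."""
    systems = [s for s in systems if system_map.members(s)]
    if len(systems) < 2:
        raise MetricError("overall integration needs at least two non-empty systems")
    vals = [integration(P, system_map, a, b) for a, b in combinations(systems, 2)]
    return float(np.mean(vals))


def node_to_system_density(
    stack: ConnectivityStack, system_map: SystemMap, node: int, system: str
) -> float:
    """Mean connectivity weight between one node and a target system.

    Averages the stack over windows and over the system's nodes (the node
    itself excluded when it belongs to the system).
    """
    targets = sorted(system_map.members(system) - {node})
    if not targets:
        raise MetricError(f"no target nodes in system {system!r} after excluding node {node}")
    return float(stack.values[:, node, targets].mean())


def percent_change(pre: np.ndarray | float, post: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Signed and magnitude percent change, 100*(post-pre)/pre."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre == 0):
        raise MetricError("percent change undefined for zero baseline")
    signed = 100.0 * (post - pre) / pre
    return signed, np.abs(signed)


def metric_frame(
    ensembles: Sequence[PartitionEnsemble],
    stacks: Sequence[ConnectivityStack] | None,
    system_map: SystemMap,
    condition: str = "",
) -> pd.DataFrame:
    """Tidy per-trial metric table feeding the statistics module.

    One row per (trial, unit, metric): system flexibility, system
    recruitment, pairwise and overall integration, and (when stacks are
    given) node-to-system density for nodes of the named systems.
    """
    records: list[dict] = []
    named = [s for s in system_map.named_systems if len(system_map.members(s)) >= 2]
    for t, ens in enumerate(ensembles):
        flex = ensemble_flexibility(ens)
        P = allegiance(ens)
        for s in named:
            nodes = sorted(system_map.members(s))
            records.append(
                dict(trial=t, unit=s, metric="flexibility", value=float(flex[nodes].mean()))
            )
            records.append(dict(trial=t, unit=s, metric="recruitment", value=recruitment(P, system_map, s)))
        for a, b in combinations([s for s in INTEGRATION_SYSTEMS if s in named], 2):
            records.append(
                dict(trial=t, unit=f"{a}-{b}", metric="integration", value=integration(P, system_map, a, b))
            )
        present = [s for s in INTEGRATION_SYSTEMS if s in named]
        if len(present) >= 2:
            records.append(
                dict(trial=t, unit="overall", metric="integration",
                     value=overall_integration(P, system_map, present))
            )
        if stacks is not None:
            stack = stacks[t]
            for s in named:
                for node in sorted(set(range(system_map.n_nodes)) - system_map.members(s)):
                    if system_map.system_of(node) == "Others":
                        continue
                    records.append(
                        dict(trial=t, unit=f"n{node}->{s}", metric="density",
                             value=node_to_system_density(stack, system_map, node, s))
                    )
    frame = pd.DataFrame.from_records(records)
    if condition:
        frame.insert(0, "condition", condition)
    return frame
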