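"""Node roster and its partition into large-scale functional systems.

A *node* is a cortical region of interest (ROI) carrying one band-limited
time series per trial.  Each node belongs to exactly one large-scale
functional system: the somatomotor network (SMN), default mode network
(DMN), visual network (VN), attention network (ATN), task-positive network
(TPN), or — for regions outside those five — "Others".  Nodes labelled
"Others" take part in connectivity and community detection but are left out
of system-level metric summaries.

The bundled default table assigns the 80 AAL cortical regions to systems
following the standard functional-systems literature.  It is a stand-in for
any study-specific parcellation: every downstream metric takes a
:class:`SystemMap` argument, so the table is fully user-replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: The five named large-scale systems, in reporting order.
NAMED_SYSTEMS: tuple[str, ...] = ("SMN", "DMN", "VN", "ATN", "TPN")

#: Label for nodes outside the five named systems.
OTHERS: str = "Others"

#: All valid system labels.
ALL_SYSTEMS: tuple[str, ...] = NAMED_SYSTEMS + (OTHERS,)

_DEFAULT_RESOURCE = "aal80_systems.csv"


class AtlasError(ValueError):
    """Raised when a node table fails validation."""


def load_node_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate a node table.

    Parameters
    ----------
    path:
        CSV file with header ``node_id,label,system``.  ``None`` loads the
        bundled 80-node default table.

    Returns
    -------
    DataFrame with columns ``node_id`` (contiguous 0..N-1 ints), ``label``
    and ``system``, sorted by ``node_id``.
    """
    if path is None:
        with resources.files("dynmodnet.data").joinpath(_DEFAULT_RESOURCE).open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return validate_node_table(table)


def validate_node_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"node_id", "label", "system"}
    missing = required - set(table.columns)
    if missing:
        raise AtlasError(f"node table missing columns: {sorted(missing)}")
    table = table.copy()
    table["node_id"] = table["node_id"].astype(int)
    ids = table["node_id"].to_numpy()
    if len(set(ids)) != len(ids):
        dupes = sorted(table["node_id"][table["node_id"].duplicated()].unique())
        raise AtlasError(f"duplicate node_id values: {dupes}")
    table = table.sort_values("node_id").reset_index(drop=True)
    if not (table["node_id"] == range(len(table))).all():
        raise AtlasError("non-contiguous node ids: expected 0..N-1 with no gaps")
    bad = table[~table["system"].isin(ALL_SYSTEMS)]
    if not bad.empty:
        row = bad.iloc[0]
        raise AtlasError(
            f"unknown system label {row['system']!r} for node_id {row['node_id']} "
            f"(label {row['label']!r}); valid labels: {ALL_SYSTEMS}"
        )
    return table


def save_node_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a node table so that :func:`load_node_table` round-trips it."""
    validate_node_table(table).to_csv(path, index=False)


@dataclass(frozen=True)
class SystemMap:
    """Assignment of each node to one large-scale system.

    ``named_systems`` lists the systems used in system-level reporting;
    "Others" nodes are retained in the roster but excluded from summaries.
    """

    systems: tuple[str, ...]          # per-node system label, index = node_id
    node_labels: tuple[str, ...] = field(default=())
    named_systems: tuple[str, ...] = NAMED_SYSTEMS

    def __post_init__(self) -> None:
        for s in self.systems:
            if s not in ALL_SYSTEMS:
                raise AtlasError(f"unknown system label {s!r}")
        present = tuple(s for s in self.named_systems if s in set(self.systems))
        object.__setattr__(self, "named_systems", present)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "SystemMap":
        table = validate_node_table(table)
        return cls(
            systems=tuple(table["system"]),
            node_labels=tuple(table["label"]),
        )

    @classmethod
    def default(cls) -> "SystemMap":
        return cls.from_table(load_node_table())

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, str] | Iterable[str]) -> "SystemMap":
        if isinstance(mapping, Mapping):
            n = len(mapping)
            if sorted(mapping) != list(range(n)):
                raise AtlasError("mapping keys must be contiguous 0..N-1 node ids")
            return cls(systems=tuple(mapping[i] for i in range(n)))
        return cls(systems=tuple(mapping))

    @property
    def n_nodes(self) -> int:
        return len(self.systems)

    def members(self, system: str) -> frozenset[int]:
        """Node ids belonging to ``system`` (may be empty)."""
        if system not in ALL_SYSTEMS:
            raise AtlasError(f"unknown system label {system!r}")
        return frozenset(i for i, s in enumerate(self.systems) if s == system)

    def system_of(self, node_id: int) -> str:
        return self.systems[node_id]


def system_members(system_map: SystemMap, system: str) -> frozenset[int]:
    """Functional alias for :meth:`SystemMap.members`."""
    return system_map.members(system)
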