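"""Wiring-diagram container: neurons, gap junctions, chemical synapses.

The connectome is represented by an ordered neuron registry and two N x N
weight matrices holding synaptic contact counts:

* ``gap`` — electrical synapses (gap junctions).  Stored symmetric with zero
  diagonal; an entry is the total contact weight of the unordered pair.
* ``chem`` — chemical synapses, directed pre -> post: ``chem[i, j]`` is the
  contact weight of the synapse from neuron ``i`` onto neuron ``j``.

Matrix order is the neuron-table order and is persisted by the writers, so
trace columns are reproducible across runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Neuron",
    "Connectome",
    "NeuronGroup",
    "ConnectomeError",
    "load_connectome",
    "write_connectome",
    "load_connectome_json",
    "write_connectome_json",
    "resolve_group",
    "ablate",
    "BUILTIN_ALIASES",
]

CATEGORIES = ("sensory", "inter", "motor")

#: Group aliases that are concepts of the avoidance-circuit literature rather
#: than anatomical class names.  "CI" = the AVA/AVD/AVE command interneurons
#: driving backward locomotion; "backward_motor" = the five motor-neuron
#: classes active during backing (VA/DA/AS excitatory-phase, VD/DD GABAergic).
BUILTIN_ALIASES: dict[str, tuple[str, ...]] = {
    "CI": ("AVA", "AVD", "AVE"),
    "backward_motor": ("VA", "DA", "VD", "DD", "AS"),
}


class ConnectomeError(ValueError):
    """Raised for malformed wiring inputs or unresolvable neuron groups."""


@dataclass(frozen=True)
class Neuron:
    """One neuron: unique name, bilateral class label, category, sign."""

    name: str
    class_label: str
    category: str  # sensory | inter | motor
    inhibitory: bool
    index: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConnectomeError(
                f"neuron {self.name!r}: category {self.category!r} "
                f"not in {CATEGORIES}"
            )


@dataclass(frozen=True)
class NeuronGroup:
    group_name: str
    members: tuple[str, ...]


@dataclass
class Connectome:
    """Ordered neuron list plus gap and chemical weight matrices."""

    neurons: list[Neuron]
    gap: np.ndarray
    chem: np.ndarray
    version_tag: str = ""
    ablated: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.neurons)
        self.gap = np.asarray(self.gap, dtype=float)
        self.chem = np.asarray(self.chem, dtype=float)
        if self.gap.shape != (n, n) or self.chem.shape != (n, n):
            raise ConnectomeError(
                f"matrix shapes {self.gap.shape}/{self.chem.shape} do not "
                f"match neuron count {n}"
            )
        names = [nr.name for nr in self.neurons]
        if len(set(names)) != n:
            raise ConnectomeError("duplicate neuron names in registry")
        if [nr.index for nr in self.neurons] != list(range(n)):
            raise ConnectomeError("neuron indices are not 0..N-1 in order")
        if (self.gap < 0).any() or (self.chem < 0).any():
            raise ConnectomeError("negative synaptic weights")
        if not np.allclose(self.gap, self.gap.T):
            raise ConnectomeError("gap matrix is not symmetric")
        if np.diagonal(self.gap).any() or np.diagonal(self.chem).any():
            raise ConnectomeError("self-connections (nonzero diagonal)")
        self._index = {name: i for i, name in enumerate(names)}

    # -- lookup helpers ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.neurons)

    @property
    def names(self) -> list[str]:
        return [nr.name for nr in self.neurons]

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConnectomeError(f"unknown neuron {name!r}") from None

    def indices_of(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.index_of(nm) for nm in names], dtype=int)

    @property
    def inhibitory_mask(self) -> np.ndarray:
        return np.array([nr.inhibitory for nr in self.neurons], dtype=bool)

    def class_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for nr in self.neurons:
            seen.setdefault(nr.class_label, None)
        return list(seen)


# ---------------------------------------------------------------------------
# loading / writing


def _symmetrize_gap(gap_in: np.ndarray) -> np.ndarray:
    """Symmetrize raw directed gap entries.

    Convention: the weight of an unordered pair is the maximum-information
    merge — if both directions are listed they are treated as the same
    contacts reported twice and the pair weight is their mean; if only one
    direction is listed it is mirrored as-is.
    """
    sym = np.maximum(gap_in, gap_in.T)
    both = (gap_in > 0) & (gap_in.T > 0)
    sym[both] = ((gap_in + gap_in.T) / 2.0)[both]
    return sym


def load_connectome(
    neuron_table_path: str | Path, edge_list_path: str | Path
) -> Connectome:
    """Load a connectome from a neuron-table CSV and an edge-list CSV.

    Neuron table header: ``name,class,category,inhibitory``.
    Edge list header: ``pre,post,type,weight`` with type in {gap, chemical}.
    """
    ntab = pd.read_csv(neuron_table_path, dtype={"name": str, "class": str})
    required = {"name", "class", "category", "inhibitory"}
    if not required.issubset(ntab.columns):
        raise ConnectomeError(
            f"neuron table must have columns {sorted(required)}"
        )
    neurons = [
        Neuron(
            name=str(r["name"]),
            class_label=str(r["class"]),
            category=str(r["category"]),
            inhibitory=_parse_bool(r["inhibitory"]),
            index=i,
        )
        for i, (_, r) in enumerate(ntab.iterrows())
    ]
    edges = pd.read_csv(edge_list_path)
    if len(edges) == 0:
        edges = pd.DataFrame(columns=["pre", "post", "type", "weight"])
    names = [nr.name for nr in neurons]
    gap_raw, chem = _accumulate_edges(names, edges)
    gap = _symmetrize_gap(gap_raw)
    return Connectome(
        neurons=neurons, gap=gap, chem=chem, version_tag=str(neuron_table_path)
    )


def _accumulate_edges(
    names: Sequence[str], edges: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    n = len(names)
    index = {nm: i for i, nm in enumerate(names)}
    gap = np.zeros((n, n))
    chem = np.zeros((n, n))
    for row_no, row in enumerate(edges.itertuples(index=False)):
        pre, post = str(row.pre), str(row.post)
        etype, w = str(row.type), float(row.weight)
        for nm in (pre, post):
            if nm not in index:
                raise ConnectomeError(f"edge row {row_no}: unknown neuron {nm!r}")
        if w < 0:
            raise ConnectomeError(f"edge row {row_no}: negative weight {w}")
        if pre == post:
            raise ConnectomeError(f"edge row {row_no}: self-edge {pre!r}")
        if etype == "gap":
            gap[index[pre], index[post]] += w
        elif etype == "chemical":
            chem[index[pre], index[post]] += w
        else:
            raise ConnectomeError(
                f"edge row {row_no}: type {etype!r} not in ('gap', 'chemical')"
            )
    if not np.array_equal(gap, gap.T):
        warnings.warn(
            "gap-junction edges not listed reciprocally; mirroring",
            stacklevel=3,
        )
    return gap, chem


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ConnectomeError(f"cannot parse inhibitory flag {x!r}")


def write_connectome(
    conn: Connectome, neuron_table_path: str | Path, edge_list_path: str | Path
) -> None:
    """Write the CSV dialect read by :func:`load_connectome` (round-trips)."""
    pd.DataFrame(
        {
            "name": conn.names,
            "class": [nr.class_label for nr in conn.neurons],
            "category": [nr.category for nr in conn.neurons],
            "inhibitory": [nr.inhibitory for nr in conn.neurons],
        }
    ).to_csv(neuron_table_path, index=False)
    rows = []
    names = conn.names
    # gap pairs written in both directions, the way reconstruction tables
    # list them, so reloading is warning-free and bit-exact
    ig, jg = np.nonzero(conn.gap)
    for i, j in zip(ig, jg):
        rows.append((names[i], names[j], "gap", conn.gap[i, j]))
    ic, jc = np.nonzero(conn.chem)
    for i, j in zip(ic, jc):
        rows.append((names[i], names[j], "chemical", conn.chem[i, j]))
    pd.DataFrame(rows, columns=["pre", "post", "type", "weight"]).to_csv(
        edge_list_path, index=False
    )


def load_connectome_json(path: str | Path) -> Connectome:
    """Single-file JSON dialect: keys ``neurons``, ``gap_edges``, ``chem_edges``."""
    with open(path) as fh:
        doc = json.load(fh)
    neurons = [
        Neuron(
            name=d["name"],
            class_label=d["class"],
            category=d["category"],
            inhibitory=bool(d["inhibitory"]),
            index=i,
        )
        for i, d in enumerate(doc["neurons"])
    ]
    names = [nr.name for nr in neurons]
    edges = pd.DataFrame(
        [(e[0], e[1], "gap", e[2]) for e in doc.get("gap_edges", [])]
        + [(e[0], e[1], "chemical", e[2]) for e in doc.get("chem_edges", [])],
        columns=["pre", "post", "type", "weight"],
    )
    gap_raw, chem = _accumulate_edges(names, edges)
    gap = _symmetrize_gap(gap_raw)
    return Connectome(
        neurons=neurons,
        gap=gap,
        chem=chem,
        version_tag=str(doc.get("version_tag", "")),
    )


def write_connectome_json(conn: Connectome, path: str | Path) -> None:
    names = conn.names
    iu, ju = np.nonzero(conn.gap)
    ic, jc = np.nonzero(conn.chem)
    doc = {
        "version_tag": conn.version_tag,
        "neurons": [
            {
                "name": nr.name,
                "class": nr.class_label,
                "category": nr.category,
                "inhibitory": nr.inhibitory,
            }
            for nr in conn.neurons
        ],
        "gap_edges": [
            [names[i], names[j], float(conn.gap[i, j])] for i, j in zip(iu, ju)
        ],
        "chem_edges": [
            [names[i], names[j], float(conn.chem[i, j])] for i, j in zip(ic, jc)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# groups and ablation


def resolve_group(
    conn: Connectome,
    group_name: str,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> NeuronGroup:
    """Resolve a class label, alias, or explicit neuron name to its members.

    A bilateral class label ("AWB") resolves to its L/R pair; a motor class
    ("VA") to all numbered members; "CI" and "backward_motor" are built-in
    aliases.  Members are returned in matrix order.
    """
    aliases = dict(BUILTIN_ALIASES) if aliases is None else dict(aliases)
    if group_name in aliases:
        members: list[str] = []
        for sub in aliases[group_name]:
            try:
                members.extend(resolve_group(conn, sub, aliases={}).members)
            except ConnectomeError:
                continue  # alias tolerates classes absent from a subnetwork
        if not members:
            raise ConnectomeError(
                f"alias {group_name!r} matches no neurons in this connectome"
            )
        return NeuronGroup(group_name, tuple(members))
    if group_name in conn._index:
        return NeuronGroup(group_name, (group_name,))
    members = [
        nr.name for nr in conn.neurons if nr.class_label == group_name
    ]
    if not members:
        available = sorted(set(conn.class_labels()) | set(aliases))
        raise ConnectomeError(
            f"unknown group {group_name!r}; available classes/aliases: "
            f"{', '.join(available)}"
        )
    return NeuronGroup(group_name, tuple(members))


def ablate(conn: Connectome, ablations: Iterable[str]) -> Connectome:
    """Structurally ablate neurons: zero every connection into or out of them.

    The neuron list and matrix ordering are unchanged, so indices stay stable
    across an ablation screen; an ablated neuron sits isolated at its leak
    equilibrium during simulation.  Idempotent.
    """
    names = frozenset(ablations)
    idx = conn.indices_of(names)  # validates existence
    gap = conn.gap.copy()
    chem = conn.chem.copy()
    if len(idx):
        gap[idx, :] = 0.0
        gap[:, idx] = 0.0
        chem[idx, :] = 0.0
        chem[:, idx] = 0.0
    return replace(
        conn, gap=gap, chem=chem, ablated=conn.ablated | names
    )
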