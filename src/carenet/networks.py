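"""Construction of provider communication networks from message records.

Three stages mirror the analysis design:

1. one **global network** over all encounter-linked messages;
2. **encounter subnetworks**, one per hospital encounter (for encounters
   with a deterioration, restricted to messages sent strictly before
   Time 0, the first rapid-response / code activation);
3. **epoch subnetworks**: 12-hour windows anchored at Time 0, by default
   (−36,−24], (−24,−12], (−12,0) — implemented as half-open [lower, upper)
   offsets in hours.

Nodes are providers labelled by role; a message with k recipients adds one
unit of weight to each of the k directed sender→recipient edges;
self-recipients never produce an edge.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd


class UsageError(ValueError):
    """An operation was called on inputs it is not defined for."""


@dataclass
class ProviderGraph:
    """Directed, integer-weighted provider graph.

    ``edges`` maps ordered (sender, recipient) pairs to the count of
    delivered (message, recipient) pairs; ``roles`` labels every node.
    """

    network_id: str
    roles: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    n_self_pairs_dropped: int = 0

    @property
    def nodes(self) -> list[str]:
        return sorted(self.roles)

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_weight(self) -> int:
        return sum(self.edges.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProviderGraph):
            return NotImplemented
        return self.roles == other.roles and self.edges == other.edges


@dataclass
class EpochSpec:
    """Ordered, contiguous, non-overlapping pre-Time-0 windows (hours)."""

    windows: list[tuple[float, float]] = field(
        default_factory=lambda: [(-36.0, -24.0), (-24.0, -12.0), (-12.0, 0.0)]
    )

    def __post_init__(self) -> None:
        if not self.windows:
            raise UsageError("EpochSpec requires at least one window")
        for lo, hi in self.windows:
            if not lo < hi:
                raise UsageError(f"window ({lo}, {hi}) has lower >= upper")
            if hi > 0:
                raise UsageError(f"window ({lo}, {hi}) extends past Time 0")
        for (_, hi_prev), (lo, _) in zip(self.windows, self.windows[1:]):
            if lo != hi_prev:
                raise UsageError("windows must be contiguous and ordered")

    def assign(self, hours_from_time0: float) -> Optional[tuple[float, float]]:
        """Window containing an offset: lower <= h < upper, else None."""
        for lo, hi in self.windows:
            if lo <= hours_from_time0 < hi:
                return (lo, hi)
        return None


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _build(
    rows: Iterable[tuple[str, list[str]]],
    role_of: Mapping[str, str],
    network_id: str,
) -> ProviderGraph:
    graph = ProviderGraph(network_id=network_id)
    edges: dict[tuple[str, str], int] = {}
    roles: dict[str, str] = {}
    dropped = 0
    for sender, recipients in rows:
        touched = False
        for r in recipients:
            if r == sender:
                dropped += 1
                continue
            key = (sender, r)
            edges[key] = edges.get(key, 0) + 1
            roles.setdefault(r, role_of.get(r, "other"))
            touched = True
        if touched:
            roles.setdefault(sender, role_of.get(sender, "other"))
    graph.edges = edges
    graph.roles = roles
    graph.n_self_pairs_dropped = dropped
    return graph


def _linked(messages: pd.DataFrame) -> pd.DataFrame:
    mask = messages["encounter_id"].notna()
    return messages.loc[mask]


def build_global_network(
    messages: pd.DataFrame,
    providers: pd.DataFrame,
    network_id: str = "global",
) -> ProviderGraph:
    """One network over all encounter-linked messages.

    A message with k distinct non-self recipients contributes weight 1 to
    each of k directed edges. Providers with no linked messages do not
    appear as nodes. An empty input yields an empty graph.
    """
    role_of = dict(zip(providers["provider_id"], providers["role"]))
    linked = _linked(messages)
    rows = zip(linked["sender_id"], linked["recipient_ids"])
    return _build(rows, role_of, network_id)


def build_encounter_subnetworks(
    messages: pd.DataFrame,
    encounters: pd.DataFrame,
    providers: pd.DataFrame,
) -> dict[str, ProviderGraph]:
    """One graph per encounter with >= 1 linked message."""
    role_of = dict(zip(providers["provider_id"], providers["role"]))
    known = set(encounters["encounter_id"])
    linked = _linked(messages)
    out: dict[str, ProviderGraph] = {}
    for enc_id, group in linked.groupby("encounter_id", sort=True):
        if enc_id not in known:
            continue
        g = _build(
            zip(group["sender_id"], group["recipient_ids"]), role_of, str(enc_id)
        )
        if g.n_nodes:
            out[str(enc_id)] = g
    return out


def encounter_time0(encounter_row: pd.Series) -> pd.Timestamp:
    dets = encounter_row["deterioration_times"]
    if not dets:
        raise UsageError(
            f"encounter '{encounter_row['encounter_id']}' has no deterioration"
        )
    return dets[0]


def filter_pre_deterioration(
    messages: pd.DataFrame, encounter_row: pd.Series
) -> pd.DataFrame:
    """Messages of one encounter sent strictly before Time 0.

    A message stamped exactly at Time 0 is excluded ("prior to" is strict).
    May legitimately return an empty frame — those encounters are the
    post-only subnetworks excluded from pre-deterioration analyses.
    """
    t0 = encounter_time0(encounter_row)
    enc_id = encounter_row["encounter_id"]
    sel = messages["encounter_id"] == enc_id
    return messages.loc[sel & (messages["sent_at"] < t0)]


def build_epoch_subnetworks(
    messages: pd.DataFrame,
    encounter_row: pd.Series,
    providers: pd.DataFrame,
    epochs: EpochSpec | None = None,
) -> dict[tuple[float, float], ProviderGraph]:
    """Per-window graphs anchored at Time 0; empty windows yield no graph."""
    epochs = epochs or EpochSpec()
    t0 = encounter_time0(encounter_row)
    enc_id = encounter_row["encounter_id"]
    role_of = dict(zip(providers["provider_id"], providers["role"]))
    sub = messages.loc[messages["encounter_id"] == enc_id]
    buckets: dict[tuple[float, float], list[tuple[str, list[str]]]] = {}
    for rec in sub.itertuples(index=False):
        hours = (rec.sent_at - t0).total_seconds() / 3600.0
        win = epochs.assign(hours)
        if win is None:
            continue
        buckets.setdefault(win, []).append((rec.sender_id, rec.recipient_ids))
    out = {}
    for win in epochs.windows:
        win = (win[0], win[1])
        if win in buckets:
            g = _build(buckets[win], role_of, f"{enc_id}@[{win[0]},{win[1]})")
            if g.n_nodes:
                out[win] = g
    return out


def undirected_projection(graph: ProviderGraph) -> dict[tuple[str, str], int]:
    """Undirected weights: {a,b} = w(a→b) + w(b→a), keyed by sorted pair."""
    out: dict[tuple[str, str], int] = {}
    for (u, v), w in graph.edges.items():
        key = (u, v) if u <= v else (v, u)
        out[key] = out.get(key, 0) + w
    return out


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def export_graph(graph: ProviderGraph, path: str | Path, format: str = "graphml") -> None:
    """Write GraphML (node attr ``role``, edge attr ``weight``) or an edge list."""
    if format == "graphml":
        _write_graphml(graph, path)
    elif format == "edgelist":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for (u, v), w in sorted(graph.edges.items()):
                writer.writerow([u, v, w])
    else:
        raise UsageError(f"unknown export format '{format}'")


def _write_graphml(graph: ProviderGraph, path: str | Path) -> None:
    root = ET.Element("graphml", xmlns=_GRAPHML_NS)
    ET.SubElement(
        root, "key", id="d0", **{"for": "node"},
        attrib={"attr.name": "role", "attr.type": "string"},
    )
    ET.SubElement(
        root, "key", id="d1", **{"for": "edge"},
        attrib={"attr.name": "weight", "attr.type": "int"},
    )
    g = ET.SubElement(root, "graph", id=graph.network_id, edgedefault="directed")
    for node in graph.nodes:
        n = ET.SubElement(g, "node", id=node)
        data = ET.SubElement(n, "data", key="d0")
        data.text = graph.roles[node]
    for (u, v), w in sorted(graph.edges.items()):
        e = ET.SubElement(g, "edge", source=u, target=v)
        data = ET.SubElement(e, "data", key="d1")
        data.text = str(w)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_graphml(path: str | Path) -> ProviderGraph:
    tree = ET.parse(path)
    ns = {"g": _GRAPHML_NS}
    root = tree.getroot()
    # map key ids to attribute names
    keymap = {k.get("id"): k.get("attr.name") for k in root.findall("g:key", ns)}
    gel = root.find("g:graph", ns)
    graph = ProviderGraph(network_id=gel.get("id", ""))
    for n in gel.findall("g:node", ns):
        role = "other"
        for d in n.findall("g:data", ns):
            if keymap.get(d.get("key")) == "role":
                role = d.text or "other"
        graph.roles[n.get("id")] = role
    for e in gel.findall("g:edge", ns):
        w = 1
        for d in e.findall("g:data", ns):
            if keymap.get(d.get("key")) == "weight":
                w = int(d.text)
        graph.edges[(e.get("source"), e.get("target"))] = w
    return graph


def read_edgelist(path: str | Path, network_id: str = "") -> ProviderGraph:
    graph = ProviderGraph(network_id=network_id)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            u, v, w = row["source"], row["target"], int(row["weight"])
            graph.edges[(u, v)] = w
            graph.roles.setdefault(u, "other")
            graph.roles.setdefault(v, "other")
    return graph
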