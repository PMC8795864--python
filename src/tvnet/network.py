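"""Weakened-connection network extraction, hubs, group averages, export.

At each post-stimulus time point the baseline-corrected influence matrix
is reduced to a directed graph of the 10% most negative off-diagonal
entries (the "weakened" connections). The edge count is
floor(fraction * n * (n - 1)), further limited to strictly negative
candidates; self-loops are never candidates. Hub nodes are ranked by
weakened out-degree (a hub is a source whose outflow has weakened),
with ties broken by summed |corrected value| and then label order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adtf import CorrectedTensor


@dataclass(frozen=True)
class WeakenedEdge:
    source: str
    sink: str
    value: float


@dataclass
class WeakenedNetworkSnapshot:
    """Thresholded weakened-connection network at one time point."""

    time_ms: float
    edges: list
    n_candidates: int
    channel_labels: tuple
    hubs: list = field(default_factory=list)

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        if any(e.value >= 0 for e in self.edges):
            raise ValueError("weakened edges must have strictly negative values")
        if not self.hubs:
            self.hubs = _rank_hubs(self.edges)

    def edge_set(self):
        return {(e.source, e.sink) for e in self.edges}


@dataclass
class GroupNetwork:
    """Group-level snapshots from subject-averaged corrected tensors."""

    label: str
    snapshots: dict       # time_ms -> WeakenedNetworkSnapshot
    n_subjects: int


def _rank_hubs(edges) -> list:
    stats: dict = {}
    for e in edges:
        cnt, tot = stats.get(e.source, (0, 0.0))
        stats[e.source] = (cnt + 1, tot + abs(e.value))
    return sorted(stats, key=lambda s: (-stats[s][0], -stats[s][1], s))


def threshold_weakened(corrected: CorrectedTensor, fraction: float = 0.10) -> list:
    """Per-time-point selection of the most negative off-diagonal entries.

    At each time point the off-diagonal entries are sorted ascending and
    the floor(fraction * n_candidates) most negative strictly-negative
    ones become edges. Ties are broken by (source, sink) index order, so
    the selection is deterministic across platforms. A time point with
    no negative entries yields an empty snapshot.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(corrected.channel_labels)
    n_candidates = n * (n - 1)
    k_max = math.floor(fraction * n_candidates)
    sink_idx, source_idx = np.nonzero(~np.eye(n, dtype=bool))
    labels = corrected.channel_labels
    snapshots = []
    for t_pos, t_ms in enumerate(corrected.times_ms):
        vals = corrected.values[t_pos][sink_idx, source_idx]
        order = np.lexsort((sink_idx, source_idx, vals))
        k = min(k_max, int(np.sum(vals < 0)))
        chosen = order[:k]
        edges = [
            WeakenedEdge(labels[source_idx[c]], labels[sink_idx[c]], float(vals[c]))
            for c in chosen
        ]
        snapshots.append(WeakenedNetworkSnapshot(
            time_ms=float(t_ms), edges=edges,
            n_candidates=n_candidates, channel_labels=labels,
        ))
    return snapshots


def snapshot_at(snapshots, time_ms: float) -> WeakenedNetworkSnapshot:
    """Snapshot whose grid time is nearest the requested time."""
    times = np.array([s.time_ms for s in snapshots])
    return snapshots[int(np.argmin(np.abs(times - time_ms)))]


def hub_nodes(snapshot: WeakenedNetworkSnapshot, top_k: int | None = None) -> list:
    """Channels ranked by weakened out-degree (most outgoing weakened edges)."""
    hubs = _rank_hubs(snapshot.edges)
    return hubs if top_k is None else hubs[:top_k]


def group_average(corrected_list) -> CorrectedTensor:
    """Element-wise mean of per-subject corrected tensors."""
    corrected_list = list(corrected_list)
    if not corrected_list:
        raise ValueError("empty subject list")
    ref = corrected_list[0]
    for c in corrected_list[1:]:
        if c.channel_labels != ref.channel_labels \
                or c.times_ms.shape != ref.times_ms.shape \
                or not np.allclose(c.times_ms, ref.times_ms):
            raise ValueError("subject grids or channel sets do not match")
    return CorrectedTensor(
        values=np.mean([c.values for c in corrected_list], axis=0),
        times_ms=ref.times_ms,
        channel_labels=ref.channel_labels,
        band=ref.band,
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

FORMATS = ("tsv", "json", "graphml")


def export_network(snapshot: WeakenedNetworkSnapshot, path, fmt: str = "tsv") -> None:
    """Write a snapshot's edges to TSV, JSON or GraphML."""
    fmt = fmt.lower()
    if fmt == "tsv":
        df = pd.DataFrame(
            [(snapshot.time_ms, e.source, e.sink, e.value) for e in snapshot.edges],
            columns=["time_ms", "source", "sink", "value"],
        )
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = {
            "time_ms": snapshot.time_ms,
            "n_candidates": snapshot.n_candidates,
            "channel_labels": list(snapshot.channel_labels),
            "edges": [
                {"source": e.source, "sink": e.sink, "value": e.value}
                for e in snapshot.edges
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph(time_ms=float(snapshot.time_ms),
                       n_candidates=int(snapshot.n_candidates),
                       channel_labels=",".join(snapshot.channel_labels))
        for pos, lab in enumerate(snapshot.channel_labels):
            g.add_node(lab, order=pos)
        for e in snapshot.edges:
            g.add_edge(e.source, e.sink, value=float(e.value))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def import_network(path, fmt: str = "tsv",
                   time_ms: float | None = None,
                   channel_labels=None) -> WeakenedNetworkSnapshot:
    """Re-read a snapshot written by :func:`export_network`."""
    fmt = fmt.lower()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        edges = [WeakenedEdge(str(r.source), str(r.sink), float(r.value))
                 for r in df.itertuples()]
        t = float(df["time_ms"].iloc[0]) if len(df) else (time_ms or 0.0)
        labels = channel_labels or sorted({e.source for e in edges} | {e.sink for e in edges})
        n = len(labels)
        return WeakenedNetworkSnapshot(time_ms=t, edges=edges,
                                       n_candidates=n * (n - 1),
                                       channel_labels=labels)
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        edges = [WeakenedEdge(d["source"], d["sink"], d["value"])
                 for d in payload["edges"]]
        return WeakenedNetworkSnapshot(time_ms=payload["time_ms"], edges=edges,
                                       n_candidates=payload["n_candidates"],
                                       channel_labels=payload["channel_labels"])
    if fmt == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        if not g.is_directed():
            raise ValueError("expected a directed GraphML graph")
        labels = tuple(g.graph["channel_labels"].split(","))
        n = len(labels)
        edges = [WeakenedEdge(u, v, float(d["value"])) for u, v, d in g.edges(data=True)]
        edges.sort(key=lambda e: (e.value, e.source, e.sink))
        return WeakenedNetworkSnapshot(time_ms=float(g.graph["time_ms"]), edges=edges,
                                       n_candidates=int(g.graph["n_candidates"]),
                                       channel_labels=labels)
    raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def plot_snapshot(snapshot: WeakenedNetworkSnapshot, ax=None):
    """Schematic ring plot of a weakened-connection snapshot (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    n = len(snapshot.channel_labels)
    ang = 2 * np.pi * np.arange(n) / n
    xy = np.c_[np.cos(ang), np.sin(ang)]
    pos = {lab: xy[i] for i, lab in enumerate(snapshot.channel_labels)}
    for lab, (x, y) in pos.items():
        ax.text(x * 1.08, y * 1.08, lab, ha="center", va="center", fontsize=7)
    vmax = max((abs(e.value) for e in snapshot.edges), default=1.0)
    for e in snapshot.edges:
        (x0, y0), (x1, y1) = pos[e.source], pos[e.sink]
        ax.annotate("", xy=(x1, y1), xytext=(x0, y0),
                    arrowprops=dict(arrowstyle="->", alpha=0.3 + 0.7 * abs(e.value) / vmax,
                                    color="seagreen"))
    ax.set_title(f"weakened connections at {snapshot.time_ms:.0f} ms")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
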