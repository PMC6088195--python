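"""Plain-text serialization helpers (TSV graphs, JSON metadata)."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = [
    "write_graph_tsv",
    "read_graph_tsv",
    "write_edge_list_tsv",
    "write_json",
    "write_nodal_reliability_tsv",
    "write_mds_tsv",
    "load_partition_tsv",
    "write_partition_tsv",
]


def _labels_for(n: int, labels=None) -> list[str]:
    return list(labels) if labels is not None else [f"roi{i:03d}" for i in range(n)]


def write_graph_tsv(path, w: np.ndarray, labels=None) -> None:
    """Square connectivity matrix as header-labeled TSV."""
    w = np.asarray(w)
    cols = _labels_for(w.shape[0], labels)
    pd.DataFrame(w, index=cols, columns=cols).to_csv(path, sep="\t",
                                                     float_format="%.10g")


def read_graph_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def write_edge_list_tsv(path, w: np.ndarray, labels=None) -> None:
    """Sparse upper-triangle edge list: node_i, node_j, weight."""
    w = np.asarray(w)
    cols = _labels_for(w.shape[0], labels)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    mask = w[iu, ju] != 0
    df = pd.DataFrame({
        "node_i": [cols[i] for i in iu[mask]],
        "node_j": [cols[j] for j in ju[mask]],
        "weight": w[iu, ju][mask],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=default)


def write_nodal_reliability_tsv(path, rel: dict, band: str, estimator: str,
                                labels=None) -> None:
    """Per-ROI reliability table: roi_label, metric, band, estimator, r, p."""
    rows = []
    for metric, entry in sorted(rel.items()):
        r, p = np.asarray(entry["r"]), np.asarray(entry["p"])
        cols = _labels_for(r.size, labels)
        for i in range(r.size):
            rows.append((cols[i], metric, band, estimator, r[i], p[i]))
    pd.DataFrame(rows, columns=["roi_label", "metric", "band", "estimator",
                                "r", "p"]).to_csv(path, sep="\t", index=False,
                                                  float_format="%.10g")


def write_mds_tsv(path, coords: np.ndarray, graph_index) -> None:
    """Plot-ready common-space projection: subject, session, x, y per line.

    ``graph_index`` pairs each coordinate row with its (subject, session);
    connecting the two session points of a subject visualizes that
    subject's test-retest similarity in the common space.
    """
    coords = np.asarray(coords)
    rows = [(sub, ses, c[0], c[1] if coords.shape[1] > 1 else 0.0)
            for (sub, ses), c in zip(graph_index, coords)]
    pd.DataFrame(rows, columns=["subject", "session", "x", "y"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def load_partition_tsv(path) -> dict[int, str]:
    """Two-column (roi_label, network) TSV -> {roi index: network}."""
    df = pd.read_csv(path, sep="\t")
    return {i: str(net) for i, net in enumerate(df.iloc[:, 1])}


def write_partition_tsv(path, networks: list[str], labels=None) -> None:
    cols = _labels_for(len(networks), labels)
    pd.DataFrame({"roi_label": cols, "network": networks}).to_csv(
        path, sep="\t", index=False)
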