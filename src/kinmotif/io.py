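"""Result serialization: CSV tables, JSON summaries, GraphML networks.

Conventions: infinite precision scores serialize as the literal string
"inf" in CSV; enrichment p-values carry both the float column ``p`` and
the display column ``p_str`` ("<2.2E-16" below machine epsilon, otherwise
two significant digits).  Readers validate schemas and report the missing
columns explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationResult
from .enrichment import KineticMotif

__all__ = [
    "write_screen",
    "read_screen",
    "write_enrichment",
    "read_enrichment",
    "write_association",
    "read_association",
    "write_motifs",
    "read_motifs",
    "write_network",
    "read_network",
    "write_cooperation",
    "read_cooperation",
]

SCREEN_COLUMNS = (
    "outcome", "O1", "Op", "O2", "settle_time", "sensitivity", "precision", "is_solution",
)
ENRICHMENT_COLUMNS = (
    "parameter", "class_index", "lower", "upper", "x", "y", "M", "N", "p", "p_str", "significant",
)
ASSOCIATION_COLUMNS = (
    "parameter", "motif", "n_motif", "n_non_motif",
    "Pr_m", "Pr_nm", "z_precision", "Sn_m", "Sn_nm", "z_sensitivity", "function",
)
COOPERATION_COLUMNS = ("param_1", "param_2", "r", "p", "correlated")


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}; has {list(df.columns)}")


def write_screen(df: pd.DataFrame, path: Path | str) -> None:
    """Annotated parameter matrix to CSV (inf serialized as 'inf')."""
    df.to_csv(path, index=True)


def read_screen(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="set_id")
    _require(df, SCREEN_COLUMNS, "screen")
    df["is_solution"] = df["is_solution"].astype(bool)
    return df


def write_enrichment(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, index=False)


def read_enrichment(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ENRICHMENT_COLUMNS, "enrichment")
    return df


def write_association(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, index=False)


def read_association(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ASSOCIATION_COLUMNS, "association")
    df["function"] = df["function"].fillna("")
    return df


def write_cooperation(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, index=False)


def read_cooperation(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, COOPERATION_COLUMNS, "cooperation")
    return df


def write_motifs(motifs: Mapping[str, KineticMotif], path: Path | str) -> None:
    """Motifs as JSON: parameter -> classes and interval endpoints (powers of 10)."""
    payload = {
        name: {
            "classes": list(m.classes),
            "interval": [m.interval[0], m.interval[1]],
            "interval_log10": [
                int(round(np.log10(m.interval[0]))),
                int(round(np.log10(m.interval[1]))),
            ],
        }
        for name, m in motifs.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_motifs(path: Path | str) -> dict[str, dict]:
    return json.loads(Path(path).read_text())


def write_network(g: nx.Graph, graphml_path: Path | str, json_path: Path | str | None = None) -> None:
    """Bipartite network as GraphML and (optionally) a JSON node/edge list."""
    nx.write_graphml(g, graphml_path)
    if json_path is not None:
        payload = {
            "nodes": [{"id": n, **{k: v for k, v in d.items()}} for n, d in g.nodes(data=True)],
            "edges": [{"source": u, "target": v, **{k: float(w) for k, w in d.items()}}
                      for u, v, d in g.edges(data=True)],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_network(graphml_path: Path | str) -> nx.Graph:
    return nx.read_graphml(graphml_path)
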