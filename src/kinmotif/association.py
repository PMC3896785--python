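"""Associating kinetic motifs with sensitivity and precision.

For every parameter carrying a motif, all screened (OK-classified)
parameter sets are split into a *motif group* (parameter value inside the
motif interval) and a *non-motif group*.  A one-sided question — does the
motif group score higher? — is asked separately for the sensitivity and
the precision score with the Mann-Whitney U test in its tie-corrected
normal approximation.  A motif is labelled SN and/or PR when the
corresponding z-score exceeds the critical value (default 3.29, the upper
99.9% bound); only positive exceedances produce a label, negative
associations are kept as signed z-scores but draw no edge in the
bipartite kinetic-functionality network.

Pairwise cooperation between motif parameters is measured by Pearson
correlation over the kinetic-solution rows, by default on log10 values
(sampling is log-uniform over up to five decades, so raw-scale
correlation would be dominated by the top decade).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .enrichment import KineticMotif

__all__ = [
    "Z_CRIT",
    "MotifPartition",
    "AssociationResult",
    "partition_by_motif",
    "mann_whitney_z",
    "classify_function",
    "associate_motifs",
    "build_bipartite_network",
    "pairwise_cooperation",
]

Z_CRIT = 3.29          # upper bound of the two-sided 99.9% normal interval
COOP_ALPHA = 0.05

SENSITIVITY = "sensitivity"
PRECISION = "precision"


@dataclass
class MotifPartition:
    """Motif/non-motif split of the screened sets for one parameter."""

    parameter: str
    motif: KineticMotif
    motif_rows: pd.DataFrame
    non_motif_rows: pd.DataFrame

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.motif_rows), len(self.non_motif_rows)


@dataclass(frozen=True)
class AssociationResult:
    """Medians, z-scores and function labels for one motif parameter."""

    parameter: str
    motif_interval: tuple[float, float]
    n_motif: int
    n_non_motif: int
    precision_median_motif: float
    precision_median_non_motif: float
    z_precision: float
    sensitivity_median_motif: float
    sensitivity_median_non_motif: float
    z_sensitivity: float
    labels: tuple[str, ...]


def partition_by_motif(
    screened: pd.DataFrame,
    motif: KineticMotif,
    outcome_col: str = "outcome",
) -> MotifPartition:
    """Split all OK-classified rows by motif membership of one parameter."""
    ok = screened[screened[outcome_col] == "OK"] if outcome_col in screened else screened
    values = ok[motif.parameter].to_numpy(dtype=float)
    inside = motif.contains(values)
    if not inside.any():
        raise ValueError(
            f"motif group for {motif.parameter} is empty; "
            "value-class scheme and sampling range disagree"
        )
    return MotifPartition(
        parameter=motif.parameter,
        motif=motif,
        motif_rows=ok[inside],
        non_motif_rows=ok[~inside],
    )


def mann_whitney_z(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Tie-corrected normal-approximation Mann-Whitney z-score.

    Positive when ``group_a`` is stochastically larger.  No continuity
    correction.  Degenerate data (every pooled value equal) gives 0.
    Infinite scores are supported: ranks are computed on the pooled sample
    where +inf simply outranks every finite value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    U = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts.astype(float) ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((U - n1 * n2 / 2.0) / np.sqrt(var))


def classify_function(
    z_sensitivity: float, z_precision: float, z_crit: float = Z_CRIT
) -> tuple[str, ...]:
    """Function labels from the two z-scores; only positive exceedances."""
    labels = []
    if z_precision > z_crit:
        labels.append("PR")
    if z_sensitivity > z_crit:
        labels.append("SN")
    return tuple(labels)


def associate_motifs(
    screened: pd.DataFrame,
    motifs: Mapping[str, KineticMotif],
    z_crit: float = Z_CRIT,
) -> list[AssociationResult]:
    """Run the motif/non-motif rank tests for every motif parameter."""
    results = []
    for name, motif in motifs.items():
        part = partition_by_motif(screened, motif)
        gm, gn = part.motif_rows, part.non_motif_rows
        z_prec = mann_whitney_z(gm["precision"], gn["precision"])
        z_sens = mann_whitney_z(gm["sensitivity"], gn["sensitivity"])
        results.append(
            AssociationResult(
                parameter=name,
                motif_interval=motif.interval,
                n_motif=len(gm),
                n_non_motif=len(gn),
                precision_median_motif=float(np.median(gm["precision"])),
                precision_median_non_motif=float(np.median(gn["precision"])),
                z_precision=z_prec,
                sensitivity_median_motif=float(np.median(gm["sensitivity"])),
                sensitivity_median_non_motif=float(np.median(gn["sensitivity"])),
                z_sensitivity=z_sens,
                labels=classify_function(z_sens, z_prec, z_crit),
            )
        )
    return results


def build_bipartite_network(results: Sequence[AssociationResult]) -> nx.Graph:
    """Bipartite graph: kinetic motifs on one side, functionalities on the other.

    Motif nodes carry the parameter name and motif interval; the two
    function nodes ("sensitivity", "precision") are always present.  An
    edge records a significant positive association and stores its z-score.
    """
    g = nx.Graph()
    g.add_node(SENSITIVITY, bipartite=1, kind="function")
    g.add_node(PRECISION, bipartite=1, kind="function")
    for r in results:
        lo, hi = r.motif_interval
        g.add_node(r.parameter, bipartite=0, kind="motif",
                   interval_low=lo, interval_high=hi)
        if "PR" in r.labels:
            g.add_edge(r.parameter, PRECISION, z=r.z_precision)
        if "SN" in r.labels:
            g.add_edge(r.parameter, SENSITIVITY, z=r.z_sensitivity)
    return g


def pairwise_cooperation(
    solutions: pd.DataFrame,
    motif_parameters: Sequence[str],
    alpha: float = COOP_ALPHA,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Pearson correlation between motif parameters over the solution sets.

    Returns one row per unordered pair: r, two-sided p and the
    ``correlated`` flag (p < alpha).  Requires at least 3 solution rows.
    """
    if len(solutions) < 3:
        raise ValueError("pairwise cooperation needs at least 3 kinetic solutions")
    rows = []
    for p1, p2 in itertools.combinations(motif_parameters, 2):
        v1 = solutions[p1].to_numpy(dtype=float)
        v2 = solutions[p2].to_numpy(dtype=float)
        if log_scale:
            v1, v2 = np.log10(v1), np.log10(v2)
        r, p = pearsonr(v1, v2)
        rows.append(dict(param_1=p1, param_2=p2, r=float(r), p=float(p),
                         correlated=bool(p < alpha)))
    return pd.DataFrame(rows)
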