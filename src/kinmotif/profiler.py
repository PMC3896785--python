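"""Statistical profiling of a screened parameter matrix.

`MotifProfiler` is the analysis entry point for the statistics layer: it
takes a screened matrix (from :func:`kinmotif.screen.run_screen`, a saved
outcomes table, or the synthetic fixture generator), and `fit()` runs the
enrichment tests, motif detection, functional association and pairwise
cooperation, returning a `MotifProfileResults` whose `summary()` prints
the enrichment and association tables in the layout of the screening
study's result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    associate_motifs,
    build_bipartite_network,
    pairwise_cooperation,
    Z_CRIT,
)
from .enrichment import (
    DEFAULT_ALPHA,
    KineticMotif,
    detect_motifs,
    enrichment_table,
    format_pvalue,
)
from .network import NFBLB_PARAM_NAMES

__all__ = ["MotifProfiler", "MotifProfileResults"]

#: parameters profiled for the NFBLB preset: the input-edge pair is
#: sampled but excluded from enrichment (ten profiled parameters)
DEFAULT_PROFILE_PARAMS = tuple(n for n in NFBLB_PARAM_NAMES if not n.endswith("_IA"))


class MotifProfiler:
    """Enrichment + association analysis over a screened matrix.

    Parameters
    ----------
    screened :
        Annotated parameter matrix: one row per sampled set with the
        kinetic parameter columns plus ``outcome``, ``sensitivity``,
        ``precision`` and ``is_solution``.
    parameters :
        Kinetic parameters to profile (default: the ten non-input NFBLB
        parameters present in the matrix).
    alpha :
        Enrichment significance threshold on the raw p-value (no
        multiple-testing correction).
    z_crit :
        Critical Mann-Whitney z for a positive function label.
    coop_alpha :
        Two-sided p threshold for a correlated parameter pair.
    per_decade :
        Value classes per decade (1 = decade classes; 2 = doubled
        resolution).
    strict_tail :
        Use the strict upper tail P(X > x) (default); False switches to
        the inclusive tail P(X >= x).
    coop_log_scale :
        Correlate log10-transformed values (default) or raw values.
    """

    def __init__(
        self,
        screened: pd.DataFrame,
        parameters: Optional[Sequence[str]] = None,
        alpha: float = DEFAULT_ALPHA,
        z_crit: float = Z_CRIT,
        coop_alpha: float = 0.05,
        per_decade: int = 1,
        strict_tail: bool = True,
        coop_log_scale: bool = True,
        bounds: Optional[Mapping[str, tuple[float, float]]] = None,
    ):
        if parameters is None:
            parameters = [p for p in DEFAULT_PROFILE_PARAMS if p in screened.columns]
            if not parameters:
                parameters = [
                    c for c in screened.columns
                    if c.startswith(("k_", "K_")) and not c.endswith("_IA")
                ]
        missing = [p for p in parameters if p not in screened.columns]
        if missing:
            raise ValueError(f"screened matrix lacks parameter columns: {missing}")
        for col in ("outcome", "sensitivity", "precision", "is_solution"):
            if col not in screened.columns:
                raise ValueError(f"screened matrix lacks required column {col!r}")
        self.screened = screened
        self.parameters = tuple(parameters)
        self.alpha = alpha
        self.z_crit = z_crit
        self.coop_alpha = coop_alpha
        self.per_decade = per_decade
        self.strict_tail = strict_tail
        self.coop_log_scale = coop_log_scale
        self.bounds = bounds

    def fit(self) -> "MotifProfileResults":
        """Run enrichment, motif detection, association and cooperation."""
        enr = enrichment_table(
            self.screened, self.parameters, bounds=self.bounds,
            alpha=self.alpha, per_decade=self.per_decade,
            strict_tail=self.strict_tail,
        )
        motifs = detect_motifs(enr, self.alpha, self.bounds, self.per_decade)
        associations = associate_motifs(self.screened, motifs, self.z_crit)
        network = build_bipartite_network(associations)
        solutions = self.screened[self.screened["is_solution"].astype(bool)]
        cooperation = (
            pairwise_cooperation(
                solutions, sorted(motifs), self.coop_alpha, self.coop_log_scale
            )
            if len(motifs) >= 2 and len(solutions) >= 3
            else pd.DataFrame(columns=["param_1", "param_2", "r", "p", "correlated"])
        )
        return MotifProfileResults(
            model=self,
            enrichment=enr,
            motifs=motifs,
            associations=associations,
            network=network,
            cooperation=cooperation,
        )


def _interval_str(lo: float, hi: float) -> str:
    fmt = lambda v: f"1E{int(round(np.log10(v)))}"
    return f"[{fmt(lo)},{fmt(hi)}]"


@dataclass
class MotifProfileResults:
    """Fitted motif profile: tables, motifs, labels and the bipartite graph."""

    model: MotifProfiler
    enrichment: pd.DataFrame
    motifs: dict[str, KineticMotif]
    associations: list[AssociationResult]
    network: nx.Graph
    cooperation: pd.DataFrame

    @property
    def M(self) -> int:
        return int(self.screened["is_solution"].astype(bool).sum())

    @property
    def N(self) -> int:
        return len(self.screened)

    @property
    def screened(self) -> pd.DataFrame:
        return self.model.screened

    @property
    def association_table(self) -> pd.DataFrame:
        """Association results in the result-table layout (one row per motif)."""
        rows = []
        for r in self.associations:
            rows.append(
                dict(
                    parameter=r.parameter,
                    motif=_interval_str(*r.motif_interval),
                    n_motif=r.n_motif,
                    n_non_motif=r.n_non_motif,
                    Pr_m=r.precision_median_motif,
                    Pr_nm=r.precision_median_non_motif,
                    z_precision=r.z_precision,
                    Sn_m=r.sensitivity_median_motif,
                    Sn_nm=r.sensitivity_median_non_motif,
                    z_sensitivity=r.z_sensitivity,
                    function=",".join(r.labels),
                )
            )
        return pd.DataFrame(rows)

    def function_degree(self) -> dict[str, int]:
        """Number of motif parameters attached to each functionality."""
        return {
            f: sum(1 for r in self.associations if lab in r.labels)
            for f, lab in (("sensitivity", "SN"), ("precision", "PR"))
        }

    def summary(self) -> str:
        """Human-readable report of the fitted profile."""
        lines = []
        lines.append("Kinetic motif profile")
        lines.append("=" * 70)
        lines.append(f"screened sets N = {self.N}, kinetic solutions M = {self.M}")
        ok = (self.screened["outcome"] == "OK").sum()
        lines.append(f"OK-classified sets: {ok} ({100.0 * ok / max(self.N, 1):.1f}%)")
        lines.append("")
        lines.append(f"Enrichment (alpha = {self.model.alpha:g}, "
                     f"{'strict' if self.model.strict_tail else 'inclusive'} tail)")
        lines.append("-" * 70)
        lines.append(f"{'parameter':<8} {'class':>5} {'interval':>14} "
                     f"{'x':>5} {'y':>7} {'p':>10} sig")
        for _, row in self.enrichment.iterrows():
            lines.append(
                f"{row.parameter:<8} {row.class_index:>5} "
                f"{_interval_str(row.lower, row.upper):>14} "
                f"{row.x:>5} {row.y:>7} {row.p_str:>10} "
                f"{'*' if row.significant else ''}"
            )
        lines.append("")
        lines.append(f"Kinetic motifs: {len(self.motifs)}")
        for name, motif in self.motifs.items():
            lines.append(f"  {name:<8} {_interval_str(*motif.interval)}")
        lines.append("")
        lines.append(f"Functional association (z_crit = {self.model.z_crit:g})")
        lines.append("-" * 70)
        tab = self.association_table
        if len(tab):
            lines.append(f"{'parameter':<8} {'motif':>14} {'Pr_m':>7} {'Pr_~m':>7} "
                         f"{'z_PR':>8} {'Sn_m':>7} {'Sn_~m':>7} {'z_SN':>8} function")
            for _, r in tab.iterrows():
                lines.append(
                    f"{r.parameter:<8} {r.motif:>14} {r.Pr_m:>7.2f} {r.Pr_nm:>7.2f} "
                    f"{r.z_precision:>8.2f} {r.Sn_m:>7.2f} {r.Sn_nm:>7.2f} "
                    f"{r.z_sensitivity:>8.2f} {r.function}"
                )
        deg = self.function_degree()
        lines.append("")
        lines.append(f"bipartite degree: precision <- {deg['precision']} motifs, "
                     f"sensitivity <- {deg['sensitivity']} motifs")
        sig = self.cooperation[self.cooperation["correlated"]] if len(self.cooperation) else self.cooperation
        lines.append(f"correlated pairs (p < {self.model.coop_alpha:g}): {len(sig)}")
        for _, r in sig.iterrows():
            lines.append(f"  {r.param_1} -- {r.param_2}: r = {r.r:+.2f}, p = {format_pvalue(r.p)}")
        return "\n".join(lines)
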