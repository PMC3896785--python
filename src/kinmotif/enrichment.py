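"""Value-class binning and hypergeometric enrichment of kinetic solutions.

Each kinetic parameter's log10 range is partitioned into decade-wide
*value classes* (five for Michaelis-Menten constants spanning [1e-3, 1e2];
the two occupied middle classes for catalytic rate constants spanning
[1e-1, 1e1]).  For a class holding ``y`` of the ``N`` sampled values and
``x`` of the ``M`` kinetic solutions, the chance of seeing that many
solutions in the class under random assortment is hypergeometric, and the
enrichment p-value is the strict upper tail P(X > x).  A class with
p below the significance threshold (default 1e-3, no multiple-testing
correction) is part of that parameter's *kinetic motif*; a motif is the
union of its significant classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "EPS_P",
    "ValueClassScheme",
    "KineticMotif",
    "assign_value_class",
    "tabulate_counts",
    "enrichment_pvalue",
    "enrichment_table",
    "detect_motifs",
    "format_pvalue",
]

#: p-values below this are reported as the sentinel "<2.2E-16"
EPS_P = 2.2e-16

DEFAULT_ALPHA = 1e-3


@dataclass(frozen=True)
class ValueClassScheme:
    """Decade bins over a parameter's log10 range.

    ``edges`` are the log10 class boundaries (len = n_classes + 1); classes
    are half-open [edge_i, edge_{i+1}) with the top class closed.  Class
    indices are global: with ``offset`` o, the first class of this scheme
    is class o+1 of the five-decade reference grid, so a catalytic rate
    constant spanning [1e-1, 1e1] occupies classes 3 and 4.
    """

    edges: tuple[float, ...]
    offset: int = 0

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("class edges must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.edges) - 1

    @property
    def class_indices(self) -> tuple[int, ...]:
        return tuple(self.offset + i + 1 for i in range(self.n_classes))

    def interval(self, class_index: int) -> tuple[float, float]:
        """(lower, upper) bounds of a global class index, linear scale."""
        i = class_index - self.offset - 1
        if not 0 <= i < self.n_classes:
            raise ValueError(f"class {class_index} not in scheme {self.class_indices}")
        return 10.0 ** self.edges[i], 10.0 ** self.edges[i + 1]


def decade_scheme(lo: float, hi: float, per_decade: int = 1) -> ValueClassScheme:
    """Equal-width log10 classes for a range, aligned to the reference grid.

    With ``per_decade=1`` the classes are whole decades; ``per_decade=2``
    gives the doubled-resolution scheme (half-decade classes, offset
    counted on the same finer grid).
    """
    llo, lhi = np.log10(lo), np.log10(hi)
    n = int(round((lhi - llo) * per_decade))
    edges = tuple(llo + i / per_decade for i in range(n + 1))
    offset = int(round((llo - (-3.0)) * per_decade))
    return ValueClassScheme(edges=edges, offset=offset)


def scheme_for(name: str, bounds: Mapping[str, tuple[float, float]] | None = None,
               per_decade: int = 1) -> ValueClassScheme:
    """Default scheme for a parameter by naming convention (k_* vs K_*)."""
    if bounds and name in bounds:
        lo, hi = bounds[name]
    else:
        lo, hi = (1e-1, 1e1) if name.startswith("k_") else (1e-3, 1e2)
    return decade_scheme(lo, hi, per_decade)


@dataclass(frozen=True)
class KineticMotif:
    """A parameter's significantly enriched value interval.

    ``classes`` are the significant global class indices; ``interval`` is
    their union, as (lower, upper) powers of ten.  Significant classes are
    contiguous for every case encountered here; a non-contiguous set is
    stored class-wise and ``interval`` spans the full hull.
    """

    parameter: str
    classes: tuple[int, ...]
    scheme: ValueClassScheme

    @property
    def interval(self) -> tuple[float, float]:
        bounds = [self.scheme.interval(c) for c in self.classes]
        return min(b[0] for b in bounds), max(b[1] for b in bounds)

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Boolean membership of values in the motif (union of classes)."""
        values = np.asarray(values, dtype=float)
        mask = np.zeros(values.shape, dtype=bool)
        for c in self.classes:
            lo, hi = self.scheme.interval(c)
            top = c == self.scheme.class_indices[-1]
            mask |= (values >= lo) & ((values <= hi) if top else (values < hi))
        return mask


def assign_value_class(value: float, scheme: ValueClassScheme) -> int:
    """Global class index of a value: half-open decades, top class closed."""
    lo, hi = 10.0 ** scheme.edges[0], 10.0 ** scheme.edges[-1]
    if not (lo <= value <= hi):
        raise ValueError(f"value {value!r} outside scheme range [{lo}, {hi}]")
    if value == hi:
        return scheme.class_indices[-1]
    i = int(np.searchsorted(scheme.edges, np.log10(value), side="right")) - 1
    i = min(max(i, 0), scheme.n_classes - 1)
    # guard against log-rounding at interior edges: enforce half-open rule
    if value < 10.0 ** scheme.edges[i]:
        i -= 1
    elif value >= 10.0 ** scheme.edges[i + 1]:
        i += 1
    return scheme.offset + i + 1


def tabulate_counts(
    matrix: pd.DataFrame,
    parameter: str,
    scheme: ValueClassScheme,
    solution_col: str = "is_solution",
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-class counts of sampled (y) and solution (x) values.

    ``y`` counts all N rows of the screened matrix, ``x`` the M rows
    flagged as kinetic solutions.  Raises when the screen found no
    solutions (enrichment is then meaningless; sample more sets).
    """
    values = matrix[parameter].to_numpy(dtype=float)
    sol_mask = matrix[solution_col].to_numpy(dtype=bool)
    M = int(sol_mask.sum())
    N = len(values)
    if M == 0:
        raise ValueError(
            "no kinetic solutions in the screened matrix; "
            "increase the sample size before running enrichment"
        )
    edges_lin = 10.0 ** np.asarray(scheme.edges)
    y_counts = np.histogram(values, bins=edges_lin)[0]
    x_counts = np.histogram(values[sol_mask], bins=edges_lin)[0]
    if y_counts.sum() != N:
        raise ValueError(f"{N - y_counts.sum()} values of {parameter} fall outside the scheme")
    return x_counts, y_counts, M, N


def enrichment_pvalue(x: int, y: int, M: int, N: int, strict_tail: bool = True) -> float:
    """Upper-tail hypergeometric enrichment p-value.

    X counts solutions landing in a class holding ``y`` of the ``N``
    sampled values when ``M`` solutions are drawn without replacement.
    Default is the strict tail P(X > x); ``strict_tail=False`` gives the
    inclusive tail P(X >= x).  Computed via scipy's log-space survival
    function; values are clamped to a floor of machine-level 1e-300 so a
    zero is never returned.
    """
    if not (0 <= M <= N and 0 <= y <= N and 0 <= x <= min(y, M)):
        raise ValueError(f"invalid hypergeometric counts x={x}, y={y}, M={M}, N={N}")
    rv = hypergeom(N, y, M)
    p = float(rv.sf(x if strict_tail else x - 1))
    return max(p, 1e-300)


def format_pvalue(p: float) -> str:
    """Two-significant-digit scientific notation; '<2.2E-16' below epsilon."""
    if p < EPS_P:
        return "<2.2E-16"
    return f"{p:.1E}"


def enrichment_table(
    matrix: pd.DataFrame,
    parameters: Sequence[str],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    per_decade: int = 1,
    strict_tail: bool = True,
) -> pd.DataFrame:
    """Per-parameter, per-class enrichment results (long format).

    Columns: parameter, class_index, lower, upper, x, y, M, N, p,
    p_str, significant.
    """
    rows = []
    for name in parameters:
        scheme = scheme_for(name, bounds, per_decade)
        x, y, M, N = tabulate_counts(matrix, name, scheme)
        for i, cls in enumerate(scheme.class_indices):
            lo, hi = scheme.interval(cls)
            p = enrichment_pvalue(int(x[i]), int(y[i]), M, N, strict_tail)
            rows.append(
                dict(parameter=name, class_index=cls, lower=lo, upper=hi,
                     x=int(x[i]), y=int(y[i]), M=M, N=N, p=p,
                     p_str=format_pvalue(p), significant=bool(p < alpha))
            )
    return pd.DataFrame(rows)


def detect_motifs(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    per_decade: int = 1,
) -> dict[str, KineticMotif]:
    """Kinetic motifs: per parameter, the union of significant classes.

    Parameters without a significant class are motif-free and absent from
    the result.
    """
    motifs: dict[str, KineticMotif] = {}
    for name, grp in table.groupby("parameter", sort=False):
        sig = grp[grp["p"] < alpha]
        if len(sig):
            scheme = scheme_for(name, bounds, per_decade)
            motifs[name] = KineticMotif(
                parameter=name,
                classes=tuple(int(c) for c in sorted(sig["class_index"])),
                scheme=scheme,
            )
    return motifs
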