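"""Synthetic screened matrices with planted statistical structure.

The generator emulates the *output* of a screen — a parameter matrix
annotated with outcome, scores and solution flags — without running any
ODE.  Value-class biases among the planted solutions and location shifts
of the scores inside chosen classes let the enrichment and association
layers be exercised against known ground truth: a class planted at a
fraction above its sampling marginal must come out enriched, a score
shift must come out as a function label, and planting at exactly the
marginal must stay null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .enrichment import ValueClassScheme, scheme_for
from .network import NFBLB_PARAM_NAMES

__all__ = ["PlantedEffect", "FixtureSpec", "generate_fixture"]

#: the ten profiled NFBLB parameters (input-edge pair excluded)
DEFAULT_FIXTURE_PARAMS = tuple(n for n in NFBLB_PARAM_NAMES if not n.endswith("_IA"))


@dataclass(frozen=True)
class PlantedEffect:
    """Bias planted for one parameter.

    planting_fraction : probability that a solution row draws its value
        from the planted class rather than from the full log-uniform
        marginal (1.0 plants every solution in the class; a fraction equal
        to the class marginal reproduces the null)
    sensitivity_shift, precision_shift : additive score shifts applied to
        every OK row whose value falls in the planted class (drives the
        association layer)
    """

    class_index: int
    planting_fraction: float
    sensitivity_shift: float = 0.0
    precision_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planting_fraction <= 1.0:
            raise ValueError("planting fraction must be in [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and planted truths of one synthetic screened matrix."""

    M: int
    N: int
    effects: Mapping[str, PlantedEffect] = field(default_factory=dict)
    seed: int = 0
    parameters: tuple[str, ...] = DEFAULT_FIXTURE_PARAMS

    def __post_init__(self) -> None:
        if not 0 <= self.M <= self.N:
            raise ValueError("need 0 <= M <= N")
        unknown = set(self.effects) - set(self.parameters)
        if unknown:
            raise ValueError(f"effects reference unknown parameters: {sorted(unknown)}")


def generate_fixture(spec: FixtureSpec) -> pd.DataFrame:
    """Emit a synthetic screened matrix per the fixture spec.

    All N rows are OK-classified and carry unit-variance normal base
    scores.  The first M rows (after shuffling, any M rows) are flagged as
    kinetic solutions; their values for planted parameters are drawn from
    the planted class at the planting fraction.  Score shifts apply to
    every row inside the planted class, solutions or not, mirroring how a
    real motif moves the scores of the whole motif group.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.N, spec.M
    sol = np.zeros(n, dtype=bool)
    sol[rng.choice(n, size=m, replace=False)] = True

    data: dict[str, np.ndarray] = {}
    sens = rng.normal(0.0, 1.0, n)
    prec = rng.normal(0.0, 1.0, n)
    for name in spec.parameters:
        scheme = scheme_for(name)
        log_lo, log_hi = scheme.edges[0], scheme.edges[-1]
        vals = 10.0 ** rng.uniform(log_lo, log_hi, n)
        eff = spec.effects.get(name)
        if eff is not None:
            c_lo, c_hi = scheme.interval(eff.class_index)
            le_lo, le_hi = np.log10(c_lo), np.log10(c_hi)
            # planting_fraction is the TOTAL in-class probability for a
            # solution row: in-class draws are log-uniform inside the class,
            # the rest land log-uniformly in the complement (proportional to
            # the sampling marginal there), so fraction == class marginal
            # reproduces the null exactly
            planted = sol & (rng.random(n) < eff.planting_fraction)
            vals[planted] = 10.0 ** rng.uniform(le_lo, le_hi, int(planted.sum()))
            outside = sol & ~planted
            n_out = int(outside.sum())
            left_len = le_lo - log_lo
            right_len = log_hi - le_hi
            total = left_len + right_len
            if total <= 0:
                if n_out:
                    raise ValueError(
                        f"planting fraction < 1 impossible: class spans the whole "
                        f"range of {name}"
                    )
            else:
                u = rng.random(n_out) * total
                vals[outside] = 10.0 ** np.where(
                    u < left_len, log_lo + u, le_hi + (u - left_len)
                )
            in_class = (vals >= c_lo) & (vals < c_hi)
            if eff.class_index == scheme.class_indices[-1]:
                in_class |= vals == c_hi
            sens[in_class] += eff.sensitivity_shift
            prec[in_class] += eff.precision_shift
        data[name] = vals

    df = pd.DataFrame(data)
    df.index.name = "set_id"
    df["outcome"] = "OK"
    df["O1"] = 0.5
    df["Op"] = 0.5
    df["O2"] = 0.5
    df["settle_time"] = 1.0
    df["sensitivity"] = sens
    df["precision"] = prec
    df["is_solution"] = sol
    return df
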