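"""Latin hypercube sampling of kinetic parameters and the screening loop.

Kinetic parameters are sampled log-uniformly: catalytic rate constants k
over [1e-1, 1e1] and Michaelis-Menten constants K over [1e-3, 1e2].  Each
parameter's marginal is stratified into n equal-width log10 strata hit
exactly once, with independent random permutations across parameters
(scipy's Latin hypercube engine).

``run_screen`` pushes every sampled set through the step-response
simulation, annotates the matrix with the outcome class, the adaptation
scores and the solution flag, and can checkpoint/resume long screens.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .network import NetworkModel
from .simulate import (
    OutcomeClass,
    RejectionThresholds,
    StimulusProtocol,
    evaluate_parameter_set,
)

__all__ = [
    "K_RATE_RANGE",
    "K_MM_RANGE",
    "ParameterRangeSpec",
    "default_range_spec",
    "latin_hypercube_sample",
    "run_screen",
]

logger = logging.getLogger(__name__)

#: default log-uniform sampling ranges
K_RATE_RANGE = (1e-1, 1e1)   # catalytic rate constants k
K_MM_RANGE = (1e-3, 1e2)     # Michaelis-Menten constants K

ANNOTATION_COLUMNS = (
    "outcome", "O1", "Op", "O2", "settle_time", "sensitivity", "precision", "is_solution",
)


@dataclass(frozen=True)
class ParameterRangeSpec:
    """Per-parameter sampling bounds, log10 scale.

    ``fixed`` maps parameter names to constant values excluded from
    sampling (used e.g. to pin the input edge parameters at 1).
    """

    bounds: Mapping[str, tuple[float, float]]
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"range for {name} must satisfy 0 < lower < upper")

    @property
    def sampled_names(self) -> tuple[str, ...]:
        return tuple(self.bounds)


def default_range_spec(model: NetworkModel, sample_input_edge: bool = False) -> ParameterRangeSpec:
    """k-type parameters over [0.1, 10], K-type over [1e-3, 1e2].

    By default the input-edge pair (e.g. k_IA, K_IA) is pinned at 1.0 so
    every sampled set experiences the same input drive and the profiled
    space is the ten regulatory parameters; ``sample_input_edge=True``
    samples the input edge like the rest.
    """
    input_suffix = None
    for e in model.topology.edges:
        if e.source == model.topology.input_label:
            input_suffix = e.suffix
            break
    bounds, fixed = {}, {}
    for name in model.param_names:
        if not sample_input_edge and input_suffix and name.endswith(f"_{input_suffix}"):
            fixed[name] = 1.0
        else:
            bounds[name] = K_RATE_RANGE if name.startswith("k_") else K_MM_RANGE
    return ParameterRangeSpec(bounds=bounds, fixed=fixed)


def latin_hypercube_sample(n: int, spec: ParameterRangeSpec, seed: int) -> pd.DataFrame:
    """Draw ``n`` kinetic parameter sets by Latin hypercube in log10 space.

    Each column independently visits n equal-width strata of its log10
    range exactly once, uniformly within each stratum.  Fixed parameters
    are appended as constant columns.  Rows are indexed by set id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = spec.sampled_names
    engine = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = engine.random(n)
    data = {}
    for j, name in enumerate(names):
        lo, hi = spec.bounds[name]
        log_lo, log_hi = np.log10(lo), np.log10(hi)
        data[name] = 10.0 ** (log_lo + unit[:, j] * (log_hi - log_lo))
    for name, value in spec.fixed.items():
        data[name] = np.full(n, value)
    df = pd.DataFrame(data)
    df.index.name = "set_id"
    return df


def _config_hash(model: NetworkModel, protocol, thresholds, columns) -> str:
    payload = json.dumps(
        {
            "params": list(columns),
            "edges": [(e.source, e.target, e.mode) for e in model.topology.edges],
            "protocol": [protocol.I1, protocol.I2],
            "thresholds": vars(thresholds) if not hasattr(thresholds, "__dataclass_fields__")
            else {k: getattr(thresholds, k) for k in thresholds.__dataclass_fields__},
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_screen(
    model: NetworkModel,
    matrix: pd.DataFrame,
    protocol: StimulusProtocol = StimulusProtocol(),
    thresholds: RejectionThresholds = RejectionThresholds(),
    checkpoint: Optional[Path] = None,
    checkpoint_every: int = 1000,
    progress_every: int = 10000,
) -> pd.DataFrame:
    """Simulate and score every sampled parameter set.

    Returns the matrix with annotation columns appended: ``outcome``,
    ``O1``, ``Op``, ``O2``, ``sensitivity``, ``precision`` (NaN where the
    outcome is not OK) and the boolean ``is_solution``.  Per-set failures
    are labelled, never raised.  When ``checkpoint`` is given, partial
    annotations are flushed there every ``checkpoint_every`` rows together
    with a hash of the screen configuration, and a matching checkpoint is
    resumed instead of recomputed.
    """
    param_cols = [c for c in matrix.columns if c in model.param_names]
    if set(param_cols) != set(model.param_names):
        missing = set(model.param_names) - set(param_cols)
        raise ValueError(f"matrix is missing parameter columns: {sorted(missing)}")
    values = matrix[list(model.param_names)].to_numpy(dtype=float)
    n = len(matrix)

    cfg_hash = _config_hash(model, protocol, thresholds, model.param_names)
    out = {
        "outcome": np.full(n, "", dtype=object),
        "O1": np.full(n, np.nan),
        "Op": np.full(n, np.nan),
        "O2": np.full(n, np.nan),
        "settle_time": np.full(n, np.nan),
        "sensitivity": np.full(n, np.nan),
        "precision": np.full(n, np.nan),
        "is_solution": np.zeros(n, dtype=bool),
    }
    start = 0
    if checkpoint is not None:
        checkpoint = Path(checkpoint)
        meta_path = checkpoint.with_suffix(".meta.json")
        if checkpoint.exists() and meta_path.exists():
            meta = json.loads(meta_path.read_text())
            if meta.get("config_hash") == cfg_hash and meta.get("n") == n:
                part = pd.read_csv(checkpoint, index_col="set_id")
                start = len(part)
                for col in ANNOTATION_COLUMNS:
                    arr = part[col].to_numpy()
                    out[col][:start] = arr.astype(bool) if col == "is_solution" else arr
                logger.info("resuming screen from checkpoint at row %d", start)
            else:
                logger.warning("checkpoint config mismatch; recomputing from scratch")

    def _flush(upto: int) -> None:
        if checkpoint is None:
            return
        part = pd.DataFrame({c: out[c][:upto] for c in ANNOTATION_COLUMNS},
                            index=matrix.index[:upto])
        part.index.name = "set_id"
        part.to_csv(checkpoint)
        checkpoint.with_suffix(".meta.json").write_text(
            json.dumps({"config_hash": cfg_hash, "n": n, "rows_done": upto})
        )

    for i in range(start, n):
        try:
            outcome, summary, scores, solution = evaluate_parameter_set(
                model, values[i], protocol, thresholds
            )
        except Exception:   # a single bad set must never abort the screen
            logger.exception("row %d failed; labelled NUMERICAL_FAILURE", i)
            outcome, summary, scores, solution = (
                OutcomeClass.NUMERICAL_FAILURE, None, None, False,
            )
        out["outcome"][i] = outcome
        if summary is not None:
            out["O1"][i] = summary.O1
            out["Op"][i] = summary.Op
            out["O2"][i] = summary.O2
            if summary.settle_time is not None:
                out["settle_time"][i] = summary.settle_time
        if scores is not None:
            out["sensitivity"][i] = scores.sensitivity
            out["precision"][i] = scores.precision
        out["is_solution"][i] = solution
        done = i + 1
        if checkpoint is not None and done % checkpoint_every == 0:
            _flush(done)
        if done % progress_every == 0:
            n_sol = int(out["is_solution"][:done].sum())
            logger.info("screened %d/%d sets (%d solutions so far)", done, n, n_sol)

    _flush(n)
    annotated = matrix.copy()
    for col in ANNOTATION_COLUMNS:
        annotated[col] = out[col]
    n_ok = int((annotated["outcome"] == OutcomeClass.OK).sum())
    logger.info(
        "screen complete: N=%d, OK=%d (%.1f%%), solutions M=%d",
        n, n_ok, 100.0 * n_ok / max(n, 1), int(annotated["is_solution"].sum()),
    )
    return annotated
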