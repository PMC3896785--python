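"""End-to-end orchestration: sample -> screen -> enrich -> associate -> cooperate.

``run_pipeline`` executes the whole chain from a :class:`RunConfig`,
writes every result table plus a config echo, a log and a machine-readable
summary into the output directory, and returns the in-memory bundle.
Identical configs (including the seed) produce identical output bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as kio
from .config import RunConfig, save_config
from .profiler import MotifProfiler, MotifProfileResults
from .screen import default_range_spec, latin_hypercube_sample, run_screen

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    config: RunConfig
    matrix: pd.DataFrame          # sampled parameters
    screened: pd.DataFrame        # annotated matrix
    profile: Optional[MotifProfileResults]
    summary: dict
    out_dir: Optional[Path]


def _summarize(config: RunConfig, screened: pd.DataFrame,
               profile: Optional[MotifProfileResults]) -> dict:
    outcome_counts = screened["outcome"].value_counts().to_dict()
    n = len(screened)
    m = int(screened["is_solution"].sum())
    summary = {
        "model": config.model,
        "N": n,
        "M": m,
        "seed": config.seed,
        "ok_fraction": float((screened["outcome"] == "OK").mean()),
        "outcome_counts": {k: int(v) for k, v in sorted(outcome_counts.items())},
    }
    if profile is not None:
        summary["motifs"] = {
            name: {"interval": list(mot.interval), "classes": list(mot.classes)}
            for name, mot in profile.motifs.items()
        }
        summary["function_labels"] = {
            r.parameter: list(r.labels) for r in profile.associations
        }
        summary["function_degree"] = profile.function_degree()
        coop = profile.cooperation
        summary["correlated_pairs"] = [
            {"pair": [r.param_1, r.param_2], "r": float(r.r), "p": float(r.p)}
            for _, r in coop[coop["correlated"]].iterrows()
        ] if len(coop) else []
    return summary


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run the full profiling pipeline defined by ``config``.

    With ``write=True`` the output directory receives parameters.csv,
    outcomes.csv, enrichment.csv, motifs.json, association.csv,
    correlations.csv, network.graphml / network.json, summary.json, a
    config echo and a run log.  Partial outputs are preserved when a later
    stage raises.
    """
    out: Optional[Path] = None
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logging.getLogger("kinmotif").addHandler(handler)
        save_config(config, out / "config.yaml")

    try:
        model = config.build_model()
        spec = default_range_spec(model, sample_input_edge=config.sample_input_edge)
        logger.info("sampling %d parameter sets (seed %d)", config.n_samples, config.seed)
        matrix = latin_hypercube_sample(config.n_samples, spec, seed=config.seed)
        if out is not None:
            matrix.to_csv(out / "parameters.csv")

        screened = run_screen(
            model, matrix, config.protocol(), config.thresholds(),
            checkpoint=(out / "outcomes.partial.csv") if out is not None else None,
            checkpoint_every=config.checkpoint_every,
        )
        if out is not None:
            kio.write_screen(screened, out / "outcomes.csv")

        profile: Optional[MotifProfileResults] = None
        if int(screened["is_solution"].sum()) > 0:
            profiler = MotifProfiler(
                screened,
                alpha=config.alpha, z_crit=config.z_crit,
                coop_alpha=config.coop_alpha, per_decade=config.per_decade,
                strict_tail=config.strict_tail, coop_log_scale=config.coop_log_scale,
                bounds=dict(spec.bounds),
            )
            profile = profiler.fit()
            if out is not None:
                kio.write_enrichment(profile.enrichment, out / "enrichment.csv")
                kio.write_motifs(profile.motifs, out / "motifs.json")
                kio.write_association(profile.association_table, out / "association.csv")
                kio.write_cooperation(profile.cooperation, out / "correlations.csv")
                kio.write_network(profile.network, out / "network.graphml", out / "network.json")
        else:
            logger.warning("no kinetic solutions found; statistical stages skipped")

        summary = _summarize(config, screened, profile)
        if out is not None:
            (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return PipelineResult(config=config, matrix=matrix, screened=screened,
                              profile=profile, summary=summary, out_dir=out)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        if write:
            logging.getLogger("kinmotif").removeHandler(handler)
            handler.close()
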