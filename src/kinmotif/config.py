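"""Run configuration: a single serializable source of truth for a pipeline run.

A run is a pure function of its :class:`RunConfig`: model preset (or
custom edge list), sample size, master seed, sampling ranges, stimulus
protocol, rejection thresholds, solution criteria and statistical
thresholds.  Configs round-trip through YAML; the pipeline echoes the
config into the output directory as provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .network import (
    Edge,
    NetworkModel,
    NetworkTopology,
    build_generic_model,
    build_nfblb_model,
)
from .simulate import RejectionThresholds, StimulusProtocol

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a screening-and-profiling run depends on."""

    model: str = "nfblb"                       # "nfblb" or "custom"
    custom_edges: tuple[tuple[str, str, str], ...] = ()   # (source, target, mode)
    custom_constant_enzymes: dict = field(default_factory=dict)
    n_samples: int = 100_000
    seed: int = 0
    sample_input_edge: bool = False            # sample k_IA/K_IA vs pin at 1.0
    # stimulus protocol
    I1: float = 0.5
    I2: float = 0.6
    # rejection thresholds (see RejectionThresholds)
    tiny_ss: float = RejectionThresholds.tiny_ss
    tiny_state: float = RejectionThresholds.tiny_state
    tol_ss: float = 1e-9
    t_max: float = 1e4
    settle_tol: float = 1e-4
    osc_floor: float = 1e-4
    rtol: float = 1e-8
    atol: float = 1e-10
    # solution criteria
    min_sensitivity: float = 1.0
    min_precision: float = 10.0
    # statistics
    alpha: float = 1e-3
    z_crit: float = 3.29
    coop_alpha: float = 0.05
    per_decade: int = 1
    strict_tail: bool = True
    coop_log_scale: bool = True
    # orchestration
    out_dir: str = "kinmotif_out"
    checkpoint_every: int = 1000

    def build_model(self) -> NetworkModel:
        if self.model == "nfblb":
            return build_nfblb_model()
        if self.model == "custom":
            if not self.custom_edges:
                raise ValueError("custom model requires custom_edges")
            topo = NetworkTopology(
                nodes=("A", "B", "C"),
                edges=tuple(Edge(s, t, m) for s, t, m in self.custom_edges),
                constant_enzymes=self.custom_constant_enzymes or {"F_B": 0.5, "F_C": 0.5},
            )
            return build_generic_model(topo)
        raise ValueError(f"unknown model preset {self.model!r}")

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(I1=self.I1, I2=self.I2)

    def thresholds(self) -> RejectionThresholds:
        return RejectionThresholds(
            tiny_ss=self.tiny_ss, tiny_state=self.tiny_state, tol_ss=self.tol_ss,
            t_max=self.t_max, settle_tol=self.settle_tol, osc_floor=self.osc_floor,
            rtol=self.rtol, atol=self.atol,
        )

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self


def load_config(path: Path | str) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "custom_edges" in raw:
        raw["custom_edges"] = tuple(tuple(e) for e in raw["custom_edges"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: Path | str) -> None:
    data = asdict(config)
    data["custom_edges"] = [list(e) for e in config.custom_edges]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
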