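"""Three-node enzyme-network models with Michaelis-Menten rate laws.

Each node is an enzyme that interconverts between an active fraction ``X``
and an inactive fraction ``1 - X``.  Every regulatory edge is a saturable
(Michaelis-Menten) activation or deactivation process driven by the active
concentration of its source, which may be another node, the external input
``I``, or a constant-level background enzyme (``F_B``, ``F_C``).

The canonical preset is the negative-feedback-loop-with-buffer (NFBLB)
topology that mirrors the E. coli chemotaxis circuit: the input activates
the receptor node A, A activates the buffer node B and the output node C,
and B closes the negative feedback by deactivating A.  Constant enzymes
F_B and F_C deactivate B and C.

All concentrations, rates and kinetic constants are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Edge",
    "NetworkTopology",
    "NetworkModel",
    "NFBLB_PARAM_NAMES",
    "nfblb_topology",
    "build_nfblb_model",
    "build_generic_model",
    "ifflp_topology",
]

ACTIVATION = "activation"
DEACTIVATION = "deactivation"


@dataclass(frozen=True)
class Edge:
    """One enzymatic regulation: ``source`` converts ``target`` between forms.

    ``mode`` is "activation" (source pushes target toward its active form,
    acting on the inactive pool ``1 - X``) or "deactivation" (source acts on
    the active pool ``X``).
    """

    source: str
    target: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in (ACTIVATION, DEACTIVATION):
            raise ValueError(f"edge mode must be activation|deactivation, got {self.mode!r}")

    @property
    def suffix(self) -> str:
        """Parameter-name suffix, e.g. edge F_B -> B gives 'FBB'."""
        return f"{self.source.replace('_', '')}{self.target.replace('_', '')}"


@dataclass(frozen=True)
class NetworkTopology:
    """Wiring diagram of a small enzyme network.

    Every node must have at least one activation and one deactivation edge;
    otherwise its active fraction is monotone and the bounded [0, 1]
    dynamics is ill-posed.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    input_label: str = "I"
    constant_enzymes: Mapping[str, float] = field(
        default_factory=lambda: {"F_B": 0.5, "F_C": 0.5}
    )

    def __post_init__(self) -> None:
        valid_sources = set(self.nodes) | {self.input_label} | set(self.constant_enzymes)
        for e in self.edges:
            if e.target not in self.nodes:
                raise ValueError(f"edge target {e.target!r} is not a node")
            if e.source not in valid_sources:
                raise ValueError(f"edge source {e.source!r} is not a node, input or constant enzyme")
        for n in self.nodes:
            modes = {e.mode for e in self.edges if e.target == n}
            if ACTIVATION not in modes or DEACTIVATION not in modes:
                raise ValueError(
                    f"node {n!r} needs at least one activation and one deactivation edge"
                )


def nfblb_topology() -> NetworkTopology:
    """The negative-feedback-loop-with-buffer topology (chemotaxis-like)."""
    return NetworkTopology(
        nodes=("A", "B", "C"),
        edges=(
            Edge("I", "A", ACTIVATION),
            Edge("B", "A", DEACTIVATION),
            Edge("A", "B", ACTIVATION),
            Edge("F_B", "B", DEACTIVATION),
            Edge("A", "C", ACTIVATION),
            Edge("F_C", "C", DEACTIVATION),
        ),
    )


def ifflp_topology() -> NetworkTopology:
    """A generic incoherent feed-forward loop with a proportioner node.

    A activates B and C; B deactivates C (the incoherent arm acting through
    the proportioner B).  Background enzymes supply the remaining
    deactivation of A and B and no extra activation is needed.  This is a
    structural preset for exploring the alternative adaptive topology; it is
    not calibrated against any published parameterisation.
    """
    return NetworkTopology(
        nodes=("A", "B", "C"),
        edges=(
            Edge("I", "A", ACTIVATION),
            Edge("F_A", "A", DEACTIVATION),
            Edge("A", "B", ACTIVATION),
            Edge("F_B", "B", DEACTIVATION),
            Edge("A", "C", ACTIVATION),
            Edge("B", "C", DEACTIVATION),
        ),
        constant_enzymes={"F_A": 0.5, "F_B": 0.5},
    )


#: Kinetic parameter names of the NFBLB preset, in edge order: a catalytic
#: rate constant k and a Michaelis-Menten constant K per edge.
NFBLB_PARAM_NAMES: tuple[str, ...] = (
    "k_IA", "K_IA",
    "k_BA", "K_BA",
    "k_AB", "K_AB",
    "k_FBB", "K_FBB",
    "k_AC", "K_AC",
    "k_FCC", "K_FCC",
)


class NetworkModel:
    """A topology together with its assembled Michaelis-Menten rate laws.

    The state vector orders the active fractions by ``topology.nodes``.
    Kinetic parameters order as (k, K) pairs per edge, in edge order; see
    :attr:`param_names`.
    """

    def __init__(self, topology: NetworkTopology):
        self.topology = topology
        self.nodes = topology.nodes
        self.param_names: tuple[str, ...] = tuple(
            name for e in topology.edges for name in (f"k_{e.suffix}", f"K_{e.suffix}")
        )
        self._node_index = {n: i for i, n in enumerate(topology.nodes)}
        # per-edge compiled info: (target_idx, sign, source_kind, source_ref, k_idx, K_idx)
        # source_kind: 0 node (ref = state index), 1 input, 2 constant (ref = level)
        self._edges = []
        for j, e in enumerate(topology.edges):
            if e.source in self._node_index:
                kind, ref = 0, self._node_index[e.source]
            elif e.source == topology.input_label:
                kind, ref = 1, 0.0
            else:
                kind, ref = 2, float(topology.constant_enzymes[e.source])
            self._edges.append(
                (self._node_index[e.target], +1 if e.mode == ACTIVATION else -1, kind, ref, 2 * j, 2 * j + 1)
            )

    @property
    def n_states(self) -> int:
        return len(self.nodes)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def params_from_mapping(self, params: Mapping[str, float]) -> np.ndarray:
        """Order a name->value mapping into the model's parameter vector."""
        return np.array([float(params[name]) for name in self.param_names])

    def rates(
        self, state: Sequence[float], input_level: float, params: Sequence[float]
    ) -> np.ndarray:
        """Time derivatives of the active fractions.

        Each node's derivative is the sum of its activation terms
        ``S * k * (1-X) / ((1-X) + K)`` minus its deactivation terms
        ``S * k * X / (X + K)`` where ``S`` is the source activity.
        """
        state = np.asarray(state, dtype=float)
        params = np.asarray(params, dtype=float)
        out = np.zeros(len(self.nodes))
        for tgt, sign, kind, ref, ki, Ki in self._edges:
            src = state[ref] if kind == 0 else (input_level if kind == 1 else ref)
            x = state[tgt]
            k, K = params[ki], params[Ki]
            if sign > 0:
                out[tgt] += src * k * (1.0 - x) / ((1.0 - x) + K)
            else:
                out[tgt] -= src * k * x / (x + K)
        return out

    def jacobian(
        self, state: Sequence[float], input_level: float, params: Sequence[float]
    ) -> np.ndarray:
        """Analytic Jacobian of :meth:`rates` with respect to the state."""
        state = np.asarray(state, dtype=float)
        params = np.asarray(params, dtype=float)
        n = len(self.nodes)
        J = np.zeros((n, n))
        for tgt, sign, kind, ref, ki, Ki in self._edges:
            src = state[ref] if kind == 0 else (input_level if kind == 1 else ref)
            x = state[tgt]
            k, K = params[ki], params[Ki]
            if sign > 0:
                # d/dx [src*k*(1-x)/((1-x)+K)] = -src*k*K/((1-x)+K)^2
                J[tgt, tgt] -= src * k * K / ((1.0 - x) + K) ** 2
                if kind == 0:
                    J[tgt, ref] += k * (1.0 - x) / ((1.0 - x) + K)
            else:
                J[tgt, tgt] -= src * k * K / (x + K) ** 2
                if kind == 0:
                    J[tgt, ref] -= k * x / (x + K)
        return J


def build_generic_model(topology: NetworkTopology) -> NetworkModel:
    """Assemble rate laws for an arbitrary activation/deactivation topology.

    Raises ``ValueError`` for topologies where some node lacks an activation
    or a deactivation edge (enforced by :class:`NetworkTopology`).
    """
    return NetworkModel(topology)


def build_nfblb_model() -> NetworkModel:
    """The NFBLB (chemotaxis-like) three-node model with its 12 parameters."""
    model = build_generic_model(nfblb_topology())
    assert model.param_names == NFBLB_PARAM_NAMES
    return model
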