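"""E(3)-equivariant message-passing encoder.

Each atom carries scalar features (invariant) and a set of 3-vector
directional features (equivariant). Message networks only ever see
invariant quantities -- scalar features, radial basis values, and
norms/inner products of directional features -- while vector-valued
updates are built from edge unit vectors and gated neighbor vectors, so
equivariance holds by construction rather than by approximation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nnkit
from .elements import DEFAULT_VOCABULARY, check_vocabulary, z_index_map
from .graphs import GraphPair
from .io_structures import AtomicComplex
from .nnkit import Dense, Tensor, concat, gather, segment_sum

#: epsilon under the square root when taking vector norms, so gradients stay
#: finite for exactly-zero directional features
NORM_EPS = 1e-24


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters shared by encoder and readout."""

    n_s: int = 32  # scalar feature width
    n_f: int = 8  # number of directional 3-vector channels
    n_passes: int = 2
    n_hidden: int = 48  # hidden width of message networks
    n_rbf: int = 8
    r_msg: float = 5.0
    r_pair: float = 5.0
    envelope_order: int = 5
    vocabulary: tuple[int, ...] = DEFAULT_VOCABULARY
    readout_hidden: int = 48
    readout_layers: int = 2
    c_L: float = 0.1
    c_P: float = 0.1
    dropout: float = 0.0
    pair_cos_all_pairs: bool = False  # n_f^2 cosines instead of n_f

    def __post_init__(self):
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")

    @property
    def n_vocab(self) -> int:
        return len(self.vocabulary)

    @property
    def edge_feature_size(self) -> int:
        # h_i, h_j, rbf, |v_i|, |v_j|, <v_i, v_j>
        return 2 * self.n_s + self.n_rbf + 3 * self.n_f

    @property
    def pair_feature_size(self) -> int:
        n_cos = self.n_f**2 if self.pair_cos_all_pairs else self.n_f
        return 2 * self.n_s + self.n_rbf + 3 * self.n_f + n_cos

    @property
    def receptive_field(self) -> float:
        return self.n_passes * self.r_msg + self.r_pair

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class NodeStates:
    """Per-atom scalar (n, n_s) and directional (n, n_f, 3) features."""

    scalar: Tensor
    directional: Tensor

    @property
    def n_atoms(self) -> int:
        return self.scalar.shape[0]

    def slice(self, idx: np.ndarray) -> "NodeStates":
        return NodeStates(gather(self.scalar, idx), gather(self.directional, idx))


class MessageLayer:
    """One message pass: a shared invariant trunk with three heads.

    phi_s updates scalars, phi_v scales edge unit vectors, phi_g gates the
    neighbor's directional features.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.trunk = Dense(cfg.edge_feature_size, cfg.n_hidden, rng)
        self.head_s = Dense(cfg.n_hidden, cfg.n_s, rng)
        self.head_v = Dense(cfg.n_hidden, cfg.n_f, rng)
        self.head_g = Dense(cfg.n_hidden, cfg.n_f, rng)

    def params(self) -> dict[str, Tensor]:
        return {
            f"{name}.{k}": v
            for name, mod in (
                ("trunk", self.trunk),
                ("head_s", self.head_s),
                ("head_v", self.head_v),
                ("head_g", self.head_g),
            )
            for k, v in mod.params().items()
        }


class EncoderParams:
    """Element embedding network plus per-pass message layers."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.embedding = nnkit.MLP([cfg.n_vocab, cfg.n_hidden, cfg.n_s], rng)
        self.layers = [MessageLayer(cfg, rng) for _ in range(cfg.n_passes)]

    def params(self) -> dict[str, Tensor]:
        out = {f"embedding.{k}": v for k, v in self.embedding.params().items()}
        for i, layer in enumerate(self.layers):
            out.update({f"pass{i}.{k}": v for k, v in layer.params().items()})
        return out


def vector_norms(v: Tensor) -> Tensor:
    """Channel-wise norms of directional features, (…, n_f, 3) -> (…, n_f)."""
    return ((v * v).sum(axis=-1) + NORM_EPS).sqrt()


def init_states(elements: np.ndarray, params: EncoderParams) -> NodeStates:
    """Embed atomic numbers into scalar features; directional start at zero."""
    cfg = params.cfg
    check_vocabulary(elements, cfg.vocabulary)
    idx_map = z_index_map(cfg.vocabulary)
    idx = np.array([idx_map[int(z)] for z in elements], dtype=np.intp)
    onehot = np.zeros((len(elements), cfg.n_vocab))
    onehot[np.arange(len(elements)), idx] = 1.0
    scalar = params.embedding(Tensor(onehot))
    directional = Tensor(np.zeros((len(elements), cfg.n_f, 3)))
    # zero tensor must stay on the tape so later updates accumulate into it
    return NodeStates(scalar, directional)


def _edge_invariants(
    states: NodeStates, edges: np.ndarray, rbf: np.ndarray
) -> tuple[Tensor, Tensor]:
    h_i = gather(states.scalar, edges[:, 0])
    h_j = gather(states.scalar, edges[:, 1])
    v_i = gather(states.directional, edges[:, 0])
    v_j = gather(states.directional, edges[:, 1])
    feats = concat(
        [
            h_i,
            h_j,
            Tensor(rbf),
            vector_norms(v_i),
            vector_norms(v_j),
            (v_i * v_j).sum(axis=-1),
        ],
        axis=-1,
    )
    return feats, v_j


def message_pass(
    states: NodeStates,
    edges: np.ndarray,
    rbf: np.ndarray,
    unit_vectors: np.ndarray,
    layer: MessageLayer,
) -> NodeStates:
    """Apply one message pass over a combined (disconnected) edge list.

    `edges` holds (receiver, sender) index pairs into the state arrays;
    `unit_vectors` are (x_recv - x_send)/r per edge. Residual updates with
    degree-normalized aggregation (keeps feature magnitudes stable across
    passes; the normalizer is a graph invariant, so equivariance holds):

        h_i   <- h_i + (1/deg_i) sum_j phi_s(e_ij)
        v_i   <- v_i + (1/deg_i) sum_j phi_v(e_ij) * u_ij + phi_g(e_ij) * v_j
    """
    n_atoms = states.n_atoms
    if len(edges) == 0:
        return states
    feats, v_j = _edge_invariants(states, edges, rbf)
    hidden = layer.trunk(feats).silu()
    m_s = layer.head_s(hidden)
    phi_v = layer.head_v(hidden)
    phi_g = layer.head_g(hidden)
    e, n_f = phi_v.shape
    dv = phi_v.reshape(e, n_f, 1) * Tensor(unit_vectors.reshape(e, 1, 3)) + phi_g.reshape(
        e, n_f, 1
    ) * v_j
    recv = edges[:, 0]
    inv_deg = 1.0 / np.maximum(np.bincount(recv, minlength=n_atoms), 1).astype(np.float64)
    return NodeStates(
        states.scalar + segment_sum(m_s, recv, n_atoms) * Tensor(inv_deg[:, None]),
        states.directional
        + segment_sum(dv, recv, n_atoms) * Tensor(inv_deg[:, None, None]),
    )


def combined_edges(
    graph: GraphPair, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge ligand and protein edge lists into complex-indexed arrays.

    Returns (edges, rbf, unit_vectors); the two molecules stay disconnected
    because neither list ever crosses the membership boundary.
    """
    parts_e, parts_rbf = [], []
    if len(graph.ligand_edges):
        parts_e.append(graph.ligand_index[graph.ligand_edges])
        parts_rbf.append(graph.ligand_rbf)
    if len(graph.protein_edges):
        parts_e.append(graph.protein_index[graph.protein_edges])
        parts_rbf.append(graph.protein_rbf)
    if not parts_e:
        n_rbf = graph.ligand_rbf.shape[1] if graph.ligand_rbf.ndim == 2 else 0
        return (
            np.empty((0, 2), dtype=np.int64),
            np.empty((0, n_rbf)),
            np.empty((0, 3)),
        )
    edges = np.vstack(parts_e)
    rbf = np.vstack(parts_rbf)
    rel = coords[edges[:, 0]] - coords[edges[:, 1]]
    r = np.linalg.norm(rel, axis=-1)
    unit = rel / np.maximum(r, 1e-6)[:, None]
    return edges, rbf, unit


def encode(
    graph: GraphPair, complex: AtomicComplex, params: EncoderParams
) -> NodeStates:
    """Run the full encoder (embedding + n_passes message passes)."""
    states = init_states(complex.elements, params)
    edges, rbf, unit = combined_edges(graph, complex.coords)
    for layer in params.layers:
        states = message_pass(states, edges, rbf, unit, layer)
    return states


def encode_arrays(
    elements: np.ndarray,
    edges: np.ndarray,
    rbf: np.ndarray,
    unit_vectors: np.ndarray,
    params: EncoderParams,
) -> NodeStates:
    """Encoder over pre-collated arrays (used for batched training)."""
    states = init_states(elements, params)
    for layer in params.layers:
        states = message_pass(states, edges, rbf, unit_vectors, layer)
    return states
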