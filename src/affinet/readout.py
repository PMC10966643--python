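"""Free-energy readout: predicted pK = shift + atom terms + pair terms.

The shift is a single trainable scalar initialized to the training-label
mean, so atomic and pair contributions represent deviations from the
average binder. The pair readout is deliberately asymmetric in (ligand i,
protein j): the feature vector puts the ligand block first and is never
symmetrized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnkit
from .egnn import (
    NORM_EPS,
    EncoderParams,
    ModelConfig,
    NodeStates,
    combined_edges,
    encode_arrays,
)
from .graphs import GraphPair, RadialBasisConfig, bessel_basis, DISTANCE_FLOOR
from .io_structures import LIGAND, AtomicComplex, InputError
from .nnkit import MLP, Tensor, concat, gather, segment_sum

MODES = ("full", "ligand_only")


class ReadoutParams:
    """Atomic and pair readout networks plus the global shift parameter."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, shift: float = 0.0):
        self.cfg = cfg
        hidden = [cfg.readout_hidden] * cfg.readout_layers
        self.atom_mlp = MLP(
            [cfg.n_s, *hidden, 1], rng, zero_init_last=True, dropout=cfg.dropout
        )
        self.pair_mlp = MLP(
            [cfg.pair_feature_size, *hidden, 1],
            rng,
            zero_init_last=True,
            dropout=cfg.dropout,
        )
        self.shift = Tensor(np.float64(shift), requires_grad=True)

    def params(self) -> dict[str, Tensor]:
        out = {f"atom_mlp.{k}": v for k, v in self.atom_mlp.params().items()}
        out.update({f"pair_mlp.{k}": v for k, v in self.pair_mlp.params().items()})
        out["shift"] = self.shift
        return out


@dataclass
class PredictionBreakdown:
    """Shift + per-atom + per-pair pK contributions and their sum."""

    shift: float
    atom_contribs: np.ndarray  # per ligand atom, storage order
    pair_contribs: np.ndarray  # per cross pair
    pair_indices: np.ndarray  # (P, 2) ligand/protein local indices
    pair_r: np.ndarray
    total: float
    mode: str = "full"
    id: str = ""

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "mode": self.mode,
            "total_pK": float(self.total),
            "shift": float(self.shift),
            "atom_contribs": [float(x) for x in self.atom_contribs],
            "pair_contribs": [
                {"i": int(i), "j": int(j), "r_ij": float(r), "value": float(v)}
                for (i, j), r, v in zip(self.pair_indices, self.pair_r, self.pair_contribs)
            ],
        }


# ---------------------------------------------------------------------------
# feature construction


def pair_feature_vector(
    h_i: np.ndarray,
    h_j: np.ndarray,
    v_i: np.ndarray,
    v_j: np.ndarray,
    r_ij: float,
    cfg: ModelConfig,
) -> np.ndarray:
    """Invariant feature vector for one (ligand i, protein j) pair.

    Layout (ligand block first): [h_i, h_j, rbf(r_ij), |v_i|_k, |v_j|_k,
    <v_i_k, v_j_k>_k, cos(theta_k)]. Cosines are 0 whenever either vector
    norm is below 1e-12.
    """
    rbf = bessel_basis(
        max(float(r_ij), DISTANCE_FLOOR),
        RadialBasisConfig(cfg.n_rbf, cfg.r_pair, cfg.envelope_order),
    )
    ni = np.sqrt((v_i**2).sum(axis=-1) + NORM_EPS)
    nj = np.sqrt((v_j**2).sum(axis=-1) + NORM_EPS)
    if cfg.pair_cos_all_pairs:
        dots_cos = (v_i[:, None, :] * v_j[None, :, :]).sum(axis=-1)
        cos = (dots_cos / (ni[:, None] * nj[None, :])).ravel()
    else:
        cos = (v_i * v_j).sum(axis=-1) / (ni * nj)
    dots = (v_i * v_j).sum(axis=-1)
    return np.concatenate([h_i, h_j, rbf, ni, nj, dots, cos])


def _pair_features_batch(
    states: NodeStates,
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    pair_rbf: np.ndarray,
    cfg: ModelConfig,
) -> Tensor:
    h_i = gather(states.scalar, pair_i)
    h_j = gather(states.scalar, pair_j)
    v_i = gather(states.directional, pair_i)
    v_j = gather(states.directional, pair_j)
    ni = ((v_i * v_i).sum(axis=-1) + NORM_EPS).sqrt()
    nj = ((v_j * v_j).sum(axis=-1) + NORM_EPS).sqrt()
    dots = (v_i * v_j).sum(axis=-1)
    if cfg.pair_cos_all_pairs:
        p = len(pair_i)
        dc = (v_i.reshape(p, cfg.n_f, 1, 3) * v_j.reshape(p, 1, cfg.n_f, 3)).sum(axis=-1)
        norm_outer = ni.reshape(p, cfg.n_f, 1) * nj.reshape(p, 1, cfg.n_f)
        cos = (dc / norm_outer).reshape(p, cfg.n_f**2)
    else:
        cos = dots / (ni * nj)
    return concat([h_i, h_j, Tensor(pair_rbf), ni, nj, dots, cos], axis=-1)


def atomic_readout(
    ligand_states: NodeStates,
    params: ReadoutParams,
    train_rng: np.random.Generator | None = None,
) -> Tensor:
    """Per-ligand-atom contributions c_L * NN(h_i^scal); scalars only."""
    n = ligand_states.scalar.shape[0]
    out = params.atom_mlp(ligand_states.scalar, train_rng)
    return out.reshape(n) * params.cfg.c_L


# ---------------------------------------------------------------------------
# collation: one or many complexes -> flat arrays for the encoder


@dataclass
class CollatedBatch:
    elements: np.ndarray
    edges: np.ndarray
    rbf: np.ndarray
    unit: np.ndarray
    lig_atom_idx: np.ndarray  # global indices of ligand atoms
    lig_atom_seg: np.ndarray  # complex id per ligand atom
    pair_i: np.ndarray  # global ligand index per cross pair
    pair_j: np.ndarray  # global protein index per cross pair
    pair_rbf: np.ndarray
    pair_seg: np.ndarray
    n_complexes: int
    labels: np.ndarray | None = None
    ids: list = field(default_factory=list)


def collate(
    complexes: list[AtomicComplex],
    graphs: list[GraphPair],
    mode: str = "full",
) -> CollatedBatch:
    """Merge complexes into one disjoint-union graph with index offsets."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    el, ed, rb, un = [], [], [], []
    lig_idx, lig_seg, p_i, p_j, p_rbf, p_seg = [], [], [], [], [], []
    offset = 0
    labels, have_labels = [], True
    for b, (cx, g) in enumerate(zip(complexes, graphs)):
        if cx.n_ligand < 1:
            raise InputError(f"complex {cx.id!r} has no ligand atoms")
        if mode == "ligand_only":
            lig_mask = cx.membership == LIGAND
            el.append(cx.elements[lig_mask])
            if len(g.ligand_edges):
                ed.append(g.ligand_edges + offset)
                rb.append(g.ligand_rbf)
                lig_xyz = cx.coords[lig_mask]
                rel = lig_xyz[g.ligand_edges[:, 0]] - lig_xyz[g.ligand_edges[:, 1]]
                r = np.linalg.norm(rel, axis=-1)
                un.append(rel / np.maximum(r, 1e-6)[:, None])
            lig_idx.append(np.arange(g.n_ligand) + offset)
            lig_seg.append(np.full(g.n_ligand, b))
            offset += g.n_ligand
        else:
            el.append(cx.elements)
            edges, rbf, unit = combined_edges(g, cx.coords)
            if len(edges):
                ed.append(edges + offset)
                rb.append(rbf)
                un.append(unit)
            lig_idx.append(g.ligand_index + offset)
            lig_seg.append(np.full(g.n_ligand, b))
            if len(g.cross_pairs):
                p_i.append(g.ligand_index[g.cross_pairs[:, 0]] + offset)
                p_j.append(g.protein_index[g.cross_pairs[:, 1]] + offset)
                p_rbf.append(g.pair_rbf)
                p_seg.append(np.full(len(g.cross_pairs), b))
            offset += len(cx)
        if cx.label is None:
            have_labels = False
        else:
            labels.append(cx.label)

    n_rbf = graphs[0].ligand_rbf.shape[1] if graphs else 0

    def cat(parts, empty_shape, dtype=np.float64):
        if parts:
            return np.concatenate(parts)
        return np.empty(empty_shape, dtype=dtype)

    return CollatedBatch(
        elements=cat(el, (0,), np.int64),
        edges=np.vstack(ed) if ed else np.empty((0, 2), dtype=np.int64),
        rbf=np.vstack(rb) if rb else np.empty((0, n_rbf)),
        unit=np.vstack(un) if un else np.empty((0, 3)),
        lig_atom_idx=cat(lig_idx, (0,), np.int64),
        lig_atom_seg=cat(lig_seg, (0,), np.int64),
        pair_i=cat(p_i, (0,), np.int64),
        pair_j=cat(p_j, (0,), np.int64),
        pair_rbf=np.vstack(p_rbf) if p_rbf else np.empty((0, n_rbf)),
        pair_seg=cat(p_seg, (0,), np.int64),
        n_complexes=len(complexes),
        labels=np.asarray(labels) if have_labels and labels else None,
        ids=[cx.id for cx in complexes],
    )


def forward_collated(
    batch: CollatedBatch,
    encoder: EncoderParams,
    readout: ReadoutParams,
    mode: str = "full",
    train_rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor, Tensor]:
    """Forward pass over a collated batch.

    Returns (totals per complex, per-ligand-atom contributions, per-pair
    contributions); the latter two are empty-safe tensors.
    """
    states = encode_arrays(batch.elements, batch.edges, batch.rbf, batch.unit, encoder)
    lig_states = states.slice(batch.lig_atom_idx)
    atom_c = atomic_readout(lig_states, readout, train_rng)
    totals = readout.shift + segment_sum(
        atom_c.reshape(-1, 1), batch.lig_atom_seg, batch.n_complexes
    ).reshape(batch.n_complexes)
    if mode == "full" and len(batch.pair_i):
        feats = _pair_features_batch(
            states, batch.pair_i, batch.pair_j, batch.pair_rbf, readout.cfg
        )
        pair_c = readout.pair_mlp(feats, train_rng).reshape(len(batch.pair_i)) * readout.cfg.c_P
        totals = totals + segment_sum(
            pair_c.reshape(-1, 1), batch.pair_seg, batch.n_complexes
        ).reshape(batch.n_complexes)
    else:
        pair_c = Tensor(np.empty(0))
    return totals, atom_c, pair_c


def predict(
    complex: AtomicComplex,
    graph: GraphPair,
    encoder: EncoderParams,
    readout: ReadoutParams,
    mode: str = "full",
) -> PredictionBreakdown:
    """Predict pK for one complex and return the full contribution breakdown."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if complex.n_ligand < 1:
        raise InputError(f"complex {complex.id!r} has no ligand atoms")
    batch = collate([complex], [graph], mode)
    totals, atom_c, pair_c = forward_collated(batch, encoder, readout, mode)
    use_pairs = mode == "full" and len(graph.cross_pairs)
    return PredictionBreakdown(
        shift=float(readout.shift.data),
        atom_contribs=atom_c.data.copy(),
        pair_contribs=pair_c.data.copy() if use_pairs else np.empty(0),
        pair_indices=graph.cross_pairs if use_pairs else np.empty((0, 2), dtype=np.int64),
        pair_r=graph.pair_r if use_pairs else np.empty(0),
        total=float(totals.data[0]),
        mode=mode,
        id=complex.id,
    )
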