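"""Distance-cutoff graph construction and Bessel radial basis expansion.

Two disconnected intra-molecular graphs (ligand and protein) carry the
message passing; an ordered ligand->protein pair list feeds the pair
readout. Edges never cross the protein/ligand boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_structures import LIGAND, AtomicComplex

#: below this distance two distinct atoms are treated as 1e-6 Angstrom apart
#: so that 1/r terms stay finite
DISTANCE_FLOOR = 1e-6

#: atom count above which neighbor search switches from the O(N^2) scan to a
#: spatial tree; both routes are tested to agree exactly
BRUTE_FORCE_LIMIT = 500


@dataclass(frozen=True)
class RadialBasisConfig:
    n_rbf: int = 8
    r_cut: float = 5.0
    envelope_order: int = 5

    def __post_init__(self):
        if self.n_rbf < 1:
            raise ValueError("n_rbf must be >= 1")
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")


def smooth_envelope(d: np.ndarray, order: int = 5) -> np.ndarray:
    """Polynomial cutoff u(d) with u(0)=1 and u, u', u'' -> 0 at d=1.

    d is the distance scaled by the cutoff radius; values >= 1 map to 0.
    """
    p = order
    d = np.asarray(d, dtype=np.float64)
    out = (
        1.0
        - (p + 1) * (p + 2) / 2.0 * d**p
        + p * (p + 2) * d ** (p + 1)
        - p * (p + 1) / 2.0 * d ** (p + 2)
    )
    return np.where(d < 1.0, out, 0.0)


def bessel_basis(
    r: np.ndarray | float, cfg: RadialBasisConfig, envelope: bool = True
) -> np.ndarray:
    """Expand distances on the spherical Bessel j0 basis.

    Component n (1-based) is sqrt(2/r_cut) * sin(n pi r / r_cut) / r, times
    a smooth polynomial envelope so every component vanishes continuously at
    r = r_cut. Returns shape r.shape + (n_rbf,).
    """
    scalar = np.isscalar(r)
    r = np.atleast_1d(np.asarray(r, dtype=np.float64))
    if np.any(r <= 0):
        raise ValueError("bessel_basis requires r > 0")
    n = np.arange(1, cfg.n_rbf + 1, dtype=np.float64)
    arg = n[None, :] * np.pi * r[:, None] / cfg.r_cut
    out = np.sqrt(2.0 / cfg.r_cut) * np.sin(arg) / r[:, None]
    if envelope:
        out = out * smooth_envelope(r / cfg.r_cut, cfg.envelope_order)[:, None]
    else:
        out = np.where((r <= cfg.r_cut)[:, None], out, 0.0)
    return out[0] if scalar else out


@dataclass
class GraphPair:
    """Edge lists and distance expansions for one complex.

    Intra-molecular edge indices are local to their molecule (ligand edges
    index ligand atoms 0..n_ligand-1 in storage order; same for protein).
    Cross pairs are ordered (ligand local index, protein local index).
    """

    n_ligand: int
    n_protein: int
    ligand_edges: np.ndarray  # (E_l, 2) directed, symmetric
    protein_edges: np.ndarray  # (E_p, 2) directed, symmetric
    cross_pairs: np.ndarray  # (P, 2) = (ligand i, protein j)
    ligand_r: np.ndarray
    protein_r: np.ndarray
    pair_r: np.ndarray
    ligand_rbf: np.ndarray
    protein_rbf: np.ndarray
    pair_rbf: np.ndarray
    r_msg: float
    r_pair: float
    ligand_index: np.ndarray = field(default=None)  # local -> complex index
    protein_index: np.ndarray = field(default=None)

    @property
    def n_edges(self) -> int:
        return len(self.ligand_edges) + len(self.protein_edges)


def _intra_edges_brute(xyz: np.ndarray, cutoff: float) -> np.ndarray:
    n = len(xyz)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    i, j = np.nonzero((d <= cutoff) & ~np.eye(n, dtype=bool))
    edges = np.stack([i, j], axis=1)
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def _intra_edges_tree(xyz: np.ndarray, cutoff: float) -> np.ndarray:
    if len(xyz) < 2:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")  # i < j, inclusive
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.vstack([pairs, pairs[:, ::-1]])
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def _cross_pairs_brute(lig: np.ndarray, prot: np.ndarray, cutoff: float) -> np.ndarray:
    if len(lig) == 0 or len(prot) == 0:
        return np.empty((0, 2), dtype=np.int64)
    d = np.linalg.norm(lig[:, None, :] - prot[None, :, :], axis=-1)
    i, j = np.nonzero(d <= cutoff)
    pairs = np.stack([i, j], axis=1)
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def _cross_pairs_tree(lig: np.ndarray, prot: np.ndarray, cutoff: float) -> np.ndarray:
    if len(lig) == 0 or len(prot) == 0:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(prot)
    pairs = [
        (i, j)
        for i, js in enumerate(tree.query_ball_point(lig, cutoff))
        for j in sorted(js)
    ]
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(pairs, dtype=np.int64)


def build_graphs(
    complex: AtomicComplex,
    r_msg: float = 5.0,
    r_pair: float = 5.0,
    rbf_cfg: RadialBasisConfig | None = None,
    brute_force: bool | None = None,
) -> GraphPair:
    """Build intra-molecular edges and the cross pair list for one complex.

    Edge ordering is deterministic (lexicographic by indices). `brute_force`
    forces the O(N^2) route (None = automatic by atom count).
    """
    if r_msg <= 0 or r_pair <= 0:
        raise ValueError("cutoffs must be positive")
    if rbf_cfg is None:
        rbf_cfg = RadialBasisConfig(r_cut=r_msg)
    pair_cfg = RadialBasisConfig(
        n_rbf=rbf_cfg.n_rbf, r_cut=r_pair, envelope_order=rbf_cfg.envelope_order
    )

    lig_mask = complex.membership == LIGAND
    lig_xyz = complex.coords[lig_mask]
    prot_xyz = complex.coords[~lig_mask]
    if brute_force is None:
        brute_force = len(complex) <= BRUTE_FORCE_LIMIT
    intra = _intra_edges_brute if brute_force else _intra_edges_tree
    cross = _cross_pairs_brute if brute_force else _cross_pairs_tree

    lig_edges = intra(lig_xyz, r_msg)
    prot_edges = intra(prot_xyz, r_msg)
    pairs = cross(lig_xyz, prot_xyz, r_pair)

    def dists(xyz_a, xyz_b):
        if len(xyz_a) == 0:
            return np.empty(0, dtype=np.float64)
        return np.linalg.norm(xyz_a - xyz_b, axis=-1)

    lig_r = dists(lig_xyz[lig_edges[:, 0]], lig_xyz[lig_edges[:, 1]])
    prot_r = dists(prot_xyz[prot_edges[:, 0]], prot_xyz[prot_edges[:, 1]])
    pair_r = dists(lig_xyz[pairs[:, 0]], prot_xyz[pairs[:, 1]])

    def expand(r, cfg):
        if len(r) == 0:
            return np.empty((0, cfg.n_rbf), dtype=np.float64)
        return bessel_basis(np.maximum(r, DISTANCE_FLOOR), cfg)

    return GraphPair(
        n_ligand=int(lig_mask.sum()),
        n_protein=int((~lig_mask).sum()),
        ligand_edges=lig_edges,
        protein_edges=prot_edges,
        cross_pairs=pairs,
        ligand_r=lig_r,
        protein_r=prot_r,
        pair_r=pair_r,
        ligand_rbf=expand(lig_r, rbf_cfg),
        protein_rbf=expand(prot_r, rbf_cfg),
        pair_rbf=expand(pair_r, pair_cfg),
        r_msg=float(r_msg),
        r_pair=float(r_pair),
        ligand_index=np.nonzero(lig_mask)[0],
        protein_index=np.nonzero(~lig_mask)[0],
    )


def dump_edges_tsv(path, graph: GraphPair) -> None:
    """Debug dump of all edges/pairs as TSV (kind, i, j, r_ij)."""
    with open(path, "w") as fh:
        fh.write("kind\ti\tj\tr_ij\n")
        for kind, edges, rs in (
            ("ligand", graph.ligand_edges, graph.ligand_r),
            ("protein", graph.protein_edges, graph.protein_r),
            ("cross", graph.cross_pairs, graph.pair_r),
        ):
            for (i, j), r in zip(edges, rs):
                fh.write(f"{kind}\t{i}\t{j}\t{r:.6f}\n")
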