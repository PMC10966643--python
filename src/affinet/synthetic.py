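"""Synthetic point-cloud complexes with a known additive affinity oracle.

The oracle assigns pK = baseline + per-ligand-atom element terms + distance-
decaying ligand-protein pair couplings, i.e. exactly the functional class
the model's atomic + pair readouts can represent. Two regimes are emulated:
a diverse "global" set and congeneric "local" series around a fixed pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_structures import (
    LIGAND,
    PROTEIN,
    AtomicComplex,
    DatasetManifest,
    ManifestRecord,
    write_complex,
    write_manifest,
)

DEFAULT_ATOMIC_TERMS = {6: 0.40, 7: 0.70, 8: -0.55, 9: 0.20, 16: 0.85, 17: 0.50}

# symmetric couplings in pK units; looked up as f[(min(Z, Z'), max(Z, Z'))].
# Magnitudes are kept at roughly half the atomic terms so the pair signal is
# a meaningful but not dominant share of the label variance.
DEFAULT_PAIR_COUPLINGS = {
    (6, 6): 0.14, (6, 7): -0.20, (6, 8): 0.24, (6, 16): 0.18, (6, 9): 0.10,
    (6, 17): -0.12, (7, 7): 0.32, (7, 8): -0.28, (7, 16): 0.12, (7, 9): -0.08,
    (7, 17): 0.16, (8, 8): 0.22, (8, 16): -0.16, (8, 9): 0.14, (8, 17): 0.08,
    (9, 9): 0.12, (9, 16): -0.10, (9, 17): 0.06, (16, 16): 0.20, (16, 17): 0.10,
    (17, 17): 0.12,
}

#: drug-like, carbon-dominant element distribution (no hydrogens: the toy
#: complexes are heavy-atom point clouds)
DEFAULT_ELEMENT_DIST = {6: 0.55, 7: 0.15, 8: 0.15, 16: 0.06, 9: 0.05, 17: 0.04}


class GenerationError(RuntimeError):
    """Packing constraints could not be satisfied after bounded retries."""


class OracleParameterError(KeyError):
    """The oracle has no term for an element present in the complex."""


@dataclass(frozen=True)
class OracleParams:
    baseline: float = 5.0
    atomic: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_ATOMIC_TERMS))
    pair: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_COUPLINGS)
    )
    decay_length: float = 2.0  # Angstrom
    pair_cutoff: float = 5.0  # Angstrom
    noise_sd: float = 0.2  # pK; 0 for exact-recovery experiments

    def __post_init__(self):
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def coupling(self, z1: int, z2: int) -> float:
        key = (min(z1, z2), max(z1, z2))
        try:
            return self.pair[key]
        except KeyError:
            raise OracleParameterError(f"no pair coupling for Z pair {key}") from None


@dataclass(frozen=True)
class GeometrySpec:
    ligand_radius: float = 2.8  # ligand atoms sampled in this ball
    shell_inner: float = 3.2  # protein shell around the ligand blob
    shell_outer: float = 6.0
    min_separation: float = 1.0
    max_tries: int = 2000


def _sample_elements(rng: np.random.Generator, n: int, dist=None) -> np.ndarray:
    dist = dist or DEFAULT_ELEMENT_DIST
    zs = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[z] for z in zs], dtype=np.float64)
    probs = probs / probs.sum()
    return rng.choice(zs, size=n, p=probs)


def _pack_points(
    rng: np.random.Generator,
    n: int,
    sampler,
    existing: np.ndarray,
    min_sep: float,
    max_tries: int,
) -> np.ndarray:
    """Dart-throwing with a minimum separation against all placed points."""
    placed: list[np.ndarray] = []
    occupied = [existing] if len(existing) else []
    for _ in range(n):
        for attempt in range(max_tries):
            cand = sampler()
            ok = True
            for block in occupied + ([np.array(placed)] if placed else []):
                if len(block) and np.min(np.linalg.norm(block - cand, axis=-1)) < min_sep:
                    ok = False
                    break
            if ok:
                placed.append(cand)
                break
        else:
            raise GenerationError(
                f"could not place point {len(placed) + 1}/{n} after {max_tries} tries"
            )
    return np.array(placed) if placed else np.empty((0, 3))


def make_complex(
    n_protein: int,
    n_ligand: int,
    seed: int | np.random.Generator,
    geometry: GeometrySpec | None = None,
    element_dist: dict[int, float] | None = None,
    id: str = "",
) -> AtomicComplex:
    """A ligand blob with a protein shell around it, min 1 A separation."""
    if n_ligand < 1:
        raise ValueError("n_ligand must be >= 1")
    if n_protein < 0:
        raise ValueError("n_protein must be >= 0")
    geo = geometry or GeometrySpec()
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    def ball():
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        return v * geo.ligand_radius * rng.random() ** (1.0 / 3.0)

    def shell():
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        r3 = rng.uniform(geo.shell_inner**3, geo.shell_outer**3)
        return v * r3 ** (1.0 / 3.0)

    lig_xyz = _pack_points(
        rng, n_ligand, ball, np.empty((0, 3)), geo.min_separation, geo.max_tries
    )
    prot_xyz = _pack_points(
        rng, n_protein, shell, lig_xyz, geo.min_separation, geo.max_tries
    )
    elements = np.concatenate(
        [
            _sample_elements(rng, n_protein, element_dist),
            _sample_elements(rng, n_ligand, element_dist),
        ]
    )
    coords = np.vstack([prot_xyz, lig_xyz])
    membership = np.concatenate(
        [np.full(n_protein, PROTEIN), np.full(n_ligand, LIGAND)]
    )
    return AtomicComplex(elements, coords, membership, id=id)


def oracle_label(
    complex: AtomicComplex,
    params: OracleParams | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Ground-truth pK: baseline + atomic terms + exp-decaying pair terms."""
    params = params or OracleParams()
    lig = complex.membership == LIGAND
    total = params.baseline
    for z in complex.elements[lig]:
        try:
            total += params.atomic[int(z)]
        except KeyError:
            raise OracleParameterError(f"no atomic term for Z={int(z)}") from None
    lig_z = complex.elements[lig]
    lig_xyz = complex.coords[lig]
    prot_z = complex.elements[~lig]
    prot_xyz = complex.coords[~lig]
    if len(prot_z):
        d = np.linalg.norm(lig_xyz[:, None, :] - prot_xyz[None, :, :], axis=-1)
        for i, j in zip(*np.nonzero(d <= params.pair_cutoff)):
            total += params.coupling(int(lig_z[i]), int(prot_z[j])) * np.exp(
                -d[i, j] / params.decay_length
            )
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_sd > 0")
        total += rng.normal(0.0, params.noise_sd)
    return float(total)


def make_global_dataset(
    n: int,
    seed: int = 0,
    params: OracleParams | None = None,
    n_protein_range: tuple[int, int] = (10, 18),
    n_ligand_range: tuple[int, int] = (4, 16),
    geometry: GeometrySpec | None = None,
) -> list[AtomicComplex]:
    """Diverse labeled complexes emulating a global training corpus."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or OracleParams()
    out = []
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(ss)
        cx = make_complex(
            int(rng.integers(*n_protein_range)),
            int(rng.integers(*n_ligand_range)),
            rng,
            geometry,
            id=f"glob-{i:05d}",
        )
        cx.label = oracle_label(cx, params, rng)
        out.append(cx)
    return out


def make_local_series(
    base: AtomicComplex,
    n_ligands: int,
    seed: int = 0,
    params: OracleParams | None = None,
    swap_fraction: float = 0.2,
    jitter_radius: float = 0.3,
    max_added_atoms: int = 2,
) -> list[AtomicComplex]:
    """A congeneric series: fixed protein pocket, scaffold-sharing ligands.

    Each ligand keeps >= 80% of the base scaffold atoms (element identity),
    jitters scaffold coordinates by <= 0.5 A, and may gain a few peripheral
    atoms. Labels come from the oracle and span a narrow range.
    """
    if n_ligands < 2:
        raise ValueError("n_ligands must be >= 2")
    params = params or OracleParams()
    lig_mask = base.membership == LIGAND
    scaffold_z = base.elements[lig_mask]
    scaffold_xyz = base.coords[lig_mask]
    prot_z = base.elements[~lig_mask]
    prot_xyz = base.coords[~lig_mask]
    n_scaffold = len(scaffold_z)
    n_swap = min(int(np.floor(swap_fraction * n_scaffold)), n_scaffold)
    swap_targets = sorted(set(DEFAULT_ATOMIC_TERMS) & set(params.atomic))

    out = []
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_ligands)):
        rng = np.random.default_rng(ss)
        zs = scaffold_z.copy()
        if n_swap:
            swap_idx = rng.choice(n_scaffold, size=rng.integers(0, n_swap + 1), replace=False)
            for k in swap_idx:
                zs[k] = rng.choice([z for z in swap_targets if z != zs[k]])
        direction = rng.normal(size=scaffold_xyz.shape)
        direction /= np.linalg.norm(direction, axis=-1, keepdims=True)
        xyz = scaffold_xyz + direction * (
            jitter_radius * rng.random(n_scaffold) ** (1.0 / 3.0)
        )[:, None]
        n_add = int(rng.integers(0, max_added_atoms + 1))
        if n_add:
            center = xyz.mean(axis=0)
            span = np.max(np.linalg.norm(xyz - center, axis=-1))

            def periph():
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                return center + v * rng.uniform(span, span + 1.5)

            added = _pack_points(rng, n_add, periph, np.vstack([xyz, prot_xyz]), 1.0, 500)
            xyz = np.vstack([xyz, added])
            zs = np.concatenate([zs, _sample_elements(rng, n_add)])
        cx = AtomicComplex(
            np.concatenate([prot_z, zs]),
            np.vstack([prot_xyz, xyz]),
            np.concatenate([np.full(len(prot_z), PROTEIN), np.full(len(zs), LIGAND)]),
            id=f"{base.id or 'local'}-lig{i:04d}",
        )
        cx.label = oracle_label(cx, params, rng)
        out.append(cx)
    return out


def write_dataset(
    dataset: list[AtomicComplex],
    out_dir: str | Path,
    manifest_name: str = "manifest.csv",
    shared_protein: bool = False,
) -> Path:
    """Write PDB+SDF files plus a manifest so the real I/O stack is exercised.

    With `shared_protein` all records reference one PDB (the local-series
    layout); otherwise each record gets its own.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    shared_pdb = None
    for cx in dataset:
        lig_path = out_dir / f"{cx.id}_ligand.sdf"
        if cx.n_protein == 0:
            prot_path = None
        elif shared_protein:
            if shared_pdb is None:
                shared_pdb = out_dir / "protein.pdb"
                write_complex(cx, shared_pdb, lig_path)
            else:
                write_complex(cx, None, lig_path)
            prot_path = shared_pdb
        else:
            prot_path = out_dir / f"{cx.id}_protein.pdb"
            write_complex(cx, prot_path, lig_path)
        records.append(
            ManifestRecord(
                id=cx.id,
                protein_path=None if prot_path is None else prot_path.name,
                ligand_path=lig_path.name,
                label=cx.label,
            )
        )
    manifest_path = out_dir / manifest_name
    write_manifest(manifest_path, DatasetManifest(records=records, provenance="synthetic"))
    return manifest_path
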