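"""Reading and writing protein/ligand structures as atomic complexes.

Proteins are read from PDB files (first altloc kept; waters and hetero
records dropped), ligands from SDF or MOL2. No protonation or preparation is
performed: the scoring function consumes coordinates as given.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .elements import (
    DEFAULT_VOCABULARY,
    VocabularyError,
    check_vocabulary,
    symbol_to_z,
    z_to_symbol,
)

logger = logging.getLogger(__name__)

PROTEIN = 0
LIGAND = 1

_WATER_RES = {"HOH", "WAT", "DOD", "H2O"}


class FormatError(ValueError):
    """A structure file could not be parsed in its declared format."""


class InputError(ValueError):
    """A structurally valid file describes an unusable input (e.g. no atoms)."""


class ManifestError(ValueError):
    """A dataset manifest is malformed (duplicate ids, missing files, ...)."""


@dataclass
class AtomicComplex:
    """A protein-ligand complex as a flat list of atoms.

    Attributes
    ----------
    elements : (n,) int array of atomic numbers Z.
    coords : (n, 3) float array, Angstrom.
    membership : (n,) int array, 0 = protein, 1 = ligand.
    label : optional pK value (pKi / pKd / pEC50).
    id : opaque identifier.
    """

    elements: np.ndarray
    coords: np.ndarray
    membership: np.ndarray
    label: float | None = None
    id: str = ""

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.membership = np.asarray(self.membership, dtype=np.int64)
        n = len(self.elements)
        if self.coords.shape != (n, 3) or self.membership.shape != (n,):
            raise InputError(
                f"inconsistent complex arrays: {n} elements, coords "
                f"{self.coords.shape}, membership {self.membership.shape}"
            )
        if n and not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates in complex")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def ligand_idx(self) -> np.ndarray:
        return np.nonzero(self.membership == LIGAND)[0]

    @property
    def protein_idx(self) -> np.ndarray:
        return np.nonzero(self.membership == PROTEIN)[0]

    @property
    def n_ligand(self) -> int:
        return int((self.membership == LIGAND).sum())

    @property
    def n_protein(self) -> int:
        return int((self.membership == PROTEIN).sum())

    def validate(self, vocabulary=DEFAULT_VOCABULARY) -> "AtomicComplex":
        check_vocabulary(self.elements, vocabulary)
        if self.n_ligand < 1:
            raise InputError(f"complex {self.id!r} has no ligand atoms")
        return self


@dataclass
class ManifestRecord:
    id: str
    protein_path: Path | None
    ligand_path: Path
    label: float | None


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    provenance: str = ""


# ---------------------------------------------------------------------------
# readers


def _ligand_from_rdkit(mol: Chem.Mol, source: str) -> tuple[np.ndarray, np.ndarray]:
    if mol is None:
        raise FormatError(f"could not parse ligand record in {source}")
    if mol.GetNumAtoms() == 0:
        raise InputError(f"ligand in {source} contains no atoms")
    if mol.GetNumConformers() == 0:
        raise FormatError(f"ligand in {source} has no 3D coordinates")
    zs = np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=np.int64)
    coords = np.asarray(mol.GetConformer().GetPositions(), dtype=np.float64)
    return zs, coords


def read_ligand(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read the first ligand record of an SDF or MOL2 file -> (Z, coords)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".sdf", ".mol", ".sd"}:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        try:
            mol = next(iter(supplier))
        except StopIteration:
            raise FormatError(f"no molecule records in {path}") from None
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    else:
        raise FormatError(f"unsupported ligand format {suffix!r} ({path})")
    return _ligand_from_rdkit(mol, str(path))


def read_protein(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read protein atoms from a PDB file -> (Z, coords).

    Keeps the first altloc, drops waters and HETATM records (the ligand is
    supplied separately), keeps hydrogens when present.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    keep = ~atoms.hetero & ~np.isin(atoms.res_name, list(_WATER_RES))
    atoms = atoms[keep]
    zs = np.array([symbol_to_z(e) for e in atoms.element], dtype=np.int64)
    return zs, np.asarray(atoms.coord, dtype=np.float64)


def read_complex(
    protein_file: str | Path | None,
    ligand_file: str | Path,
    label: float | None = None,
    id: str = "",
    vocabulary=DEFAULT_VOCABULARY,
) -> AtomicComplex:
    """Assemble one AtomicComplex from a PDB protein and an SDF/MOL2 ligand.

    `protein_file` may be None for ligand-only records.
    """
    lig_z, lig_xyz = read_ligand(ligand_file)
    if protein_file is not None:
        prot_z, prot_xyz = read_protein(protein_file)
    else:
        prot_z = np.empty(0, dtype=np.int64)
        prot_xyz = np.empty((0, 3), dtype=np.float64)
    elements = np.concatenate([prot_z, lig_z])
    coords = np.vstack([prot_xyz, lig_xyz])
    membership = np.concatenate(
        [np.full(len(prot_z), PROTEIN), np.full(len(lig_z), LIGAND)]
    )
    cx = AtomicComplex(elements, coords, membership, label=label, id=id or str(ligand_file))
    return cx.validate(vocabulary)


def extract_pocket(complex: AtomicComplex, radius: float) -> AtomicComplex:
    """Keep all ligand atoms plus protein atoms within `radius` of the ligand.

    Atom ordering is preserved. `radius = inf` is the identity.
    """
    if radius < 0:
        raise ValueError(f"pocket radius must be non-negative, got {radius}")
    if math.isinf(radius) or complex.n_protein == 0:
        return complex
    lig_xyz = complex.coords[complex.membership == LIGAND]
    prot_mask = complex.membership == PROTEIN
    d = np.linalg.norm(
        complex.coords[prot_mask, None, :] - lig_xyz[None, :, :], axis=-1
    )
    keep_prot = d.min(axis=1) <= radius
    keep = np.ones(len(complex), dtype=bool)
    keep[prot_mask] = keep_prot
    return replace(
        complex,
        elements=complex.elements[keep],
        coords=complex.coords[keep],
        membership=complex.membership[keep],
    )


# ---------------------------------------------------------------------------
# writers (used by the synthetic `simulate` path and round-trip tests)


def write_ligand_sdf(path: str | Path, elements, coords, name: str = "ligand") -> None:
    mol = Chem.RWMol()
    for z in elements:
        mol.AddAtom(Chem.Atom(int(z)))
    conf = Chem.Conformer(len(elements))
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*[float(v) for v in xyz]))
    out = mol.GetMol()
    out.SetProp("_Name", name)
    out.AddConformer(conf)
    with open(path, "w") as fh:
        fh.write(Chem.MolToMolBlock(out, kekulize=False))
        fh.write("$$$$\n")


def write_protein_pdb(path: str | Path, elements, coords) -> None:
    n = len(elements)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float64)
    symbols = [z_to_symbol(z) for z in elements]
    arr.element = np.array([s.upper() for s in symbols])
    arr.atom_name = np.array([f"{s.upper()}{i + 1}"[:4] for i, s in enumerate(symbols)])
    arr.res_name = np.array(["GLY"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_complex(
    complex: AtomicComplex, protein_path: str | Path | None, ligand_path: str | Path
) -> None:
    lig = complex.membership == LIGAND
    write_ligand_sdf(ligand_path, complex.elements[lig], complex.coords[lig], name=complex.id)
    if protein_path is not None:
        prot = complex.membership == PROTEIN
        write_protein_pdb(protein_path, complex.elements[prot], complex.coords[prot])


# ---------------------------------------------------------------------------
# manifests


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "protein_path", "ligand_path", "label"])
        for rec in manifest.records:
            writer.writerow(
                [
                    rec.id,
                    "" if rec.protein_path is None else str(rec.protein_path),
                    str(rec.ligand_path),
                    "" if rec.label is None else repr(float(rec.label)),
                ]
            )


def read_manifest(
    path: str | Path,
    strict: bool = True,
    vocabulary=DEFAULT_VOCABULARY,
) -> list[AtomicComplex]:
    """Load every record of a CSV manifest as a labeled AtomicComplex.

    Paths are resolved relative to the manifest location. In strict mode any
    failing record aborts the load; in lenient mode it is logged and skipped.
    """
    path = Path(path)
    base = path.parent
    delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    try:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter=delimiter))
    except OSError as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    required = {"id", "protein_path", "ligand_path", "label"}
    if rows and not required.issubset(rows[0].keys()):
        raise ManifestError(
            f"manifest {path} missing columns {sorted(required - set(rows[0]))}"
        )
    ids = [r["id"] for r in rows]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ManifestError(f"duplicate ids in manifest {path}: {sorted(dupes)}")

    complexes: list[AtomicComplex] = []
    for row in rows:
        rec_id = row["id"]
        protein = row["protein_path"].strip()
        ligand = row["ligand_path"].strip()
        label = float(row["label"]) if row["label"].strip() else None
        try:
            cx = read_complex(
                base / protein if protein else None,
                base / ligand,
                label=label,
                id=rec_id,
                vocabulary=vocabulary,
            )
        except (OSError, FormatError, InputError, VocabularyError) as exc:
            if strict:
                raise ManifestError(f"record {rec_id!r} failed to load: {exc}") from exc
            logger.warning("skipping manifest record %r: %s", rec_id, exc)
            continue
        complexes.append(cx)
    return complexes
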