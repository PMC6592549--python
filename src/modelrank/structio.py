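"""Structure and pose I/O, Ballesteros-Weinstein residue resolution, atom subsets.

Receptor models are stored as :class:`biotite.structure.AtomArray` wrapped in
:class:`ReceptorModel`; ligand poses are lightweight coordinate/charge records
parsed from SDF or MOL2 via RDKit.  Ballesteros-Weinstein (BW) labels such as
"3.32" are resolved through a user-supplied tabular map -- never computed from
sequence alignment.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureFormatError(ValueError):
    """Raised when a structure or pose file cannot be parsed."""


class BWResolutionError(ValueError):
    """Raised when a BW label does not resolve cleanly against a structure."""


# ---------------------------------------------------------------------------
# Receptor models


@dataclass
class ReceptorModel:
    """One receptor structure: an identified, ordered set of atoms."""

    model_id: str
    atoms: struc.AtomArray

    @property
    def topology_key(self) -> str:
        """Hash of the (chain, residue number, residue name, atom name) sequence.

        Equal keys certify that two models can be compared atom-by-atom.
        """
        h = hashlib.sha1()
        for ch, num, rname, aname in zip(
            self.atoms.chain_id, self.atoms.res_id, self.atoms.res_name, self.atoms.atom_name
        ):
            h.update(f"{ch}|{num}|{rname}|{aname}\n".encode())
        return h.hexdigest()

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def heavy_mask(self) -> np.ndarray:
        return ~np.isin(self.atoms.element, ("H", "D"))

    def copy(self) -> "ReceptorModel":
        return ReceptorModel(self.model_id, self.atoms.copy())


def _infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (protein heavy atoms + H)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "HD" and len(atom_name.strip()) <= 4:
        # 1H, HB2, HD11 ... all hydrogens / deuteriums in amino acids
        return "H" if stripped[0] == "H" else "D"
    return stripped[0].upper()


def _locate_bad_atom_line(text: str) -> int | None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                return lineno
    return None


def read_pdb(path: str | Path) -> ReceptorModel | list[ReceptorModel]:
    """Read a PDB file into one :class:`ReceptorModel` (or a list for multi-MODEL files).

    Atoms keep file order.  Elements come from columns 77-78 when present,
    otherwise they are inferred from the atom name.  Alternate locations are
    reduced to the highest-occupancy conformer (ties resolve to the first,
    i.e. altloc 'A').
    """
    path = Path(path)
    text = path.read_text()
    try:
        pdb = PDBFile.read(io.StringIO(text))
        n_models = pdb.get_model_count()
        if n_models == 0:
            raise StructureFormatError(f"{path}: no atoms found")
        models = []
        for i in range(1, n_models + 1):
            arr = pdb.get_structure(model=i, altloc="occupancy")
            models.append(arr)
    except StructureFormatError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        lineno = _locate_bad_atom_line(text)
        loc = f" (line {lineno})" if lineno else ""
        raise StructureFormatError(f"{path}: unparsable ATOM record{loc}: {exc}") from exc
    out = []
    for i, arr in enumerate(models):
        if arr.array_length() == 0:
            raise StructureFormatError(f"{path}: model {i + 1} contains no atoms")
        missing = (arr.element == "") | (arr.element == " ")
        if missing.any():
            arr.element = np.array(
                [e if e.strip() else _infer_element(n) for e, n in zip(arr.element, arr.atom_name)],
                dtype="U2",
            )
        if not np.isfinite(arr.coord).all():
            raise StructureFormatError(f"{path}: non-finite coordinates")
        mid = path.stem if n_models == 1 else f"{path.stem}#{i + 1}"
        out.append(ReceptorModel(mid, arr))
    return out[0] if n_models == 1 else out


def write_pdb(model: ReceptorModel | Sequence[ReceptorModel], path: str | Path) -> None:
    """Write one model (or several, as MODEL blocks) to a PDB file."""
    pdb = PDBFile()
    if isinstance(model, ReceptorModel):
        pdb.set_structure(model.atoms)
    else:
        stack = struc.stack([m.atoms for m in model])
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Atom subsets


def atom_subset(model: ReceptorModel, subset: str) -> np.ndarray:
    """Boolean mask over the model's atoms for ``all_heavy | backbone | sidechain``.

    Backbone = heavy atoms named N, CA, C, O (plus OXT); sidechain = the
    remaining heavy atoms.  The two partition ``all_heavy`` exactly;
    hydrogens are excluded from every subset.
    """
    if model.n_atoms == 0:
        raise ValueError("empty model")
    heavy = model.heavy_mask()
    bb = heavy & np.isin(model.atoms.atom_name, tuple(BACKBONE_NAMES))
    if subset == "all_heavy":
        return heavy
    if subset == "backbone":
        return bb
    if subset == "sidechain":
        return heavy & ~bb
    raise ValueError(f"unknown subset {subset!r}")


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein maps and binding-site specs


@dataclass
class BWMap:
    """Map between Ballesteros-Weinstein labels and author residue numbering."""

    entries: pd.DataFrame  # columns: bw_label, chain, resnum, resname

    def __post_init__(self) -> None:
        required = {"bw_label", "chain", "resnum", "resname"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"BW map missing columns: {sorted(missing)}")
        if self.entries["bw_label"].duplicated().any():
            dup = self.entries["bw_label"][self.entries["bw_label"].duplicated()].iloc[0]
            raise ValueError(f"duplicate BW label {dup!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BWMap":
        df = pd.read_csv(path, sep="\t", dtype={"bw_label": str, "chain": str, "resname": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def entry(self, bw_label: str) -> pd.Series:
        hit = self.entries[self.entries["bw_label"] == bw_label]
        if hit.empty:
            raise KeyError(f"BW label {bw_label!r} not in map")
        return hit.iloc[0]

    def label_for(self, chain: str, resnum: int) -> str | None:
        hit = self.entries[
            (self.entries["chain"] == chain) & (self.entries["resnum"] == resnum)
        ]
        return None if hit.empty else str(hit.iloc[0]["bw_label"])


def resolve_bw(model: ReceptorModel, bwmap: BWMap, bw_label: str) -> struc.AtomArray:
    """Return all atoms of the residue a BW label maps to, validating identity.

    Raises :class:`KeyError` for an unmapped label and
    :class:`BWResolutionError` when the structure's residue name disagrees
    with the map's expectation (a guard against mis-specified maps).
    """
    ent = bwmap.entry(bw_label)
    mask = (model.atoms.chain_id == ent["chain"]) & (model.atoms.res_id == int(ent["resnum"]))
    atoms = model.atoms[mask]
    if atoms.array_length() == 0:
        raise BWResolutionError(
            f"{bw_label} -> {ent['chain']}:{ent['resnum']} not present in model {model.model_id}"
        )
    names = set(np.unique(atoms.res_name))
    if names != {ent["resname"]}:
        raise BWResolutionError(
            f"{bw_label}: expected {ent['resname']} at {ent['chain']}:{ent['resnum']}, "
            f"structure has {sorted(names)}"
        )
    return atoms


@dataclass
class BindingSiteSpec:
    """Binding-site residue roles in BW labels.

    Defaults follow the canonical aminergic-GPCR orthosteric site: the
    carboxylate anchor at 3.32 plus 3.33, 4.56, 5.46, 6.48, 6.51 and 7.39.
    """

    anchor: str = "3.32"
    auxiliary_acidic: str | None = "5.46"
    site_residues: tuple[str, ...] = ("3.32", "3.33", "4.56", "5.46", "6.48", "6.51", "7.39")

    def __post_init__(self) -> None:
        if self.anchor not in self.site_residues:
            raise ValueError(f"anchor {self.anchor!r} must be among site_residues")

    def validate(self, model: ReceptorModel, bwmap: BWMap) -> None:
        """Check the anchor resolves to an aspartate or glutamate in this model."""
        atoms = resolve_bw(model, bwmap, self.anchor)
        rname = atoms.res_name[0]
        if rname not in ("ASP", "GLU"):
            raise BWResolutionError(f"anchor {self.anchor} is {rname}, expected ASP or GLU")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BindingSiteSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "anchor" in data:
            kwargs["anchor"] = str(data["anchor"])
        if "auxiliary_acidic" in data:
            aux = data["auxiliary_acidic"]
            kwargs["auxiliary_acidic"] = None if aux is None else str(aux)
        if "site_residues" in data:
            kwargs["site_residues"] = tuple(str(x) for x in data["site_residues"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "anchor": self.anchor,
                    "auxiliary_acidic": self.auxiliary_acidic,
                    "site_residues": list(self.site_residues),
                },
                sort_keys=False,
            )
        )


# ---------------------------------------------------------------------------
# Ligand poses


@dataclass
class LigandPose:
    """One docked ligand conformation: coordinates, elements, formal charges."""

    pose_id: str
    ligand_id: str
    coords: np.ndarray  # (n, 3) Angstrom
    elements: tuple[str, ...]
    formal_charges: np.ndarray  # (n,) int
    inferred_cation_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.formal_charges = np.asarray(self.formal_charges, dtype=int)
        if self.coords.shape[0] == 0:
            raise ValueError(f"pose {self.pose_id}: no atoms")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(f"pose {self.pose_id}: coordinate/element length mismatch")
        if self.formal_charges.shape[0] != self.coords.shape[0]:
            raise ValueError(f"pose {self.pose_id}: charge/coordinate length mismatch")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class PoseSet:
    """All poses docked into one (model, run) pair."""

    model_id: str
    run_id: str
    poses: list[LigandPose] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.pose_id for p in self.poses]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate pose_ids in PoseSet {self.model_id}/{self.run_id}")

    def __len__(self) -> int:
        return len(self.poses)


def _protonatable_amine_indices(mol: Chem.Mol) -> tuple[int, ...]:
    """Heuristic: nitrogens bonded only to C/H and not part of an amide or aromatic ring."""
    hits = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N" or atom.GetIsAromatic():
            continue
        neighbors = atom.GetNeighbors()
        if any(n.GetSymbol() not in ("C", "H") for n in neighbors):
            continue
        amide = any(
            any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(n).GetSymbol() == "O"
                for b in n.GetBonds()
            )
            for n in neighbors
            if n.GetSymbol() == "C"
        )
        if not amide:
            hits.append(atom.GetIdx())
    return tuple(hits)


def _pose_from_mol(mol: Chem.Mol, pose_id: str, ligand_id: str) -> LigandPose:
    if mol.GetNumConformers() == 0:
        raise StructureFormatError(f"pose {pose_id}: record has no coordinates")
    conf = mol.GetConformer()
    if not conf.Is3D():
        raise StructureFormatError(f"pose {pose_id}: record has no 3D coordinates")
    coords = conf.GetPositions()
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    charges = np.array([a.GetFormalCharge() for a in mol.GetAtoms()], dtype=int)
    inferred = ()
    if not (charges >= 1).any():
        inferred = _protonatable_amine_indices(mol)
    return LigandPose(pose_id, ligand_id, coords, elements, charges, inferred)


def read_poses(path: str | Path, model_id: str, run_id: str) -> PoseSet:
    """Read a multi-record SDF or MOL2 file into a :class:`PoseSet`.

    Formal charges are preserved exactly as stated in SDF ``M  CHG`` blocks.
    MOL2 stores partial rather than formal charges, so formal charges for
    MOL2 records are inferred by RDKit valence perception during
    sanitization.
    """
    path = Path(path)
    ext = path.suffix.lower()
    poses: list[LigandPose] = []
    if ext == ".sdf":
        try:
            supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        except OSError as exc:
            raise StructureFormatError(f"{path}: {exc}") from exc
        for i, mol in enumerate(supplier):
            if mol is None:
                raise StructureFormatError(f"{path}: unreadable SDF record {i}")
            ligand_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"ligand{i}"
            poses.append(_pose_from_mol(mol, f"{ligand_id}:{i}", ligand_id))
    elif ext == ".mol2":
        text = path.read_text()
        blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
        for i, block in enumerate(blocks):
            mol = Chem.MolFromMol2Block(block, sanitize=True, removeHs=False)
            if mol is None:
                mol = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
            if mol is None:
                raise StructureFormatError(f"{path}: unreadable MOL2 record {i}")
            ligand_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"ligand{i}"
            poses.append(_pose_from_mol(mol, f"{ligand_id}:{i}", ligand_id))
    else:
        raise StructureFormatError(f"{path}: unknown pose-file extension {ext!r}")
    if not poses:
        raise StructureFormatError(f"{path}: no pose records found")
    return PoseSet(model_id, run_id, poses)


# ---------------------------------------------------------------------------
# Manifests


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest TSV associating models, runs and files.

    Columns: model_id, run_id, model_path, pose_path.  Paths are interpreted
    relative to the manifest's own directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"model_id", "run_id", "model_path", "pose_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    df["model_path"] = [str(base / p) for p in df["model_path"]]
    df["pose_path"] = [str(base / p) for p in df["pose_path"]]
    return df
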