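"""Synthetic study fixtures: receptor ensembles, docked pose sets, activity tables.

The generator emulates the outputs of a ligand-guided model-selection study
without any modeling, docking or database engine:

* a hand-built seven-helix "bundle" template whose binding site carries the
  canonical aminergic residues (ASP anchor at 3.32, GLU at 5.46, aromatics),
  copied ``n_models`` times with independent isotropic Gaussian noise --
  tighter on the backbone (sigma 0.4 A) than on side chains (sigma 1.6 A);
* models planted as "low-score" additionally have one E5.46 carboxyl oxygen
  displaced by a fixed shift (default 4.7 A) pointing away from the pocket;
* per model and replicate run, 9 ligands x 10 poses of a small cationic
  fragment placed so that exactly k of 90 poses sit 4.0-5.5 A from the
  anchor carboxyl carbon (interacting, with >= 0.5 A margin to the 6 A
  cutoff) and the rest 7-12 A away;
* ChEMBL-like activity tables where profiled records fail exactly one
  assigned curation stage, so kept counts are known by construction.

Every artifact comes with a machine-readable ground-truth record, and all
randomness is driven by a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import biotite.structure as struc
from rdkit import Chem
from rdkit.Chem import SDWriter

from .structio import BWMap, BindingSiteSpec, LigandPose, PoseSet, ReceptorModel, write_pdb

# ---------------------------------------------------------------------------
# Template geometry
#
# Local residue frames: backbone roughly along x, side chain extending +y.
# Rough but self-consistent bond geometry; atom names follow PDB convention.

_BB = [("N", "N", (-1.2, 0.2, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
       ("C", "C", (1.3, 0.5, 0.0)), ("O", "O", (1.5, 1.7, 0.0))]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": _BB,
    "ALA": _BB + [("CB", "C", (0.0, 1.5, 0.0))],
    "ASP": _BB + [("CB", "C", (0.0, 1.5, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
                  ("OD1", "O", (-1.1, 3.6, 0.0)), ("OD2", "O", (1.1, 3.6, 0.0))],
    "GLU": _BB + [("CB", "C", (0.0, 1.5, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
                  ("CD", "C", (0.0, 4.4, 0.0)), ("OE1", "O", (-1.1, 5.1, 0.0)),
                  ("OE2", "O", (1.1, 5.1, 0.0))],
    "LEU": _BB + [("CB", "C", (0.0, 1.5, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
                  ("CD1", "C", (-1.2, 3.7, 0.0)), ("CD2", "C", (1.2, 3.7, 0.0))],
    "PHE": _BB + [("CB", "C", (0.0, 1.5, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
                  ("CD1", "C", (-1.2, 3.6, 0.0)), ("CD2", "C", (1.2, 3.6, 0.0)),
                  ("CE1", "C", (-1.2, 5.0, 0.0)), ("CE2", "C", (1.2, 5.0, 0.0)),
                  ("CZ", "C", (0.0, 5.7, 0.0))],
    "TYR": _BB + [("CB", "C", (0.0, 1.5, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
                  ("CD1", "C", (-1.2, 3.6, 0.0)), ("CD2", "C", (1.2, 3.6, 0.0)),
                  ("CE1", "C", (-1.2, 5.0, 0.0)), ("CE2", "C", (1.2, 5.0, 0.0)),
                  ("CZ", "C", (0.0, 5.7, 0.0)), ("OH", "O", (0.0, 7.1, 0.0))],
    "TRP": _BB + [("CB", "C", (0.0, 1.5, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
                  ("CD1", "C", (-1.1, 3.7, 0.0)), ("NE1", "N", (-0.7, 5.0, 0.0)),
                  ("CD2", "C", (1.2, 3.6, 0.0)), ("CE2", "C", (0.7, 5.0, 0.0)),
                  ("CE3", "C", (2.6, 3.6, 0.0)), ("CZ2", "C", (1.4, 6.2, 0.0)),
                  ("CZ3", "C", (3.3, 4.8, 0.0)), ("CH2", "C", (2.8, 6.1, 0.0))],
}

#: (helix, [(bw position, residue name), ...]); the binding-site residues sit
#: mid-helix around z = 0, pointing into the central pocket
_HELIX_LAYOUT: list[tuple[int, list[tuple[int, str]]]] = [
    (1, [(49, "ALA"), (50, "ALA"), (51, "ALA")]),
    (2, [(49, "ALA"), (50, "ALA"), (51, "ALA")]),
    (3, [(31, "ALA"), (32, "ASP"), (33, "TYR")]),
    (4, [(55, "ALA"), (56, "TYR"), (57, "ALA")]),
    (5, [(45, "ALA"), (46, "GLU"), (47, "ALA")]),
    (6, [(48, "TRP"), (49, "ALA"), (50, "ALA"), (51, "TYR")]),
    (7, [(39, "PHE"), (40, "ALA"), (41, "ALA"), (42, "LEU")]),
]

_BUNDLE_RADIUS = 10.0
_RISE = 3.0


def build_template() -> tuple[ReceptorModel, BWMap]:
    """The hand-built helix-bundle receptor template and its BW map."""
    atoms: list[struc.Atom] = []
    bw_rows = []
    for helix, residues in _HELIX_LAYOUT:
        angle = 2.0 * np.pi * (helix - 1) / 7.0
        radial = np.array([np.cos(angle), np.sin(angle), 0.0])
        tangential = np.array([-np.sin(angle), np.cos(angle), 0.0])
        up = np.array([0.0, 0.0, 1.0])
        # local x -> tangential, y -> inward (toward bundle axis), z -> up
        frame = np.column_stack([tangential, -radial, up])
        z0 = -_RISE * (len(residues) - 1) / 2.0
        for i, (pos, res_name) in enumerate(residues):
            res_id = helix * 100 + pos
            ca = radial * _BUNDLE_RADIUS + up * (z0 + i * _RISE)
            for name, element, local in RESIDUE_TEMPLATES[res_name]:
                coord = ca + frame @ np.asarray(local)
                atoms.append(
                    struc.Atom(coord, chain_id="A", res_id=res_id, res_name=res_name,
                               atom_name=name, element=element, hetero=False)
                )
            bw_rows.append(
                {"bw_label": f"{helix}.{pos}", "chain": "A", "resnum": res_id,
                 "resname": res_name}
            )
    arr = struc.array(atoms)
    return ReceptorModel("template", arr), BWMap(pd.DataFrame(bw_rows))


# ---------------------------------------------------------------------------
# Configuration and truth


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark (defaults mirror the full study)."""

    n_models: int = 1000
    n_ligands: int = 9
    poses_per_ligand: int = 10
    n_runs: int = 2
    sigma_backbone: float = 0.4  # A, per coordinate
    sigma_sidechain: float = 1.6  # A, per coordinate
    shift_bw_label: str = "5.46"
    shift_atom: str = "OE1"
    shift_delta: float = 4.7  # A
    low_score_threshold: float = 0.1  # models at or below get the planted shift
    planted_scores: list[float] | None = None  # per-model target fractions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_backbone < 0 or self.sigma_sidechain < 0:
            raise ValueError("sigmas must be >= 0")
        if self.shift_delta < 0:
            raise ValueError("shift delta must be >= 0")
        if self.planted_scores is not None:
            if len(self.planted_scores) != self.n_models:
                raise ValueError("planted_scores length must equal n_models")
            if any(not 0 <= s <= 1 for s in self.planted_scores):
                raise ValueError("planted scores must lie in [0, 1]")

    @property
    def poses_per_model(self) -> int:
        return self.n_ligands * self.poses_per_ligand


def planted_fraction_table(config: FixtureConfig, rng: np.random.Generator) -> list[Fraction]:
    """Per-model planted interacting fractions k/n_poses.

    The default distribution mimics the qualitative shape of a real scoring
    campaign: a unique top model at 75/90 (~0.833), one quarter of models at
    or below 0.1 including a handful at exactly 0, the rest spread in
    between.  These are fixture conventions, not asserted reproductions.
    """
    n_poses = config.poses_per_model
    if config.planted_scores is not None:
        return [Fraction(round(s * n_poses), n_poses) for s in config.planted_scores]
    n = config.n_models
    n_zero = max(1, round(0.007 * n)) if n >= 8 else min(1, n - 1)
    n_low = max(n_zero, round(0.25 * n))
    ks = [0] * n_zero
    low_hi = max(1, int(config.low_score_threshold * n_poses))  # k <= 9 for 90 poses
    ks += list(rng.integers(1, low_hi + 1, size=n_low - n_zero))
    n_high = n - n_low
    if n_high > 0:
        top_k = round(0.8333 * n_poses)  # 75/90
        ks += [top_k] + list(rng.integers(low_hi + 1, top_k, size=n_high - 1))
    ks = np.array(ks[:n])
    rng.shuffle(ks)
    return [Fraction(int(k), n_poses) for k in ks]


@dataclass
class FixtureEnsemble:
    models: list[ReceptorModel]
    bwmap: BWMap
    site_spec: BindingSiteSpec
    config: FixtureConfig
    truth: dict


def _model_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"m{str(i).zfill(width)}" for i in range(n)]


def make_receptor_ensemble(config: FixtureConfig) -> FixtureEnsemble:
    """Noisy copies of the template; low-score models get the planted shift.

    Deterministic under ``config.seed``: the same seed yields byte-identical
    structures.  Raises when the shift label is absent from the BW map.
    """
    template, bwmap = build_template()
    if config.shift_delta > 0:
        ent = bwmap.entry(config.shift_bw_label)  # KeyError for unmapped label
        shift_mask = (
            (template.atoms.res_id == int(ent["resnum"]))
            & (template.atoms.chain_id == ent["chain"])
            & (template.atoms.atom_name == config.shift_atom)
        )
        if not shift_mask.any():
            raise ValueError(
                f"shift atom {config.shift_atom} not found at BW {config.shift_bw_label}"
            )
        # push the atom outward, away from the pocket center
        angle = 2.0 * np.pi * (int(config.shift_bw_label.split(".")[0]) - 1) / 7.0
        shift_vec = np.array([np.cos(angle), np.sin(angle), 0.0]) * config.shift_delta
    else:
        shift_mask = np.zeros(template.n_atoms, dtype=bool)
        shift_vec = np.zeros(3)

    rng = np.random.default_rng(config.seed)
    fractions = planted_fraction_table(config, rng)
    ids = _model_ids(config.n_models)
    bb_names = ("N", "CA", "C", "O", "OXT")
    bb = np.isin(template.atoms.atom_name, bb_names)
    sigma = np.where(bb, config.sigma_backbone, config.sigma_sidechain)[:, None]

    models = []
    truth_models = {}
    for mid, frac in zip(ids, fractions):
        low = float(frac) <= config.low_score_threshold + 1e-12
        atoms = template.atoms.copy()
        coord = atoms.coord.copy()
        if low:
            coord[shift_mask] += shift_vec
        coord += rng.normal(size=coord.shape) * sigma
        atoms.coord = coord
        models.append(ReceptorModel(mid, atoms))
        truth_models[mid] = {
            "planted_numerator": frac.numerator,
            "planted_denominator": frac.denominator,
            "planted_fraction": float(frac),
            "low_score": bool(low),
            "shifted": bool(low and config.shift_delta > 0),
        }
    truth = {
        "seed": config.seed,
        "n_models": config.n_models,
        "poses_per_model": config.poses_per_model,
        "n_runs": config.n_runs,
        "models": truth_models,
        "shift": {
            "bw_label": config.shift_bw_label,
            "atom": config.shift_atom,
            "delta": config.shift_delta,
            "residue_number": int(bwmap.entry(config.shift_bw_label)["resnum"]),
        },
        "top_model_id": max(
            truth_models, key=lambda m: (truth_models[m]["planted_fraction"], m)
        ),
        "zero_score_models": sorted(
            m for m, t in truth_models.items() if t["planted_numerator"] == 0
        ),
    }
    return FixtureEnsemble(models, bwmap, BindingSiteSpec(), config, truth)


# ---------------------------------------------------------------------------
# Pose sets

_LIGAND_ELEMENTS = ("N", "C", "C")  # protonated amine fragment, heavy atoms only
_LIGAND_CHARGES = np.array([1, 0, 0])
_INTERACT_RANGE = (4.0, 5.5)  # >= 0.5 A margin below the 6 A cutoff
_NONINTERACT_RANGE = (7.0, 12.0)


def _anchor_carbon_coord(model: ReceptorModel, bwmap: BWMap, site: BindingSiteSpec) -> np.ndarray:
    ent = bwmap.entry(site.anchor)
    name = "CG" if ent["resname"] == "ASP" else "CD"
    mask = (
        (model.atoms.res_id == int(ent["resnum"]))
        & (model.atoms.chain_id == ent["chain"])
        & (model.atoms.atom_name == name)
    )
    return model.atoms.coord[mask][0]


def _random_units(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_pose_set(
    config: FixtureConfig,
    model: ReceptorModel,
    bwmap: BWMap,
    site: BindingSiteSpec,
    k_interacting: int,
    run_id: str,
    rng: np.random.Generator,
) -> PoseSet:
    """Poses of a small cationic fragment around one model's anchor carboxyl carbon.

    Exactly ``k_interacting`` of the poses place their charged nitrogen
    4.0-5.5 A from the carboxyl carbon; the remainder 7-12 A.
    """
    n = config.poses_per_model
    if not 0 <= k_interacting <= n:
        raise ValueError("k_interacting outside [0, n_poses]")
    cg = _anchor_carbon_coord(model, bwmap, site)
    interacting = np.zeros(n, dtype=bool)
    interacting[rng.permutation(n)[:k_interacting]] = True
    d = np.where(
        interacting,
        rng.uniform(*_INTERACT_RANGE, size=n),
        rng.uniform(*_NONINTERACT_RANGE, size=n),
    )
    u = _random_units(rng, n)
    n_pos = cg + d[:, None] * u
    v1 = _random_units(rng, n)
    v2 = _random_units(rng, n)
    c1 = n_pos + 1.5 * v1
    c2 = c1 + 1.5 * v2
    poses = []
    for i in range(n):
        ligand = f"L{i // config.poses_per_ligand + 1}"
        coords = np.stack([n_pos[i], c1[i], c2[i]])
        poses.append(
            LigandPose(f"{ligand}:{i}", ligand, coords, _LIGAND_ELEMENTS,
                       _LIGAND_CHARGES.copy())
        )
    return PoseSet(model.model_id, run_id, poses)


def iter_pose_sets(
    config: FixtureConfig, ensemble: FixtureEnsemble
) -> Iterator[PoseSet]:
    """Yield one PoseSet per (model, run), deterministically under the seed."""
    for run_idx in range(config.n_runs):
        run_id = f"run{run_idx + 1}"
        for model_idx, model in enumerate(ensemble.models):
            t = ensemble.truth["models"][model.model_id]
            k = round(t["planted_numerator"] * config.poses_per_model
                      / t["planted_denominator"])
            rng = np.random.default_rng([config.seed, 1000003, run_idx, model_idx])
            yield generate_pose_set(
                config, model, ensemble.bwmap, ensemble.site_spec, k, run_id, rng
            )


def _ligand_template_mol() -> Chem.RWMol:
    mol = Chem.RWMol()
    idx_n = mol.AddAtom(Chem.Atom("N"))
    mol.GetAtomWithIdx(idx_n).SetFormalCharge(1)
    mol.GetAtomWithIdx(idx_n).SetNoImplicit(True)
    idx_c1 = mol.AddAtom(Chem.Atom("C"))
    mol.GetAtomWithIdx(idx_c1).SetNoImplicit(True)
    idx_c2 = mol.AddAtom(Chem.Atom("C"))
    mol.GetAtomWithIdx(idx_c2).SetNoImplicit(True)
    mol.AddBond(idx_n, idx_c1, Chem.BondType.SINGLE)
    mol.AddBond(idx_c1, idx_c2, Chem.BondType.SINGLE)
    conf = Chem.Conformer(3)
    conf.Set3D(True)
    mol.AddConformer(conf)
    return mol


def write_pose_set_sdf(pose_set: PoseSet, path: str | Path) -> None:
    """Write a PoseSet of the fixture ligand fragment to an SDF file."""
    mol = _ligand_template_mol()
    conf = mol.GetConformer()
    writer = SDWriter(str(path))
    writer.SetKekulize(False)
    for pose in pose_set.poses:
        for i in range(pose.n_atoms):
            conf.SetAtomPosition(i, pose.coords[i].tolist())
        mol.SetProp("_Name", pose.ligand_id)
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# Activity tables

_ACTIVITY_STAGE_FAIL = {
    "mw": {"mw": lambda rng: float(rng.uniform(501, 900))},
    "confidence": {"confidence": lambda rng: int(rng.integers(1, 9))},
    "std_type": {"std_type": lambda rng: "other"},
    "std_relation": {"std_relation": lambda rng: ">"},
    "std_value": {"std_value": lambda rng: float(rng.uniform(11, 1000))},
    "std_unit": {"std_unit": lambda rng: "uM"},
    "stereo": {"stereo_clear": lambda rng: False},
}

_BASE_SMILES = ("CCN", "CCCN", "CC(C)N", "CCOC", "CCCC", "CNC", "CCO", "CCC")


def make_activity_table(
    n: int, fail_profile: dict[str, int] | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """ChEMBL-like activity table where profiled records fail exactly one stage.

    ``fail_profile`` maps stage name -> number of records that fail (only)
    that stage; all other records pass every filter.  Returns the table and
    a truth dict with the expected kept count and per-stage drops.
    """
    fail_profile = dict(fail_profile or {})
    unknown = set(fail_profile) - set(_ACTIVITY_STAGE_FAIL)
    if unknown:
        raise ValueError(f"unknown stages in fail profile: {sorted(unknown)}")
    total_fail = sum(fail_profile.values())
    if total_fail > n:
        raise ValueError(f"fail profile ({total_fail}) exceeds table size ({n})")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append(
            {
                "ligand_id": f"SYN{i:05d}",
                "smiles": _BASE_SMILES[i % len(_BASE_SMILES)],
                "mw": float(rng.uniform(200, 500)),
                "confidence": 9,
                "std_type": str(rng.choice(["Ki", "Kd", "IC50", "EC50"])),
                "std_relation": "=",
                "std_value": float(rng.uniform(0.1, 10)),
                "std_unit": "nM",
                "year": int(rng.integers(1990, 2016)),
                "stereo_clear": True,
            }
        )
    df = pd.DataFrame(rows)
    fail_idx = rng.permutation(n)[:total_fail]
    cursor = 0
    for stage, count in fail_profile.items():
        for idx in fail_idx[cursor:cursor + count]:
            for col, fn in _ACTIVITY_STAGE_FAIL[stage].items():
                df.at[idx, col] = fn(rng)
        cursor += count
    truth = {
        "n": n,
        "expected_kept": n - total_fail,
        "expected_drops": fail_profile,
    }
    return df, truth


def make_duplicate_records(n_groups: int, seed: int = 0) -> pd.DataFrame:
    """Groups of records sharing a ligand_id with varied type/year/value.

    For exercising the deduplication preference order (binding over
    functional, newer over older, then lower value); survivors are checked
    against a brute-force comparator, not asserted here.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        for j in range(int(rng.integers(2, 6))):
            rows.append(
                {
                    "ligand_id": f"DUP{g:05d}",
                    "smiles": "CCN",
                    "mw": 200.0,
                    "confidence": 9,
                    "std_type": str(rng.choice(["Ki", "Kd", "IC50", "EC50"])),
                    "std_relation": "=",
                    "std_value": float(rng.uniform(0.1, 10)),
                    "std_unit": "nM",
                    "year": int(rng.integers(1990, 2016)),
                    "stereo_clear": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk fixture bundles


def write_fixture_dir(outdir: str | Path, config: FixtureConfig) -> dict:
    """Write a complete fixture bundle: PDBs, SDFs, manifest, BW map, site, truth.

    Layout: ``models/<model_id>.pdb``, ``poses/<model_id>__<run_id>.sdf``,
    ``manifest.tsv`` (relative paths), ``bwmap.tsv``, ``site.yaml``,
    ``truth.json``.  Byte-identical for identical (config, seed).
    """
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    (outdir / "poses").mkdir(parents=True, exist_ok=True)
    ensemble = make_receptor_ensemble(config)
    for model in ensemble.models:
        write_pdb(model, outdir / "models" / f"{model.model_id}.pdb")
    manifest_rows = []
    for pose_set in iter_pose_sets(config, ensemble):
        fname = f"{pose_set.model_id}__{pose_set.run_id}.sdf"
        write_pose_set_sdf(pose_set, outdir / "poses" / fname)
        manifest_rows.append(
            {
                "model_id": pose_set.model_id,
                "run_id": pose_set.run_id,
                "model_path": f"models/{pose_set.model_id}.pdb",
                "pose_path": f"poses/{fname}",
            }
        )
    manifest = pd.DataFrame(manifest_rows).sort_values(["model_id", "run_id"])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    ensemble.bwmap.to_tsv(outdir / "bwmap.tsv")
    ensemble.site_spec.to_yaml(outdir / "site.yaml")
    (outdir / "truth.json").write_text(json.dumps(ensemble.truth, indent=1, sort_keys=True))
    return {
        "outdir": str(outdir),
        "manifest": str(outdir / "manifest.tsv"),
        "bwmap": str(outdir / "bwmap.tsv"),
        "site": str(outdir / "site.yaml"),
        "truth": str(outdir / "truth.json"),
        "n_models": config.n_models,
    }
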