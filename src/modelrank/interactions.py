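"""Ionic-contact detection between docked ligand poses and the anchor carboxylate.

The scoring criterion of the whole pipeline lives here: a pose forms the
hallmark aminergic charged interaction when the distance from the carboxyl
carbon of the anchor residue (CG of ASP, CD of GLU) to any formally cationic
ligand atom is at most 6.0 A (boundary inclusive).  An optional extended
geometric fingerprint (hydrogen bond / pi-cation / hydrophobic) is provided
for pose inspection; it does not enter the headline score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .structio import BWMap, BindingSiteSpec, LigandPose, ReceptorModel, resolve_bw

CARBOXYL_CARBON = {"ASP": "CG", "GLU": "CD"}

AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class IonicContactCriterion:
    """Distance rule for the anchor charged contact."""

    max_distance: float = 6.0  # Angstrom
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")

    def satisfied(self, distance: float) -> bool:
        if self.inclusive:
            return distance <= self.max_distance
        return distance < self.max_distance


@dataclass
class FingerprintParams:
    """Geometric thresholds of the extended fingerprint (not from the scoring rule)."""

    hbond_max: float = 3.5
    pi_cation_max: float = 6.0
    hydrophobic_max: float = 4.5


@dataclass
class InteractionRecord:
    pose_id: str
    ionic_to_anchor: bool
    min_distance: float  # inf when the pose has no cationic atom
    contributing_ligand_atom: int | None
    extended: list[tuple[str, str, float]] | None = None

    def as_dict(self) -> dict:
        return {
            "pose_id": self.pose_id,
            "ionic_to_anchor": self.ionic_to_anchor,
            "min_distance": None if np.isinf(self.min_distance) else self.min_distance,
            "contributing_ligand_atom": self.contributing_ligand_atom,
            "extended": self.extended,
        }


def cationic_atoms(pose: LigandPose, allow_inferred: bool = False) -> list[int]:
    """Indices of formally cationic atoms (charge >= +1), regardless of element.

    File dialects place the positive charge of guanidinium or quaternary
    groups on different atoms, so the rule is charge-based, not element-based.
    With ``allow_inferred=True``, poses without any formal charge fall back
    to protonatable-amine nitrogens flagged at read time.
    """
    idx = np.nonzero(pose.formal_charges >= 1)[0].tolist()
    if not idx and allow_inferred:
        return list(pose.inferred_cation_indices)
    return idx


def anchor_carboxyl_carbon(anchor_residue: struc.AtomArray) -> np.ndarray:
    """Coordinates of the carboxyl carbon (CG for ASP, CD for GLU)."""
    res_name = anchor_residue.res_name[0]
    if res_name not in CARBOXYL_CARBON:
        raise ValueError(f"anchor residue is {res_name}, expected ASP or GLU")
    name = CARBOXYL_CARBON[res_name]
    mask = anchor_residue.atom_name == name
    if not mask.any():
        raise ValueError(f"anchor {res_name} lacks carboxyl carbon atom {name}")
    return anchor_residue.coord[mask][0]


def ionic_contact(
    pose: LigandPose,
    anchor_residue: struc.AtomArray,
    criterion: IonicContactCriterion | None = None,
    allow_inferred: bool = False,
) -> InteractionRecord:
    """Test a pose for the charged contact with the anchor carboxylate.

    ``min_distance`` is the minimum Euclidean distance from the carboxyl
    carbon to any cationic ligand atom; a pose with no cationic atom scores
    false with ``min_distance = inf``.
    """
    criterion = criterion or IonicContactCriterion()
    carbon = anchor_carboxyl_carbon(anchor_residue)
    cations = cationic_atoms(pose, allow_inferred=allow_inferred)
    if not cations:
        return InteractionRecord(pose.pose_id, False, float("inf"), None)
    dists = np.linalg.norm(pose.coords[cations] - carbon, axis=1)
    k = int(np.argmin(dists))
    dmin = float(dists[k])
    return InteractionRecord(pose.pose_id, criterion.satisfied(dmin), dmin, cations[k])


def extended_fingerprint(
    pose: LigandPose,
    model: ReceptorModel,
    bwmap: BWMap,
    site_spec: BindingSiteSpec | None = None,
    params: FingerprintParams | None = None,
    allow_inferred: bool = False,
) -> list[tuple[str, str, float]]:
    """Geometric interaction fingerprint against the binding-site residues.

    Emits (type, bw_label, distance) tuples: ``hbond`` for ligand N/O within
    ``hbond_max`` of a residue N/O; ``pi_cation`` for a cationic ligand atom
    within ``pi_cation_max`` of an aromatic ring centroid; ``hydrophobic``
    for a ligand carbon within ``hydrophobic_max`` of a side-chain carbon.
    Only the closest pair per (type, residue) is reported.
    """
    site_spec = site_spec or BindingSiteSpec()
    params = params or FingerprintParams()
    out: list[tuple[str, str, float]] = []
    lig_polar = np.isin(pose.elements, ("N", "O"))
    lig_carbon = np.array([e == "C" for e in pose.elements])
    cations = cationic_atoms(pose, allow_inferred=allow_inferred)
    for label in site_spec.site_residues:
        res = resolve_bw(model, bwmap, label)
        heavy = ~np.isin(res.element, ("H", "D"))
        res_polar = heavy & np.isin(res.element, ("N", "O"))
        if lig_polar.any() and res_polar.any():
            d = np.linalg.norm(
                pose.coords[lig_polar][:, None, :] - res.coord[res_polar][None, :, :], axis=2
            )
            dmin = float(d.min())
            if dmin <= params.hbond_max:
                out.append(("hbond", label, dmin))
        rname = res.res_name[0]
        if cations and rname in AROMATIC_RING_ATOMS:
            ring_mask = np.isin(res.atom_name, AROMATIC_RING_ATOMS[rname]) & heavy
            if ring_mask.sum() >= 3:
                centroid = res.coord[ring_mask].mean(axis=0)
                d = np.linalg.norm(pose.coords[cations] - centroid, axis=1)
                dmin = float(d.min())
                if dmin <= params.pi_cation_max:
                    out.append(("pi_cation", label, dmin))
        sc_carbon = heavy & (res.element == "C") & ~np.isin(res.atom_name, ("C", "CA"))
        if lig_carbon.any() and sc_carbon.any():
            d = np.linalg.norm(
                pose.coords[lig_carbon][:, None, :] - res.coord[sc_carbon][None, :, :], axis=2
            )
            dmin = float(d.min())
            if dmin <= params.hydrophobic_max:
                out.append(("hydrophobic", label, dmin))
    return out
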