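"""Rigid-body superposition (Kabsch), subset-decomposed RMSD, ensemble means.

One superposition (fit on backbone heavy atoms by default) is reused for all
atom subsets, so the decomposition identity

    n_all * rmsd_all^2 = n_bb * rmsd_bb^2 + n_sc * rmsd_sc^2

holds exactly for every model pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structio import ReceptorModel, atom_subset

SUBSETS = ("all_heavy", "backbone", "sidechain")


@dataclass
class Superposition:
    """Proper rotation + translation mapping mobile coordinates onto a reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd_after: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDSummary:
    all_heavy: float
    backbone: float
    sidechain: float
    n_all: int
    n_backbone: int
    n_sidechain: int

    def as_dict(self) -> dict:
        return {
            "all_heavy": self.all_heavy,
            "backbone": self.backbone,
            "sidechain": self.sidechain,
            "n_all": self.n_all,
            "n_backbone": self.n_backbone,
            "n_sidechain": self.n_sidechain,
        }


def kabsch_fit(mobile_coords: np.ndarray, reference_coords: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation + translation (Kabsch, via SVD).

    Requires >= 3 non-collinear point pairs.  The returned transform maps
    ``mobile_coords`` onto ``reference_coords`` with minimal RMSD.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("coordinate arrays must be paired (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    cm = mob.mean(axis=0)
    cr = ref.mean(axis=0)
    x = mob - cm
    y = ref - cr
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = x @ rot.T + cr
    rmsd_after = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return Superposition(rot, cr - rot @ cm, rmsd_after)


def _coord_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape[0] == 0:
        return math.nan
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _summary_from_coords(
    coords_a: np.ndarray, coords_b: np.ndarray, model: ReceptorModel
) -> RMSDSummary:
    masks = {s: atom_subset(model, s) for s in SUBSETS}
    vals = {s: _coord_rmsd(coords_a[m], coords_b[m]) for s, m in masks.items()}
    return RMSDSummary(
        all_heavy=vals["all_heavy"],
        backbone=vals["backbone"],
        sidechain=vals["sidechain"],
        n_all=int(masks["all_heavy"].sum()),
        n_backbone=int(masks["backbone"].sum()),
        n_sidechain=int(masks["sidechain"].sum()),
    )


def rmsd(
    model_a: ReceptorModel,
    model_b: ReceptorModel,
    superpose: bool = True,
    fit_subset: str = "backbone",
) -> RMSDSummary:
    """RMSD between two topology-identical models, decomposed by atom subset.

    With ``superpose=True`` the models are first fitted on ``fit_subset``
    (backbone heavy atoms by default); that single fit is then used to
    evaluate the RMSD of every subset.
    """
    if model_a.topology_key != model_b.topology_key:
        raise ValueError(
            f"topology mismatch between {model_a.model_id} and {model_b.model_id}"
        )
    ca = model_a.atoms.coord
    cb = model_b.atoms.coord
    if superpose:
        fit_mask = atom_subset(model_a, fit_subset)
        sup = kabsch_fit(ca[fit_mask], cb[fit_mask])
        ca = sup.apply(ca)
    return _summary_from_coords(ca, cb, model_a)


def superpose_ensemble(
    models: list[ReceptorModel], reference: str = "mean", fit_subset: str = "backbone"
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all models onto a common reference; return fitted coords + reference.

    ``reference="mean"`` uses one round of iterative fitting: fit every model
    to the first, average, refit every model once onto that average, and
    average again.  ``reference="first"`` fits onto the first model directly.
    Returns ``(stack, ref_coords)`` with ``stack`` of shape (n_models, n_atoms, 3).
    """
    if not models:
        raise ValueError("empty ensemble")
    keys = {m.topology_key for m in models}
    if len(keys) > 1:
        raise ValueError("mixed topologies in ensemble")
    fit_mask = atom_subset(models[0], fit_subset)
    stack = np.stack([m.atoms.coord for m in models]).astype(np.float64)
    # canonical processing order so the result is invariant to input order
    order = np.argsort([m.model_id for m in models], kind="stable")

    def _fit_all(target: np.ndarray) -> np.ndarray:
        out = np.empty_like(stack)
        for i in range(stack.shape[0]):
            sup = kabsch_fit(stack[i][fit_mask], target[fit_mask])
            out[i] = sup.apply(stack[i])
        return out

    if reference == "first":
        fitted = _fit_all(stack[0])
        return fitted, stack[0]
    if reference != "mean":
        raise ValueError(f"unknown reference {reference!r}")
    fitted = _fit_all(stack[order[0]])
    mean1 = fitted[order].mean(axis=0)
    fitted = _fit_all(mean1)
    mean2 = fitted[order].mean(axis=0)
    return fitted, mean2


def ensemble_rmsd(
    models: list[ReceptorModel],
    reference: str = "mean",
    include_pairwise: bool = False,
) -> dict:
    """Per-model RMSDs to a common reference plus ensemble averages.

    Each model is superposed (backbone heavy-atom fit) onto the reference
    (``mean`` by default, see :func:`superpose_ensemble`); averages are
    arithmetic means over models.  ``include_pairwise=True`` additionally
    reports the all-pairs average RMSD (each pair individually fitted).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    fitted, ref_coords = superpose_ensemble(models, reference=reference)
    per_model = [
        _summary_from_coords(fitted[i], ref_coords, models[0]) for i in range(len(models))
    ]
    averages = {
        s: float(np.nanmean([getattr(pm, s) for pm in per_model])) for s in SUBSETS
    }
    result = {
        "per_model": {m.model_id: pm for m, pm in zip(models, per_model)},
        "averages": averages,
        "reference": reference,
    }
    if include_pairwise:
        n = len(models)
        pair_vals: dict[str, list[float]] = {s: [] for s in SUBSETS}
        for i in range(n):
            for j in range(i + 1, n):
                s_ij = rmsd(models[i], models[j], superpose=True)
                for s in SUBSETS:
                    pair_vals[s].append(getattr(s_ij, s))
        result["pairwise_averages"] = {
            s: float(np.nanmean(v)) for s, v in pair_vals.items()
        }
    return result


def mean_structure(models: list[ReceptorModel], model_id: str = "mean") -> ReceptorModel:
    """Coordinate-wise unweighted mean structure of already-superposed models."""
    if not models:
        raise ValueError("empty ensemble")
    keys = {m.topology_key for m in models}
    if len(keys) > 1:
        raise ValueError("mixed topologies in ensemble")
    atoms = models[0].atoms.copy()
    atoms.coord = np.mean([m.atoms.coord for m in models], axis=0)
    return ReceptorModel(model_id, atoms)
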