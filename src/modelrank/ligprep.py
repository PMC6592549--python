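"""Bioactivity-table curation, deduplication, fingerprint diversity, Cheng-Prusoff.

The curation pipeline applies ChEMBL-style filters in a fixed stage order
(molecular weight <= 500 Da, confidence score = 9, binding/functional
activity types, relation "=", value <= 10, unit nM, unambiguous
stereochemistry), records the first failing stage of every dropped record,
then keeps one activity per ligand preferring binding (Ki/Kd) over
functional (IC50/EC50) data and more recent over older measurements.
Tanimoto similarity and MaxMin diversity picking operate on abstract
feature sets so they are testable without chemistry; helpers compute Morgan
feature fingerprints (diameter 4, i.e. radius 2) from SMILES via RDKit.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BINDING_TYPES = ("Ki", "Kd")
FUNCTIONAL_TYPES = ("IC50", "EC50")

#: stage order of the curation pipeline; every dropped record is charged to
#: the first stage it fails
STAGES = ("mw", "confidence", "std_type", "std_relation", "std_value", "std_unit", "stereo")

REQUIRED_COLUMNS = (
    "ligand_id",
    "mw",
    "confidence",
    "std_type",
    "std_relation",
    "std_value",
    "std_unit",
    "year",
    "stereo_clear",
)


@dataclass
class CurationThresholds:
    mw_max: float = 500.0
    confidence: int = 9
    allowed_types: tuple[str, ...] = BINDING_TYPES + FUNCTIONAL_TYPES
    relation: str = "="
    value_max: float = 10.0  # in value units; with unit filter "nM" this is <= 10 nM
    unit: str = "nM"


@dataclass
class CurationReport:
    stage_counts: dict[str, int]  # records remaining after each stage
    dropped: pd.DataFrame  # ligand_id, stage
    n_in: int
    n_kept: int

    def as_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_kept": self.n_kept,
            "remaining_after_stage": self.stage_counts,
            "dropped_per_stage": self.dropped["stage"].value_counts().to_dict(),
        }


def _stage_pass(df: pd.DataFrame, stage: str, t: CurationThresholds) -> pd.Series:
    if stage == "mw":
        return df["mw"].notna() & (df["mw"] <= t.mw_max)
    if stage == "confidence":
        return df["confidence"] == t.confidence
    if stage == "std_type":
        return df["std_type"].isin(t.allowed_types)
    if stage == "std_relation":
        return df["std_relation"] == t.relation
    if stage == "std_value":
        return df["std_value"].notna() & (df["std_value"] <= t.value_max)
    if stage == "std_unit":
        return df["std_unit"] == t.unit
    if stage == "stereo":
        return df["stereo_clear"].astype(bool)
    raise ValueError(f"unknown stage {stage!r}")


def curate(
    records: pd.DataFrame, thresholds: CurationThresholds | None = None
) -> tuple[pd.DataFrame, CurationReport]:
    """Apply the filter stages in order; return kept records and a stage report."""
    thresholds = thresholds or CurationThresholds()
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    kept = records.copy()
    stage_counts: dict[str, int] = {}
    dropped_rows = []
    for stage in STAGES:
        ok = _stage_pass(kept, stage, thresholds)
        for lid in kept.loc[~ok, "ligand_id"]:
            dropped_rows.append({"ligand_id": lid, "stage": stage})
        kept = kept[ok]
        stage_counts[stage] = len(kept)
    report = CurationReport(
        stage_counts=stage_counts,
        dropped=pd.DataFrame(dropped_rows, columns=["ligand_id", "stage"]),
        n_in=len(records),
        n_kept=len(kept),
    )
    return kept.reset_index(drop=True), report


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one activity record per ligand_id.

    Preference order: binding data (Ki/Kd) beats functional (IC50/EC50);
    within a class the most recent year wins; remaining ties resolve to the
    lowest activity value, then to stable input order.
    """
    df = records.copy()
    df["_class"] = np.where(df["std_type"].isin(BINDING_TYPES), 0, 1)
    df["_order"] = np.arange(len(df))
    df = df.sort_values(
        ["_class", "year", "std_value", "_order"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    out = df.drop_duplicates("ligand_id", keep="first")
    out = out.sort_values("_order").drop(columns=["_class", "_order"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fingerprints, similarity, diversity


def tanimoto(fp_a: Iterable[int], fp_b: Iterable[int]) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| on feature/bit sets.

    Two empty fingerprints are defined as identical (similarity 1.0); the
    event is logged since it usually signals a degenerate featurization.
    """
    a, b = set(fp_a), set(fp_b)
    union = a | b
    if not union:
        logger.warning("tanimoto of two empty fingerprints defined as 1.0")
        return 1.0
    return len(a & b) / len(union)


def maxmin_pick(fingerprints: Sequence[Iterable[int]], n: int, seed: int = 0) -> list[int]:
    """MaxMin diversity selection over fingerprint sets.

    The first pick is drawn by the seeded RNG; each subsequent pick maximizes
    its minimum Tanimoto distance (1 - similarity) to the already-picked set,
    with ties broken by lowest index.  Deterministic for a fixed seed.
    """
    fps = [frozenset(fp) for fp in fingerprints]
    size = len(fps)
    if n > size:
        raise ValueError(f"cannot pick {n} items from {size}")
    if n == 0:
        return []
    rng = random.Random(seed)
    picked = [rng.randrange(size)]
    min_dist = np.array([1.0 - tanimoto(fps[picked[0]], fp) for fp in fps])
    min_dist[picked[0]] = -1.0  # exclude
    while len(picked) < n:
        nxt = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        picked.append(nxt)
        d = np.array([1.0 - tanimoto(fps[nxt], fp) for fp in fps])
        min_dist = np.minimum(min_dist, d)
        min_dist[nxt] = -1.0
    return picked


def morgan_feature_fingerprints(smiles: Sequence[str], radius: int = 2) -> list[frozenset]:
    """Morgan feature-invariant fingerprints (diameter = 2*radius) as on-bit sets."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius,
        fpSize=2048,
        atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
    )
    out = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smi!r}")
        out.append(frozenset(gen.GetFingerprint(mol).GetOnBits()))
    return out


def stereo_is_clear(smiles: str) -> bool:
    """True when the molecule has no unassigned stereocenters."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    centers = Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    return not any(code == "?" for _, code in centers)


# ---------------------------------------------------------------------------
# Cheng-Prusoff


def cheng_prusoff(ic50: float, radioligand_conc: float, radioligand_kd: float) -> float:
    """Ki = IC50 / (1 + [L]/Kd) for a competition binding experiment.

    All three inputs must be positive and in consistent concentration units;
    the result carries the unit of ``ic50``.
    """
    if ic50 <= 0 or radioligand_conc <= 0 or radioligand_kd <= 0:
        raise ValueError("Cheng-Prusoff inputs must be positive")
    return ic50 / (1.0 + radioligand_conc / radioligand_kd)


def to_pki(ki_molar: float) -> float:
    """pKi = -log10(Ki) with Ki in molar."""
    if ki_molar <= 0:
        raise ValueError("Ki must be positive")
    return -math.log10(ki_molar)
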