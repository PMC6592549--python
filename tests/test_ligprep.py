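import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modelrank import fixtures as fx
from modelrank import ligprep
from modelrank.ligprep import (
    CurationThresholds,
    STAGES,
    cheng_prusoff,
    curate,
    deduplicate,
    maxmin_pick,
    morgan_feature_fingerprints,
    stereo_is_clear,
    tanimoto,
    to_pki,
)


def base_record(**over):
    rec = {
        "ligand_id": "L1",
        "smiles": "CCN",
        "mw": 300.0,
        "confidence": 9,
        "std_type": "Ki",
        "std_relation": "=",
        "std_value": 5.0,
        "std_unit": "nM",
        "year": 2010,
        "stereo_clear": True,
    }
    rec.update(over)
    return rec


class TestCurate:
    def test_constructed_drops_charged_to_first_failing_stage(self):
        rows = (
            [base_record(ligand_id=f"hw{i}", mw=600.0) for i in range(4)]
            + [base_record(ligand_id=f"rel{i}", std_relation=">") for i in range(2)]
            + [base_record(ligand_id=f"ok{i}") for i in range(4)]
        )
        kept, report = curate(pd.DataFrame(rows))
        assert len(kept) == 4
        drops = report.dropped["stage"].value_counts().to_dict()
        assert drops == {"mw": 4, "std_relation": 2}

    def test_activity_value_boundary_inclusive(self):
        kept, _ = curate(pd.DataFrame([base_record(std_value=10.0)]))
        assert len(kept) == 1
        kept, _ = curate(pd.DataFrame([base_record(std_value=10.01)]))
        assert len(kept) == 0

    def test_unclear_stereo_dropped_at_stereo_stage(self):
        kept, report = curate(pd.DataFrame([base_record(stereo_clear=False)]))
        assert len(kept) == 0
        assert report.dropped.iloc[0]["stage"] == "stereo"

    def test_missing_column_named_in_error(self):
        df = pd.DataFrame([base_record()]).drop(columns=["confidence"])
        with pytest.raises(ValueError, match="confidence"):
            curate(df)

    def test_missing_mw_dropped_at_mw_stage(self):
        kept, report = curate(pd.DataFrame([base_record(mw=np.nan)]))
        assert len(kept) == 0
        assert report.dropped.iloc[0]["stage"] == "mw"

    def test_stage_counts_monotonically_non_increasing(self):
        df, _ = fx.make_activity_table(200, {"mw": 20, "std_unit": 10, "stereo": 5}, seed=3)
        _, report = curate(df)
        counts = list(report.stage_counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_idempotent(self):
        df, _ = fx.make_activity_table(150, {"mw": 10, "confidence": 10}, seed=4)
        kept1, _ = curate(df)
        kept2, _ = curate(kept1)
        pd.testing.assert_frame_equal(kept1, kept2)

    def test_stage_order_never_changes_kept_set(self):
        df, _ = fx.make_activity_table(80, {"mw": 8, "std_relation": 8, "stereo": 8}, seed=5)
        kept_ref, _ = curate(df)
        t = CurationThresholds()
        for order in itertools.islice(itertools.permutations(STAGES), 0, 24, 6):
            ok = pd.Series(True, index=df.index)
            for stage in order:
                ok &= ligprep._stage_pass(df, stage, t)
            assert set(df.loc[ok, "ligand_id"]) == set(kept_ref["ligand_id"])


def brute_force_survivor(group: pd.DataFrame) -> int:
    """Independent preference comparator: binding > functional, newer, lower value."""
    best = None
    for pos, (_, row) in enumerate(group.iterrows()):
        key = (
            0 if row["std_type"] in ("Ki", "Kd") else 1,
            -row["year"],
            row["std_value"],
            pos,
        )
        if best is None or key < best[0]:
            best = (key, row.name)
    return best[1]


class TestDeduplicate:
    def test_binding_beats_newer_functional(self):
        df = pd.DataFrame([
            base_record(std_type="Ki", year=2005, std_value=3.0),
            base_record(std_type="IC50", year=2010, std_value=1.0),
        ])
        out = deduplicate(df)
        assert len(out) == 1 and out.iloc[0]["std_type"] == "Ki"

    def test_newer_binding_beats_older_binding(self):
        df = pd.DataFrame([
            base_record(std_type="Ki", year=2005),
            base_record(std_type="Ki", year=2012),
        ])
        assert deduplicate(df).iloc[0]["year"] == 2012

    def test_single_record_passthrough(self):
        df = pd.DataFrame([base_record()])
        pd.testing.assert_frame_equal(deduplicate(df), df)

    def test_survivors_match_brute_force_on_random_groups(self):
        df = fx.make_duplicate_records(200, seed=6)
        out = deduplicate(df)
        assert out["ligand_id"].is_unique
        for lid, group in df.groupby("ligand_id", sort=False):
            expect = group.loc[brute_force_survivor(group)]
            got = out[out["ligand_id"] == lid].iloc[0]
            assert (got["std_type"], got["year"], got["std_value"]) == (
                expect["std_type"], expect["year"], expect["std_value"])


class TestTanimoto:
    def test_identical_sets(self):
        assert tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_sets(self):
        assert tanimoto({1, 2}, {3, 4}) == 0.0

    def test_half_overlap(self):
        assert tanimoto({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_defined_as_identical(self):
        assert tanimoto(set(), set()) == 1.0

    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_symmetric(self, a, b):
        s = tanimoto(a, b)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(b, a)

    def test_agrees_with_rdkit_on_bitvectors(self):
        from rdkit import DataStructs

        fps = morgan_feature_fingerprints(["CCN", "CCCN", "c1ccccc1O", "CC(=O)NC"])
        from rdkit.Chem import rdFingerprintGenerator
        from rdkit import Chem

        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=2048,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen())
        bvs = [gen.GetFingerprint(Chem.MolFromSmiles(s))
               for s in ["CCN", "CCCN", "c1ccccc1O", "CC(=O)NC"]]
        for i in range(4):
            for j in range(4):
                assert tanimoto(fps[i], fps[j]) == pytest.approx(
                    DataStructs.TanimotoSimilarity(bvs[i], bvs[j]))


class TestMaxMinPick:
    TOY = [frozenset({0, 1}), frozenset({0, 1, 2}), frozenset({1, 2}),
           frozenset({0, 2}), frozenset({100, 101, 102})]

    def test_picking_everything_returns_all_indices(self):
        assert sorted(maxmin_pick(self.TOY, len(self.TOY), seed=1)) == list(range(5))

    def test_second_pick_matches_brute_force_argmax(self):
        picked = maxmin_pick(self.TOY, 2, seed=0)
        first = picked[0]
        dists = [1.0 - tanimoto(self.TOY[first], fp) for fp in self.TOY]
        dists[first] = -1.0
        assert picked[1] == int(np.argmax(dists))

    def test_deterministic_under_seed(self):
        fps = [frozenset(np.random.default_rng(i).integers(0, 100, 10).tolist())
               for i in range(50)]
        assert maxmin_pick(fps, 10, seed=42) == maxmin_pick(fps, 10, seed=42)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            maxmin_pick(self.TOY, 6, seed=0)

    def test_picked_set_more_diverse_than_random_subsets(self):
        rng = np.random.default_rng(9)
        fps = [frozenset(rng.integers(0, 60, 12).tolist()) for _ in range(60)]

        def min_pairwise(idx):
            return min(1.0 - tanimoto(fps[i], fps[j])
                       for i, j in itertools.combinations(idx, 2))

        picked = maxmin_pick(fps, 8, seed=0)
        rand_avg = np.mean([
            min_pairwise(rng.choice(60, 8, replace=False)) for _ in range(100)
        ])
        assert min_pairwise(picked) >= rand_avg


class TestChengPrusoff:
    def test_ligand_at_kd_halves_ic50(self):
        assert cheng_prusoff(10.0, 2.0, 2.0) == pytest.approx(5.0)

    def test_vanishing_ligand_concentration_limit(self):
        assert cheng_prusoff(10.0, 1e-9, 2.0) == pytest.approx(10.0, rel=1e-6)

    def test_pki_of_nanomolar_ki(self):
        assert to_pki(1e-9) == pytest.approx(9.0)

    @pytest.mark.parametrize("args", [(-1, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_non_positive_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            cheng_prusoff(*args)

    def test_pki_requires_positive_ki(self):
        with pytest.raises(ValueError):
            to_pki(0.0)


def test_stereo_clarity_detection():
    assert stereo_is_clear("C[C@H](N)C(=O)O") is True  # assigned center
    assert stereo_is_clear("CC(N)C(=O)O") is False  # unassigned center
    assert stereo_is_clear("CCN") is True  # no center
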