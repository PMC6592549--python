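import numpy as np
import pytest
import biotite.structure as struc

from modelrank import fixtures as fx
from modelrank.structio import ReceptorModel, write_pdb


def make_residue_model(res_name: str, res_id: int = 114, model_id: str = "fix") -> ReceptorModel:
    """Single-residue model built from the fixture residue templates."""
    atoms = [
        struc.Atom(np.asarray(xyz), chain_id="A", res_id=res_id, res_name=res_name,
                   atom_name=name, element=element, hetero=False)
        for name, element, xyz in fx.RESIDUE_TEMPLATES[res_name]
    ]
    return ReceptorModel(model_id, struc.array(atoms))


@pytest.fixture
def asp_model():
    return make_residue_model("ASP")


@pytest.fixture
def asp_pdb(tmp_path, asp_model):
    path = tmp_path / "asp.pdb"
    write_pdb(asp_model, path)
    return path


@pytest.fixture
def template_and_map():
    return fx.build_template()


@pytest.fixture
def small_ensemble():
    cfg = fx.FixtureConfig(n_models=30, seed=7)
    return fx.make_receptor_ensemble(cfg), cfg


def rigid_motion(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Apply an arbitrary but reproducible rotation + translation."""
    rng = np.random.default_rng(seed)
    a, b, c = rng.uniform(0, 2 * np.pi, 3)
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rx = np.array([[1, 0, 0], [0, np.cos(c), -np.sin(c)], [0, np.sin(c), np.cos(c)]])
    rot = rz @ ry @ rx
    return coords @ rot.T + rng.uniform(-20, 20, 3)
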