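import numpy as np
import pytest

from abypap.structure_io import FvStructure, NumberedResidue
from abypap.synthetic import GeometrySpec, make_fv_fixture


@pytest.fixture(scope="session")
def fv_minus46():
    """Exact-geometry fixture with packing angle -46 deg."""
    return make_fv_fixture(GeometrySpec(target_angle_deg=-46.0))


@pytest.fixture
def fv_factory(tmp_path):
    """Build fixtures, optionally written to PDB files in tmp_path."""

    def build(theta=-46.0, name="synth", write=False, **kwargs):
        spec = GeometrySpec(target_angle_deg=theta, seed=kwargs.pop("seed", 0),
                            jitter_sd=kwargs.pop("jitter_sd", 0.0))
        out = tmp_path / f"{name}.pdb" if write else None
        fv = make_fv_fixture(spec, fixture_id=name, out_path=out, **kwargs)
        return (fv, out) if write else fv

    return build


def transform_fv(fv: FvStructure, rotation: np.ndarray, translation: np.ndarray,
                 reflect: bool = False) -> FvStructure:
    """Apply a rigid (or reflected) transform to every C-alpha."""
    matrix = rotation.copy()
    if reflect:
        matrix = matrix @ np.diag([1.0, 1.0, -1.0])

    def moved(chain):
        out = {}
        for key, res in chain.items():
            ca = None if res.ca is None else matrix @ res.ca + translation
            out[key] = NumberedResidue(key=key, aa=res.aa, ca=ca)
        return out

    return FvStructure(id=fv.id, light=moved(fv.light), heavy=moved(fv.heavy),
                       resolution=fv.resolution, method=fv.method)
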