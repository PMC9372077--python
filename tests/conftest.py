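import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mhsfx.stream_io import IndexedCrystal, Reflection, UnitCell

TETRAGONAL_CELL = UnitCell(79.30, 79.30, 37.73, 90.0, 90.0, 90.0)

# canonical reciprocal basis of the tetragonal cell, rows a*, b*, c* in nm^-1
BASIS0 = np.diag([10.0 / 79.30, 10.0 / 79.30, 10.0 / 37.73])


@pytest.fixture
def cell():
    return TETRAGONAL_CELL


@pytest.fixture
def basis0():
    return BASIS0.copy()


def make_crystal(rotation=None, scale=1.0, reflections=(),
                 cell=TETRAGONAL_CELL, basis=None):
    """Crystal with the canonical basis, optionally rotated and scaled."""
    b = BASIS0.copy() if basis is None else np.asarray(basis, dtype=float)
    if rotation is not None:
        b = b @ np.asarray(rotation).T
    b = b * scale
    return IndexedCrystal(astar=b[0], bstar=b[1], cstar=b[2], cell=cell,
                          reflections=list(reflections))


def rotation_about(axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(
        np.deg2rad(angle_deg) * axis / np.linalg.norm(axis)).as_matrix()


def simple_reflections():
    return [Reflection(1, 0, 0, 100.0, 5.0), Reflection(0, 0, 2, 50.0, 4.0)]


FIXTURE_STREAM = """\
CrystFEL stream format 2.3
Generated by CrystFEL 0.6.3
----- Begin chunk -----
Image filename: run0066.h5
Event: //12-3
Image serial number: 0
--- Begin crystal
Cell parameters 7.9300000 7.9300000 3.7730000 nm, 90.00000 90.00000 90.00000 deg
astar = +0.126103405 +0.000000000 +0.000000000 nm^-1
bstar = +0.000000000 +0.126103405 +0.000000000 nm^-1
cstar = +0.000000000 +0.000000000 +0.265041081 nm^-1
diffraction_resolution_limit = 5.0000 nm^-1 or 2.0000 A
Reflections measured after indexing
   h    k    l          I   sigma(I)       peak background  fs/px  ss/px panel
   1    0    0 1.20000000e+02 6.00000000e+00 0.00 0.00  100.00  200.00 p0
   0    0    2 4.00000000e+01 5.00000000e+00 0.00 0.00  110.00  210.00 p0
End of reflections
--- End crystal
----- End chunk -----
----- Begin chunk -----
Image filename: run0066.h5
Event: //12-4
Image serial number: 1
--- Begin crystal
Cell parameters 7.9300000 7.9300000 3.7730000 nm, 90.00000 90.00000 90.00000 deg
astar = +0.126103405 +0.000000000 +0.000000000 nm^-1
bstar = +0.000000000 +0.126103405 +0.000000000 nm^-1
cstar = +0.000000000 +0.000000000 +0.265041081 nm^-1
--- End crystal
----- End chunk -----
"""


@pytest.fixture
def fixture_stream(tmp_path):
    path = tmp_path / "fixture.stream"
    path.write_text(FIXTURE_STREAM)
    return path
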