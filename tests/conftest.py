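import numpy as np
import pytest

from tprm.synthetic import PhantomSpec, generate_phantom


def chi_bruteforce(vol: np.ndarray) -> int:
    """Independent Euler-characteristic oracle by explicit cell enumeration.

    Builds the closed cubical complex voxel by voxel with Python sets of
    vertex/edge/face/cube keys and returns n0 - n1 + n2 - n3.
    """
    verts, edges, faces, cubes = set(), set(), set(), set()
    for x, y, z in zip(*np.nonzero(np.asarray(vol, dtype=bool))):
        cubes.add((x, y, z))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    verts.add((x + dx, y + dy, z + dz))
        for d1 in (0, 1):
            for d2 in (0, 1):
                edges.add(("x", x, y + d1, z + d2))
                edges.add(("y", x + d1, y, z + d2))
                edges.add(("z", x + d1, y + d2, z))
        for d in (0, 1):
            faces.add(("x", x + d, y, z))
            faces.add(("y", x, y + d, z))
            faces.add(("z", x, y, z + d))
    return len(verts) - len(edges) + len(faces) - len(cubes)


@pytest.fixture(scope="session")
def three_class_phantom():
    """Zero-noise phantom with 60/30/10 Norm/fSAD/Emph planted fractions."""
    spec = PhantomSpec(class_fractions={"Norm": 0.6, "fSAD": 0.3, "Emph": 0.1},
                       seed=11)
    ct, truth = generate_phantom(spec)
    return spec, ct, truth
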