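import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from secdimer.interface import Structure

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_pentapeptide(chain: str = "A", offset=(0.0, 0.0, 0.0)) -> Structure:
    """Synthetic 5-residue poly-Ala chain with roughly peptide-like geometry.

    Bond lengths are plausible but not refined; the fixture only needs a
    nontrivial cluster of touching atoms for surface-area tests.
    """
    ox, oy, oz = offset
    atoms = []
    for i in range(5):
        x0 = 3.8 * i + ox
        y0 = 0.6 * (i % 2) + oy
        res = i + 1
        atoms += [
            (chain, res, "ALA", "N",  "N", x0 + 0.00, y0 + 0.0, oz + 0.0),
            (chain, res, "ALA", "CA", "C", x0 + 1.46, y0 + 0.2, oz + 0.3),
            (chain, res, "ALA", "C",  "C", x0 + 2.00, y0 + 1.4, oz + 0.0),
            (chain, res, "ALA", "O",  "O", x0 + 1.80, y0 + 2.4, oz + 0.6),
            (chain, res, "ALA", "CB", "C", x0 + 1.90, y0 - 0.8, oz + 1.2),
        ]
    return Structure.from_atoms(atoms)


def build_dimer(separation: float) -> Structure:
    """Two identical synthetic chains stacked along z at a given gap (A)."""
    a = build_pentapeptide("A")
    b = build_pentapeptide("B", offset=(0.0, 0.0, separation))
    return Structure(
        chain=np.concatenate([a.chain, b.chain]),
        res_id=np.concatenate([a.res_id, b.res_id]),
        icode=np.concatenate([a.icode, b.icode]),
        res_name=np.concatenate([a.res_name, b.res_name]),
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        element=np.concatenate([a.element, b.element]),
        coords=np.vstack([a.coords, b.coords]),
        radius=np.concatenate([a.radius, b.radius]),
    )


@pytest.fixture
def pentapeptide() -> Structure:
    return build_pentapeptide()


@pytest.fixture
def contact_dimer() -> Structure:
    return build_dimer(separation=4.5)


@pytest.fixture
def distant_dimer() -> Structure:
    return build_dimer(separation=100.0)
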