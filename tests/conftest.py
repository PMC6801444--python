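import numpy as np
import pytest

import chiralmem as cm
from chiralmem.contacts import ContactPolicy


@pytest.fixture(scope="session")
def peptide_L():
    return cm.build_peptide(chirality="L")


@pytest.fixture(scope="session")
def peptide_D():
    return cm.build_peptide(chirality="D")


@pytest.fixture(scope="session")
def barrier_surface():
    return cm.ReferenceSurface.barrier()


@pytest.fixture(scope="session")
def downhill_surface():
    return cm.ReferenceSurface.downhill()


@pytest.fixture
def policy():
    return ContactPolicy()


@pytest.fixture(scope="session")
def barrier_windows(barrier_surface):
    """Moderate-size umbrella sample set on the barrier preset, shared."""
    return cm.sample_umbrella(barrier_surface, n_samples=8000, seed=42)


def random_cluster_frame(rng, n_lipids, chirality="L"):
    """Random small peptide+lipid cluster for brute-force oracle checks."""
    pep = cm.build_peptide(chirality=chirality,
                           phase_deg=float(rng.uniform(0, 360)))
    lipids = []
    for lid in range(n_lipids):
        center = rng.uniform(-1.5, 1.5, size=3)
        heads = center + rng.uniform(-0.15, 0.15, size=(2, 3))
        c2 = center + rng.uniform(-0.15, 0.15, size=3)
        tails = center + rng.uniform(-0.25, 0.25, size=(2, 3))
        lipids.append(cm.LipidPseudo(lipid_id=lid, head_atoms=heads,
                                     c2_atom=c2, tail_atoms=tails,
                                     leaflet="upper"))
    return cm.Frame(peptide=pep, lipids=lipids, box=None)
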