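import numpy as np
import pandas as pd
import pytest

from tnckit.io import StructureEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_structure(
    n_res: int = 30,
    atoms_per_res: int = 1,
    n_models: int = 1,
    seed: int = 0,
    resnames=None,
    spread: float = 6.0,
) -> StructureEnsemble:
    """Random compact toy structure for contact/frustration oracles.

    atoms_per_res=1 gives a Calpha-only chain; >1 adds pseudo side-chain
    heavy atoms near each Calpha.
    """
    r = np.random.default_rng(seed)
    if resnames is None:
        from tnckit.frustration import AMINO_ACIDS

        resnames = r.choice(AMINO_ACIDS, n_res)
    names = ["CA", "CB", "CG", "CD"][:atoms_per_res]
    rows = []
    for i in range(n_res):
        for nm in names:
            rows.append({"resnum": i + 1, "resname": resnames[i], "atom": nm, "chain": "A"})
    atoms = pd.DataFrame(rows)
    ca = r.normal(0.0, spread, (n_models, n_res, 3))
    coords = np.repeat(ca, atoms_per_res, axis=1)
    coords = coords + r.normal(0.0, 0.8, coords.shape)  # side-chain scatter
    return StructureEnsemble(atoms=atoms, coords=coords)
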