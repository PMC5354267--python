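import numpy as np
import pytest

from hdclms import SyntheticConfig, simulate_study
from hdclms.structure import Residue, StructureModel


def make_chain(sequence: str, rise: float = 3.3, unresolved=()) -> StructureModel:
    """Extended straight chain along z, one residue per ``rise`` Å."""
    residues = []
    for i, aa in enumerate(sequence, start=1):
        ca = None if i in unresolved else np.array([0.0, 0.0, (i - 1) * rise])
        residues.append(Residue(i, aa, ca))
    return StructureModel(residues)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study shared by read-only tests."""
    cfg = SyntheticConfig(n_residues=80, fold_spec="mixed", n_runs=4,
                          n_true_psms=800, n_false_psms=300, seed=11)
    structure, ss, seq, psms, ground = simulate_study(cfg)
    return {"config": cfg, "structure": structure, "ss": ss, "seq": seq,
            "psms": psms, "ground": ground}
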