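import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

import albudock as ad


@pytest.fixture
def sdf_file(tmp_path):
    """Three small drugs as an SDF, written programmatically."""
    path = tmp_path / "ligands.sdf"
    writer = Chem.SDWriter(str(path))
    for name, smi in [
        ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
        ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
        ("benzene", "c1ccccc1"),
    ]:
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        AllChem.Compute2DCoords(mol)
        mol.SetProp("_Name", name)
        writer.write(mol)
    writer.close()
    return path


@pytest.fixture
def smiles_file(tmp_path):
    """Five SMILES lines, one of them unparsable."""
    path = tmp_path / "ligands.smi"
    path.write_text(
        "CCO\tethanol\n"
        "c1ccccc1\tbenzene\n"
        "not_a_smiles\tbroken\n"
        "CC(=O)Oc1ccccc1C(=O)O\taspirin\n"
        "CCCCC\tpentane\n"
        "CCCCCCCCCC\tdecane\n"
    )
    return path


@pytest.fixture
def score_table_file(tmp_path):
    path = tmp_path / "scores.tsv"
    pd.DataFrame(
        {
            "ligand_id": ["L1", "L2", "L3"],
            "logp": [2.0, -0.5, 3.1],
            "hsa_percent": [92.0, 10.0, 85.0],
            "2BXP:site_I": [-9.1, -3.0, -10.5],
            "1N5U:site_II": [-9.5, -2.1, -7.0],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic strict set, shared across tests."""
    return ad.generate_synthetic(ad.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
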