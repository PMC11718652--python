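from pathlib import Path

import pytest

from hybridscreen.synthetic import SyntheticLibrarySpec, generate_library

REPO_ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = REPO_ROOT / "data"


@pytest.fixture(scope="session")
def morgan_table_path() -> Path:
    return DATA_DIR / "morgan_cluster_table.csv"


@pytest.fixture(scope="session")
def pharm_table_path() -> Path:
    return DATA_DIR / "pharmacophore_cluster_table.csv"


@pytest.fixture(scope="session")
def default_library():
    """The default synthetic benchmark library (20 analogs + 200 decoys)."""
    return generate_library(SyntheticLibrarySpec())


@pytest.fixture(scope="session")
def corpus_smiles(default_library) -> list[str]:
    """A varied corpus of valid SMILES for property tests."""
    seen, out = set(), []
    for entry in default_library:
        if entry.smiles not in seen:
            seen.add(entry.smiles)
            out.append(entry.smiles)
    extra = [
        "CCO", "c1ccccc1", "Oc1ccccc1", "CC(=O)[O-]", "C[N+](C)(C)C",
        "c1ccc2ccccc2c1", "C1CC1", "C.C", "CC(C)(C)c1ccc(O)cc1",
        "O=S(=O)(N)c1ccccc1", "OP(=O)(O)OC", "FC(F)(F)c1ccncc1",
        "c1cc[nH]c1", "CC#N", "N#Cc1ccccc1", "CSC", "CC(=O)Nc1ccccc1",
    ]
    out.extend(s for s in extra if s not in seen)
    return out
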