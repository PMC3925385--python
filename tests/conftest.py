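import numpy as np
import pytest
from hypothesis import settings

from barcode_diet.dietstats import load_clone_table
from barcode_diet.refdb import Lineage, ReferenceDB, ReferenceRecord
from barcode_diet.synthdata import SimParams, make_reference_db

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def _seq(rng: np.random.Generator, n: int = 120) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def tiny_db() -> ReferenceDB:
    """Hand-sized library: two orders, three families, five species."""
    rng = np.random.default_rng(42)
    base = _seq(rng)

    def mut(seq: str, k: int, salt: int) -> str:
        r = np.random.default_rng(1000 + salt)
        pos = r.choice(len(seq), size=k, replace=False)
        out = list(seq)
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
        tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for i, p in enumerate(pos):  # alternate transition/transversion
            out[p] = (ts if i % 2 else tv)[out[p]]
        return "".join(out)

    recs = [
        ReferenceRecord("AC001", base,
                        Lineage("Arthropoda", "Insecta", "Diptera",
                                "Chironomidae", "Chironomus", "Chironomus alpha")),
        ReferenceRecord("AC002", mut(base, 6, 1),
                        Lineage("Arthropoda", "Insecta", "Diptera",
                                "Chironomidae", "Chironomus", "Chironomus beta")),
        ReferenceRecord("AC003", mut(base, 12, 2),
                        Lineage("Arthropoda", "Insecta", "Diptera",
                                "Chironomidae", "Glyptotendipes", "Glyptotendipes gamma")),
        ReferenceRecord("AC004", mut(base, 25, 3),
                        Lineage("Arthropoda", "Insecta", "Diptera",
                                "Culicidae", "Culex", "Culex delta")),
        ReferenceRecord("AC005", mut(base, 30, 4),
                        Lineage("Arthropoda", "Insecta", "Ephemeroptera",
                                "Caenidae", "Caenis", "Caenis epsilon")),
    ]
    return ReferenceDB(recs)


@pytest.fixture(scope="session")
def synth_db():
    params = SimParams(seed=11)
    db, ancestors = make_reference_db(params)
    return params, db, ancestors


@pytest.fixture(scope="session")
def clone_table():
    return load_clone_table()
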