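import pytest

import qsarscreen as qs


@pytest.fixture(scope="session")
def simple_records():
    """A handful of standardized molecules with activities."""
    rows = [
        ("m1", "c1ccccc1", 50.0),        # benzene, weak
        ("m2", "Cc1ccccc1", 120.0),      # toluene, weak
        ("m3", "c1ccncc1", 0.05),        # pyridine, high
        ("m4", "Clc1ccccc1", 0.02),      # chlorobenzene, high
        ("m5", "Oc1ccccc1", 30.0),       # phenol, weak
        ("m6", "c1ccc2ccccc2c1", 0.08),  # naphthalene, high
    ]
    return [qs.standardize(smi, id=i, ic50_um=a) for i, smi, a in rows]


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A small synthetic study used by the module-level integration tests."""
    spec = qs.SyntheticSpec(n_molecules=250, seed=11)
    return qs.generate_benchmark(spec, n_external=80)
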