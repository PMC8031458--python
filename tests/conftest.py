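import pytest

import soluthermo as st


@pytest.fixture(scope="session")
def curves():
    """The packaged 25-curve simvastatin shake-flask dataset."""
    return st.load_simvastatin_table()


@pytest.fixture(scope="session")
def m59_curve(curves):
    """The 20 mM Myrj-59 sample — the best-behaved curve in the dataset."""
    return next(c for c in curves if c.sample_id == "20 mM M59")


@pytest.fixture(scope="session")
def fusion():
    """Simvastatin fusion properties (T_fus, dH_fus, dCp from DSC)."""
    return st.load_simvastatin_fusion()


@pytest.fixture(scope="session")
def hansen_records():
    return st.load_hansen_table()


@pytest.fixture(scope="session")
def study_temps():
    """The three shake-flask study temperatures, K."""
    return (300.2, 310.2, 320.2)
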