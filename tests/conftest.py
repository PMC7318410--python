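import pytest

from lacferm.kinetics import qu25_table1


@pytest.fixture(scope="session")
def qu25():
    """E. mundtii QU 25 parameter preset, all three sugars, no decay."""
    return qu25_table1()


@pytest.fixture(scope="session")
def qu25_glucose_decay():
    """Glucose-only preset with the generator's decay coefficient."""
    return qu25_table1(sugars=("glucose",), K_D=0.02)
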