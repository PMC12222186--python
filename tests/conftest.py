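import numpy as np
import pytest

from saltmeta.io import (
    ObservationRecord,
    SalinityMeasure,
    SalinityUnit,
    Setting,
    Stage,
    Variable,
    VariableKey,
)


def make_record(
    study="S1",
    experiment="E1",
    setting=Setting.GREENHOUSE,
    variable=Variable.GRAIN_YIELD,
    stage=Stage.NONE,
    control_ec=1.0,
    stress_ec=11.0,
    control_value=100.0,
    stress_value=60.0,
    **kwargs,
):
    """Convenience factory for a valid observation record."""
    return ObservationRecord(
        study_id=study,
        experiment_id=experiment,
        setting=setting,
        variable=VariableKey(variable, stage),
        control_salinity=SalinityMeasure(control_ec, SalinityUnit.DS_PER_M),
        stress_salinity=SalinityMeasure(stress_ec, SalinityUnit.DS_PER_M),
        control_value=control_value,
        stress_value=stress_value,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def brute_force_hampel(values, k=3.0, scale=1.4826):
    """Set-builder definition of the Hampel exclusion rule, evaluated
    literally: excluded = {v : |v - median| > k*scale*MAD}."""
    v = list(map(float, values))
    med = float(np.median(v))
    mad = float(np.median([abs(x - med) for x in v]))
    if mad == 0:
        return v, []
    retained = [x for x in v if abs(x - med) <= k * scale * mad]
    excluded = [x for x in v if abs(x - med) > k * scale * mad]
    return retained, excluded
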