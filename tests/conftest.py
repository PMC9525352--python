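import numpy as np
import pytest

from dntbattery import ResponseSeries, TrueCurveSpec, simulate_endpoint
from dntbattery.simulate import DilutionSpec


@pytest.fixture
def clean_sigmoid_spec():
    """Full-effect decreasing sigmoid: EC50 1 µM, Hill 1, no noise."""
    return TrueCurveSpec("sigmoid_decreasing", 0.0, 100.0, 1.0, 1.0)


@pytest.fixture
def dilution():
    return DilutionSpec(top_conc=20.0, factor=3.0, n_concentrations=7)


def series_from_spec(
    spec: TrueCurveSpec,
    dilution: DilutionSpec = DilutionSpec(),
    n_replicates: int = 5,
    seed: int = 0,
    direction: str = "decrease",
) -> ResponseSeries:
    """Simulate one endpoint and pack it as a ResponseSeries (no renormalization)."""
    conc = dilution.concentrations()
    wells = simulate_endpoint(spec, conc, n_replicates, seed)
    treated = wells[wells["concentration_uM"] > 0]
    levels = np.sort(treated["concentration_uM"].unique())
    values = [
        treated.loc[treated["concentration_uM"] == c, "value_pct_control"].to_numpy()
        for c in levels
    ]
    controls = wells.loc[wells["concentration_uM"] == 0, "value_pct_control"].to_numpy()
    return ResponseSeries(
        "comp", "ep", levels, values, direction=direction, control_values=controls
    )


@pytest.fixture
def clean_sigmoid_series(clean_sigmoid_spec, dilution):
    return series_from_spec(clean_sigmoid_spec, dilution)
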