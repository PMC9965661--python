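import numpy as np
import pytest

from marbod.io_experiment import BottleSeries, Experiment, MaterialMeta, Role
from marbod.kinetics import ModelForm, model_value
from marbod.preprocess import CorrectedSeries
from marbod.synthetic_data import MaterialKinetics, SimSpec, simulate


def make_corrected(
    form=ModelForm.VARIABLE_SLOPE,
    params=None,
    times=None,
    noise_sd=0.0,
    n_replicates=2,
    rng=None,
    material_id="M1",
) -> CorrectedSeries:
    """Corrected series generated directly from a kinetic curve."""
    params = params or {"bod_l": 22.2, "a": 10.0, "b": 1.40}
    times = np.arange(1.0, 29.0) if times is None else np.asarray(times, float)
    truth = np.asarray(model_value(form, params, times))
    reps = np.tile(truth, (n_replicates, 1))
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        reps = reps + rng.normal(0.0, noise_sd, reps.shape)
    return CorrectedSeries(
        material_id=material_id,
        times=times,
        bod_corrected=reps.mean(axis=0),
        bod_replicates=reps,
    )


def make_experiment(
    sample_bod,
    cplus_bod,
    blank_bod,
    times=None,
    sample_id="S1",
    cplus_formula={"C": 4, "H": 6, "O": 2},
) -> Experiment:
    """Two-replicate experiment from explicit per-day BOD vectors."""
    times = (
        np.arange(0.0, len(np.atleast_1d(sample_bod)))
        if times is None
        else np.asarray(times, float)
    )

    def bottles(mid, role, values):
        return [
            BottleSeries(f"{mid}-{r}", role, mid if role is not Role.BLANK else "BLANK",
                         r, times, values)
            for r in (1, 2)
        ]

    return Experiment(
        bottles=[
            *bottles("BLANK", Role.BLANK, np.asarray(blank_bod, float)),
            *bottles("C+", Role.POSITIVE_CONTROL, np.asarray(cplus_bod, float)),
            *bottles(sample_id, Role.SAMPLE, np.asarray(sample_bod, float)),
        ],
        materials=[
            MaterialMeta("C+", "PHB positive control", 100.0, cplus_formula),
            MaterialMeta(sample_id, sample_id),
        ],
    )


@pytest.fixture
def id016_spec():
    """Home-compostable-bag scenario: published slope and asymptote,
    half-degradation mid-assay."""
    return SimSpec(
        materials={"ID016": MaterialKinetics(bod_l=22.2, a=10.0, b=1.40)},
        noise_sd=0.0,
        blank_base=0.0,
        blank_slope=0.0,
        days=np.arange(0.0, 29.0),
    )


@pytest.fixture
def id016_experiment(id016_spec):
    return simulate(id016_spec)
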