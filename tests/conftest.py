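import numpy as np
import pytest

from phenoplate import ConditionSpec, KineticSeries, SyntheticStudySpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def series_factory():
    """Build a KineticSeries from a signal list on a 0.25-h grid."""

    def make(signals, strain="strA", cond="ctrl", rep=1, step=0.25):
        signals = np.asarray(signals, dtype=float)
        times = np.arange(signals.size) * step
        return KineticSeries(strain, cond, rep, times, signals)

    return make


@pytest.fixture
def small_panel():
    """One control plus two stresses, one of them the 40 degC / 24 h case."""
    return [
        ConditionSpec("ctrl30", "glucose control", 6, "%w/v", 30, 50, ""),
        ConditionSpec("sorb10", "sorbitol", 10, "%w/v", 30, 50, "ctrl30"),
        ConditionSpec("heat40", "temperature", 40, "C", 40, 24, "ctrl30"),
    ]


@pytest.fixture
def small_study_spec(small_panel):
    """A reduced synthetic study used by unit tests (fast, still multi-block)."""
    return SyntheticStudySpec(
        n_strains=12,
        conditions=small_panel,
        replicates=2,
        noise_sd=1.0,
        seed=7,
    )
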