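import numpy as np
import pytest

from ultrasens import DoseResponseCurve, IndependentParameters, MWCParameters


def make_hill_curve(h: float, k: float) -> DoseResponseCurve:
    """A pure Hill function x^h / (k^h + x^h), the canonical reference curve."""
    return DoseResponseCurve(
        evaluate=lambda u: u ** h / (k ** h + u ** h) if u > 0 else 0.0,
        max_response=1.0, basal=0.0, label=f"hill(h={h}, k={k})")


@pytest.fixture
def michaelis():
    return make_hill_curve(1.0, 1.0)


@pytest.fixture
def mwc3():
    """The 3-site reference target: all c=0.01, alpha=1, L=1000."""
    return MWCParameters.uniform(3, 0.01, L=1000.0)


@pytest.fixture
def mwc4():
    return MWCParameters.uniform(4, 0.01, L=1000.0)


@pytest.fixture
def ind_linear():
    """2-site independent target at the linear-regime locus d = sqrt(v1 v2)."""
    return IndependentParameters.uniform(2, 1e4, d=1e4)


def random_mwc(rng: np.random.Generator, n=None) -> MWCParameters:
    n = n or int(rng.integers(1, 7))
    return MWCParameters(
        n=n,
        c=tuple(np.exp(rng.uniform(np.log(1e-4), np.log(0.9), n))),
        alpha=tuple(np.exp(rng.uniform(np.log(0.1), np.log(10.0), n))),
        L=float(np.exp(rng.uniform(np.log(1.0), np.log(1e4)))),
    )
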