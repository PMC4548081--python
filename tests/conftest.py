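import math

import pytest

from chronodisc import LatentProfile, MCMCConfig, RatingMCMCConfig


def noiseless_profile(log_k=-3.0, a_time=0.05, b_time=0.5,
                      a_circ=1.0, b_circ=1.0) -> LatentProfile:
    """A deterministic agent: vanishing decision noise, infinite rating precision."""
    return LatentProfile(log_k=log_k, beta=1e-12, a_time=a_time, b_time=b_time,
                         a_circ=a_circ, b_circ=b_circ, pi=math.inf,
                         eft_details=40.0, am_details=40.0)


@pytest.fixture
def det_profile():
    return noiseless_profile()


@pytest.fixture
def fast_hier_mcmc():
    """Reduced-draw hierarchical MCMC settings for small test fits."""
    return MCMCConfig(chains=2, warmup=500, draws=500, ess_min=100,
                      on_nonconvergence="warn")


@pytest.fixture
def fast_rating_mcmc():
    return RatingMCMCConfig(chains=2, warmup=300, draws=400)
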