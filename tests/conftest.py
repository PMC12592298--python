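import numpy as np
import pandas as pd
import pytest

from pkautoinit.dataio import annotate_doses, parse_dataset
from pkautoinit.fixtures import DesignSpec, generate_dataset
from pkautoinit.simulate import ModelSpec, StructuralParams


def make_design(route="bolus", cl=2.0, vc=20.0, ka=1.0, sampling="rich",
                n_subjects=6, dosing=(100.0, 24.0, 1), seed=1,
                iiv=None, sigma_add=0.0, sigma_prop=0.0, model=None,
                **params):
    sp = dict(cl=cl, vc=vc)
    if route == "extravascular":
        sp["ka"] = ka
    sp.update(params)
    return DesignSpec(
        route=route,
        model=model or ModelSpec(route=route),
        true_params=StructuralParams(**sp),
        n_subjects=n_subjects,
        dosing=dosing,
        sampling=sampling,
        iiv_omega2=iiv or {},
        sigma_add=sigma_add,
        sigma_prop=sigma_prop,
        seed=seed,
    )


@pytest.fixture(scope="session")
def rich_bolus_df():
    """Noise-free rich single-dose IV bolus cohort (CL=2, V=20)."""
    return generate_dataset(make_design("bolus"))


@pytest.fixture(scope="session")
def rich_oral_df():
    """Noise-free rich single-dose oral cohort (CL=2, V=20, Ka=1)."""
    return generate_dataset(make_design("extravascular"))


@pytest.fixture(scope="session")
def annotated_bolus(rich_bolus_df):
    return annotate_doses(parse_dataset(rich_bolus_df))


def mono_exp_profile(c0=10.0, ke=0.1, times=(4, 8, 12, 16, 20, 24)):
    """Exact mono-exponential pooled profile for terminal-fit tests."""
    from pkautoinit.dataio import PooledProfile

    t = np.asarray(times, float)
    return PooledProfile(
        group="first_dose", tad=t, conc=c0 * np.exp(-ke * t),
        n_points=np.ones(len(t), dtype=int), n_bins_requested=10,
    )
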