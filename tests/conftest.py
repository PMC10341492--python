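import numpy as np
import pytest

from cuprank.design import EndpointSpec, GroupParams, StudyDesign, StudyParams, WeightModel, DoseSchedule


@pytest.fixture(scope="session")
def study_params():
    from cuprank import load_study_params

    return load_study_params(seed=0)


def small_params(
    groups=("control", "cuprizone_A"),
    endpoint_names=("PLP_OD",),
    region=265,
    n_per_group=4,
    seed=0,
    means=None,
    sems=None,
):
    """Minimal StudyParams for focused cohort tests."""
    endpoints = [EndpointSpec.standard(n, region) for n in endpoint_names]
    means = means or {}
    sems = sems or {}
    gp = [
        GroupParams(
            group=g,
            endpoint=e.name,
            region=e.region,
            mean=means.get((g, e.name), 50.0 if e.name.endswith("_OD") else 2.0),
            sem=sems.get((g, e.name), 1.0 if e.name.endswith("_OD") else 0.1),
            source_n=5,
        )
        for g in groups
        for e in endpoints
    ]
    design = StudyDesign(
        groups=list(groups),
        n_per_group=n_per_group,
        regions=[region],
        endpoints=endpoints,
        seed=seed,
    )
    weights = WeightModel(
        start_mean_g=22.0,
        start_sd_g=0.0,
        noise_sd_g=0.0,
        final_g={g: {"mean": 24.0, "sem": 0.0} for g in groups},
    )
    return StudyParams(
        design=design, schedule=DoseSchedule(), weights=weights, group_params=gp
    )


def random_histogram(rng: np.random.Generator, sparse: bool = False) -> np.ndarray:
    """A random 256-bin histogram with at least two occupied bins."""
    if sparse:
        h = np.zeros(256, dtype=np.int64)
        k = rng.integers(2, 12)
        bins = rng.choice(256, size=k, replace=False)
        h[bins] = rng.integers(1, 500, size=k)
    else:
        h = rng.poisson(rng.uniform(0.5, 30.0), size=256).astype(np.int64)
        if np.count_nonzero(h) < 2:
            h[[40, 200]] += 1
    return h
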