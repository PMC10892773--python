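import pytest

from pdseverity.evaluate import PipelineConfig, prepare_features
from pdseverity.simulate import GeneratorConfig, SubjectProfile, generate_cohort

TEST_ACTIVITIES = (2, 3)


def make_profile(severity=2, seed=0, subject_id="P0", duty_cycle=0.5,
                 tremor_amp=None, brady_factor=None, activities=tuple(range(1, 13))):
    """Hand-built profile with sane per-activity tremor frequencies."""
    from pdseverity.simulate import ACTIVITY_KIND, TREMOR_BANDS

    freq = {}
    for a in activities:
        lo, hi = TREMOR_BANDS[ACTIVITY_KIND[a]]
        freq[a] = (lo + hi) / 2.0
    if severity == 0:
        tremor_amp, brady_factor, duty_cycle = 0.0, 1.0, 0.0
    else:
        tremor_amp = 2.0 if tremor_amp is None else tremor_amp
        brady_factor = 0.6 if brady_factor is None else brady_factor
    return SubjectProfile(
        subject_id=subject_id,
        severity=severity,
        tremor_freq=freq,
        tremor_amp=tremor_amp,
        brady_factor=brady_factor,
        duty_cycle=duty_cycle,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects/class, 2 activities, 9 s recordings — plumbing-scale."""
    cfg = GeneratorConfig.from_preset("easy", activities=TEST_ACTIVITIES, duration=9.0)
    return generate_cohort((2, 2, 2, 2), seed=11, config=cfg)


@pytest.fixture(scope="session")
def small_config():
    from pdseverity.evaluate import ClassifierConfig

    return PipelineConfig(
        activities=TEST_ACTIVITIES,
        k=4,
        t=2,
        kmeans_restarts=2,
        classifier=ClassifierConfig(algorithm="knn", params={"n_neighbors": 3}),
    )


@pytest.fixture(scope="session")
def small_features(small_cohort, small_config):
    features, labels, subjects = prepare_features(small_cohort, small_config)
    return features, labels, subjects


@pytest.fixture(scope="session")
def small_documents(small_features, small_config):
    """Documents for all subjects from a model fitted on all subjects."""
    from pdseverity.bags import BagModel, group_by_subject

    features, labels, subjects = small_features
    model = BagModel(
        k=small_config.k, t=small_config.t, seed=0,
        kmeans_restarts=small_config.kmeans_restarts,
    ).fit(features, labels, subjects)
    grouped = group_by_subject(features)
    docs = [model.document(grouped[s], label=labels[s]) for s in subjects]
    return model, docs
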