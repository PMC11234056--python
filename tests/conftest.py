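import numpy as np
import pytest

import ebmkit as e
from ebmkit import io as fio
from ebmkit import model as m


@pytest.fixture(scope="session")
def registry():
    return e.load_packaged_terminologies()


@pytest.fixture()
def walkthrough():
    return e.build_walkthrough()


@pytest.fixture()
def walkthrough_resolver(walkthrough):
    return fio.Resolver(walkthrough.resources)


@pytest.fixture()
def sim_bundle():
    cfg = e.SimulationConfig(k=6, seed=11)
    return e.simulate_evidence_set(cfg)


def random_estimate(rng: np.random.Generator, measure: str = "odds-ratio"):
    """A random, internally consistent effect estimate for property tests."""
    import math

    from ebmkit.statistics import _z

    level = float(rng.uniform(0.8, 0.99))
    z = _z(level)
    if measure in ("odds-ratio", "risk-ratio"):
        log_point = float(rng.normal(0, 0.6))
        se = float(rng.uniform(0.05, 0.5))
        return e.EffectEstimate(
            measure=measure,
            point=math.exp(log_point),
            se=se,
            ci_low=math.exp(log_point - z * se),
            ci_high=math.exp(log_point + z * se),
            ci_level=level,
            events=int(rng.integers(1, 500)),
            total=int(rng.integers(500, 2000)),
        )
    point = float(rng.normal(0, 0.2))
    se = float(rng.uniform(0.01, 0.2))
    return e.EffectEstimate(
        measure=measure,
        point=point,
        se=se,
        ci_low=point - z * se,
        ci_high=point + z * se,
        ci_level=level,
    )


def all_resource_examples():
    """One representative of every supported resource type."""
    bundle = e.build_walkthrough()
    assessment = m.ArtifactAssessmentResource(
        id="assessment-1",
        artifact=m.Reference(target="Evidence/walkthrough-evidence"),
        content=[
            m.AssessmentContent(
                information_type="rating",
                type=m.CodeableConcept(text="overall quality"),
                rating_quantity=m.Quantity(value=4.0),
                author="reviewer",
            ),
            m.AssessmentContent(
                information_type="comment",
                author="reviewer",
                components=[
                    m.AssessmentContent(information_type="response", author="editor")
                ],
            ),
        ],
    )
    return bundle.resources + [assessment]
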