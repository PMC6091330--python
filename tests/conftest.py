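import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from mmstage.impetus import EmSite, ImpetusDescriptor, parse_descriptor
from mmstage.cohort import fixture_table2

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """The packaged 33-patient baseline cohort."""
    return fixture_table2()


@pytest.fixture(scope="session")
def descriptors(cohort):
    """Parsed IMPeTUs descriptors for all 33 fixture patients, in order."""
    return [parse_descriptor(r.impetus) for r in cohort]


deauville = st.integers(1, 5)
grade = st.integers(1, 4)


@st.composite
def em_sites(draw):
    sites = []
    for name in ("nodal", "extranodal"):
        if draw(st.booleans()):
            sites.append(EmSite(name, draw(st.none() | deauville)))
    return tuple(sites)


@st.composite
def impetus_descriptors(draw):
    """Random syntactically valid descriptors spanning the whole grammar."""
    kwargs = {
        "bm_score": draw(deauville),
        "bm_appendicular": draw(st.booleans()),
        "fracture": draw(st.booleans()),
        "paramedullary": draw(st.booleans()),
    }
    if draw(st.booleans()):
        kwargs["focal_grade"] = draw(grade)
        kwargs["focal_sites"] = frozenset(
            draw(
                st.sets(st.sampled_from(["skull", "spine", "extraspine"]), max_size=3)
            )
        )
        kwargs["focal_score"] = draw(st.none() | deauville)
    if draw(st.booleans()):
        kwargs["lytic_grade"] = draw(grade)
    sites = draw(em_sites())
    if sites or draw(st.booleans()):
        kwargs["em_present"] = True
        kwargs["em_sites"] = sites
    return ImpetusDescriptor(**kwargs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180730)
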