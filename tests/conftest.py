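"""Shared fixtures: a small seeded simulation reused across test modules."""

from __future__ import annotations

import pytest

import nrltr as N


@pytest.fixture(scope="session")
def elements():
    return N.make_element_library(seed=3)


@pytest.fixture(scope="session")
def library(elements):
    return N.ltr_library(elements)


@pytest.fixture(scope="session")
def small_world(elements):
    """200-kb reference with six planted insertions and 50x error-free reads."""
    ref = N.generate_reference(N.GenomeSpec(1, 200_000, 0.42, seed=11))
    events = N.plan_insertions(ref, elements, n=6, seed=5)
    donor = N.insert_elements(ref, events, elements)
    reads = N.simulate_reads(donor, N.ReadSimParams(coverage=50, seed=9))
    return {"reference": ref, "events": events, "donor": donor, "reads": reads}


@pytest.fixture(scope="session")
def pipeline_result(small_world, library):
    return N.run_pipeline(small_world["reads"].pairs,
                          small_world["reference"], library)
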