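"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from macall.repeats import find_repeats
from macall.synth import TruthParams, generate_pair, generate_reference, plan_mutations


@pytest.fixture(scope="session")
def small_reference():
    """60-kb random reference with planted homopolymers, plus its repeats."""
    reference, planted = generate_reference(
        101, 60_000, [("A", length, 2) for length in range(7, 13)]
    )
    repeats = find_repeats(reference["chr1"])
    return reference, repeats, planted


@pytest.fixture(scope="session")
def small_pair(small_reference):
    """Ancestor/outgrowth pair with 12 substitutions and 4 repeat indels."""
    reference, repeats, _ = small_reference
    mutations = plan_mutations(reference, repeats, 12, 4, seed=202)
    params = TruthParams(mutations=mutations)
    pair = generate_pair(reference, params, seed=303, repeats=repeats)
    return pair, mutations
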