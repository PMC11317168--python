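"""Shared fixtures: seeded spacers, designed gates and the orthogonal panel.

Design runs are the expensive step, so designed objects are session-scoped;
everything is generated programmatically from fixed seeds.
"""

import pytest

from cgrnakit.circuit_model import TargetSite, parse_gate
from cgrnakit.compiler import compile_design
from cgrnakit.designer import DesignObjective, DesignRunConfig, design_sequences
from cgrnakit.io import FixtureSpec, fixture_spacers, generate_fixtures

#: Architecture test matrix: expression, compile variant, search budget.
GATE_CASES = [
    ("A", None, 150),
    ("A OR B", None, 200),
    ("A AND B", None, 300),
    ("NOT A", None, 60),
    ("A AND (NOT B)", 1, 200),
    ("A AND (NOT B)", 2, 200),
    ("A OR (B AND C)", None, 400),
]


@pytest.fixture(scope="session")
def spacer_set():
    return fixture_spacers(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def site(spacer_set):
    return TargetSite(spacer=spacer_set["malT-like"])


@pytest.fixture(scope="session")
def designed_single(site):
    skeleton = compile_design(parse_gate("A"), site)
    res = design_sequences(
        skeleton, DesignObjective(), DesignRunConfig(seed=1, max_iters=150)
    )
    return res


@pytest.fixture(scope="session")
def designed_gates(site):
    """One designed instance per supported architecture."""
    out = {}
    for expr, variant, iters in GATE_CASES:
        skeleton = compile_design(parse_gate(expr), site, variant=variant)
        res = design_sequences(
            skeleton, DesignObjective(), DesignRunConfig(seed=3, max_iters=iters)
        )
        out[(expr, variant)] = res
    return out


@pytest.fixture(scope="session")
def fixture_panel():
    """The seeded four-design orthogonal panel (runs the audit loop)."""
    spacers, results = generate_fixtures(FixtureSpec(seed=7))
    return spacers, results
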