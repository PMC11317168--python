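"""Evaluator: state prediction, truth tables, crosstalk, fold reduction."""

import itertools

import numpy as np
import pytest

from cgrnakit.circuit_model import eval_expr
from cgrnakit.evaluator import (
    ACTIVE,
    INACTIVE,
    ActivationRule,
    crosstalk_matrix,
    fold_reduction,
    predict_state,
    truth_table,
)


def test_activation_rule_validation():
    with pytest.raises(ValueError):
        ActivationRule(theta_seed=0.0)
    with pytest.raises(ValueError):
        ActivationRule(assembly_min_frac=1.5)


def test_single_design_state_calls(designed_single):
    d = designed_single.design
    assert predict_state(d, ["A"]).state == ACTIVE
    assert predict_state(d, []).state == INACTIVE
    assert predict_state(d, ["decoy_A"]).state == INACTIVE


def test_predict_state_rejects_unknown_inputs(designed_single):
    with pytest.raises(KeyError):
        predict_state(designed_single.design, ["Z"])


def test_and_design_requires_both_triggers(designed_gates):
    d = designed_gates[("A AND B", None)].design
    assert predict_state(d, ["A"]).state == INACTIVE
    assert predict_state(d, ["B"]).state == INACTIVE
    pred = predict_state(d, ["A", "B"])
    assert pred.state == ACTIVE
    assert pred.assembled.get("A+B") is True


def test_not_design_is_active_by_default_and_blocked_by_input(designed_gates):
    d = designed_gates[("NOT A", None)].design
    assert predict_state(d, []).state == ACTIVE
    pred = predict_state(d, ["A"])
    assert pred.state == INACTIVE and pred.blocked
    assert predict_state(d, ["decoy_A"]).state == ACTIVE


def test_antisense_variant_neutralizes_its_target(designed_gates):
    d = designed_gates[("A AND (NOT B)", 2)].design
    pred = predict_state(d, ["A", "B"])
    assert pred.state == INACTIVE and pred.neutralized == ["A"]
    # the carried expression ratio decides dominance
    d.expression_weights["B"] = 0.5
    assert predict_state(d, ["A", "B"]).state == ACTIVE
    d.expression_weights["B"] = 5.0


def test_truth_tables_match_independent_boolean_evaluation(designed_gates):
    """Oracle equivalence for every architecture: the expected column must
    equal a from-scratch evaluation of the Boolean AST, and every predicted
    row must pass."""
    for (expr, variant), res in designed_gates.items():
        d = res.design
        tt = truth_table(d)
        assert len(tt.rows) == 2 ** len(d.gate.inputs)
        for row in tt.rows:
            assignment = {n: bool(row[n]) for n in tt.inputs}
            expected = eval_expr(d.gate.expression, assignment)
            assert (row["expected"] == ACTIVE) == expected
            assert row["pass"], (expr, variant, row)


def test_predict_state_is_monotone_for_activating_architectures(designed_gates):
    """Adding an activating input never flips ACTIVE -> INACTIVE."""
    for expr in ("A", "A OR B", "A AND B", "A OR (B AND C)"):
        d = designed_gates[(expr, None)].design
        names = d.gate.inputs
        state = {}
        for r in itertools.product((0, 1), repeat=len(names)):
            present = frozenset(n for n, b in zip(names, r) if b)
            state[present] = predict_state(d, present).state
        for sub, st in state.items():
            for sup, st_sup in state.items():
                if sub < sup and st == ACTIVE:
                    assert st_sup == ACTIVE, (expr, sub, sup)


def test_crosstalk_matrix_single_design(designed_single):
    mat = crosstalk_matrix([designed_single.design])
    assert mat.n_entries == 1
    assert mat.states[0, 0] == ACTIVE


def test_crosstalk_matrix_permutation_invariance(fixture_panel):
    _, results = fixture_panel
    panel = [r.design for r in results]
    mat = crosstalk_matrix(panel)
    perm = [2, 0, 3, 1]
    mat_p = crosstalk_matrix([panel[i] for i in perm])
    for a, i in enumerate(perm):
        for b, j in enumerate(perm):
            assert mat_p.states[a, b] == mat.states[i, j]
            assert mat_p.accessibility[a, b] == pytest.approx(mat.accessibility[i, j])


def test_crosstalk_matrix_rejects_empty_panel():
    with pytest.raises(ValueError):
        crosstalk_matrix([])


# -- fold reduction ---------------------------------------------------------


def test_fold_reduction_direct_ratio():
    rec = fold_reduction([1000.0], [10.0])
    assert rec.fold_reduction == pytest.approx(100.0)
    assert rec.n_ratios == 1 and rec.sd_pairwise == 0.0


def test_fold_reduction_identity_has_unit_ratio_and_zero_sd():
    rec = fold_reduction([7.0, 7.0, 7.0], [7.0, 7.0, 7.0])
    assert rec.fold_reduction == pytest.approx(1.0)
    assert rec.sd_pairwise == pytest.approx(0.0)


def test_fold_reduction_geometric_means_and_nine_ratios():
    rec = fold_reduction([100.0, 200.0, 400.0], [10.0, 20.0, 40.0])
    assert rec.fluor_decoy == pytest.approx(200.0)  # geometric mean
    assert rec.fluor_trigger == pytest.approx(20.0)
    assert rec.fold_reduction == pytest.approx(10.0)
    assert rec.n_ratios == 9
    ratios = np.array([d / t for d in (100, 200, 400) for t in (10, 20, 40)])
    assert rec.sd_pairwise == pytest.approx(ratios.std(ddof=1))


def test_fold_reduction_input_validation():
    with pytest.raises(ValueError):
        fold_reduction([], [1.0])
    with pytest.raises(ValueError):
        fold_reduction([1.0], [0.0])
    with pytest.raises(ValueError):
        fold_reduction([-1.0], [1.0])
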