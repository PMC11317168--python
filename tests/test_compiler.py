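"""Gate compiler: domain layouts, reference structural constants, invariants."""

import numpy as np
import pytest

from cgrnakit.circuit_model import Architecture, TargetSite, parse_gate, reverse_complement
from cgrnakit.compiler import (
    SCAFFOLD_SEQUENCE,
    SCAFFOLD_TETRALOOP_SPAN,
    CompileError,
    CompilerParams,
    compile_design,
    compile_gate,
    dinucleotide_shuffle,
    free_domain_spec,
)
from cgrnakit.thermo import EnergyModel, pairs_from_dotbracket

SPACER = "AAGGAGAAGAAAGGGAAGAA"


@pytest.fixture()
def single_design():
    return compile_gate("A", SPACER)


def test_scaffold_constant_is_plausible():
    assert set(SCAFFOLD_SEQUENCE) <= set("ACGU")
    a, b = SCAFFOLD_TETRALOOP_SPAN
    assert SCAFFOLD_SEQUENCE[a:b] == "GAAA"  # the tetraloop replaced in NOT designs


def test_single_layout_and_defaults(single_design):
    d = single_design
    names = [x.name for x in d.cgrna.domains]
    assert names[:6] == [
        "toehold",
        "antispacer_5p",
        "bulge",
        "antispacer_3p",
        "hairpin_loop",
        "spacer",
    ]
    assert d.cgrna.domain("toehold").length == 15
    assert d.cgrna.domain("bulge").length == 4  # reference bulge size
    assert d.cgrna.domain("hairpin_loop").length == 12
    trig = d.triggers["A"]
    assert [x.name for x in trig.domains] == [
        "loopbind_A",
        "invasion_A",
        "antitoehold_A",
    ]
    assert len(trig) == 12 + 24 + 15


def test_antispacer_is_exact_reverse_complement(single_design):
    d = single_design
    a5 = d.cgrna.domain("antispacer_5p").sequence
    a3 = d.cgrna.domain("antispacer_3p").sequence
    assert a5 + a3 == reverse_complement(SPACER)


def test_zero_bulge_variant_has_contiguous_stem():
    d = compile_gate("A", SPACER, params=CompilerParams(bulge_len=0))
    names = [x.name for x in d.cgrna.domains]
    assert "bulge" not in names
    assert "bulge" not in free_domain_spec(d.gate.architecture, d.params)


def test_off_target_structure_is_legal_and_sequesters_the_seed(single_design):
    d = single_design
    assert len(d.target_off_structure) == len(d.cgrna)
    pairs = pairs_from_dotbracket(d.target_off_structure)
    model = EnergyModel()
    seq_known = {
        i: c
        for dom, (a, b) in (
            (x, d.cgrna.span(x.name)) for x in d.cgrna.domains if x.assigned
        )
        for i, c in zip(range(a, b), dom.sequence)
    }
    paired = {i for p in pairs for i in p}
    seed_a, seed_b = d.seed_span
    assert all(i in paired for i in range(seed_a, seed_b))
    bulge_a, bulge_b = d.cgrna.span("bulge")
    assert all(i not in paired for i in range(bulge_a, bulge_b))
    sc_a, sc_b = d.scaffold_span
    assert all(i not in paired for i in range(sc_a, sc_b))
    for i, j in pairs:
        assert j - i - 1 >= model.min_hairpin_loop
        if i in seq_known and j in seq_known:
            assert model.pair_weight(seq_known[i], seq_known[j]) is not None


def test_compile_is_byte_deterministic():
    free = {"toehold": "CCUCCUCCUCCUCCU", "hairpin_loop": "CCUCCUCCUCCU", "bulge": "GGAA"}
    a = compile_gate("A", SPACER, free_seqs=free)
    b = compile_gate("A", SPACER, free_seqs=free)
    assert a.cgrna.sequence == b.cgrna.sequence
    assert {k: v.sequence for k, v in a.triggers.items()} == {
        k: v.sequence for k, v in b.triggers.items()
    }
    assert {k: v.sequence for k, v in a.decoys.items()} == {
        k: v.sequence for k, v in b.decoys.items()
    }


def test_and_gate_reference_constants():
    d = compile_gate("A AND B", SPACER)
    info_a = d.trigger_info["A"]
    # trigger A stem-interaction domain: 17 nt beyond its loop-binding part
    core_len = info_a.core_span[1] - info_a.core_span[0]
    assert core_len == d.params.hairpin_loop_len + 17
    # both split triggers carry 6-bp safety-hairpin arms
    for nm in ("A", "B"):
        assert d.triggers[nm].domain(f"sh_arm_{nm}").length == 6
    # assembly domains exist on both strands and have the default length
    asm_a = d.trigger_info["A"].assembly_span
    asm_b = d.trigger_info["B"].assembly_span
    assert asm_a[1] - asm_a[0] == 20 and asm_b[1] - asm_b[0] == 20


def test_and_gate_rejects_short_assembly_domains():
    with pytest.raises(CompileError):
        compile_gate("A AND B", SPACER, params=CompilerParams(and_assembly_len=6))


def test_or_gate_trigger_b_seeds_at_the_loop():
    free = {"toehold": "CCUCCUCCUCCUCCU", "hairpin_loop": "CCUCCUCCUCCU", "bulge": "GGAA"}
    d = compile_gate("A OR B", SPACER, free_seqs=free)
    loop = d.cgrna.domain("hairpin_loop").sequence
    trig_b = d.triggers["B"].sequence
    assert trig_b[:12] == reverse_complement(loop)  # 5' end binds the 12-nt loop
    assert "decoy_A" in d.decoys and "decoy_B" in d.decoys


def test_or_gate_rejects_too_short_loop():
    with pytest.raises(CompileError):
        compile_gate("A OR B", SPACER, params=CompilerParams(hairpin_loop_len=5))


def test_not_gate_extends_the_scaffold_loop_to_20nt():
    d = compile_gate("NOT A", SPACER)
    assert d.cgrna.domain("scaffold_loop_ext").length == 20
    assert d.sensor_span is None
    a, b = d.cgrna.span("scaffold_loop_ext")
    sc_a, sc_b = d.scaffold_span
    assert sc_a <= a < b <= sc_b


def test_a_and_not_b_variants():
    d1 = compile_gate("A AND (NOT B)", SPACER, variant=1)
    assert d1.gate.architecture == Architecture.A_AND_NOT_B_V1
    assert d1.cgrna.domain("scaffold_loop_ext").length == 20
    assert d1.trigger_info["B"].kind == "inhibitor_loop"

    d2 = compile_gate("A AND (NOT B)", SPACER, variant=2)
    assert d2.gate.architecture == Architecture.A_AND_NOT_B_V2
    assert d2.trigger_info["B"].kind == "inhibitor_antisense"
    assert d2.expression_weights["B"] == pytest.approx(5.0)  # ~5x promoter strength
    with pytest.raises(CompileError):
        compile_gate("A AND (NOT B)", SPACER, variant=3)


def test_antisense_inhibitor_is_reverse_complement_of_trigger_a():
    free = {"toehold": "CCUCCUCCUCCUCCU", "hairpin_loop": "CCUCCUCCUCCU", "bulge": "GGAA"}
    d = compile_gate("A AND (NOT B)", SPACER, variant=2, free_seqs=free)
    assert d.triggers["B"].sequence == reverse_complement(d.triggers["A"].sequence)


def test_or_and_gate_splits_the_loop_branch():
    d = compile_gate("A OR (B AND C)", SPACER)
    assert d.trigger_info["A"].kind == "toehold_path"
    assert d.trigger_info["B"].kind == "split"
    assert d.trigger_info["C"].kind == "split"
    assert d.trigger_info["B"].partner == "C"
    # the foothold (loop-binding) core precedes the stem core in assembly order
    assert d.trigger_info["C"].order == 0 and d.trigger_info["B"].order == 1


def test_every_gate_input_has_a_trigger_and_same_length_decoy():
    base = {"toehold": "CCUCCUCCUCCUCCU", "hairpin_loop": "CCUCCUCCUCCU", "bulge": "GGAA"}
    extra = {"assembly": "CCUCCUCCUCCUCCUCCUCC", "sh_loop": "CACA"}
    for expr in ("A", "A OR B", "A AND B"):
        free = dict(base, **extra) if "AND" in expr else base
        d = compile_gate(expr, SPACER, free_seqs=free)
        for name in d.gate.inputs:
            assert name in d.triggers
            decoy = d.decoys[f"decoy_{name}"]
            assert len(decoy) == len(d.triggers[name])


def test_unknown_free_domain_and_bad_length_rejected():
    with pytest.raises(CompileError):
        compile_gate("A", SPACER, free_seqs={"nonsense": "ACGU"})
    with pytest.raises(CompileError):
        compile_gate("A", SPACER, free_seqs={"bulge": "GG"})


def test_dinucleotide_shuffle_preserves_composition():
    seq = "AAGGAGAAGAAAGGGAAGAACCUCCUCC"

    def dinucs(s):
        out = {}
        for a, b in zip(s, s[1:]):
            out[a + b] = out.get(a + b, 0) + 1
        return out

    rng = np.random.RandomState(0)
    shuffled = dinucleotide_shuffle(seq, rng)
    assert sorted(shuffled) == sorted(seq)
    assert dinucs(shuffled) == dinucs(seq)
    # seeded: reproducible
    again = dinucleotide_shuffle(seq, np.random.RandomState(0))
    assert again == shuffled


def test_compile_gate_accepts_dna_spacer():
    d = compile_gate("A", SPACER.replace("U", "T"))
    assert d.site.spacer == SPACER
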