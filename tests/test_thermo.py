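"""Folding engine: frozen examples plus brute-force equivalence suites.

The oracle (tests/_oracles.py) enumerates every pseudoknot-free structure
explicitly; the dynamic programs must agree exactly for every sequence
tested up to length 12.
"""

import numpy as np
import pytest

import _oracles as oracle
from cgrnakit.thermo import (
    EnergyModel,
    cofold,
    cofold_pair_probabilities,
    count_structures,
    dotbracket_from_pairs,
    ensemble_defect,
    fold_mfe,
    pair_probabilities,
    pairs_from_dotbracket,
    spacer_accessibility,
)

MODEL = EnergyModel()


def _random_suite(n_seqs=40, max_len=12, seed=20240629):
    rng = np.random.RandomState(seed)
    out = []
    for _ in range(n_seqs):
        n = rng.randint(4, max_len + 1)
        out.append(oracle.random_rna(rng, n))
    # a few adversarial compositions
    out += ["GGGGCCCC", "GUGUGUGUGU", "ACGUACGUACGU", "GGGAAAACCC", "GACGUC"]
    return out


SUITE = _random_suite()


# -- frozen examples --------------------------------------------------------


def test_fold_mfe_examples():
    assert fold_mfe("AAAAAA", MODEL).dot_bracket == "......"
    assert fold_mfe("AAAAAA", MODEL).score == 0.0
    r = fold_mfe("GGGAAAACCC", MODEL)
    assert r.dot_bracket == "(((....)))" and r.score == 9.0
    r = fold_mfe("GACGUC", MODEL)
    assert r.pairs == [(0, 5)] and r.score == 3.0  # the G1-C6 pair beats G1-U5


def test_count_structures_examples():
    assert count_structures("ACGU", MODEL) == 1
    assert count_structures("GACGUC", MODEL) == 3  # {empty, (1,5), (1,6)}
    assert count_structures("A" * 9, MODEL) == 1


def test_pair_probabilities_uniform_at_beta_zero():
    flat = EnergyModel(beta=0.0)
    P = pair_probabilities("GACGUC", flat).p
    assert P[0, 5] == pytest.approx(1 / 3)
    assert P[0, 4] == pytest.approx(1 / 3)
    # normalization for position 1: paired + unpaired mass
    assert P[0].sum() + (1 - P[0].sum()) == pytest.approx(1.0)


def test_ensemble_defect_examples():
    r = ensemble_defect("AAAA", "....", MODEL)
    assert r.defect == pytest.approx(0.0)
    flat = EnergyModel(beta=0.0)
    # hand value: p(1,6)=p(1,5)=1/3; positions 1,6 each contribute 2/3 and
    # position 5 contributes 1/3 against target (....)
    r = ensemble_defect("GACGUC", "(....)", flat)
    assert r.defect == pytest.approx(5 / 3)
    assert 0.0 <= r.normalized_defect <= 1.0


def test_ensemble_defect_rejects_illegal_targets():
    with pytest.raises(ValueError):
        ensemble_defect("GACGUC", "((..))", MODEL)  # A:U? position 2 A vs 5 U ok, 1:6... loop violation
    with pytest.raises(ValueError):
        ensemble_defect("AAAA", "(..)", MODEL)  # A:A is not a pair
    with pytest.raises(ValueError):
        ensemble_defect("GACGUC", "(...)", MODEL)  # length mismatch


def test_cofold_examples():
    r = cofold("GGGG", "CCCC", MODEL)
    assert len(r.intermolecular_pairs) == 4 and r.score == 12.0
    assert r.dot_bracket == "((((&))))"
    assert cofold("AAAA", "AAAA", MODEL).pairs == []


def test_cofold_of_reverse_complement_is_a_full_duplex():
    from cgrnakit.circuit_model import reverse_complement

    s = "GAUACA"
    r = cofold(s, reverse_complement(s), MODEL)
    assert len(r.intermolecular_pairs) >= len(s) - 1


def test_spacer_accessibility_span_semantics():
    r = fold_mfe("A" * 10, MODEL)
    assert spacer_accessibility(r, (0, 10), (5, 10)) == (1.0, 1.0)
    r2 = fold_mfe("GGGGAAAACCCC", MODEL)
    frac, _ = spacer_accessibility(r2, (0, 4), (0, 2))
    assert frac == 0.0  # the G run is fully paired
    with pytest.raises(ValueError):
        spacer_accessibility(r, (0, 11), (0, 1))


def test_dotbracket_round_trip():
    pairs = [(0, 9), (1, 8), (3, 7)]
    db = dotbracket_from_pairs(10, pairs)
    assert pairs_from_dotbracket(db) == pairs
    with pytest.raises(ValueError):
        pairs_from_dotbracket("(()")


def test_energy_model_validation():
    with pytest.raises(ValueError):
        EnergyModel(min_hairpin_loop=2)
    with pytest.raises(ValueError):
        EnergyModel(pair_weights={"GC": 0.0})
    # GU wobble is toggleable by dropping the weight
    no_gu = EnergyModel(pair_weights={"GC": 3.0, "AU": 2.0})
    assert no_gu.pair_weight("G", "U") is None
    assert fold_mfe("GGGGGU", no_gu).score == 0.0  # only GU pairs were possible
    assert fold_mfe("GGGGGU", MODEL).score == 1.0


# -- brute-force equivalence ------------------------------------------------


@pytest.mark.parametrize("seq", SUITE)
def test_fold_mfe_matches_brute_force(seq):
    assert fold_mfe(seq, MODEL).score == pytest.approx(
        oracle.brute_mfe_score(seq, MODEL)
    )


@pytest.mark.parametrize("seq", SUITE)
def test_count_structures_matches_enumeration(seq):
    assert count_structures(seq, MODEL) == len(oracle.enumerate_structures(seq, MODEL))


@pytest.mark.parametrize("seq", SUITE[:25])
def test_pair_probabilities_match_boltzmann_enumeration(seq):
    P = pair_probabilities(seq, MODEL).p
    expected = oracle.brute_pair_probabilities(seq, MODEL)
    assert np.allclose(P, expected, atol=1e-9)
    assert np.allclose(P, P.T)
    assert (P.sum(axis=1) <= 1 + 1e-12).all()


@pytest.mark.parametrize("seq", SUITE[:15])
def test_ensemble_defect_matches_brute_force(seq):
    mfe = fold_mfe(seq, MODEL)
    target = mfe.dot_bracket
    got = ensemble_defect(seq, target, MODEL).defect
    expected = oracle.brute_ensemble_defect(seq, mfe.pairs, MODEL)
    assert got == pytest.approx(expected, abs=1e-9)
    assert 0.0 <= got <= len(seq)


def test_structure_results_satisfy_model_constraints():
    for seq in SUITE[:20]:
        r = fold_mfe(seq, MODEL)
        for i, j in r.pairs:
            assert j - i - 1 >= MODEL.min_hairpin_loop
            assert MODEL.pair_weight(seq[i], seq[j]) is not None
        assert pairs_from_dotbracket(r.dot_bracket) == r.pairs


def test_cofold_never_scores_below_single_strand_folds():
    rng = np.random.RandomState(5)
    for _ in range(10):
        a = oracle.random_rna(rng, rng.randint(5, 12))
        b = oracle.random_rna(rng, rng.randint(5, 12))
        joint = cofold(a, b, MODEL).score
        assert joint >= fold_mfe(a, MODEL).score
        assert joint >= fold_mfe(b, MODEL).score


def test_increasing_beta_never_decreases_mfe_structure_probability():
    seq = "GGGAAAACCCGAC"
    mfe = fold_mfe(seq, MODEL)
    probs = []
    for beta in (0.25, 0.5, 1.0, 2.0):
        P = pair_probabilities(seq, EnergyModel(beta=beta)).p
        probs.append(min(P[i, j] for i, j in mfe.pairs))
    assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


def test_cofold_pair_probabilities_are_normalized_and_symmetric():
    P = cofold_pair_probabilities("GGGG", "CCCC", MODEL).p
    assert P.shape == (8, 8)
    assert np.allclose(P, P.T)
    assert (P.sum(axis=1) <= 1 + 1e-12).all()
    assert P[0, 7] > 0.5  # the terminal GC pair dominates the duplex ensemble
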