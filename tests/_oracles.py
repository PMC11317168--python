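"""Independent brute-force oracles for the folding engine tests.

Everything here enumerates structures explicitly and never calls the dynamic
programs it is used to validate.
"""

from itertools import combinations
from typing import Dict, List, Tuple

import numpy as np

from cgrnakit.thermo import EnergyModel


def legal_pairs(seq: str, model: EnergyModel) -> List[Tuple[int, int]]:
    out = []
    for i in range(len(seq)):
        for j in range(i + 1 + model.min_hairpin_loop, len(seq)):
            if model.pair_weight(seq[i], seq[j]) is not None:
                out.append((i, j))
    return out


def enumerate_structures(seq: str, model: EnergyModel) -> List[List[Tuple[int, int]]]:
    """All pseudoknot-free structures (lists of pairs), including the empty one."""
    cand = legal_pairs(seq, model)
    out: List[List[Tuple[int, int]]] = []

    def compatible(a, b):
        i, j = a
        k, l = b
        if len({i, j, k, l}) < 4:
            return False
        return not ((i < k < j < l) or (k < i < l < j))

    def rec(chosen, remaining):
        out.append(list(chosen))
        for idx, p in enumerate(remaining):
            rest = [q for q in remaining[idx + 1 :] if compatible(p, q)]
            chosen.append(p)
            rec(chosen, rest)
            chosen.pop()

    rec([], cand)
    return out


def structure_weight(seq: str, pairs, model: EnergyModel) -> float:
    return sum(model.pair_weight(seq[i], seq[j]) for i, j in pairs) if pairs else 0.0


def brute_mfe_score(seq: str, model: EnergyModel) -> float:
    return max(
        structure_weight(seq, st, model) for st in enumerate_structures(seq, model)
    )


def brute_pair_probabilities(seq: str, model: EnergyModel) -> np.ndarray:
    structs = enumerate_structures(seq, model)
    n = len(seq)
    weights = [np.exp(model.beta * structure_weight(seq, st, model)) for st in structs]
    Z = sum(weights)
    P = np.zeros((n, n))
    for st, w in zip(structs, weights):
        for i, j in st:
            P[i, j] += w
            P[j, i] += w
    return P / Z


def brute_ensemble_defect(seq: str, target_pairs, model: EnergyModel) -> float:
    P = brute_pair_probabilities(seq, model)
    partner: Dict[int, int] = {}
    for i, j in target_pairs:
        partner[i] = j
        partner[j] = i
    defect = 0.0
    for i in range(len(seq)):
        if i in partner:
            defect += 1.0 - P[i, partner[i]]
        else:
            defect += P[i].sum()
    return defect


def random_rna(rng: np.random.RandomState, n: int) -> str:
    return "".join(rng.choice(list("ACGU")) for _ in range(n))
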