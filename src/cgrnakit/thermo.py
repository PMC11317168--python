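"""Self-contained RNA secondary-structure engine under a pair-weight model.

The engine scores a pseudoknot-free structure as the sum of its base-pair
weights (GC=3, AU=2, GU=1 stability units by default) with a minimum hairpin
loop of 3 nt.  This deliberately simple model -- a weighted Nussinov /
McCaskill scheme rather than a nearest-neighbor parameter set -- is exactly
checkable against brute-force enumeration, which is how the dynamic programs
here are validated.  It provides:

* maximum-weight (MFE-analog) folding with a deterministic traceback,
* exact structure counting,
* Boltzmann base-pair probabilities via an inside-outside computation,
* ensemble defect against a target structure,
* two-strand co-folding through an unpairable 4-nt linker.

Boltzmann weights are ``exp(beta * score)`` in linear space; with the default
weights this is safe in float64 up to roughly 400 nt, far beyond the strand
sizes handled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .circuit_model import SequenceError, clean_rna

__all__ = [
    "EnergyModel",
    "StructureResult",
    "PairProbabilityMatrix",
    "DefectReport",
    "fold_mfe",
    "count_structures",
    "pair_probabilities",
    "ensemble_defect",
    "cofold",
    "spacer_accessibility",
    "pairs_from_dotbracket",
    "dotbracket_from_pairs",
]

DEFAULT_PAIR_WEIGHTS: Dict[str, float] = {"GC": 3.0, "AU": 2.0, "GU": 1.0}

#: Number of unpairable sentinel positions inserted between co-folded strands.
LINKER_LEN = 4


@dataclass(frozen=True)
class EnergyModel:
    """Pair-weight energy model (higher weight = more stable pair)."""

    pair_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS)
    )
    min_hairpin_loop: int = 3
    beta: float = 1.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.pair_weights.values()):
            raise ValueError("pair weights must be > 0")
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")

    def pair_weight(self, a: str, b: str) -> Optional[float]:
        """Weight of pairing bases *a*:*b*, or None if not a legal pair."""
        for key in (a + b, b + a):
            if key in self.pair_weights:
                return self.pair_weights[key]
        return None


@dataclass
class StructureResult:
    """A single secondary structure: dot-bracket, score and pair list.

    For two-strand complexes ``strand_break`` is the 0-based index of the
    first position of the second strand (linker positions are excised from
    the coordinate system) and the dot-bracket carries an ``&`` separator.
    """

    dot_bracket: str
    score: float
    pairs: List[Tuple[int, int]]
    strand_break: Optional[int] = None

    def __len__(self) -> int:
        return len(self.dot_bracket.replace("&", ""))

    @property
    def paired_positions(self) -> set:
        out = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out

    @property
    def intermolecular_pairs(self) -> List[Tuple[int, int]]:
        if self.strand_break is None:
            return []
        b = self.strand_break
        return [(i, j) for i, j in self.pairs if i < b <= j]


@dataclass
class PairProbabilityMatrix:
    """Symmetric matrix of P(i pairs j) under the Boltzmann ensemble."""

    p: np.ndarray

    def p_unpaired(self, i: int) -> float:
        return 1.0 - float(self.p[i].sum())

    def unpaired_vector(self) -> np.ndarray:
        return 1.0 - self.p.sum(axis=1)


@dataclass
class DefectReport:
    """Ensemble defect: expected nt whose pairing state differs from a target."""

    defect: float
    normalized_defect: float


# --------------------------------------------------------------------------
# Dot-bracket utilities
# --------------------------------------------------------------------------


def pairs_from_dotbracket(db: str) -> List[Tuple[int, int]]:
    """Parse ``.()`` notation (``&`` separators ignored) into (i, j) pairs."""
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    pos = 0
    for ch in db:
        if ch == "&":
            continue
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced ')' in dot-bracket")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"illegal dot-bracket character {ch!r}")
        pos += 1
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket")
    return sorted(pairs)


def dotbracket_from_pairs(
    n: int, pairs: Sequence[Tuple[int, int]], strand_break: Optional[int] = None
) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    s = "".join(chars)
    if strand_break is not None:
        s = s[:strand_break] + "&" + s[strand_break:]
    return s


# --------------------------------------------------------------------------
# Weight matrix construction
# --------------------------------------------------------------------------


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def _pair_table(model: EnergyModel) -> np.ndarray:
    table = np.full((4, 4), -np.inf)
    for a, i in _BASE_INDEX.items():
        for b, j in _BASE_INDEX.items():
            pw = model.pair_weight(a, b)
            if pw is not None:
                table[i, j] = pw
    return table


def _weight_matrix(
    seq: str,
    model: EnergyModel,
    junction: Optional[int] = None,
    blocked: Optional[set] = None,
) -> np.ndarray:
    """(n, n) matrix of pair weights; -inf marks illegal pairs.

    ``junction`` (position index) exempts pairs spanning it from the
    hairpin-loop minimum; ``blocked`` positions may not pair at all.
    """
    n = len(seq)
    codes = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.intp, count=n)
    w = _pair_table(model)[codes[:, None], codes[None, :]]
    idx = np.arange(n)
    legal = idx[None, :] - idx[:, None] - 1 >= model.min_hairpin_loop
    if junction is not None:
        legal |= (idx[:, None] < junction) & (idx[None, :] >= junction)
    legal &= idx[None, :] > idx[:, None]
    w = np.where(legal, w, -np.inf)
    if blocked:
        bl = list(blocked)
        w[bl, :] = -np.inf
        w[:, bl] = -np.inf
    return w


# --------------------------------------------------------------------------
# Maximum-weight folding (Nussinov-style DP, vectorized over diagonals)
# --------------------------------------------------------------------------


def _fill_mfe(w: np.ndarray, min_loop_row: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    N = np.zeros((n + 1, n + 1))
    for d in range(1, n):
        i_idx = np.arange(0, n - d)
        j_idx = i_idx + d
        best = N[i_idx + 1, j_idx].copy()  # i unpaired
        # i paired with k = i + t
        t = np.arange(1, d + 1)
        cand = (
            w[i_idx[:, None], i_idx[:, None] + t[None, :]]
            + N[i_idx[:, None] + 1, i_idx[:, None] + t[None, :] - 1]
            + N[i_idx[:, None] + t[None, :] + 1, j_idx[:, None]]
        )
        np.maximum(best, cand.max(axis=1), out=best)
        N[i_idx, j_idx] = best
    return N


def _traceback(
    w: np.ndarray, N: np.ndarray, i0: int, j0: int
) -> List[Tuple[int, int]]:
    """Deterministic traceback: prefer i unpaired, then the smallest partner."""
    pairs: List[Tuple[int, int]] = []
    stack = [(i0, j0)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if N[i, j] == N[i + 1, j]:
            stack.append((i + 1, j))
            continue
        target = N[i, j]
        for k in range(i + 1, j + 1):
            if w[i, k] == -np.inf:
                continue
            if w[i, k] + N[i + 1, k - 1] + N[k + 1, j] == target:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - DP consistency guard
            raise RuntimeError("traceback failed; inconsistent DP matrix")
    return sorted(pairs)


def fold_mfe(seq: str, model: Optional[EnergyModel] = None) -> StructureResult:
    """Maximum-weight pseudoknot-free structure of a single strand."""
    model = model or EnergyModel()
    s = clean_rna(seq)
    n = len(s)
    w = _weight_matrix(s, model)
    N = _fill_mfe(w, np.array([]))
    pairs = _traceback(w, N, 0, n - 1) if n > 1 else []
    return StructureResult(
        dot_bracket=dotbracket_from_pairs(n, pairs),
        score=float(N[0, n - 1]) if n > 1 else 0.0,
        pairs=pairs,
    )


# --------------------------------------------------------------------------
# Structure counting
# --------------------------------------------------------------------------


def count_structures(seq: str, model: Optional[EnergyModel] = None) -> int:
    """Exact number of legal pseudoknot-free structures (incl. the empty one).

    Counts with exact integer arithmetic; the recursion conditions on the
    status of position *i* so every structure is counted once.
    """
    model = model or EnergyModel()
    s = clean_rna(seq)
    n = len(s)
    pairable = [
        [
            (j - i - 1 >= model.min_hairpin_loop)
            and model.pair_weight(s[i], s[j]) is not None
            for j in range(n)
        ]
        for i in range(n)
    ]
    C: Dict[Tuple[int, int], int] = {}

    def count(i: int, j: int) -> int:
        if j - i < model.min_hairpin_loop:
            return 1
        key = (i, j)
        if key in C:
            return C[key]
        total = count(i + 1, j)
        for k in range(i + model.min_hairpin_loop + 1, j + 1):
            if pairable[i][k]:
                total += count(i + 1, k - 1) * count(k + 1, j)
        C[key] = total
        return total

    return count(0, n - 1) if n else 1


# --------------------------------------------------------------------------
# Partition function and pair probabilities (inside-outside)
# --------------------------------------------------------------------------


def _boltzmann_weights(w: np.ndarray, beta: float) -> np.ndarray:
    finite = np.isfinite(w)
    bw = np.zeros_like(w)
    bw[finite] = np.exp(beta * w[finite])
    return bw


def _fill_inside(bw: np.ndarray) -> np.ndarray:
    n = bw.shape[0]
    Z = np.ones((n + 1, n + 1))
    for d in range(1, n):
        i_idx = np.arange(0, n - d)
        j_idx = i_idx + d
        total = Z[i_idx + 1, j_idx].copy()
        t = np.arange(1, d + 1)
        total += (
            bw[i_idx[:, None], i_idx[:, None] + t[None, :]]
            * Z[i_idx[:, None] + 1, i_idx[:, None] + t[None, :] - 1]
            * Z[i_idx[:, None] + t[None, :] + 1, j_idx[:, None]]
        ).sum(axis=1)
        Z[i_idx, j_idx] = total
    return Z


def _pair_probability_matrix(bw: np.ndarray) -> np.ndarray:
    """Boltzmann pair probabilities via the inside-outside recursion.

    ``Zout[i, j]`` is the partition function over everything outside [i, j]
    given that (i, j) pair, decomposed by the innermost enclosing pair.
    """
    n = bw.shape[0]
    if n < 2:
        return np.zeros((max(n, 1), max(n, 1)))
    Z = _fill_inside(bw)
    Ztot = Z[0, n - 1]

    # B[j, q] = Z over (j, q) exclusive interval [j+1, q-1]; 0 unless q > j
    jj, qq = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    B = np.where(qq > jj, Z[np.minimum(jj + 1, n), np.maximum(qq - 1, 0)], 0.0)
    # fix q - 1 < j + 1 (empty interval) cells that the clip mangled
    B[(qq > jj) & (qq - 1 < jj + 1)] = 1.0

    Zpre = np.array([1.0 if i == 0 else Z[0, i - 1] for i in range(n)])
    Zsuf = np.array([Z[j + 1, n - 1] for j in range(n)])

    Zout = np.zeros((n, n))
    for i in range(n):
        outer = Zpre[i] * Zsuf
        if i > 0:
            zvals = np.array([Z[p + 1, i - 1] for p in range(i)])
            M = (bw[:i, :] * Zout[:i, :]).T @ zvals  # M[q]
            outer = outer + B @ M
        Zout[i, :] = outer

    inner = np.array(
        [[Z[i + 1, j - 1] if j - 1 >= i + 1 else 1.0 for j in range(n)] for i in range(n)]
    )
    P = np.triu(bw * inner * Zout, k=1) / Ztot
    return P + P.T


def pair_probabilities(
    seq: str, model: Optional[EnergyModel] = None
) -> PairProbabilityMatrix:
    """Base-pair probability matrix of a single strand."""
    model = model or EnergyModel()
    s = clean_rna(seq)
    w = _weight_matrix(s, model)
    bw = _boltzmann_weights(w, model.beta)
    return PairProbabilityMatrix(p=_pair_probability_matrix(bw))


# --------------------------------------------------------------------------
# Ensemble defect
# --------------------------------------------------------------------------


def _validate_target(seq: str, pairs: Sequence[Tuple[int, int]], model: EnergyModel):
    for i, j in pairs:
        if j - i - 1 < model.min_hairpin_loop:
            raise ValueError(
                f"target pair ({i + 1},{j + 1}) violates the minimum hairpin loop"
            )
        if model.pair_weight(seq[i], seq[j]) is None:
            raise ValueError(
                f"target pair ({i + 1},{j + 1}) {seq[i]}:{seq[j]} is not a legal pair"
            )


def ensemble_defect(
    seq: str, target: str, model: Optional[EnergyModel] = None
) -> DefectReport:
    """Expected number of nucleotides deviating from *target* over the ensemble.

    For a position the target wants paired to j the contribution is
    ``1 - p(i, j)``; for a position the target wants unpaired it is the
    probability of being paired at all.
    """
    model = model or EnergyModel()
    s = clean_rna(seq)
    if len(target.replace("&", "")) != len(s):
        raise ValueError("target length does not match sequence length")
    tpairs = pairs_from_dotbracket(target)
    _validate_target(s, tpairs, model)
    P = pair_probabilities(s, model).p
    partner = {}
    for i, j in tpairs:
        partner[i] = j
        partner[j] = i
    defect = 0.0
    for i in range(len(s)):
        if i in partner:
            defect += 1.0 - float(P[i, partner[i]])
        else:
            defect += float(P[i].sum())
    return DefectReport(defect=defect, normalized_defect=defect / len(s))


# --------------------------------------------------------------------------
# Two-strand co-folding
# --------------------------------------------------------------------------


def cofold(
    seq_a: str, seq_b: str, model: Optional[EnergyModel] = None
) -> StructureResult:
    """Fold the complex A:B via concatenation through an unpairable linker.

    The 4 linker positions cannot pair and pairs spanning the junction are
    exempt from the hairpin-loop minimum, so a blunt intermolecular duplex is
    representable.  Both intramolecular and intermolecular pairs are allowed.
    Returned coordinates exclude the linker: strand A occupies
    ``[0, len(A))`` and strand B ``[len(A), len(A)+len(B))``.
    """
    model = model or EnergyModel()
    a = clean_rna(seq_a)
    b = clean_rna(seq_b)
    na, nb = len(a), len(b)
    combined = a + "A" * LINKER_LEN + b  # linker bases are masked, identity moot
    blocked = set(range(na, na + LINKER_LEN))
    w = _weight_matrix(combined, model, junction=na + LINKER_LEN, blocked=blocked)
    n = len(combined)
    N = _fill_mfe(w, np.array([]))
    raw_pairs = _traceback(w, N, 0, n - 1)

    def remap(k: int) -> int:
        return k if k < na else k - LINKER_LEN

    pairs = [(remap(i), remap(j)) for i, j in raw_pairs]
    return StructureResult(
        dot_bracket=dotbracket_from_pairs(na + nb, pairs, strand_break=na),
        score=float(N[0, n - 1]),
        pairs=pairs,
        strand_break=na,
    )


def cofold_pair_probabilities(
    seq_a: str, seq_b: str, model: Optional[EnergyModel] = None
) -> PairProbabilityMatrix:
    """Base-pair probabilities over the A:B complex ensemble.

    Same linker construction as :func:`cofold`; returned coordinates exclude
    the linker (strand A then strand B).
    """
    model = model or EnergyModel()
    a = clean_rna(seq_a)
    b = clean_rna(seq_b)
    na = len(a)
    combined = a + "A" * LINKER_LEN + b
    blocked = set(range(na, na + LINKER_LEN))
    w = _weight_matrix(combined, model, junction=na + LINKER_LEN, blocked=blocked)
    bw = _boltzmann_weights(w, model.beta)
    P = _pair_probability_matrix(bw)
    keep = [k for k in range(len(combined)) if k not in blocked]
    return PairProbabilityMatrix(p=P[np.ix_(keep, keep)])


# --------------------------------------------------------------------------
# Accessibility
# --------------------------------------------------------------------------


def spacer_accessibility(
    complex_result: StructureResult,
    spacer_span: Tuple[int, int],
    seed_span: Tuple[int, int],
) -> Tuple[float, float]:
    """Fractions of spacer / seed positions unpaired in the given structure.

    Spans are 0-based half-open in the coordinates of the (first strand of
    the) structure.
    """
    n = len(complex_result)
    for a, b in (spacer_span, seed_span):
        if not (0 <= a < b <= n):
            raise ValueError(f"span ({a}, {b}) out of range for length {n}")
    paired = complex_result.paired_positions

    def frac(span: Tuple[int, int]) -> float:
        a, b = span
        free = sum(1 for k in range(a, b) if k not in paired)
        return free / (b - a)

    return frac(spacer_span), frac(seed_span)
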