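"""Predict ON/OFF behaviour of compiled designs and score design panels.

Activation is a thresholded structural criterion, not a kinetic model: a
design counts ACTIVE when, in the predicted minimum-energy complex of its
sensor module with an activating species, at least ``theta_seed`` of the
PAM-proximal seed positions are free of the sequestering antispacer (a seed
no longer base-paired to the cis-regulatory element can nucleate R-loop
formation; transient pairing with other single-stranded regions is not a
displacement barrier and is not counted).  The scaffold is treated as
dCas9-occupied and therefore excluded from the activation fold; it
participates only in the NOT-gate blocking check, where an inhibitory input
hybridizing the extended scaffold loop prevents dCas9 loading.

Also provided: truth-table enumeration against the gate's Boolean expression,
pairwise crosstalk matrices for design panels, and the fold-reduction metric
(geometric-mean reporter signal with decoy over signal with trigger).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .circuit_model import Architecture, CgRNADesign, eval_expr
from .thermo import (
    EnergyModel,
    StructureResult,
    cofold,
    cofold_pair_probabilities,
    spacer_accessibility,
)

__all__ = [
    "ActivationRule",
    "StatePrediction",
    "TruthTable",
    "CrosstalkMatrix",
    "FoldReductionRecord",
    "predict_state",
    "truth_table",
    "crosstalk_matrix",
    "fold_reduction",
]

ACTIVE = "ACTIVE"
INACTIVE = "INACTIVE"


@dataclass(frozen=True)
class ActivationRule:
    """Thresholds turning predicted structures into ON/OFF calls."""

    theta_seed: float = 0.8
    assembly_min_frac: float = 0.8
    not_block_min_frac: float = 0.8

    def __post_init__(self) -> None:
        for name in ("theta_seed", "assembly_min_frac", "not_block_min_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class StatePrediction:
    state: str
    seed_accessibility: float
    blocked: bool
    species_accessibility: Dict[str, float] = field(default_factory=dict)
    assembled: Dict[str, bool] = field(default_factory=dict)
    neutralized: List[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Species construction
# --------------------------------------------------------------------------


def _strand_seq(design: CgRNADesign, name: str) -> str:
    if name in design.triggers:
        return design.triggers[name].sequence
    if name in design.decoys:
        return design.decoys[name].sequence
    raise KeyError(f"unknown input name {name!r}")


def _assembled_core(design: CgRNADesign, first: str, second: str) -> str:
    """Concatenated functional cores of a split pair, in assembled order."""
    parts = []
    for nm in (first, second):
        info = design.trigger_info[nm]
        a, b = info.core_span  # type: ignore[misc]
        parts.append(design.triggers[nm].sequence[a:b])
    return "".join(parts)


def _assembly_fraction(
    design: CgRNADesign, a: str, b: str, model: EnergyModel
) -> float:
    """Fraction of the assembly-domain positions of *a* intermolecularly paired
    in the co-fold of split triggers *a* and *b*."""
    sa = design.triggers[a].sequence
    sb = design.triggers[b].sequence
    res = cofold(sa, sb, model)
    span = design.trigger_info[a].assembly_span
    assert span is not None
    inter = {i for i, j in res.intermolecular_pairs} | {
        j for i, j in res.intermolecular_pairs
    }
    hits = sum(1 for k in range(span[0], span[1]) if k in inter)
    return hits / (span[1] - span[0])


def activating_species(
    design: CgRNADesign,
    present: Sequence[str],
    model: EnergyModel,
    rule: ActivationRule,
) -> Tuple[List[Tuple[str, str]], Dict[str, bool], List[str]]:
    """Resolve present inputs into activating species sequences.

    Returns (species list of (label, sequence), split-assembly flags,
    neutralized trigger names).  Inhibitory inputs are handled by the caller.
    """
    present_set = set(present)
    for name in present_set:
        if name not in design.triggers and name not in design.decoys:
            raise KeyError(f"unknown input name {name!r}")

    neutralized: List[str] = []
    for name in present_set & set(design.triggers):
        info = design.trigger_info[name]
        if info.kind == "inhibitor_antisense" and info.partner in present_set:
            w_inhib = design.expression_weights.get(name, 1.0)
            w_target = design.expression_weights.get(info.partner, 1.0)
            if w_inhib >= w_target:
                neutralized.append(info.partner)

    species: List[Tuple[str, str]] = []
    assembled: Dict[str, bool] = {}
    done_pairs = set()
    for name in sorted(present_set):
        if name in neutralized:
            continue
        if name in design.decoys and name not in design.triggers:
            info = design.trigger_info.get(name.removeprefix("decoy_"))
            if info is not None and info.kind in ("inhibitor_loop", "inhibitor_antisense"):
                continue  # decoys of inhibitors are handled by the blocking check
            species.append((name, design.decoys[name].sequence))
            continue
        info = design.trigger_info[name]
        if info.kind in ("toehold_path", "loop_path"):
            species.append((name, design.triggers[name].sequence))
        elif info.kind == "split":
            pair = tuple(sorted((name, info.partner)))  # type: ignore[arg-type]
            if pair in done_pairs:
                continue
            done_pairs.add(pair)
            if info.partner in present_set and info.partner not in neutralized:
                frac = _assembly_fraction(design, name, info.partner, model)
                ok = frac >= rule.assembly_min_frac
                assembled[f"{pair[0]}+{pair[1]}"] = ok
                if ok:
                    first, second = sorted(
                        pair, key=lambda nm: design.trigger_info[nm].order
                    )
                    species.append(
                        (f"{first}+{second}", _assembled_core(design, first, second))
                    )
                # lone-strand species retained: monotone and lets leak show up
                species.append((name, design.triggers[name].sequence))
                species.append((info.partner, design.triggers[info.partner].sequence))
            else:
                species.append((name, design.triggers[name].sequence))
        # inhibitor kinds produce no activating species
    return species, assembled, neutralized


def _blocked(
    design: CgRNADesign,
    present: Sequence[str],
    model: EnergyModel,
    rule: ActivationRule,
) -> bool:
    """True when an inhibitory input hybridizes the extended scaffold loop."""
    try:
        loop_span = design.cgrna.span("scaffold_loop_ext")
    except KeyError:
        return False
    sc_a, sc_b = design.scaffold_span
    loop_rel = (loop_span[0] - sc_a, loop_span[1] - sc_a)
    scaffold_seq = design.scaffold_sequence
    for name in sorted(set(present)):
        base = name.removeprefix("decoy_")
        info = design.trigger_info.get(base)
        if info is None or info.kind != "inhibitor_loop":
            continue
        seq = _strand_seq(design, name)
        res = cofold(scaffold_seq, seq, model)
        inter = {i for i, j in res.intermolecular_pairs}
        hits = sum(1 for k in range(loop_rel[0], loop_rel[1]) if k in inter)
        if hits / (loop_rel[1] - loop_rel[0]) >= rule.not_block_min_frac:
            return True
    return False


# --------------------------------------------------------------------------
# State prediction
# --------------------------------------------------------------------------


def _antispacer_positions(design: CgRNADesign) -> List[int]:
    out: List[int] = []
    for dom in ("antispacer_5p", "antispacer_3p"):
        a, b = design.cgrna.span(dom)
        out.extend(range(a, b))
    return out


def ensemble_seed_access(
    design: CgRNADesign, species_seq: str, model: EnergyModel
) -> float:
    """Seed accessibility: one minus the mean Boltzmann probability that a
    seed position is sequestered by the antispacer.

    Sequestration by the cis-regulatory antispacer is what blocks R-loop
    nucleation; transient pairing of the released seed with short
    single-stranded regions elsewhere (e.g. the hairpin loop) is not a
    displacement barrier and is not counted.  The ensemble average is used
    rather than one minimum-energy traceback because the pair-weight model
    admits large co-optimal manifolds; the ensemble quantity is smooth and
    basis-independent, in the spirit of partition-function evaluation of
    nucleic-acid devices.
    """
    sensor = design.sensor_sequence
    assert sensor is not None
    P = cofold_pair_probabilities(sensor, species_seq, model).p
    a, b = design.seed_span
    anti = _antispacer_positions(design)
    sequestered = P[np.ix_(range(a, b), anti)].sum(axis=1)
    return float((1.0 - sequestered).mean())


def mfe_seed_access(
    design: CgRNADesign, species_seq: str, model: EnergyModel
) -> float:
    """Fraction of seed positions not paired to the antispacer in the
    minimum-energy complex structure."""
    sensor = design.sensor_sequence
    assert sensor is not None
    res = cofold(sensor, species_seq, model)
    a, b = design.seed_span
    anti = set(_antispacer_positions(design))
    hits = sum(
        1 for i, j in res.pairs
        if (a <= i < b and j in anti) or (a <= j < b and i in anti)
    )
    return 1.0 - hits / (b - a)


_sensor_seed_access = mfe_seed_access


def predict_state(
    design: CgRNADesign,
    present_inputs: Iterable[str],
    rule: Optional[ActivationRule] = None,
    model: Optional[EnergyModel] = None,
) -> StatePrediction:
    """ON/OFF call for a design under a set of present inputs.

    Pipeline: resolve antisense neutralization, assemble split-trigger pairs
    (checked by assembly-domain hybridization), test scaffold-loop blocking,
    then co-fold every surviving activating species with the sensor module.
    ACTIVE requires seed accessibility >= ``theta_seed`` for at least one
    species and no scaffold block; sensor-less (NOT-architecture) designs are
    ACTIVE by default until blocked.
    """
    rule = rule or ActivationRule()
    model = model or EnergyModel()
    present = list(present_inputs)
    species, assembled, neutralized = activating_species(design, present, model, rule)
    blocked = _blocked(design, present, model, rule)

    per_species: Dict[str, float] = {}
    if design.sensor_span is not None:
        for label, seq in species:
            per_species[label] = _sensor_seed_access(design, seq, model)
        best = max(per_species.values(), default=0.0)
        state = ACTIVE if (best >= rule.theta_seed and not blocked) else INACTIVE
    else:
        best = 1.0 if not blocked else 0.0
        state = ACTIVE if not blocked else INACTIVE

    return StatePrediction(
        state=state,
        seed_accessibility=best,
        blocked=blocked,
        species_accessibility=per_species,
        assembled=assembled,
        neutralized=neutralized,
    )


# --------------------------------------------------------------------------
# Truth tables
# --------------------------------------------------------------------------


@dataclass
class TruthTable:
    inputs: List[str]
    rows: List[Dict[str, object]]

    @property
    def n_pass(self) -> int:
        return sum(1 for r in self.rows if r["pass"])

    @property
    def all_pass(self) -> bool:
        return self.n_pass == len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def truth_table(
    design: CgRNADesign,
    rule: Optional[ActivationRule] = None,
    model: Optional[EnergyModel] = None,
) -> TruthTable:
    """Enumerate all 2^k input combinations through :func:`predict_state`.

    The expected column is the independent Boolean evaluation of the gate
    expression; each row records predicted state and pass/fail.
    """
    names = design.gate.inputs
    if len(names) > 3:
        raise ValueError("supported architectures have at most 3 inputs")
    rows: List[Dict[str, object]] = []
    for bits in itertools.product((0, 1), repeat=len(names)):
        present = [n for n, b in zip(names, bits) if b]
        assignment = {n: bool(b) for n, b in zip(names, bits)}
        expected = eval_expr(design.gate.expression, assignment)
        pred = predict_state(design, present, rule, model)
        predicted_on = pred.state == ACTIVE
        row: Dict[str, object] = {n: b for n, b in zip(names, bits)}
        row.update(
            {
                "predicted": pred.state,
                "expected": ACTIVE if expected else INACTIVE,
                "pass": predicted_on == expected,
                "seed_accessibility": round(pred.seed_accessibility, 4),
            }
        )
        rows.append(row)
    return TruthTable(inputs=names, rows=rows)


# --------------------------------------------------------------------------
# Crosstalk matrices
# --------------------------------------------------------------------------


@dataclass
class CrosstalkMatrix:
    labels: List[str]
    states: np.ndarray  # dtype=object, ACTIVE/INACTIVE
    accessibility: np.ndarray

    @property
    def n_entries(self) -> int:
        return self.states.size

    @property
    def cognate_active(self) -> int:
        return sum(
            1 for k in range(len(self.labels)) if self.states[k, k] == ACTIVE
        )

    @property
    def noncognate_inactive(self) -> int:
        k = len(self.labels)
        return sum(
            1
            for i in range(k)
            for j in range(k)
            if i != j and self.states[i, j] == INACTIVE
        )

    @property
    def orthogonal(self) -> bool:
        k = len(self.labels)
        return self.cognate_active == k and self.noncognate_inactive == k * (k - 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states, index=self.labels, columns=self.labels
        )


def foreign_activation(
    design: CgRNADesign,
    other: CgRNADesign,
    rule: Optional[ActivationRule] = None,
    model: Optional[EnergyModel] = None,
) -> Tuple[str, float]:
    """State of *design* exposed to the cognate activating triggers of *other*."""
    rule = rule or ActivationRule()
    model = model or EnergyModel()
    species, _, _ = activating_species(
        other, [n for n in other.gate.inputs
                if other.trigger_info[n].kind in ("toehold_path", "loop_path", "split")],
        model, rule,
    )
    if design.sensor_span is None:
        return ACTIVE, 1.0
    best = 0.0
    for _, seq in species:
        best = max(best, _sensor_seed_access(design, seq, model))
    return (ACTIVE if best >= rule.theta_seed else INACTIVE), best


def crosstalk_matrix(
    panel: Sequence[CgRNADesign],
    rule: Optional[ActivationRule] = None,
    model: Optional[EnergyModel] = None,
) -> CrosstalkMatrix:
    """k x k evaluation: cgRNA_i against the trigger set of design_j."""
    if not panel:
        raise ValueError("panel must be non-empty")
    rule = rule or ActivationRule()
    model = model or EnergyModel()
    k = len(panel)
    labels = [d.cgrna.name if d.cgrna.name != "cgRNA" else f"design_{i}"
              for i, d in enumerate(panel)]
    states = np.empty((k, k), dtype=object)
    access = np.zeros((k, k))
    for i, di in enumerate(panel):
        for j, dj in enumerate(panel):
            if i == j:
                pred = predict_state(di, di.gate.inputs, rule, model)
                states[i, j], access[i, j] = pred.state, pred.seed_accessibility
            else:
                states[i, j], access[i, j] = foreign_activation(di, dj, rule, model)
    return CrosstalkMatrix(labels=labels, states=states, accessibility=access)


# --------------------------------------------------------------------------
# Fold reduction
# --------------------------------------------------------------------------


@dataclass
class FoldReductionRecord:
    """Dynamic-range metric: reporter signal with decoy over signal with trigger.

    ``fluor_decoy`` / ``fluor_trigger`` are geometric means of the replicate
    measurements (fluorescence distributions are approximately log-normal);
    ``sd_pairwise`` is the sample s.d. over all decoy x trigger pairwise
    ratios (nine for 3 x 3 replicates).
    """

    fluor_decoy: float
    fluor_trigger: float
    fold_reduction: float
    sd_pairwise: float
    n_ratios: int


def fold_reduction(
    decoy_values: Sequence[float], trigger_values: Sequence[float]
) -> FoldReductionRecord:
    if not len(decoy_values) or not len(trigger_values):
        raise ValueError("replicate lists must be non-empty")
    d = np.asarray(decoy_values, dtype=float)
    t = np.asarray(trigger_values, dtype=float)
    if (d <= 0).any() or (t <= 0).any():
        raise ValueError("fluorescence values must be > 0")
    gm_d = float(np.exp(np.log(d).mean()))
    gm_t = float(np.exp(np.log(t).mean()))
    ratios = (d[:, None] / t[None, :]).ravel()
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return FoldReductionRecord(
        fluor_decoy=gm_d,
        fluor_trigger=gm_t,
        fold_reduction=gm_d / gm_t,
        sd_pairwise=sd,
        n_ratios=int(ratios.size),
    )
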