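"""Assign nucleotides to designable domains by seeded stochastic local search.

The designer fills the placeholder domains of a compiled design (toehold,
bulge, sequestering-hairpin loop, assembly domains, safety-hairpin loops,
extended scaffold loop) by hill-climbing with sideways moves on a weighted
thermodynamic objective:

* ensemble defect of the sensor module against its OFF-state target
  (the spacer-sequestering stem must dominate the ensemble),
* ON-state seed exposure: seed accessibility of the sensor co-folded with
  each required activating species (and, for NOT inputs, the blocking
  fraction of the extended scaffold loop),
* unwanted trigger self-structure beyond the mandated safety hairpin,
* in panel mode, crosstalk against previously accepted designs.

Single-base moves propagate to complementary partner domains by
reconstruction: every candidate is recompiled from the free-domain
assignment, so derived strands can never drift out of complementarity.
The spacer and scaffold are never mutated.  Runs are deterministic given
the seed.

The first restart starts from deterministic pattern tiles in the regime
where the architecture's thermodynamic margins hold; later restarts draw
random domains from per-domain reduced alphabets (see DOMAIN_ALPHABETS).
Moves explore single-base substitutions within those alphabets under
GC-content and homopolymer constraints; smooth ensemble quantities provide
the search gradient while the evaluator's discrete minimum-energy calls
enter as unit-step penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .circuit_model import Architecture, CgRNADesign, GateSpec, TargetSite, gc_fraction, max_homopolymer
from .compiler import CompilerParams, compile_design, free_domain_spec
from .evaluator import (
    ActivationRule,
    activating_species,
    _blocked,
    ensemble_seed_access,
    mfe_seed_access,
)
from .thermo import EnergyModel, cofold_pair_probabilities, ensemble_defect, fold_mfe

__all__ = [
    "DesignObjective",
    "DesignRunConfig",
    "DesignResult",
    "design_sequences",
    "design_orthogonal_panel",
]


class DesignError(ValueError):
    """Raised for infeasible design constraints."""


#: Alphabets the search explores, per designable domain, in the spirit of
#: reduced-alphabet strand-displacement design.  Against the purine
#: low-structure spacers the fixture generator emits, the sensor free
#: domains (toehold, hairpin loop) are pyrimidine like the antispacer:
#: pyrimidines cannot pair pyrimidines and purines cannot pair purines, so
#: the only legal channels in the OFF sensor are the designed
#: spacer:antispacer stem plus a couple of boundary pairs that the
#: non-crossing constraint pins, and the all-purine triggers (reverse
#: complements of the sensed region) are essentially structure-free.  The
#: bulge stays purine so the sensor pyrimidine count equals the spacer
#: length, which pins the sequestering-stem register uniquely; its trigger
#: complement then hands the activated duplex a strict displacement margin.
#: Letter multisets double as proposal distributions (repeated letters bias
#: mutation): pyrimidine domains are C-biased because C pairs only G while
#: U also wobble-pairs G, so C-rich free domains admit fewer spurious
#: channels.
DOMAIN_ALPHABETS: Dict[str, str] = {
    "toehold": "CCU",
    "bulge": "GGA",
    "hairpin_loop": "CCU",
    "assembly": "CCU",
    "sh_loop": "AC",
    "scaffold_loop_ext": "ACGU",
}


@dataclass(frozen=True)
class DesignObjective:
    """Weights of the design objective (all >= 0, at least one > 0)."""

    w_off_defect: float = 0.2
    w_on_exposure: float = 20.0
    w_trigger_structure: float = 0.5
    w_crosstalk: float = 20.0
    trigger_structure_allowance: int = 3

    def __post_init__(self) -> None:
        ws = (self.w_off_defect, self.w_on_exposure, self.w_trigger_structure, self.w_crosstalk)
        if any(w < 0 for w in ws):
            raise ValueError("objective weights must be >= 0")
        if not any(w > 0 for w in ws):
            raise ValueError("at least one objective weight must be > 0")


@dataclass(frozen=True)
class DesignRunConfig:
    """Search configuration; hill-climb with sideways moves, seeded."""

    seed: int = 1
    max_iters: int = 150
    restarts: int = 2  # restart 0 starts from the deterministic pattern tiles
    gc_min: float = 0.3
    gc_max: float = 0.7
    max_homopolymer: int = 3

    def __post_init__(self) -> None:
        if self.max_iters <= 0 or self.restarts <= 0:
            raise ValueError("max_iters and restarts must be > 0")
        if not (0.0 < self.gc_min < self.gc_max < 1.0):
            raise ValueError("need 0 < gc_min < gc_max < 1")


@dataclass
class DesignResult:
    design: CgRNADesign
    trace: List[Dict[str, float]]
    converged: bool
    warnings: List[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Constrained random domains
# --------------------------------------------------------------------------


def _gc_ok(seq: str, cfg: DesignRunConfig) -> bool:
    if len(seq) < 4:  # GC windows are meaningless for very short domains
        return True
    return cfg.gc_min <= gc_fraction(seq) <= cfg.gc_max


def _constraints_ok(seq: str, cfg: DesignRunConfig) -> bool:
    return _gc_ok(seq, cfg) and max_homopolymer(seq) <= cfg.max_homopolymer


#: Deterministic tile used to seed the first restart of the search; random
#: draws from DOMAIN_ALPHABETS seed later restarts.  The tiles sit in the
#: C-rich (or G-lean purine) regime in which the architecture's strict
#: thermodynamic margins hold, so the climb starts near a working design.
DOMAIN_PATTERNS: Dict[str, str] = {
    "toehold": "CCU",
    "bulge": "GGAA",
    "hairpin_loop": "CCU",
    "assembly": "CCU",
    "sh_loop": "CA",
    "scaffold_loop_ext": "GACU",
}


def _patterned_domain(name: str, length: int, cfg: DesignRunConfig) -> Optional[str]:
    tile = DOMAIN_PATTERNS.get(name)
    if tile is None:
        return None
    seq = (tile * (length // len(tile) + 1))[:length]
    return seq if _constraints_ok(seq, cfg) else None


def _random_domain(
    rng: np.random.RandomState, length: int, alphabet: str, cfg: DesignRunConfig
) -> str:
    letters = list(alphabet)
    for _ in range(2000):
        seq = "".join(rng.choice(letters) for _ in range(length))
        if _constraints_ok(seq, cfg):
            return seq
    raise DesignError(
        f"cannot satisfy GC window [{cfg.gc_min}, {cfg.gc_max}] and homopolymer "
        f"limit for a {length}-nt domain over alphabet {alphabet!r}"
    )


# --------------------------------------------------------------------------
# Objective evaluation
# --------------------------------------------------------------------------


def _required_species(
    design: CgRNADesign, model: EnergyModel, rule: ActivationRule
) -> List[Tuple[str, str]]:
    """Species whose ON behaviour the design is responsible for.

    Each single-strand activator individually; each split pair as its
    assembled functional core.
    """
    species: List[Tuple[str, str]] = []
    seen_pairs = set()
    for name in design.gate.inputs:
        info = design.trigger_info[name]
        if info.kind in ("toehold_path", "loop_path"):
            species.append((name, design.triggers[name].sequence))
        elif info.kind == "split":
            pair = tuple(sorted((name, info.partner)))  # type: ignore[arg-type]
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            first, second = sorted(pair, key=lambda nm: design.trigger_info[nm].order)
            from .evaluator import _assembled_core

            species.append((f"{first}+{second}", _assembled_core(design, first, second)))
    return species


def _hairpin_allowed_pairs(design: CgRNADesign, name: str) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Spans (arm, occluded core start) of the mandated safety hairpin, if any."""
    strand = design.triggers[name]
    info = design.trigger_info[name]
    if info.kind != "split" or info.core_span is None:
        return None
    try:
        arm = strand.span(f"sh_arm_{name}")
    except KeyError:
        return None
    stem = arm[1] - arm[0]
    return arm, (info.core_span[0], info.core_span[0] + stem)


def _trigger_structure_penalty(
    design: CgRNADesign, model: EnergyModel, allowance: int
) -> float:
    total = 0.0
    for name in design.gate.inputs:
        info = design.trigger_info[name]
        if info.kind in ("inhibitor_loop",):
            continue
        strand = design.triggers[name]
        res = fold_mfe(strand.sequence, model)
        mandated = _hairpin_allowed_pairs(design, name)
        unwanted = 0
        for i, j in res.pairs:
            if mandated is not None:
                (a0, a1), (c0, c1) = mandated
                if a0 <= i < a1 and c0 <= j < c1:
                    continue
            unwanted += 1
        total += max(0, unwanted - allowance)
    return total


def _block_fraction(design: CgRNADesign, name: str, model: EnergyModel) -> float:
    """Fraction of extended-scaffold-loop positions paired by inhibitor *name*."""
    from .thermo import cofold

    loop_span = design.cgrna.span("scaffold_loop_ext")
    sc_a, _ = design.scaffold_span
    rel = (loop_span[0] - sc_a, loop_span[1] - sc_a)
    res = cofold(design.scaffold_sequence, design.triggers[name].sequence, model)
    inter = {i for i, j in res.intermolecular_pairs}
    return sum(1 for k in range(rel[0], rel[1]) if k in inter) / (rel[1] - rel[0])


def _decoy_leak(design: CgRNADesign, model: EnergyModel) -> float:
    """Non-cognate leakage: seed accessibility against shuffled decoys.

    Averaged over a few independent dinucleotide shuffles of each trigger so
    the term reflects shuffle-class leakage rather than one arbitrary
    realization (a single draw makes the search landscape needlessly noisy).
    """
    from .compiler import dinucleotide_shuffle

    worst = 0.0
    for idx, name in enumerate(sorted(design.triggers)):
        strand = design.triggers[name]
        if design.trigger_info[name].kind in ("inhibitor_loop", "inhibitor_antisense"):
            continue
        vals = []
        for k in range(2):
            rng = np.random.RandomState((design.params.decoy_seed + idx + 7777 * k) % (2**31))  # type: ignore[union-attr]
            shuf = dinucleotide_shuffle(strand.sequence, rng)
            vals.append(ensemble_seed_access(design, shuf, model))
        if vals:
            worst = max(worst, sum(vals) / len(vals))
    return worst


def _score(
    design: CgRNADesign,
    objective: DesignObjective,
    model: EnergyModel,
    rule: ActivationRule,
    rivals: Sequence[CgRNADesign],
) -> Dict[str, float]:
    comp: Dict[str, float] = {"off_defect": 0.0, "on_exposure": 0.0,
                              "trigger_structure": 0.0, "crosstalk": 0.0}
    sensor = design.sensor_sequence
    if sensor is not None and objective.w_off_defect > 0:
        target = design.target_off_structure[: len(sensor)]
        comp["off_defect"] = ensemble_defect(sensor, target, model).defect

    if objective.w_on_exposure > 0:
        exposure_losses: List[float] = []
        if sensor is not None:
            for _, seq in _required_species(design, model, rule):
                exposure_losses.append(1.0 - ensemble_seed_access(design, seq, model))
        seen_pairs = set()
        for name in design.gate.inputs:
            info = design.trigger_info[name]
            if info.kind == "inhibitor_loop":
                exposure_losses.append(1.0 - _block_fraction(design, name, model))
            elif info.kind == "split":
                pair = tuple(sorted((name, info.partner)))  # type: ignore[arg-type]
                if pair not in seen_pairs:
                    seen_pairs.add(pair)
                    from .evaluator import _assembly_fraction

                    exposure_losses.append(
                        1.0 - _assembly_fraction(design, name, info.partner, model)  # type: ignore[arg-type]
                    )
        if exposure_losses:
            comp["on_exposure"] = max(exposure_losses)

    if objective.w_trigger_structure > 0:
        comp["trigger_structure"] = _trigger_structure_penalty(
            design, model, objective.trigger_structure_allowance
        )

    if objective.w_crosstalk > 0 and design.sensor_span is not None:
        # smooth ensemble leakage plus a unit step whenever the evaluator's
        # minimum-energy call would actually fire on a non-cognate species
        worst = _decoy_leak(design, model)
        step = 0.0
        for dec_name, decoy in design.decoys.items():
            base = dec_name.removeprefix("decoy_")
            if design.trigger_info[base].kind in ("inhibitor_loop", "inhibitor_antisense"):
                continue
            if mfe_seed_access(design, decoy.sequence, model) >= rule.theta_seed:
                step = 1.0
        # lone split triggers must not activate on their own
        for name in design.gate.inputs:
            if design.trigger_info[name].kind != "split":
                continue
            seq = design.triggers[name].sequence
            worst = max(worst, ensemble_seed_access(design, seq, model))
            if mfe_seed_access(design, seq, model) >= rule.theta_seed:
                step = 1.0
        for rival in rivals:
            for _, seq in _required_species(rival, model, rule):
                worst = max(worst, ensemble_seed_access(design, seq, model))
                if mfe_seed_access(design, seq, model) >= rule.theta_seed:
                    step = 1.0
            if rival.sensor_span is not None:
                for _, seq in _required_species(design, model, rule):
                    worst = max(worst, ensemble_seed_access(rival, seq, model))
                    if mfe_seed_access(rival, seq, model) >= rule.theta_seed:
                        step = 1.0
        comp["crosstalk"] = worst + step

    comp["total"] = (
        objective.w_off_defect * comp["off_defect"]
        + objective.w_on_exposure * comp["on_exposure"]
        + objective.w_trigger_structure * comp["trigger_structure"]
        + objective.w_crosstalk * comp["crosstalk"]
    )
    return comp


# --------------------------------------------------------------------------
# Hill climb
# --------------------------------------------------------------------------


def _recompile(design: CgRNADesign, free: Dict[str, str]) -> CgRNADesign:
    variant = 2 if design.gate.architecture == Architecture.A_AND_NOT_B_V2 else None
    return compile_design(
        design.gate, design.site, params=design.params, free_seqs=free, variant=variant
    )


def design_sequences(
    design: CgRNADesign,
    objective: Optional[DesignObjective] = None,
    config: Optional[DesignRunConfig] = None,
    model: Optional[EnergyModel] = None,
    rule: Optional[ActivationRule] = None,
    rivals: Sequence[CgRNADesign] = (),
) -> DesignResult:
    """Fill all placeholder domains of *design*, minimizing the objective.

    Hill-climbing with sideways moves and random restarts; the accepted-move
    score trace is non-increasing within each restart, and the best restart
    wins.  Non-convergence (residual ON-exposure or crosstalk loss) is
    reported through ``warnings`` on the result, never as an exception.
    """
    objective = objective or DesignObjective()
    config = config or DesignRunConfig()
    model = model or EnergyModel()
    rule = rule or ActivationRule()
    if design.site is None or design.params is None:
        raise DesignError("design must carry its target site and compiler params")

    spec = free_domain_spec(design.gate.architecture, design.params)
    if not spec:
        raise DesignError("design has no designable domains")
    existing = {
        k: v for k, v in _current_free(design).items() if v is not None
    }

    best_free: Optional[Dict[str, str]] = None
    best_comp: Optional[Dict[str, float]] = None
    trace: List[Dict[str, float]] = []

    flat_positions = [
        (name, off) for name, length in sorted(spec.items()) for off in range(length)
    ]

    for restart in range(config.restarts):
        rng = np.random.RandomState((config.seed + 7919 * restart) % (2**31))
        free = {}
        for name, length in sorted(spec.items()):
            seq = existing.get(name)
            if seq is None and restart == 0:
                seq = _patterned_domain(name, length, config)
            if seq is None:
                seq = _random_domain(
                    rng, length, DOMAIN_ALPHABETS.get(name, "ACGU"), config
                )
            free[name] = seq
        current = _recompile(design, free)
        comp = _score(current, objective, model, rule, rivals)
        trace.append({"restart": restart, "iter": 0, **comp})
        for it in range(1, config.max_iters + 1):
            name, off = flat_positions[rng.randint(len(flat_positions))]
            alphabet = DOMAIN_ALPHABETS.get(name, "ACGU")
            old = free[name]
            choices = [b for b in alphabet if b != old[off]]
            if not choices:
                continue
            newbase = choices[rng.randint(len(choices))]
            candidate_dom = old[:off] + newbase + old[off + 1 :]
            if not _constraints_ok(candidate_dom, config):
                continue
            cand_free = dict(free)
            cand_free[name] = candidate_dom
            cand_design = _recompile(design, cand_free)
            cand_comp = _score(cand_design, objective, model, rule, rivals)
            if cand_comp["total"] <= comp["total"]:
                free, comp = cand_free, cand_comp
                trace.append({"restart": restart, "iter": it, **comp})
        if best_comp is None or comp["total"] < best_comp["total"]:
            best_comp, best_free = comp, free

    assert best_free is not None and best_comp is not None
    final = _recompile(design, best_free)
    warnings: List[str] = []
    if best_comp["on_exposure"] > 1.0 - (rule.theta_seed):
        warnings.append(
            f"ON-state exposure did not converge (residual loss "
            f"{best_comp['on_exposure']:.3f})"
        )
    if best_comp["crosstalk"] >= 1.0:
        # the unit step fires only when a non-cognate species actually
        # activates the sensor under the evaluator's minimum-energy call
        warnings.append(
            f"a non-cognate species still activates this design "
            f"(crosstalk score {best_comp['crosstalk']:.3f})"
        )
    final.warnings.extend(warnings)
    return DesignResult(
        design=final, trace=trace, converged=not warnings, warnings=warnings
    )


def _current_free(design: CgRNADesign) -> Dict[str, Optional[str]]:
    """Free-domain assignment currently carried by a design (None = placeholder)."""
    out: Dict[str, Optional[str]] = {}
    spec = free_domain_spec(design.gate.architecture, design.params)  # type: ignore[arg-type]
    for name in spec:
        seq: Optional[str] = None
        for strand in (design.cgrna, *design.triggers.values()):
            try:
                dom = strand.domain(name)
            except KeyError:
                continue
            seq = dom.sequence
            break
        if seq is None and name == "sh_loop":
            for strand in design.triggers.values():
                for dom in strand.domains:
                    if dom.name.startswith("sh_loop_") and dom.sequence is not None:
                        seq = dom.sequence
                        break
        if seq is None and name == "assembly":
            for strand in design.triggers.values():
                for dom in strand.domains:
                    if dom.name.startswith("assembly_") and dom.sequence is not None:
                        seq = dom.sequence
                        break
                if seq is not None:
                    break
        out[name] = seq
    return out


# --------------------------------------------------------------------------
# Orthogonal panels
# --------------------------------------------------------------------------


def design_orthogonal_panel(
    sites: Sequence[TargetSite],
    gate_template: GateSpec,
    objective: Optional[DesignObjective] = None,
    config: Optional[DesignRunConfig] = None,
    params: Optional[CompilerParams] = None,
    model: Optional[EnergyModel] = None,
    rule: Optional[ActivationRule] = None,
) -> List[DesignResult]:
    """Design one cgRNA per target site, sequentially penalizing crosstalk.

    Each design is optimized against all previously accepted designs (both
    directions: its sensor vs their triggers, their sensors vs its triggers);
    a second round-robin pass then refines every design against the full
    panel, since the first design never saw its successors.  A panel of one
    degenerates to :func:`design_sequences`.  Spacers must be pairwise
    distinct.
    """
    if not sites:
        raise DesignError("need at least one target site")
    spacers = [s.spacer for s in sites]
    if len(set(spacers)) != len(spacers):
        raise DesignError("panel spacers must be pairwise distinct")
    objective = objective or DesignObjective()
    config = config or DesignRunConfig()
    params = params or CompilerParams()
    results: List[DesignResult] = []
    accepted: List[CgRNADesign] = []
    for i, site in enumerate(sites):
        skeleton = compile_design(gate_template, site, params=params)
        skeleton.cgrna.name = f"cgRNA_{i + 1}"
        cfg_i = DesignRunConfig(
            seed=(config.seed + 104729 * i) % (2**31),
            max_iters=config.max_iters,
            restarts=config.restarts,
            gc_min=config.gc_min,
            gc_max=config.gc_max,
            max_homopolymer=config.max_homopolymer,
        )
        res = design_sequences(
            skeleton, objective, cfg_i, model=model, rule=rule, rivals=accepted
        )
        res.design.cgrna.name = f"cgRNA_{i + 1}"
        results.append(res)
        accepted.append(res.design)

    if len(sites) > 1:  # refinement pass with the full rival set
        for i in range(len(sites)):
            rivals = [d for k, d in enumerate(accepted) if k != i]
            cfg_i = DesignRunConfig(
                seed=(config.seed + 104729 * i + 31337) % (2**31),
                max_iters=config.max_iters,
                restarts=1,
                gc_min=config.gc_min,
                gc_max=config.gc_max,
                max_homopolymer=config.max_homopolymer,
            )
            res = design_sequences(
                accepted[i], objective, cfg_i, model=model, rule=rule, rivals=rivals
            )
            res.design.cgrna.name = f"cgRNA_{i + 1}"
            results[i] = res
            accepted[i] = res.design
    return results
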