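"""Compile Boolean gate specifications into domain-level cgRNA designs.

Each supported architecture is laid out from a target site and a parameter
set whose defaults are the reference construct choices: a 4-nt bulge in the
middle of the spacer-sequestering stem, a 17-nt stem-interaction domain on
the split AND trigger, a 20-nt extended scaffold loop for NOT inputs, and a
5x expression ratio for the antisense NOT variant.

Layout of a single-input cgRNA (5'->3'):

    [toehold 15][antispacer_5p][bulge 4][antispacer_3p][hairpin loop 12]
    [spacer 20][scaffold 76]

The antispacer is the exact reverse complement of the spacer, split by the
bulge; in the OFF state it sequesters the full spacer with the PAM-proximal
seed paired at the toehold-proximal end of the stem.  Trigger strands are
derived by reverse complement from the cgRNA domains, so compilation is
byte-deterministic.  Designable ("free") domains -- toehold, bulge, hairpin
loop, assembly, safety-hairpin loops, extended scaffold loop -- may be left
as placeholders for the sequence designer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .circuit_model import (
    Architecture,
    CgRNADesign,
    Domain,
    GateSpec,
    Strand,
    TargetSite,
    TriggerInfo,
    reverse_complement,
)

__all__ = [
    "CompilerParams",
    "SCAFFOLD_SEQUENCE",
    "SCAFFOLD_TETRALOOP_SPAN",
    "compile_design",
    "compile_gate",
    "free_domain_spec",
    "dinucleotide_shuffle",
]

#: Constant S. pyogenes sgRNA scaffold 3' of the spacer (repeat:anti-repeat
#: duplex with GAAA tetraloop, nexus and terminal hairpins).
SCAFFOLD_SEQUENCE = (
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC"
)

#: 0-based half-open span of the GAAA tetraloop replaced in NOT-style designs.
SCAFFOLD_TETRALOOP_SPAN = (12, 16)


class CompileError(ValueError):
    """Raised for unsupported architectures or inconsistent parameters."""


@dataclass(frozen=True)
class CompilerParams:
    """Structural parameters of the architectures (lengths in nt).

    Reference-construct values: ``bulge_len=4`` (the bulge screen ran 0-6 nt),
    ``and_triggerA_stem_len=17`` (shortened from 20), ``scaffold_loop_ext_len=20``,
    ``not_b_expression_ratio=5.0``.  The remaining defaults are this package's
    choices: a 15-nt toehold (typical for strand-displacement activation), a
    12-nt sequestering-hairpin loop (enough foothold for a loop-binding
    trigger), 20-nt assembly domains and a 6-bp/4-nt safety hairpin.
    """

    toehold_len: int = 15
    bulge_len: int = 4
    bulge_offset: Optional[int] = None  # antispacer nt 5' of the bulge; None=center
    hairpin_loop_len: int = 12
    scaffold_loop_ext_len: int = 20
    and_assembly_len: int = 20
    and_triggerA_stem_len: int = 17
    or_and_b_stem_len: int = 13
    or_b_clamp_len: int = 8  # loop-path triggers clamp this many 3' toehold nt
    safety_hairpin_stem: int = 6
    safety_hairpin_loop: int = 4
    not_b_expression_ratio: float = 5.0
    decoy_seed: int = 101

    def validate(self, site: TargetSite) -> None:
        if not (0 <= self.bulge_len <= 6):
            raise CompileError("bulge_len must be in [0, 6]")
        for name in (
            "toehold_len",
            "hairpin_loop_len",
            "scaffold_loop_ext_len",
            "and_assembly_len",
            "and_triggerA_stem_len",
            "safety_hairpin_stem",
            "safety_hairpin_loop",
        ):
            if getattr(self, name) <= 0:
                raise CompileError(f"{name} must be > 0")
        if self.and_triggerA_stem_len > len(site.spacer):
            raise CompileError("and_triggerA_stem_len exceeds the spacer stem length")
        if self.and_assembly_len < 8:
            raise CompileError("assembly domains shorter than 8 nt are unreliable")


# --------------------------------------------------------------------------
# Free-domain bookkeeping
# --------------------------------------------------------------------------


def free_domain_spec(
    arch: Architecture, params: CompilerParams
) -> Dict[str, int]:
    """Designable domain names -> lengths for an architecture."""
    sensor = {
        "toehold": params.toehold_len,
        "hairpin_loop": params.hairpin_loop_len,
    }
    if params.bulge_len > 0:
        sensor["bulge"] = params.bulge_len
    if arch == Architecture.SINGLE or arch == Architecture.OR2:
        return dict(sensor)
    if arch == Architecture.AND2 or arch == Architecture.A_OR_B_AND_C:
        return {
            **sensor,
            "assembly": params.and_assembly_len,
            "sh_loop": params.safety_hairpin_loop,
        }
    if arch == Architecture.NOT1:
        return {"scaffold_loop_ext": params.scaffold_loop_ext_len}
    if arch == Architecture.A_AND_NOT_B_V1:
        return {**sensor, "scaffold_loop_ext": params.scaffold_loop_ext_len}
    if arch == Architecture.A_AND_NOT_B_V2:
        return dict(sensor)
    raise CompileError(f"unsupported architecture {arch}")


def _dom(name: str, role: str, seq: Optional[str], length: int) -> Domain:
    return Domain(name=name, role=role, sequence=seq, length=length)


def _rc(seq: Optional[str]) -> Optional[str]:
    return None if seq is None else reverse_complement(seq)


# --------------------------------------------------------------------------
# Decoys: dinucleotide-preserving shuffle
# --------------------------------------------------------------------------


def dinucleotide_shuffle(seq: str, rng: np.random.RandomState) -> str:
    """Shuffle preserving the exact dinucleotide composition.

    Performs a seeded random Eulerian walk over the dinucleotide edge
    multigraph (retrying when the walk dead-ends early), which preserves the
    first and last nucleotide as a side effect.
    """
    if len(seq) < 3:
        return seq
    edges: Dict[str, List[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    for _ in range(1000):
        pool = {k: list(v) for k, v in edges.items()}
        for v in pool.values():
            rng.shuffle(v)
        out = [seq[0]]
        node = seq[0]
        while pool.get(node):
            node = pool[node].pop()
            out.append(node)
        if len(out) == n_edges + 1:
            return "".join(out)
    return seq  # pathological composition; keep the original


# --------------------------------------------------------------------------
# Sensor construction shared by the activating architectures
# --------------------------------------------------------------------------


def _sensor_domains(
    site: TargetSite, params: CompilerParams, free: Dict[str, Optional[str]]
) -> Tuple[List[Domain], Dict[str, str]]:
    """cgRNA sensor domain list plus the derived antispacer halves."""
    spacer = site.spacer
    n = len(spacer)
    a5_len = params.bulge_offset if params.bulge_offset is not None else n // 2
    if not (0 < a5_len < n):
        raise CompileError("bulge_offset must fall strictly inside the antispacer")
    antispacer = reverse_complement(spacer)
    a5p, a3p = antispacer[:a5_len], antispacer[a5_len:]
    doms = [
        _dom("toehold", "toehold", free.get("toehold"), params.toehold_len),
        _dom("antispacer_5p", "antispacer_5p", a5p, a5_len),
    ]
    if params.bulge_len > 0:
        doms.append(_dom("bulge", "bulge", free.get("bulge"), params.bulge_len))
    doms += [
        _dom("antispacer_3p", "antispacer_3p", a3p, n - a5_len),
        _dom(
            "hairpin_loop", "hairpin_loop", free.get("hairpin_loop"), params.hairpin_loop_len
        ),
        _dom("spacer", "spacer", spacer, n),
    ]
    return doms, {"antispacer_5p": a5p, "antispacer_3p": a3p}


def _scaffold_domains(
    params: CompilerParams, extend_loop: bool, free: Dict[str, Optional[str]]
) -> List[Domain]:
    if not extend_loop:
        return [_dom("scaffold", "scaffold", SCAFFOLD_SEQUENCE, len(SCAFFOLD_SEQUENCE))]
    a, b = SCAFFOLD_TETRALOOP_SPAN
    return [
        _dom("scaffold_5p", "scaffold", SCAFFOLD_SEQUENCE[:a], a),
        _dom(
            "scaffold_loop_ext",
            "scaffold_loop_ext",
            free.get("scaffold_loop_ext"),
            params.scaffold_loop_ext_len,
        ),
        _dom(
            "scaffold_3p",
            "scaffold",
            SCAFFOLD_SEQUENCE[b:],
            len(SCAFFOLD_SEQUENCE) - b,
        ),
    ]


def _off_structure(design_domains: List[Domain]) -> str:
    """Dot-bracket OFF target: antispacer '(' pairs spacer ')', rest dots."""
    chars: List[str] = []
    for d in design_domains:
        if d.role in ("antispacer_5p", "antispacer_3p"):
            chars.append("(" * d.length)
        elif d.role == "spacer":
            chars.append(")" * d.length)
        else:
            chars.append("." * d.length)
    return "".join(chars)


def _placeholder_or(seq: Optional[str], name: str, role: str, length: int) -> Domain:
    return _dom(name, role, seq, length)


def _seg(seq: Optional[str], a: int, b: int) -> Optional[str]:
    return None if seq is None else seq[a:b]


def _safety_arm(core: Optional[str], stem: int) -> Optional[str]:
    """5' hairpin arm sequestering the first *stem* nt of a split-trigger core."""
    return None if core is None else reverse_complement(core[:stem])


# --------------------------------------------------------------------------
# Architecture builders
# --------------------------------------------------------------------------


def _ext_segment(
    free: Dict[str, Optional[str]], a5p: str, a3p: str, params: CompilerParams
) -> Optional[str]:
    """5' extension sequence (toehold..antispacer_3p) if fully assigned."""
    parts = [free.get("toehold"), a5p]
    if params.bulge_len > 0:
        parts.append(free.get("bulge"))
    parts.append(a3p)
    if any(p is None for p in parts):
        return None
    return "".join(parts)  # type: ignore[arg-type]


def _full_segment(
    free: Dict[str, Optional[str]], a5p: str, a3p: str, params: CompilerParams
) -> Optional[str]:
    """toehold..hairpin_loop sequence if fully assigned."""
    ext = _ext_segment(free, a5p, a3p, params)
    loop = free.get("hairpin_loop")
    if ext is None or loop is None:
        return None
    return ext + loop


def _single_trigger(
    name: str,
    free: Dict[str, Optional[str]],
    a5p: str,
    a3p: str,
    params: CompilerParams,
) -> Strand:
    """Toehold-path trigger: rc(toehold..hairpin_loop).

    The invasion extends through the sequestering-hairpin loop: in the
    activated complex every sensor pyrimidine is hybridized to the trigger,
    and any competing intramolecular pairing of the released spacer would
    cross the loop:trigger duplex, so displacement carries a strict
    thermodynamic margin.
    """
    seg = _full_segment(free, a5p, a3p, params)
    rc_seg = _rc(seg)  # rc(loop) + invasion + rc(toehold)
    loop_len = params.hairpin_loop_len
    inv_len = len(a5p) + len(a3p) + params.bulge_len
    return Strand(
        name=name,
        domains=[
            _placeholder_or(_seg(rc_seg, 0, loop_len), f"loopbind_{name}", "invasion", loop_len),
            _placeholder_or(
                _seg(rc_seg, loop_len, loop_len + inv_len),
                f"invasion_{name}",
                "invasion",
                inv_len,
            ),
            _placeholder_or(
                _seg(rc_seg, loop_len + inv_len, loop_len + inv_len + params.toehold_len),
                f"antitoehold_{name}",
                "toehold",
                params.toehold_len,
            ),
        ],
    )


def _loop_segment(
    free: Dict[str, Optional[str]], a5p: str, a3p: str, params: CompilerParams
) -> Tuple[Optional[str], int]:
    """Sequence sensed by loop-path triggers and its length.

    Covers the toehold's 3'-most ``or_b_clamp_len`` nt, the antispacer with
    bulge, and the hairpin loop: the trigger enters through the loop and the
    short toehold clamp offsets the docking advantage of the sequestered
    state, so loop-path displacement carries a clear thermodynamic margin.
    """
    clamp = min(params.or_b_clamp_len, params.toehold_len)
    toe = free.get("toehold")
    parts: List[Optional[str]] = [None if toe is None else toe[len(toe) - clamp :]]
    parts.append(a5p)
    if params.bulge_len > 0:
        parts.append(free.get("bulge"))
    parts += [a3p, free.get("hairpin_loop")]
    seg = None if any(p is None for p in parts) else "".join(parts)  # type: ignore[arg-type]
    length = (
        clamp + len(a5p) + params.bulge_len + len(a3p) + params.hairpin_loop_len
    )
    return seg, length


def _loop_trigger(
    name: str,
    free: Dict[str, Optional[str]],
    a5p: str,
    a3p: str,
    params: CompilerParams,
) -> Strand:
    """Loop-path trigger: rc(toehold clamp..hairpin_loop), loop binder first."""
    seg, seg_len = _loop_segment(free, a5p, a3p, params)
    rc_seg = _rc(seg)
    loop_len = params.hairpin_loop_len
    inv_len = len(a5p) + len(a3p) + params.bulge_len
    clamp = seg_len - loop_len - inv_len
    return Strand(
        name=name,
        domains=[
            _placeholder_or(_seg(rc_seg, 0, loop_len), f"loopbind_{name}", "invasion", loop_len),
            _placeholder_or(
                _seg(rc_seg, loop_len, loop_len + inv_len),
                f"invasion_{name}",
                "invasion",
                inv_len,
            ),
            _placeholder_or(
                _seg(rc_seg, loop_len + inv_len, seg_len),
                f"clamp_{name}",
                "toehold",
                clamp,
            ),
        ],
    )


def _split_pair(
    deep_name: str,
    foot_name: str,
    full_core: Optional[str],
    full_core_len: int,
    deep_core_len: int,
    free: Dict[str, Optional[str]],
    params: CompilerParams,
    deep_first_in_assembly: bool,
) -> Tuple[Strand, Strand, TriggerInfo, TriggerInfo]:
    """Split a functional trigger core into a deep + foothold strand pair.

    Each strand carries a 5' safety hairpin whose arm sequesters the first
    ``safety_hairpin_stem`` nt of its functional core, preventing single-
    trigger activation; dedicated assembly domains hybridize the two strands
    into the complete trigger complex.  The designable assembly domain is
    pyrimidine (it cannot displace the pyrimidine antispacer), and each
    strand's assembly segment sits on the end of its core that points away
    from the seed-ward continuation of displacement -- the piece whose core
    binds the loop-side sensor window (first in the assembled complex)
    carries it 5', the toehold-side piece 3' -- so that continued invasion
    by a lone strand would have to cross its own core duplex.
    """
    stem = params.safety_hairpin_stem
    asm = free.get("assembly")
    shl = free.get("sh_loop")
    asm_len = params.and_assembly_len
    if deep_first_in_assembly:
        deep_core = _seg(full_core, 0, deep_core_len)
        foot_core = _seg(full_core, deep_core_len, full_core_len)
    else:
        foot_core = _seg(full_core, 0, full_core_len - deep_core_len)
        deep_core = _seg(full_core, full_core_len - deep_core_len, full_core_len)
    foot_core_len = full_core_len - deep_core_len
    hp = stem + params.safety_hairpin_loop

    def build(name: str, core: Optional[str], core_len: int, asm_seq: Optional[str],
              asm_tag: str, asm_at_5p: bool) -> Tuple[Strand, Tuple[int, int], Tuple[int, int]]:
        doms = [
            _placeholder_or(_safety_arm(core, stem), f"sh_arm_{name}", "safety_hairpin", stem),
            _placeholder_or(shl, f"sh_loop_{name}", "safety_hairpin", params.safety_hairpin_loop),
            _placeholder_or(core, f"core_{name}", "invasion", core_len),
        ]
        asm_dom = _placeholder_or(asm_seq, f"{asm_tag}_{name}", "assembly", asm_len)
        if asm_at_5p:
            doms.insert(0, asm_dom)
            core_span = (asm_len + hp, asm_len + hp + core_len)
            asm_span = (0, asm_len)
        else:
            doms.append(asm_dom)
            core_span = (hp, hp + core_len)
            asm_span = (hp + core_len, hp + core_len + asm_len)
        return Strand(name=name, domains=doms), core_span, asm_span

    # the loop-side (first-in-assembly) strand carries the purine assembly
    # complement -- its open continuation direction is the purine spacer,
    # which purines cannot pair -- while the toehold-side strand carries the
    # designable pyrimidine assembly domain, whose continuation direction is
    # the pyrimidine toehold head
    if deep_first_in_assembly:
        deep_asm, deep_tag = _rc(asm), "antiassembly"
        foot_asm, foot_tag = asm, "assembly"
    else:
        deep_asm, deep_tag = asm, "assembly"
        foot_asm, foot_tag = _rc(asm), "antiassembly"
    deep, deep_core_span, deep_asm_span = build(
        deep_name, deep_core, deep_core_len, deep_asm, deep_tag, deep_first_in_assembly
    )
    foot, foot_core_span, foot_asm_span = build(
        foot_name, foot_core, foot_core_len, foot_asm, foot_tag,
        not deep_first_in_assembly,
    )
    deep_info = TriggerInfo(
        name=deep_name,
        kind="split",
        partner=foot_name,
        core_span=deep_core_span,
        assembly_span=deep_asm_span,
    )
    foot_info = TriggerInfo(
        name=foot_name,
        kind="split",
        partner=deep_name,
        core_span=foot_core_span,
        assembly_span=foot_asm_span,
    )
    return deep, foot, deep_info, foot_info


# --------------------------------------------------------------------------
# Top-level compilation
# --------------------------------------------------------------------------


def compile_design(
    gate: GateSpec,
    site: TargetSite,
    params: Optional[CompilerParams] = None,
    free_seqs: Optional[Dict[str, str]] = None,
    variant: Optional[int] = None,
) -> CgRNADesign:
    """Compile a gate + target site into a domain-level :class:`CgRNADesign`.

    ``free_seqs`` assigns designable domains (see :func:`free_domain_spec`);
    omitted entries stay placeholders for the sequence designer.  ``variant``
    selects between the two A AND (NOT B) mechanisms (1: input B blocks the
    extended scaffold loop; 2: input B is antisense to trigger A, expressed at
    ``not_b_expression_ratio`` relative strength).
    """
    params = params or CompilerParams()
    params.validate(site)
    arch = gate.architecture
    if arch in (Architecture.A_AND_NOT_B_V1, Architecture.A_AND_NOT_B_V2):
        if variant == 2:
            arch = Architecture.A_AND_NOT_B_V2
        elif variant in (None, 1):
            arch = Architecture.A_AND_NOT_B_V1 if variant == 1 or arch == Architecture.A_AND_NOT_B_V1 else arch
        else:
            raise CompileError(f"unsupported A AND (NOT B) variant {variant!r}")
    gate = GateSpec(expression=gate.expression, architecture=arch)

    spec = free_domain_spec(arch, params)
    free: Dict[str, Optional[str]] = {k: None for k in spec}
    if free_seqs:
        for k, v in free_seqs.items():
            if k not in spec:
                raise CompileError(f"{k!r} is not a designable domain of {arch.value}")
            if len(v) != spec[k]:
                raise CompileError(
                    f"domain {k!r} must be {spec[k]} nt, got {len(v)}"
                )
            free[k] = v

    inputs = gate.inputs
    triggers: Dict[str, Strand] = {}
    info: Dict[str, TriggerInfo] = {}
    weights: Dict[str, float] = {}

    if arch in (
        Architecture.SINGLE,
        Architecture.OR2,
        Architecture.AND2,
        Architecture.A_AND_NOT_B_V1,
        Architecture.A_AND_NOT_B_V2,
        Architecture.A_OR_B_AND_C,
    ):
        sensor_doms, anti = _sensor_domains(site, params, free)
        a5p, a3p = anti["antispacer_5p"], anti["antispacer_3p"]
        extended = arch == Architecture.A_AND_NOT_B_V1
        cg_domains = sensor_doms + _scaffold_domains(params, extended, free)
        cgrna = Strand(name="cgRNA", domains=cg_domains)
        off = _off_structure(cg_domains)
        inv_len = len(site.spacer) + params.bulge_len

        if arch == Architecture.SINGLE:
            (a_name,) = inputs
            triggers[a_name] = _single_trigger(a_name, free, a5p, a3p, params)
            info[a_name] = TriggerInfo(name=a_name, kind="toehold_path")

        elif arch == Architecture.OR2:
            if params.hairpin_loop_len < 6:
                raise CompileError(
                    "hairpin loop shorter than 6 nt cannot seed the loop-path trigger"
                )
            a_name, b_name = inputs
            triggers[a_name] = _single_trigger(a_name, free, a5p, a3p, params)
            info[a_name] = TriggerInfo(name=a_name, kind="toehold_path")
            triggers[b_name] = _loop_trigger(b_name, free, a5p, a3p, params)
            info[b_name] = TriggerInfo(name=b_name, kind="loop_path")

        elif arch == Architecture.AND2:
            a_name, b_name = inputs
            seg = _full_segment(free, a5p, a3p, params)
            rc_seg = _rc(seg)  # rc(loop) + invasion + rc(toehold)
            full_len = params.hairpin_loop_len + inv_len + params.toehold_len
            # trigger A: loop-binding foothold plus the 17-nt stem-interaction
            # domain; trigger B: remaining stem nt plus the toehold binder
            deep, foot, di, fi = _split_pair(
                a_name,
                b_name,
                rc_seg,
                full_len,
                params.hairpin_loop_len + params.and_triggerA_stem_len,
                free,
                params,
                deep_first_in_assembly=True,
            )
            di.order, fi.order = 0, 1
            triggers[a_name], triggers[b_name] = deep, foot
            info[a_name], info[b_name] = di, fi

        elif arch == Architecture.A_AND_NOT_B_V1:
            a_name, b_name = _a_and_not_b_names(gate)
            triggers[a_name] = _single_trigger(a_name, free, a5p, a3p, params)
            info[a_name] = TriggerInfo(name=a_name, kind="toehold_path")
            loop_ext = free.get("scaffold_loop_ext")
            triggers[b_name] = Strand(
                name=b_name,
                domains=[
                    _placeholder_or(
                        _rc(loop_ext), f"loopblock_{b_name}", "invasion",
                        params.scaffold_loop_ext_len,
                    )
                ],
            )
            info[b_name] = TriggerInfo(name=b_name, kind="inhibitor_loop")

        elif arch == Architecture.A_AND_NOT_B_V2:
            a_name, b_name = _a_and_not_b_names(gate)
            trig_a = _single_trigger(a_name, free, a5p, a3p, params)
            triggers[a_name] = trig_a
            info[a_name] = TriggerInfo(name=a_name, kind="toehold_path")
            # antisense inhibitor: exact reverse complement of trigger A
            anti_seq = _full_segment(free, a5p, a3p, params)
            full_len = params.hairpin_loop_len + inv_len + params.toehold_len
            triggers[b_name] = Strand(
                name=b_name,
                domains=[
                    _placeholder_or(
                        anti_seq, f"antisense_{b_name}", "invasion", full_len
                    )
                ],
            )
            info[b_name] = TriggerInfo(
                name=b_name, kind="inhibitor_antisense", partner=a_name
            )
            weights[b_name] = params.not_b_expression_ratio

        else:  # A OR (B AND C)
            a_name, b_name, c_name = _or_and_names(gate)
            triggers[a_name] = _single_trigger(a_name, free, a5p, a3p, params)
            info[a_name] = TriggerInfo(name=a_name, kind="toehold_path")
            # loop-branch core: rc(toehold clamp..hairpin_loop), split so the
            # foothold carries the loop binder and the deep trigger the
            # stem-interaction domain plus the toehold clamp
            seg, seg_len = _loop_segment(free, a5p, a3p, params)
            loop_core = _rc(seg)
            clamp = seg_len - params.hairpin_loop_len - inv_len
            deep, foot, di, fi = _split_pair(
                b_name,
                c_name,
                loop_core,
                seg_len,
                params.or_and_b_stem_len + clamp,
                free,
                params,
                deep_first_in_assembly=False,
            )
            fi.order, di.order = 0, 1  # foothold (loop-binding) core comes first
            triggers[b_name], triggers[c_name] = deep, foot
            info[b_name], info[c_name] = di, fi

    elif arch == Architecture.NOT1:
        spacer_dom = _dom("spacer", "spacer", site.spacer, len(site.spacer))
        cg_domains = [spacer_dom] + _scaffold_domains(params, True, free)
        cgrna = Strand(name="cgRNA", domains=cg_domains)
        off = "." * sum(d.length for d in cg_domains)  # type: ignore[misc]
        (a_name,) = inputs
        loop_ext = free.get("scaffold_loop_ext")
        triggers[a_name] = Strand(
            name=a_name,
            domains=[
                _placeholder_or(
                    _rc(loop_ext), f"loopblock_{a_name}", "invasion",
                    params.scaffold_loop_ext_len,
                )
            ],
        )
        info[a_name] = TriggerInfo(name=a_name, kind="inhibitor_loop")
    else:
        raise CompileError(f"unsupported architecture {arch}")

    design = CgRNADesign(
        gate=gate,
        cgrna=cgrna,
        triggers=triggers,
        decoys={},
        target_off_structure=off,
        expression_weights=weights,
        trigger_info=info,
        site=site,
        params=params,
    )
    _attach_decoys(design, params)
    return design


def _a_and_not_b_names(gate: GateSpec) -> Tuple[str, str]:
    """(activating, inhibitory) input names of an A AND (NOT B) expression."""
    from .circuit_model import And, Not, Var

    e = gate.expression
    assert isinstance(e, And)
    for a, nb in ((e.left, e.right), (e.right, e.left)):
        if isinstance(a, Var) and isinstance(nb, Not) and isinstance(nb.arg, Var):
            return a.name, nb.arg.name
    raise CompileError("expression is not of the form A AND (NOT B)")


def _or_and_names(gate: GateSpec) -> Tuple[str, str, str]:
    """(A, B, C) of an A OR (B AND C) expression."""
    from .circuit_model import And, Or, Var

    e = gate.expression
    assert isinstance(e, Or)
    for a, bc in ((e.left, e.right), (e.right, e.left)):
        if isinstance(a, Var) and isinstance(bc, And):
            assert isinstance(bc.left, Var) and isinstance(bc.right, Var)
            return a.name, bc.left.name, bc.right.name
    raise CompileError("expression is not of the form A OR (B AND C)")


def _attach_decoys(design: CgRNADesign, params: CompilerParams) -> None:
    """Non-cognate decoys: seeded dinucleotide shuffles of each trigger."""
    for idx, (name, strand) in enumerate(sorted(design.triggers.items())):
        if not all(d.assigned for d in strand.domains):
            continue
        rng = np.random.RandomState(params.decoy_seed + idx)
        shuffled = dinucleotide_shuffle(strand.sequence, rng)
        design.decoys[f"decoy_{name}"] = Strand(
            name=f"decoy_{name}",
            domains=[_dom(f"decoy_{name}", "invasion", shuffled, len(shuffled))],
        )


def compile_gate(
    expr_text: str,
    spacer: str,
    params: Optional[CompilerParams] = None,
    free_seqs: Optional[Dict[str, str]] = None,
    variant: Optional[int] = None,
    seed_length: int = 12,
) -> CgRNADesign:
    """Convenience front-end: parse, build the target site, compile."""
    from .circuit_model import parse_gate

    gate = parse_gate(expr_text)
    site = TargetSite(spacer=spacer, seed_length=seed_length)
    return compile_design(gate, site, params=params, free_seqs=free_seqs, variant=variant)
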