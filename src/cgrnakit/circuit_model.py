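"""Core domain types for conditional guide RNA (cgRNA) circuits.

A cgRNA is a guide RNA whose 20-nt spacer is sequestered by a cis-regulatory
5' extension until a cognate trigger RNA releases it by toehold-mediated
strand displacement.  This module holds the vocabulary in which such designs
are expressed: validated RNA sequences, named functional domains, strands
(ordered domain lists), CRISPRi target sites, Boolean gate specifications
over named trigger inputs, and the compiled-design container.

Sequences are stored in RNA form (A/C/G/U); DNA input is transcribed on
ingestion.  Internal coordinates are 0-based half-open; rendered reports use
1-based positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple, Union

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class SequenceError(ValueError):
    """Raised for malformed or illegal nucleotide sequences."""


class GateError(ValueError):
    """Raised for malformed or unsupported Boolean gate expressions."""


def clean_rna(seq: str) -> str:
    """Validate *seq* as RNA (uppercased); raise :class:`SequenceError` otherwise."""
    s = seq.strip().upper()
    if not s:
        raise SequenceError("empty sequence")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid RNA characters {sorted(bad)} in {s!r}")
    return s


def transcribe(dna: str) -> str:
    """DNA -> RNA (T->U).  Accepts the protospacer-strand sequence of a target."""
    s = dna.strip().upper()
    if not s:
        raise SequenceError("empty sequence")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid DNA characters {sorted(bad)} in {s!r}")
    return s.replace("T", "U")


def ingest(seq: str) -> str:
    """Accept RNA or DNA text; return canonical RNA form."""
    s = seq.strip().upper()
    if "T" in s and "U" in s:
        raise SequenceError("sequence mixes T and U")
    return transcribe(s) if "T" in s else clean_rna(s)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, RNA alphabet preserved."""
    return clean_rna(seq).translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    s = clean_rna(seq)
    return (s.count("G") + s.count("C")) / len(s)


def max_homopolymer(seq: str) -> int:
    return max(len(m.group(0)) for m in re.finditer(r"(.)\1*", seq))


# --------------------------------------------------------------------------
# Domains and strands
# --------------------------------------------------------------------------

#: Functional roles a domain may play inside a design.  The compiler only
#: accepts a domain in slots matching its role.
DOMAIN_ROLES = frozenset(
    {
        "toehold",
        "spacer",
        "antispacer_5p",
        "antispacer_3p",
        "bulge",
        "hairpin_loop",
        "scaffold",
        "scaffold_loop_ext",
        "assembly",
        "safety_hairpin",
        "invasion",
        "linker",
    }
)


@dataclass
class Domain:
    """A named sequence segment with a functional role.

    ``sequence`` may be ``None`` for a placeholder whose nucleotides are
    assigned later by the sequence designer; placeholders must then carry a
    declared ``length`` > 0.
    """

    name: str
    role: str
    sequence: Optional[str] = None
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in DOMAIN_ROLES:
            raise ValueError(f"unknown domain role {self.role!r}")
        if self.sequence is not None:
            self.sequence = clean_rna(self.sequence)
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise ValueError(
                    f"domain {self.name}: declared length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
        else:
            if not self.length or self.length <= 0:
                raise ValueError(f"placeholder domain {self.name} needs length > 0")

    @property
    def assigned(self) -> bool:
        return self.sequence is not None


@dataclass
class Strand:
    """An ordered 5'->3' list of domains forming one RNA strand."""

    name: str
    domains: List[Domain] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        parts = []
        for d in self.domains:
            if d.sequence is None:
                raise SequenceError(
                    f"strand {self.name}: domain {d.name} is unassigned"
                )
            parts.append(d.sequence)
        return "".join(parts)

    def __len__(self) -> int:
        return sum(d.length for d in self.domains)  # type: ignore[misc]

    def span(self, domain_name: str) -> Tuple[int, int]:
        """0-based half-open span of the first domain with this name."""
        pos = 0
        for d in self.domains:
            if d.name == domain_name:
                return pos, pos + d.length  # type: ignore[operator]
            pos += d.length  # type: ignore[operator]
        raise KeyError(f"strand {self.name} has no domain {domain_name!r}")

    def domain(self, domain_name: str) -> Domain:
        for d in self.domains:
            if d.name == domain_name:
                return d
        raise KeyError(f"strand {self.name} has no domain {domain_name!r}")


# --------------------------------------------------------------------------
# Target sites
# --------------------------------------------------------------------------

_PAM_RE = re.compile(r"^[ACGU]GG$")


@dataclass
class TargetSite:
    """A CRISPRi target: 20-nt spacer plus optional NGG PAM.

    ``seed_length`` counts PAM-proximal nucleotides (the 3' end of the spacer,
    adjacent to the scaffold) that nucleate R-loop formation; the OFF-state
    design must keep these paired.
    """

    spacer: str
    pam: Optional[str] = None
    seed_length: int = 12

    def __post_init__(self) -> None:
        self.spacer = ingest(self.spacer)
        if self.pam is not None:
            self.pam = ingest(self.pam)
            if not _PAM_RE.match(self.pam):
                raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.seed_length <= 0 or self.seed_length > len(self.spacer):
            raise ValueError("spacer length must be >= seed_length > 0")

    @property
    def seed(self) -> str:
        """PAM-proximal seed sequence (3' end of the spacer)."""
        return self.spacer[-self.seed_length :]


# --------------------------------------------------------------------------
# Boolean gate grammar
# --------------------------------------------------------------------------


class Architecture(str, Enum):
    """The six demonstrated cgRNA architectures (plus the trivial single input)."""

    SINGLE = "SINGLE"
    OR2 = "OR2"
    AND2 = "AND2"
    NOT1 = "NOT1"
    A_AND_NOT_B_V1 = "A_AND_NOT_B_v1"
    A_AND_NOT_B_V2 = "A_AND_NOT_B_v2"
    A_OR_B_AND_C = "A_OR_B_AND_C"


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Not:
    arg: "Expr"


@dataclass(frozen=True)
class And:
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Or:
    left: "Expr"
    right: "Expr"


Expr = Union[Var, Not, And, Or]


def expr_inputs(expr: Expr) -> List[str]:
    """Input names in left-to-right order of first appearance."""
    out: List[str] = []

    def walk(e: Expr) -> None:
        if isinstance(e, Var):
            if e.name not in out:
                out.append(e.name)
        elif isinstance(e, Not):
            walk(e.arg)
        else:
            walk(e.left)
            walk(e.right)

    walk(expr)
    return out


def eval_expr(expr: Expr, present: Dict[str, bool]) -> bool:
    """Evaluate the Boolean AST under an input assignment."""
    if isinstance(expr, Var):
        return present[expr.name]
    if isinstance(expr, Not):
        return not eval_expr(expr.arg, present)
    if isinstance(expr, And):
        return eval_expr(expr.left, present) and eval_expr(expr.right, present)
    return eval_expr(expr.left, present) or eval_expr(expr.right, present)


@dataclass
class GateSpec:
    """A Boolean expression restricted to one of the supported architecture shapes."""

    expression: Expr
    architecture: Architecture

    @property
    def inputs(self) -> List[str]:
        return expr_inputs(self.expression)


_TOKEN_RE = re.compile(r"\s*(\(|\)|AND\b|OR\b|NOT\b|[A-Za-z_][A-Za-z0-9_]*)", re.I)


def _tokenize(text: str) -> List[str]:
    tokens: List[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise GateError(f"syntax error near {text[pos:pos + 10]!r}")
            break
        tok = m.group(1)
        tokens.append(tok.upper() if tok.upper() in ("AND", "OR", "NOT") else tok)
        pos = m.end()
    if not tokens:
        raise GateError("empty gate expression")
    return tokens


def _parse_expr(tokens: List[str], pos: int) -> Tuple[Expr, int]:
    # or_expr := and_expr (OR and_expr)*
    left, pos = _parse_and(tokens, pos)
    while pos < len(tokens) and tokens[pos] == "OR":
        right, pos = _parse_and(tokens, pos + 1)
        left = Or(left, right)
    return left, pos


def _parse_and(tokens: List[str], pos: int) -> Tuple[Expr, int]:
    left, pos = _parse_unary(tokens, pos)
    while pos < len(tokens) and tokens[pos] == "AND":
        right, pos = _parse_unary(tokens, pos + 1)
        left = And(left, right)
    return left, pos


def _parse_unary(tokens: List[str], pos: int) -> Tuple[Expr, int]:
    if pos >= len(tokens):
        raise GateError("unexpected end of expression")
    tok = tokens[pos]
    if tok == "NOT":
        arg, pos = _parse_unary(tokens, pos + 1)
        return Not(arg), pos
    if tok == "(":
        inner, pos = _parse_expr(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GateError("unbalanced parentheses")
        return inner, pos + 1
    if tok in (")", "AND", "OR"):
        raise GateError(f"unexpected token {tok!r}")
    return Var(tok), pos + 1


class UnsupportedArchitectureError(GateError):
    """The expression parses but matches none of the supported shapes."""


def classify(expr: Expr) -> Architecture:
    """Map an AST onto one of the supported architecture shapes.

    ``A AND (NOT B)`` classifies as variant 1 by default; the compiler accepts
    an explicit variant selection.
    """
    if isinstance(expr, Var):
        return Architecture.SINGLE
    if isinstance(expr, Not) and isinstance(expr.arg, Var):
        return Architecture.NOT1
    if isinstance(expr, Or):
        l, r = expr.left, expr.right
        if isinstance(l, Var) and isinstance(r, Var):
            return Architecture.OR2
        # A OR (B AND C), either operand order
        for a, bc in ((l, r), (r, l)):
            if (
                isinstance(a, Var)
                and isinstance(bc, And)
                and isinstance(bc.left, Var)
                and isinstance(bc.right, Var)
            ):
                return Architecture.A_OR_B_AND_C
    if isinstance(expr, And):
        l, r = expr.left, expr.right
        if isinstance(l, Var) and isinstance(r, Var):
            return Architecture.AND2
        for a, nb in ((l, r), (r, l)):
            if (
                isinstance(a, Var)
                and isinstance(nb, Not)
                and isinstance(nb.arg, Var)
            ):
                return Architecture.A_AND_NOT_B_V1
    raise UnsupportedArchitectureError(
        f"expression shape {render_expr(expr)!r} is not among the supported "
        "architectures (single input, A OR B, A AND B, NOT A, A AND (NOT B), "
        "A OR (B AND C))"
    )


def _literals(expr: Expr) -> List[str]:
    """All variable occurrences, duplicates included."""
    if isinstance(expr, Var):
        return [expr.name]
    if isinstance(expr, Not):
        return _literals(expr.arg)
    return _literals(expr.left) + _literals(expr.right)  # type: ignore[union-attr]


def parse_gate(expr_text: str) -> GateSpec:
    """Parse gate text such as ``"A OR (B AND C)"`` into a classified GateSpec."""
    tokens = _tokenize(expr_text)
    expr, pos = _parse_expr(tokens, 0)
    if pos != len(tokens):
        raise GateError(f"trailing tokens {tokens[pos:]!r}")
    lits = _literals(expr)
    if len(lits) != len(set(lits)):
        raise GateError("input names must be unique")
    return GateSpec(expression=expr, architecture=classify(expr))


def render_expr(expr: Expr) -> str:
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        return f"NOT {render_expr(expr.arg)}"
    if isinstance(expr, And):
        return f"{_paren(expr.left)} AND {_paren(expr.right)}"
    return f"{_paren(expr.left)} OR {_paren(expr.right)}"


def _paren(expr: Expr) -> str:
    if isinstance(expr, Var):
        return render_expr(expr)
    return f"({render_expr(expr)})"


def render_gate(gate: GateSpec) -> str:
    return render_expr(gate.expression)


# --------------------------------------------------------------------------
# Compiled designs
# --------------------------------------------------------------------------


@dataclass
class TriggerInfo:
    """Mechanistic metadata the evaluator needs about one trigger strand.

    kind:
      ``toehold_path`` / ``loop_path`` -- single-strand activators invading
        from the 5' toehold or from the sequestering-hairpin loop;
      ``split`` -- one half of a split-trigger AND pair (``partner`` names the
        other half, ``core_span`` marks the functional core within the strand,
        i.e. everything outside the 5' safety hairpin and assembly domain);
      ``inhibitor_loop`` -- NOT input hybridizing the extended scaffold loop;
      ``inhibitor_antisense`` -- NOT input that is antisense to another
        trigger (``partner`` names the neutralized trigger).
    """

    name: str
    kind: str
    partner: Optional[str] = None
    core_span: Optional[Tuple[int, int]] = None
    assembly_span: Optional[Tuple[int, int]] = None
    order: int = 0  # position of this core in the assembled split complex


@dataclass
class CgRNADesign:
    """A compiled cgRNA with its trigger and decoy strands.

    ``target_off_structure`` is the dot-bracket OFF-state target over the full
    cgRNA (sensor stem sequestering the spacer; scaffold rendered unpaired --
    it is modeled as dCas9-occupied, see the evaluator).  ``expression_weights``
    carry per-trigger relative expression multipliers (the NOT variant-2
    antisense input is expressed ~5x its target trigger in the reference
    system).
    """

    gate: GateSpec
    cgrna: Strand
    triggers: Dict[str, Strand]
    decoys: Dict[str, Strand] = field(default_factory=dict)
    target_off_structure: str = ""
    expression_weights: Dict[str, float] = field(default_factory=dict)
    trigger_info: Dict[str, TriggerInfo] = field(default_factory=dict)
    site: Optional[TargetSite] = None
    params: Optional["object"] = None
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in self.gate.inputs:
            if name not in self.triggers:
                raise ValueError(f"gate input {name!r} has no trigger strand")
        for name in self.triggers:
            self.expression_weights.setdefault(name, 1.0)

    # -- span helpers (0-based, cgRNA coordinates) ---------------------------

    def _maybe_span(self, name: str) -> Optional[Tuple[int, int]]:
        try:
            return self.cgrna.span(name)
        except KeyError:
            return None

    @property
    def spacer_span(self) -> Tuple[int, int]:
        return self.cgrna.span("spacer")

    @property
    def seed_span(self) -> Tuple[int, int]:
        """PAM-proximal seed positions (3' end of the spacer)."""
        s0, s1 = self.spacer_span
        seed_len = self.site.seed_length if self.site else 12
        return s1 - seed_len, s1

    @property
    def sensor_span(self) -> Optional[Tuple[int, int]]:
        """5' sensor extension through spacer end; None for sensor-less designs."""
        toe = self._maybe_span("toehold")
        if toe is None:
            return None
        return toe[0], self.spacer_span[1]

    @property
    def scaffold_span(self) -> Tuple[int, int]:
        start = None
        end = 0
        pos = 0
        for d in self.cgrna.domains:
            if d.role in ("scaffold", "scaffold_loop_ext"):
                if start is None:
                    start = pos
                end = pos + d.length  # type: ignore[operator]
            pos += d.length  # type: ignore[operator]
        if start is None:
            raise KeyError("design has no scaffold")
        return start, end

    @property
    def sensor_sequence(self) -> Optional[str]:
        span = self.sensor_span
        if span is None:
            return None
        return self.cgrna.sequence[span[0] : span[1]]

    @property
    def scaffold_sequence(self) -> str:
        a, b = self.scaffold_span
        return self.cgrna.sequence[a:b]

    @property
    def fully_assigned(self) -> bool:
        strands = [self.cgrna, *self.triggers.values(), *self.decoys.values()]
        return all(d.assigned for s in strands for d in s.domains)
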