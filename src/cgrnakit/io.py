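"""File I/O: FASTA, design bundles (JSON), fixtures and configuration.

A design bundle is a directory holding a manifest (tool version, seed,
parameter echo), strand FASTA, target structures (Vienna dot-bracket,
1-based conventions noted in headers) and report tables; the manifest seed
suffices to regenerate the bundle byte-identically.

The fixture generator emits seeded random low-structure spacers and a
pre-designed orthogonal cgRNA panel; it deterministically searches candidate
spacer sets (all derived from its seed) until the designed panel passes the
evaluator's orthogonality and decoy-leakage audit, so shipped fixtures are
valid by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__ as _pkg_version
from .circuit_model import (
    Architecture,
    CgRNADesign,
    Domain,
    GateSpec,
    SequenceError,
    Strand,
    TargetSite,
    TriggerInfo,
    gc_fraction,
    max_homopolymer,
    parse_gate,
    render_gate,
)
from .compiler import CompilerParams, compile_design
from .designer import DesignObjective, DesignResult, DesignRunConfig, design_orthogonal_panel
from .evaluator import ActivationRule, crosstalk_matrix, predict_state, truth_table
from .thermo import EnergyModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "design_to_dict",
    "design_from_dict",
    "save_bundle",
    "load_bundle",
    "FixtureSpec",
    "generate_fixtures",
    "load_config",
]


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    """Named sequences from a FASTA file (RNA or DNA; not auto-transcribed)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    out: Dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTU")
        if bad:
            raise SequenceError(
                f"record {rec.id!r} in {path} has illegal characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(records: Dict[str, str], path, descriptions: Optional[Dict[str, str]] = None) -> None:
    path = Path(path)
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description=(descriptions or {}).get(name, ""))
        for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


# --------------------------------------------------------------------------
# Design (de)serialization
# --------------------------------------------------------------------------


def _strand_to_dict(s: Strand) -> dict:
    return {
        "name": s.name,
        "domains": [
            {"name": d.name, "role": d.role, "sequence": d.sequence, "length": d.length}
            for d in s.domains
        ],
    }


def _strand_from_dict(d: dict) -> Strand:
    return Strand(
        name=d["name"],
        domains=[
            Domain(name=x["name"], role=x["role"], sequence=x["sequence"], length=x["length"])
            for x in d["domains"]
        ],
    )


def design_to_dict(design: CgRNADesign) -> dict:
    return {
        "gate": {
            "expression": render_gate(design.gate),
            "architecture": design.gate.architecture.value,
        },
        "cgrna": _strand_to_dict(design.cgrna),
        "triggers": {k: _strand_to_dict(v) for k, v in design.triggers.items()},
        "decoys": {k: _strand_to_dict(v) for k, v in design.decoys.items()},
        "target_off_structure": design.target_off_structure,
        "expression_weights": design.expression_weights,
        "trigger_info": {
            k: dataclasses.asdict(v) for k, v in design.trigger_info.items()
        },
        "site": {
            "spacer": design.site.spacer,
            "pam": design.site.pam,
            "seed_length": design.site.seed_length,
        }
        if design.site
        else None,
        "params": dataclasses.asdict(design.params) if design.params else None,
        "warnings": design.warnings,
    }


def design_from_dict(d: dict) -> CgRNADesign:
    gate = parse_gate(d["gate"]["expression"])
    gate = GateSpec(
        expression=gate.expression,
        architecture=Architecture(d["gate"]["architecture"]),
    )
    info = {
        k: TriggerInfo(
            name=v["name"],
            kind=v["kind"],
            partner=v.get("partner"),
            core_span=tuple(v["core_span"]) if v.get("core_span") else None,
            assembly_span=tuple(v["assembly_span"]) if v.get("assembly_span") else None,
            order=v.get("order", 0),
        )
        for k, v in d["trigger_info"].items()
    }
    site = TargetSite(**d["site"]) if d.get("site") else None
    params = CompilerParams(**d["params"]) if d.get("params") else None
    return CgRNADesign(
        gate=gate,
        cgrna=_strand_from_dict(d["cgrna"]),
        triggers={k: _strand_from_dict(v) for k, v in d["triggers"].items()},
        decoys={k: _strand_from_dict(v) for k, v in d["decoys"].items()},
        target_off_structure=d["target_off_structure"],
        expression_weights=dict(d.get("expression_weights", {})),
        trigger_info=info,
        site=site,
        params=params,
        warnings=list(d.get("warnings", [])),
    )


# --------------------------------------------------------------------------
# Bundles
# --------------------------------------------------------------------------

_CONVENTION_NOTE = "coordinates 1-based in reports; internal spans 0-based half-open"


def save_bundle(
    designs: Sequence[CgRNADesign],
    outdir,
    seed: Optional[int] = None,
    extra_manifest: Optional[dict] = None,
) -> Path:
    """Write a design bundle directory: manifest, designs JSON, strand FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "cgrnakit",
        "version": _pkg_version,
        "seed": seed,
        "convention": _CONVENTION_NOTE,
        "n_designs": len(designs),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "designs.json").write_text(
        json.dumps([design_to_dict(x) for x in designs], indent=2) + "\n"
    )
    records: Dict[str, str] = {}
    descriptions: Dict[str, str] = {}
    structures: List[str] = [f"# {_CONVENTION_NOTE}"]
    for idx, design in enumerate(designs):
        tag = design.cgrna.name if design.cgrna.name != "cgRNA" else f"design{idx + 1}"
        if design.fully_assigned:
            records[f"{tag}"] = design.cgrna.sequence
            descriptions[f"{tag}"] = "domains: " + "+".join(
                d.name for d in design.cgrna.domains
            )
            for name, strand in {**design.triggers, **design.decoys}.items():
                records[f"{tag}|{name}"] = strand.sequence
            structures.append(f">{tag}")
            structures.append(design.cgrna.sequence)
            structures.append(design.target_off_structure)
    if records:
        write_fasta(records, outdir / "strands.fasta", descriptions)
        (outdir / "structures.db").write_text("\n".join(structures) + "\n")
    return outdir


def load_bundle(outdir) -> List[CgRNADesign]:
    outdir = Path(outdir)
    data = json.loads((outdir / "designs.json").read_text())
    return [design_from_dict(d) for d in data]


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

FIXTURE_LABELS = ("lacZ-like", "malT-like", "poxB-like", "ftsZ-like")


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded synthetic target panel standing in for real construct tables."""

    n_spacers: int = 4
    spacer_len: int = 20
    seed: int = 7
    labels: Tuple[str, ...] = FIXTURE_LABELS
    gc_min: float = 0.3
    gc_max: float = 0.7
    max_homopolymer: int = 3

    def __post_init__(self) -> None:
        if self.n_spacers < 1:
            raise ValueError("n_spacers must be >= 1")
        if self.spacer_len < 12:
            raise ValueError("spacer_len must be >= 12 (seed region)")


def _random_spacer(rng: np.random.RandomState, spec: FixtureSpec) -> str:
    """Low-self-structure spacer: purine alphabet, constrained GC.

    Purine-only spacers cannot pair themselves (no intra-purine pairs), so
    the sequestering stem against the pyrimidine antispacer is the only
    strong channel -- the reduced-alphabet trick of strand-displacement
    sequence design applied to the fixture panel.
    """
    for _ in range(5000):
        seq = "".join(rng.choice(["A", "G"]) for _ in range(spec.spacer_len))
        if (
            spec.gc_min <= gc_fraction(seq) <= spec.gc_max
            and max_homopolymer(seq) <= spec.max_homopolymer
            and _max_shift_similarity(seq, 6) <= 0.65
        ):
            return seq
    raise RuntimeError("could not sample a constrained spacer")


def _max_shift_similarity(seq: str, max_shift: int) -> float:
    """Worst self-similarity under small register shifts.

    Near-periodic spacers admit register-shifted sequestering stems that tie
    the designed stem, degrading both ensemble defect and strand-displacement
    specificity, so the generator screens them out.
    """
    worst = 0.0
    for k in range(1, max_shift + 1):
        n = len(seq) - k
        if n <= 0:
            break
        worst = max(
            worst, sum(seq[i] == seq[i + k] for i in range(n)) / n
        )
    return worst


def fixture_spacers(spec: FixtureSpec, attempt: int = 0) -> Dict[str, str]:
    """Deterministic labelled spacer set for a given generation attempt."""
    rng = np.random.RandomState((spec.seed + 31 * attempt) % (2**31))
    spacers: Dict[str, str] = {}
    seen = set()
    i = 0
    while len(spacers) < spec.n_spacers:
        s = _random_spacer(rng, spec)
        if s in seen:
            continue
        seen.add(s)
        label = spec.labels[len(spacers) % len(spec.labels)]
        suffix = "" if len(spacers) < len(spec.labels) else f"_{len(spacers) // len(spec.labels) + 1}"
        spacers[f"{label}{suffix}"] = s
        i += 1
    return spacers


def _panel_audit_ok(
    results: Sequence[DesignResult],
    rule: ActivationRule,
    model: EnergyModel,
) -> bool:
    designs = [r.design for r in results]
    if any(r.warnings for r in results):
        return False
    for d in designs:
        tt = truth_table(d, rule, model)
        if not tt.all_pass:
            return False
        for name in d.gate.inputs:
            decoy = f"decoy_{name}"
            if decoy in d.decoys:
                if predict_state(d, [decoy], rule, model).state != "INACTIVE":
                    return False
    if len(designs) > 1:
        if not crosstalk_matrix(designs, rule, model).orthogonal:
            return False
    return True


def generate_fixtures(
    spec: Optional[FixtureSpec] = None,
    outdir=None,
    gate_text: str = "A",
    max_attempts: int = 8,
    design_config: Optional[DesignRunConfig] = None,
    objective: Optional[DesignObjective] = None,
) -> Tuple[Dict[str, str], List[DesignResult]]:
    """Seeded spacer FASTA plus a designed orthogonal cgRNA panel.

    Deterministic given ``spec.seed``: candidate spacer sets are derived from
    the seed and the first panel passing the evaluator audit (truth tables,
    decoy leakage, pairwise orthogonality) is returned.  Raises if no panel
    passes within ``max_attempts`` candidate sets.
    """
    spec = spec or FixtureSpec()
    model = EnergyModel()
    rule = ActivationRule()
    gate = parse_gate(gate_text)
    base_cfg = design_config or DesignRunConfig(seed=spec.seed, max_iters=120)
    last: Optional[Tuple[Dict[str, str], List[DesignResult]]] = None
    for attempt in range(max_attempts):
        spacers = fixture_spacers(spec, attempt)
        sites = [TargetSite(spacer=s) for s in spacers.values()]
        cfg = DesignRunConfig(
            seed=(base_cfg.seed + 613 * attempt) % (2**31),
            max_iters=base_cfg.max_iters,
            restarts=base_cfg.restarts,
            gc_min=base_cfg.gc_min,
            gc_max=base_cfg.gc_max,
            max_homopolymer=base_cfg.max_homopolymer,
        )
        results = design_orthogonal_panel(sites, gate, objective=objective, config=cfg)
        for label, res in zip(spacers, results):
            res.design.cgrna.name = f"cgRNA_{label}"
        last = (spacers, results)
        if _panel_audit_ok(results, rule, model):
            if outdir is not None:
                outdir = Path(outdir)
                outdir.mkdir(parents=True, exist_ok=True)
                write_fasta(spacers, outdir / "spacers.fasta")
                save_bundle(
                    [r.design for r in results],
                    outdir / "panel",
                    seed=spec.seed,
                    extra_manifest={"fixture_attempt": attempt},
                )
            return spacers, results
    raise RuntimeError(
        f"no fixture panel passed the orthogonality audit in {max_attempts} attempts"
    )


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


def load_config(path) -> dict:
    """YAML config -> dict with compiler/designer/rule/model sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    if "compiler" in raw:
        out["compiler"] = CompilerParams(**raw["compiler"])
    if "designer" in raw:
        out["designer"] = DesignRunConfig(**raw["designer"])
    if "objective" in raw:
        out["objective"] = DesignObjective(**raw["objective"])
    if "rule" in raw:
        out["rule"] = ActivationRule(**raw["rule"])
    if "model" in raw:
        out["model"] = EnergyModel(**raw["model"])
    return out
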