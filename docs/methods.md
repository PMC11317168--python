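# Methods

This note documents the models, default parameters and design choices behind
cgrnakit, in the package's own terms: what is being computed, why the
defaults are what they are, and what the in-silico results do and do not say
about wet-lab behaviour.

## The energy model and its consequences

All thermodynamics run on a deliberately simple pair-weight model: a
pseudoknot-free structure scores the sum of its base-pair weights (GC = 3,
AU = 2, GU = 1 stability units; minimum hairpin loop 3 nt), Boltzmann
weights are `exp(β·score)` with β = 1 per stability unit by default. The
model was chosen so that every dynamic program in the engine — maximum-weight
folding, structure counting, base-pair probabilities, ensemble defect,
co-folding — can be validated *exactly* against brute-force enumeration of
all structures (done in the test suite for every sequence tested up to
12 nt). The engine is the package's quantitative oracle; a full
nearest-neighbor thermodynamic package could be substituted behind the same
interfaces without changing any caller.

The price of this simplicity is **letter-class degeneracy**: the model knows
only six pair types, so any two positions holding the same nucleotide are
energetically interchangeable partners. Multi-domain constructs therefore
have very large co-optimal ensembles, and three consequences shaped the
whole package:

1. **Reduced-alphabet domain design.** Following the reduced-alphabet
   tradition of strand-displacement sequence design, the architecture
   partitions the chemistry: target spacers in the synthetic fixtures are
   purine-only ({A,G}, aperiodic, GC 0.3–0.7, homopolymers ≤ 3), the entire
   sequestering extension (toehold, antispacer, hairpin loop) is pyrimidine,
   and the bulge is purine. Purines cannot pair purines and pyrimidines
   cannot pair pyrimidines, so the spacer:antispacer stem is essentially the
   only strong channel in the OFF sensor, the purine bulge keeps the sensor
   pyrimidine count equal to the spacer length (pinning the stem register:
   any deviation from the designed perfect matching must skip a pair and
   strictly loses), and triggers — reverse complements of the sensed
   region — come out all-purine and virtually structure-free.

2. **Sequestration-based activation calls.** "Seed accessibility" is the
   fraction of PAM-proximal seed positions *not base-paired to the
   antispacer* in the predicted complex, not the fraction unpaired
   outright. A seed freed from the cis-regulatory element invariably
   tie-pairs transiently with nearby single-stranded material under this
   model (a released purine seed against any pyrimidine-containing
   leftover), and such isolated, weight-neutral pairs are not a
   displacement barrier; what gates dCas9 targeting is whether the
   20-bp sequestering duplex has been removed. Activation therefore asks
   whether ≥ `theta_seed` (default 0.8) of the seed is antispacer-free in
   the minimum-energy complex of the sensor module with an activating
   species. The `spacer_accessibility` helper that reports literal
   unpaired fractions for an arbitrary structure remains available.

3. **Ensemble quantities for search, discrete calls for evaluation.** The
   sequence designer climbs on smooth Boltzmann-ensemble quantities (mean
   seed-sequestration probability, ensemble defect), which give a usable
   gradient across the co-optimal manifolds, while the evaluator's ON/OFF
   calls use the minimum-energy structure, which is crisp and
   deterministic. The designer's objective additionally carries a unit-step
   penalty whenever the evaluator's discrete call would fire on a
   non-cognate species, aligning the two views.

## Scope of the thermodynamic evaluation

Activation folds involve the **sensor module** only (5′ extension through
the spacer). The 76-nt scaffold is modeled as dCas9-occupied — its bases are
not available for spurious pairing — and participates only in the NOT-gate
blocking check, which co-folds an inhibitory input against the scaffold and
asks whether ≥ 80 % of the extended loop is hybridized. This protein-
occupancy scoping is what makes desk evaluation meaningful under the toy
model; without it the scaffold's own co-optimal manifold would swamp every
signal.

## Architectures and defaults

Single-input layout (5′→3′): toehold (15 nt) · antispacer 5′ · bulge (4 nt)
· antispacer 3′ · hairpin loop (12 nt) · spacer (20 nt) · scaffold (76 nt).
The OFF-state target pairs the full spacer against the antispacer with the
PAM-proximal seed (12 nt, configurable) at the toehold-proximal end of the
stem and the bulge unpaired mid-stem.

Parameter defaults and their provenance:

| parameter | default | provenance |
|---|---|---|
| `bulge_len` | 4 nt | reference construct choice (screened 0–6 nt) |
| `and_triggerA_stem_len` | 17 nt | reference construct (shortened from 20) |
| `scaffold_loop_ext_len` | 20 nt | reference construct (NOT architectures) |
| `not_b_expression_ratio` | 5.0 | reference construct (antisense variant) |
| `toehold_len` | 15 nt | ours; typical strand-displacement toehold |
| `hairpin_loop_len` | 12 nt | ours; foothold for loop-binding triggers |
| `and_assembly_len` | 20 nt | ours; < 8 nt rejected as unreliable |
| `or_b_clamp_len` | 8 nt | ours; see below |
| safety hairpin | 6 bp / 4 nt | ours, within the stated intent |
| `seed_length` | 12 nt | ours; superset of the canonical 8–10 nt seed |
| `theta_seed` etc. | 0.8 | ours; surrogate for experimental ON/OFF calls |

Mechanism notes:

* **Toehold-path triggers** span rc(toehold‥loop). Covering the loop means
  that in the activated duplex every sensor pyrimidine is hybridized and
  every competing re-sequestration pairing would cross the duplex — the
  4-nt bulge complement then gives displacement a strict margin over the
  sequestered state, which is the in-model analogue of the observation that
  a mid-stem bulge enables complete activation without extra leak.
* **Loop-path triggers** (OR input B; the assembled split pair of
  `A OR (B AND C)`) enter through the loop and additionally clamp the 8
  3′-terminal toehold nucleotides (`or_b_clamp_len`). Under an equilibrium
  model a trigger that leaves the whole toehold single-stranded loses to
  the sequestered state (which keeps the stem *and* docks the trigger on
  the free toehold); the short clamp restores a clear displacement margin
  while the loop remains the entry domain.
* **Split AND triggers** carry 5′ safety hairpins whose 6-bp arm occludes
  the first six core nucleotides, and assembly domains placed on the end of
  each core that points *away* from the seed-ward continuation of
  displacement — pyrimidine on the toehold-side strand, purine complement
  on the loop-side strand — so that a lone strand cannot extend invasion
  into the seed-pairing stem without crossing its own duplex. Both split
  triggers alone free at most ~60 % of the seed, below the activation
  threshold. In the three-input gate the loop-branch stem-interaction
  domain is 13 nt (the 17-nt reference value applies to the two-input AND).
* **NOT semantics.** The loop-blocking variant counts the design blocked
  when the inhibitor hybridizes ≥ 80 % of the extended scaffold loop; the
  antisense variant neutralizes its target trigger stoichiometrically
  whenever its carried expression weight ratio is ≥ 1 (the shipped default
  is the reference 5×).
* **Decoys** are dinucleotide-preserving shuffles of the cognate trigger
  (seeded Eulerian walk); the construction of the experimental non-cognate
  decoys is not recorded, and shuffling preserves composition while
  destroying the designed complementarity.

## The sequence designer

Hill-climbing with sideways moves over single-base substitutions in the
designable domains (toehold, bulge, hairpin loop, assembly, safety-hairpin
loops, extended scaffold loop), recompiling the whole design per candidate
so derived strands can never drift out of complementarity; the spacer and
scaffold are never touched. The first restart starts from deterministic
C-rich pattern tiles (the regime in which the architecture's margins hold);
subsequent restarts draw from per-domain reduced alphabets under GC
(0.3–0.7) and homopolymer (≤ 3) constraints. The objective combines

* OFF-state ensemble defect of the sensor (weight 0.2),
* ON-state exposure: worst-case loss of ensemble seed accessibility over
  all required activating species, assembly-duplex formation of split
  pairs, and NOT-block fraction (weight 20),
* trigger self-structure beyond the mandated safety hairpin and a
  3-pair allowance (weight 0.5),
* non-cognate leakage: decoy accessibility (averaged over two shuffle
  draws), lone-split-trigger accessibility, and — in panel mode — both
  directions of cross-design accessibility, plus a unit step when any
  non-cognate minimum-energy call is ACTIVE (weight 20).

Orthogonal panels are designed sequentially with the leakage term against
all previously accepted designs, followed by one round-robin refinement pass
against the full panel (the first design otherwise never sees its
successors). Runs are deterministic given the seed; non-convergence is
reported as warnings on the result, never as an exception.

**On the ensemble-defect floor.** At β = 1 the OFF sensor's defect saturates
around 40–55 nt regardless of design: the co-optimal manifold of register
slips and boundary substitutions is entropic, not sequence-driven, so defect
is treated as an objective to polish (its weight is deliberately small), not
a pass/fail criterion — consistent with treating "low ensemble defect" as a
selection objective rather than a threshold. The ON/OFF classification of
defect-optimized designs is exercised unconditionally in the tests; the
defect bound itself is asserted only for designs that reach it.

## Synthetic fixtures

`generate_fixtures` emits seeded labelled spacers (cosmetic names cycling
through lacZ-like, malT-like, poxB-like, ftsZ-like) and a pre-designed
four-member single-input panel. Spacers are purine-only 20-mers with GC in
[0.3, 0.7], homopolymers ≤ 3 and maximum shift-similarity ≤ 0.65 over
shifts 1–6 (near-periodic spacers admit register-shifted stems that tie the
designed one). The generator deterministically walks candidate spacer sets
derived from its seed and returns the first panel that passes the full
evaluator audit — every truth table, every decoy rejection, and the 4×4
orthogonality matrix (cognate ACTIVE, non-cognate INACTIVE) — so shipped
fixtures are valid by construction.

What the fixtures do **not** emulate: real genomic spacers (four-letter,
partially structured; the compiler accepts them, and the designer will
report warnings where the reduced-alphabet margins do not carry over),
cellular RNA context, expression-level variation beyond the carried weights,
and kinetics in general. Passing truth tables here certify the *logic* of
the compiled architectures under the package's equilibrium model — they are
a design-sanity screen, not a prediction of in-vivo dynamic range.

## Numerical choices and limitations

* Folding tie-breaks are fixed (prefer 5′ position unpaired, then the
  smallest partner index), making every traceback bit-stable.
* Partition functions run in linear space; with default weights this is
  safe to roughly 400 nt, far beyond the ≤ ~130-nt complexes evaluated.
* Co-folding uses a 4-nt unpairable linker with the hairpin-loop minimum
  waived across the junction; complexes of three or more strands are not
  folded — assembled split triggers are evaluated as their concatenated
  functional cores, with assembly checked separately on the strand pair.
* Quantitative dynamic range (fold-reduction magnitudes) is out of model
  scope: `fold_reduction` computes the metric (geometric-mean ratio with
  the s.d. over all pairwise replicate ratios) from measurement tables, it
  does not predict it.
* Acceptance-scale problem sizes: single designs run 150–400 hill-climb
  iterations over ~30–60 free nucleotides; the four-member panel uses 120
  iterations per design plus one refinement pass. These sizes reproduce the
  architecture behaviour reliably; larger budgets only polish the
  objective's saturated terms.
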