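# Methods

## Sequence model

The generator is a character-level language model over SMILES strings.  A
molecule `S = s_1 … s_t` is modelled autoregressively,
`P_θ(S) = Π_t P_θ(s_t | s_1 … s_{t-1})`, with a stack of LSTM layers and a
dense projection from the top hidden state to vocabulary logits; softmax is
applied only when sampling or evaluating likelihoods.  Each molecule is
bracketed by a start symbol `G` and an end symbol `\n`; the vocabulary is
the set of unique characters in the corpus plus these two delimiters,
ordered by code point for reproducibility.  Tokenization is strictly per
character, so `Cl` is two tokens.

Training uses teacher forcing on next-character targets with cross-entropy
loss, backpropagation through time, and Adam with global gradient-norm
clipping at 5.  The training stream is the concatenation `G + molecule +
\n` over the whole corpus, cut into non-overlapping windows of
`window_length` tokens (default 75) with hidden state reset per window; the
last 5% of windows are held out for monitoring and never trained on.
Inter-layer inverted dropout (default 0.2) is applied between LSTM layers
during training only.

The implementation is plain NumPy.  Correctness is checked two independent
ways in the test suite: analytic BPTT gradients against central finite
differences on a float64 toy model, and the parameter tally of the built
model against the closed form `Σ_layers 4·(H·(D+H) + b·H) + H·V + V`
(`b` = bias vectors per gate; both the one- and two-bias conventions round
to 21 million parameters at the 53-vocabulary, 3×1024 scale).

Sampling starts each molecule from `G` with zeroed hidden and cell states
and draws symbols from the softmax at temperature 1 until `\n`.  Chains
exceeding `max_sample_length` (default 120) characters are discarded and
restarted.  Sampling runs many chains in parallel and stops once the
emitted stream reaches the requested character budget; a hard cap on total
drawn tokens guarantees termination even for a degenerate model that never
emits the end symbol.  All randomness flows through seeded
`numpy.random.Generator` streams, one per pipeline stage (sampling,
tie-breaking, archive eviction, fingerprint subsampling), derived from the
master seed via `SeedSequence` so stages are independently reproducible.

## Objectives and chemistry

All structure handling is delegated to RDKit.  A sampled string is
whitespace-stripped (spaces inside otherwise well-formed SMILES are
typographic noise), parsed, and canonicalized; invalidity is a value, not
an exception.  Valid molecules get the five-objective vector

| objective   | definition                              | RO3 bound |
|-------------|-----------------------------------------|-----------|
| logP        | Wildman–Crippen octanol–water logP      | ≤ 3       |
| mol_weight  | average molecular weight (g/mol)        | ≤ 480     |
| hbd         | Lipinski H-bond donor count             | ≤ 3       |
| hba         | Lipinski H-bond acceptor count          | ≤ 3       |
| rot_bonds   | rotatable bonds (non-strict definition) | ≤ 3       |

The weight bound is the Ghose-filter 480 g/mol variant of the fragment
rule (which originally bounds molecular *mass* at 300 Da).  Bounds are
inclusive.  Constraint satisfaction is reported as the percentage of
molecules meeting at least k of the five bounds, k = 1…5.

Deduplication and novelty use canonical-SMILES string equality; novelty is
checked against the original training corpus only, not against earlier
iterations.  Structural diversity is the mean Tanimoto similarity
`T(a,b) = |m_a ∩ m_b| / |m_a ∪ m_b|` over Morgan fingerprints (radius 2,
2048 bits by default) of all pairs in a seeded random sample of up to 500
molecules; two all-zero fingerprints are defined to have `T = 0`.

## Selection

All five objectives are minimized directly on their raw descriptor values —
no scalarization, no hinge on the bounds (a hinge mode
`max(0, value − bound)` exists but is not the default).  The
Fonseca–Fleming rank of a molecule is the exact count of population members
dominating it, computed by the O(k²) pairwise rule; the rank-0 set is the
Pareto front.  Selection takes the best `floor(k/2)` members: whole rank
classes in increasing order, with the boundary class subsampled uniformly at
random under a dedicated seed (so a population of 9,415 yields exactly
4,707).  The elite archive is capped (10,000 at full scale, 1,000 at desk
scale); after each iteration the newly generated unique/novel molecules are
merged in (deduplicated by canonical SMILES), the union is re-ranked, and
the same rank-then-random rule trims it back to the cap.  The boundary-only
scope of the random tie-break is a design choice; the alternative
(randomizing across all tied classes) would only matter when a single rank
class straddles the quota.

Each iteration's fine-tuning set is the selected half of (new unique/novel
molecules ∪ archive); per-iteration metrics are computed on the new
unique/novel molecules alone, so reported percentages describe what the
generator currently samples, not the accumulated elite.

## Synthetic corpus

The fixture generator assembles molecules from a template grammar rather
than random characters, so every emitted string is valid by construction:

* a **compliant family** (substituted benzenes and pyridines, small
  saturated rings, short functionalized chains) whose members always
  satisfy all five constraints, and
* a **violating family** (long mixed C/O/N chains, polyethers, polyamines,
  greasy aryl chains) whose members always break at least one constraint by
  a wide margin — e.g. any linear chain of ≥ 10 backbone atoms has > 3
  rotatable bonds regardless of decoration.

Mixing the families at probability `fraction_in_ro3_region` (default 0.10)
therefore controls the in-region fraction directly; the realized fraction
is re-measured with the chemistry layer after generation and must fall
within ±10 percentage points of the target, otherwise the spec is declared
infeasible.  At n = 1000 roughly 70–75% of canonical forms are distinct.

What the fixture does *not* emulate: real drug-like property
distributions, stereochemistry, charged species, fused polycyclics, or the
35–75-character length profile of a curated corpus.  Desk-scale results
therefore demonstrate that the optimization loop works — that Pareto-driven
fine-tuning shifts a trained generator toward the feasible region — not
that any particular full-scale number would be reproduced on real data.

## Scale profiles and defaults

The default study conditions for tests are the desk profile: a
5,000-molecule fixture corpus with ~10% in-region, a 2-layer × 128-unit
generator trained 20 epochs (enough to reach ≈ 78% sampling validity on
the fixture grammar), 3 cycle iterations of 50,000 sampled characters, and
an archive cap of 1,000.  One full desk cycle takes roughly two minutes on
a single CPU.  The full-scale profile (3 × 1024 units, dropout 0.2,
windows of 75, batch 128, five iterations of 10⁶ characters, cap 10,000)
is exposed behind `--paper-scale` and is intended for a ChEMBL-class corpus.

Fine-tuning defaults differ by profile.  The generator's generic default is
one epoch at a tenth of the source learning rate — a conservative setting
for large selections.  The desk profile instead fine-tunes 5 epochs at a
third of the source rate: a desk-scale selection is only ~1,000–2,500 short
molecules (about 20 gradient steps per epoch), and a single low-rate epoch
measurably cannot move the sampling distribution.  Both knobs are plain
config fields.

Other numerical choices: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at learning
rate 3e-3; forget-gate biases initialized to 1; weights uniform in
±1/√fan-in; float32 parameters (float64 only in gradient tests); sampling
temperature fixed at 1.0; softmax stabilized by max-subtraction;
cross-entropy clamped at 1e-12.  Corpus lines that fail RDKit parsing are
still used for language-model training but excluded from the novelty
reference set.

## Known limitations

* Descriptor-space optimization only; no synthesizability, activity, or
  3-D terms — one good objective can carry an otherwise unreasonable
  molecule through selection.
* The O(k²) ranking is quadratic in population size; fine for ≤ ~10⁵
  molecules per iteration, not for orders beyond.
* Character-level sampling can emit unparseable strings by design; validity
  is a measured outcome, not a guarantee.
* The NumPy trainer is single-device and CPU-bound; full-scale training is
  possible in principle but slow, and the full-scale percentages reported
  for ChEMBL-class runs are not verified by this package's test suite.
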