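# molcycle

Multiobjective de novo molecule design: a character-level recurrent SMILES
generator whose outputs are Pareto-ranked on five physicochemical objectives
and fed back as fine-tuning data, iteration after iteration.

## The problem

Early-stage drug discovery needs candidate molecules that satisfy several
physicochemical criteria *at once*.  Screening pre-made libraries scales
poorly, and single-objective generative approaches tend to trade one property
for another.  `molcycle` implements an in-silico analogue of the
design–synthesis–test cycle:

1. **Generate.**  A stacked-LSTM language model over SMILES characters,
   trained by next-character cross-entropy (teacher forcing, Adam), samples
   new molecules autoregressively: each starts at the start symbol `G` and
   runs until the end symbol `\n`.
2. **Test.**  RDKit scores each valid, unique, novel molecule on five
   minimization objectives, u = (logP, MW, HBD, HBA, RotB), checked against
   the modified Rule of Three: logP ≤ 3, molecular weight ≤ 480 g/mol
   (the Ghose bound), ≤ 3 H-bond donors, ≤ 3 acceptors, ≤ 3 rotatable bonds.
3. **Select.**  Fonseca–Fleming nondominated sorting ranks every molecule by
   the number of population members that dominate it (u² dominates u¹ iff
   u²ᵢ ≤ u¹ᵢ for all i with at least one strict inequality; rank 0 is the
   Pareto front).  The best half of the generated molecules, pooled with a
   capped elite archive, becomes the fine-tuning set.
4. **Learn.**  The generator is retrained on the selection (transfer
   learning), shifting its sampling distribution toward the feasible region.

No hand-written scoring function is involved: selection pressure comes
entirely from Pareto domination on raw descriptor values.

The LSTM is implemented directly in NumPy (forward pass, backpropagation
through time, Adam, multinomial sampling) and is verified against
finite-difference gradients and a closed-form parameter-count formula; at
full scale (53-character vocabulary, three layers of 1024 units) it carries
21,255,221 trainable parameters — 21 million.

## Worked example

Every input can be synthesized on the spot — the `fixtures` module writes a
deterministic corpus of valid SMILES with a controllable fraction (default
10%) inside the Rule-of-Three region:

```sh
molcycle fixtures --n 5000 --seed 0 --out corpus.smi
molcycle -v cycle --corpus corpus.smi --outdir run/
```

or equivalently in Python:

```python
from molcycle import CycleConfig, FixtureSpec, generate_fixture_corpus, run_cycle
from molcycle.fixtures import write_corpus
from molcycle import build_vocabulary

mols = generate_fixture_corpus(FixtureSpec())     # 5000 molecules, seed 0
write_corpus(mols, "corpus.smi")
config = CycleConfig.desk(vocab_size=build_vocabulary(mols).size, seed=0)
reports, model, archive = run_cycle("corpus.smi", config, outdir="run/")
```

The desk-scale profile (2×128-unit LSTM, 3 iterations of 50,000 sampled
characters, archive cap 1,000) finishes in about two minutes on one CPU
and writes `run/report.tsv`:

```
iteration	pct_ge_1	pct_ge_2	pct_ge_3	pct_ge_4	pct_ge_5	pct_valid	mean_tanimoto
0	99.56	97.65	79.38	37.18	5.33	77.76	0.1797
1	99.39	96.60	79.04	41.37	9.36	80.13	0.1751
2	100.00	99.47	86.17	47.18	14.72	82.74	0.1792
3	100.00	98.26	81.76	42.53	15.32	82.57	0.1864
```

Each row describes the unique, novel, valid molecules sampled at that
iteration (iteration 0 = the source-trained model, before any fine-tuning).
`pct_ge_k` is the percentage satisfying at least k of the five constraints —
necessarily non-increasing in k.  Here the fraction satisfying **all five**
constraints nearly triples, from 5.33% to 15.32%, while validity rises from
77.8% to 82.6% and the mean pairwise Tanimoto similarity of Morgan
fingerprints (structural redundancy; lower = more diverse) stays near the
training corpus level.  The loop is byte-for-byte reproducible under a fixed
seed.

Full-scale settings — a 3×1024 generator, five iterations of one million
sampled characters against a 10,000-molecule archive — suit a corpus on the
order of 500,000 drug-like molecules (e.g. a ChEMBL extract, 35–75
characters per SMILES) and GPU-class training time; given such a corpus the
command is

```sh
molcycle cycle --corpus chembl.smi --outdir run-full/ --paper-scale
```

This run is not part of the test suite.

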