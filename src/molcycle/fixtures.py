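"""Deterministic synthetic SMILES corpora with known property structure.

Real training corpora for the generator are hundreds of thousands of
drug-like molecules; tests need a few thousand strings that (a) are valid
SMILES by construction, (b) exercise rings, branches, heteroatoms and
halogens so the character-level model has real grammar to learn, and (c)
contain a controllable fraction of molecules inside the modified
Rule-of-Three region (logP <= 3, MW <= 480, HBD/HBA/rotatable bonds <= 3).

Molecules are assembled from two template families rather than random
characters, so validity never depends on toolkit parse-failure rates:

* a *compliant* family — substituted benzenes, small saturated rings and
  short functionalized chains whose descriptors predictably sit inside the
  RO3 region;
* a *violating* family — long alkanes, polyethers, polyamines and greasy
  aryl chains that each break at least one constraint by a wide margin
  (too many rotatable bonds, acceptors, donors, or too lipophilic).

The realized in-region fraction therefore tracks the requested mixing
fraction closely; it is re-measured with the chemistry layer after
generation and must land within +/-10 percentage points of the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus."""

    n_molecules: int = 5000
    seed: int = 0
    length_bounds: tuple[int, int] = (5, 100)
    fraction_in_ro3_region: float = 0.10

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")
        lo, hi = self.length_bounds
        if not (5 <= lo <= hi <= 120):
            raise ValueError("length bounds must lie within [5, 120]")
        if not (0.0 <= self.fraction_in_ro3_region <= 1.0):
            raise ValueError("fraction must be in [0, 1]")


# substituents in prefix form (written before the ring) and branch form
# (written inside parentheses); chosen so any combination below keeps a
# benzene inside the RO3 region
_PREFIX_SUBS = ["C", "CC", "O", "N", "F", "Cl", "CO", "CC(=O)", "N#C"]
_BRANCH_SUBS = ["C", "O", "N", "F", "Cl", "OC", "C(=O)C", "C#N"]
_CHAIN_CAPS = ["O", "N", "C(=O)O", "C(=O)N", "OC", "C(C)O"]
_SMALL_RINGS = ["C1CCCC1", "C1CCCCC1", "C1CCOC1", "C1CCNC1", "C1CCOCC1"]
_AROMATIC_CORES = ["c1ccccc1", "c1ccncc1"]


def _compliant(rng) -> str:
    kind = rng.integers(0, 3)
    if kind == 0:  # substituted benzene / pyridine
        core = _pick(rng, _AROMATIC_CORES)
        n_subs = int(rng.integers(0, 3))
        if n_subs == 0:
            return core
        if n_subs == 1:
            return _pick(rng, _PREFIX_SUBS) + core
        if core == "c1ccccc1":
            pattern = _pick(rng, ["{x}c1ccc({y})cc1", "{x}c1cccc({y})c1",
                                  "{x}c1ccccc1{y}"])
        else:
            pattern = "{x}c1ccnc({y})c1"
        return pattern.format(x=_pick(rng, _PREFIX_SUBS), y=_pick(rng, _BRANCH_SUBS))
    if kind == 1:  # short functionalized chain, optionally methyl-branched
        chain = "C" * int(rng.integers(1, 4))
        if len(chain) > 1 and rng.random() < 0.3:
            chain = chain[:-1] + "C(C)"
        return chain + _pick(rng, _CHAIN_CAPS)
    # small saturated ring, optionally with one polar handle
    ring = _pick(rng, _SMALL_RINGS)
    if rng.random() < 0.5:
        return _pick(rng, ["O", "N", "C"]) + ring
    return ring


def _hetero_chain(rng, n_atoms: int) -> str:
    """Linear mixed C/O/N chain; heteroatoms never adjacent; optional
    methyl branches.  Any chain of >= 10 backbone atoms has > 3 rotatable
    bonds, so these are violators by construction."""
    atoms = []
    prev_hetero = True  # never start on a heteroatom
    for _ in range(n_atoms):
        if not prev_hetero and rng.random() < 0.3:
            atoms.append(_pick(rng, ["O", "N"]))
            prev_hetero = True
        else:
            atoms.append("C")
            prev_hetero = False
    # methyl branches on interior carbons
    parts = []
    for i, a in enumerate(atoms):
        parts.append(a)
        if a == "C" and 0 < i < n_atoms - 1 and rng.random() < 0.2:
            parts.append("(C)")
    return "".join(parts)


def _violating(rng) -> str:
    # the mixed-chain families carry most of the corpus entropy; the
    # regular polyether/polyamine families are kept rarer
    u = rng.random()
    if u < 0.40:  # mixed heteroatom chain: rotatable bonds blow up
        return _hetero_chain(rng, int(rng.integers(10, 26)))
    if u < 0.55:  # polyether: acceptors and rotatable bonds blow up
        return ("C" * int(rng.integers(1, 4))
                + "OCC" * int(rng.integers(4, 8))
                + _pick(rng, ["", "C", "O"]))
    if u < 0.70:  # polyamine: donors blow up
        return (_pick(rng, ["N", "CN"]) + "CCN" * int(rng.integers(4, 8))
                + _pick(rng, ["", "C"]))
    # greasy aryl chain: logP and rotatable bonds blow up
    return _hetero_chain(rng, int(rng.integers(8, 14))) + _pick(rng, _AROMATIC_CORES)


def _pick(rng, seq):
    return seq[int(rng.integers(0, len(seq)))]


def generate_fixture_corpus(spec: FixtureSpec = FixtureSpec()) -> list[str]:
    """Emit ``spec.n_molecules`` valid SMILES with the requested RO3 mix.

    Deterministic in ``spec.seed``.  Raises if the realized fraction of
    molecules satisfying all five constraints (measured with the chemistry
    layer) deviates from the target by more than 10 percentage points,
    which would indicate an infeasible spec (e.g. length bounds that
    exclude one family entirely).
    """
    from molcycle.chem_eval import ConstraintSet, count_satisfied, parse_and_canonicalize

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_bounds
    out: list[str] = []
    max_attempts = spec.n_molecules * 200
    attempts = 0
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "length bounds reject too many template molecules; spec infeasible"
            )
        s = (_compliant(rng) if rng.random() < spec.fraction_in_ro3_region
             else _violating(rng))
        if lo <= len(s) <= hi:
            out.append(s)

    constraints = ConstraintSet()
    n_in = 0
    for s in out:
        rec = parse_and_canonicalize(s)
        if not rec.valid:
            raise AssertionError(f"template grammar emitted an unparseable string: {s!r}")
        if count_satisfied(rec.descriptors, constraints) == 5:
            n_in += 1
    realized = n_in / len(out)
    logger.info("fixture corpus: %d molecules, %.1f%% in RO3 region",
                len(out), 100 * realized)
    if abs(realized - spec.fraction_in_ro3_region) > 0.10:
        raise ValueError(
            f"realized RO3 fraction {realized:.3f} is more than 10 points from "
            f"target {spec.fraction_in_ro3_region:.3f}; spec infeasible"
        )
    return out


def write_corpus(molecules: list[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in molecules:
            fh.write(m + "\n")
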