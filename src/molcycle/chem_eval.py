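"""Chemistry layer: validity, descriptors, constraint counting, diversity.

All structure handling goes through RDKit.  The five design objectives are
the modified Rule of Three (RO3) descriptors, all minimized:

==============  ======================================  ==========
objective       definition                              RO3 bound
==============  ======================================  ==========
logP            Wildman–Crippen octanol–water logP      <= 3
mol_weight      average molecular weight (g/mol)        <= 480
hbd             Lipinski H-bond donor count             <= 3
hba             Lipinski H-bond acceptor count          <= 3
rot_bonds       rotatable bond count (non-strict)       <= 3
==============  ======================================  ==========

The molecular-weight bound is the Ghose-filter 480 g/mol variant rather than
the 300 Da molecular-mass bound of the original fragment rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

# candidate strings sampled from an undertrained model are mostly garbage;
# keep RDKit's parse warnings out of the logs
RDLogger.DisableLog("rdApp.*")

OBJECTIVE_NAMES = ("logP", "mol_weight", "hbd", "hba", "rot_bonds")


@dataclass(frozen=True)
class ObjectiveVector:
    """The five RO3 descriptors of one molecule, as a minimization vector."""

    logP: float
    mol_weight: float
    hbd: int
    hba: int
    rot_bonds: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.logP, self.mol_weight, self.hbd, self.hba, self.rot_bonds],
            dtype=float,
        )


@dataclass
class MoleculeRecord:
    """A raw SMILES string with its parse outcome and descriptors.

    ``valid``, ``canonical_smiles`` and ``descriptors`` stand or fall
    together: an unparseable string has neither a canonical form nor
    descriptor values.
    """

    raw_smiles: str
    valid: bool
    canonical_smiles: str | None = None
    descriptors: ObjectiveVector | None = None
    novel: bool = True


@dataclass(frozen=True)
class ConstraintSet:
    """Upper bounds on the five objectives; defaults are the modified RO3."""

    bounds: tuple[float, ...] = (3.0, 480.0, 3.0, 3.0, 3.0)

    def __post_init__(self):
        if len(self.bounds) != len(OBJECTIVE_NAMES):
            raise ValueError("one bound per objective is required")
        if not all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")


def canonical_smiles(smiles: str) -> str | None:
    """Canonical form of a SMILES string, or None if it does not parse.

    Whitespace is stripped first: sampled strings occasionally carry spaces
    inside otherwise well-formed SMILES, and those are typographic noise, not
    chemistry.
    """
    cleaned = "".join(smiles.split())
    if not cleaned:
        return None
    mol = Chem.MolFromSmiles(cleaned)
    return None if mol is None else Chem.MolToSmiles(mol)


def parse_and_canonicalize(smiles: str) -> MoleculeRecord:
    """Parse a candidate string; invalidity is a value, not an exception."""
    cleaned = "".join(smiles.split())
    mol = Chem.MolFromSmiles(cleaned) if cleaned else None
    if mol is None:
        return MoleculeRecord(raw_smiles=smiles, valid=False)
    return MoleculeRecord(
        raw_smiles=smiles,
        valid=True,
        canonical_smiles=Chem.MolToSmiles(mol),
        descriptors=_descriptors_from_mol(mol),
    )


def _descriptors_from_mol(mol) -> ObjectiveVector:
    return ObjectiveVector(
        logP=Crippen.MolLogP(mol),
        mol_weight=Descriptors.MolWt(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rot_bonds=Lipinski.NumRotatableBonds(mol),
    )


def compute_descriptors(record: MoleculeRecord) -> ObjectiveVector:
    """Descriptor vector of a valid record (contract: record.valid)."""
    if not record.valid:
        raise ValueError("descriptors are undefined for an invalid molecule")
    if record.descriptors is None:
        mol = Chem.MolFromSmiles(record.canonical_smiles)
        record.descriptors = _descriptors_from_mol(mol)
    return record.descriptors


def count_satisfied(
    desc: ObjectiveVector, constraints: ConstraintSet = ConstraintSet()
) -> int:
    """How many of the five bounds the molecule meets (bounds inclusive)."""
    return int(np.sum(desc.as_array() <= np.asarray(constraints.bounds)))


def filter_unique_valid_novel(
    records: list[MoleculeRecord], training_set: frozenset[str] | set[str]
) -> list[MoleculeRecord]:
    """Keep valid molecules, first occurrence by canonical form, not in training.

    Order of first occurrence is preserved; the ``novel`` flag is set on every
    valid record as a side effect.
    """
    seen: set[str] = set()
    kept = []
    for rec in records:
        if not rec.valid:
            continue
        rec.novel = rec.canonical_smiles not in training_set
        if not rec.novel or rec.canonical_smiles in seen:
            continue
        seen.add(rec.canonical_smiles)
        kept.append(rec)
    return kept


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def morgan_fingerprint(
    record: MoleculeRecord, radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    """Morgan (circular) fingerprint of a valid record as a uint8 bit vector."""
    if not record.valid:
        raise ValueError("fingerprints are undefined for an invalid molecule")
    key = (radius, n_bits)
    gen = _FP_GENERATORS.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        _FP_GENERATORS[key] = gen
    mol = Chem.MolFromSmiles(record.canonical_smiles)
    return np.array(gen.GetFingerprint(mol), dtype=np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∩ b| / |a ∪ b| over two equal-length bit vectors.

    Two all-zero fingerprints are defined to have similarity 0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def mean_pairwise_tanimoto(
    records: list[MoleculeRecord],
    sample_size: int = 500,
    seed: int = 0,
    radius: int = 2,
    n_bits: int = 2048,
) -> float:
    """Mean Tanimoto similarity over all pairs of a seeded random sample.

    Lower values mean a structurally more diverse population.
    """
    valid = [r for r in records if r.valid]
    if len(valid) < 2:
        raise ValueError("need at least 2 valid molecules")
    rng = np.random.default_rng(seed)
    if len(valid) > sample_size:
        picked = [valid[i] for i in rng.choice(len(valid), sample_size, replace=False)]
    else:
        picked = valid
    fps = np.array([morgan_fingerprint(r, radius, n_bits) for r in picked], dtype=bool)
    # vectorized pairwise counts: all pairs of a few hundred fingerprints
    inter = (fps.astype(np.int32) @ fps.T.astype(np.int32))
    popcnt = fps.sum(axis=1)
    union = popcnt[:, None] + popcnt[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    iu = np.triu_indices(len(picked), k=1)
    return float(sim[iu].mean())


def descriptor_table(records: list[MoleculeRecord], constraints=ConstraintSet()):
    """Descriptor DataFrame (canonical_smiles, five objectives, n_satisfied)."""
    import pandas as pd

    rows = []
    for rec in records:
        if not rec.valid:
            continue
        d = compute_descriptors(rec)
        rows.append(
            {
                "canonical_smiles": rec.canonical_smiles,
                "logP": d.logP,
                "mol_weight": d.mol_weight,
                "hbd": d.hbd,
                "hba": d.hba,
                "rot_bonds": d.rot_bonds,
                "n_satisfied": count_satisfied(d, constraints),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "canonical_smiles",
            "logP",
            "mol_weight",
            "hbd",
            "hba",
            "rot_bonds",
            "n_satisfied",
        ],
    )
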