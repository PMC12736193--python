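"""Batch-level scores for generated molecules: validity, uniqueness,
internal diversity and drug-likeness (QED).

Validity is the fraction of strings the sanitizing parser accepts (empty
strings count as invalid). Uniqueness is the fraction of distinct canonical
forms among the valid entries. Internal diversity is one minus the mean
pairwise Tanimoto similarity of radius-2, 2048-bit circular (Morgan)
fingerprints over all unordered pairs of valid molecules. QED is the usual
[0, 1] composite desirability score, averaged over valid molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import QED, rdFingerprintGenerator

from .chem import canonical_smiles

__all__ = [
    "GenerationReport",
    "validity",
    "uniqueness",
    "internal_diversity",
    "mean_qed",
    "report",
]

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _mols(smiles_list: Sequence[str]):
    """Parsed molecules for the valid entries, in order."""
    mols = []
    for s in smiles_list:
        if not s:
            continue
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            mols.append(mol)
    return mols


def validity(smiles_list: Sequence[str]) -> float:
    """Fraction of the list accepted by the sanitizing parser."""
    if len(smiles_list) == 0:
        raise ValueError("validity of an empty list is undefined")
    return len(_mols(smiles_list)) / len(smiles_list)


def uniqueness(smiles_list: Sequence[str]) -> float:
    """Distinct canonical forms over valid entries.

    Raises
    ------
    ValueError
        If no entry is valid (canonical forms undefined).
    """
    canon = [c for c in (canonical_smiles(s) for s in smiles_list) if c is not None]
    if not canon:
        raise ValueError("uniqueness requires at least one valid SMILES")
    return len(set(canon)) / len(canon)


def internal_diversity(smiles_list: Sequence[str]) -> float:
    """1 - mean pairwise Tanimoto similarity over valid molecules.

    Raises
    ------
    ValueError
        With fewer than two valid entries.
    """
    mols = _mols(smiles_list)
    if len(mols) < 2:
        raise ValueError("internal diversity requires at least two valid molecules")
    fps = [_FP_GEN.GetFingerprint(m) for m in mols]
    sims = []
    for i in range(len(fps) - 1):
        sims.extend(DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :]))
    return float(1.0 - np.mean(sims))


def mean_qed(smiles_list: Sequence[str]) -> float:
    """Mean QED over valid molecules; each score lies in [0, 1]."""
    mols = _mols(smiles_list)
    if not mols:
        raise ValueError("mean QED requires at least one valid SMILES")
    return float(np.mean([QED.qed(m) for m in mols]))


@dataclass(frozen=True)
class GenerationReport:
    """All four batch metrics plus the underlying counts.

    ``validity`` is computed over the whole input; ``validity_nonempty``
    restricts the denominator to non-empty strings (the natural score after
    trimming repair, which can produce empties).
    """

    validity: float
    validity_nonempty: float
    uniqueness: float
    diversity: float
    mean_qed: float
    n_input: int
    n_valid: int
    n_unique: int

    def __post_init__(self) -> None:
        if not self.n_unique <= self.n_valid <= self.n_input:
            raise ValueError("counts must satisfy n_unique <= n_valid <= n_input")


def report(smiles_list: Sequence[str]) -> GenerationReport:
    """Score a batch with all four metrics on a consistent valid subset."""
    if len(smiles_list) == 0:
        raise ValueError("cannot score an empty batch")
    canon = [canonical_smiles(s) for s in smiles_list]
    valid = [c for c in canon if c is not None]
    nonempty = [s for s in smiles_list if s]
    return GenerationReport(
        validity=len(valid) / len(smiles_list),
        validity_nonempty=(len(valid) / len(nonempty)) if nonempty else 0.0,
        uniqueness=uniqueness(smiles_list),
        diversity=internal_diversity(smiles_list),
        mean_qed=mean_qed(smiles_list),
        n_input=len(smiles_list),
        n_valid=len(valid),
        n_unique=len(set(valid)),
    )
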