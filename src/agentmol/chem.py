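"""Thin wrappers around the cheminformatics toolkit used as the validity oracle.

A SMILES string is *valid* iff it is non-empty and parses **and** sanitizes.
The empty string is never valid (an empty molecule is not a candidate ligand).
"""

from __future__ import annotations

from rdkit import Chem, RDLogger

# Parsing junk strings is routine here; keep the console quiet.
RDLogger.DisableLog("rdApp.*")


def is_valid_smiles(smiles: str) -> bool:
    """Return True iff ``smiles`` is non-empty and parses + sanitizes."""
    if not smiles:
        return False
    return Chem.MolFromSmiles(smiles) is not None


def canonical_smiles(smiles: str) -> str | None:
    """Canonical form of ``smiles``, or None if it does not parse."""
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)
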