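"""Reading, transforming, filtering and splitting ligand-protein affinity tables.

The atomic record is a :class:`LigandProteinPair`: one ligand SMILES, one
target amino-acid sequence and an inhibition constant, either as Ki in
nanomolar or as pKi (the negative base-10 log of Ki on the molar scale,
``pKi = 9 - log10(Ki[nM])``; higher pKi means tighter binding).

Preprocessing mirrors the standard affinity-regression recipe: transform Ki
to pKi, drop pairs whose combined SMILES+protein length exceeds 800
characters, and drop pairs with pKi above 10; then split 70/30 at the pair
level for training.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LigandProteinPair",
    "AffinityDataset",
    "DatasetSummary",
    "ColumnMap",
    "ki_to_pki",
    "pki_to_ki",
    "read_pairs",
    "filter_pairs",
    "split_dataset",
    "summarize",
]

_CONSISTENCY_TOL = 1e-9


def ki_to_pki(ki_nM: float) -> float:
    """Transform an inhibition constant in nM into pKi.

    pKi = -log10(Ki[M]) = 9 - log10(Ki[nM]); monotonically decreasing in Ki.

    Raises
    ------
    ValueError
        If ``ki_nM`` is not strictly positive.
    """
    if not ki_nM > 0:
        raise ValueError(f"Ki must be strictly positive (nM), got {ki_nM!r}")
    return 9.0 - math.log10(ki_nM)


def pki_to_ki(pki: float) -> float:
    """Inverse of :func:`ki_to_pki`: Ki in nM for a given pKi."""
    return 10.0 ** (9.0 - pki)


@dataclass(frozen=True)
class LigandProteinPair:
    """One ligand-protein record: SMILES + amino-acid sequence + affinity.

    Either or both of ``ki_nM`` (nanomolar, positive) and ``pki`` may be
    present; when both are, they must agree through the pKi transform.
    """

    smiles: str
    protein_seq: str
    ki_nM: float | None = None
    pki: float | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if not self.protein_seq:
            raise ValueError("protein_seq must be non-empty")
        if self.ki_nM is not None and not self.ki_nM > 0:
            raise ValueError(f"ki_nM must be positive, got {self.ki_nM!r}")
        if self.ki_nM is not None and self.pki is not None:
            if abs(self.pki - ki_to_pki(self.ki_nM)) > 1e-6:
                raise ValueError(
                    f"inconsistent affinities: ki_nM={self.ki_nM!r} implies "
                    f"pKi={ki_to_pki(self.ki_nM):.9f}, got {self.pki!r}"
                )

    @property
    def pair_length(self) -> int:
        """Combined character length of SMILES and protein sequence."""
        return len(self.smiles) + len(self.protein_seq)


@dataclass
class AffinityDataset:
    """An ordered collection of :class:`LigandProteinPair` records."""

    pairs: list[LigandProteinPair] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[LigandProteinPair]:
        return iter(self.pairs)

    def __getitem__(self, i: int) -> LigandProteinPair:
        return self.pairs[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles": [p.smiles for p in self.pairs],
                "protein_seq": [p.protein_seq for p in self.pairs],
                "ki_nM": [p.ki_nM for p in self.pairs],
                "pki": [p.pki for p in self.pairs],
            }
        )

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class ColumnMap:
    """Names of the SMILES / protein-sequence / Ki columns in a table."""

    smiles: str = "smiles"
    protein: str = "protein_seq"
    ki: str = "ki_nM"


@dataclass(frozen=True)
class DatasetSummary:
    """Descriptive statistics of pair length and pKi for a dataset."""

    n: int
    mean_length: float
    std_length: float
    min_length: float
    quartiles_length: tuple[float, float, float]
    max_length: float
    mean_pki: float
    std_pki: float
    min_pki: float
    quartiles_pki: tuple[float, float, float]
    max_pki: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def read_pairs(
    path: str | Path,
    column_map: ColumnMap | Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> AffinityDataset:
    """Read ligand-protein pairs from a CSV/TSV export.

    Rows with a missing/empty SMILES or sequence, or a missing, non-numeric
    or non-positive Ki, are dropped; drop counts are emitted on the module
    logger. pKi is computed from Ki on ingestion.

    Parameters
    ----------
    path
        Tabular file; the delimiter is sniffed unless ``delimiter`` is given.
    column_map
        Names of the smiles / protein / ki columns.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    KeyError
        If a mapped column is absent (the message names it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if column_map is None:
        column_map = ColumnMap()
    elif isinstance(column_map, Mapping):
        column_map = ColumnMap(
            smiles=column_map.get("smiles", "smiles"),
            protein=column_map.get("protein", "protein_seq"),
            ki=column_map.get("ki", "ki_nM"),
        )

    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)

    for col in (column_map.smiles, column_map.protein, column_map.ki):
        if col not in df.columns:
            raise KeyError(f"required column {col!r} not found in {path.name}")

    pairs: list[LigandProteinPair] = []
    drops = {"smiles": 0, "protein": 0, "ki": 0}
    for _, rec in df.iterrows():
        smiles = rec[column_map.smiles]
        protein = rec[column_map.protein]
        ki_raw = rec[column_map.ki]
        if pd.isna(smiles) or not str(smiles).strip():
            drops["smiles"] += 1
            continue
        if pd.isna(protein) or not str(protein).strip():
            drops["protein"] += 1
            continue
        try:
            ki = float(ki_raw)
        except (TypeError, ValueError):
            drops["ki"] += 1
            continue
        if not math.isfinite(ki) or ki <= 0:
            drops["ki"] += 1
            continue
        pairs.append(
            LigandProteinPair(
                smiles=str(smiles).strip(),
                protein_seq=str(protein).strip().upper(),
                ki_nM=ki,
                pki=ki_to_pki(ki),
            )
        )
    n_dropped = sum(drops.values())
    if n_dropped:
        logger.info(
            "read_pairs(%s): dropped %d row(s) (smiles=%d, protein=%d, ki=%d)",
            path.name, n_dropped, drops["smiles"], drops["protein"], drops["ki"],
        )
    return AffinityDataset(pairs=pairs, provenance=str(path))


def filter_pairs(
    ds: AffinityDataset,
    max_pair_length: int = 800,
    max_pki: float = 10.0,
) -> AffinityDataset:
    """Keep pairs with pair_length <= ``max_pair_length`` and pKi <= ``max_pki``.

    Both bounds are inclusive; order is preserved; exclusion counts are
    logged. Every pair must already carry a pKi.

    Raises
    ------
    RuntimeError
        If any pair lacks a pKi value.
    """
    for i, p in enumerate(ds):
        if p.pki is None:
            raise RuntimeError(f"pair {i} has no pKi; transform Ki before filtering")
    kept: list[LigandProteinPair] = []
    n_len = n_pki = 0
    for p in ds:
        if p.pair_length > max_pair_length:
            n_len += 1
            continue
        if p.pki > max_pki:
            n_pki += 1
            continue
        kept.append(p)
    if n_len or n_pki:
        logger.info(
            "filter_pairs: excluded %d by length > %d, %d by pKi > %g",
            n_len, max_pair_length, n_pki, max_pki,
        )
    return AffinityDataset(pairs=kept, provenance=ds.provenance)


def split_dataset(
    ds: AffinityDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[AffinityDataset, AffinityDataset]:
    """Randomly partition a dataset into train/validation at the pair level.

    The train set gets ``floor(n * train_fraction)`` pairs; the validation
    set the rest. Deterministic given ``seed``; the two halves are disjoint
    and together contain every input pair exactly once.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(ds)
    n_train = math.floor(n * train_fraction)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = sorted(perm[:n_train].tolist())
    val_idx = sorted(perm[n_train:].tolist())
    train = AffinityDataset([ds.pairs[i] for i in train_idx], provenance=ds.provenance)
    val = AffinityDataset([ds.pairs[i] for i in val_idx], provenance=ds.provenance)
    return train, val


def summarize(ds: AffinityDataset) -> DatasetSummary:
    """Descriptive statistics of pair_length and pKi.

    Standard deviations are sample sds (ddof=1); for a single record the sd
    is defined as 0. Quartiles use linear interpolation. Every pair must
    carry a pKi.

    Raises
    ------
    ValueError
        If the dataset is empty or a pair lacks pKi.
    """
    if len(ds) == 0:
        raise ValueError("cannot summarize an empty dataset")
    lengths = np.array([p.pair_length for p in ds], dtype=float)
    pkis = [p.pki for p in ds]
    if any(v is None for v in pkis):
        raise ValueError("every pair needs a pKi before summarizing")
    pki = np.array(pkis, dtype=float)

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    def _q(x: np.ndarray) -> tuple[float, float, float]:
        q25, q50, q75 = np.percentile(x, [25, 50, 75])
        return (float(q25), float(q50), float(q75))

    return DatasetSummary(
        n=len(ds),
        mean_length=float(lengths.mean()),
        std_length=_sd(lengths),
        min_length=float(lengths.min()),
        quartiles_length=_q(lengths),
        max_length=float(lengths.max()),
        mean_pki=float(pki.mean()),
        std_pki=_sd(pki),
        min_pki=float(pki.min()),
        quartiles_pki=_q(pki),
        max_pki=float(pki.max()),
    )
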