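"""2D molecular descriptor computation and train-statistics normalization.

Descriptor definitions are delegated to RDKit's registered descriptor
set (the same toolkit families the QSAR literature uses: BCUT2D eigen
descriptors, partial-charge / polarizability / lipophilicity-binned Van
der Waals surface areas, electrotopological-state indices, connectivity
chis, QED and the sp3 carbon fraction).  The default name list is the
curated 16-descriptor panel found to discriminate NOX2 actives, in
importance order.

Normalization is plain z-scoring with statistics fitted on the training
set only — mean and n-1 standard deviation per descriptor over both
classes — and re-applied verbatim to any later matrix (held-out test
sets, deployment queries), never refitted.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _rd_descriptors

from .data_io import CompoundRecord
from .errors import ConfigurationError, DegenerateDataError, FormatError

logger = logging.getLogger(__name__)

#: curated high-importance descriptor panel, in published importance order
DEFAULT_DESCRIPTORS: tuple[str, ...] = (
    "BCUT2D_MWHI",
    "PEOE_VSA6",
    "Chi2v",
    "BCUT2D_MRHI",
    "qed",
    "SMR_VSA10",
    "VSA_EState2",
    "SlogP_VSA6",
    "FractionCSP3",
    "VSA_EState6",
    "BCUT2D_MWLOW",
    "EState_VSA7",
    "MinAbsEStateIndex",
    "Chi2n",
    "VSA_EState8",
    "PEOE_VSA9",
)

_DESCRIPTOR_FUNCS = dict(_rd_descriptors.descList)


@dataclass
class DescriptorMatrix:
    """Compounds x named-descriptor values; NaN marks an undefined value."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.columns.has_duplicates:
            raise FormatError("descriptor names must be unique")

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def select(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"descriptors not present: {', '.join(missing)}")
        return DescriptorMatrix(self.frame.loc[:, list(names)])

    def drop_incomplete(self) -> tuple["DescriptorMatrix", int]:
        """Drop rows with any undefined value; returns (matrix, n_dropped)."""
        mask = self.frame.notna().all(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            logger.warning("dropping %d compound(s) with undefined descriptors", dropped)
        return DescriptorMatrix(self.frame.loc[mask]), dropped

    def to_csv(self, path: str | Path) -> None:
        self.frame.rename_axis("id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        return cls(pd.read_csv(path, index_col="id"))


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        logger.info("multi-fragment structure: keeping largest covalent fragment")
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def compute_descriptors(
    compounds: Iterable[CompoundRecord],
    names: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> DescriptorMatrix:
    """Compute named 2D descriptors from SMILES, one row per compound.

    Multi-fragment structures (salts, hydrates) are reduced to their
    largest covalent fragment before computation.  A descriptor that is
    undefined for a molecule, or whose computation fails, is recorded as
    NaN rather than silently zeroed.
    """
    unknown = [n for n in names if n not in _DESCRIPTOR_FUNCS]
    if unknown:
        raise ConfigurationError(f"unknown descriptor name(s): {', '.join(unknown)}")
    rows = []
    ids = []
    for record in compounds:
        mol = _largest_fragment(record.mol())
        row = []
        for name in names:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    value = float(_DESCRIPTOR_FUNCS[name](mol))
            except Exception:  # descriptor undefined for this structure
                value = math.nan
            if not math.isfinite(value):
                value = math.nan
            row.append(value)
        rows.append(row)
        ids.append(record.id)
    return DescriptorMatrix(pd.DataFrame(rows, index=ids, columns=list(names)))


@dataclass(frozen=True)
class NormalizationStats:
    """Per-descriptor mean and sd fitted on a training matrix."""

    mean: pd.Series
    sd: pd.Series

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {"mean": float(self.mean[name]), "sd": float(self.sd[name])}
            for name in self.mean.index
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        payload = json.loads(Path(path).read_text())
        names = list(payload)
        mean = pd.Series({n: payload[n]["mean"] for n in names})
        sd = pd.Series({n: payload[n]["sd"] for n in names})
        return cls(mean=mean, sd=sd)


def fit_normalization(train: DescriptorMatrix) -> NormalizationStats:
    """Fit z-score statistics over all training rows, both classes pooled."""
    if len(train.frame) < 2:
        raise DegenerateDataError("need >= 2 training rows to fit normalization")
    mean = train.frame.mean(axis=0)
    sd = train.frame.std(axis=0, ddof=1)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        raise DegenerateDataError(
            f"zero-variance descriptor(s) in training set: {', '.join(zero)}"
        )
    return NormalizationStats(mean=mean, sd=sd)


def normalize(matrix: DescriptorMatrix, stats: NormalizationStats) -> DescriptorMatrix:
    """Apply (value - train mean) / train sd elementwise; stats never refit."""
    missing = [n for n in matrix.names if n not in stats.mean.index]
    if missing:
        raise ConfigurationError(
            f"normalization stats missing descriptor(s): {', '.join(missing)}"
        )
    scaled = (matrix.frame - stats.mean[matrix.names]) / stats.sd[matrix.names]
    return DescriptorMatrix(scaled)
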