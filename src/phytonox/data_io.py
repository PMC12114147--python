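"""Readers, writers and annotation rules for the two data arms.

This module holds the tabular interchange layer: metabolite annotation
tables from untargeted negative-mode LC-MS/MS (one row per tentatively
identified compound, with its deprotonated precursor m/z, characteristic
fragment ions, retention time and fruit/leaf presence flags), long-format
sample-by-metabolite intensity matrices, and labeled compound sets for
the QSAR arm.  It also implements two small but load-bearing rules:

* the *tentative identification* rule — an observed feature is matched to
  a reference annotation when its precursor m/z agrees within the MS
  tolerance and at least ``min_fragments`` reference fragment ions each
  have an observed counterpart within the MS/MS tolerance; and
* IC50-based activity labeling for enzyme-inhibition datasets, with an
  explicit ``excluded`` class for concentrations falling in the gap
  between the active and inactive windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

METABOLITE_COLUMNS = ("name", "group", "mw", "precursor_mz", "fragments", "rt", "presence")

ACTIVE = "active"
NOT_ACTIVE = "not_active"
EXCLUDED = "excluded"
UNKNOWN = "unknown"

#: accepted glyphs for the absence half of a presence code ("+/-" dialect;
#: the typeset minus sign is tolerated alongside ASCII "-")
_ABSENT = {"-", "−"}


# ---------------------------------------------------------------------------
# records and policies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaboliteRecord:
    """One annotated metabolite: identity, negative-mode ions, tissue presence."""

    name: str
    group: str
    mw: float
    precursor_mz: float
    fragments: tuple[float, ...]
    rt: float
    in_fruit: bool
    in_leaf: bool

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise FormatError(f"{self.name}: precursor m/z must be positive")
        if not self.fragments:
            raise FormatError(f"{self.name}: fragment list must be non-empty")
        if self.rt < 0:
            raise FormatError(f"{self.name}: retention time must be >= 0")
        # [M-H]- consistency: MW should exceed precursor - 2 Da.  Printed
        # tables contain approximate MWs for partially characterised
        # structures, so violations warn instead of failing.
        if self.mw <= self.precursor_mz - 2:
            warnings.warn(
                f"{self.name}: MW {self.mw} inconsistent with [M-H]- "
                f"{self.precursor_mz} (tolerance 2 Da)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class IdentificationPolicy:
    """Mass tolerances and fragment-count threshold for tentative identification.

    Defaults follow triple-quadrupole practice for unit-resolution data:
    0.1 Da precursor tolerance, 0.5 Da fragment tolerance, and at least
    two characteristic fragment ions in addition to the precursor match.
    """

    ms_tol: float = 0.1
    msms_tol: float = 0.5
    min_fragments: int = 2

    def __post_init__(self) -> None:
        if self.ms_tol <= 0 or self.msms_tol <= 0:
            raise ConfigurationError("mass tolerances must be positive")
        if self.min_fragments < 1:
            raise ConfigurationError("min_fragments must be >= 1")


@dataclass(frozen=True)
class IdentificationResult:
    identified: bool
    n_matched_fragments: int
    precursor_delta: float
    matched_pairs: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class LabelPolicy:
    """IC50 windows (molar) defining the active / not-active classes.

    ``active_low < ic50 < active_high`` labels a compound active;
    ``ic50 > inactive_low`` labels it not active; anything else —
    including the gap between ``active_high`` and ``inactive_low`` —
    is excluded rather than silently binned.
    """

    active_low: float = 30e-9
    active_high: float = 99e-6
    inactive_low: float = 100e-6

    def __post_init__(self) -> None:
        if not (self.active_low < self.active_high <= self.inactive_low):
            raise ConfigurationError(
                "label policy requires active_low < active_high <= inactive_low"
            )


@dataclass(frozen=True)
class CompoundRecord:
    """A compound with its SMILES and (optional) activity annotation."""

    id: str
    smiles: str
    label: str = UNKNOWN
    ic50: float | None = None

    def __post_init__(self) -> None:
        if self.label not in {ACTIVE, NOT_ACTIVE, UNKNOWN, EXCLUDED}:
            raise FormatError(f"{self.id}: unknown label {self.label!r}")

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise FormatError(f"{self.id}: SMILES does not parse: {self.smiles!r}")
        return mol


# ---------------------------------------------------------------------------
# intensity matrices
# ---------------------------------------------------------------------------

FRUIT = "fruit"
LEAF = "leaf"
SAMPLE_LEVELS = ("tissue", "day", "replicate")


@dataclass
class IntensityMatrix:
    """Samples x metabolites table of positive LC-MS peak intensities.

    ``data`` is indexed by a (tissue, day, replicate) MultiIndex; columns
    are metabolite names.  Replicate counts must be balanced within each
    (tissue, day) cell of a tissue, and all intensities strictly positive.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if list(idx.names) != list(SAMPLE_LEVELS):
            raise FormatError(f"index levels must be {SAMPLE_LEVELS}, got {idx.names}")
        if idx.has_duplicates:
            raise FormatError("duplicate (tissue, day, replicate) sample keys")
        values = self.data.to_numpy(dtype=float)
        if not np.all(values > 0):
            raise FormatError("intensity values must be strictly positive")
        for tissue, sub in self.data.groupby(level="tissue"):
            counts = sub.groupby(level="day").size()
            if counts.nunique() > 1:
                raise FormatError(
                    f"unbalanced replicate counts within tissue {tissue!r}: "
                    f"{counts.to_dict()}"
                )

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    @property
    def samples(self) -> list[tuple[str, int, int]]:
        return list(self.data.index)

    def tissue(self, tissue: str) -> "IntensityMatrix":
        sub = self.data.xs(tissue, level="tissue", drop_level=False)
        if sub.empty:
            raise FormatError(f"no samples for tissue {tissue!r}")
        return IntensityMatrix(sub)

    def days(self, tissue: str | None = None) -> list[int]:
        frame = self.data if tissue is None else self.tissue(tissue).data
        return sorted(frame.index.get_level_values("day").unique())

    def day_groups(self, tissue: str) -> dict[int, pd.DataFrame]:
        sub = self.data.xs(tissue, level="tissue", drop_level=False)
        if sub.empty:
            raise FormatError(f"no samples for tissue {tissue!r}")
        return {int(d): g for d, g in sub.groupby(level="day")}

    def to_csv(self, path: str | Path) -> None:
        out = self.data.reset_index()
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntensityMatrix":
        frame = pd.read_csv(path)
        missing = [c for c in SAMPLE_LEVELS if c not in frame.columns]
        if missing:
            raise FormatError(f"intensity CSV missing column(s): {', '.join(missing)}")
        frame["day"] = frame["day"].astype(int)
        frame["replicate"] = frame["replicate"].astype(int)
        frame = frame.set_index(list(SAMPLE_LEVELS))
        return cls(frame)


# ---------------------------------------------------------------------------
# metabolite tables
# ---------------------------------------------------------------------------


def _parse_presence(code: str, row: int) -> tuple[bool, bool]:
    parts = str(code).strip().split("/")
    if len(parts) != 2:
        raise FormatError(f"row {row}: unparsable presence code {code!r}")
    flags = []
    for token in parts:
        token = token.strip()
        if token == "+":
            flags.append(True)
        elif token in _ABSENT:
            flags.append(False)
        else:
            raise FormatError(f"row {row}: unparsable presence code {code!r}")
    return flags[0], flags[1]


def _parse_fragments(text: str, row: int) -> tuple[float, ...]:
    try:
        frags = tuple(float(tok) for tok in str(text).split(";") if tok.strip())
    except ValueError as exc:
        raise FormatError(f"row {row}: unparsable fragment list {text!r}") from exc
    return frags


def load_metabolite_table(path: str | Path) -> list[MetaboliteRecord]:
    """Read an annotation table (CSV or TSV by extension) into records.

    The presence column uses the "+/-" dialect with fruit first and leaf
    second; any other dialect is rejected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty or headerless file") from exc
    missing = [c for c in METABOLITE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    records = []
    for row, entry in enumerate(frame.itertuples(index=False)):
        in_fruit, in_leaf = _parse_presence(entry.presence, row)
        records.append(
            MetaboliteRecord(
                name=str(entry.name),
                group=str(entry.group),
                mw=float(entry.mw),
                precursor_mz=float(entry.precursor_mz),
                fragments=_parse_fragments(entry.fragments, row),
                rt=float(entry.rt),
                in_fruit=in_fruit,
                in_leaf=in_leaf,
            )
        )
    return records


def write_metabolite_table(records: Iterable[MetaboliteRecord], path: str | Path) -> None:
    """Inverse of :func:`load_metabolite_table` (field-exact round trip)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "group": r.group,
                "mw": r.mw,
                "precursor_mz": r.precursor_mz,
                "fragments": ";".join(repr(f) for f in r.fragments),
                "rt": r.rt,
                "presence": f"{'+' if r.in_fruit else '-'}/{'+' if r.in_leaf else '-'}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# tentative identification
# ---------------------------------------------------------------------------


def tentative_identify(
    observed_precursor: float,
    observed_fragments: Sequence[float],
    reference: MetaboliteRecord,
    policy: IdentificationPolicy = IdentificationPolicy(),
) -> IdentificationResult:
    """Apply the tentative-identification rule to one observed feature.

    Reference fragments are paired to observed fragments greedily by
    smallest absolute m/z difference, each side used at most once; a pair
    counts as matched when its difference is within ``policy.msms_tol``.
    """
    delta = abs(observed_precursor - reference.precursor_mz)
    candidates = sorted(
        (abs(obs - ref), i, j, ref, obs)
        for i, ref in enumerate(reference.fragments)
        for j, obs in enumerate(observed_fragments)
    )
    used_ref: set[int] = set()
    used_obs: set[int] = set()
    pairs: list[tuple[float, float]] = []
    for diff, i, j, ref, obs in candidates:
        if diff > policy.msms_tol:
            break
        if i in used_ref or j in used_obs:
            continue
        used_ref.add(i)
        used_obs.add(j)
        pairs.append((ref, obs))
    identified = delta <= policy.ms_tol and len(pairs) >= policy.min_fragments
    return IdentificationResult(
        identified=identified,
        n_matched_fragments=len(pairs),
        precursor_delta=delta,
        matched_pairs=tuple(pairs),
    )


# ---------------------------------------------------------------------------
# activity labels and compound sets
# ---------------------------------------------------------------------------


def assign_activity_labels(
    ic50s: Sequence[float], policy: LabelPolicy = LabelPolicy()
) -> list[str]:
    """Map molar IC50 values to {active, not_active, excluded}."""
    labels = []
    for value in ic50s:
        if not value > 0:
            raise ValueError(f"IC50 must be positive, got {value}")
        if policy.active_low < value < policy.active_high:
            labels.append(ACTIVE)
        elif value > policy.inactive_low:
            labels.append(NOT_ACTIVE)
        else:
            labels.append(EXCLUDED)
    return labels


def load_compound_set(
    path: str | Path,
    strict: bool = True,
    label_policy: LabelPolicy | None = None,
) -> list[CompoundRecord]:
    """Read a compound CSV (id, smiles, optional label/ic50) preserving order.

    Every SMILES is validated by parsing.  In strict mode (default) an
    unparsable SMILES aborts with the offending id; in lenient mode the
    row is skipped with a logged warning.  When ``label_policy`` is given
    and an ``ic50`` column is present, labels are (re)assigned from IC50.
    """
    frame = pd.read_csv(path)
    for col in ("id", "smiles"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column(s): {col}")
    records: list[CompoundRecord] = []
    for entry in frame.itertuples(index=False):
        cid = str(entry.id)
        smiles = str(entry.smiles)
        if Chem.MolFromSmiles(smiles) is None:
            if strict:
                raise FormatError(f"unparsable SMILES for compound {cid!r}")
            logger.warning("skipping compound %r: unparsable SMILES", cid)
            continue
        ic50 = None
        if "ic50" in frame.columns and pd.notna(getattr(entry, "ic50")):
            ic50 = float(getattr(entry, "ic50"))
        label = UNKNOWN
        if "label" in frame.columns and pd.notna(getattr(entry, "label")):
            label = str(getattr(entry, "label"))
        if label_policy is not None and ic50 is not None:
            label = assign_activity_labels([ic50], label_policy)[0]
        records.append(CompoundRecord(id=cid, smiles=smiles, label=label, ic50=ic50))
    return records


def write_compound_set(records: Iterable[CompoundRecord], path: str | Path) -> None:
    rows = [
        {"id": r.id, "smiles": r.smiles, "label": r.label, "ic50": r.ic50}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_compound_sdf(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Optional SDF export of a compound set (stereo preserved)."""
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = r.mol()
            mol.SetProp("_Name", r.id)
            mol.SetProp("label", r.label)
            writer.write(mol)
    finally:
        writer.close()
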