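"""Synthetic data generators for both analysis arms.

The study's raw inputs — per-sample LC-MS peak intensities and the
ChEMBL-derived NOX2 training set — are not deposited, so this module
generates statistically controlled stand-ins:

* :func:`simulate_intensity_matrix` builds sample-by-metabolite intensity
  matrices with planted storage-time trends and multiplicative log-normal
  noise, mirroring the study layout (12 replicates per time point; days
  1, 4, 6, 8, 11 for fruit and 1, 4, 6, 8 for leaves).  Log-normal noise
  keeps intensities positive, the defining constraint of LC-MS peak
  areas.
* :func:`simulate_compound_dataset` builds labeled descriptor matrices
  with class-conditional Gaussian descriptors: informative columns are
  shifted by ``effect`` standard deviations in the active class, the
  rest are pure noise.  Unit variance makes power calculations
  closed-form (two-class Bayes error = Phi(-effect*sqrt(k)/2) for k
  informative descriptors).

Every generator is a pure function of (design, seed) and writes the same
CSV dialects the readers consume, plus a JSON manifest echoing design
and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import ACTIVE, FRUIT, LEAF, NOT_ACTIVE, SAMPLE_LEVELS, IntensityMatrix
from .descriptors import DEFAULT_DESCRIPTORS, DescriptorMatrix
from .errors import ConfigurationError

FRUIT_DAYS = (1, 4, 6, 8, 11)
LEAF_DAYS = (1, 4, 6, 8)

TREND_SHAPES = ("flat", "exp_decline", "exp_incline", "transient_peak")


@dataclass(frozen=True)
class TrendSpec:
    """Deterministic mean trajectory of one metabolite over storage days.

    ``flat`` holds the baseline; the exponential shapes apply a per-day
    rate relative to the first sampled day; ``transient_peak`` multiplies
    the baseline by ``peak_fold`` under a Gaussian bump (sd ``peak_width``
    days) centered at ``peak_day``.
    """

    shape: str = "flat"
    baseline: float = 100.0
    rate: float = 0.0
    peak_day: float | None = None
    peak_fold: float = 1.0
    peak_width: float = 1.5

    def __post_init__(self) -> None:
        if self.shape not in TREND_SHAPES:
            raise ConfigurationError(f"unknown trend shape {self.shape!r}")
        if self.baseline <= 0:
            raise ConfigurationError("baseline must be positive")
        if self.peak_fold <= 0:
            raise ConfigurationError("peak_fold must be positive")
        if self.shape == "transient_peak" and self.peak_day is None:
            raise ConfigurationError("transient_peak requires peak_day")

    def value(self, day: float, first_day: float) -> float:
        t = day - first_day
        if self.shape == "flat":
            return self.baseline
        if self.shape == "exp_decline":
            return self.baseline * float(np.exp(-self.rate * t))
        if self.shape == "exp_incline":
            return self.baseline * float(np.exp(self.rate * t))
        bump = float(np.exp(-0.5 * ((day - self.peak_day) / self.peak_width) ** 2))
        return self.baseline * self.peak_fold**bump


@dataclass(frozen=True)
class IntensityDesign:
    """Design of one simulated tissue block."""

    tissue: str = FRUIT
    days: tuple[int, ...] | None = None
    replicates: int = 12
    trends: Mapping[str, TrendSpec] = field(default_factory=dict)
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in (FRUIT, LEAF):
            raise ConfigurationError(f"unknown tissue {self.tissue!r}")
        if self.days is not None and list(self.days) != sorted(set(self.days)):
            raise ConfigurationError("days must be strictly increasing")
        if self.replicates < 2:
            raise ConfigurationError("need >= 2 replicates")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not self.trends:
            raise ConfigurationError("at least one metabolite trend is required")

    @property
    def resolved_days(self) -> tuple[int, ...]:
        if self.days is not None:
            return tuple(self.days)
        return FRUIT_DAYS if self.tissue == FRUIT else LEAF_DAYS


def flat_trends(names, baseline: float = 100.0) -> dict[str, TrendSpec]:
    """Convenience: a null (flat) trend map over the given metabolites."""
    return {name: TrendSpec(shape="flat", baseline=baseline) for name in names}


def simulate_intensity_matrix(
    design: IntensityDesign,
) -> tuple[IntensityMatrix, dict]:
    """Draw an intensity matrix; returns (matrix, ground-truth manifest).

    value(metabolite, day, replicate) = trend(day) * exp(eps) with
    eps ~ Normal(0, noise_sigma^2), independent across cells; bit-stable
    for a fixed (design, seed).
    """
    rng = np.random.default_rng(design.seed)
    days = design.resolved_days
    names = list(design.trends)
    first = days[0]
    index = pd.MultiIndex.from_tuples(
        [(design.tissue, d, r + 1) for d in days for r in range(design.replicates)],
        names=SAMPLE_LEVELS,
    )
    base = np.array(
        [[design.trends[m].value(d, first) for m in names] for d in days]
    )  # days x metabolites
    noise = rng.normal(0.0, design.noise_sigma, size=(len(days), design.replicates, len(names)))
    values = base[:, None, :] * np.exp(noise)
    frame = pd.DataFrame(values.reshape(-1, len(names)), index=index, columns=names)
    truth = {
        "seed": design.seed,
        "tissue": design.tissue,
        "days": list(days),
        "replicates": design.replicates,
        "noise_sigma": design.noise_sigma,
        "trends": {m: asdict(spec) for m, spec in design.trends.items()},
    }
    return IntensityMatrix(frame), truth


@dataclass(frozen=True)
class CompoundSimDesign:
    """Design of a class-conditional Gaussian descriptor dataset.

    Defaults reproduce the curated NOX2 set's shape: 107 active and 72
    not-active compounds over 16 descriptors.  The first
    ``n_informative`` descriptors carry a mean shift of ``effect``
    (in sd units) in the active class; the rest are exchangeable noise.
    """

    n_active: int = 107
    n_inactive: int = 72
    n_descriptors: int = 16
    n_informative: int = 0
    effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_inactive, self.n_descriptors) <= 0:
            raise ConfigurationError("counts must be positive")
        if not 0 <= self.n_informative <= self.n_descriptors:
            raise ConfigurationError("0 <= n_informative <= n_descriptors required")
        if self.effect < 0:
            raise ConfigurationError("effect must be >= 0")


def descriptor_column_names(n: int) -> list[str]:
    """Column names for simulated descriptors.

    The first 16 reuse the curated high-importance descriptor names so
    simulated tables are drop-in compatible with the QSAR tooling;
    additional columns get generic ``noise_NN`` names.
    """
    names = list(DEFAULT_DESCRIPTORS[: min(n, len(DEFAULT_DESCRIPTORS))])
    names += [f"noise_{i:02d}" for i in range(len(names) + 1, n + 1)]
    return names


def simulate_compound_dataset(
    design: CompoundSimDesign,
) -> tuple[DescriptorMatrix, np.ndarray, list[str]]:
    """Draw (descriptor matrix, labels, informative-descriptor names)."""
    rng = np.random.default_rng(design.seed)
    n = design.n_active + design.n_inactive
    names = descriptor_column_names(design.n_descriptors)
    values = rng.normal(0.0, 1.0, size=(n, design.n_descriptors))
    labels = np.array([ACTIVE] * design.n_active + [NOT_ACTIVE] * design.n_inactive)
    informative = names[: design.n_informative]
    values[: design.n_active, : design.n_informative] += design.effect
    ids = [f"cpd_{i:04d}" for i in range(1, n + 1)]
    frame = pd.DataFrame(values, index=ids, columns=names)
    return DescriptorMatrix(frame), labels, informative


def write_compound_dataset(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    design: CompoundSimDesign,
    informative: list[str],
    out_dir: str | Path,
) -> None:
    """Write descriptors + labels CSV and a ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = matrix.frame.copy()
    table.insert(0, "label", labels)
    table.rename_axis("id").to_csv(out / "compounds.csv")
    manifest = {**asdict(design), "informative": informative}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
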