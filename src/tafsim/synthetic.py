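"""Synthetic cohorts, focus-lifetime tracks and telomere-intensity sets.

Generates every input the analysis pipeline consumes, with the statistical
structure of the study design it emulates: mouse cohorts sampled at several
ages (4–7 mice per age, ~100 cardiomyocytes scored per mouse, each cell
carrying a TAF count and a total-foci count), per-telomere FISH intensity
sets labelled TAF / non-TAF, and live-imaging focus tracks observed over a
24-h window with right-censoring.

Per-cell TAF counts are drawn from the single-cell law implied by the
mechanistic hypothesis (Poisson for stress, compound Poisson for
proliferation, their sum for hybrid); mouse-to-mouse variability enters as
a unit-mean gamma multiplier on the damage-accrual rates.  Non-telomeric
foci are drawn from their stationary Poisson law (mean ``lambda_N/rho``),
which is what keeps total foci flat in age while TAF rise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import ModelSpec

__all__ = [
    "CohortDesign",
    "MouseSample",
    "CohortDataset",
    "FociTrackSet",
    "IntensityDataset",
    "DEFAULT_DESIGN",
    "generate_cohort",
    "generate_foci_tracks",
    "generate_intensities",
]


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of a cross-sectional ageing cohort.

    ``heterogeneity_shape`` is the shape of the unit-mean gamma distribution
    of per-mouse rate multipliers; larger means less between-mouse
    variability (CV = shape**-0.5).
    """

    ages: tuple = (3.0, 15.0, 22.0, 30.0)
    mice_per_age: int = 5
    cells_per_mouse: int = 100
    heterogeneity_shape: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.ages)
        object.__setattr__(self, "ages", ages)
        if len(ages) == 0:
            raise ValueError("ages must be nonempty")
        if any(a < 0 for a in ages):
            raise ValueError("ages must be nonnegative")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        if self.mice_per_age < 1 or self.cells_per_mouse < 1:
            raise ValueError("mice_per_age and cells_per_mouse must be >= 1")
        if not (self.heterogeneity_shape > 0):
            raise ValueError("heterogeneity_shape must be > 0")


DEFAULT_DESIGN = CohortDesign()


@dataclass
class MouseSample:
    """Per-cell TAF and total-foci counts for one mouse."""

    mouse_id: str
    age_months: float
    taf_counts: np.ndarray
    total_foci_counts: np.ndarray

    def __post_init__(self) -> None:
        self.taf_counts = np.asarray(self.taf_counts, dtype=np.int64)
        self.total_foci_counts = np.asarray(self.total_foci_counts, dtype=np.int64)
        if self.taf_counts.shape != self.total_foci_counts.shape:
            raise ValueError("taf and total-foci counts must have equal length")
        if np.any(self.taf_counts < 0):
            raise ValueError("taf_counts must be nonnegative")
        if np.any(self.total_foci_counts < self.taf_counts):
            raise ValueError("every total_foci_count must be >= its taf_count")

    @property
    def n_cells(self) -> int:
        return self.taf_counts.size

    @property
    def mean_taf(self) -> float:
        return float(self.taf_counts.mean())

    @property
    def frac_positive(self) -> float:
        return float(np.mean(self.taf_counts > 0))


@dataclass
class CohortDataset:
    """A full synthetic cohort plus its generating provenance."""

    samples: list
    generating_model: object  # ModelSpec or "external"
    seed: int

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("cohort must contain at least one mouse")

    @property
    def ages(self) -> tuple:
        return tuple(sorted({s.age_months for s in self.samples}))

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.samples:
            for i, (taf, tot) in enumerate(
                zip(s.taf_counts, s.total_foci_counts)
            ):
                rows.append((s.mouse_id, s.age_months, i, int(taf), int(tot)))
        return pd.DataFrame(
            rows,
            columns=[
                "mouse_id",
                "age_months",
                "cell_index",
                "taf_count",
                "total_foci_count",
            ],
        )

    @classmethod
    def from_frame(cls, df, generating_model="external", seed=-1):
        samples = []
        for (mid, age), g in df.groupby(["mouse_id", "age_months"], sort=True):
            g = g.sort_values("cell_index")
            samples.append(
                MouseSample(
                    mouse_id=str(mid),
                    age_months=float(age),
                    taf_counts=g["taf_count"].to_numpy(),
                    total_foci_counts=g["total_foci_count"].to_numpy(),
                )
            )
        return cls(samples=samples, generating_model=generating_model, seed=seed)


@dataclass
class FociTrackSet:
    """Observed focus lifetimes (minutes) with right-censoring flags."""

    condition: str
    lifetimes_min: np.ndarray
    censored: np.ndarray
    window_min: float

    def __post_init__(self) -> None:
        self.lifetimes_min = np.asarray(self.lifetimes_min, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.lifetimes_min.shape != self.censored.shape:
            raise ValueError("lifetimes and censoring flags must align")
        if self.window_min <= 0:
            raise ValueError("window_min must be > 0")
        if np.any(self.lifetimes_min <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(self.lifetimes_min > self.window_min + 1e-9):
            raise ValueError("lifetimes cannot exceed the observation window")
        # censoring may occur before the window end (track lost), at the
        # window at the latest; uncensored times must lie inside the window

    @property
    def n(self) -> int:
        return self.lifetimes_min.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "track_id": np.arange(self.n),
                "lifetime_min": self.lifetimes_min,
                "censored": self.censored.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df, condition="external", window_min=None):
        lifetimes = df["lifetime_min"].to_numpy(dtype=float)
        censored = df["censored"].to_numpy().astype(bool)
        if window_min is None:
            window_min = float(lifetimes.max())
        return cls(condition, lifetimes, censored, float(window_min))


@dataclass
class IntensityDataset:
    """Per-telomere fluorescence intensities with TAF / non-TAF labels."""

    intensities: np.ndarray
    is_taf: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.is_taf = np.asarray(self.is_taf, dtype=bool)
        if self.intensities.shape != self.is_taf.shape:
            raise ValueError("intensities and labels must align")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be positive")

    @property
    def taf(self) -> np.ndarray:
        return self.intensities[self.is_taf]

    @property
    def non_taf(self) -> np.ndarray:
        return self.intensities[~self.is_taf]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"intensity": self.intensities, "is_taf": self.is_taf.astype(int)}
        )


def _single_cell_taf(
    model: ModelSpec, age: float, effect: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-cell TAF from the mechanism's single-cell law at ``age``."""
    taf = np.zeros(n, dtype=np.int64)
    if model.initial_mean_taf > 0:
        taf += rng.poisson(model.initial_mean_taf, size=n)
    if model.lambda_T > 0:
        taf += rng.poisson(model.lambda_T * effect * age, size=n)
    if model.delta_c > 0 and model.mu_d > 0:
        divisions = rng.poisson(model.delta_c * effect * age, size=n)
        taf += rng.poisson(model.mu_d * divisions)
    return taf


def generate_cohort(
    design: CohortDesign, model: ModelSpec
) -> CohortDataset:
    """Simulate a full cross-sectional cohort under one mechanistic model.

    One mouse-level gamma multiplier (unit mean, shape
    ``design.heterogeneity_shape``) scales the damage-accrual intensities
    of all cells of that mouse; the non-TAF count per cell is a stationary
    Poisson(``lambda_N/rho``) draw added to TAF to give total foci.
    Deterministic given (design, model, design.seed).
    """
    rng = np.random.default_rng(design.seed)
    shape = design.heterogeneity_shape
    nontaf_mean = model.lambda_N / model.rho if model.rho > 0 else 0.0

    samples = []
    for age in design.ages:
        for m in range(design.mice_per_age):
            effect = rng.gamma(shape, 1.0 / shape)
            taf = _single_cell_taf(
                model, age, effect, design.cells_per_mouse, rng
            )
            nontaf = (
                rng.poisson(nontaf_mean, size=design.cells_per_mouse)
                if nontaf_mean > 0
                else np.zeros(design.cells_per_mouse, dtype=np.int64)
            )
            samples.append(
                MouseSample(
                    mouse_id=f"age{age:g}_m{m}",
                    age_months=age,
                    taf_counts=taf,
                    total_foci_counts=taf + nontaf,
                )
            )
    return CohortDataset(samples=samples, generating_model=model, seed=design.seed)


def generate_foci_tracks(
    n_foci: int,
    persistent_fraction: float = 0.2,
    transient_mean_min: float = 60.0,
    window_min: float = 1440.0,
    seed: int = 0,
    condition: str = "synthetic",
) -> FociTrackSet:
    """Simulate time-lapse focus lifetimes over an observation window.

    Each focus is persistent (survives the whole window, hence censored)
    with probability ``persistent_fraction``; otherwise its lifetime is
    exponential with mean ``transient_mean_min`` and is censored only if it
    outlives the window.  Defaults mirror a 24-h track set in which roughly
    20% of damage foci persist.
    """
    if n_foci < 1:
        raise ValueError("n_foci must be >= 1")
    if not 0 <= persistent_fraction <= 1:
        raise ValueError("persistent_fraction must be in [0, 1]")
    if transient_mean_min <= 0 or window_min <= 0:
        raise ValueError("transient_mean_min and window_min must be > 0")

    rng = np.random.default_rng(seed)
    persistent = rng.random(n_foci) < persistent_fraction
    lifetimes = rng.exponential(transient_mean_min, size=n_foci)
    over = lifetimes >= window_min
    censored = persistent | over
    lifetimes[censored] = window_min
    # exponential can produce exact zeros only at float resolution; clamp up
    np.maximum(lifetimes, np.finfo(float).tiny, out=lifetimes)
    return FociTrackSet(condition, lifetimes, censored, window_min)


def generate_intensities(
    n: int,
    log_mean: float = 0.0,
    log_sd: float = 0.5,
    taf_fraction: float = 0.5,
    taf_log_shift: float = 0.0,
    seed: int = 0,
) -> IntensityDataset:
    """Simulate per-telomere FISH intensities with TAF / non-TAF labels.

    Intensities are log-normal; TAF-labelled telomeres have their log-mean
    shifted by ``taf_log_shift``.  A shift of 0 encodes the null of
    length-independent telomere damage (TAF no dimmer than non-TAF).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if log_sd <= 0:
        raise ValueError("log_sd must be > 0")
    if not 0 <= taf_fraction <= 1:
        raise ValueError("taf_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    is_taf = rng.random(n) < taf_fraction
    logs = rng.normal(log_mean, log_sd, size=n)
    logs[is_taf] += taf_log_shift
    return IntensityDataset(np.exp(logs), is_taf)
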