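"""Mechanistic hypotheses for TAF accumulation and their closed-form observables.

Telomere-associated foci (TAF) are irreparable DNA-damage foci at telomeres.
Two competing mechanisms can in principle produce an age-dependent rise of
mean TAF per cardiomyocyte:

* **stress** — TAF arise in non-dividing cells as a Poisson event stream with
  rate ``lambda_T`` per cell per month, so per-cell TAF at age *t* is
  Poisson(``initial_mean_taf`` + ``lambda_T``·t).
* **proliferation** — a cell divides as a Poisson stream with rate
  ``delta_c``; each division deposits Poisson(``mu_d``) new TAF, giving a
  compound-Poisson per-cell law with mean ``delta_c``·``mu_d``·t and Fano
  factor 1 + ``mu_d``.
* **hybrid** — the independent sum of both channels.

TAF are never removed (irreparability); non-telomeric foci follow an
immigration–death process with gain rate ``lambda_N`` and first-order repair
rate ``rho``, whose mean is stationary at ``lambda_N / rho``.

The closed forms here are the analytic oracle for the stochastic engine and
the source of the feasibility bound that rejects proliferation-driven TAF:
for a proliferation-only model the fraction of TAF-positive cells can never
exceed the fraction of cells that have divided at least once,
1 − exp(−``delta_c``·t), whatever ``mu_d`` is.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

__all__ = [
    "MECHANISMS",
    "ModelSpec",
    "mean_taf_analytic",
    "frac_taf_positive_analytic",
    "mean_nontaf_analytic",
    "max_frac_positive_bound",
    "delta_from_lifetime_fraction",
]

MECHANISMS = ("stress", "proliferation", "hybrid")


class InvalidModelError(ValueError):
    """Raised when a ModelSpec violates its invariants."""


@dataclass(frozen=True)
class ModelSpec:
    """Kinetic specification of one mechanistic hypothesis.

    Rates are per cell per month; ``horizon_months`` is the modelled window
    of the mouse lifespan (27 months, from the 3-month baseline to 30
    months); ``taf_cap`` truncates the per-cell TAF state space (the top
    bin absorbs overflow); ``initial_mean_taf`` is the Poisson mean of TAF
    already present at time zero.
    """

    mechanism: str = "stress"
    lambda_T: float = 0.0
    delta_c: float = 0.0
    mu_d: float = 0.0
    lambda_N: float = 0.0
    rho: float = 0.0
    horizon_months: float = 27.0
    n_cells: int = 10_000
    taf_cap: int = 50
    initial_mean_taf: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise InvalidModelError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )
        for name in ("lambda_T", "delta_c", "mu_d", "lambda_N", "rho",
                     "initial_mean_taf"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidModelError(f"{name} must be finite and >= 0, got {v}")
        if self.lambda_N > 0 and self.rho <= 0:
            raise InvalidModelError("rho must be > 0 whenever lambda_N > 0")
        if self.horizon_months <= 0:
            raise InvalidModelError("horizon_months must be > 0")
        if self.n_cells < 1:
            raise InvalidModelError("n_cells must be >= 1")
        if self.taf_cap < 1:
            raise InvalidModelError("taf_cap must be >= 1")
        if self.mechanism == "stress" and self.delta_c * self.mu_d != 0:
            raise InvalidModelError(
                "stress mechanism must not carry a division TAF channel "
                "(delta_c * mu_d must be 0)"
            )
        if self.mechanism == "proliferation" and self.lambda_T != 0:
            raise InvalidModelError(
                "proliferation mechanism must have lambda_T = 0"
            )

    # -- accrual intensities ------------------------------------------------

    @property
    def taf_accrual_rate(self) -> float:
        """Mean TAF gained per cell per month, both channels combined."""
        return self.lambda_T + self.delta_c * self.mu_d

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls(**json.loads(text))

    def with_(self, **changes) -> "ModelSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _check_time(t: float) -> None:
    if t < 0 or not math.isfinite(t):
        raise ValueError(f"time must be finite and >= 0, got {t}")


def mean_taf_analytic(model: ModelSpec, t: float) -> float:
    """Expected TAF per cell at age ``t`` months.

    TAF are irreparable, so the mean is nondecreasing:
    ``initial_mean_taf + (lambda_T + delta_c * mu_d) * t``.
    """
    _check_time(t)
    return model.initial_mean_taf + model.taf_accrual_rate * t


def frac_taf_positive_analytic(model: ModelSpec, t: float) -> float:
    """Probability a cell carries at least one TAF at age ``t``.

    The stress channel contributes Poisson(``lambda_T``·t) TAF; each
    division is "marked" (yields >= 1 TAF) with probability
    1 − exp(−``mu_d``), so marked divisions thin the division stream to a
    Poisson stream of rate ``delta_c``·(1 − exp(−``mu_d``)).  A cell is
    TAF-free iff all three independent Poisson counts (initial, stress,
    marked divisions) are zero.
    """
    _check_time(t)
    marked = model.delta_c * t * -math.expm1(-model.mu_d)
    total = model.initial_mean_taf + model.lambda_T * t + marked
    return -math.expm1(-total)


def mean_nontaf_analytic(
    model: ModelSpec, t: float, initial_mean_nontaf: float = 0.0
) -> float:
    """Expected non-telomeric foci per cell at age ``t`` (immigration–death).

    ``(lambda_N/rho)(1 − e^{−rho t}) + initial · e^{−rho t}``; relaxes to the
    stationary mean ``lambda_N / rho``, which is why total foci counts stay
    flat with age while TAF rise.
    """
    _check_time(t)
    if initial_mean_nontaf < 0:
        raise ValueError("initial_mean_nontaf must be >= 0")
    if model.rho == 0:
        if model.lambda_N > 0:
            raise InvalidModelError("rho = 0 with lambda_N > 0 is invalid")
        return initial_mean_nontaf
    decay = math.exp(-model.rho * t)
    return (model.lambda_N / model.rho) * (1.0 - decay) + initial_mean_nontaf * decay


def max_frac_positive_bound(model: ModelSpec, t: float) -> float:
    """Upper bound on the TAF-positive fraction under proliferation only.

    Equals 1 − exp(−``delta_c``·t): the expected fraction of cells that have
    divided at least once by ``t``, which is the supremum of
    :func:`frac_taf_positive_analytic` over ``mu_d``.  This bound is what
    makes division rates of a few percent over the lifespan incompatible
    with a large observed TAF-positive fraction.
    """
    if model.mechanism != "proliferation":
        raise InvalidModelError(
            "max_frac_positive_bound applies to proliferation-only models, "
            f"got mechanism {model.mechanism!r}"
        )
    _check_time(t)
    return -math.expm1(-model.delta_c * t)


def delta_from_lifetime_fraction(fraction_divided: float, horizon: float) -> float:
    """Per-month division rate giving the stated lifetime division fraction.

    Inverts ``fraction = 1 − exp(−delta_c · horizon)``; e.g. 15% of cells
    dividing over 27 months maps to ``delta_c`` ≈ 0.00602 per month.
    """
    if not 0 <= fraction_divided < 1:
        raise ValueError(
            f"fraction_divided must be in [0, 1), got {fraction_divided}"
        )
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    return -math.log1p(-fraction_divided) / horizon
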