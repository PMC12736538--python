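"""Resource-use, productivity and competition indices for two-crop intercrops.

All indices compare an intercrop's per-crop yields (Y_IM maize, Y_IA
alfalfa) with the sole-crop yields of the same species (Y_MM, Y_AM), with
the sowing proportions (Z_M, Z_A) where the definition requires them:

* partial land equivalent ratios  pLER_M = Y_IM / Y_MM,  pLER_A = Y_IA / Y_AM
* land equivalent ratio           LER = pLER_M + pLER_A
* land equivalent coefficient     LEC = pLER_M x pLER_A
* system productivity index       SPI = Y_IM + (Y_MM / Y_AM) x Y_IA
* relative crowding coefficients  K_IM = (Y_IM Z_A) / ((Y_MM - Y_IM) Z_M),
                                  K_IA analogously; system K = K_IM x K_IA
* aggressivity                    A_M = Y_IM/(Y_MM Z_M) - Y_IA/(Y_AM Z_A),
                                  A_A = -A_M
* competitive ratio               CR_M = (pLER_M / pLER_A)(Z_A / Z_M),
                                  CR_A its reciprocal

LER > 1 signals a land-use advantage (the relative sole-crop area needed to
match the intercrop's output), LEC > 0.25 is impossible below LER = 1,
system K > 1 an intercropping benefit, positive A_M maize dominance.

Indices can be evaluated per replicate pairing and then averaged
(``per_replicate_mean``) or on treatment means (``ratio_of_means``); with
replicate noise the two differ (a Jensen gap, upward for the ratio-heavy K).

Crowding coefficients degenerate when a crop yields at least its sole-crop
reference (the denominator hits zero or below); degenerate values are
reported as ``inf`` with an explicit flag, never as a silently negative
number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import DomainError, MissingCellError, ValidationError
from .trial_data import ALFALFA, MAIZE, TrialDataset

#: Which alfalfa trait enters the ratio indices alongside maize grain yield.
YIELD_POLICIES = ("forage", "biomass")
MODES = ("per_replicate_mean", "ratio_of_means")


@dataclass(frozen=True)
class IndexInputs:
    """The yield quadruple and sowing proportions feeding every index."""

    y_im: float
    y_ia: float
    y_mm: float
    y_am: float
    z_maize: float = 0.5
    z_alfalfa: float = 0.5

    def __post_init__(self) -> None:
        for name in ("y_im", "y_ia", "y_mm", "y_am"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be a finite non-negative yield, got {v!r}")
        if self.y_mm <= 0 or self.y_am <= 0:
            raise DomainError("mono-crop reference yields must be positive")
        if not math.isclose(self.z_maize + self.z_alfalfa, 1.0, abs_tol=1e-9):
            raise ValidationError("sowing proportions must sum to 1")
        if self.z_maize < 0 or self.z_alfalfa < 0:
            raise ValidationError("sowing proportions must be non-negative")


class CrowdingCoefficients(NamedTuple):
    k_maize: float
    k_alfalfa: float
    k_system: float
    flags: tuple[str, ...]


def partial_ler(y_intercrop: float, y_mono: float) -> float:
    """Partial land equivalent ratio: intercrop yield over sole-crop yield."""
    if y_mono <= 0:
        raise DomainError(f"mono-crop yield must be positive, got {y_mono!r}")
    if y_intercrop < 0:
        raise DomainError(f"intercrop yield must be non-negative, got {y_intercrop!r}")
    return y_intercrop / y_mono


def ler(inputs: IndexInputs) -> float:
    """Land equivalent ratio, the sum of the two partial LERs."""
    return partial_ler(inputs.y_im, inputs.y_mm) + partial_ler(inputs.y_ia, inputs.y_am)


def lec(inputs: IndexInputs) -> float:
    """Land equivalent coefficient, the product of the two partial LERs."""
    return partial_ler(inputs.y_im, inputs.y_mm) * partial_ler(inputs.y_ia, inputs.y_am)


def spi(inputs: IndexInputs) -> float:
    """System productivity index: system output in maize-grain equivalents.

    The companion crop's yield is converted through the ratio of sole-crop
    yields, so the result carries maize yield units (kg ha-1).
    """
    return inputs.y_im + (inputs.y_mm / inputs.y_am) * inputs.y_ia


def relative_crowding(inputs: IndexInputs) -> CrowdingCoefficients:
    """Relative crowding coefficients (K_IM, K_IA) and the system product.

    A coefficient whose denominator is <= 0 (the crop yielded at least its
    sole-crop reference) is reported as ``inf`` with a flag; the system
    product is then flagged too.
    """
    if inputs.z_maize <= 0 or inputs.z_alfalfa <= 0:
        raise DomainError("crowding coefficients need positive sowing proportions")
    flags: list[str] = []

    def _one(y_i: float, y_m: float, z_own: float, z_other: float, tag: str) -> float:
        denom = (y_m - y_i) * z_own
        if denom <= 0:
            flags.append(f"{tag}:infinite")
            return math.inf
        return (y_i * z_other) / denom

    k_m = _one(inputs.y_im, inputs.y_mm, inputs.z_maize, inputs.z_alfalfa, "k_maize")
    k_a = _one(inputs.y_ia, inputs.y_am, inputs.z_alfalfa, inputs.z_maize, "k_alfalfa")
    if math.isinf(k_m) or math.isinf(k_a):
        flags.append("k_system:infinite")
        k_sys = math.inf
    else:
        k_sys = k_m * k_a
    return CrowdingCoefficients(k_m, k_a, k_sys, tuple(flags))


def aggressivity(inputs: IndexInputs) -> tuple[float, float]:
    """Aggressivity of maize (and its negation for alfalfa).

    Positive values mean maize dominates the mixture, negative values mean
    alfalfa does; zero means the crops are equally competitive.
    """
    if inputs.z_maize <= 0 or inputs.z_alfalfa <= 0:
        raise DomainError("aggressivity needs positive sowing proportions")
    a_m = inputs.y_im / (inputs.y_mm * inputs.z_maize) - inputs.y_ia / (
        inputs.y_am * inputs.z_alfalfa
    )
    return a_m, -a_m


def competitive_ratio(inputs: IndexInputs) -> tuple[float, float, tuple[str, ...]]:
    """Competitive ratios (CR_M, CR_A); their product is 1 when both defined.

    A zero partial LER makes one ratio infinite and the other zero; both are
    flagged rather than raising, mirroring the crowding coefficients.
    """
    if inputs.z_maize <= 0 or inputs.z_alfalfa <= 0:
        raise DomainError("competitive ratio needs positive sowing proportions")
    p_m = partial_ler(inputs.y_im, inputs.y_mm)
    p_a = partial_ler(inputs.y_ia, inputs.y_am)
    if p_m == 0 and p_a == 0:
        raise DomainError("competitive ratio undefined when both partial LERs are zero")
    flags: list[str] = []
    if p_a == 0:
        flags.append("cr_maize:infinite")
        return math.inf, 0.0, tuple(flags)
    if p_m == 0:
        flags.append("cr_alfalfa:infinite")
        return 0.0, math.inf, tuple(flags)
    cr_m = (p_m / p_a) * (inputs.z_alfalfa / inputs.z_maize)
    return cr_m, 1.0 / cr_m, tuple(flags)


def cumulative_yield(maize_grain: float, alfalfa_component: float) -> float:
    """Total system output: maize grain plus the alfalfa biomass component."""
    if maize_grain < 0 or alfalfa_component < 0:
        raise ValidationError("yields must be non-negative")
    return maize_grain + alfalfa_component


class PercentOfControl(NamedTuple):
    exact: float
    truncated: int
    rounded: int


def percent_of_control(treatment_value: float, control_value: float) -> PercentOfControl:
    """Treatment as a percentage of its control, with both integer renderings.

    Published summaries mix conventions, so the exact percentage is returned
    together with its truncation and its half-up rounding.
    """
    if control_value <= 0:
        raise DomainError(f"control value must be positive, got {control_value!r}")
    pct = 100.0 * treatment_value / control_value
    return PercentOfControl(pct, int(math.floor(pct)), int(math.floor(pct + 0.5)))


@dataclass(frozen=True)
class GasExchangeReading:
    """A closed-chamber CO2 draw-down measurement over a fixed interval."""

    n1: float
    n2: float
    interval: float = 60.0
    chamber_factor: float = 0.6 * 0.6  # 60 cm x 60 cm chamber constant

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValidationError("measurement interval must be positive")


def photosynthetic_rate(reading: GasExchangeReading) -> float:
    """Net photosynthetic rate (umol CO2 m-2 s-1) from a chamber reading.

    Computed as (N2 - N1) / (0.36 x interval); with the standard 60 s
    interval the denominator is 21.6.  Negative values (net CO2 release)
    are returned but flagged with a warning.
    """
    rate = (reading.n2 - reading.n1) / (reading.chamber_factor * reading.interval)
    if rate < 0:
        warnings.warn("negative photosynthetic rate: net CO2 release", stacklevel=2)
    return rate


@dataclass(frozen=True)
class IndexSet:
    """All indices for one configuration x year under one policy and mode."""

    year: int
    configuration: str
    yield_policy: str
    mode: str
    pler_maize: float
    pler_alfalfa: float
    ler: float
    lec: float
    spi: float
    k_maize: float
    k_alfalfa: float
    k_system: float
    aggressivity_maize: float
    aggressivity_alfalfa: float
    cr_maize: float
    cr_alfalfa: float
    cumulative_yield: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    _VALUE_FIELDS = (
        "pler_maize", "pler_alfalfa", "ler", "lec", "spi",
        "k_maize", "k_alfalfa", "k_system",
        "aggressivity_maize", "aggressivity_alfalfa",
        "cr_maize", "cr_alfalfa", "cumulative_yield",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._VALUE_FIELDS}


def compute_index_set(
    inputs: IndexInputs,
    *,
    cumulative: tuple[float, float] | None = None,
    year: int = 0,
    configuration: str = "",
    yield_policy: str = "forage",
    mode: str = "ratio_of_means",
) -> IndexSet:
    """Evaluate every index on one yield quadruple.

    ``cumulative`` supplies the (maize grain, alfalfa biomass) pair for the
    cumulative yield, which by definition uses biomass dry matter regardless
    of the ratio-index policy; when omitted, ``y_im + y_ia`` is used.
    """
    p_m = partial_ler(inputs.y_im, inputs.y_mm)
    p_a = partial_ler(inputs.y_ia, inputs.y_am)
    crowd = relative_crowding(inputs)
    a_m, a_a = aggressivity(inputs)
    cr_m, cr_a, cr_flags = competitive_ratio(inputs)
    cum_pair = cumulative if cumulative is not None else (inputs.y_im, inputs.y_ia)
    return IndexSet(
        year=year,
        configuration=configuration,
        yield_policy=yield_policy,
        mode=mode,
        pler_maize=p_m,
        pler_alfalfa=p_a,
        ler=p_m + p_a,
        lec=p_m * p_a,
        spi=spi(inputs),
        k_maize=crowd.k_maize,
        k_alfalfa=crowd.k_alfalfa,
        k_system=crowd.k_system,
        aggressivity_maize=a_m,
        aggressivity_alfalfa=a_a,
        cr_maize=cr_m,
        cr_alfalfa=cr_a,
        cumulative_yield=cumulative_yield(*cum_pair),
        flags=crowd.flags + cr_flags,
    )


def _alfalfa_trait(yield_policy: str) -> str:
    if yield_policy not in YIELD_POLICIES:
        raise ValueError(f"yield_policy must be one of {YIELD_POLICIES}, got {yield_policy!r}")
    return "forage_yield" if yield_policy == "forage" else "biomass_dm"


def _cell_or_missing(dataset: TrialDataset, year, configuration, crop, trait) -> np.ndarray:
    try:
        return dataset.cell(year, configuration, crop, trait)
    except MissingCellError as exc:
        raise MissingCellError(
            f"missing control/treatment cell for index computation: {exc}"
        ) from exc


def compute_all(
    dataset: TrialDataset,
    year: int,
    configuration: str,
    yield_policy: str = "forage",
    mode: str = "ratio_of_means",
) -> IndexSet:
    """Compute the full :class:`IndexSet` for one intercrop pattern and year.

    ``ratio_of_means`` evaluates the formulas on treatment means;
    ``per_replicate_mean`` evaluates them on each replicate pairing and
    averages, excluding (and flagging) replicates where a coefficient
    degenerates to infinity.  The modes coincide when replicate variance is
    zero.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    cfg = dataset.configurations.get(configuration)
    if cfg is None:
        raise ValidationError(f"unknown configuration {configuration!r}")
    if not cfg.is_intercrop:
        raise ValidationError(f"indices are defined for intercrop patterns, not {configuration!r}")
    a_trait = _alfalfa_trait(yield_policy)
    y_im = _cell_or_missing(dataset, year, configuration, MAIZE, "grain_yield")
    y_ia = _cell_or_missing(dataset, year, configuration, ALFALFA, a_trait)
    y_mm = _cell_or_missing(dataset, year, "MM", MAIZE, "grain_yield")
    y_am = _cell_or_missing(dataset, year, "AM", ALFALFA, a_trait)
    cum_a = _cell_or_missing(dataset, year, configuration, ALFALFA, "biomass_dm")

    def _mk(i_m, i_a, m_m, a_m_, c_a) -> IndexSet:
        return compute_index_set(
            IndexInputs(i_m, i_a, m_m, a_m_, cfg.z_maize, cfg.z_alfalfa),
            cumulative=(i_m, c_a),
            year=year,
            configuration=configuration,
            yield_policy=yield_policy,
            mode=mode,
        )

    if mode == "ratio_of_means":
        return _mk(
            float(np.mean(y_im)), float(np.mean(y_ia)),
            float(np.mean(y_mm)), float(np.mean(y_am)), float(np.mean(cum_a)),
        )

    n = {len(y_im), len(y_ia), len(y_mm), len(y_am), len(cum_a)}
    if len(n) != 1:
        raise ValidationError(
            "per-replicate averaging needs equal replicate counts in every cell"
        )
    per_rep = [
        _mk(float(y_im[r]), float(y_ia[r]), float(y_mm[r]), float(y_am[r]), float(cum_a[r]))
        for r in range(n.pop())
    ]
    values: dict[str, float] = {}
    flags: list[str] = []
    for name in IndexSet._VALUE_FIELDS:
        vals = np.array([getattr(s, name) for s in per_rep], dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size < vals.size:
            flags.append(f"{name}:{vals.size - finite.size}/{vals.size} replicates degenerate")
        values[name] = float(np.mean(finite)) if finite.size else math.inf
    return IndexSet(
        year=year,
        configuration=configuration,
        yield_policy=yield_policy,
        mode=mode,
        flags=tuple(flags),
        **values,
    )
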