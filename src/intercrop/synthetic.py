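"""Replacement-series trial simulator with closed-form ground truth.

The generator emulates the structure of a two-crop row-ratio field trial:
sole-crop means per crop x year x trait, one competition multiplier f per
intercrop pattern x crop (expected intercrop yield = f x sole-crop mean),
multiplicative replicate noise with a shared coefficient of variation, and a
fixed replicate count.  Because expected intercrop yields are proportional
to the sole-crop means, every ratio index has a closed form in the
multipliers alone (pLER_M = f_M, LER = f_M + f_A, A = f_M/Z_M - f_A/Z_A,
...), which makes parameter-recovery tests exact.

Randomness is derived from one root seed through per-cell seed streams, so
adding a year, pattern or trait never perturbs the draws of existing cells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .indices import IndexInputs, IndexSet, compute_all, compute_index_set
from .trial_data import (
    ALFALFA,
    MAIZE,
    STANDARD_CONFIGURATIONS,
    TRAIT_UNITS,
    PlotObservation,
    RowConfiguration,
    TrialDataset,
    load_reference_means,
    parse_configuration,
)

_ALFALFA_TRAIT = {"forage": "forage_yield", "biomass": "biomass_dm"}


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to draw one synthetic trial.

    ``mono_means`` is keyed by (crop, year, trait); ``multipliers`` by
    (pattern label, crop).  Sole-crop cells always use multiplier 1.
    """

    years: tuple[int, ...]
    configurations: tuple[RowConfiguration, ...]
    mono_means: Mapping[tuple[str, int, str], float]
    multipliers: Mapping[tuple[str, str], float]
    replicate_cv: float = 0.07
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValidationError("a trial needs at least two replicates")
        if self.replicate_cv < 0:
            raise ValidationError("replicate CV must be non-negative")
        if any(v <= 0 for v in self.mono_means.values()):
            raise ValidationError("sole-crop means must be positive")
        if any(f <= 0 for f in self.multipliers.values()):
            raise ValidationError("competition multipliers must be positive")
        for cfg in self.configurations:
            if not cfg.is_intercrop:
                continue
            for crop in cfg.crops:
                if (cfg.label, crop) not in self.multipliers:
                    raise ValidationError(
                        f"no competition multiplier for ({cfg.label!r}, {crop!r})"
                    )

    def traits_for(self, crop: str, year: int) -> tuple[str, ...]:
        return tuple(
            sorted(t for (c, y, t) in self.mono_means if c == crop and y == year)
        )

    def expected_value(self, year: int, configuration: str, crop: str, trait: str) -> float:
        mono = self.mono_means[(crop, year, trait)]
        cfg = next(c for c in self.configurations if c.label == configuration)
        if cfg.is_mono:
            return mono
        return self.multipliers[(configuration, crop)] * mono


def _cell_rng(seed: int, year: int, configuration: str, crop: str, trait: str):
    key = f"{year}|{configuration}|{crop}|{trait}".encode()
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(key)]))


def simulate_trial(spec: SimulationSpec) -> TrialDataset:
    """Draw one trial: value = expected x (1 + cv * eps), truncated at zero.

    eps is standard normal with an independent, seed-derived stream per
    (year, pattern, crop, trait) cell; the draw is deterministic in the
    spec's seed and invariant to the ordering of patterns in the spec.
    """
    obs: list[PlotObservation] = []
    for year in spec.years:
        for cfg in spec.configurations:
            for crop in cfg.crops:
                for trait in spec.traits_for(crop, year):
                    mean = spec.expected_value(year, cfg.label, crop, trait)
                    rng = _cell_rng(spec.seed, year, cfg.label, crop, trait)
                    eps = rng.standard_normal(spec.replicates)
                    values = np.maximum(mean * (1.0 + spec.replicate_cv * eps), 0.0)
                    for rep, v in enumerate(values, start=1):
                        obs.append(
                            PlotObservation(
                                year=year,
                                configuration=cfg.label,
                                replicate=rep,
                                crop=crop,
                                trait=trait,
                                value=float(v),
                                units=TRAIT_UNITS[trait],
                            )
                        )
    return TrialDataset.from_observations(obs, allow_unbalanced=True)


def theoretical_indices(
    spec: SimulationSpec,
    configuration: str,
    year: int,
    yield_policy: str = "forage",
) -> IndexSet:
    """The exact IndexSet implied by the spec's multipliers (no noise).

    Evaluates the index formulas at the expected yields, where every ratio
    index reduces to an expression in (f_M, f_A, Z_M, Z_A); e.g. the partial
    LERs are the multipliers themselves.
    """
    cfg = next(c for c in spec.configurations if c.label == configuration)
    a_trait = _ALFALFA_TRAIT[yield_policy]
    y_mm = spec.mono_means[(MAIZE, year, "grain_yield")]
    y_am = spec.mono_means[(ALFALFA, year, a_trait)]
    f_m = spec.multipliers[(configuration, MAIZE)]
    f_a = spec.multipliers[(configuration, ALFALFA)]
    am_biomass = spec.mono_means[(ALFALFA, year, "biomass_dm")]
    return compute_index_set(
        IndexInputs(f_m * y_mm, f_a * y_am, y_mm, y_am, cfg.z_maize, cfg.z_alfalfa),
        cumulative=(f_m * y_mm, f_a * am_biomass),
        year=year,
        configuration=configuration,
        yield_policy=yield_policy,
        mode="theoretical",
    )


def recovery_report(
    spec: SimulationSpec,
    n_trials: int,
    configuration: str | None = None,
    year: int | None = None,
    yield_policy: str = "forage",
) -> pd.DataFrame:
    """Monte-Carlo bias/spread of every index estimator against ground truth.

    Simulates ``n_trials`` independent trials from ``spec`` (the trial seeds
    are derived from the spec seed), estimates the indices of one pattern and
    year in both averaging modes, and summarizes each estimator against the
    theoretical value.  Degenerate (infinite) estimates are excluded from
    the mean/SD and counted in ``n_degenerate``.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if configuration is None:
        configuration = next(c.label for c in spec.configurations if c.is_intercrop)
    year = year if year is not None else spec.years[0]
    needed = {configuration, "MM", "AM"}
    sub = replace(
        spec,
        years=(year,),
        configurations=tuple(c for c in spec.configurations if c.label in needed),
    )
    truth = theoretical_indices(spec, configuration, year, yield_policy)
    estimates: dict[str, dict[str, list[float]]] = {
        mode: {name: [] for name in IndexSet._VALUE_FIELDS}
        for mode in ("per_replicate_mean", "ratio_of_means")
    }
    for i in range(n_trials):
        trial_seed = int(
            np.random.SeedSequence([sub.seed, 0x5EED, i]).generate_state(1)[0] % (2**31)
        )
        ds = simulate_trial(replace(sub, seed=trial_seed))
        for mode in estimates:
            idx = compute_all(ds, year, configuration, yield_policy, mode)
            for name in IndexSet._VALUE_FIELDS:
                estimates[mode][name].append(getattr(idx, name))
    rows = []
    for mode, per_index in estimates.items():
        for name, vals in per_index.items():
            arr = np.asarray(vals, dtype=float)
            finite = arr[np.isfinite(arr)]
            est_mean = float(np.mean(finite)) if finite.size else np.nan
            est_sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
            theo = getattr(truth, name)
            rows.append(
                {
                    "configuration": configuration,
                    "year": year,
                    "index": name,
                    "mode": mode,
                    "theoretical": theo,
                    "estimate_mean": est_mean,
                    "estimate_sd": est_sd,
                    "bias": est_mean - theo,
                    "n_trials": n_trials,
                    "n_degenerate": int(arr.size - finite.size),
                }
            )
    return pd.DataFrame(rows)


def reference_spec(seed: int = 0, replicate_cv: float = 0.07, replicates: int = 3) -> SimulationSpec:
    """A spec emulating the shipped reference trial.

    Sole-crop means are taken from the reference tables per year; each
    intercrop pattern's competition multipliers are the first-year
    intercrop/sole ratios of maize grain yield and alfalfa forage yield.
    The default CV of 0.07 matches the magnitude of the printed replicate
    SDs relative to their means.
    """
    means = load_reference_means("yields")
    mono_means: dict[tuple[str, int, str], float] = {}
    for _, row in means.iterrows():
        if row["configuration"] in ("MM", "AM"):
            mono_means[(row["crop"], int(row["year"]), row["trait"])] = float(row["mean"])
    first_year = int(means["year"].min())
    ref_trait = {MAIZE: "grain_yield", ALFALFA: "forage_yield"}
    multipliers: dict[tuple[str, str], float] = {}
    for cfg in STANDARD_CONFIGURATIONS:
        if cfg.is_mono:
            continue
        for crop in cfg.crops:
            trait = ref_trait[crop]
            inter = means[
                (means["configuration"] == cfg.label)
                & (means["crop"] == crop)
                & (means["trait"] == trait)
                & (means["year"] == first_year)
            ]["mean"].iloc[0]
            multipliers[(cfg.label, crop)] = float(inter) / mono_means[(crop, first_year, trait)]
    return SimulationSpec(
        years=tuple(int(y) for y in sorted(means["year"].unique())),
        configurations=STANDARD_CONFIGURATIONS,
        mono_means=mono_means,
        multipliers=multipliers,
        replicate_cv=replicate_cv,
        replicates=replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML round-trip for simulation specs
# ---------------------------------------------------------------------------

def spec_to_dict(spec: SimulationSpec) -> dict:
    return {
        "years": list(spec.years),
        "configurations": [c.label for c in spec.configurations],
        "mono_means": {
            crop: {
                int(year): {t: float(v) for (c, y, t), v in spec.mono_means.items()
                            if c == crop and y == year}
                for year in spec.years
            }
            for crop in (MAIZE, ALFALFA)
        },
        "multipliers": {
            label: {crop: float(f) for (lb, crop), f in spec.multipliers.items() if lb == label}
            for label in sorted({lb for lb, _ in spec.multipliers})
        },
        "replicate_cv": spec.replicate_cv,
        "replicates": spec.replicates,
        "seed": spec.seed,
    }


def spec_from_dict(data: Mapping) -> SimulationSpec:
    mono_means = {
        (crop, int(year), trait): float(v)
        for crop, per_year in data["mono_means"].items()
        for year, per_trait in per_year.items()
        for trait, v in per_trait.items()
    }
    multipliers = {
        (label, crop): float(f)
        for label, per_crop in data["multipliers"].items()
        for crop, f in per_crop.items()
    }
    return SimulationSpec(
        years=tuple(int(y) for y in data["years"]),
        configurations=tuple(parse_configuration(lbl) for lbl in data["configurations"]),
        mono_means=mono_means,
        multipliers=multipliers,
        replicate_cv=float(data.get("replicate_cv", 0.07)),
        replicates=int(data.get("replicates", 3)),
        seed=int(data.get("seed", 0)),
    )


def save_spec(spec: SimulationSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False), encoding="utf-8")


def load_spec(path: str | Path) -> SimulationSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
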