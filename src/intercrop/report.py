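"""Report assembly: index tables, ANOVA/letter tables, and the built-in
verification of the shipped reference tables.

``verify_reference`` recomputes every anchor value that is recoverable from
the shipped treatment-mean tables (LER, LEC, cumulative yield, plant-height
percentages, crowding bound) and compares it with the printed value at a
stated tolerance.  Three printed quantities are *not* recoverable from the
means and are reported as documented discrepancies rather than failures:
the exact SPI and system-K values (consistent with per-replicate averaging
of unpublished replicate data; the Jensen direction of the gap is
reproduced by the simulator) and the sign of the 3:1 maize aggressivity
(the printed positive value has the opposite sign to the formula evaluated
on the printed means).
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd

from .anova_lsd import analyze_trait, significance_stars
from .errors import DesignError
from .indices import compute_all, percent_of_control
from .trial_data import ALFALFA, MAIZE, TrialDataset, load_reference_dataset

SUMMARY_INDICES = ("ler", "lec", "spi", "k_system", "cumulative_yield")


def indices_table(
    dataset: TrialDataset,
    yield_policy: str = "forage",
    mode: str = "ratio_of_means",
    years: Iterable[int] | None = None,
) -> pd.DataFrame:
    """One row per (year, configuration, index): the machine-readable output."""
    years = tuple(years) if years is not None else dataset.years
    rows = []
    for year in years:
        for label in dataset.intercrop_labels():
            idx = compute_all(dataset, year, label, yield_policy, mode)
            for name, value in idx.as_dict().items():
                flag = ";".join(f for f in idx.flags if f.startswith(name))
                rows.append(
                    {
                        "year": year,
                        "configuration": label,
                        "index": name,
                        "mode": mode,
                        "yield_policy": yield_policy,
                        "value": value,
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows)


def letters_table(dataset: TrialDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Mean separation per (year, crop, trait): mean, SD, letter, stars."""
    df = dataset.observations
    rows = []
    combos = df[["year", "crop", "trait"]].drop_duplicates().itertuples(index=False)
    for year, crop, trait in combos:
        try:
            table, anova = analyze_trait(dataset, int(year), crop, trait, alpha)
        except DesignError:
            continue
        for _, r in table.iterrows():
            rows.append(
                {
                    "year": int(year),
                    "crop": crop,
                    "trait": trait,
                    "configuration": r["configuration"],
                    "mean": r["mean"],
                    "sd": r["sd"],
                    "letter": r["letter"],
                    "anova_p": anova.p_value,
                    "stars": significance_stars(anova.p_value),
                }
            )
    return pd.DataFrame(rows)


def best_configurations(indices: pd.DataFrame) -> dict:
    """Highest-scoring pattern per year for each headline index."""
    out: dict = {}
    finite = indices[indices["value"].apply(math.isfinite)]
    for year, per_year in finite.groupby("year"):
        out[int(year)] = {}
        for name in SUMMARY_INDICES:
            sub = per_year[per_year["index"] == name]
            if sub.empty:
                continue
            top = sub.loc[sub["value"].idxmax()]
            out[int(year)][name] = {
                "configuration": str(top["configuration"]),
                "value": float(top["value"]),
            }
    return out


# ---------------------------------------------------------------------------
# Verification against the printed anchor values
# ---------------------------------------------------------------------------

#: (anchor, year, printed value) - recoverable from the mean tables.
_ROUND1_ANCHORS = [
    ("LER MA(2:2), 1 d.p.", 2023, 1.5),
    ("LER MA(2:2), 1 d.p.", 2024, 1.5),
    ("LEC MA(2:2), 1 d.p.", 2023, 0.6),
    ("LEC MA(2:2), 1 d.p.", 2024, 0.6),
]
_CUMULATIVE_ANCHORS = [(2023, 14676.72), (2024, 15424.42)]
_HEIGHT_ANCHORS = [  # (year, crop, pattern, printed percent of control)
    (2023, MAIZE, "MA(3:1)", 97),
    (2024, MAIZE, "MA(3:1)", 97),
    (2023, ALFALFA, "MA(2:2)", 98),
    (2024, ALFALFA, "MA(2:2)", 98),
]
#: Printed values not recoverable from the mean tables (see module docstring).
DOCUMENTED_DISCREPANCIES = [
    ("SPI MA(2:2)", 2023, 14724.18),
    ("SPI MA(2:2)", 2024, 15552.09),
    ("K_system MA(2:2)", 2023, 12.82),
    ("K_system MA(2:2)", 2024, 13.63),
    ("A_maize MA(3:1)", 2023, 0.57),
    ("A_maize MA(3:1)", 2024, 0.58),
]


def verify_reference(
    strict: bool = False,
    rel_tolerance: float = 0.001,
    yield_policy: str = "forage",
) -> pd.DataFrame:
    """Recompute every printed anchor from the shipped tables and compare.

    Returns one row per anchor with the computed value, the printed value,
    the tolerance applied and a status: ``pass``/``fail`` for recoverable
    anchors, ``documented_discrepancy`` for the three quantities that cannot
    be recovered from the mean tables.  ``strict`` appends the discrepancy
    anchors with their computed counterparts so the gap is visible.
    """
    ds = load_reference_dataset("all")
    rows = []

    idx = {
        (year, lbl): compute_all(ds, year, lbl, yield_policy, "ratio_of_means")
        for year in ds.years
        for lbl in ds.intercrop_labels()
    }
    idx_biomass = {
        (year, "MA(2:2)"): compute_all(ds, year, "MA(2:2)", "biomass", "ratio_of_means")
        for year in ds.years
    }

    for name, year, printed in _ROUND1_ANCHORS:
        value = idx[(year, "MA(2:2)")].ler if name.startswith("LER") else idx[(year, "MA(2:2)")].lec
        rows.append(
            {
                "anchor": name,
                "year": year,
                "computed": value,
                "printed": printed,
                "tolerance": "round to 1 d.p.",
                "status": "pass" if round(value, 1) == printed else "fail",
            }
        )

    for year, printed in _CUMULATIVE_ANCHORS:
        value = idx[(year, "MA(2:2)")].cumulative_yield
        ok = abs(value - printed) <= rel_tolerance * printed
        rows.append(
            {
                "anchor": "cumulative yield MA(2:2) (kg ha-1)",
                "year": year,
                "computed": value,
                "printed": printed,
                "tolerance": f"relative {rel_tolerance:g}",
                "status": "pass" if ok else "fail",
            }
        )

    mono = {MAIZE: "MM", ALFALFA: "AM"}
    for year, crop, pattern, printed in _HEIGHT_ANCHORS:
        treat, _ = ds.aggregate_means(year, pattern, crop, "plant_height")
        ctrl, _ = ds.aggregate_means(year, mono[crop], crop, "plant_height")
        pct = percent_of_control(treat, ctrl)
        ok = printed in (pct.truncated, pct.rounded)
        rows.append(
            {
                "anchor": f"{crop} {pattern} plant height, % of control",
                "year": year,
                "computed": pct.exact,
                "printed": printed,
                "tolerance": "integer (truncated or rounded)",
                "status": "pass" if ok else "fail",
            }
        )

    for year in ds.years:
        lers = [idx[(year, lbl)].ler for lbl in ds.intercrop_labels()]
        lecs = [idx[(year, lbl)].lec for lbl in ds.intercrop_labels()]
        rows.append(
            {
                "anchor": "minimum intercrop LER",
                "year": year,
                "computed": min(lers),
                "printed": 1.0,
                "tolerance": "strict bound (>)",
                "status": "pass" if min(lers) > 1.0 and min(lecs) > 0.0 else "fail",
            }
        )
        k = idx[(year, "MA(2:2)")].k_system
        rows.append(
            {
                "anchor": "K_system MA(2:2) bound",
                "year": year,
                "computed": k,
                "printed": 1.0,
                "tolerance": "strict bound (>)",
                "status": "pass" if k > 1.0 else "fail",
            }
        )

    if strict:
        computed_lookup = {
            ("SPI MA(2:2)", 2023): idx_biomass[(2023, "MA(2:2)")].spi,
            ("SPI MA(2:2)", 2024): idx_biomass[(2024, "MA(2:2)")].spi,
            ("K_system MA(2:2)", 2023): idx_biomass[(2023, "MA(2:2)")].k_system,
            ("K_system MA(2:2)", 2024): idx_biomass[(2024, "MA(2:2)")].k_system,
            ("A_maize MA(3:1)", 2023): idx[(2023, "MA(3:1)")].aggressivity_maize,
            ("A_maize MA(3:1)", 2024): idx[(2024, "MA(3:1)")].aggressivity_maize,
        }
        for name, year, printed in DOCUMENTED_DISCREPANCIES:
            rows.append(
                {
                    "anchor": name,
                    "year": year,
                    "computed": computed_lookup[(name, year)],
                    "printed": printed,
                    "tolerance": "not recoverable from mean tables",
                    "status": "documented_discrepancy",
                }
            )
    return pd.DataFrame(rows)
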