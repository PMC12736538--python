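"""One-way CRD ANOVA and Fisher's protected LSD with compact letter display.

The trial design is a completely randomized design analyzed one trait at a
time within each year, so the model is the classical one-way decomposition:
SS_total = SS_treatment + SS_error, F = MS_treatment / MS_error on
(g - 1, N - g) degrees of freedom.

Mean separation uses Fisher's least significant difference,
LSD = t(1 - alpha/2, df_error) * sqrt(2 * MS_error / n), applied to all
treatment pairs; "protected" means pairwise comparison happens only when the
ANOVA F-test itself is significant at alpha, otherwise every treatment
shares the letter "a".  Letters are assigned in descending-mean order by the
insert-and-absorb algorithm: treatments sharing any letter do not differ by
more than the LSD, treatments sharing none do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .trial_data import TrialDataset


@dataclass(frozen=True)
class AnovaTable:
    df_treatment: int
    df_error: int
    ss_treatment: float
    ss_error: float
    f_statistic: float
    p_value: float

    @property
    def ms_treatment(self) -> float:
        return self.ss_treatment / self.df_treatment

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error


@dataclass(frozen=True)
class LetterGroups:
    """Compact letter display: per-treatment letter strings at level alpha."""

    letters: dict[str, str]
    alpha: float
    lsd: float
    protected: bool


def significance_stars(p: float) -> str:
    """Conventional star codes: *** p<=0.001, ** p<=0.01, * p<=0.05, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """Completely-randomized one-way ANOVA from replicate value lists.

    Zero total variance (all observations identical) is reported as F = 0
    with p = 1 rather than the 0/0 indeterminate form.
    """
    if len(groups) < 2:
        raise DesignError("ANOVA needs at least two treatment groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise DesignError("every treatment group needs at least two replicates")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_treat = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_error = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_treat = len(arrays) - 1
    df_error = all_values.size - len(arrays)
    if ss_error <= 0.0:
        if ss_treat <= 0.0:
            return AnovaTable(df_treat, df_error, 0.0, 0.0, 0.0, 1.0)
        return AnovaTable(df_treat, df_error, ss_treat, 0.0, np.inf, 0.0)
    f = (ss_treat / df_treat) / (ss_error / df_error)
    if ss_treat <= 0.0:
        return AnovaTable(df_treat, df_error, ss_treat, ss_error, 0.0, 1.0)
    p = float(stats.f.sf(f, df_treat, df_error))
    return AnovaTable(df_treat, df_error, ss_treat, ss_error, float(f), p)


def lsd_threshold(ms_error: float, df_error: int, n_per_group: int, alpha: float = 0.05) -> float:
    """Fisher's least significant difference for balanced groups."""
    if df_error < 1:
        raise DesignError("LSD needs at least one error degree of freedom")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df_error)
    return float(t_crit * np.sqrt(2.0 * ms_error / n_per_group))


def _letters_from_matrix(order: list[str], differ: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` lists treatments by descending mean; ``differ[i, j]`` is True
    when treatments i and j are significantly different.  Each letter is a
    maximal set of mutually non-different treatments; absorption removes
    letter columns that are subsets of another.
    """
    m = len(order)
    columns: list[set[int]] = [set(range(m))]
    for i in range(m):
        for j in range(i + 1, m):
            if not differ[i, j]:
                continue
            for col in list(columns):
                if i in col and j in col:
                    columns.remove(col)
                    a, b = col - {j}, col - {i}
                    for new in (a, b):
                        if not any(new <= other for other in columns):
                            columns.append(new)
                    columns = [
                        c for c in columns
                        if not any(c < other for other in columns)
                    ]
    # order letters by the highest-mean member, then size, for stable output
    columns.sort(key=lambda c: (min(c), -len(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {t: "" for t in order}
    for idx, col in enumerate(columns):
        if idx >= len(alphabet):
            raise DesignError("compact letter display exceeded 26 letters")
        for i in sorted(col):
            letters[order[i]] += alphabet[idx]
    return letters


def lsd_letters(
    means: Mapping[str, float],
    ms_error: float,
    df_error: int,
    n_per_group: int,
    alpha: float = 0.05,
    *,
    anova_p: float | None = None,
    protected: bool = True,
) -> LetterGroups:
    """Compact letter display from all-pairs LSD comparisons.

    With ``protected=True`` (the default) letters are only split when the
    ANOVA p-value passed as ``anova_p`` is <= alpha; without a significant
    F-test every treatment is reported as "a".  Ties in means are broken by
    treatment label, which only affects presentation order.
    """
    if n_per_group < 2:
        raise DesignError("LSD needs at least two replicates per group")
    order = sorted(means, key=lambda t: (-means[t], t))
    lsd = lsd_threshold(ms_error, df_error, n_per_group, alpha)
    if protected and anova_p is not None and anova_p > alpha:
        return LetterGroups({t: "a" for t in order}, alpha, lsd, protected)
    m = len(order)
    differ = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            differ[i, j] = differ[j, i] = abs(means[order[i]] - means[order[j]]) > lsd
    letters = _letters_from_matrix(order, differ)
    return LetterGroups(letters, alpha, lsd, protected)


def analyze_trait(
    dataset: TrialDataset,
    year: int,
    crop: str,
    trait: str,
    alpha: float = 0.05,
    *,
    protected: bool = True,
) -> tuple[pd.DataFrame, AnovaTable]:
    """ANOVA + LSD letters for one (year, crop, trait) across its patterns.

    Returns a table with one row per planting pattern (mean, sd, letter)
    sorted by descending mean, plus the underlying :class:`AnovaTable`.
    """
    df = dataset.observations
    sel = df[(df["year"] == year) & (df["crop"] == crop) & (df["trait"] == trait)]
    if sel.empty:
        raise DesignError(f"no observations for year={year}, crop={crop!r}, trait={trait!r}")
    labels = sorted(sel["configuration"].unique())
    groups = [dataset.cell(year, lbl, crop, trait) for lbl in labels]
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise DesignError("LSD mean separation requires balanced groups")
    table = one_way_anova(groups)
    means = {lbl: float(np.mean(g)) for lbl, g in zip(labels, groups)}
    sds = {lbl: float(np.std(g, ddof=1)) for lbl, g in zip(labels, groups)}
    lg = lsd_letters(
        means,
        table.ms_error,
        table.df_error,
        sizes.pop(),
        alpha,
        anova_p=table.p_value,
        protected=protected,
    )
    out = pd.DataFrame(
        {
            "configuration": list(means),
            "mean": [means[t] for t in means],
            "sd": [sds[t] for t in means],
            "letter": [lg.letters[t] for t in means],
        }
    ).sort_values("mean", ascending=False, kind="stable").reset_index(drop=True)
    out.attrs["stars"] = significance_stars(table.p_value)
    out.attrs["lsd"] = lg.lsd
    return out, table
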