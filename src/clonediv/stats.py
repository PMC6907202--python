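"""Thin delegations to standard group-comparison routines.

One-way ANOVA + Tukey HSD (with compact significance letters), two-sample
Kolmogorov-Smirnov, and Mann-Whitney U.  Nothing here is novel statistics;
the value is a uniform tabular interface for the feature-class and
clone-group comparisons the analysis reports.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def tukey_hsd(groups: Mapping[str, Sequence[float]],
              alpha: float = 0.01) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise Tukey HSD plus compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    """
    names = [n for n in groups if len(groups[n]) >= 2]
    if len(names) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups with >= 2 values each")
    values = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
    labels = np.concatenate([[n] * len(groups[n]) for n in names])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    table["reject"] = table["reject"].astype(bool)
    letters = _compact_letters(names, table, groups)
    return table, letters


def _compact_letters(names, tukey_table, groups) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise rejections."""
    different = {
        frozenset((r["group1"], r["group2"]))
        for _, r in tukey_table.iterrows() if r["reject"]
    }
    order = sorted(names, key=lambda n: -np.mean(groups[n]))
    letter_sets: list[set[str]] = []
    for n in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((n, m)) not in different for m in s):
                s.add(n)
                placed = True
        if not placed:
            letter_sets.append({n})
    # absorb subsets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for letter, s in zip(alphabet, letter_sets):
        for n in s:
            out[n] += letter
    return {n: "".join(sorted(v)) for n, v in out.items()}


def ks_test(a: Sequence[float], b: Sequence[float]) -> pd.DataFrame:
    stat, p = sps.ks_2samp(a, b)
    return pd.DataFrame([{"test": "kolmogorov-smirnov",
                          "statistic": stat, "pvalue": p}])


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 alternative: str = "two-sided") -> pd.DataFrame:
    stat, p = sps.mannwhitneyu(a, b, alternative=alternative)
    return pd.DataFrame([{"test": "mann-whitney",
                          "statistic": stat, "pvalue": p}])


def compare_groups(groups: Mapping[str, Sequence[float]],
                   test: str = "tukey", alpha: float = 0.01) -> pd.DataFrame:
    """Dispatch to the named test; returns a tidy summary table."""
    names = list(groups)
    if test == "tukey":
        table, letters = tukey_hsd(groups, alpha=alpha)
        table["letters_group1"] = table["group1"].map(letters)
        table["letters_group2"] = table["group2"].map(letters)
        return table
    if len(names) != 2:
        raise ValueError(f"{test} test needs exactly 2 groups")
    a, b = groups[names[0]], groups[names[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs >= 2 values")
    if test == "ks":
        return ks_test(a, b)
    if test == "mannwhitney":
        return mann_whitney(a, b)
    raise ValueError(f"unknown test {test!r}")
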