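"""Inferential statistics for the concentration survey.

Two jobs: (i) the inter-metal Pearson correlation matrix used to argue for
a common contamination source, robust to metals whose column is constant
after below-detection substitution; (ii) species/season comparisons —
Brown–Forsythe (median-centred Levene) homogeneity, one-way ANOVA,
Tukey(–Kramer) HSD post hoc with a compact letter display, and the
pooled-variance t-test for the two-group case.

The heavy lifting is delegated to scipy; this module owns the degenerate
cases, the letter display and the table rendering conventions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson coefficients with per-cell diagnostics.

    ``r`` and ``p`` are symmetric DataFrames indexed by metal; a cell is
    NaN (flagged ``constant_input``) when at least one of the two vectors
    has zero variance, in which case the coefficient does not exist.
    """

    metals: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame

    def render(self, star_levels: tuple[tuple[float, str], ...] = ((0.01, "**"), (0.05, "*"))) -> pd.DataFrame:
        """Lower-triangular display with significance stars.

        Undefined cells render as ``"c"`` (constant input), mirroring the
        footnote convention of survey correlation tables.
        """
        out = pd.DataFrame("", index=self.metals, columns=self.metals)
        for i, a in enumerate(self.metals):
            for j, b in enumerate(self.metals[: i + 1]):
                if self.flags.loc[a, b] == "constant_input":
                    out.loc[a, b] = "c"
                    continue
                r = self.r.loc[a, b]
                stars = ""
                if a != b:
                    for level, mark in sorted(star_levels):
                        if self.p.loc[a, b] < level:
                            stars = mark
                            break
                out.loc[a, b] = f"{r:.3f}{stars}"
        return out


def pearson_matrix(samples: pd.DataFrame | Mapping[str, Sequence[float]]) -> CorrelationMatrix:
    """Product-moment correlation over common samples, per metal pair.

    ``samples`` holds one equal-length value vector per metal. Two-tailed
    p-values come from the t-transform with n-2 degrees of freedom. A
    zero-variance vector makes every cell involving it undefined (NaN,
    flag ``constant_input``) instead of raising — below-detection metals
    substituted at a constant produce exactly this degeneracy.
    """
    df = pd.DataFrame(samples, dtype=float) if not isinstance(samples, pd.DataFrame) else samples.astype(float)
    lengths = {len(df[c].dropna()) for c in df.columns}
    if len(lengths) > 1 or df.isna().any().any():
        raise ValueError("metal vectors must be complete and of equal length")
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 common samples, got {n}")
    metals = tuple(df.columns)
    r = pd.DataFrame(np.nan, index=metals, columns=metals)
    p = pd.DataFrame(np.nan, index=metals, columns=metals)
    flags = pd.DataFrame("", index=metals, columns=metals)
    constant = {m: bool(np.ptp(df[m].to_numpy()) == 0) for m in metals}
    for a, b in itertools.combinations_with_replacement(metals, 2):
        if constant[a] or constant[b]:
            flags.loc[a, b] = flags.loc[b, a] = "constant_input"
            continue
        if a == b:
            r.loc[a, b], p.loc[a, b] = 1.0, 0.0
            continue
        res = sps.pearsonr(df[a], df[b])
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return CorrelationMatrix(metals=metals, r=r, p=p, flags=flags)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a k-group location comparison for one factor."""

    factor: str
    groups: tuple[str, ...]
    levene_stat: float
    levene_p: float
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, diff, p_adj, significant
    letters: dict[str, str]
    alpha: float
    t_stat: float | None = None  # pooled-variance t-test, two-group case only
    t_p: float | None = None


def compare_groups(
    values: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    factor: str = "group",
) -> ComparisonResult:
    """Homogeneity, ANOVA, Tukey HSD and letter display for >= 2 groups.

    Levene's test uses median centring (Brown–Forsythe). Unequal group
    sizes get the Tukey–Kramer correction (scipy's ``tukey_hsd``). With
    exactly two groups the pooled-variance t-test is reported as well; its
    squared statistic equals the ANOVA F. Groups with zero variance are
    legal. The compact letter display assigns a shared letter to exactly
    those group pairs whose Tukey-adjusted p exceeds ``alpha``.
    """
    names = tuple(values)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = [np.asarray(values[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if len(a) < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")

    lev_stat, lev_p = sps.levene(*arrays, center="median")
    f_stat, f_p = sps.f_oneway(*arrays)

    hsd = sps.tukey_hsd(*arrays)
    rows = []
    sig_pairs = set()
    for i, j in itertools.combinations(range(len(names)), 2):
        p_adj = float(hsd.pvalue[i, j])
        significant = bool(p_adj <= alpha)
        if significant:
            sig_pairs.add((names[i], names[j]))
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p_adj": p_adj,
                "significant": significant,
            }
        )
    tukey = pd.DataFrame(rows, columns=["group1", "group2", "diff", "p_adj", "significant"])

    means = {g: float(np.mean(a)) for g, a in zip(names, arrays)}
    letters = compact_letter_display(names, sig_pairs, means)

    t_stat = t_p = None
    if len(names) == 2:
        t_stat, t_p = (float(x) for x in sps.ttest_ind(arrays[0], arrays[1], equal_var=True))

    return ComparisonResult(
        factor=factor,
        groups=names,
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        anova_f=float(f_stat),
        anova_p=float(f_p),
        tukey=tukey,
        letters=letters,
        alpha=alpha,
        t_stat=t_stat,
        t_p=t_p,
    )


def compact_letter_display(
    groups: Sequence[str],
    significant_pairs: set[tuple[str, str]],
    means: Mapping[str, float] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups that are NOT significantly different share at least one letter;
    significantly different pairs share none. The output depends only on
    the significant-pair set (and on means for letter ordering), not on the
    insertion order of the groups.
    """
    sig = {frozenset(p) for p in significant_pairs}
    order = sorted(groups, key=lambda g: (-(means or {}).get(g, 0.0), g))
    columns: list[set[str]] = [set(order)]
    for pair in sorted(sig, key=lambda fs: sorted(fs)):
        a, b = sorted(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.extend(({x for x in col if x != a}, {x for x in col if x != b}))
        # absorb columns contained in another
        columns = [
            c for c in columns if c and not any(c < other for other in columns)
        ]
        # drop duplicates, keep deterministic order
        seen: list[set[str]] = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen
    # letter columns ordered by the best-ranked group they contain
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in col:
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in groups}


def seasonal_comparisons(
    seasonal_values: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-metal factor comparisons on replicate-level wet-weight values.

    ``seasonal_values`` is tidy with columns ``species_id, metal, season,
    ww``. For each metal, compares seasons (pooled over species, two-group
    t-test/ANOVA) and species (pooled over seasons, Tukey letters).
    Metals left constant by below-detection substitution are reported with
    NaN statistics and the flag ``constant_input``.
    """
    rows = []
    for metal, sub in seasonal_values.groupby("metal"):
        for factor, key in (("season", "season"), ("species", "species_id")):
            groups = {g: d["ww"].to_numpy() for g, d in sub.groupby(key)}
            if np.ptp(sub["ww"].to_numpy()) == 0:
                rows.append(
                    {
                        "metal": metal, "factor": factor, "levene_p": np.nan,
                        "anova_f": np.nan, "anova_p": np.nan,
                        "letters": "", "flag": "constant_input",
                    }
                )
                continue
            res = compare_groups(groups, alpha=alpha, factor=factor)
            rows.append(
                {
                    "metal": metal,
                    "factor": factor,
                    "levene_p": res.levene_p,
                    "anova_f": res.anova_f,
                    "anova_p": res.anova_p,
                    "letters": "; ".join(f"{g}:{l}" for g, l in sorted(res.letters.items())),
                    "flag": "",
                }
            )
    return pd.DataFrame(
        rows, columns=["metal", "factor", "levene_p", "anova_f", "anova_p", "letters", "flag"]
    )
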