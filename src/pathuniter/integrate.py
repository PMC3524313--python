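"""Cross-platform combination of pathway P-values and significance calls.

Fisher's method combines k independent P-values into chi2 = -2 * sum(ln p)
with an upper-tail probability at 2k degrees of freedom.  Pathways eligible
on both platforms are combined, BH-adjusted over the intersection, and
flagged by two significance tiers: nominal P below 0.01 and FDR below 0.2
(both strict).  A Venn-style overlap summary compares the significant
pathway lists of up to four methods.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TIER1_P_CUT = 0.01
TIER2_FDR_CUT = 0.2


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability test.

    chi2 = -2 * sum(ln p_i); the combined P is the upper tail of a
    chi-square with 2k degrees of freedom.  Inputs must lie in (0, 1];
    a zero P is an error — empirical P-values produced upstream use the
    (1+b)/(B+1) convention and can never be zero, so a zero here means the
    caller must clamp at 1/(B+1) first.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one P-value")
    if np.any(p <= 0):
        raise ValueError(
            "P-values must be positive; clamp empirical zeros at 1/(B+1)"
        )
    if np.any(p > 1):
        raise ValueError("P-values must be <= 1")
    chi2 = float(-2.0 * np.log(p).sum())
    p_combined = float(stats.chi2.sf(chi2, df=2 * p.size))
    return chi2, p_combined


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, order-stable."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tier_select(
    results: pd.DataFrame,
    p_cut: float = TIER1_P_CUT,
    fdr_cut: float = TIER2_FDR_CUT,
) -> pd.DataFrame:
    """Attach tier flags: tier1 = nominal P < p_cut, tier2 = FDR < fdr_cut.

    Both inequalities are strict: a pathway at exactly the cutoff is not
    selected.
    """
    if not {"p", "fdr"} <= set(results.columns):
        raise ValueError("results must carry 'p' and 'fdr' columns")
    out = results.copy()
    out["tier1"] = out["p"] < p_cut
    out["tier2"] = out["fdr"] < fdr_cut
    return out


def significant_sets(flagged: pd.DataFrame) -> set[str]:
    """Pathways passing either tier (the union used for method comparison)."""
    mask = flagged["tier1"] | flagged["tier2"]
    return set(flagged.loc[mask, "set"])


def combine_platforms(
    gwas: pd.DataFrame, expr: pd.DataFrame
) -> pd.DataFrame:
    """Fisher-combine per-pathway P-values across the two platforms.

    Restricted to pathways present in both tables; per pathway the GWAS
    and expression P-values are combined at 4 df, BH FDR is computed over
    the intersection, and tier flags are attached.  Output is sorted by
    combined P then name, so it is invariant to input row order.
    """
    g = gwas.set_index("set")["p"]
    e = expr.set_index("set")["p"]
    common = sorted(set(g.index) & set(e.index))
    if not common:
        raise ValueError("no pathway is eligible on both platforms")
    n_only_gwas = len(set(g.index) - set(common))
    n_only_expr = len(set(e.index) - set(common))
    rows = []
    for name in common:
        chi2, p_comb = fisher_combine([float(g[name]), float(e[name])])
        rows.append((name, float(g[name]), float(e[name]), chi2, p_comb))
    df = pd.DataFrame(
        rows, columns=["set", "p_gwas", "p_expr", "chi2", "p_combined"]
    )
    df["fdr"] = bh_fdr(df["p_combined"].to_numpy())
    df["tier1"] = df["p_combined"] < TIER1_P_CUT
    df["tier2"] = df["fdr"] < TIER2_FDR_CUT
    df.attrs["n_common"] = len(common)
    df.attrs["n_excluded_gwas_only"] = n_only_gwas
    df.attrs["n_excluded_expr_only"] = n_only_expr
    return df.sort_values(["p_combined", "set"], kind="stable").reset_index(drop=True)


def overlap_summary(named_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Venn-partition counts for 2-4 named collections of significant sets.

    Returns one row per non-empty-label region of the Venn partition
    (region = the exact combination of methods an element belongs to) plus
    "shared by >= m methods" rows for m = 1..k.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("overlap summary supports 2 to 4 collections")
    sets = {n: set(v) for n, v in named_sets.items()}
    universe = set().union(*sets.values())
    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            region_counts[combo] = len(inside)
    rows = [
        ("&".join(combo), "exactly", count)
        for combo, count in region_counts.items()
    ]
    membership_count = {
        el: sum(el in sets[n] for n in names) for el in universe
    }
    for m in range(1, len(names) + 1):
        rows.append(
            (f">={m}", "at_least", sum(1 for c in membership_count.values() if c >= m))
        )
    return pd.DataFrame(rows, columns=["region", "kind", "count"])
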