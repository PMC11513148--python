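"""Lipidome acyl-chain analysis: per-class normalization, total-acyl
aggregation, asymmetry classification, and group statistics with two-stage
adaptive FDR.

Shotgun-lipidomics species tables carry, per sample, a mol% for each
species identified by lipid class (PI, PS, PA, PC, PE, sphingolipids …)
and — where resolved — the two acyl chains as carbons:double-bonds.  The
analysis normalizes abundances within each class (mol%/class), labels
species by total acyl carbons (C-26, C-28, …), and classifies a species as
*asymmetric* when its paired chains differ in length by at least Δ_min
carbons (default 6, covering 10:0/16:0 and 10:0/18:x pairings while
excluding common 16/18 combinations), recording whether both chains are
saturated or the long chain is mono-unsaturated.  Group differences are
tested per species by an unpaired pooled-variance t-test, with discoveries
controlled by the two-stage linear step-up procedure of Benjamini, Krieger
and Yekutieli at Q (default 1%), applied per lipid-class family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "parse_chain",
    "AsymmetryCall",
    "normalize_per_class",
    "total_acyl_label",
    "classify_asymmetry",
    "two_stage_bky",
    "compare_groups",
]


def parse_chain(chain: str | None) -> tuple[int, int] | None:
    """Parse an acyl chain ``"carbons:double_bonds"``; None/'' means unknown."""
    if chain is None or (isinstance(chain, float) and np.isnan(chain)) or chain == "":
        return None
    c, d = str(chain).split(":")
    c, d = int(c), int(d)
    if c <= 0 or d < 0:
        raise ValueError(f"invalid acyl chain {chain!r}")
    return c, d


def normalize_per_class(table: pd.DataFrame, value_col: str = "mol_percent") -> pd.DataFrame:
    """Renormalize abundances to mol%/class: within every (sample, class)
    block the values sum to 100.  Idempotent; a zero class total raises
    ``ValueError`` naming the sample and class."""
    out = table.copy()
    totals = out.groupby(["sample", "class"])[value_col].transform("sum")
    bad = totals == 0
    if bad.any():
        row = out[bad].iloc[0]
        raise ValueError(f"class total is 0 for sample {row['sample']!r}, class {row['class']!r}")
    out[value_col] = 100.0 * out[value_col] / totals
    return out


def total_acyl_label(
    chain1: str | None, chain2: str | None, total_carbons: int | None = None
) -> str:
    """Total-acyl-carbon label, e.g. chains 10:0 and 16:0 → ``"C-26"``.

    Falls back to ``total_carbons`` when chains are unresolved; with
    neither available the label is ``"unknown"``.
    """
    c1, c2 = parse_chain(chain1), parse_chain(chain2)
    if c1 is not None and c2 is not None:
        return f"C-{c1[0] + c2[0]}"
    if total_carbons is not None:
        if total_carbons <= 0:
            raise ValueError("total_carbons must be positive")
        return f"C-{int(total_carbons)}"
    return "unknown"


@dataclass(frozen=True)
class AsymmetryCall:
    delta_carbons: int | None
    call: str                 # asymmetric | symmetric | unknown
    saturation_profile: str   # both_saturated | long_chain_monounsaturated | other | unknown


def classify_asymmetry(
    chain1: str | None, chain2: str | None, delta_min: int = 6
) -> AsymmetryCall:
    """Call a species asymmetric when its chains differ by ≥ ``delta_min``
    carbons; symmetric under chain swap.

    The saturation profile distinguishes species with two saturated chains
    from those whose *long* chain carries exactly one double bond (the two
    profiles characteristic of the asymmetric species that accumulate when
    Golgi quality control is impaired); anything else is ``other``.
    Species with an unresolved chain are ``unknown``/``unknown``.
    """
    c1, c2 = parse_chain(chain1), parse_chain(chain2)
    if c1 is None or c2 is None:
        return AsymmetryCall(None, "unknown", "unknown")
    (ca, da), (cb, db) = sorted([c1, c2])  # short chain first
    delta = cb - ca
    call = "asymmetric" if delta >= delta_min else "symmetric"
    if da == 0 and db == 0:
        sat = "both_saturated"
    elif da == 0 and db == 1:
        sat = "long_chain_monounsaturated"
    else:
        sat = "other"
    return AsymmetryCall(delta, call, sat)


def two_stage_bky(p_values, q: float = 0.01) -> np.ndarray:
    """Two-stage linear step-up discovery flags (Benjamini–Krieger–Yekutieli).

    Stage 1 runs a BH step-up at q′ = Q/(1+Q); with r₁ rejections the
    number of true nulls is estimated as m₀ = m − r₁ (all rejected → reject
    everything; none → stop).  Stage 2 reruns the step-up at q′·m/m₀.
    Flags are returned in input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.isnan(p).any() or ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if not (0 < q < 1):
        raise ValueError("Q must lie in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)

    def step_up(level: float) -> np.ndarray:
        order = np.argsort(p, kind="stable")
        sorted_p = p[order]
        thresh = level * (np.arange(1, m + 1)) / m
        below = np.nonzero(sorted_p <= thresh)[0]
        k = below[-1] + 1 if below.size else 0
        flags = np.zeros(m, dtype=bool)
        flags[order[:k]] = True
        return flags

    stage1 = step_up(q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return stage1
    if r1 == m:
        return stage1
    m0 = m - r1
    return step_up(q1 * m / m0)


def compare_groups(
    table: pd.DataFrame,
    group_pair: tuple[str, str],
    q: float = 0.01,
    family: str = "class",
    value_col: str = "mol_percent",
) -> pd.DataFrame:
    """Per-species unpaired pooled-variance t-tests between two groups with
    two-stage step-up FDR control at ``q``.

    The test family over which the correction runs is each lipid class's
    species set (``family="class"``, mirroring one figure panel per class)
    or all species at once (``family="global"``).  Species constant in both
    groups get p = 1 with a warning.  Returns one row per species:
    group means ± SD, t, raw p, and the discovery flag.
    """
    ga, gb = group_pair
    sub = table[table["group"].isin(group_pair)]
    if sub.empty:
        raise ValueError(f"no rows for groups {group_pair}")
    keys = ["class", "chain1", "chain2"]
    sub = sub.copy()
    for k in keys[1:]:
        sub[k] = sub[k].fillna("")
    rows = []
    for (cls, c1, c2), grp in sub.groupby(keys, sort=True):
        va = grp.loc[grp["group"] == ga, value_col].to_numpy(dtype=float)
        vb = grp.loc[grp["group"] == gb, value_col].to_numpy(dtype=float)
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"species {(cls, c1, c2)}: need ≥ 2 replicates per group")
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            warnings.warn(
                f"species {cls} {c1};{c2} constant in both groups; p set to 1", stacklevel=2
            )
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(va, vb, equal_var=True)
            p = float(min(max(p, np.finfo(float).tiny), 1.0))
        rows.append(
            {
                "class": cls,
                "chain1": c1 or None,
                "chain2": c2 or None,
                f"mean_{ga}": va.mean(),
                f"sd_{ga}": va.std(ddof=1),
                f"mean_{gb}": vb.mean(),
                f"sd_{gb}": vb.std(ddof=1),
                "t": float(t_stat),
                "p": p,
            }
        )
    res = pd.DataFrame(rows)
    res["discovery"] = False
    if family == "global":
        res["discovery"] = two_stage_bky(res["p"].to_numpy(), q=q)
    elif family == "class":
        for cls, idx in res.groupby("class").groups.items():
            res.loc[idx, "discovery"] = two_stage_bky(res.loc[idx, "p"].to_numpy(), q=q)
    else:
        raise ValueError("family must be 'class' or 'global'")
    return res
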