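"""SILAC differential-abundance calling and two-contrast overlap analysis.

Peptide-level heavy/light (H/L) log2 ratios — heavy wild-type versus light
mutant — are reduced to per-protein, per-replicate values, filtered by
evidence (≥ 2 distinct peptides, quantified in ≥ 2 of 3 replicates), tested
against the background distribution of unregulated proteins, and flagged as
significantly upregulated in the mutant when the mean −log2(H/L) is ≥ 0.3
with p ≤ 0.05.  Benjamini–Hochberg adjusted p-values are reported alongside
the raw-p significance call.  Two contrasts (e.g. two deletion mutants
against the same wild type) are then overlapped on their shared quantified
membrane proteins, and GO cellular-component frequencies tabulated for the
hit sets.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_peptides",
    "filter_quantified",
    "background_t_test",
    "adjust_bh",
    "call_significant",
    "diff_analysis",
    "overlap_contrasts",
    "go_component_frequency",
]

PEPTIDE_COLUMNS = ["protein_id", "replicate", "peptide_id", "log2_hl"]


def aggregate_peptides(records: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Reduce peptide H/L ratios to per-protein, per-replicate values.

    Returns a tidy frame with columns ``protein_id, replicate, log2_hl,
    n_peptides, n_distinct_peptides`` where ``log2_hl`` is the median (or
    mean) of the replicate's peptide log2 ratios and
    ``n_distinct_peptides`` counts distinct peptide ids per protein across
    all replicates.  Empty input yields an empty frame.
    """
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    if records.empty:
        return pd.DataFrame(
            columns=["protein_id", "replicate", "log2_hl", "n_peptides", "n_distinct_peptides"]
        )
    if not np.isfinite(records["log2_hl"]).all():
        raise ValueError("non-finite peptide log2 ratios")
    per_rep = (
        records.groupby(["protein_id", "replicate"], sort=True)["log2_hl"]
        .agg([method, "size"])
        .rename(columns={method: "log2_hl", "size": "n_peptides"})
        .reset_index()
    )
    distinct = records.groupby("protein_id")["peptide_id"].nunique().rename("n_distinct_peptides")
    return per_rep.merge(distinct, on="protein_id")


def filter_quantified(
    quants: pd.DataFrame, min_peptides: int = 2, min_replicates: int = 2
) -> pd.DataFrame:
    """Keep proteins with ≥ ``min_peptides`` distinct peptides quantified in
    at least ``min_replicates`` replicates."""
    if min_peptides < 1 or min_replicates < 1:
        raise ValueError("thresholds must be ≥ 1")
    if quants.empty:
        return quants
    g = quants[quants["n_peptides"] >= 1].groupby("protein_id")
    n_reps = g["replicate"].nunique()
    n_dist = g["n_distinct_peptides"].first()
    keep = n_reps.index[(n_reps >= min_replicates) & (n_dist >= min_peptides)]
    return quants[quants["protein_id"].isin(keep)].reset_index(drop=True)


def background_t_test(
    target: np.ndarray | Iterable[float],
    background: np.ndarray | Iterable[float],
    policy: str = "background",
) -> float:
    """Two-sided p for the target protein's mean log2 ratio differing from
    the unregulated background.

    ``background`` is the distribution of protein-level log2 ratios over the
    whole (mostly unregulated) proteome.  Policies:

    * ``background`` (default) — t of the target mean against the
      background mean with the background's own SD as scale,
      df = n_background − 1.  Calibrated: under a global null the
      background spread *is* the sampling spread of a protein mean.
    * ``target_only`` — one-sample t of the target replicate values
      against the background mean.
    * ``pooled`` — one-sample t with scale from
      max(target variance, background variance) and df = n_target − 1;
      deliberately conservative.
    """
    t_vals = np.asarray(list(target), dtype=float)
    bg = np.asarray(list(background), dtype=float)
    if t_vals.size < 2 and policy != "background":
        raise ValueError("target needs ≥ 2 values")
    if t_vals.size < 1:
        raise ValueError("target needs ≥ 1 value")
    if bg.size < 30:
        raise ValueError("background needs ≥ 30 values")
    bg_mean = bg.mean()
    bg_var = bg.var(ddof=1)
    if bg_var == 0:
        raise ValueError("degenerate background: zero variance")
    if policy == "background":
        t = (t_vals.mean() - bg_mean) / np.sqrt(bg_var)
        df = bg.size - 1
    elif policy == "target_only":
        s = t_vals.std(ddof=1)
        if s == 0:
            s = np.sqrt(bg_var)  # fall back to background scale
        t = (t_vals.mean() - bg_mean) / (s / np.sqrt(t_vals.size))
        df = t_vals.size - 1
    elif policy == "pooled":
        s2 = max(t_vals.var(ddof=1), bg_var)
        t = (t_vals.mean() - bg_mean) / np.sqrt(s2 / t_vals.size)
        df = t_vals.size - 1
    else:
        raise ValueError(f"unknown background policy {policy!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def adjust_bh(p_values: np.ndarray | Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    results: pd.DataFrame,
    membrane_proteins: Iterable[str] | None = None,
    ratio_min: float = 0.3,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Flag significance (inclusive thresholds) and join membrane annotation.

    ``results`` must carry ``protein_id, neg_log2, p``.  Significance is
    ``neg_log2 ≥ ratio_min and p ≤ p_max`` on the raw p-value; the adjusted
    p is emitted alongside.  Proteins absent from the membrane list are
    annotated ``is_membrane=False`` with a logged warning when no list is
    given at all.
    """
    out = results.copy()
    out["adj_p"] = adjust_bh(out["p"].to_numpy())
    out["significant"] = (out["neg_log2"] >= ratio_min) & (out["p"] <= p_max)
    if membrane_proteins is None:
        logger.warning("no membrane annotation supplied; is_membrane set to False throughout")
        out["is_membrane"] = False
    else:
        mem = set(membrane_proteins)
        out["is_membrane"] = out["protein_id"].isin(mem)
    return out


def diff_analysis(
    peptides: pd.DataFrame,
    membrane_proteins: Iterable[str] | None = None,
    min_peptides: int = 2,
    min_replicates: int = 2,
    ratio_min: float = 0.3,
    p_max: float = 0.05,
    background_policy: str = "background",
    aggregate_method: str = "median",
) -> pd.DataFrame:
    """Full chain: aggregate → filter → background t-test → BH → call.

    Returns the volcano table with one row per retained protein:
    ``protein_id, neg_log2, p, adj_p, significant, is_membrane``.
    """
    quants = filter_quantified(
        aggregate_peptides(peptides, method=aggregate_method), min_peptides, min_replicates
    )
    if quants.empty:
        return pd.DataFrame(
            columns=["protein_id", "neg_log2", "p", "adj_p", "significant", "is_membrane"]
        )
    # per-protein mean of −log2(H/L) over quantified replicates
    prot = quants.groupby("protein_id")["log2_hl"].apply(lambda v: -v.to_numpy().mean())
    background = (-quants.groupby("protein_id")["log2_hl"].mean()).to_numpy()
    rows = []
    for pid, grp in quants.groupby("protein_id"):
        p = background_t_test(-grp["log2_hl"].to_numpy(), background, policy=background_policy)
        rows.append((pid, float(prot[pid]), p))
    res = pd.DataFrame(rows, columns=["protein_id", "neg_log2", "p"])
    return call_significant(res, membrane_proteins, ratio_min=ratio_min, p_max=p_max)


def overlap_contrasts(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    display_floor: float = -1.0,
    membrane_only: bool = True,
) -> pd.DataFrame:
    """Classify shared quantified (membrane) proteins across two contrasts.

    Classes: ``both`` (significant in A and B), ``contrastA_only``,
    ``contrastB_only``, ``neither``.  The ``in_display`` column marks rows
    passing the scatter-plot floor (both neg_log2 values > ``display_floor``);
    it never affects classification.
    """
    a = res_a.set_index("protein_id")
    b = res_b.set_index("protein_id")
    shared = a.index.intersection(b.index)
    if membrane_only:
        shared = [
            p for p in shared if a.loc[p, "is_membrane"] and b.loc[p, "is_membrane"]
        ]
    if len(shared) == 0:
        raise ValueError("no shared quantified proteins between the contrasts")
    rows = []
    for pid in shared:
        sa, sb = bool(a.loc[pid, "significant"]), bool(b.loc[pid, "significant"])
        cls = {
            (True, True): "both",
            (True, False): "contrastA_only",
            (False, True): "contrastB_only",
            (False, False): "neither",
        }[(sa, sb)]
        na, nb = float(a.loc[pid, "neg_log2"]), float(b.loc[pid, "neg_log2"])
        rows.append((pid, cls, na, nb, na > display_floor and nb > display_floor))
    return pd.DataFrame(
        rows, columns=["protein_id", "class", "neg_log2_A", "neg_log2_B", "in_display"]
    )


def go_component_frequency(
    protein_set: Iterable[str],
    slim_map: Mapping[str, Iterable[str]],
    genome_map: Mapping[str, Iterable[str]] | None = None,
    fusion_rules: Mapping[str, object] | None = None,
    min_hits: int = 2,
) -> pd.DataFrame:
    """Per-term hit counts and frequencies over a protein set.

    ``slim_map`` maps protein → GO slim terms.  ``fusion_rules`` reassigns
    terms before counting: term → replacement term, or term →
    {protein → replacement} for per-protein routing (e.g. splitting
    'cytoplasmic vesicle' hits between plasma membrane and endosome by
    known localization).  Terms with fewer than ``min_hits`` hits are
    dropped.  With ``genome_map``, genome frequency and the
    dataset/genome enrichment ratio are added.
    """
    prots = list(dict.fromkeys(protein_set))
    fusion_rules = dict(fusion_rules or {})
    known_terms = {t for terms in slim_map.values() for t in terms}
    for term in fusion_rules:
        if term not in known_terms:
            warnings.warn(f"fusion rule for unknown term {term!r}", stacklevel=2)

    def fused_terms(pid: str, mapping: Mapping[str, Iterable[str]]) -> set[str]:
        out = set()
        for t in mapping.get(pid, ()):  # proteins without annotation contribute nothing
            rule = fusion_rules.get(t)
            if rule is None:
                out.add(t)
            elif isinstance(rule, str):
                out.add(rule)
            else:
                out.add(rule.get(pid, t))
        return out

    counts: dict[str, int] = {}
    for pid in prots:
        for t in fused_terms(pid, slim_map):
            counts[t] = counts.get(t, 0) + 1
    n = len(prots)
    rows = [
        (t, c, c / n) for t, c in sorted(counts.items()) if c >= min_hits
    ]
    df = pd.DataFrame(rows, columns=["term", "dataset_hits", "dataset_frequency"])
    if genome_map is not None:
        g_counts: dict[str, int] = {}
        g_n = len(genome_map)
        for pid in genome_map:
            for t in fused_terms(pid, genome_map):
                g_counts[t] = g_counts.get(t, 0) + 1
        df["genome_frequency"] = [
            g_counts.get(t, 0) / g_n if g_n else np.nan for t in df["term"]
        ]
        with np.errstate(divide="ignore", invalid="ignore"):
            df["enrichment"] = df["dataset_frequency"] / df["genome_frequency"]
    return df
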