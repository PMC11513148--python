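"""SILAC differential calling: reductions, background test calibration,
BH adjustment against brute-force oracles, overlap and GO tabulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qcprof import silac as sil
from qcprof import synthetic as syn


def _table(rows):
    return pd.DataFrame(rows, columns=sil.PEPTIDE_COLUMNS)


# --- aggregation ------------------------------------------------------------


def test_aggregate_zero_peptides_mean_zero_count_three():
    df = _table([("P1", 1, f"P1_pep{i}", 0.0) for i in range(3)])
    out = sil.aggregate_peptides(df)
    assert out.loc[0, "log2_hl"] == 0.0
    assert out.loc[0, "n_peptides"] == 3


def test_aggregate_median_of_symmetric_triple():
    df = _table([("P1", 1, "a", -1.0), ("P1", 1, "b", -1.2), ("P1", 1, "c", -0.8)])
    assert sil.aggregate_peptides(df).loc[0, "log2_hl"] == pytest.approx(-1.0)


def test_aggregate_matches_sort_and_pick_median_oracle(rng):
    vals = rng.normal(size=50)
    df = _table([("P1", 1, f"p{i}", v) for i, v in enumerate(vals)])
    expected = np.sort(vals)[len(vals) // 2] if len(vals) % 2 else np.sort(vals)[24:26].mean()
    assert sil.aggregate_peptides(df).loc[0, "log2_hl"] == pytest.approx(expected)


def test_aggregate_empty_input_gives_empty_output():
    assert sil.aggregate_peptides(_table([])).empty


# --- evidence filter --------------------------------------------------------


def test_filter_drops_single_replicate_protein():
    df = _table([("P1", 1, "a", 0.1), ("P1", 1, "b", 0.2)])
    assert sil.filter_quantified(sil.aggregate_peptides(df)).empty


def test_filter_keeps_boundary_protein_two_peptides_two_replicates():
    df = _table(
        [("P1", 1, "a", 0.1), ("P1", 1, "b", 0.2), ("P1", 2, "a", 0.0), ("P1", 2, "b", 0.1)]
    )
    out = sil.filter_quantified(sil.aggregate_peptides(df))
    assert set(out["protein_id"]) == {"P1"}


def test_filter_matches_brute_force_on_random_table(rng):
    spec = syn.SyntheticSilacSpec(n_proteins=60, missingness_rate=0.5, seed=33,
                                  peptides_per_protein_sampler=syn.uniform_int(0, 4))
    df = syn.generate_silac_table(spec)
    kept = set(sil.filter_quantified(sil.aggregate_peptides(df))["protein_id"])
    expected = set()
    for pid, grp in df.groupby("protein_id"):
        if grp["peptide_id"].nunique() >= 2 and grp["replicate"].nunique() >= 2:
            expected.add(pid)
    assert kept == expected


# --- background t-test ------------------------------------------------------


def test_target_at_background_mean_gives_p_one(rng):
    bg = rng.normal(0.0, 0.2, size=200)
    p = sil.background_t_test([bg.mean()] * 3, bg)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_strong_shift_is_highly_significant(rng):
    bg = rng.normal(0.0, 0.1, size=500)
    assert sil.background_t_test([-1.0, -1.0, -1.01], bg) < 0.001
    # the alternative policies use df = n_target − 1 and are deliberately
    # heavier-tailed; they still flag a 10-sigma shift decisively
    for policy in ("target_only", "pooled"):
        assert sil.background_t_test([-1.0, -1.0, -1.01], bg, policy=policy) < 0.01


def test_background_policy_matches_closed_form_t(rng):
    bg = rng.normal(0.0, 0.3, size=100)
    target = [0.5, 0.4, 0.6]
    t = (np.mean(target) - bg.mean()) / bg.std(ddof=1)
    expected = 2 * stats.t.sf(abs(t), 99)
    assert sil.background_t_test(target, bg) == pytest.approx(expected)


def test_degenerate_background_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        sil.background_t_test([0.1, 0.2], [0.5] * 50)


def test_global_null_type_i_error_calibrated():
    """Full filter→test chain: fraction of p ≤ 0.05 under the null = 0.05 ± 0.01."""
    spec = syn.SyntheticSilacSpec(n_proteins=2000, peptide_noise_sd=0.2,
                                  missingness_rate=0.1, seed=101)
    df = syn.generate_silac_table(spec)
    res = sil.diff_analysis(df)
    frac = (res["p"] <= 0.05).mean()
    assert 0.04 <= frac <= 0.06


# --- BH adjustment ----------------------------------------------------------


def _bh_oracle(p):
    """Textbook definition: adj_i = min over j with p_j >= p_i of min(1, m·p_j/rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


def test_bh_hand_example():
    assert np.allclose(sil.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_p_unchanged():
    assert sil.adjust_bh([0.2])[0] == pytest.approx(0.2)


def test_bh_matches_oracle_on_random_inputs(rng):
    for size in [2, 3, 5, 12, 100]:
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=size)
            assert np.allclose(sil.adjust_bh(p), _bh_oracle(p))


def test_bh_properties(rng):
    p = rng.uniform(1e-6, 1, size=50)
    adj = sil.adjust_bh(p)
    assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        sil.adjust_bh([0.1, np.nan])


# --- significance calling ---------------------------------------------------


def _results(rows):
    return pd.DataFrame(rows, columns=["protein_id", "neg_log2", "p"])


def test_boundary_below_ratio_threshold_not_significant():
    out = sil.call_significant(_results([("P1", 0.29, 0.01)]), ["P1"])
    assert not out.loc[0, "significant"]


def test_inclusive_boundaries_are_significant():
    out = sil.call_significant(_results([("P1", 0.3, 0.05)]), ["P1"])
    assert bool(out.loc[0, "significant"])
    assert bool(out.loc[0, "is_membrane"])


def test_significance_monotone_in_effect(rng):
    """Raising neg_log2 at fixed p never un-flags a protein."""
    p = 0.01
    flags = [
        sil.call_significant(_results([("P1", e, p)]), ["P1"]).loc[0, "significant"]
        for e in np.linspace(0.0, 2.0, 41)
    ]
    assert flags == sorted(flags)


def test_planted_effects_recovered_exactly_at_low_noise():
    planted = {f"P{i + 1:04d}": 1.0 for i in range(15)}
    spec = syn.SyntheticSilacSpec(n_proteins=300, effect_map=planted,
                                  peptide_noise_sd=0.1, seed=21)
    res = sil.diff_analysis(syn.generate_silac_table(spec),
                            membrane_proteins=list(planted))
    assert set(res[res["significant"]]["protein_id"]) == set(planted)


# --- overlap ----------------------------------------------------------------


def _mk_res(sig_ids, all_ids, neg=1.0):
    rows = [(p, neg if p in sig_ids else 0.0, 0.001 if p in sig_ids else 0.9)
            for p in all_ids]
    df = _results(rows)
    return sil.call_significant(df, all_ids)


def test_overlap_classes_and_partition():
    ids = [f"P{i}" for i in range(10)]
    ra = _mk_res({"P0", "P1", "P2"}, ids)
    rb = _mk_res({"P2", "P3"}, ids)
    out = sil.overlap_contrasts(ra, rb)
    by = out.set_index("protein_id")["class"]
    assert by["P0"] == "contrastA_only"
    assert by["P2"] == "both"
    assert by["P3"] == "contrastB_only"
    assert by["P9"] == "neither"
    counts = out["class"].value_counts()
    assert counts.sum() == len(out) == 10


def test_overlap_display_floor_only_affects_display_column():
    ids = ["P0", "P1"]
    ra = sil.call_significant(_results([("P0", 1.0, 0.001), ("P1", -2.0, 0.9)]), ids)
    rb = sil.call_significant(_results([("P0", 1.0, 0.001), ("P1", -2.0, 0.9)]), ids)
    out = sil.overlap_contrasts(ra, rb, display_floor=-1.0)
    assert len(out) == 2  # classification keeps the filtered protein
    assert not out.set_index("protein_id").loc["P1", "in_display"]


def test_overlap_empty_intersection_rejected():
    ra = _mk_res(set(), ["P1"])
    rb = _mk_res(set(), ["P2"])
    with pytest.raises(ValueError):
        sil.overlap_contrasts(ra, rb)


# --- GO tabulation ----------------------------------------------------------


def test_go_two_hits_full_frequency():
    out = sil.go_component_frequency(["P1", "P2"], {"P1": ["ER"], "P2": ["ER"]})
    assert out.loc[0, "term"] == "ER"
    assert out.loc[0, "dataset_hits"] == 2
    assert out.loc[0, "dataset_frequency"] == pytest.approx(1.0)


def test_go_single_hit_terms_removed():
    out = sil.go_component_frequency(
        ["P1", "P2"], {"P1": ["ER", "vacuole"], "P2": ["ER"]}
    )
    assert set(out["term"]) == {"ER"}


def test_go_fusion_and_enrichment_match_brute_force(rng):
    terms = ["ER", "PM", "endosome", "vesicle"]
    prots = [f"P{i}" for i in range(30)]
    slim = {p: list(rng.choice(terms, size=rng.integers(1, 3), replace=False)) for p in prots}
    genome = {f"G{i}": list(rng.choice(terms, size=1)) for i in range(100)}
    fusion = {"vesicle": "PM"}
    subset = prots[:12]
    out = sil.go_component_frequency(subset, slim, genome_map=genome, fusion_rules=fusion)
    # brute force
    tally = {}
    for p in subset:
        for t in {("PM" if t == "vesicle" else t) for t in slim[p]}:
            tally[t] = tally.get(t, 0) + 1
    for _, row in out.iterrows():
        assert tally[row["term"]] == row["dataset_hits"]
        assert row["dataset_hits"] >= 2
        g_tally = sum(
            1 for g in genome if row["term"] in {("PM" if t == "vesicle" else t) for t in genome[g]}
        )
        assert row["genome_frequency"] == pytest.approx(g_tally / 100)
        if row["genome_frequency"] > 0:
            assert row["enrichment"] == pytest.approx(
                row["dataset_frequency"] / row["genome_frequency"]
            )
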