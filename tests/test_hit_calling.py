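import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pisa_screen.hit_calling import (
    _trimmed_row_stats,
    call_hits,
    compute_log2fc,
    compute_nsd,
    dmso_false_hit_rate,
    per_compound_hit_counts,
    protein_variability,
)
from pisa_screen.quant_io import AbundanceMatrix, normalize_channel_sums
from pisa_screen.simulate import NoiseModel, simulate_null_screen

from conftest import make_matrix, trimmed_stats_brute


def long_table(rows):
    """Hand-build a replicate-level log2fc table."""
    return pd.DataFrame(
        rows,
        columns=["protein_id", "plex_id", "channel_id", "treatment_id",
                 "replicate_index", "is_vehicle", "log2fc"],
    )


class TestComputeLog2FC:
    def test_fold_changes_against_vehicle_mean(self, tiny_matrix):
        fc = compute_log2fc(tiny_matrix)
        drug = fc[fc["treatment_id"] == "drugA"].set_index(["protein_id", "replicate_index"])
        # P1 doubled -> +1; P2 at vehicle mean -> 0; P3 halved -> -1
        assert drug.loc[("P1", 1), "log2fc"] == pytest.approx(1.0)
        assert drug.loc[("P2", 1), "log2fc"] == pytest.approx(0.0)
        assert drug.loc[("P3", 2), "log2fc"] == pytest.approx(-1.0)

    def test_vehicle_channels_become_per_plex_pseudo_treatment(self, tiny_matrix):
        fc = compute_log2fc(tiny_matrix)
        veh = fc[fc["is_vehicle"]]
        assert set(veh["treatment_id"]) == {"DMSO::plex1"}
        assert np.allclose(veh["log2fc"], 0.0)  # both vehicles equal their mean

    def test_missing_protein_yields_missing_fold_change(self, tiny_matrix):
        tiny_matrix.values.loc["P1", "c1"] = np.nan
        fc = compute_log2fc(tiny_matrix)
        cell = fc[(fc["protein_id"] == "P1") & (fc["channel_id"] == "c1")]
        assert cell["log2fc"].isna().all()


class TestTrimmedStats:
    def test_constant_vector_has_zero_sd(self):
        _, sd, _ = _trimmed_row_stats(np.full((1, 6), 0.3), 0.1)
        assert sd[0] == 0.0

    def test_outlier_removed_by_trimming(self):
        vals = np.array([[0.0, 0.0, 0.0, 0.0, 10.0]])
        _, sd, _ = _trimmed_row_stats(vals, 0.2)
        assert sd[0] < np.std(vals)

    def test_matches_sort_and_slice_oracle(self):
        vals = [-0.3, -0.1, 0.0, 0.1, 0.3, 2.0]
        mean, sd, n = _trimmed_row_stats(np.array([vals]), 1 / 6)
        want_mean, want_sd = trimmed_stats_brute(vals, 1 / 6)  # keeps {-0.1,0,0.1,0.3}
        assert mean[0] == pytest.approx(want_mean)
        assert sd[0] == pytest.approx(want_sd)
        assert n[0] == 6

    def test_trim_removing_everything_rejected(self):
        with pytest.raises(ValueError, match="trim"):
            _trimmed_row_stats(np.ones((1, 4)), 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=20),
           st.floats(0.0, 0.45))
    def test_trimmed_sd_never_exceeds_untrimmed(self, values, trim):
        arr = np.array([values], dtype=float)
        _, sd, _ = _trimmed_row_stats(arr, trim)
        assert sd[0] <= np.std(arr) + 1e-12


class TestNSD:
    def test_treatment_at_grand_mean_scores_zero(self):
        rows = []
        for i, t in enumerate(["t1", "t2", "t3", "t4"]):
            for r in (1, 2):
                rows.append(("P1", "plex1", f"{t}r{r}", t, r, False, float(i) - 1.5))
        tbl = long_table(rows)
        stats = protein_variability(tbl, trim_fraction=0.0)
        nsd = compute_nsd(tbl, stats).set_index("treatment_id")["nsd"]
        # grand mean is the midpoint between t2 (-0.5) and t3 (+0.5)
        assert nsd["t2"] == pytest.approx(-nsd["t3"])
        assert (nsd["t2"] + nsd["t3"]) == pytest.approx(0.0)

    def test_nsd_arithmetic_with_injected_stats(self):
        tbl = long_table([("P1", "plex1", "c1", "t1", 1, False, -0.35),
                          ("P1", "plex1", "c2", "t1", 2, False, -0.35)])
        stats = pd.DataFrame(
            {"mean_log2fc_all_treatments": [0.0], "trimmed_sd": [0.1],
             "n_treatments": [10], "usable": [True]}, index=pd.Index(["P1"]))
        nsd = compute_nsd(tbl, stats)
        assert nsd["nsd"].iloc[0] == pytest.approx(-3.5)

    def test_zero_sd_yields_missing_nsd(self):
        tbl = long_table([("P1", "plex1", f"c{i}", f"t{i}", 1, False, 0.2)
                          for i in range(5)])
        stats = protein_variability(tbl, trim_fraction=0.1)
        nsd = compute_nsd(tbl, stats)
        assert nsd["nsd"].isna().all()

    def test_matches_groupby_zscore_oracle(self):
        rng = np.random.default_rng(4)
        rows = []
        for p in ("P1", "P2", "P3"):
            for t in [f"t{i}" for i in range(8)]:
                for r in (1, 2):
                    rows.append((p, "plex1", f"{p}{t}{r}", t, r, False,
                                 float(rng.normal())))
        tbl = long_table(rows)
        stats = protein_variability(tbl, trim_fraction=0.1)
        got = compute_nsd(tbl, stats).set_index(["protein_id", "treatment_id"])["nsd"]
        # independent oracle: pandas-free loop over groups
        tmeans = {}
        for (p, t), grp in tbl.groupby(["protein_id", "treatment_id"]):
            tmeans.setdefault(p, {})[t] = grp["log2fc"].mean()
        for p, per_t in tmeans.items():
            mean, sd = trimmed_stats_brute(list(per_t.values()), 0.1)
            for t, v in per_t.items():
                assert got[(p, t)] == pytest.approx((v - mean) / sd)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        base = [float(rng.normal()) for _ in range(12)]
        rows1, rows2 = [], []
        for i, v in enumerate(base):
            rows1.append(("P1", "plex1", f"c{i}", f"t{i // 2}", i % 2 + 1, False, v))
            rows2.append(("P1", "plex1", f"c{i}", f"t{i // 2}", i % 2 + 1, False, 3.7 * v))
        nsd1 = call_hits(long_table(rows1))["nsd"]
        nsd2 = call_hits(long_table(rows2))["nsd"]
        assert np.allclose(nsd1, nsd2, atol=1e-9)


class TestCallHits:
    def _one_treatment(self, rep1, rep2, trimmed_sd, center=0.0):
        tbl = long_table([("P1", "plex1", "c1", "cmpd", 1, False, rep1),
                          ("P1", "plex1", "c2", "cmpd", 2, False, rep2)])
        stats = pd.DataFrame(
            {"mean_log2fc_all_treatments": [center], "trimmed_sd": [trimmed_sd],
             "n_treatments": [20], "usable": [True]}, index=pd.Index(["P1"]))
        return call_hits(tbl, stats=stats).iloc[0]

    def test_strong_destabilization_is_a_hit(self):
        # mean log2FC -0.840 at trimmed SD 0.1477 -> nSD -5.688
        row = self._one_treatment(-0.80, -0.88, trimmed_sd=0.840 / 5.688)
        assert row["mean_log2fc"] == pytest.approx(-0.840)
        assert row["nsd"] == pytest.approx(-5.688, abs=1e-3)
        assert row["is_hit"] and row["direction"] == "destabilized"

    def test_strong_stabilization_is_a_hit(self):
        # mean log2FC 1.726 at trimmed SD 0.06434 -> nSD 26.825
        row = self._one_treatment(1.70, 1.752, trimmed_sd=1.726 / 26.825)
        assert row["nsd"] == pytest.approx(26.825, abs=1e-2)
        assert row["is_hit"] and row["direction"] == "stabilized"

    def test_fails_nsd_cutoff(self):
        row = self._one_treatment(0.5, 0.5, trimmed_sd=0.25)  # nSD = 2.0
        assert not row["is_hit"] and row["direction"] == "none"

    def test_fails_fold_change_cutoff(self):
        row = self._one_treatment(0.15, 0.15, trimmed_sd=0.15 / 8.0)  # nSD = 8.0
        assert not row["is_hit"]

    def test_both_replicates_must_pass(self):
        row = self._one_treatment(0.9, 0.15, trimmed_sd=0.05)
        assert not row["is_hit"]

    def test_missing_replicate_is_ineligible(self):
        tbl = long_table([("P1", "plex1", "c1", "cmpd", 1, False, 1.5),
                          ("P1", "plex1", "c2", "cmpd", 2, False, np.nan)])
        stats = pd.DataFrame(
            {"mean_log2fc_all_treatments": [0.0], "trimmed_sd": [0.05],
             "n_treatments": [20], "usable": [True]}, index=pd.Index(["P1"]))
        assert not call_hits(tbl, stats=stats)["is_hit"].iloc[0]

    def test_raising_cutoffs_never_adds_hits(self):
        rng = np.random.default_rng(8)
        rows = []
        for p in [f"P{i}" for i in range(20)]:
            for t in [f"t{i}" for i in range(6)]:
                for r in (1, 2):
                    rows.append((p, "plex1", f"{p}{t}{r}", t, r, False,
                                 float(rng.normal(0, 0.3))))
        tbl = long_table(rows)
        counts = []
        for fc_cut, nsd_cut in [(0.1, 1.0), (0.2, 1.0), (0.2, 2.0), (0.3, 3.0)]:
            counts.append(call_hits(tbl, fc_cutoff=fc_cut, nsd_cutoff=nsd_cut)["is_hit"].sum())
        assert counts == sorted(counts, reverse=True)


class TestFalseHitRate:
    def test_noise_free_null_screen_has_zero_rate(self):
        matrix, _ = simulate_null_screen(n_compounds=6, n_proteins=100, seed=0,
                                         noise=NoiseModel(0.0, 0.0, 0))
        fhr = dmso_false_hit_rate(matrix)
        assert fhr.rate == 0.0
        assert fhr.n_measurements > 0

    def test_null_hit_rate_decreases_with_nsd_cutoff(self):
        matrix, _ = simulate_null_screen(n_compounds=12, n_proteins=800, seed=2)
        norm = normalize_channel_sums(matrix)
        rates = [dmso_false_hit_rate(norm, fc_cutoff=0.0, nsd_cutoff=c).rate
                 for c in (2.0, 3.0, 4.0, 5.0)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))
        assert rates[0] > rates[-1]

    def test_injected_vehicle_shift_dominates_pseudo_hits(self):
        # multi-plex screen; contaminate one plex's vehicle reference so the
        # held-out pseudo pair of that plex reports the injected proteins
        matrix, _ = simulate_null_screen(n_compounds=48, n_proteins=500, seed=5)
        ann = matrix.annotations
        veh = [c for c in ann.index
               if ann.loc[c, "plex_id"] == "plex1" and ann.loc[c, "is_vehicle"]]
        injected = set(matrix.values.index[:50])
        vals = matrix.values.copy()
        vals.loc[list(injected), veh[2]] *= 2.0  # +1 log2 in a reference channel
        shifted = normalize_channel_sums(AbundanceMatrix(vals, ann.copy()))
        fhr = dmso_false_hit_rate(shifted)
        assert fhr.n_hits > 0
        # recover which proteins the contaminated plex's pseudo pair flags
        new_ann = ann.copy()
        new_ann.loc[[veh[0], veh[1]], "treatment_id"] = "pseudo"
        new_ann.loc[[veh[0], veh[1]], "is_vehicle"] = False
        new_ann.loc[veh[0], "replicate_index"] = 1
        new_ann.loc[veh[1], "replicate_index"] = 2
        relabeled = normalize_channel_sums(AbundanceMatrix(vals, new_ann))
        hits = call_hits(compute_log2fc(relabeled))
        flagged = set(hits[(hits["treatment_id"] == "pseudo") & hits["is_hit"]]["protein_id"])
        assert injected <= flagged
        assert len(flagged & injected) / len(flagged) >= 0.8

    def test_requires_four_vehicle_channels(self):
        matrix, _ = simulate_null_screen(n_compounds=7, n_proteins=50, mode="lysate",
                                         seed=0)
        with pytest.raises(ValueError, match="vehicle"):
            dmso_false_hit_rate(matrix)


class TestPerCompoundCounts:
    def test_empty_table_gives_zeros(self):
        empty = pd.DataFrame(columns=["protein_id", "treatment_id", "mean_log2fc",
                                      "nsd", "is_hit", "direction", "is_vehicle"])
        counts, median = per_compound_hit_counts(empty)
        assert counts.empty and median == 0.0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in [f"P{i}" for i in range(30)]:
            for t in ("t1", "t2", "t3"):
                hit = bool(rng.random() < 0.2)
                mfc = float(rng.normal())
                rows.append({"protein_id": p, "treatment_id": t, "mean_log2fc": mfc,
                             "is_hit": hit, "is_vehicle": False,
                             "direction": ("stabilized" if mfc > 0 else "destabilized")
                             if hit else "none"})
        tbl = pd.DataFrame(rows)
        counts, median = per_compound_hit_counts(tbl)
        for t in ("t1", "t2", "t3"):
            sub = [r for r in rows if r["treatment_id"] == t and r["is_hit"]]
            row = counts[counts["treatment_id"] == t].iloc[0]
            assert row["n_total"] == len(sub)
            assert row["n_stabilized"] == sum(r["direction"] == "stabilized" for r in sub)
            assert row["n_destabilized"] == sum(r["direction"] == "destabilized" for r in sub)
        assert median == float(np.median(counts["n_total"]))
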