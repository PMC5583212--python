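import numpy as np
import pandas as pd
import pytest

from lncfibro.biomarker_qpcr import (
    concordance_summary,
    concordant_biomarkers,
    delta_delta_ct,
    spike_in_normalize,
)
from lncfibro.models import DERecord


def de(tid, direction, significant=True):
    lfc = {"up": 2.0, "down": -2.0, "none": 0.0}[direction]
    return DERecord(tid, 1.0, 1.0, lfc, 0.01 if significant else 0.5, direction, significant)


class TestConcordance:
    def test_same_direction_is_concordant(self):
        (rec,) = concordant_biomarkers([de("a", "up")], [de("a", "up")])
        assert rec.concordant

    def test_opposite_direction_reported_but_not_concordant(self):
        (rec,) = concordant_biomarkers([de("a", "up")], [de("a", "down")])
        assert not rec.concordant

    def test_set_intersection_example(self):
        tissue = [de("a", "up"), de("b", "down"), de("c", "up")]
        urine = [de("a", "up"), de("b", "up"), de("d", "down")]
        records = concordant_biomarkers(tissue, urine)
        assert {r.transcript_id for r in records} == {"a", "b"}
        biomarkers = {r.transcript_id for r in records if r.concordant}
        assert biomarkers == {"a"}
        summary = concordance_summary(records)
        assert (summary["n_concordant_up"], summary["n_concordant_down"]) == (1, 0)

    def test_only_jointly_significant_transcripts_appear(self):
        tissue = [de("a", "up"), de("b", "none", significant=False)]
        urine = [de("a", "up"), de("b", "up")]
        assert {r.transcript_id for r in concordant_biomarkers(tissue, urine)} == {"a"}

    def test_disjoint_sets_empty(self):
        assert concordant_biomarkers([de("a", "up")], [de("b", "up")]) == []

    def test_matches_brute_force_set_logic(self):
        rng = np.random.default_rng(9)
        ids = [f"t{i}" for i in range(30)]
        for _ in range(50):
            def sample():
                return [
                    de(t, rng.choice(["up", "down"]), significant=bool(rng.integers(0, 2)))
                    for t in ids
                ]
            tissue, urine = sample(), sample()
            records = concordant_biomarkers(tissue, urine)
            t_sig = {r.transcript_id: r.direction for r in tissue if r.significant}
            u_sig = {r.transcript_id: r.direction for r in urine if r.significant}
            expected = {
                (t, t_sig[t], u_sig[t], t_sig[t] == u_sig[t])
                for t in set(t_sig) & set(u_sig)
            }
            got = {
                (r.transcript_id, r.tissue_direction, r.urine_direction, r.concordant)
                for r in records
            }
            assert got == expected


def qpcr_table(delta_shift=0.0, ref="REF"):
    """Target with treated dCt = 4, calibrator dCt = 6 (fold 4); reference flat."""
    rows = []
    for group, dct in (("UUO", 4.0), ("Sham", 6.0)):
        for i in (1, 2, 3):
            sample = f"{group}_{i}"
            rows.append({"sample_id": sample, "group": group, "gene": ref, "ct": 20.0 + delta_shift})
            rows.append({"sample_id": sample, "group": group, "gene": "tgt", "ct": 20.0 + delta_shift + dct})
    return pd.DataFrame(rows)


class TestDeltaDeltaCt:
    def test_hand_arithmetic_fold_four(self):
        records, summary = delta_delta_ct(qpcr_table(), reference_gene="REF")
        uuo = [r for r in records if r.group == "UUO"]
        assert all(r.delta_delta_ct == -2.0 and r.fold == 4.0 for r in uuo)
        row = summary[(summary["target"] == "tgt") & (summary["group"] == "UUO")].iloc[0]
        assert row["mean_fold"] == pytest.approx(4.0)

    def test_calibrator_geometric_mean_fold_is_one(self):
        rng = np.random.default_rng(2)
        table = qpcr_table()
        table.loc[table["gene"] == "tgt", "ct"] += rng.normal(0, 0.3, size=6)
        records, summary = delta_delta_ct(table, reference_gene="REF")
        cal = np.array([r.fold for r in records if r.group == "Sham"])
        assert 2.0 ** np.mean(np.log2(cal)) == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_delta_ct_gives_fold_one_p_one(self):
        table = qpcr_table()
        table.loc[table["gene"] == "tgt", "ct"] = 26.0
        records, summary = delta_delta_ct(table, reference_gene="REF")
        assert all(r.fold == 1.0 for r in records)
        assert summary["p_value"].iloc[0] == 1.0

    def test_reciprocal_group_fold_identity(self):
        records, _ = delta_delta_ct(qpcr_table(), reference_gene="REF")
        ddct = {g: np.mean([r.delta_delta_ct for r in records if r.group == g])
                for g in ("UUO", "Sham")}
        fold_fwd = 2.0 ** -(ddct["UUO"] - ddct["Sham"])
        fold_rev = 2.0 ** -(ddct["Sham"] - ddct["UUO"])
        assert fold_fwd * fold_rev == pytest.approx(1.0)

    def test_missing_reference_errors(self):
        table = qpcr_table()
        table = table[~((table["gene"] == "REF") & (table["sample_id"] == "UUO_2"))]
        with pytest.raises(ValueError, match="UUO_2"):
            delta_delta_ct(table, reference_gene="REF")

    def test_negative_ct_errors(self):
        table = qpcr_table()
        table.loc[0, "ct"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            delta_delta_ct(table, reference_gene="REF")

    def test_small_calibrator_group_errors(self):
        table = qpcr_table()
        table = table[table["sample_id"] != "Sham_1"]
        table = table[table["sample_id"] != "Sham_2"]
        with pytest.raises(ValueError, match="calibrator"):
            delta_delta_ct(table, reference_gene="REF")


class TestSpikeIn:
    def test_constant_spike_matches_reference_normalization(self):
        table = qpcr_table(ref="cel-miR-39")
        records, summary = spike_in_normalize(table)
        assert all(r.fold == 4.0 for r in records if r.group == "UUO")
        assert summary["spike_normalized"].all()

    def test_global_spike_shift_cancels(self):
        base = spike_in_normalize(qpcr_table(ref="cel-miR-39"))[0]
        shifted_table = qpcr_table(ref="cel-miR-39")
        shifted_table.loc[shifted_table["gene"] == "cel-miR-39", "ct"] += 1.0
        shifted = spike_in_normalize(shifted_table)[0]
        for a, b in zip(base, shifted):
            assert b.delta_ct == pytest.approx(a.delta_ct - 1.0)
            assert b.fold == pytest.approx(a.fold)

    def test_missing_spike_lists_samples(self):
        table = qpcr_table(ref="cel-miR-39")
        table = table[~((table["gene"] == "cel-miR-39") & (table["sample_id"].isin(["UUO_1", "Sham_3"])))]
        with pytest.raises(ValueError, match=r"Sham_3.*|UUO_1.*"):
            spike_in_normalize(table)


class TestGeneratorInversion:
    def test_noiseless_simulation_recovers_fold_exactly(self, small_dataset):
        from lncfibro.synthetic_data import simulate_qpcr

        config, _, truth = small_dataset
        import dataclasses

        noiseless = dataclasses.replace(config, qpcr_noise_sd=0.0)
        table = simulate_qpcr(truth, noiseless, "tissue")
        _, summary = delta_delta_ct(table, reference_gene="GAPDH")
        for target, fold in truth.qpcr_true_folds["tissue"].items():
            row = summary[(summary["target"] == target) & (summary["group"] == "UUO")].iloc[0]
            assert row["mean_fold"] == pytest.approx(fold, abs=1e-12)

    def test_fold_one_recovered_as_identity(self, small_dataset):
        from lncfibro.synthetic_data import simulate_qpcr
        import dataclasses

        config, _, truth = small_dataset
        noiseless = dataclasses.replace(config, qpcr_noise_sd=0.0)
        flat_truth = dataclasses.replace(truth, qpcr_true_folds={"tissue": {"FLAT": 1.0}})
        table = simulate_qpcr(flat_truth, noiseless, "tissue")
        _, summary = delta_delta_ct(table, reference_gene="GAPDH")
        row = summary[(summary["target"] == "FLAT") & (summary["group"] == "UUO")].iloc[0]
        assert row["mean_fold"] == pytest.approx(1.0, abs=1e-12)
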