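import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncfibro.expression_de import (
    call_de,
    compute_rpkm,
    log2_fold_change,
    per_transcript_test,
)
from lncfibro.models import ExpressionMatrix


def make_matrix(counts: dict, conditions: list[str], compartment: str = "tissue"):
    samples = list(next(iter(counts.values())).keys()) if counts else []
    frame = pd.DataFrame(counts).T
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "compartment": compartment,
            "replicate": list(range(1, len(conditions) + 1)),
        },
        index=pd.Index(frame.columns, name="sample"),
    )
    return ExpressionMatrix(counts=frame, samples=meta)


class TestRpkm:
    def test_direct_formula(self):
        m = make_matrix(
            {"t1": {"s1": 10}, "fill": {"s1": 10**6 - 10}}, conditions=["UUO"]
        )
        rpkm = compute_rpkm(m, {"t1": 1000, "fill": 1000})
        assert rpkm.loc["t1", "s1"] == pytest.approx(10.0)

    def test_zero_count_zero_rpkm(self):
        m = make_matrix({"t1": {"s1": 0}, "t2": {"s1": 50}}, conditions=["UUO"])
        rpkm = compute_rpkm(m, {"t1": 500, "t2": 500})
        assert rpkm.loc["t1", "s1"] == 0.0

    def test_scale_invariance_when_all_counts_double(self):
        counts = {"t1": {"s1": 10}, "t2": {"s1": 30}}
        doubled = {"t1": {"s1": 20}, "t2": {"s1": 60}}
        lengths = {"t1": 100, "t2": 700}
        a = compute_rpkm(make_matrix(counts, ["UUO"]), lengths)
        b = compute_rpkm(make_matrix(doubled, ["UUO"]), lengths)
        assert np.allclose(a.values, b.values)

    def test_conservation_identity(self):
        rng = np.random.default_rng(0)
        counts = {
            f"t{i}": {f"s{j}": int(rng.integers(0, 500)) + 1 for j in range(4)}
            for i in range(50)
        }
        lengths = {f"t{i}": int(rng.integers(200, 5000)) for i in range(50)}
        m = make_matrix(counts, ["UUO", "UUO", "Sham", "Sham"])
        rpkm = compute_rpkm(m, lengths)
        L = np.array([lengths[t] for t in rpkm.index])
        totals = (rpkm.values * L[:, None]).sum(axis=0)
        assert np.allclose(totals, 1e9, rtol=1e-9)

    def test_missing_length_names_transcript(self):
        m = make_matrix({"t1": {"s1": 5}}, ["UUO"])
        with pytest.raises(ValueError, match="t1"):
            compute_rpkm(m, {})


class TestLog2FoldChange:
    def test_hand_arithmetic(self):
        assert log2_fold_change(8, 2, pseudocount=0) == pytest.approx(2.0)

    def test_equal_means_zero(self):
        assert log2_fold_change(5, 5) == 0.0

    def test_antisymmetry(self):
        assert log2_fold_change(9, 2) == pytest.approx(-log2_fold_change(2, 9))

    def test_negative_pseudocount_errors(self):
        with pytest.raises(ValueError):
            log2_fold_change(1, 1, pseudocount=-0.1)


class TestWelch:
    def test_identical_constant_groups_give_p_one(self):
        assert per_transcript_test([4, 4, 4], [4, 4, 4]) == 1.0

    def test_separated_groups_significant_and_match_scipy(self):
        case, control = [100, 110, 95], [10, 12, 9]
        p = per_transcript_test(case, control)
        assert p < 0.01
        expected = stats.ttest_ind(
            np.log2(np.array(case) + 0.25),
            np.log2(np.array(control) + 0.25),
            equal_var=False,
        ).pvalue
        assert p == pytest.approx(expected)

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="2 values"):
            per_transcript_test([1], [2, 3])


def boundary_matrix(case_count: int):
    """Two conditions, zero within-group variance, filler fixing N = 1e6.

    With L = 1000 everywhere, RPKM equals the raw count, so the target's
    fold change is exactly case_count / 100 at pseudocount 0.
    """
    counts = {
        "target": {"u1": case_count, "u2": case_count, "u3": case_count,
                   "s1": 100, "s2": 100, "s3": 100},
        "fill": {f"{c}{i}": 10**6 - n
                 for c, n in (("u", case_count), ("s", 100)) for i in (1, 2, 3)},
    }
    return make_matrix(counts, ["UUO"] * 3 + ["Sham"] * 3)


class TestCallDe:
    def test_lfc_cutoff_is_inclusive(self):
        records = {r.transcript_id: r for r in call_de(
            boundary_matrix(200), {"target": 1000, "fill": 1000}, pseudocount=0.0)}
        target = records["target"]
        assert target.log2fc == pytest.approx(1.0)
        assert target.significant and target.direction == "up"

    def test_just_below_cutoff_not_significant(self):
        records = {r.transcript_id: r for r in call_de(
            boundary_matrix(199), {"target": 1000, "fill": 1000}, pseudocount=0.0)}
        target = records["target"]
        assert target.log2fc < 1.0 and target.p_value < 0.05
        assert not target.significant and target.direction == "none"

    def test_swapping_condition_labels_swaps_directions(self):
        m = boundary_matrix(500)
        swapped = ExpressionMatrix(
            counts=m.counts,
            samples=m.samples.assign(
                condition=m.samples["condition"].map({"UUO": "Sham", "Sham": "UUO"})
            ),
        )
        lengths = {"target": 1000, "fill": 1000}
        a = {r.transcript_id: r.direction for r in call_de(m, lengths)}
        b = {r.transcript_id: r.direction for r in call_de(swapped, lengths)}
        assert a["target"] == "up" and b["target"] == "down"

    def test_compartment_mixing_errors(self):
        m = boundary_matrix(500)
        mixed = ExpressionMatrix(
            counts=m.counts,
            samples=m.samples.assign(
                compartment=["tissue", "urine", "tissue", "tissue", "urine", "tissue"]
            ),
        )
        with pytest.raises(ValueError, match="compartment"):
            call_de(mixed, {"target": 1000, "fill": 1000})

    def test_no_significant_record_lacks_direction(self, small_dataset):
        from lncfibro.io_formats import read_counts, read_gtf

        _, paths, _ = small_dataset
        genes = read_gtf(paths["annotation"])
        lengths = {t.transcript_id: t.exonic_length for g in genes for t in g.transcripts}
        matrix = read_counts(paths["tissue_counts"], paths["tissue_samples"])
        records = call_de(matrix, lengths)
        for r in records:
            assert r.significant == (r.direction != "none")
            if r.significant:
                assert (r.direction == "up") == (r.log2fc > 0)
                assert abs(r.log2fc) >= 1.0 and r.p_value < 0.05

    def test_planted_effect_recovered_without_flips(self, small_dataset):
        from lncfibro.io_formats import read_counts, read_gtf
        from lncfibro.synthetic_data import transcript_of

        _, paths, truth = small_dataset
        genes = read_gtf(paths["annotation"])
        lengths = {t.transcript_id: t.exonic_length for g in genes for t in g.transcripts}
        matrix = read_counts(paths["tissue_counts"], paths["tissue_samples"])
        records = {r.transcript_id: r for r in call_de(matrix, lengths)}
        for gid, lfc in {**truth.de_lnc_up, **truth.de_lnc_down}.items():
            r = records[transcript_of(gid)]
            want = "up" if lfc > 0 else "down"
            assert r.direction in (want, "none")  # never the opposite direction


class TestEffectRecovery:
    def test_mean_estimated_lfc_near_truth(self):
        """500 planted genes at log2FC 2 among a large null background: the
        mean estimated fold change lands within +/-0.25 of the truth."""
        from lncfibro.synthetic_data import (
            GroundTruth,
            SyntheticConfig,
            simulate_counts,
            stub_genes,
        )

        n_de, n_total = 500, 22_000
        genes = stub_genes(n_total)
        de_ids = [g.gene_id for g in genes[:n_de]]
        truth = GroundTruth(
            de_lnc_up={gid: 2.0 for gid in de_ids},
            de_lnc_down={}, de_mrna={},
            urine_de_lnc_up={}, urine_de_lnc_down={}, urine_de_mrna={},
            motif_counts={}, cis_pairs=set(),
        )
        config = SyntheticConfig(seed=11)
        matrix = simulate_counts(genes, truth, config, "tissue")
        lengths = {t.transcript_id: 1200 for g in genes for t in g.transcripts}
        records = call_de(matrix, lengths)
        de_set = set(de_ids)
        lfcs = [r.log2fc for r in records if r.transcript_id[:-2] in de_set]
        assert len(lfcs) == n_de
        assert abs(float(np.mean(lfcs)) - 2.0) <= 0.25
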