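"""Translational efficiency: counting, normalisation, the Welch test, BH, and
codon-filtered re-analysis."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from ribopause.model import OffsetTable, Transcriptome
from ribopause.te import (
    GeneFilterConfig,
    TECountTable,
    apply_gene_filters,
    count_for_te,
    differential_expression,
    differential_te,
    filter_codon_asite_reads,
    footprint_gene_counts,
    log2_te_matrix,
    size_factors,
    top_gene_report,
)
from conftest import toy_transcript
from oracles import (
    asite_codon_bruteforce,
    bh_qvalues_bruteforce,
    codon_filter_removed_bruteforce,
    welch_t_bruteforce,
)


def frame(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "transcript_id", "five_prime_pos", "length"]
    )


SAMPLES = ["control_rep1", "control_rep2", "control_rep3",
           "mutant_rep1", "mutant_rep2", "mutant_rep3"]
CONDITION_MAP = {s: s.rsplit("_rep", 1)[0] for s in SAMPLES}


def count_table(fp, rna, genes):
    idx = pd.Index(genes, name="gene_id")
    return TECountTable(
        pd.DataFrame(fp, index=idx, columns=SAMPLES),
        pd.DataFrame(rna, index=idx, columns=SAMPLES),
    )


class TestGeneFilters:
    def test_histone_prefix_removed(self):
        genes = pd.Index(["Hist1h1a", "Actb", "Hist2h2be", "Gapdh"])
        kept = apply_gene_filters(genes, GeneFilterConfig())
        assert list(kept) == ["Actb", "Gapdh"]

    def test_prefix_match_is_case_sensitive(self):
        genes = pd.Index(["HIST1H1A", "hist1h1a", "Hist1h1a"])
        kept = apply_gene_filters(genes, GeneFilterConfig())
        assert list(kept) == ["HIST1H1A", "hist1h1a"]

    def test_no_filters_is_identity(self):
        genes = pd.Index(["Actb", "Gapdh"])
        kept = apply_gene_filters(genes, GeneFilterConfig(histone_prefix="Hist"))
        assert list(kept) == ["Actb", "Gapdh"]

    def test_extra_exclusion_list(self):
        genes = pd.Index(["Actb", "Gapdh", "Rn45s"])
        kept = apply_gene_filters(
            genes, GeneFilterConfig(extra_exclusion={"Rn45s"})
        )
        assert list(kept) == ["Actb", "Gapdh"]


class TestFootprintCounting:
    def test_counts_equal_bruteforce_in_cds_tally(self, rng):
        t1 = toy_transcript(["AAA"] * 20, "tx1", "g1", utr5=25, utr3=25)
        t2 = toy_transcript(["CCC"] * 15, "tx2", "g2", utr5=25, utr3=25)
        tx = Transcriptome([t1, t2])
        offsets = OffsetTable({30: 15})
        rows = []
        for i in range(200):
            t = t1 if rng.random() < 0.5 else t2
            pos = int(rng.integers(0, len(t.sequence) - 30))
            rows.append((f"r{i}", t.transcript_id, pos, 30))
        lib = frame(rows)
        got = footprint_gene_counts(lib, offsets, tx)
        expected = {"g1": 0, "g2": 0}
        for r in rows:
            t = tx[r[1]]
            c = asite_codon_bruteforce(r[2], r[3], 15, t.cds_start, t.cds_end)
            if c is not None:
                expected[t.gene_id] += 1
        assert got["g1"] == expected["g1"] and got["g2"] == expected["g2"]

    def test_count_for_te_drops_single_assay_genes(self, caplog):
        t1 = toy_transcript(["AAA"] * 10, "tx1", "g1")
        tx = Transcriptome([t1])
        offsets = OffsetTable({30: 15})
        libs = {s: frame([]) for s in SAMPLES}
        rna = pd.DataFrame(
            {s: [5, 7] for s in SAMPLES},
            index=pd.Index(["g1", "ghost"], name="gene_id"),
        )
        with caplog.at_level("WARNING"):
            table = count_for_te(libs, offsets, tx, rna)
        assert list(table.genes) == ["g1"]
        assert any("only one assay" in r.message for r in caplog.records)


class TestDifferentialTE:
    def test_identical_te_gives_zero_delta(self, rng):
        """fp == rna for every sample: log2 TE is identically 0, delta exact 0."""
        counts = rng.integers(50, 500, size=(40, 6))
        table = count_table(counts, counts, [f"g{i}" for i in range(40)])
        res = differential_te(table, CONDITION_MAP)
        assert np.allclose(res["delta_log2_te"], 0.0)

    def test_library_scaling_cancels_through_size_factors(self, rng):
        counts_fp = rng.integers(100, 1000, size=(60, 6))
        counts_rna = rng.integers(100, 1000, size=(60, 6))
        genes = [f"g{i}" for i in range(60)]
        base = differential_te(count_table(counts_fp, counts_rna, genes),
                               CONDITION_MAP)
        scaled = differential_te(count_table(counts_fp * 3, counts_rna, genes),
                                 CONDITION_MAP)
        assert np.allclose(
            base["delta_log2_te"], scaled["delta_log2_te"], atol=5e-3
        )

    def test_welch_p_matches_bruteforce_t(self, rng):
        counts_fp = rng.integers(50, 500, size=(10, 6))
        counts_rna = rng.integers(50, 500, size=(10, 6))
        genes = [f"g{i}" for i in range(10)]
        table = count_table(counts_fp, counts_rna, genes)
        res = differential_te(table, CONDITION_MAP)
        te = log2_te_matrix(table)
        mut = te[[s for s in SAMPLES if "mutant" in s]].to_numpy()
        ctl = te[[s for s in SAMPLES if "control" in s]].to_numpy()
        from scipy import stats as sps
        for i, g in enumerate(genes):
            t, df = welch_t_bruteforce(mut[i], ctl[i])
            p = 2 * sps.t.sf(abs(t), df)
            assert res.loc[g, "p_value"] == pytest.approx(p, rel=1e-9)

    def test_zero_variance_gene_has_undefined_p(self):
        # 9 flat genes pin every size factor at 1, so their log2 TE has zero
        # variance in both groups; one shifted gene still gets a finite p.
        fp = np.full((10, 6), 100)
        fp[9] = [80, 90, 100, 300, 310, 290]
        rna = np.full((10, 6), 100)
        genes = [f"flat{i}" for i in range(9)] + ["shift"]
        res = differential_te(count_table(fp, rna, genes), CONDITION_MAP)
        assert np.isnan(res.loc["flat0", "p_value"])
        assert np.isnan(res.loc["flat0", "q_value"])
        assert res.loc["shift", "p_value"] < 0.05

    def test_bh_qvalues_match_stepup_oracle(self, rng):
        pvals = rng.uniform(0, 1, size=10)
        oracle = bh_qvalues_bruteforce(pvals.tolist())
        got = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(got, oracle, atol=1e-12)
        # and q >= p always
        assert (got >= pvals - 1e-15).all()

    def test_size_factors_undo_depth_differences(self, rng):
        base = rng.integers(100, 1000, size=50).astype(float)
        scales = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 3.0])
        counts = pd.DataFrame(np.outer(base, scales), columns=SAMPLES)
        sf = size_factors(counts)
        assert np.allclose(
            sf.to_numpy() / sf.iloc[0], scales / scales[0], rtol=1e-6
        )


class TestCodonFilteredReads:
    def make_case(self):
        # AGA at codon 5 only
        body = ["AAA"] * 4 + ["AGA"] + ["CCC"] * 6
        t = toy_transcript(body, utr5=20, utr3=20)
        return Transcriptome([t]), t, OffsetTable({30: 15})

    def asite_read(self, t, codon_index, rid):
        return (rid, t.transcript_id, t.cds_start + 3 * codon_index - 15, 30)

    def test_window_one_removes_adjacent_asites(self):
        tx, t, offsets = self.make_case()
        lib = frame([self.asite_read(t, c, f"r{c}") for c in (4, 5, 6, 7)])
        kept, stats = filter_codon_asite_reads(lib, offsets, tx, "AGA", 1)
        assert set(kept["read_id"]) == {"r7"}
        assert stats.n_discarded == 3

    def test_transcript_without_target_is_identity(self):
        t = toy_transcript(["AAA"] * 10, utr5=20, utr3=20)
        tx = Transcriptome([t])
        offsets = OffsetTable({30: 15})
        lib = frame([self.asite_read(t, c, f"r{c}") for c in (2, 5)])
        kept, stats = filter_codon_asite_reads(lib, offsets, tx, "AGA", 1)
        pd.testing.assert_frame_equal(kept, lib)
        assert stats.n_discarded == 0

    def test_removal_set_matches_bruteforce_window_scan(self, rng):
        from ribopause.model import SENSE_CODONS
        from ribopause.asite import assign_asite_codons, OUTSIDE_CDS

        bodies = [
            [SENSE_CODONS[i] for i in rng.integers(0, 61, size=15)]
            for _ in range(4)
        ]
        tx = Transcriptome(
            [toy_transcript(b, f"tx{i}", f"g{i}", utr5=20, utr3=20)
             for i, b in enumerate(bodies)]
        )
        offsets = OffsetTable({30: 15})
        rows = []
        for i in range(150):
            tid = f"tx{int(rng.integers(4))}"
            pos = int(rng.integers(0, len(tx[tid].sequence) - 30))
            rows.append((f"r{i}", tid, pos, 30))
        lib = frame(rows)
        for window in (0, 1, 2):
            kept, _ = filter_codon_asite_reads(lib, offsets, tx, "AGA", window)
            kept_ids = set(kept["read_id"])
            assigned = assign_asite_codons(lib, offsets, tx)
            for i, r in enumerate(rows):
                t = tx[r[1]]
                a = None if assigned[i] == OUTSIDE_CDS else int(assigned[i])
                removed = codon_filter_removed_bruteforce(
                    a, list(t.codons), "AGA", window
                )
                assert (r[0] not in kept_ids) == removed

    def test_filtering_never_increases_counts_and_is_exact_without_target(
        self, small_experiment
    ):
        from ribopause.asite import calibrate_offsets
        from ribopause.preprocess import filter_lengths

        exp = small_experiment
        tx = exp.transcriptome
        lib, _ = filter_lengths(exp.footprints["mutant_rep1"])
        offsets = calibrate_offsets(lib, tx)
        kept, stats = filter_codon_asite_reads(lib, offsets, tx, "AGA", 1)
        assert len(kept) <= len(lib)
        before = footprint_gene_counts(lib, offsets, tx)
        after = footprint_gene_counts(kept, offsets, tx)
        assert (after <= before).all()
        no_target = [
            tx[t].gene_id for t in tx.ids
            if "AGA" not in tx[t].codons
        ]
        assert before[no_target].equals(after[no_target])


class TestTopGeneReport:
    def make_results(self):
        return pd.DataFrame(
            {
                "delta_log2_te": [0.1, -1.2, 0.0],
                "p_value": [0.5, 0.001, 0.9],
                "q_value": [0.6, 0.01, 0.9],
            },
            index=pd.Index(["Rps6", "Eef2", "Actb"], name="gene_id"),
        )

    def test_disjoint_list_gives_empty_subset(self):
        subset, n = top_gene_report(self.make_results(), {"Rpl10", "Rps24"})
        assert subset.empty and n == 0

    def test_membership_filter_and_count(self):
        subset, n = top_gene_report(self.make_results(), {"Rps6", "Eef2"})
        assert set(subset.index) == {"Rps6", "Eef2"}
        assert n == 1  # only Eef2 has q <= 0.05

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            top_gene_report(self.make_results(), set())


class TestDifferentialExpression:
    def test_beta_is_natural_log_fold_change(self, rng):
        base = rng.integers(200, 400, size=20)
        rna = pd.DataFrame(
            {s: base * (2 if "mutant" in s else 1) for s in SAMPLES},
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
        )
        res = differential_expression(rna, CONDITION_MAP).set_index("gene_id")
        # uniform doubling is absorbed by size factors -> beta ~ 0
        assert res["beta"].abs().max() < 0.02

    def test_shifted_gene_has_positive_beta(self, rng):
        counts = rng.integers(200, 300, size=(20, 6))
        counts[0, 3:] *= 4
        rna = pd.DataFrame(
            counts, columns=SAMPLES,
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
        )
        res = differential_expression(rna, CONDITION_MAP).set_index("gene_id")
        assert res.loc["g0", "beta"] > 1.0
        assert res.loc["g0", "q_value"] <= res["q_value"].max()
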