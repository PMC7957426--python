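"""Ribosome-profiling analysis: periodicity gating, P-site assignment,
occupancy normalization, fold changes, TE, gene sets, profiles, polysome
fraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsribo import riboprof
from bsribo.riboprof import (
    PsiteTable,
    assign_psites,
    cds_annotation,
    cds_sequences,
    codon_enrichment_sets,
    codon_occupancy,
    compare_te_groups,
    drop_first_codons,
    gene_occupancy,
    occupancy_fold_change,
    periodicity_filter,
    polysome_fraction,
    profile_gene,
    translation_efficiency,
)
from bsribo.study import STALLED_CODON, run_ribo_study


def _cds(n_codons: int = 50, cds_start: int = 30) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": ["g1"],
            "transcript": ["tx1"],
            "cds_start": [cds_start],
            "cds_end": [cds_start + 3 * n_codons],
            "n_codons": [n_codons],
        }
    )


def _alignments(starts: list[int], length: int = 28) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(starts))],
            "transcript": "tx1",
            "start": starts,
            "mismatches": 0,
            "length": length,
        }
    )


class TestPeriodicityFilter:
    def test_pure_frame_retained_with_modal_fraction_one(self):
        cds = _cds()
        aln = _alignments([30 + 3 * k for k in range(20)])
        retained, table = periodicity_filter(aln, cds, lengths=[28])
        assert retained == {28}
        assert table.iloc[0]["modal_fraction"] == 1.0

    def test_uniform_frames_rejected(self):
        cds = _cds()
        aln = _alignments([30, 31, 32, 33, 34, 35])
        retained, table = periodicity_filter(aln, cds, lengths=[28],
                                             min_frame_fraction=0.5)
        assert retained == set()

    def test_no_cds_reads_is_an_error(self):
        cds = _cds()
        aln = _alignments([0, 1, 2])
        with pytest.raises(ValueError, match="no CDS-overlapping"):
            periodicity_filter(aln, cds, lengths=[28])

    def test_lengths_outside_candidate_window_rejected(self):
        with pytest.raises(ValueError, match="20-40"):
            periodicity_filter(_alignments([30]), _cds(), lengths=[45])

    def test_frame_noise_matches_closed_form(self, small_config):
        # modal fraction expectation is (1 - fn) + fn / 3
        from bsribo.sim.reference import make_reference
        from bsribo.sim.ribo import simulate_ribo_and_rna
        from bsribo.bsalign import UniqueAligner

        cfg = small_config.with_(frame_noise=0.2, ribo_depth=30_000)
        ref = make_reference(cfg)
        sample = simulate_ribo_and_rna(ref, cfg, "WT", "27C")
        aln = UniqueAligner(ref, max_mismatch=0).align(sample.reads)
        _, table = periodicity_filter(aln, cds_annotation(ref),
                                      lengths=sorted(cfg.rpf_len_dist))
        expected = 0.8 + 0.2 / 3
        pooled = table[["frame0", "frame1", "frame2"]].sum()
        n = pooled.sum()
        observed = pooled.max() / n
        assert observed == pytest.approx(expected, abs=4 * np.sqrt(expected / n))


class TestAssignPsites:
    def test_read_at_cds_start_maps_to_codon_four(self):
        pst = assign_psites(_alignments([30]), _cds(), shift=12)
        assert pst.counts.iloc[0]["codon_index"] == 4

    def test_off_frame_read_dropped_and_counted(self):
        pst = assign_psites(_alignments([31]), _cds(), shift=12)
        assert pst.total() == 0
        assert pst.n_off_frame == 1
        assert pst.n_cds_assigned == 1

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            assign_psites(_alignments([30]), _cds(), shift=-1)

    def test_zero_frame_noise_counts_equal_provenance_census(self, small_config):
        from bsribo.sim.reference import make_reference
        from bsribo.sim.ribo import provenance_codon_census, simulate_ribo_and_rna
        from bsribo.bsalign import UniqueAligner

        cfg = small_config.with_(frame_noise=0.0, ribo_depth=15_000)
        ref = make_reference(cfg)
        sample = simulate_ribo_and_rna(ref, cfg, "WT", "27C")
        aln = UniqueAligner(ref, max_mismatch=0).align(sample.reads)
        pst = assign_psites(aln, cds_annotation(ref))
        assert pst.n_off_frame == 0
        census = provenance_codon_census(sample.provenance)
        gene_of = {t.id: t.gene for t in ref.mrnas}
        census["gene"] = census["transcript"].map(gene_of)
        lhs = pst.counts.set_index(["gene", "codon_index"])["count"].sort_index()
        rhs = census.set_index(["gene", "codon_index"])["count"].sort_index()
        # alignment may drop a handful of multi-mapping footprints
        shared = lhs.index.intersection(rhs.index)
        assert len(shared) == len(rhs)
        assert (rhs.loc[shared] - lhs.loc[shared]).abs().sum() <= 0.001 * rhs.sum()


class TestDropFirstCodons:
    def test_gene_with_only_early_codons_empties(self):
        counts = pd.DataFrame({"gene": ["g"] * 3, "codon_index": [0, 5, 9],
                               "count": [4, 5, 6]})
        table = PsiteTable(counts, 12, (28,), n_cds_assigned=15, n_off_frame=0)
        out = drop_first_codons(table, 10)
        assert out.total() == 0
        assert out.n_first_dropped == 15
        assert out.conservation_ok()

    def test_zero_is_identity(self):
        counts = pd.DataFrame({"gene": ["g"], "codon_index": [3], "count": [7]})
        table = PsiteTable(counts, 12, (28,), n_cds_assigned=7, n_off_frame=0)
        out = drop_first_codons(table, 0)
        pd.testing.assert_frame_equal(out.counts, table.counts)

    def test_recount_oracle(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            {
                "gene": rng.choice(["g1", "g2"], size=100),
                "codon_index": rng.integers(0, 40, size=100),
                "count": rng.integers(1, 10, size=100),
            }
        )
        total = counts["count"].sum()
        table = PsiteTable(counts, 12, (28,), n_cds_assigned=int(total), n_off_frame=0)
        out = drop_first_codons(table, 10)
        early = counts.loc[counts["codon_index"] < 10, "count"].sum()
        assert out.total() == total - early


def _uniform_psites(seq: str, count: int = 30) -> tuple[PsiteTable, pd.DataFrame, dict]:
    n_codons = len(seq) // 3
    cds = pd.DataFrame(
        {"gene": ["g"], "transcript": ["t"], "cds_start": [0],
         "cds_end": [len(seq)], "n_codons": [n_codons]}
    )
    counts = pd.DataFrame(
        {"gene": "g", "codon_index": range(10, n_codons - 1), "count": count}
    )
    table = PsiteTable(counts, 12, (28,), n_cds_assigned=int(counts["count"].sum()),
                       n_off_frame=0)
    return table, cds, {"g": seq}


class TestCodonOccupancy:
    def test_uniform_counts_normalize_to_one(self):
        # every codon equally covered: occupancy must be exactly 1
        seq = "ATG" + "GCT" * 40 + "TAA"
        table, cds, seqs = _uniform_psites(seq)
        occ = codon_occupancy(table, cds, seqs)
        assert occ.loc["GCT", "occupancy"] == pytest.approx(1.0)

    def test_zero_p_count_with_background_gives_zero(self):
        seq = "ATG" + "GCT" * 20 + "TTG" + "GCT" * 20 + "TAA"
        table, cds, seqs = _uniform_psites(seq)
        table.counts.loc[table.counts["codon_index"] == 21, "count"] = 0  # the TTG
        occ = codon_occupancy(table, cds, seqs)
        assert occ.loc["TTG", "occupancy"] == 0.0

    def test_undefined_background_flagged_nan(self):
        seq = "ATG" + "GCT" * 40 + "TAA"
        table, cds, seqs = _uniform_psites(seq)
        occ = codon_occupancy(table, cds, seqs)
        assert np.isnan(occ.loc["AAA", "occupancy"])

    def test_positions_near_stop_skipped(self):
        # a P-site whose +3 A-site-relative codon crosses the stop contributes nothing
        seq = "ATG" + "GCT" * 20 + "TAA"
        n_codons = len(seq) // 3
        cds = pd.DataFrame(
            {"gene": ["g"], "transcript": ["t"], "cds_start": [0],
             "cds_end": [len(seq)], "n_codons": [n_codons]}
        )
        counts = pd.DataFrame({"gene": ["g"], "codon_index": [n_codons - 3],
                               "count": [50]})
        table = PsiteTable(counts, 12, (28,), n_cds_assigned=50, n_off_frame=0)
        occ = codon_occupancy(table, cds, {"g": seq})
        assert occ["p_count"].sum() == 0


class TestFoldChange:
    def _occ(self, values: dict[str, float]) -> pd.DataFrame:
        from bsribo.config import SENSE_CODONS

        occ = pd.DataFrame(index=pd.Index(SENSE_CODONS, name="codon"))
        occ["occupancy"] = [values.get(c, 1.0) for c in SENSE_CODONS]
        return occ

    def test_identical_tables_give_unit_fc_and_no_hits(self):
        t = self._occ({"TTG": 1.3})
        fc = occupancy_fold_change([t, t, t], [t, t, t])
        assert np.allclose(fc["fold_change"], 1.0)
        assert not fc["significant"].any()

    def test_swapping_genotypes_inverts_fold_changes(self, ribo_stall_study):
        ko = ribo_stall_study.occupancies("noNSUN", "27C")
        wt = ribo_stall_study.occupancies("WT", "27C")
        fwd = occupancy_fold_change(ko, wt)
        rev = occupancy_fold_change(wt, ko)
        ok = fwd["defined"]
        assert np.allclose(fwd.loc[ok, "fold_change"],
                           1.0 / rev.loc[ok, "fold_change"])

    def test_undefined_replicate_excludes_codon(self):
        t = self._occ({})
        bad = t.copy()
        bad.loc["TTG", "occupancy"] = np.nan
        fc = occupancy_fold_change([t, bad], [t, t])
        assert not fc.loc["TTG", "defined"]
        assert np.isnan(fc.loc["TTG", "p_value"])

    @pytest.mark.parametrize("multiplier", [1.5, 2.0])
    def test_planted_dwell_recovered_within_fifteen_percent(self, multiplier):
        study = run_ribo_study(
            seed=13, dwell_multipliers={("noNSUN", "27C", STALLED_CODON): multiplier},
            n_reps=3,
        )
        fc = study.fold_change()
        defined = fc[fc["defined"]]
        assert defined["fold_change"].idxmax() == STALLED_CODON
        assert defined.loc[STALLED_CODON, "fold_change"] == pytest.approx(
            multiplier, rel=0.15
        )


class TestGeneOccupancyAndTE:
    def test_gene_occupancy_is_column_sum(self):
        counts = pd.DataFrame({"gene": ["a", "a", "b"], "codon_index": [10, 11, 12],
                               "count": [2, 3, 4]})
        table = PsiteTable(counts, 12, (28,), n_cds_assigned=9, n_off_frame=0)
        out = gene_occupancy(table)
        assert out.to_dict() == {"a": 5, "b": 4}

    def test_te_direct_ratio(self):
        rpf = pd.Series({"a": 100, "b": 100})
        rna = pd.Series({"a": 50, "b": 150})
        te = translation_efficiency(rpf, rna, min_rna=1)
        assert te.loc["a", "te"] == pytest.approx(2.0)

    def test_te_invariant_under_library_rescaling(self):
        rpf = pd.Series({"a": 100, "b": 300, "c": 50})
        rna = pd.Series({"a": 60, "b": 90, "c": 120})
        te1 = translation_efficiency(rpf, rna, min_rna=1)["te"]
        te2 = translation_efficiency(rpf * 7, rna, min_rna=1)["te"]
        pd.testing.assert_series_equal(te1, te2)

    def test_rna_floor_excludes_genes(self):
        rpf = pd.Series({"a": 100, "b": 100})
        rna = pd.Series({"a": 50, "b": 3})
        te = translation_efficiency(rpf, rna, min_rna=10)
        assert list(te.index) == ["a"]

    def test_all_genes_below_floor_errors(self):
        with pytest.raises(ValueError, match="floor"):
            translation_efficiency(pd.Series({"a": 1}), pd.Series({"a": 2}), min_rna=10)

    def test_te_uncorrelated_with_expression_under_uniform_dwell(
        self, ribo_uniform_study
    ):
        from bsribo.sim.reference import expression_levels

        study = ribo_uniform_study
        expr = expression_levels(study.config, study.ref)
        gene_expr = pd.Series(
            {t.gene: np.log2(expr[t.id]) for t in study.ref.mrnas}
        )
        te = riboprof.mean_log2_te(study.te_tables("WT", "27C"))
        joined = pd.concat([te, gene_expr.rename("expr")], axis=1, join="inner").dropna()
        r = np.corrcoef(joined["log2_te"], joined["expr"])[0, 1]
        assert abs(r) < 0.1


class TestEnrichmentSets:
    def test_enriched_example(self):
        seqs = {
            "hot": "ATG" + "TTG" * 15 + "GCA" * 84 + "TAA",
            **{f"g{i}": "ATG" + "GCA" * 99 + "TAA" for i in range(20)},
        }
        genes, table = codon_enrichment_sets(seqs, "TTG", factor=3.0)
        assert genes == ["hot"]
        assert table.loc["hot", "ratio"] > 3

    def test_exactly_threefold_is_enriched(self):
        # "at least 3-fold" is inclusive: 3 genes, one with triple proportion
        seqs = {
            "a": "ATG" + "TTG" * 3 + "GCA" * 6 + "TAA",  # 3/10
            "b": "ATG" + "GCA" * 9 + "TAA",
            "c": "ATG" + "TTG" * 0 + "GCA" * 9 + "TAA",
        }
        genes, table = codon_enrichment_sets(seqs, "TTG", factor=3.0)
        assert table.loc["a", "ratio"] == pytest.approx(3.0)
        assert "a" in genes

    def test_non_sense_codon_rejected(self):
        with pytest.raises(ValueError, match="sense codon"):
            codon_enrichment_sets({"g": "ATGTAA"}, "TAA")

    def test_membership_equals_brute_force_census(self, ribo_stall_study):
        seqs = ribo_stall_study.sequences
        genes, table = codon_enrichment_sets(seqs, "TTG", factor=3.0)
        # brute-force oracle: recount codons by hand
        from bsribo.config import STOP_CODONS

        counts = {}
        total_t = total_s = 0
        for g, seq in seqs.items():
            cods = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            sense = [c for c in cods if c not in STOP_CODONS]
            counts[g] = (sum(c == "TTG" for c in sense), len(sense))
            total_t += counts[g][0]
            total_s += counts[g][1]
        base = total_t / total_s
        expected = sorted(
            g for g, (t, s) in counts.items() if s and (t / s) >= 3.0 * base
        )
        assert sorted(genes) == expected


class TestCompareTeGroups:
    def test_zero_variance_groups_flagged_not_tested(self):
        te = pd.Series(1.0, index=[f"g{i}" for i in range(20)], name="log2_te")
        out = compare_te_groups(te, {"s": ["g0", "g1", "g2", "g3"]}, seed=0)
        assert not out.loc["s", "tested"]
        assert np.isnan(out.loc["s", "p_value"])

    def test_small_set_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        te = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)],
                       name="log2_te")
        with pytest.warns(UserWarning, match="too small"):
            out = compare_te_groups(te, {"s": ["g0", "g1"]}, seed=0)
        assert not out.loc["s", "tested"]

    def test_null_set_p_values_roughly_uniform(self):
        # sets drawn from the pool itself: ~5% rejections at alpha = 0.05
        rng = np.random.default_rng(7)
        te = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)],
                       name="log2_te")
        n_reject = 0
        n_trials = 200
        for i in range(n_trials):
            r = np.random.default_rng(i)
            chosen = list(r.choice(te.index.to_numpy(), size=8, replace=False))
            out = compare_te_groups(te, {"s": chosen}, seed=1000 + i)
            n_reject += bool(out.loc["s", "p_value"] < 0.05)
        bound = stats.binom.ppf(0.999, n_trials, 0.05)
        assert n_reject <= bound


class TestProfileGene:
    def test_vector_sums_to_gene_occupancy_and_highlights_match_scan(
        self, ribo_stall_study
    ):
        s = ribo_stall_study.samples[("noNSUN", "27C", 0)]
        gene = ribo_stall_study.cds["gene"].iloc[0]
        vec, highlight = profile_gene(s.psites, gene, "TTG",
                                      ribo_stall_study.sequences)
        assert vec.sum() == gene_occupancy(s.psites).get(gene, 0)
        seq = ribo_stall_study.sequences[gene]
        brute = [i for i in range(len(seq) // 3) if seq[3 * i : 3 * i + 3] == "TTG"]
        assert highlight == brute

    def test_absent_codon_gives_empty_highlight(self):
        counts = pd.DataFrame({"gene": ["g"], "codon_index": [10], "count": [1]})
        table = PsiteTable(counts, 12, (28,), n_cds_assigned=1, n_off_frame=0)
        _, highlight = profile_gene(table, "g", "TGG", {"g": "ATG" + "AAA" * 20 + "TAA"})
        assert highlight == []

    def test_unknown_gene_errors(self):
        counts = pd.DataFrame({"gene": ["g"], "codon_index": [10], "count": [1]})
        table = PsiteTable(counts, 12, (28,), n_cds_assigned=1, n_off_frame=0)
        with pytest.raises(KeyError):
            profile_gene(table, "nope", "TTG", {"g": "ATGAAATAA"})


class TestPolysomeFraction:
    def test_rectangular_trace(self):
        x = [0, 7, 10]
        y = [10, 10, 10]
        assert polysome_fraction(x, y, 7) == pytest.approx(0.30)

    def test_boundary_at_start_is_all_polysomal(self):
        assert polysome_fraction([0, 1, 2], [1, 2, 1], 0) == pytest.approx(1.0)

    def test_piecewise_linear_matches_closed_form(self):
        # triangle on [0, 2] peaking at 1: area right of b is (2-b)^2/2 * h / ...
        x = np.linspace(0, 2, 2001)
        y = np.where(x <= 1, x, 2 - x)
        b = 1.25
        total = 1.0
        right = 0.5 * (2 - b) ** 2
        assert polysome_fraction(x, y, b) == pytest.approx(right / total, abs=1e-9)

    def test_boundary_outside_range_errors(self):
        with pytest.raises(ValueError, match="outside"):
            polysome_fraction([0, 1], [1, 1], 2.0)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            polysome_fraction([0, 1], [1, -0.1], 0.5)


class TestCountConservation:
    def test_chain_conserves_reads_exactly(self, ribo_stall_study):
        for s in ribo_stall_study.samples.values():
            assert s.psites.conservation_ok()
            assert (
                s.psites.n_cds_assigned
                == s.psites.n_off_frame + s.psites.n_first_dropped + s.psites.total()
            )
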