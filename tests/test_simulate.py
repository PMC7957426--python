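"""Synthetic-data generator: reference structure, planted truth, bisulfite
conversion statistics, footprint placement."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsribo.config import ConfigError, SimulationConfig, STOP_CODONS
from bsribo.sim.bisulfite import simulate_bisulfite_reads
from bsribo.sim.methylation import MethylationPlan, SiteSpec, plant_methylation
from bsribo.sim.reference import MRNA, TRNA, make_reference
from bsribo.sim.ribo import simulate_ribo_and_rna


class TestMakeReference:
    def test_deterministic_under_fixed_seed(self, small_config):
        a = make_reference(small_config)
        b = make_reference(small_config)
        assert [(t.id, t.sequence, t.cds) for t in a] == [
            (t.id, t.sequence, t.cds) for t in b
        ]

    def test_no_mrna_gives_only_noncoding(self):
        cfg = SimulationConfig(seed=1, n_mrna=0, n_trna=4, n_rrna=2)
        ref = make_reference(cfg)
        assert len(ref.mrnas) == 0
        assert len(ref) == 6

    def test_cds_contracts_brute_force(self, small_ref):
        # codon-by-codon scan of every CDS: ATG start, stop end, no internal stops
        for t in small_ref.mrnas:
            cds = small_ref.cds_sequence(t.id)
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            assert codons[0] == "ATG"
            assert codons[-1] in STOP_CODONS
            assert sum(c in STOP_CODONS for c in codons[:-1]) == 0

    def test_trnas_end_in_cca(self, small_ref):
        for t in small_ref.by_class("tRNA", "mt-tRNA"):
            assert t.sequence.endswith("CCA")

    def test_rejects_tiny_cds(self):
        with pytest.raises(ConfigError, match="12 codons"):
            SimulationConfig(seed=1, cds_len_range=(8, 10))

    def test_biased_codon_frequency_elevated(self, small_ref, small_config):
        biased = small_config.n_codon_biased
        hits = []
        totals = []
        for t in small_ref.mrnas:
            cds = small_ref.cds_sequence(t.id)
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            hits.append(sum(c == small_config.biased_codon for c in codons))
            totals.append(len(codons))
        pooled_biased = sum(hits[:biased]) / sum(totals[:biased])
        pooled_rest = sum(hits[biased:]) / sum(totals[biased:])
        assert pooled_biased > 2 * pooled_rest


class TestPlantMethylation:
    def test_single_wobble_site_at_position_33(self, small_ref):
        plan = plant_methylation(
            small_ref, [SiteSpec(TRNA, 1, (0.9, 1.0))], seed=1
        )
        assert len(plan) == 1
        (site,) = plan.sites
        assert site.position == 33
        assert "Leu-CAA" in site.transcript

    def test_stoichiometry_range_respected(self, small_ref):
        plan = plant_methylation(
            small_ref, [SiteSpec(TRNA, 10, (0.9, 1.0))], seed=1
        )
        assert all(0.9 <= s.stoichiometry <= 1.0 for s in plan)

    def test_every_site_is_reference_cytosine(self, small_ref):
        plan = plant_methylation(
            small_ref,
            [SiteSpec(MRNA, 10, (0.5, 0.8)), SiteSpec(TRNA, 5, (0.7, 1.0))],
            seed=2,
        )
        for s in plan:
            assert small_ref[s.transcript].sequence[s.position] == "C"

    def test_overfull_request_fails(self, small_ref):
        with pytest.raises(ValueError, match="eligible C positions"):
            plant_methylation(small_ref, [SiteSpec(TRNA, 500, (0.5, 1.0))], seed=1)

    def test_artifact_sites_behave_identically_in_both_genotypes(self, small_config):
        # high-depth simulation of both genotypes; artifact non-conversion must
        # agree within binomial error
        cfg = small_config.with_(bs_depth=300.0, seq_error_rate=0.0)
        ref = make_reference(cfg)
        plan = plant_methylation(
            ref, [SiteSpec(MRNA, 3, (0.4, 0.6), nsun_dependent=False)], seed=3,
            end_margin=cfg.bs_read_len,
        )
        ratios = {}
        for genotype in ("WT", "noNSUN"):
            rs = simulate_bisulfite_reads(ref, plan, genotype, cfg)
            ratios[genotype] = _site_ratios(rs, plan, ref, cfg)
        for site in plan:
            key = (site.transcript, site.position)
            n = 300
            sd = np.sqrt(site.stoichiometry * (1 - site.stoichiometry) / n)
            assert abs(ratios["WT"][key] - ratios["noNSUN"][key]) < 6 * sd


def _site_ratios(readset, plan, ref, cfg) -> dict:
    """Non-conversion ratio at planted sites straight from the raw reads."""
    out = {}
    reads = dict(readset.reads)
    prov = readset.provenance
    for site in plan:
        c = t = 0
        sel = prov[prov["transcript"] == site.transcript]
        for rid, start in zip(sel["read_id"], sel["start"]):
            if start <= site.position < start + cfg.bs_read_len:
                base = reads[rid][site.position - start]
                c += base == "C"
                t += base == "T"
        out[(site.transcript, site.position)] = c / (c + t)
    return out


class TestBisulfiteReads:
    def test_full_conversion_leaves_no_cytosines(self, small_config):
        cfg = small_config.with_(deamination_rate=1.0, seq_error_rate=0.0)
        ref = make_reference(cfg)
        rs = simulate_bisulfite_reads(ref, MethylationPlan([]), "WT", cfg)
        reads = dict(rs.reads)
        for row in rs.provenance.itertuples():
            seq = reads[row.read_id]
            ref_frag = ref[row.transcript].sequence[
                row.start : row.start + len(seq)
            ]
            for rb, sb in zip(seq, ref_frag):
                if sb == "C":
                    assert rb == "T"

    def test_fully_methylated_site_always_reads_c(self, small_config):
        cfg = small_config.with_(deamination_rate=1.0, seq_error_rate=0.0)
        ref = make_reference(cfg)
        plan = plant_methylation(
            ref, [SiteSpec(MRNA, 1, (1.0, 1.0))], seed=5, end_margin=cfg.bs_read_len
        )
        (site,) = plan.sites
        rs = simulate_bisulfite_reads(ref, plan, "WT", cfg)
        ratios = _site_ratios(rs, plan, ref, cfg)
        assert ratios[(site.transcript, site.position)] == 1.0

    def test_partial_stoichiometry_binomial_oracle(self, small_config):
        # stoichiometry 0.7 at very high depth: observed ratio within 3 binomial SD
        cfg = small_config.with_(bs_depth=400.0, seq_error_rate=0.0)
        ref = make_reference(cfg)
        plan = plant_methylation(
            ref, [SiteSpec(MRNA, 1, (0.7, 0.7))], seed=6, end_margin=cfg.bs_read_len
        )
        (site,) = plan.sites
        rs = simulate_bisulfite_reads(ref, plan, "WT", cfg)
        ratio = _site_ratios(rs, plan, ref, cfg)[(site.transcript, site.position)]
        n = 400
        expected = 0.7 + (1 - 0.7) * (1 - cfg.deamination_rate)
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(ratio - expected) < 3 * sd

    def test_knockout_erases_nsun_dependent_sites_only(self, small_config):
        cfg = small_config.with_(bs_depth=200.0, seq_error_rate=0.0)
        ref = make_reference(cfg)
        plan = plant_methylation(
            ref, [SiteSpec(MRNA, 2, (0.9, 1.0), nsun_dependent=True)], seed=7,
            end_margin=cfg.bs_read_len,
        )
        rs = simulate_bisulfite_reads(ref, plan, "noNSUN", cfg)
        for ratio in _site_ratios(rs, plan, ref, cfg).values():
            # expected residual non-conversion is (1 - deamination) only
            assert ratio < 0.06

    def test_one_provenance_record_per_read(self, small_config):
        ref = make_reference(small_config)
        rs = simulate_bisulfite_reads(ref, MethylationPlan([]), "WT", small_config)
        assert len(rs.reads) == len(rs.provenance)
        assert rs.provenance["read_id"].is_unique

    def test_replicate_streams_are_stable(self, small_config):
        ref = make_reference(small_config)
        plan = MethylationPlan([])
        first = simulate_bisulfite_reads(ref, plan, "WT", small_config, replicate=0)
        simulate_bisulfite_reads(ref, plan, "WT", small_config, replicate=1)
        again = simulate_bisulfite_reads(ref, plan, "WT", small_config, replicate=0)
        assert first.reads == again.reads


class TestRiboSimulation:
    def test_zero_frame_noise_means_pure_frame_zero(self, small_config):
        cfg = small_config.with_(frame_noise=0.0)
        ref = make_reference(cfg)
        sample = simulate_ribo_and_rna(ref, cfg, "WT", "27C")
        cds_start = {t.id: t.cds[0] for t in ref.mrnas}
        for row in sample.provenance.itertuples():
            assert row.five_prime == cds_start[row.transcript] + 3 * row.psite_codon - 12

    def test_uniform_dwell_matches_codon_census(self, small_config):
        # chi-square of P-site codon counts against the exact expected shares
        # computed from a brute-force codon census of every CDS
        n_tx = small_config.n_mrna + small_config.n_trna + small_config.n_rrna
        cfg = small_config.with_(
            biol_noise_sd_log2=0.0,
            expression_levels=tuple([1.0] * n_tx),
            ribo_depth=60_000,
        )
        ref = make_reference(cfg)
        sample = simulate_ribo_and_rna(ref, cfg, "WT", "27C")
        census: dict[tuple[str, int], float] = {}
        for t in ref.mrnas:
            cds = ref.cds_sequence(t.id)
            for ci in range(len(cds) // 3 - 1):  # sense codons only
                census[(t.id, ci)] = 1.0
        observed = (
            sample.provenance.groupby(["transcript", "psite_codon"]).size()
        )
        expected_share = 1.0 / len(census)
        obs = np.array([observed.get(k, 0) for k in census])
        exp = np.full(len(census), expected_share * cfg.ribo_depth)
        stat = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(stat, df=len(census) - 1)
        assert p > 1e-4

    def test_rna_abundance_independent_of_dwell(self, small_config):
        cfg_stall = small_config.with_(
            dwell_multipliers={("WT", "27C", "TTG"): 2.5}
        )
        ref = make_reference(small_config)
        a = simulate_ribo_and_rna(ref, small_config, "WT", "27C").rna_counts
        b = simulate_ribo_and_rna(ref, cfg_stall, "WT", "27C").rna_counts
        pd.testing.assert_series_equal(a, b)

    def test_gene_counts_track_expression_times_length_under_uniform_dwell(
        self, small_config
    ):
        cfg = small_config.with_(biol_noise_sd_log2=0.0, ribo_depth=100_000)
        ref = make_reference(cfg)
        from bsribo.sim.reference import expression_levels

        expr = expression_levels(cfg, ref)
        sample = simulate_ribo_and_rna(ref, cfg, "WT", "27C")
        counts = sample.provenance.groupby("transcript").size()
        w = pd.Series(
            {
                t.id: expr[t.id] * ((t.cds[1] - t.cds[0]) // 3 - 1)
                for t in ref.mrnas
            }
        )
        expected = w / w.sum() * cfg.ribo_depth
        z = (counts - expected) / np.sqrt(expected)
        assert np.abs(z).max() < 5

    def test_dwell_multiplier_must_be_positive(self):
        with pytest.raises(ConfigError, match="must be > 0"):
            SimulationConfig(
                seed=1, dwell_multipliers={("WT", "27C", "TTG"): 0.0}
            )

    def test_provenance_matches_read_count(self, small_config):
        ref = make_reference(small_config)
        sample = simulate_ribo_and_rna(ref, small_config, "noNSUN", "20C")
        assert len(sample.reads) == len(sample.provenance)
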