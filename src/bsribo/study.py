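"""Canonical study conditions and end-to-end runners.

These functions fix the synthetic experimental design the package is
validated against: a wild-type and a pan-NSUN-null genotype, three replicates
per bisulfite library, three replicates per genotype and temperature for
ribosome profiling, planted m5C truth (100 NSUN-dependent sites plus
conversion artifacts), 99% deamination, ~50x bisulfite coverage, and 200,000
footprints per profiling sample with a 2.5-fold UUG dwell multiplier planted
in the null genotype under heat. Tests, the analysis drivers and the
acceptance script all run these same conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsalign import UniqueAligner, merge_bisulfite_identical, pileup_cytosines
from .config import SimulationConfig
from .methcall import (
    LABEL_NSUN,
    CallingParams,
    call_sites,
    deamination_rate,
)
from . import riboprof
from .riboprof import (
    PsiteTable,
    assign_psites,
    cds_annotation,
    cds_sequences,
    codon_occupancy,
    drop_first_codons,
    gene_occupancy,
    occupancy_fold_change,
    periodicity_filter,
    translation_efficiency,
)
from .sim.bisulfite import simulate_bisulfite_reads
from .sim.methylation import MethylationPlan, SiteSpec, plant_methylation
from .sim.reference import MRNA, MT_RRNA, MT_TRNA, RRNA, TRNA, ReferenceSet, make_reference
from .sim.ribo import provenance_codon_census, simulate_ribo_and_rna

HEAT = "27C"
CONTROL = "20C"
STALLED_CODON = "TTG"
STALL_MULTIPLIER = 2.5

#: footprints per sample for the uniform-dwell neutrality experiment: deep
#: enough (counting error ~1.5% per codon) that the ±10% neutrality band
#: probes the normalisation's bias rather than sampling noise
NEUTRAL_DEPTH = 500_000


def neutral_study_config(seed: int, **overrides) -> SimulationConfig:
    """Study conditions for the occupancy-neutrality experiment.

    Neutrality of the background normalisation is an asymptotic property; on a
    small transcriptome each codon's P-site and background position sets
    differ by a handful of CDS-boundary slots, a finite-reference composition
    bias unrelated to the normalisation itself. The neutrality experiment
    therefore uses a larger transcriptome (120 genes, 200-300 codon CDSs) and
    deep sampling so that residual deviation reflects the estimator, not the
    reference draw.
    """
    defaults = dict(
        n_mrna=120,
        cds_len_range=(200, 300),
        ribo_depth=NEUTRAL_DEPTH,
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


def study_config(seed: int, **overrides) -> SimulationConfig:
    """The default study configuration (see module docstring)."""
    return SimulationConfig(seed=seed, **overrides)


def bs_site_specs() -> list[SiteSpec]:
    """Planted truth: 100 NSUN-dependent sites in stoichiometry 0.5-1.0 across
    classes (tRNA variable loop and one wobble-34 site, rRNA, rare lower-
    stoichiometry mRNA sites) plus 30 NSUN-independent artifact sites."""
    return [
        SiteSpec(TRNA, 40, (0.7, 1.0), nsun_dependent=True),
        SiteSpec(MT_TRNA, 2, (0.9, 1.0), nsun_dependent=True),
        SiteSpec(RRNA, 8, (0.8, 1.0), nsun_dependent=True),
        SiteSpec(MT_RRNA, 2, (0.8, 1.0), nsun_dependent=True),
        SiteSpec(MRNA, 48, (0.5, 0.8), nsun_dependent=True),
        SiteSpec(MRNA, 20, (0.2, 0.6), nsun_dependent=False),
        SiteSpec(TRNA, 5, (0.2, 0.6), nsun_dependent=False),
        SiteSpec(RRNA, 5, (0.2, 0.6), nsun_dependent=False),
    ]


@dataclass
class BsStudy:
    config: SimulationConfig
    ref: ReferenceSet
    merged_ref: ReferenceSet
    merge_map: dict[str, str]
    plan: MethylationPlan
    wt_reports: list[pd.DataFrame]
    ko_reports: list[pd.DataFrame]
    n_reads: dict[str, int] = field(default_factory=dict)
    n_aligned: dict[str, int] = field(default_factory=dict)

    def calls(self, params: CallingParams | None = None) -> pd.DataFrame:
        return call_sites(self.wt_reports, self.ko_reports, params)

    def deamination_estimate(self, genotype: str = "WT", replicate: int = 0) -> float:
        """Bisulfite-efficiency estimate on rRNA with planted sites excluded."""
        report = (
            self.wt_reports[replicate] if genotype == "WT" else self.ko_reports[replicate]
        )
        rrna_ids = {t.id for t in self.ref.by_class(RRNA, MT_RRNA)}
        sub = report[report["transcript"].isin(rrna_ids)]
        exclude = {
            (s.transcript, s.position) for s in self.plan if s.transcript in rrna_ids
        }
        return deamination_rate(sub, exclude=exclude)


def run_bs_study(
    seed: int,
    n_reps: int = 3,
    site_specs: list[SiteSpec] | None = None,
    config: SimulationConfig | None = None,
) -> BsStudy:
    """Simulate, align and pile up the full two-genotype bisulfite experiment.

    ``site_specs=[]`` gives the site-free symmetric-noise experiment used for
    threshold-sweep calibration.
    """
    config = config or study_config(seed)
    ref = make_reference(config)
    merged, merge_map = merge_bisulfite_identical(ref)
    specs = bs_site_specs() if site_specs is None else site_specs
    plan = plant_methylation(ref, specs, seed=config.seed, end_margin=config.bs_read_len)
    aligner = UniqueAligner(merged, bisulfite=True, max_mismatch=2)

    reports: dict[str, list[pd.DataFrame]] = {"WT": [], "noNSUN": []}
    n_reads: dict[str, int] = {}
    n_aligned: dict[str, int] = {}
    for genotype in ("WT", "noNSUN"):
        for rep in range(n_reps):
            readset = simulate_bisulfite_reads(ref, plan, genotype, config, replicate=rep)
            aln = aligner.align(readset.reads)
            report = pileup_cytosines(aln, readset.as_dict(), merged)
            reports[genotype].append(report)
            key = f"{genotype}-rep{rep}"
            n_reads[key] = len(readset.reads)
            n_aligned[key] = len(aln)
    return BsStudy(
        config=config,
        ref=ref,
        merged_ref=merged,
        merge_map=merge_map,
        plan=plan,
        wt_reports=reports["WT"],
        ko_reports=reports["noNSUN"],
        n_reads=n_reads,
        n_aligned=n_aligned,
    )


def recall_metrics(calls: pd.DataFrame, plan: MethylationPlan) -> dict:
    """Truth-table comparison of the caller against the planted plan."""
    called = calls.set_index(["transcript", "position"])["label"]
    nsun_positions = [(s.transcript, s.position) for s in plan.nsun_dependent]
    artifact_positions = [(s.transcript, s.position) for s in plan.artifacts]
    labels_nsun = [called.get(p, "absent") for p in nsun_positions]
    labels_art = [called.get(p, "absent") for p in artifact_positions]
    n_recovered = sum(l == LABEL_NSUN for l in labels_nsun)
    false_nsun_artifacts = sum(l == LABEL_NSUN for l in labels_art)
    planted_set = set(nsun_positions)
    false_calls = [
        idx
        for idx, label in called.items()
        if label == LABEL_NSUN and idx not in planted_set
    ]
    return {
        "n_planted": len(nsun_positions),
        "n_recovered": n_recovered,
        "recall": n_recovered / len(nsun_positions) if nsun_positions else float("nan"),
        "n_artifacts": len(artifact_positions),
        "artifacts_mislabelled_nsun": false_nsun_artifacts,
        "false_nsun_calls": len(false_calls),
    }


# ---------------------------------------------------------------------------
# Ribosome profiling study


@dataclass
class RiboSampleResult:
    genotype: str
    condition: str
    replicate: int
    retained_lengths: set[int]
    frame_table: pd.DataFrame
    psites: PsiteTable  # after first-10-codon removal
    occupancy: pd.DataFrame
    gene_counts: pd.Series
    te: pd.DataFrame
    census: pd.DataFrame  # true per-(transcript, codon) P-site counts
    n_reads: int
    n_aligned: int


@dataclass
class RiboStudy:
    config: SimulationConfig
    ref: ReferenceSet
    cds: pd.DataFrame
    sequences: dict[str, str]
    samples: dict[tuple[str, str, int], RiboSampleResult]

    def occupancies(self, genotype: str, condition: str) -> list[pd.DataFrame]:
        return [
            s.occupancy
            for key, s in sorted(self.samples.items())
            if s.genotype == genotype and s.condition == condition
        ]

    def te_tables(self, genotype: str, condition: str) -> list[pd.DataFrame]:
        return [
            s.te
            for key, s in sorted(self.samples.items())
            if s.genotype == genotype and s.condition == condition
        ]

    def fold_change(self, condition: str = HEAT) -> pd.DataFrame:
        return occupancy_fold_change(
            self.occupancies("noNSUN", condition), self.occupancies("WT", condition)
        )


def run_ribo_study(
    seed: int,
    dwell_multipliers: dict[tuple[str, str, str], float] | None = None,
    conditions: tuple[str, ...] = (HEAT,),
    n_reps: int = 3,
    config: SimulationConfig | None = None,
    min_frame_fraction: float = 0.5,
    depth: int | None = None,
) -> RiboStudy:
    """Simulate, align and analyse the profiling experiment for both genotypes.

    ``dwell_multipliers=None`` gives the uniform-dwell (neutral) experiment;
    the stall experiment plants ``{("noNSUN", "27C", "TTG"): 2.5}``.
    """
    if config is None:
        config = study_config(seed, dwell_multipliers=dict(dwell_multipliers or {}))
    if depth is not None:
        config = config.with_(ribo_depth=depth)
    ref = make_reference(config)
    cds = cds_annotation(ref)
    seqs = cds_sequences(ref)
    aligner = UniqueAligner(ref, bisulfite=False, max_mismatch=0)

    samples: dict[tuple[str, str, int], RiboSampleResult] = {}
    for genotype in ("WT", "noNSUN"):
        for condition in conditions:
            for rep in range(n_reps):
                sample = simulate_ribo_and_rna(ref, config, genotype, condition, rep)
                aln = aligner.align(sample.reads)
                retained, frame_table = periodicity_filter(
                    aln, cds, lengths=sorted(config.rpf_len_dist),
                    min_frame_fraction=min_frame_fraction,
                )
                pst = assign_psites(aln, cds, retained_lengths=retained)
                pst = drop_first_codons(pst)
                occ = codon_occupancy(pst, cds, seqs)
                gocc = gene_occupancy(pst)
                te = translation_efficiency(gocc, sample.rna_counts)
                samples[(genotype, condition, rep)] = RiboSampleResult(
                    genotype=genotype,
                    condition=condition,
                    replicate=rep,
                    retained_lengths=retained,
                    frame_table=frame_table,
                    psites=pst,
                    occupancy=occ,
                    gene_counts=gocc,
                    te=te,
                    census=provenance_codon_census(sample.provenance),
                    n_reads=len(sample.reads),
                    n_aligned=len(aln),
                )
    return RiboStudy(config=config, ref=ref, cds=cds, sequences=seqs, samples=samples)


def stall_dwell() -> dict[tuple[str, str, str], float]:
    return {("noNSUN", HEAT, STALLED_CODON): STALL_MULTIPLIER}


def te_group_analysis(study: RiboStudy, condition: str = HEAT, seed: int = 0) -> dict:
    """Enriched-set TE comparison between genotypes plus a random-set control.

    Returns the UUG-enriched gene set, Welch statistics for the enriched set
    and for a seeded size-matched random set (noNSUN vs WT, per-gene log2 TE
    averaged across replicates).
    """
    enriched, enrich_table = riboprof.codon_enrichment_sets(
        study.sequences, STALLED_CODON, factor=3.0
    )
    te_wt = riboprof.mean_log2_te(study.te_tables("WT", condition))
    te_ko = riboprof.mean_log2_te(study.te_tables("noNSUN", condition))

    def _compare(genes):
        try:
            return {"tested": True, **riboprof.compare_te_between(te_ko, te_wt, genes)}
        except ValueError as exc:
            return {"tested": False, "error": str(exc), "p_value": float("nan")}

    result_enriched = _compare(enriched)
    rng = np.random.default_rng(seed)
    pool = te_wt.index.difference(pd.Index(enriched))
    size = min(max(len(enriched), 3), len(pool))
    random_genes = list(rng.choice(pool.to_numpy(), size=size, replace=False))
    result_random = _compare(random_genes)
    return {
        "enriched_genes": enriched,
        "enrichment_table": enrich_table,
        "enriched": result_enriched,
        "random": result_random,
        "te_wt": te_wt,
        "te_ko": te_ko,
    }


def null_te_rejection_rate(
    study: RiboStudy,
    condition: str = HEAT,
    n_seeds: int = 20,
    set_size: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Calibration of the set-vs-random Welch test under the null: random gene
    sets compared against random controls within one genotype's TE table."""
    te = riboprof.mean_log2_te(study.te_tables("WT", condition)).dropna()
    genes = te.index.to_numpy()
    n_reject = 0
    for i in range(n_seeds):
        rng = np.random.default_rng([seed, i])
        chosen = rng.choice(genes, size=set_size, replace=False)
        result = riboprof.compare_te_groups(
            te, {"null": list(chosen)}, seed=int(rng.integers(2**31))
        )
        p = result.loc["null", "p_value"]
        if result.loc["null", "tested"] and p < alpha:
            n_reject += 1
    return n_reject / n_seeds


def demo_polysome_trace(
    n_points: int = 200, boundary: float = 0.35, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Synthetic sucrose-gradient absorbance trace: a monosome peak followed by
    decaying polysome peaks; returns (x, absorbance, boundary)."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_points)
    y = np.zeros_like(x)
    peaks = [(0.25, 0.035, 1.0)] + [
        (0.42 + 0.11 * k, 0.025, 0.55 * 0.7**k) for k in range(4)
    ]
    for mu, sigma, h in peaks:
        y += h * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    y += 0.01 * rng.random(n_points)
    return x, y, boundary
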