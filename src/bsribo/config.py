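"""Simulation configuration.

A single :class:`SimulationConfig` parameterizes every synthetic dataset:
reference composition, bisulfite chemistry, sequencing-error model, and the
ribosome-profiling generative model (footprint length distribution, frame
jitter, per-codon dwell multipliers, stall-coupled load feedback).

Seed handling: one master seed; every sample draws from an independent,
documented stream (see :func:`stream_rng`) so adding a sample never perturbs
reads generated for earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

GENOTYPES = ("WT", "noNSUN")
CONDITIONS = ("20C", "27C")

#: stage codes for deriving independent RNG streams from the master seed
_STAGES = {
    "reference": 0,
    "plan": 1,
    "bisulfite": 2,
    "ribo": 3,
    "rna": 4,
    "expression": 5,
}
_GENO_CODE = {"WT": 0, "noNSUN": 1}
_COND_CODE = {"20C": 0, "27C": 1}

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in STOP_CODONS
)


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


def _default_rpf_len_dist() -> dict[int, float]:
    # footprint lengths concentrated at 28-29 nt, as in metazoan monosome data
    return {26: 0.10, 27: 0.15, 28: 0.30, 29: 0.25, 30: 0.15, 31: 0.03, 32: 0.02}


@dataclass
class SimulationConfig:
    """All knobs for the synthetic two-genotype experiment.

    Parameters
    ----------
    seed
        Master seed; required, no silent default.
    n_mrna, cds_len_range, utr_len
        mRNA count, CDS length range in codons (start and stop included), and
        flanking UTR length in nt.
    n_trna, trna_len, n_rrna, rrna_len
        Non-coding reference composition. tRNAs always end in CCA and carry
        cytosines at variable-loop positions 48-50 (0-based) so methylation can
        be planted there; the first tRNA is a cytoplasmic Leu-CAA carrying a C
        at the wobble position 33 (0-based; position 34 in tRNA numbering).
    n_codon_biased, biased_codon, biased_codon_freq
        The first ``n_codon_biased`` mRNAs have ``biased_codon`` planted at the
        given per-gene frequency, creating codon-enriched gene sets.
    deamination_rate
        Probability an unmethylated C converts to T under bisulfite; must be in
        the bisulfite regime (> 0.5).
    seq_error_rate
        Uniform substitution error per sequenced base, applied after conversion.
    bs_read_len, bs_depth
        Bisulfite read length (nt) and mean per-base coverage per sample.
    rpf_len_dist, frame_noise, ribo_depth
        Footprint length distribution over 26-32 nt, probability that a
        footprint 5' end is jittered off-frame by +/-1 nt, and total footprints
        per ribosome-profiling sample.
    rna_depth
        Total RNA-seq fragments (or total counts on the fast path) per sample.
    expression_sd_log2
        SD of the log2-normal relative-abundance distribution drawn per
        transcript from the master seed (shared by all samples).
    biol_noise_sd_log2
        SD of per-gene, per-sample log2-normal overdispersion applied
        independently to ribosome loading and RNA abundance (replicate
        variability beyond counting noise).
    dwell_multipliers
        Map (genotype, condition, codon) -> relative dwell; absent keys mean 1.
    te_feedback
        Curvature g of the stall-coupled output loss: a gene's total footprint
        load scales as 2**(-g * log2(mean codon dwell)**2) relative to its RNA
        abundance, while the within-gene footprint distribution stays
        proportional to per-codon dwell. The quadratic form mimics ribosome
        queueing, where mild slowdowns are buffered by initiation limitation
        but concentrated stalling collapses output superlinearly. 0 keeps gene
        totals neutral to planted stalls (local redistribution only).
    """

    seed: int
    n_mrna: int = 60
    cds_len_range: tuple[int, int] = (120, 180)
    utr_len: int = 60
    n_trna: int = 20
    trna_len: int = 75
    n_rrna: int = 2
    rrna_len: int = 500
    gc_content: float = 0.5
    n_codon_biased: int = 10
    biased_codon: str = "TTG"
    biased_codon_freq: float = 0.09
    deamination_rate: float = 0.99
    seq_error_rate: float = 0.002
    bs_read_len: int = 50
    bs_depth: float = 50.0
    rpf_len_dist: dict[int, float] = field(default_factory=_default_rpf_len_dist)
    frame_noise: float = 0.05
    ribo_depth: int = 200_000
    rna_depth: int = 400_000
    expression_sd_log2: float = 0.8
    biol_noise_sd_log2: float = 0.1
    dwell_multipliers: dict[tuple[str, str, str], float] = field(default_factory=dict)
    te_feedback: float = 10.0
    expression_levels: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required and has no default")
        probs = {
            "deamination_rate": self.deamination_rate,
            "seq_error_rate": self.seq_error_rate,
            "frame_noise": self.frame_noise,
            "gc_content": self.gc_content,
            "biased_codon_freq": self.biased_codon_freq,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.deamination_rate <= 0.5:
            raise ConfigError(
                "deamination_rate must exceed 0.5 (bisulfite conversion regime)"
            )
        lo, hi = self.cds_len_range
        if lo < 12:
            raise ConfigError(
                "cds_len_range below 12 codons: the first-10-codon exclusion "
                "would leave no analysable codons"
            )
        if hi < lo:
            raise ConfigError("cds_len_range must be (low, high) with low <= high")
        total = sum(self.rpf_len_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"rpf_len_dist sums to {total}, expected 1")
        if not all(26 <= length <= 32 for length in self.rpf_len_dist):
            raise ConfigError("rpf_len_dist lengths must lie in 26-32 nt")
        for key, mult in self.dwell_multipliers.items():
            if mult <= 0:
                raise ConfigError(f"dwell multiplier {key} must be > 0, got {mult}")
            geno, cond, codon = key
            if geno not in GENOTYPES or cond not in CONDITIONS:
                raise ConfigError(f"unknown genotype/condition in dwell key {key}")
            if codon not in SENSE_CODONS:
                raise ConfigError(f"dwell key {key}: {codon} is not a sense codon")
        if self.biased_codon not in SENSE_CODONS:
            raise ConfigError(f"biased_codon {self.biased_codon} is not a sense codon")
        if self.expression_levels is not None and len(self.expression_levels) != (
            self.n_mrna + self.n_trna + self.n_rrna
        ):
            raise ConfigError("expression_levels length must match transcript count")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def dwell(self, genotype: str, condition: str, codon: str) -> float:
        return self.dwell_multipliers.get((genotype, condition, codon), 1.0)


def stream_rng(
    seed: int,
    stage: str,
    genotype: str = "WT",
    condition: str = "20C",
    replicate: int = 0,
) -> np.random.Generator:
    """Derive the RNG stream for one (stage, sample) from the master seed.

    The stream key is the tuple (seed, stage code, genotype code, condition
    code, replicate); streams are therefore independent and stable — adding a
    replicate or sample never changes the draws of an existing one.
    """
    key = (
        int(seed),
        _STAGES[stage],
        _GENO_CODE[genotype],
        _COND_CODE[condition],
        int(replicate),
    )
    return np.random.default_rng(key)


def config_from_mapping(mapping: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed YAML/JSON mapping.

    ``dwell_multipliers`` may be given as a list of
    ``{genotype, condition, codon, multiplier}`` records (YAML cannot express
    tuple keys); ``rpf_len_dist`` keys are coerced to int.
    """
    data = dict(mapping)
    unknown = set(data) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    if "cds_len_range" in data:
        data["cds_len_range"] = tuple(data["cds_len_range"])
    if "rpf_len_dist" in data:
        data["rpf_len_dist"] = {int(k): float(v) for k, v in data["rpf_len_dist"].items()}
    if "dwell_multipliers" in data and isinstance(data["dwell_multipliers"], list):
        data["dwell_multipliers"] = {
            (rec["genotype"], rec["condition"], rec["codon"]): float(rec["multiplier"])
            for rec in data["dwell_multipliers"]
        }
    if "seed" not in data:
        raise ConfigError("config missing required key: seed")
    return SimulationConfig(**data)
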