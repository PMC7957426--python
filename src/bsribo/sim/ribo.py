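"""Ribosome-profiling and RNA-seq simulation.

Generative model
----------------
A footprint's P-site is sampled over (gene, sense codon) with probability
proportional to

    expression[gene] * noise[gene, sample] * scale(gene) * dwell[codon]

where ``dwell`` is the per-codon relative dwell time for the sample's
(genotype, condition) and ``scale(gene)`` implements stall-coupled load
reduction: slow codons locally accumulate ribosomes (within-gene density
∝ dwell) while concentrated stalling reduces the transcript's total ribosome
load (queueing, drop-off, initiation down-regulation). A gene's footprint
total scales as ``2**(-g * log2(mean_dwell)**2)`` relative to its RNA
abundance — quadratic in the log slowdown, so genes with only background
levels of a slowed codon are essentially untouched while codon-enriched
genes lose output superlinearly (``g`` is ``te_feedback``). With uniform
dwell the model reduces to load ∝ expression × CDS length, the neutral case.

The footprint 5' end is placed 12 nt upstream of the P-site first nucleotide,
its length drawn from ``rpf_len_dist``; with probability ``frame_noise`` the
5' end is re-drawn uniformly over the frame offsets {-1, 0, +1}. RNA-seq abundance is independent of
dwell and may be emitted as true counts (fast path) or as uniform fragment
reads (full path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import CONDITIONS, GENOTYPES, SimulationConfig, stream_rng
from .reference import ReferenceSet, expression_levels

PSITE_OFFSET = 12  # nt from footprint 5' end to the P-site first nucleotide


@dataclass
class RiboSample:
    """One profiling sample: footprint reads, their provenance, RNA abundance."""

    reads: list[tuple[str, str]]
    provenance: pd.DataFrame
    rna_counts: pd.Series  # per gene; fast path
    rna_reads: list[tuple[str, str]] | None = None  # full path only

    def as_dict(self) -> dict[str, str]:
        return dict(self.reads)


def _gene_codon_model(
    ref: ReferenceSet, config: SimulationConfig, genotype: str, condition: str
):
    """Per-gene sense-codon identities and dwell vectors."""
    genes = []
    for t in ref.mrnas:
        cds = ref.cds_sequence(t.id)
        n_codons = len(cds) // 3
        codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons - 1)]  # excl. stop
        dwell = np.array(
            [config.dwell(genotype, condition, c) for c in codons], dtype=float
        )
        genes.append((t, codons, dwell))
    return genes


def simulate_ribo_and_rna(
    ref: ReferenceSet,
    config: SimulationConfig,
    genotype: str,
    condition: str,
    replicate: int = 0,
    rna_mode: str = "counts",
) -> RiboSample:
    """Simulate one ribosome-profiling sample plus its matched RNA-seq.

    ``rna_mode`` is ``"counts"`` (true per-gene counts, fast path) or
    ``"reads"`` (uniform fragments emitted as read tuples, full path).
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if rna_mode not in ("counts", "reads"):
        raise ValueError("rna_mode must be 'counts' or 'reads'")

    rng = stream_rng(config.seed, "ribo", genotype, condition, replicate)
    expr = expression_levels(config, ref)
    genes = _gene_codon_model(ref, config, genotype, condition)
    if not genes:
        raise ValueError("reference contains no mRNAs")

    # flattened (gene, codon) sampling weights
    weights = []
    index = []  # (transcript, cds_start, codon_index)
    for t, codons, dwell in genes:
        noise = 2.0 ** rng.normal(0.0, config.biol_noise_sd_log2)
        # gene footprint total ∝ 2**(-g*log2(mean_dwell)**2); the extra 1/mean
        # cancels the within-gene dwell sum (n_codons * mean_dwell)
        log2_mean = np.log2(float(dwell.mean()))
        scale = 2.0 ** (-config.te_feedback * log2_mean**2 - log2_mean)
        w = expr[t.id] * noise * scale * dwell
        weights.append(w)
        index.extend((t.id, t.cds[0], ci) for ci in range(len(codons)))
    w_flat = np.concatenate(weights)
    p = w_flat / w_flat.sum()
    counts = rng.multinomial(config.ribo_depth, p)

    lens = np.array(sorted(config.rpf_len_dist), dtype=int)
    len_p = np.array([config.rpf_len_dist[int(l)] for l in lens], dtype=float)
    len_p = len_p / len_p.sum()

    sample = f"RPF-{genotype}-{condition}-rep{replicate}"
    reads: list[tuple[str, str]] = []
    prov_rows: list[tuple] = []
    serial = 0
    seqs = {t.id: t.sequence for t in ref.mrnas}

    for flat_i in np.flatnonzero(counts):
        tid, cds_start, ci = index[flat_i]
        n = int(counts[flat_i])
        psite_nt = cds_start + 3 * ci
        # with probability frame_noise the 5' end lands uniformly on one of the
        # three frame offsets {-1, 0, +1}; the expected modal-frame fraction is
        # therefore (1 - frame_noise) + frame_noise / 3
        jitter = np.zeros(n, dtype=int)
        off = rng.random(n) < config.frame_noise
        if off.any():
            jitter[off] = rng.choice([-1, 0, 1], size=int(off.sum()))
        read_lens = lens[rng.choice(len(lens), size=n, p=len_p)]
        seq = seqs[tid]
        for j in range(n):
            five = psite_nt - PSITE_OFFSET + int(jitter[j])
            L = int(read_lens[j])
            if five < 0 or five + L > len(seq):
                raise ValueError(
                    f"footprint out of transcript bounds on {tid}; increase utr_len"
                )
            rid = f"{sample}:{serial}"
            serial += 1
            reads.append((rid, seq[five : five + L]))
            prov_rows.append((rid, tid, five, L, ci, genotype, condition, replicate))

    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "read_id",
            "transcript",
            "five_prime",
            "length",
            "psite_codon",
            "genotype",
            "condition",
            "replicate",
        ],
    )

    # RNA-seq: abundance independent of dwell
    rng_rna = stream_rng(config.seed, "rna", genotype, condition, replicate)
    mrnas = ref.mrnas
    rna_w = np.array(
        [
            expr[t.id]
            * len(t.sequence)
            * 2.0 ** rng_rna.normal(0.0, config.biol_noise_sd_log2)
            for t in mrnas
        ]
    )
    rna_p = rna_w / rna_w.sum()
    rna_n = rng_rna.multinomial(config.rna_depth, rna_p)
    gene_of = {t.id: t.gene for t in mrnas}
    rna_counts = pd.Series(
        rna_n, index=[gene_of[t.id] for t in mrnas], name="rna_count", dtype=int
    )

    rna_reads = None
    if rna_mode == "reads":
        rna_reads = []
        rl = config.bs_read_len  # reuse the short-read length for RNA fragments
        for t, n in zip(mrnas, rna_n):
            L = len(t.sequence)
            if L < rl:
                continue
            starts = rng_rna.integers(0, L - rl + 1, size=int(n))
            for k, s in enumerate(starts):
                rna_reads.append(
                    (f"RNA-{genotype}-{condition}-rep{replicate}:{t.id}:{k}",
                     t.sequence[int(s) : int(s) + rl])
                )

    return RiboSample(
        reads=reads, provenance=provenance, rna_counts=rna_counts, rna_reads=rna_reads
    )


def provenance_codon_census(provenance: pd.DataFrame) -> pd.DataFrame:
    """True per-(transcript, codon) P-site counts from provenance (the oracle)."""
    out = (
        provenance.groupby(["transcript", "psite_codon"])
        .size()
        .rename("count")
        .reset_index()
    )
    return out.rename(columns={"psite_codon": "codon_index"})
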