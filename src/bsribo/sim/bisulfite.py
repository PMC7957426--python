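"""Bisulfite read simulation.

The generative inverse of the deamination-rate estimate: every unmethylated
cytosine on a molecule converts C->T with probability ``deamination_rate``;
each molecule's methylation state at a planted site is an independent
Bernoulli(stoichiometry) draw, and methylated cytosines are protected.
Sequencing errors (uniform substitutions) are applied after conversion.
RNA bisulfite chemistry is strand-preserving, so only sense-strand fragments
are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import GENOTYPES, SimulationConfig, stream_rng
from .methylation import MethylationPlan, effective_stoichiometry
from .reference import ReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadSet:
    """Reads plus one provenance record per read (the oracle)."""

    reads: list[tuple[str, str]]
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.provenance):
            raise ValueError("one provenance record per emitted read is required")

    def as_dict(self) -> dict[str, str]:
        return dict(self.reads)


def simulate_bisulfite_reads(
    ref: ReferenceSet,
    plan: MethylationPlan,
    genotype: str,
    config: SimulationConfig,
    replicate: int = 0,
) -> ReadSet:
    """Simulate one bisulfite library for one genotype replicate.

    Fragments are fixed-length and uniform over each transcript; the number of
    reads per transcript is Poisson with mean ``bs_depth * len / read_len``
    (mean per-base coverage ``bs_depth``). Transcripts shorter than the read
    length are skipped. Provenance records the molecule-level methylation state
    of every planted site covered by the read.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}, got {genotype!r}")
    rng = stream_rng(config.seed, "bisulfite", genotype, replicate=replicate)
    d = config.deamination_rate
    e = config.seq_error_rate
    rl = config.bs_read_len
    sites_by_t = plan.by_transcript()

    reads: list[tuple[str, str]] = []
    prov: list[dict] = []
    serial = 0
    sample = f"BS-{genotype}-rep{replicate}"

    for t in ref.transcripts:
        L = len(t.sequence)
        if L < rl:
            continue
        n_reads = int(rng.poisson(config.bs_depth * L / rl))
        if n_reads == 0:
            continue
        seq_arr = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
        c_mask = seq_arr == ord("C")
        t_sites = sites_by_t.get(t.id, [])
        site_pos = np.array([s.position for s in t_sites], dtype=int)
        site_p = np.array(
            [effective_stoichiometry(s, genotype) for s in t_sites], dtype=float
        )
        starts = rng.integers(0, L - rl + 1, size=n_reads)
        for start in starts:
            frag = seq_arr[start : start + rl].copy()
            # methylation state of covered planted sites (per molecule)
            meth_state: dict[int, int] = {}
            if len(site_pos):
                covered = (site_pos >= start) & (site_pos < start + rl)
                for pos, p in zip(site_pos[covered], site_p[covered]):
                    meth_state[int(pos)] = int(rng.random() < p)
            # conversion of unmethylated cytosines
            c_idx = np.flatnonzero(c_mask[start : start + rl])
            if len(c_idx):
                convert = rng.random(len(c_idx)) < d
                for j, conv in zip(c_idx, convert):
                    pos = int(start) + int(j)
                    if meth_state.get(pos, 0) == 1:
                        continue  # protected
                    if conv:
                        frag[j] = ord("T")
            # sequencing errors after conversion
            if e > 0:
                err_idx = np.flatnonzero(rng.random(rl) < e)
                for j in err_idx:
                    alt = _BASES[_BASES != frag[j]]
                    frag[j] = alt[int(rng.integers(3))]
            rid = f"{sample}:{serial}"
            serial += 1
            reads.append((rid, frag.tobytes().decode()))
            prov.append(
                {
                    "read_id": rid,
                    "transcript": t.id,
                    "start": int(start),
                    "genotype": genotype,
                    "replicate": replicate,
                    "meth_states": ";".join(
                        f"{p}:{s}" for p, s in sorted(meth_state.items())
                    ),
                }
            )

    provenance = pd.DataFrame(
        prov,
        columns=["read_id", "transcript", "start", "genotype", "replicate", "meth_states"],
    )
    return ReadSet(reads=reads, provenance=provenance)
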