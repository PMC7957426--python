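"""Synthetic reference transcriptome.

One transcript per gene by construction: mRNAs with UTR-flanked CDSs free of
internal stop codons, CCA-ended tRNAs with cytosines guaranteed at the
variable-loop positions (48-50, 0-based) and — for the designated Leu-CAA
tRNA — at the wobble position 33, plus nuclear and mitochondrial rRNAs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ..config import STOP_CODONS, ConfigError, SimulationConfig, stream_rng

MRNA = "mRNA"
TRNA = "tRNA"
RRNA = "rRNA"
MT_TRNA = "mt-tRNA"
MT_RRNA = "mt-rRNA"

#: amino-acid / anticodon cycle used to name tRNA isoacceptors. The first
#: entry is the Leu-CAA that carries the wobble-position cytosine.
_TRNA_FAMILIES = [
    ("Leu", "CAA"),
    ("Pro", "TGG"),
    ("Ser", "AGA"),
    ("Gly", "GCC"),
    ("Ala", "AGC"),
    ("Val", "AAC"),
    ("Thr", "AGT"),
    ("Arg", "ACG"),
    ("Lys", "CTT"),
    ("Glu", "TTC"),
]


@dataclass(frozen=True)
class Transcript:
    id: str
    ref_class: str
    sequence: str
    gene: str
    cds: tuple[int, int] | None = None  # 0-based half-open, mRNA only

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValueError("transcript ids must be unique")
        for t in self.transcripts:
            if not t.sequence:
                raise ValueError(f"{t.id}: empty sequence")
            if (t.cds is not None) != (t.ref_class == MRNA):
                raise ValueError(f"{t.id}: CDS present iff class is mRNA")
            if t.cds is not None and (t.cds[1] - t.cds[0]) % 3 != 0:
                raise ValueError(f"{t.id}: CDS length not a multiple of 3")

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, tid: str) -> Transcript:
        return self._by_id()[tid]

    def _by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}

    def by_class(self, *classes: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.ref_class in classes]

    @property
    def mrnas(self) -> list[Transcript]:
        return self.by_class(MRNA)

    def cds_sequence(self, tid: str) -> str:
        t = self[tid]
        if t.cds is None:
            raise ValueError(f"{tid} has no CDS")
        return t.sequence[t.cds[0] : t.cds[1]]

    def c_positions(self, tid: str) -> np.ndarray:
        seq = np.frombuffer(self[tid].sequence.encode(), dtype=np.uint8)
        return np.flatnonzero(seq == ord("C"))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _random_sense_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = bytes(_random_bases(rng, 3, gc)).decode()
        if codon not in STOP_CODONS:
            return codon


def make_reference(config: SimulationConfig) -> ReferenceSet:
    """Generate the synthetic transcriptome (deterministic given the seed).

    mRNA CDSs start with ATG, end with a stop codon and contain no internal
    stops; the first ``n_codon_biased`` mRNAs carry ``biased_codon`` at an
    elevated per-gene frequency. The last tRNA and last rRNA are labelled
    mitochondrial so both genome compartments are represented.
    """
    config.validate()
    rng = stream_rng(config.seed, "reference")
    gc = config.gc_content
    transcripts: list[Transcript] = []

    lo, hi = config.cds_len_range
    for i in range(config.n_mrna):
        n_codons = int(rng.integers(lo, hi + 1))
        biased = i < config.n_codon_biased
        codons = ["ATG"]
        for _ in range(n_codons - 2):
            if biased and rng.random() < config.biased_codon_freq:
                codons.append(config.biased_codon)
            else:
                codons.append(_random_sense_codon(rng, gc))
        codons.append(STOP_CODONS[int(rng.integers(len(STOP_CODONS)))])
        cds = "".join(codons)
        utr5 = bytes(_random_bases(rng, config.utr_len, gc)).decode()
        utr3 = bytes(_random_bases(rng, config.utr_len, gc)).decode()
        gene = f"gene-{i + 1:04d}"
        transcripts.append(
            Transcript(
                id=f"mRNA-{i + 1:04d}",
                ref_class=MRNA,
                sequence=utr5 + cds + utr3,
                gene=gene,
                cds=(config.utr_len, config.utr_len + len(cds)),
            )
        )

    families = itertools.cycle(_TRNA_FAMILIES)
    for i in range(config.n_trna):
        aa, anticodon = next(families)
        body = bytearray(bytes(_random_bases(rng, config.trna_len - 3, gc)))
        for pos in (48, 49, 50):  # variable-loop cytosines
            if pos < len(body):
                body[pos] = ord("C")
        if i == 0:
            body[33] = ord("C")  # wobble position 34 (1-based) of Leu-CAA
        seq = body.decode() + "CCA"
        mito = i == config.n_trna - 1 and config.n_trna > 1
        prefix = "mt-tRNA" if mito else "tRNA"
        if mito:
            aa, anticodon = "Met", "CAT"
        tid = f"{prefix}-{aa}-{anticodon}-{i + 1}"
        transcripts.append(
            Transcript(
                id=tid,
                ref_class=MT_TRNA if mito else TRNA,
                sequence=seq,
                gene=tid,
            )
        )

    rrna_names = ["18S", "26S", "5.8S", "5S"]
    for i in range(config.n_rrna):
        mito = i == config.n_rrna - 1 and config.n_rrna > 1
        name = "mt-rRNA-12S" if mito else f"rRNA-{rrna_names[i % len(rrna_names)]}"
        seq = bytes(_random_bases(rng, config.rrna_len, gc)).decode()
        transcripts.append(
            Transcript(
                id=name,
                ref_class=MT_RRNA if mito else RRNA,
                sequence=seq,
                gene=name,
            )
        )

    ref = ReferenceSet(transcripts)
    _check_no_internal_stops(ref)
    return ref


def _check_no_internal_stops(ref: ReferenceSet) -> None:
    for t in ref.mrnas:
        cds = ref.cds_sequence(t.id)
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons[0] != "ATG":
            raise ConfigError(f"{t.id}: CDS does not start with ATG")
        if codons[-1] not in STOP_CODONS:
            raise ConfigError(f"{t.id}: CDS does not end with a stop codon")
        if any(c in STOP_CODONS for c in codons[:-1]):
            raise ConfigError(f"{t.id}: internal stop codon")


def expression_levels(config: SimulationConfig, ref: ReferenceSet) -> dict[str, float]:
    """Relative abundance per transcript, shared by every sample.

    Drawn log2-normal from the master seed unless fixed in the config.
    """
    if config.expression_levels is not None:
        return {t.id: x for t, x in zip(ref.transcripts, config.expression_levels)}
    rng = stream_rng(config.seed, "expression")
    levels = 2.0 ** rng.normal(0.0, config.expression_sd_log2, size=len(ref))
    return {t.id: float(x) for t, x in zip(ref.transcripts, levels)}
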