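"""Standard-format I/O: FASTA / FASTQ via Biopython, BED-like CDS tables,
TSV reports (gzip-capable via the ``.gz`` suffix)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sim.reference import MRNA, ReferenceSet, Transcript


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fasta(ref: ReferenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=f"class={t.ref_class} gene={t.gene}")
        for t in ref.transcripts
    ]
    with _open_text(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_cds_bed(ref: ReferenceSet, path: str | Path) -> None:
    """BED-like 4-column CDS file: transcript, cds_start, cds_end, gene
    (0-based half-open)."""
    with _open_text(path, "w") as fh:
        for t in ref.mrnas:
            fh.write(f"{t.id}\t{t.cds[0]}\t{t.cds[1]}\t{t.gene}\n")


def read_reference(fasta_path: str | Path, cds_bed_path: str | Path | None = None) -> ReferenceSet:
    """Load a reference FASTA (class taken from the ``class=`` description tag,
    default mRNA) plus an optional CDS BED file."""
    cds: dict[str, tuple[int, int]] = {}
    genes: dict[str, str] = {}
    if cds_bed_path is not None:
        with _open_text(cds_bed_path, "r") as fh:
            for line in fh:
                tid, start, end, gene = line.rstrip("\n").split("\t")[:4]
                cds[tid] = (int(start), int(end))
                genes[tid] = gene
    transcripts = []
    with _open_text(fasta_path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            tags = dict(
                kv.split("=", 1) for kv in rec.description.split() if "=" in kv
            )
            ref_class = tags.get("class", MRNA)
            transcripts.append(
                Transcript(
                    id=rec.id,
                    ref_class=ref_class,
                    sequence=str(rec.seq).upper(),
                    gene=genes.get(rec.id, tags.get("gene", rec.id)),
                    cds=cds.get(rec.id),
                )
            )
    return ReferenceSet(transcripts)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (id, sequence) tuples as FASTQ with uniform quality."""
    n = 0
    with _open_text(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path, "r") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_cytosine_report_tsv(report: pd.DataFrame, path: str | Path) -> None:
    """Export a cytosine report with 1-based inclusive positions."""
    out = report.copy()
    out["position"] = out["position"] + 1
    with _open_text(path, "w") as fh:
        fh.write("# positions are 1-based inclusive\n")
        out.to_csv(fh, sep="\t", index=False)


def read_cytosine_report_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["position"] = df["position"] - 1
    return df


def write_sam(
    alignments: pd.DataFrame,
    reads: dict[str, str] | Iterable[tuple[str, str]],
    refs: ReferenceSet,
    path: str | Path,
) -> None:
    """Export alignments as plain-text SAM for inspection (flag 0, ungapped
    CIGAR; mismatch count in the NM tag)."""
    read_map = dict(reads) if not isinstance(reads, dict) else reads
    with _open_text(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for t in refs.transcripts:
            fh.write(f"@SQ\tSN:{t.id}\tLN:{len(t.sequence)}\n")
        for row in alignments.itertuples():
            seq = read_map[row.read_id]
            fh.write(
                f"{row.read_id}\t0\t{row.transcript}\t{row.start + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t{'I' * len(seq)}\tNM:i:{row.mismatches}\n"
            )
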