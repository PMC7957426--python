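"""Reference preparation and unique read alignment in bisulfite space.

The aligner is an exact seed-and-verify scan over the (desk-scale)
transcriptome. The contract is what matters: a read is retained only when it
has exactly one best-scoring location; ties are discarded, never broken. In
bisulfite mode matching is asymmetric in the standard three-letter sense — a
read T matches a reference C (conversion), but a read C does not match a
reference T.

Seeding uses the pigeonhole principle: a read with at most ``max_mismatch``
mismatches is split into ``max_mismatch + 1`` segments, at least one of which
matches the reference exactly in C->T-collapsed space (collapsed mismatches
are a subset of asymmetric mismatches), so no qualifying location is missed
and tie detection is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim.reference import ReferenceSet, Transcript

_COLLAPSE = bytes.maketrans(b"C", b"T")

ALIGNMENT_COLUMNS = ["read_id", "transcript", "start", "mismatches", "length"]


def append_cca(trna_sequence: str) -> str:
    """Append the 3' CCA end to a tRNA sequence if it is missing (idempotent)."""
    if any(b not in "ACGT" for b in trna_sequence):
        raise ValueError("sequence must be over {A,C,G,T}")
    if trna_sequence.endswith("CCA"):
        return trna_sequence
    return trna_sequence + "CCA"


def collapse_ct(seq: str) -> str:
    """Collapse a sequence to bisulfite space (every C becomes T)."""
    return seq.translate(str.maketrans("C", "T"))


def merge_bisulfite_identical(
    refs: ReferenceSet,
) -> tuple[ReferenceSet, dict[str, str]]:
    """Merge reference sequences identical after C->T collapse.

    At each position of a merged group the representative keeps C whenever any
    member carries C (the C polymorphism is kept, so methylation at either
    allele remains observable). Returns the reduced reference set and a map
    member id -> representative id for every member of a merged group.
    """
    groups: dict[str, list[Transcript]] = {}
    order: list[str] = []
    for t in refs.transcripts:
        key = collapse_ct(t.sequence)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(t)

    merged: list[Transcript] = []
    merge_map: dict[str, str] = {}
    for key in order:
        members = groups[key]
        rep = members[0]
        if len(members) == 1:
            merged.append(rep)
            continue
        consensus = bytearray(rep.sequence.encode())
        for m in members[1:]:
            for i, b in enumerate(m.sequence.encode()):
                if b == ord("C"):
                    consensus[i] = ord("C")
        merged.append(
            Transcript(
                id=rep.id,
                ref_class=rep.ref_class,
                sequence=consensus.decode(),
                gene=rep.gene,
                cds=rep.cds,
            )
        )
        for m in members:
            merge_map[m.id] = rep.id
    return ReferenceSet(merged), merge_map


@dataclass
class _IndexedTranscript:
    id: str
    seq: bytes
    collapsed: bytes


class UniqueAligner:
    """Seed-and-verify unique aligner over a transcript set.

    Parameters
    ----------
    refs : ReferenceSet
    bisulfite : bool
        Use asymmetric C/T matching (read T ~ reference C).
    max_mismatch : int
        Maximum mismatches (in asymmetric space when ``bisulfite``).
    min_read_len : int
        Reads shorter than this are dropped up front.
    """

    def __init__(
        self,
        refs: ReferenceSet,
        bisulfite: bool = False,
        max_mismatch: int = 2,
        min_read_len: int = 15,
    ) -> None:
        if len(refs) == 0:
            raise ValueError("empty reference set")
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.bisulfite = bisulfite
        self.max_mismatch = max_mismatch
        self.min_read_len = min_read_len
        self._transcripts = [
            _IndexedTranscript(
                id=t.id,
                seq=t.sequence.encode(),
                collapsed=t.sequence.encode().translate(_COLLAPSE),
            )
            for t in refs.transcripts
        ]
        self._max_tlen = max(len(t.seq) for t in self._transcripts)
        self._indexes: dict[int, dict[bytes, list[tuple[int, int]]]] = {}

    def _index_for(self, k: int) -> dict[bytes, list[tuple[int, int]]]:
        idx = self._indexes.get(k)
        if idx is None:
            idx = {}
            for ti, t in enumerate(self._transcripts):
                ref = t.collapsed if self.bisulfite else t.seq
                for pos in range(len(ref) - k + 1):
                    idx.setdefault(ref[pos : pos + k], []).append((ti, pos))
            self._indexes[k] = idx
        return idx

    def _mismatches(self, read: bytes, ti: int, start: int, limit: int) -> int:
        t = self._transcripts[ti]
        window = t.seq[start : start + len(read)]
        if not self.bisulfite:
            if read == window:
                return 0
            mm = 0
            for r, s in zip(read, window):
                if r != s:
                    mm += 1
                    if mm > limit:
                        return mm
            return mm
        cwindow = t.collapsed[start : start + len(read)]
        cread = read.translate(_COLLAPSE)
        if cread == cwindow:
            # only possible mismatches: read C over reference T
            mm = 0
            ci = read.find(ord("C"))
            while ci != -1:
                if window[ci] == ord("T"):
                    mm += 1
                    if mm > limit:
                        return mm
                ci = read.find(ord("C"), ci + 1)
            return mm
        mm = 0
        for r, s in zip(read, window):
            if r == s or (r == ord("T") and s == ord("C")):
                continue
            mm += 1
            if mm > limit:
                return mm
        return mm

    def align(self, reads: list[tuple[str, str]]) -> pd.DataFrame:
        """Align reads; return retained unique-best alignments.

        Reads with two or more equally good best locations are discarded.
        Reads longer than every transcript are dropped with a warning.
        """
        if not reads:
            raise ValueError("no reads to align")
        mm_max = self.max_mismatch
        rows: list[tuple] = []
        n_too_long = 0
        for rid, seq in reads:
            L = len(seq)
            if L < self.min_read_len:
                continue
            if L > self._max_tlen:
                n_too_long += 1
                continue
            read = seq.encode()
            query = read.translate(_COLLAPSE) if self.bisulfite else read
            k = max(1, L // (mm_max + 1))
            index = self._index_for(k)
            candidates: set[tuple[int, int]] = set()
            for seg in range(mm_max + 1):
                off = seg * k
                for ti, pos in index.get(query[off : off + k], ()):
                    start = pos - off
                    if 0 <= start <= len(self._transcripts[ti].seq) - L:
                        candidates.add((ti, start))
            best_mm = mm_max + 1
            best_loc = None
            n_best = 0
            for ti, start in candidates:
                mm = self._mismatches(read, ti, start, best_mm)
                if mm < best_mm:
                    best_mm, best_loc, n_best = mm, (ti, start), 1
                elif mm == best_mm:
                    n_best += 1
            if best_loc is not None and n_best == 1 and best_mm <= mm_max:
                ti, start = best_loc
                rows.append((rid, self._transcripts[ti].id, start, best_mm, L))
        if n_too_long:
            warnings.warn(
                f"dropped {n_too_long} reads longer than every reference transcript",
                stacklevel=2,
            )
        return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def align_unique(
    reads: list[tuple[str, str]],
    refs: ReferenceSet,
    max_mismatch: int = 2,
    bisulfite_mode: bool = False,
    min_read_len: int = 15,
) -> pd.DataFrame:
    """One-shot convenience wrapper around :class:`UniqueAligner`."""
    aligner = UniqueAligner(
        refs,
        bisulfite=bisulfite_mode,
        max_mismatch=max_mismatch,
        min_read_len=min_read_len,
    )
    return aligner.align(reads)


CYTOSINE_REPORT_COLUMNS = [
    "transcript",
    "position",
    "coverage",
    "nonconverted",
    "converted",
    "other",
]


def pileup_cytosines(
    alignments: pd.DataFrame,
    reads: dict[str, str] | list[tuple[str, str]],
    refs: ReferenceSet,
) -> pd.DataFrame:
    """Per-cytosine conversion pileup over reference C positions.

    A read base C at a reference C increments ``nonconverted``, T increments
    ``converted``; any other base increments ``other`` and is excluded from
    coverage (it is a sequencing error, not conversion evidence). Every
    reference C position appears in the report, including uncovered ones.
    Positions are 0-based here; TSV export is 1-based.
    """
    read_map = dict(reads) if not isinstance(reads, dict) else reads
    per_t: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    counts: dict[str, np.ndarray] = {}
    for t in refs.transcripts:
        cpos = refs.c_positions(t.id)
        per_t[t.id] = (cpos, np.frombuffer(t.sequence.encode(), dtype=np.uint8))
        counts[t.id] = np.zeros((3, len(cpos)), dtype=np.int64)  # nonconv, conv, other

    for rid, tid, start, length in alignments[
        ["read_id", "transcript", "start", "length"]
    ].itertuples(index=False):
        cpos, ref_arr = per_t[tid]
        if start < 0 or start + length > len(ref_arr):
            raise ValueError(f"alignment of {rid} beyond bounds of {tid}")
        lo = np.searchsorted(cpos, start)
        hi = np.searchsorted(cpos, start + length)
        if lo == hi:
            continue
        seq = read_map[rid]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        bases = arr[cpos[lo:hi] - start]
        cnt = counts[tid]
        idx = np.arange(lo, hi)
        cnt[0, idx[bases == ord("C")]] += 1
        cnt[1, idx[bases == ord("T")]] += 1
        cnt[2, idx[(bases != ord("C")) & (bases != ord("T"))]] += 1

    frames = []
    for t in refs.transcripts:
        cpos, _ = per_t[t.id]
        if len(cpos) == 0:
            continue
        cnt = counts[t.id]
        frames.append(
            pd.DataFrame(
                {
                    "transcript": t.id,
                    "position": cpos,
                    "coverage": cnt[0] + cnt[1],
                    "nonconverted": cnt[0],
                    "converted": cnt[1],
                    "other": cnt[2],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CYTOSINE_REPORT_COLUMNS]


def nonconversion_ratio(report: pd.DataFrame) -> pd.Series:
    """Non-conversion ratio per row; NaN where coverage is 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = report["nonconverted"] / report["coverage"]
    return ratio.where(report["coverage"] > 0)
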