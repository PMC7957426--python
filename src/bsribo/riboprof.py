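"""Ribosome-profiling analysis.

Footprint 5' ends are checked for 3-nt periodicity per read length; retained
reads are shifted +12 nt to the P-site first nucleotide, reads landing in the
first 10 codons of a CDS are removed, and per-codon P-site counts are
normalised by the counts of the same codon in the +1, +2 and +3 codons
relative to the A-site (A-site = P-site + 3 nt, so nucleotide offsets +6, +9,
+12 from the P-site first nucleotide). Downstream: codon fold changes between
genotypes, per-gene translation efficiency (CPM footprints / CPM mRNA),
codon-enrichment gene sets, stall profiles along single genes, and the
polysomal fraction of a gradient absorbance trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SENSE_CODONS, STOP_CODONS
from .sim.reference import ReferenceSet

PSITE_SHIFT_DEFAULT = 12
FIRST_CODONS_DROPPED = 10


# ---------------------------------------------------------------------------
# CDS annotation


def cds_annotation(ref: ReferenceSet) -> pd.DataFrame:
    """Per-gene CDS table: transcript, cds_start, cds_end, n_codons (one
    transcript per gene)."""
    rows = [
        {
            "gene": t.gene,
            "transcript": t.id,
            "cds_start": t.cds[0],
            "cds_end": t.cds[1],
            "n_codons": (t.cds[1] - t.cds[0]) // 3,
        }
        for t in ref.mrnas
    ]
    df = pd.DataFrame(rows, columns=["gene", "transcript", "cds_start", "cds_end", "n_codons"])
    if df["gene"].duplicated().any():
        raise ValueError("one transcript per gene is required")
    return df


def cds_sequences(ref: ReferenceSet) -> dict[str, str]:
    """Gene -> CDS nucleotide sequence."""
    return {t.gene: ref.cds_sequence(t.id) for t in ref.mrnas}


# ---------------------------------------------------------------------------
# Periodicity gating and P-site assignment


def periodicity_filter(
    alignments: pd.DataFrame,
    cds: pd.DataFrame,
    lengths: Iterable[int] = range(26, 33),
    min_frame_fraction: float = 0.5,
) -> tuple[set[int], pd.DataFrame]:
    """Retain read lengths whose 5'-end frame distribution is periodic.

    For each candidate length the frame of every CDS-overlapping read,
    (5' end - cds_start) mod 3, is tabulated; a length is retained when its
    modal-frame fraction reaches ``min_frame_fraction``.
    """
    lengths = sorted(set(int(l) for l in lengths))
    if any(not 20 <= l <= 40 for l in lengths):
        raise ValueError("candidate lengths must lie within 20-40 nt")
    ann = cds.set_index("transcript")
    df = alignments.merge(
        ann[["cds_start", "cds_end"]], left_on="transcript", right_index=True, how="inner"
    )
    df = df[(df["start"] >= df["cds_start"]) & (df["start"] < df["cds_end"])]
    if df.empty:
        raise ValueError("no CDS-overlapping reads; cannot assess periodicity")
    df = df[df["length"].isin(lengths)]
    frame = ((df["start"] - df["cds_start"]) % 3).astype(int)
    rows = []
    retained: set[int] = set()
    for L in lengths:
        sel = frame[df["length"] == L]
        n = len(sel)
        counts = sel.value_counts().reindex([0, 1, 2], fill_value=0)
        modal = counts.max() / n if n else np.nan
        keep = bool(n and modal >= min_frame_fraction)
        if keep:
            retained.add(L)
        rows.append(
            {
                "length": L,
                "n_reads": n,
                "frame0": int(counts[0]),
                "frame1": int(counts[1]),
                "frame2": int(counts[2]),
                "modal_fraction": modal,
                "retained": keep,
            }
        )
    return retained, pd.DataFrame(rows)


@dataclass
class PsiteTable:
    """Per-(gene, codon index) in-frame shifted footprint counts plus the
    bookkeeping needed for exact count conservation."""

    counts: pd.DataFrame  # columns: gene, codon_index, count
    shift: int
    retained_lengths: tuple[int, ...]
    n_cds_assigned: int  # reads whose shifted P-site lies inside a CDS
    n_off_frame: int
    n_first_dropped: int = 0
    first_dropped_below: int = 0

    def total(self) -> int:
        return int(self.counts["count"].sum())

    def conservation_ok(self) -> bool:
        """CDS-assigned reads == off-frame + first-10-removed + table total."""
        return self.n_cds_assigned == self.n_off_frame + self.n_first_dropped + self.total()


def assign_psites(
    alignments: pd.DataFrame,
    cds: pd.DataFrame,
    shift: int = PSITE_SHIFT_DEFAULT,
    retained_lengths: Iterable[int] | None = None,
) -> PsiteTable:
    """Shift footprint 5' ends to P-sites and map them to codon indices.

    The P-site first nucleotide is ``5' end + shift``; reads whose P-site lies
    in a CDS but off-frame are dropped and counted, never rounded into frame.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    df = alignments
    if retained_lengths is not None:
        retained_lengths = tuple(sorted(set(int(l) for l in retained_lengths)))
        df = df[df["length"].isin(retained_lengths)]
    else:
        retained_lengths = tuple(sorted(df["length"].unique()))
    ann = cds.set_index("transcript")
    df = df.merge(
        ann[["gene", "cds_start", "cds_end"]],
        left_on="transcript",
        right_index=True,
        how="inner",
    )
    psite = df["start"] + shift
    in_cds = (psite >= df["cds_start"]) & (psite < df["cds_end"])
    df = df[in_cds]
    psite = psite[in_cds]
    offset = psite - df["cds_start"]
    in_frame = (offset % 3) == 0
    n_cds = int(len(df))
    n_off = int((~in_frame).sum())
    kept = df[in_frame].copy()
    kept["codon_index"] = (offset[in_frame] // 3).astype(int)
    counts = (
        kept.groupby(["gene", "codon_index"]).size().rename("count").reset_index()
    )
    return PsiteTable(
        counts=counts,
        shift=shift,
        retained_lengths=retained_lengths,
        n_cds_assigned=n_cds,
        n_off_frame=n_off,
    )


def drop_first_codons(table: PsiteTable, n: int = FIRST_CODONS_DROPPED) -> PsiteTable:
    """Remove counts on the first ``n`` codons of every gene."""
    if n < 0:
        raise ValueError("n must be non-negative")
    mask = table.counts["codon_index"] >= n
    removed = int(table.counts.loc[~mask, "count"].sum())
    return replace(
        table,
        counts=table.counts[mask].reset_index(drop=True),
        n_first_dropped=table.n_first_dropped + removed,
        first_dropped_below=max(table.first_dropped_below, n),
    )


# ---------------------------------------------------------------------------
# Codon occupancy


def codon_occupancy(
    table: PsiteTable,
    cds: pd.DataFrame,
    sequences: Mapping[str, str],
) -> pd.DataFrame:
    """Normalised bulk P-site occupancy per sense codon for one sample.

    For every ribosome position the P-site codon identity is tallied into
    ``p_count`` and the codon identities at nucleotide offsets +6, +9, +12
    from the P-site first nucleotide (the +1..+3 codons relative to the
    A-site) into three background tallies. Positions whose background codons
    would run past the last sense codon are skipped entirely. Normalised
    occupancy is ``p_count / (background_sum / 3)``; it is NaN (flagged) where
    the background mean is zero.
    """
    codon_lists: dict[str, list[str]] = {}
    for gene, seq in sequences.items():
        codon_lists[gene] = [seq[i : i + 3] for i in range(0, len(seq), 3)]

    p_count = {c: 0 for c in SENSE_CODONS}
    bg = {c: np.zeros(3, dtype=np.int64) for c in SENSE_CODONS}
    for gene, ci, n in table.counts[["gene", "codon_index", "count"]].itertuples(
        index=False
    ):
        codons = codon_lists[gene]
        n_codons = len(codons)
        # last sense codon index is n_codons - 2 (stop excluded)
        if ci + 4 > n_codons - 2:
            continue
        window = codons[ci : ci + 5]
        if any("N" in c for c in window):
            warnings.warn(f"codon containing N in {gene} at {ci}; skipped", stacklevel=2)
            continue
        pc = window[0]
        if pc in STOP_CODONS:
            continue
        p_count[pc] += int(n)
        for k in range(3):
            bgc = window[2 + k]
            if bgc in bg:
                bg[bgc][k] += int(n)

    rows = []
    for c in SENSE_CODONS:
        b = bg[c]
        bmean = b.sum() / 3.0
        occ = p_count[c] / bmean if bmean > 0 else np.nan
        rows.append(
            {
                "codon": c,
                "p_count": p_count[c],
                "bg_plus1": int(b[0]),
                "bg_plus2": int(b[1]),
                "bg_plus3": int(b[2]),
                "occupancy": occ,
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def occupancy_fold_change(
    ko_tables: Sequence[pd.DataFrame],
    wt_tables: Sequence[pd.DataFrame],
    alpha: float = 0.05,
    center: bool = True,
) -> pd.DataFrame:
    """Per-codon knockout/wild-type occupancy fold change with a Welch t-test
    on log2 occupancies across replicates.

    Normalised occupancies are compositional: a strong stall at one codon
    slightly deflates every other codon's share, which a replicate t-test
    would flag as a global artifact. With ``center`` (default) each
    replicate's log2 occupancies are median-centred over the codons defined
    in all replicates before averaging and testing, so fold changes isolate
    codon-specific effects; fold change is then the ratio of geometric means.
    ``center=False`` gives the plain ratio of arithmetic means and a test on
    raw log2 occupancies. Codons with an undefined occupancy in any replicate
    are flagged and excluded from testing.
    """
    if len(ko_tables) < 2 or len(wt_tables) < 2:
        raise ValueError("need at least two replicates per genotype")
    ko = pd.concat([t["occupancy"] for t in ko_tables], axis=1)
    wt = pd.concat([t["occupancy"] for t in wt_tables], axis=1)
    both = pd.concat([ko, wt], axis=1)
    defined = both.notna().all(axis=1) & (both > 0).all(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ko_log = np.log2(ko.where(ko > 0))
        wt_log = np.log2(wt.where(wt > 0))
    if center:
        ko_log = ko_log - ko_log[defined].median(axis=0)
        wt_log = wt_log - wt_log[defined].median(axis=0)

    rows = []
    for codon in ko.index:
        if not defined[codon]:
            rows.append(
                {
                    "codon": codon,
                    "mean_ko": np.nan,
                    "mean_wt": np.nan,
                    "fold_change": np.nan,
                    "log2_fc": np.nan,
                    "p_value": np.nan,
                    "significant": False,
                    "defined": False,
                }
            )
            continue
        ko_l = ko_log.loc[codon].to_numpy(dtype=float)
        wt_l = wt_log.loc[codon].to_numpy(dtype=float)
        if center:
            log2_fc = ko_l.mean() - wt_l.mean()
            fc = float(2.0**log2_fc)
            mean_ko = float(2.0 ** ko_l.mean())
            mean_wt = float(2.0 ** wt_l.mean())
        else:
            ko_v = ko.loc[codon].to_numpy(dtype=float)
            wt_v = wt.loc[codon].to_numpy(dtype=float)
            mean_ko, mean_wt = float(ko_v.mean()), float(wt_v.mean())
            fc = mean_ko / mean_wt
            log2_fc = float(np.log2(fc))
        t, p = stats.ttest_ind(ko_l, wt_l, equal_var=False)
        rows.append(
            {
                "codon": codon,
                "mean_ko": mean_ko,
                "mean_wt": mean_wt,
                "fold_change": fc,
                "log2_fc": log2_fc,
                "p_value": float(p),
                "significant": bool(p < alpha),
                "defined": True,
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def gene_occupancy(table: PsiteTable) -> pd.Series:
    """Ribosome occupancy per gene: the sum of filtered in-frame P-site counts."""
    return table.counts.groupby("gene")["count"].sum().rename("rpf_count")


# ---------------------------------------------------------------------------
# Translation efficiency


def translation_efficiency(
    ribo_counts: pd.Series,
    rna_counts: pd.Series,
    min_rna: int = 10,
) -> pd.DataFrame:
    """Per-gene TE: footprint CPM / mRNA CPM over genes passing the RNA floor.

    Both libraries are normalised to counts-per-million over the included
    genes, making TE invariant under per-library rescaling.
    """
    genes = rna_counts.index[rna_counts >= min_rna]
    if len(genes) == 0:
        raise ValueError("all genes fall below the RNA abundance floor")
    rpf = ribo_counts.reindex(genes).fillna(0.0)
    rna = rna_counts.reindex(genes).astype(float)
    rpf_cpm = rpf / rpf.sum() * 1e6
    rna_cpm = rna / rna.sum() * 1e6
    te = rpf_cpm / rna_cpm
    with np.errstate(divide="ignore"):
        log2_te = np.log2(te.where(te > 0))
    return pd.DataFrame(
        {
            "rpf_count": rpf.astype(int),
            "rna_count": rna.astype(int),
            "rpf_cpm": rpf_cpm,
            "rna_cpm": rna_cpm,
            "te": te,
            "log2_te": log2_te,
        }
    )


def mean_log2_te(te_tables: Sequence[pd.DataFrame]) -> pd.Series:
    """Average log2 TE across replicate TE tables (genes present in all)."""
    stacked = pd.concat([t["log2_te"] for t in te_tables], axis=1, join="inner")
    return stacked.mean(axis=1).rename("log2_te")


# ---------------------------------------------------------------------------
# Codon-enrichment gene sets and TE group comparisons


def codon_enrichment_sets(
    sequences: Mapping[str, str],
    codons: str | Sequence[str],
    factor: float = 3.0,
) -> tuple[list[str], pd.DataFrame]:
    """Genes whose proportion of the given codon(s) is at least ``factor``-fold
    the transcriptome-wide proportion.

    ``codons`` may be one codon or several synonymous codons pooled (amino-acid
    level sets). Proportions are over sense codons; stops are excluded from
    both numerator and denominator.
    """
    if isinstance(codons, str):
        codons = [codons]
    codons = [c.upper() for c in codons]
    for c in codons:
        if c not in SENSE_CODONS:
            raise ValueError(f"{c} is not a sense codon")
    target = set(codons)
    rows = []
    total_hits = 0
    total_sense = 0
    for gene, seq in sequences.items():
        cods = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        sense = [c for c in cods if c not in STOP_CODONS]
        hits = sum(c in target for c in sense)
        rows.append({"gene": gene, "n_target": hits, "n_sense": len(sense)})
        total_hits += hits
        total_sense += len(sense)
    if total_sense == 0:
        raise ValueError("no sense codons in input sequences")
    transcriptome_prop = total_hits / total_sense
    df = pd.DataFrame(rows).set_index("gene")
    df["proportion"] = df["n_target"] / df["n_sense"]
    if transcriptome_prop == 0:
        df["ratio"] = np.nan
        df["enriched"] = False
    else:
        df["ratio"] = df["proportion"] / transcriptome_prop
        # "at least 3-fold" is inclusive; cross-multiplied on integer counts so
        # an exact 3-fold gene is never lost to float division
        df["enriched"] = (
            df["n_target"].to_numpy() * float(total_sense)
            >= factor * df["n_sense"].to_numpy() * float(total_hits)
        )
    df.attrs["transcriptome_proportion"] = transcriptome_prop
    return list(df.index[df["enriched"]]), df


def compare_te_groups(
    te: pd.DataFrame | pd.Series,
    sets: Mapping[str, Sequence[str]],
    n_random: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Welch's t-test of log2 TE between each gene set and a seeded,
    size-matched random gene sample drawn from the remaining genes.

    Sets smaller than 3 genes after TE filtering are skipped with a warning;
    degenerate zero-variance comparisons are flagged, not tested.
    """
    log2_te = te["log2_te"] if isinstance(te, pd.DataFrame) else te
    log2_te = log2_te.dropna()
    rng = np.random.default_rng(seed)
    rows = []
    for name, genes in sets.items():
        in_set = log2_te.index.intersection(pd.Index(genes))
        pool = log2_te.index.difference(in_set)
        size = n_random or len(in_set)
        if len(in_set) < 3 or len(pool) < 3:
            warnings.warn(f"gene set {name!r} too small after TE filtering; skipped",
                          stacklevel=2)
            rows.append({"set": name, "n_set": len(in_set), "n_random": 0,
                         "mean_set": np.nan, "mean_random": np.nan,
                         "difference": np.nan, "p_value": np.nan, "tested": False})
            continue
        size = min(size, len(pool))
        random_genes = rng.choice(pool.to_numpy(), size=size, replace=False)
        a = log2_te.loc[in_set].to_numpy(dtype=float)
        b = log2_te.loc[random_genes].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            rows.append({"set": name, "n_set": len(a), "n_random": len(b),
                         "mean_set": a.mean(), "mean_random": b.mean(),
                         "difference": a.mean() - b.mean(),
                         "p_value": np.nan, "tested": False})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"set": name, "n_set": len(a), "n_random": len(b),
                     "mean_set": a.mean(), "mean_random": b.mean(),
                     "difference": a.mean() - b.mean(),
                     "p_value": float(p), "tested": True})
    return pd.DataFrame(rows).set_index("set")


def compare_te_between(
    te_a: pd.Series, te_b: pd.Series, genes: Sequence[str], center: bool = True
) -> dict:
    """Welch's t-test of a gene set's log2 TE between two sample groups
    (e.g. knockout-heat vs wild-type-heat).

    With ``center`` (default) each group's log2 TE values are median-centred
    over all genes first: CPM-based TE is compositional, so a genuine drop in
    one gene set inflates every other gene's share; centring (in the spirit of
    median-of-ratios library normalisation) removes that global shift so the
    comparison reflects the set itself.
    """
    if center:
        te_a = te_a - te_a.median()
        te_b = te_b - te_b.median()
    idx = pd.Index(genes)
    a = te_a.reindex(idx).dropna().to_numpy(dtype=float)
    b = te_b.reindex(idx).dropna().to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("gene set too small for a between-group comparison")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "difference": float(a.mean() - b.mean()),
        "t": float(t),
        "p_value": float(p),
        "n": int(min(len(a), len(b))),
    }


# ---------------------------------------------------------------------------
# Single-gene stall profile and polysome fraction


def profile_gene(
    table: PsiteTable,
    gene: str,
    highlight_codon: str,
    sequences: Mapping[str, str],
) -> tuple[np.ndarray, list[int]]:
    """Per-codon footprint counts along one gene plus the positions of a
    highlighted codon (e.g. every UUG) from a scan of the CDS."""
    if gene not in sequences:
        raise KeyError(f"unknown gene {gene!r}")
    seq = sequences[gene]
    n_codons = len(seq) // 3
    vec = np.zeros(n_codons, dtype=np.int64)
    sel = table.counts[table.counts["gene"] == gene]
    for ci, n in sel[["codon_index", "count"]].itertuples(index=False):
        vec[int(ci)] = int(n)
    highlight = [
        i for i in range(n_codons) if seq[3 * i : 3 * i + 3] == highlight_codon.upper()
    ]
    return vec, highlight


def polysome_fraction(
    x: Sequence[float], absorbance: Sequence[float], boundary: float
) -> float:
    """Fraction of the absorbance trace area beyond the monosome/polysome
    boundary: area(x >= boundary) / total area, by trapezoidal integration
    with the boundary point interpolated onto the trace."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("trace x values must be sorted ascending")
    if np.any(y < 0):
        raise ValueError("absorbance must be baseline-corrected to >= 0")
    if not x[0] <= boundary <= x[-1]:
        raise ValueError("boundary outside the trace range")
    total = np.trapezoid(y, x)
    if total <= 0:
        raise ValueError("trace has zero total area")
    yb = np.interp(boundary, x, y)
    mask = x > boundary
    xs = np.concatenate([[boundary], x[mask]])
    ys = np.concatenate([[yb], y[mask]])
    return float(np.trapezoid(ys, xs) / total)
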