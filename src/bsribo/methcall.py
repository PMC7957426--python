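"""m5C site calling from paired wild-type / knockout cytosine reports.

The calling rule is thresholding, not hypothesis testing: a position is a
putative NSUN-dependent m5C site when it is covered deeply enough in every
required replicate of both genotypes, its pooled wild-type non-conversion
ratio exceeds the threshold, and its pooled knockout ratio stays below the
knockout ceiling (non-conversion "exclusively in wild-type samples").
Positions non-converted in both genotypes are conversion artifacts
(NSUN-independent); positions non-converted only in the knockout are the
mirror-image artifact class used to gauge the false-discovery scale.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bsalign import nonconversion_ratio
from .sim.reference import ReferenceSet, TRNA, MT_TRNA

LABEL_NSUN = "nsun_dependent"
LABEL_ARTIFACT = "nsun_independent_artifact"
LABEL_KO_EXCLUSIVE = "ko_exclusive_artifact"
LABEL_UNMETH = "unmethylated"
LABEL_LOWCOV = "insufficient_coverage"


@dataclass
class CallingParams:
    """Thresholds of the calling rule.

    ``min_coverage`` of 11 encodes "coverage higher than 10"; it must be met in
    at least ``n_replicates_required`` replicates of each genotype. Ratios are
    computed on counts pooled across replicates (per-replicate ratios are also
    reported for audit).
    """

    min_coverage: int = 11
    wt_ratio_threshold: float = 0.1
    ko_max_ratio: float = 0.1
    n_replicates_required: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.wt_ratio_threshold < 1 or not 0 < self.ko_max_ratio < 1:
            raise ValueError("ratio thresholds must lie strictly in (0, 1)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def deamination_rate(
    report: pd.DataFrame, exclude: set[tuple[str, int]] | list | None = None
) -> float:
    """Bisulfite efficiency: converted / (converted + nonconverted).

    ``exclude`` lists (transcript, position) pairs of known methylation sites
    to remove before summing (conventionally computed on rRNA with known sites
    removed). Raises when no evaluable cytosines remain.
    """
    df = report
    if exclude:
        excl = set(map(tuple, exclude))
        mask = [
            (t, int(p)) not in excl
            for t, p in zip(df["transcript"], df["position"])
        ]
        df = df[mask]
    conv = int(df["converted"].sum())
    nonconv = int(df["nonconverted"].sum())
    if conv + nonconv == 0:
        raise ValueError("no evaluable cytosines after exclusion")
    return conv / (conv + nonconv)


def _stack_replicates(reports: list[pd.DataFrame], prefix: str) -> pd.DataFrame:
    """Wide table keyed by (transcript, position) with per-replicate counts."""
    keys = reports[0][["transcript", "position"]]
    for r in reports[1:]:
        if not keys.equals(r[["transcript", "position"]]):
            raise ValueError("replicate reports cover different references")
    out = keys.copy()
    for i, r in enumerate(reports):
        out[f"{prefix}_cov_{i}"] = r["coverage"].to_numpy()
        out[f"{prefix}_nonconv_{i}"] = r["nonconverted"].to_numpy()
        out[f"{prefix}_ratio_{i}"] = nonconversion_ratio(r).to_numpy()
    return out


def _pooled(df: pd.DataFrame, prefix: str, n: int) -> tuple[pd.Series, pd.Series]:
    cov = sum(df[f"{prefix}_cov_{i}"] for i in range(n))
    nonconv = sum(df[f"{prefix}_nonconv_{i}"] for i in range(n))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = nonconv / cov
    return cov, ratio.where(cov > 0)


def call_sites(
    wt_reports: list[pd.DataFrame],
    ko_reports: list[pd.DataFrame],
    params: CallingParams | None = None,
) -> pd.DataFrame:
    """Classify every reference cytosine from replicate reports of both
    genotypes.

    Returns one row per position with per-replicate and pooled ratios and a
    ``label`` column: ``nsun_dependent`` (wild-type-exclusive non-conversion),
    ``nsun_independent_artifact`` (non-converted in both genotypes),
    ``ko_exclusive_artifact`` (knockout-exclusive), ``unmethylated``, or
    ``insufficient_coverage``.
    """
    params = params or CallingParams()
    if len(wt_reports) < params.n_replicates_required or len(ko_reports) < params.n_replicates_required:
        raise ValueError(
            f"need at least {params.n_replicates_required} replicates per genotype"
        )
    wt = _stack_replicates(wt_reports, "wt")
    ko = _stack_replicates(ko_reports, "ko")
    if not wt[["transcript", "position"]].equals(ko[["transcript", "position"]]):
        raise ValueError("replicate reports cover different references")
    df = pd.concat([wt, ko.drop(columns=["transcript", "position"])], axis=1)

    n_wt, n_ko = len(wt_reports), len(ko_reports)
    wt_pass = sum(
        (df[f"wt_cov_{i}"] >= params.min_coverage).astype(int) for i in range(n_wt)
    )
    ko_pass = sum(
        (df[f"ko_cov_{i}"] >= params.min_coverage).astype(int) for i in range(n_ko)
    )
    covered = (wt_pass >= params.n_replicates_required) & (
        ko_pass >= params.n_replicates_required
    )

    _, df["wt_pooled_ratio"] = _pooled(df, "wt", n_wt)
    _, df["ko_pooled_ratio"] = _pooled(df, "ko", n_ko)

    wt_high = df["wt_pooled_ratio"] > params.wt_ratio_threshold
    ko_low = df["ko_pooled_ratio"] <= params.ko_max_ratio
    ko_high = df["ko_pooled_ratio"] > params.wt_ratio_threshold
    wt_low = df["wt_pooled_ratio"] <= params.ko_max_ratio

    label = np.full(len(df), LABEL_UNMETH, dtype=object)
    label[(wt_high & ko_high).to_numpy()] = LABEL_ARTIFACT
    label[(wt_high & ko_low).to_numpy()] = LABEL_NSUN
    label[(ko_high & wt_low).to_numpy()] = LABEL_KO_EXCLUSIVE
    label[~covered.to_numpy()] = LABEL_LOWCOV
    df["label"] = label
    return df


def threshold_sweep(
    wt_reports: list[pd.DataFrame],
    ko_reports: list[pd.DataFrame],
    thresholds: list[float],
    params: CallingParams | None = None,
) -> pd.DataFrame:
    """Count genotype-exclusive positions over a non-conversion threshold sweep.

    At each threshold t: ``wt_exclusive`` counts coverage-passing positions
    with pooled WT ratio >= t and pooled KO ratio < t; ``ko_exclusive`` is the
    mirror image. Thresholds must be ascending and inside (0, 1).
    """
    params = params or CallingParams()
    if any(not 0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    calls = call_sites(wt_reports, ko_reports, params)
    ok = calls["label"] != LABEL_LOWCOV
    wt_ratio = calls.loc[ok, "wt_pooled_ratio"].to_numpy(dtype=float)
    ko_ratio = calls.loc[ok, "ko_pooled_ratio"].to_numpy(dtype=float)
    rows = []
    for t in thresholds:
        rows.append(
            {
                "threshold": t,
                "wt_exclusive": int(((wt_ratio >= t) & (ko_ratio < t)).sum()),
                "ko_exclusive": int(((ko_ratio >= t) & (wt_ratio < t)).sum()),
            }
        )
    return pd.DataFrame(rows)


_TRNA_ID_RE = re.compile(r"^(?:mt-)?tRNA-([A-Za-z]{3})-")


def parse_isoacceptor(transcript_id: str) -> str | None:
    """Amino-acid family from a tRNA id like ``tRNA-Leu-CAA-1``."""
    m = _TRNA_ID_RE.match(transcript_id)
    return m.group(1) if m else None


def summarize_isoacceptors(
    calls: pd.DataFrame,
    refs: ReferenceSet,
    min_stoichiometry: float = 0.5,
) -> pd.DataFrame:
    """Count NSUN-dependent tRNA sites above a stoichiometry floor, grouped by
    amino-acid family (pooled WT non-conversion ratio as the stoichiometry
    proxy)."""
    trna_ids = {t.id for t in refs.by_class(TRNA, MT_TRNA)}
    hits = calls[
        (calls["label"] == LABEL_NSUN)
        & calls["transcript"].isin(trna_ids)
        & (calls["wt_pooled_ratio"] > min_stoichiometry)
    ]
    families = []
    for tid in hits["transcript"]:
        fam = parse_isoacceptor(tid)
        if fam is None:
            warnings.warn(f"unparseable tRNA id {tid!r}; grouped as unknown", stacklevel=2)
            fam = "unknown"
        families.append(fam)
    out = (
        pd.Series(families, dtype=object)
        .value_counts()
        .rename_axis("isoacceptor")
        .rename("n_sites")
        .reset_index()
    )
    return out
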