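"""Planted methylation truth.

The plan emulates the structure of an NSUN-dependent m5C methylome over a
knockout design: high-stoichiometry tRNA sites in the variable loop (positions
48-50) plus exactly one wobble-position site on the Leu-CAA tRNA, rRNA sites,
rare lower-stoichiometry mRNA sites, and NSUN-independent "artifact" sites
(incomplete conversion) that behave identically in both genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ..config import stream_rng
from .reference import MRNA, RRNA, TRNA, MT_RRNA, MT_TRNA, ReferenceSet

VARIABLE_LOOP = (48, 49, 50)
WOBBLE_POS = 33  # 0-based; position 34 in standard tRNA numbering


@dataclass(frozen=True)
class Site:
    transcript: str
    position: int  # 0-based, must hold a C in the reference
    stoichiometry: float
    nsun_dependent: bool


@dataclass
class SiteSpec:
    """Request ``n_sites`` sites on transcripts of ``ref_class`` with per-site
    stoichiometry drawn uniformly from ``stoich_range``."""

    ref_class: str
    n_sites: int
    stoich_range: tuple[float, float]
    nsun_dependent: bool = True


@dataclass
class MethylationPlan:
    sites: list[Site] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def nsun_dependent(self) -> list[Site]:
        return [s for s in self.sites if s.nsun_dependent]

    @property
    def artifacts(self) -> list[Site]:
        return [s for s in self.sites if not s.nsun_dependent]

    def by_transcript(self) -> dict[str, list[Site]]:
        out: dict[str, list[Site]] = {}
        for s in self.sites:
            out.setdefault(s.transcript, []).append(s)
        return out

    def positions(self) -> set[tuple[str, int]]:
        return {(s.transcript, s.position) for s in self.sites}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript": s.transcript,
                    "position": s.position,
                    "stoichiometry": s.stoichiometry,
                    "nsun_dependent": s.nsun_dependent,
                }
                for s in self.sites
            ],
            columns=["transcript", "position", "stoichiometry", "nsun_dependent"],
        )


def _validate_against_reference(plan: MethylationPlan, ref: ReferenceSet) -> None:
    for s in plan.sites:
        seq = ref[s.transcript].sequence
        if not 0 <= s.position < len(seq) or seq[s.position] != "C":
            raise ValueError(
                f"planted site {s.transcript}:{s.position} is not a reference C"
            )
        if not 0.0 <= s.stoichiometry <= 1.0:
            raise ValueError("stoichiometry outside [0, 1]")


def plant_methylation(
    ref: ReferenceSet,
    specs: Sequence[SiteSpec],
    seed: int,
    end_margin: int = 50,
    wobble: bool = True,
) -> MethylationPlan:
    """Choose planted sites satisfying the per-class requests.

    tRNA-class NSUN-dependent sites go to variable-loop cytosines first (one
    wobble-34 site on the first Leu-CAA tRNA when ``wobble`` is set); all other
    sites are drawn from cytosines at least ``end_margin`` nt from the ends of
    long transcripts, where read coverage is uniform (short transcripts such as
    tRNAs are exempt — every mid-molecule position is fully covered there).

    Raises ``ValueError`` when a requested class lacks enough distinct C
    positions.
    """
    rng = stream_rng(seed, "plan")
    taken: set[tuple[str, int]] = set()
    sites: list[Site] = []

    class_members = {
        cls: ref.by_class(cls) for cls in (MRNA, TRNA, RRNA, MT_TRNA, MT_RRNA)
    }

    def draw_stoich(spec: SiteSpec) -> float:
        lo, hi = spec.stoich_range
        return float(rng.uniform(lo, hi))

    def candidate_positions(t) -> list[int]:
        cpos = ref.c_positions(t.id)
        L = len(t.sequence)
        if L > 3 * end_margin:
            cpos = cpos[(cpos >= end_margin) & (cpos < L - end_margin)]
        return [int(p) for p in cpos if (t.id, int(p)) not in taken]

    for spec in specs:
        members = class_members.get(spec.ref_class)
        if not members:
            raise ValueError(f"reference has no transcripts of class {spec.ref_class}")
        needed = spec.n_sites
        if needed == 0:
            continue
        chosen: list[tuple[str, int]] = []

        if spec.ref_class in (TRNA, MT_TRNA) and spec.nsun_dependent:
            if wobble:
                leu = next(
                    (t for t in members if "Leu-CAA" in t.id and t.sequence[WOBBLE_POS] == "C"),
                    None,
                )
                if leu is not None and (leu.id, WOBBLE_POS) not in taken and needed > 0:
                    chosen.append((leu.id, WOBBLE_POS))
                    needed -= 1
            # fill from variable-loop cytosines, round-robin over tRNAs
            pool = [
                (t.id, p)
                for t in members
                for p in VARIABLE_LOOP
                if p < len(t.sequence)
                and t.sequence[p] == "C"
                and (t.id, p) not in taken
                and (t.id, p) not in chosen
            ]
            take = min(needed, len(pool))
            idx = rng.choice(len(pool), size=take, replace=False) if take else []
            chosen.extend(pool[int(i)] for i in idx)
            needed -= take

        if needed > 0:
            pool = [
                (t.id, p)
                for t in members
                for p in candidate_positions(t)
                if (t.id, p) not in chosen
            ]
            if len(pool) < needed:
                raise ValueError(
                    f"class {spec.ref_class}: requested {spec.n_sites} sites but only "
                    f"{len(pool) + len(chosen)} eligible C positions available"
                )
            idx = rng.choice(len(pool), size=needed, replace=False)
            chosen.extend(pool[int(i)] for i in idx)

        for tid, pos in chosen:
            taken.add((tid, pos))
            sites.append(
                Site(
                    transcript=tid,
                    position=pos,
                    stoichiometry=draw_stoich(spec),
                    nsun_dependent=spec.nsun_dependent,
                )
            )

    plan = MethylationPlan(sites)
    _validate_against_reference(plan, ref)
    return plan


def effective_stoichiometry(site: Site, genotype: str) -> float:
    """Per-molecule methylation probability of a site in a genotype.

    NSUN-dependent sites have stoichiometry 0 in the knockout; artifact sites
    behave identically in both genotypes.
    """
    if site.nsun_dependent and genotype == "noNSUN":
        return 0.0
    return site.stoichiometry
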