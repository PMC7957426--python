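"""Pipeline orchestration: simulate -> align -> call / profile from one
config document, with a digest-based run manifest for reproducibility and
partial reruns.

Stages communicate through files in the output directory, so a rerun with an
unchanged config skips any stage whose recorded output digests still match.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, riboprof
from .bsalign import UniqueAligner, merge_bisulfite_identical, pileup_cytosines
from .config import ConfigError, SimulationConfig, config_from_mapping
from .methcall import CallingParams, call_sites, threshold_sweep, summarize_isoacceptors
from .sim.bisulfite import simulate_bisulfite_reads
from .sim.methylation import SiteSpec, plant_methylation
from .sim.reference import make_reference, MRNA, TRNA, RRNA, MT_TRNA, MT_RRNA
from .sim.ribo import simulate_ribo_and_rna
from .study import bs_site_specs, te_group_analysis, RiboStudy, RiboSampleResult

log = logging.getLogger("bsribo")

_TOP_KEYS = {
    "seed",
    "simulation",
    "bs_replicates",
    "ribo_replicates",
    "conditions",
    "site_specs",
    "calling",
    "sweep",
    "ribo",
}
_CLASS_NAMES = {MRNA, TRNA, RRNA, MT_TRNA, MT_RRNA}


@dataclass
class StageRecord:
    name: str
    status: str = "pending"  # completed | skipped | failed | pending
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    started: float = 0.0
    finished: float = 0.0
    error: str = ""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": [asdict(s) for s in self.stages],
            },
            indent=2,
        )

    @classmethod
    def from_file(cls, path: Path) -> "RunManifest | None":
        if not path.exists():
            return None
        data = json.loads(path.read_text())
        m = cls(
            config_hash=data["config_hash"],
            seed=data["seed"],
            version=data.get("version", ""),
        )
        m.stages = [StageRecord(**s) for s in data.get("stages", [])]
        return m


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    return yaml.safe_load(text)


def validate_pipeline_config(cfg: dict) -> dict:
    """Validate the pipeline config document; raise listing offending keys."""
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    unknown = sorted(set(cfg) - _TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {unknown}")
    if "seed" not in cfg:
        raise ConfigError("config missing required key: seed")
    specs = cfg.get("site_specs", "default")
    if isinstance(specs, list):
        for rec in specs:
            missing = {"ref_class", "n_sites", "stoich_range"} - set(rec)
            if missing:
                raise ConfigError(f"site_spec entry missing keys: {sorted(missing)}")
            if rec["ref_class"] not in _CLASS_NAMES:
                raise ConfigError(f"unknown ref_class {rec['ref_class']!r}")
    elif specs not in ("default", "none"):
        raise ConfigError("site_specs must be 'default', 'none', or a list")
    return cfg


def _site_specs(cfg: dict) -> list[SiteSpec]:
    specs = cfg.get("site_specs", "default")
    if specs == "default":
        return bs_site_specs()
    if specs == "none":
        return []
    return [
        SiteSpec(
            ref_class=rec["ref_class"],
            n_sites=int(rec["n_sites"]),
            stoich_range=tuple(rec["stoich_range"]),
            nsun_dependent=bool(rec.get("nsun_dependent", True)),
        )
        for rec in specs
    ]


def _sim_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg.get("simulation", {}))
    sim["seed"] = cfg["seed"]
    return config_from_mapping(sim)


class PipelineRunner:
    """Executes the stages of one configured run in dependency order."""

    def __init__(self, cfg: dict, outdir: str | Path) -> None:
        self.cfg = validate_pipeline_config(cfg)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        canon = json.dumps(cfg, sort_keys=True, default=str)
        self.config_hash = hashlib.sha256(canon.encode()).hexdigest()[:16]
        self.sim = _sim_config(cfg)
        self.previous = RunManifest.from_file(self.outdir / "manifest.json")
        self.manifest = RunManifest(
            config_hash=self.config_hash, seed=int(cfg["seed"]), version=__version__
        )
        self.failed = False

    # -- helpers ---------------------------------------------------------

    def _can_skip(self, name: str, outputs: list[Path]) -> bool:
        if self.previous is None or self.previous.config_hash != self.config_hash:
            return False
        prev = next(
            (s for s in self.previous.stages if s.name == name and s.status in
             ("completed", "skipped")),
            None,
        )
        if prev is None:
            return False
        rels = {str(p.relative_to(self.outdir)) for p in outputs}
        if set(prev.outputs) != rels:
            return False
        for rel, digest in prev.outputs.items():
            path = self.outdir / rel
            if not path.exists() or _sha256(path) != digest:
                return False
        return True

    def _run_stage(self, name: str, outputs: list[Path], fn) -> None:
        rec = StageRecord(name=name, started=time.time())
        self.manifest.stages.append(rec)
        if self.failed:
            rec.status = "pending"
            rec.error = "upstream stage failed"
            return
        try:
            if self._can_skip(name, outputs):
                log.info("stage %s: outputs up to date, skipped", name)
                rec.status = "skipped"
            else:
                log.info("stage %s: running", name)
                fn()
                rec.status = "completed"
            rec.outputs = {
                str(p.relative_to(self.outdir)): _sha256(p) for p in outputs
            }
        except Exception as exc:  # noqa: BLE001 - recorded in the manifest
            log.error("stage %s failed: %s", name, exc)
            rec.status = "failed"
            rec.error = str(exc)
            self.failed = True
        finally:
            rec.finished = time.time()
            (self.outdir / "manifest.json").write_text(self.manifest.to_json())

    # -- stages ----------------------------------------------------------

    def run(self) -> RunManifest:
        out = self.outdir
        self._run_stage(
            "reference",
            [out / "reference.fasta", out / "cds.bed", out / "plan.tsv"],
            self._stage_reference,
        )
        bs_reps = int(self.cfg.get("bs_replicates", 3))
        bs_outputs = [
            out / f"cytosine_report_{g}_rep{r}.tsv"
            for g in ("WT", "noNSUN")
            for r in range(bs_reps)
        ]
        self._run_stage("bisulfite", bs_outputs, self._stage_bisulfite)
        self._run_stage(
            "methcall",
            [out / "calls.tsv", out / "sweep.tsv", out / "isoacceptors.tsv"],
            self._stage_methcall,
        )
        ribo_outputs = [out / "occupancy_fc.tsv", out / "te_groups.tsv", out / "te.tsv"]
        self._run_stage("riboprof", ribo_outputs, self._stage_riboprof)
        self._run_stage("report", [out / "report" / "summary.json"], self._stage_report)
        return self.manifest

    def _stage_reference(self) -> None:
        ref = make_reference(self.sim)
        self._ref = ref
        io.write_fasta(ref, self.outdir / "reference.fasta")
        io.write_cds_bed(ref, self.outdir / "cds.bed")
        plan = plant_methylation(
            ref, _site_specs(self.cfg), seed=self.sim.seed,
            end_margin=self.sim.bs_read_len,
        )
        self._plan = plan
        io.write_tsv(plan.to_frame(), self.outdir / "plan.tsv")

    def _load_reference(self):
        if not hasattr(self, "_ref"):
            self._ref = io.read_reference(
                self.outdir / "reference.fasta", self.outdir / "cds.bed"
            )
            plan_df = io.read_tsv(self.outdir / "plan.tsv")
            specs = []  # plan reloaded directly, not re-planted
            from .sim.methylation import MethylationPlan, Site

            self._plan = MethylationPlan(
                [
                    Site(r.transcript, int(r.position), float(r.stoichiometry),
                         bool(r.nsun_dependent))
                    for r in plan_df.itertuples()
                ]
            )
        return self._ref, self._plan

    def _stage_bisulfite(self) -> None:
        ref, plan = self._load_reference()
        merged, _ = merge_bisulfite_identical(ref)
        aligner = UniqueAligner(merged, bisulfite=True, max_mismatch=2)
        bs_reps = int(self.cfg.get("bs_replicates", 3))
        for genotype in ("WT", "noNSUN"):
            for rep in range(bs_reps):
                readset = simulate_bisulfite_reads(ref, plan, genotype, self.sim, rep)
                aln = aligner.align(readset.reads)
                report = pileup_cytosines(aln, readset.as_dict(), merged)
                io.write_cytosine_report_tsv(
                    report, self.outdir / f"cytosine_report_{genotype}_rep{rep}.tsv"
                )
                log.info(
                    "bisulfite %s rep%d: %d reads, %d aligned",
                    genotype, rep, len(readset.reads), len(aln),
                )

    def _stage_methcall(self) -> None:
        ref, _ = self._load_reference()
        bs_reps = int(self.cfg.get("bs_replicates", 3))
        calling = self.cfg.get("calling", {})
        params = CallingParams(
            min_coverage=int(calling.get("min_coverage", 11)),
            wt_ratio_threshold=float(calling.get("wt_ratio_threshold", 0.1)),
            ko_max_ratio=float(calling.get("ko_max_ratio", 0.1)),
            n_replicates_required=int(
                calling.get("n_replicates_required", min(3, bs_reps))
            ),
        )
        wt = [
            io.read_cytosine_report_tsv(self.outdir / f"cytosine_report_WT_rep{r}.tsv")
            for r in range(bs_reps)
        ]
        ko = [
            io.read_cytosine_report_tsv(
                self.outdir / f"cytosine_report_noNSUN_rep{r}.tsv"
            )
            for r in range(bs_reps)
        ]
        calls = call_sites(wt, ko, params)
        out = calls.copy()
        out["position"] = out["position"] + 1  # 1-based export
        io.write_tsv(out, self.outdir / "calls.tsv")
        thresholds = list(self.cfg.get("sweep", {}).get(
            "thresholds", [0.25, 0.30, 0.35, 0.40]
        ))
        io.write_tsv(
            threshold_sweep(wt, ko, thresholds, params), self.outdir / "sweep.tsv"
        )
        io.write_tsv(
            summarize_isoacceptors(calls, ref), self.outdir / "isoacceptors.tsv"
        )

    def _stage_riboprof(self) -> None:
        ref, _ = self._load_reference()
        ribo_cfg = self.cfg.get("ribo", {})
        conditions = tuple(self.cfg.get("conditions", ["27C"]))
        n_reps = int(self.cfg.get("ribo_replicates", 3))
        cds = riboprof.cds_annotation(ref)
        seqs = riboprof.cds_sequences(ref)
        aligner = UniqueAligner(ref, bisulfite=False, max_mismatch=0)
        samples: dict[tuple[str, str, int], RiboSampleResult] = {}
        for genotype in ("WT", "noNSUN"):
            for condition in conditions:
                for rep in range(n_reps):
                    sample = simulate_ribo_and_rna(ref, self.sim, genotype, condition, rep)
                    aln = aligner.align(sample.reads)
                    retained, frame_table = riboprof.periodicity_filter(
                        aln, cds, lengths=sorted(self.sim.rpf_len_dist),
                        min_frame_fraction=float(
                            ribo_cfg.get("min_frame_fraction", 0.5)
                        ),
                    )
                    pst = riboprof.assign_psites(
                        aln, cds, shift=int(ribo_cfg.get("shift", 12)),
                        retained_lengths=retained,
                    )
                    pst = riboprof.drop_first_codons(
                        pst, int(ribo_cfg.get("drop_first", 10))
                    )
                    occ = riboprof.codon_occupancy(pst, cds, seqs)
                    gocc = riboprof.gene_occupancy(pst)
                    te = riboprof.translation_efficiency(
                        gocc, sample.rna_counts,
                        min_rna=int(ribo_cfg.get("min_rna", 10)),
                    )
                    samples[(genotype, condition, rep)] = RiboSampleResult(
                        genotype=genotype, condition=condition, replicate=rep,
                        retained_lengths=retained, frame_table=frame_table,
                        psites=pst, occupancy=occ, gene_counts=gocc, te=te,
                        census=pd.DataFrame(), n_reads=len(sample.reads),
                        n_aligned=len(aln),
                    )
        study = RiboStudy(
            config=self.sim, ref=ref, cds=cds, sequences=seqs, samples=samples
        )
        condition = conditions[-1]
        fc = study.fold_change(condition)
        io.write_tsv(fc.reset_index(), self.outdir / "occupancy_fc.tsv")
        te_groups = te_group_analysis(study, condition=condition, seed=self.sim.seed)
        rows = [
            {"set": f"{self.sim.biased_codon}_enriched", **te_groups["enriched"]},
            {"set": "random", **te_groups["random"]},
        ]
        io.write_tsv(pd.DataFrame(rows), self.outdir / "te_groups.tsv")
        te_wide = pd.concat(
            {
                f"{g}-{condition}-rep{r}": s.te["log2_te"]
                for (g, c, r), s in sorted(study.samples.items())
                if c == condition
            },
            axis=1,
        )
        io.write_tsv(te_wide.reset_index(names="gene"), self.outdir / "te.tsv")

    def _stage_report(self) -> None:
        render_report(self.outdir)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Execute the full configured pipeline; returns the run manifest."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    return PipelineRunner(cfg, outdir).run()


def render_report(outdir: str | Path) -> Path:
    """Summarise stage outputs into a report directory.

    Sections whose stage output is missing are marked absent rather than
    crashing; a truth-comparison section is included when the planted-site
    table is present.
    """
    outdir = Path(outdir)
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    summary: dict = {"sections": {}}

    calls_path = outdir / "calls.tsv"
    if calls_path.exists():
        calls = io.read_tsv(calls_path)
        label_counts = calls["label"].value_counts().to_dict()
        summary["sections"]["methylation_calls"] = {"label_counts": label_counts}
        top = calls[calls["label"] == "nsun_dependent"].nlargest(
            20, "wt_pooled_ratio"
        )
        io.write_tsv(top, report_dir / "top_calls.tsv")
        plan_path = outdir / "plan.tsv"
        if plan_path.exists():
            plan = io.read_tsv(plan_path)
            planted = set(
                zip(plan.loc[plan["nsun_dependent"], "transcript"],
                    plan.loc[plan["nsun_dependent"], "position"] + 1)
            )
            called = set(
                zip(calls.loc[calls["label"] == "nsun_dependent", "transcript"],
                    calls.loc[calls["label"] == "nsun_dependent", "position"])
            )
            summary["sections"]["truth_comparison"] = {
                "planted_nsun_sites": len(planted),
                "recovered": len(planted & called),
                "recall": len(planted & called) / len(planted) if planted else None,
                "false_positive_calls": len(called - planted),
            }
    else:
        summary["sections"]["methylation_calls"] = "absent"

    sweep_path = outdir / "sweep.tsv"
    summary["sections"]["threshold_sweep"] = (
        io.read_tsv(sweep_path).to_dict("records") if sweep_path.exists() else "absent"
    )

    fc_path = outdir / "occupancy_fc.tsv"
    if fc_path.exists():
        fc = io.read_tsv(fc_path).set_index("codon")
        defined = fc[fc["defined"]]
        top_codon = defined["fold_change"].idxmax()
        summary["sections"]["codon_occupancy"] = {
            "top_fc_codon": top_codon,
            "top_fc": float(defined.loc[top_codon, "fold_change"]),
            "n_significant": int(defined["significant"].sum()),
        }
    else:
        summary["sections"]["codon_occupancy"] = "absent"

    te_path = outdir / "te_groups.tsv"
    summary["sections"]["te_groups"] = (
        io.read_tsv(te_path).to_dict("records") if te_path.exists() else "absent"
    )

    (report_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return report_dir
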