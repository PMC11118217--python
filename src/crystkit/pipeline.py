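"""End-to-end orchestration: FASTA (+ optional CDS and structures) in;
composition, refractivity, dissimilarity dendrogram, codon-level NJ bootstrap
tree, exposure reports and subfamily calls out.

Every output is a plain-text standard (TSV, FASTA, Newick, PHYLIP).  The run
is deterministic given the configuration: every stochastic stage takes an
explicit seed, the configuration is echoed into the output directory, and the
run log carries a checksum per written file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import alignment, composition, motif_classify, refractivity
from . import structure_exposure as sx
from . import trees
from .errors import ConfigurationError
from .seq_core import read_fasta


@dataclass
class PipelineConfig:
    fasta: str
    out_dir: str
    cds_fasta: str | None = None
    structures: list[str] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)  # id -> group label
    boundaries: dict[str, int] = field(default_factory=dict)  # struct id -> res
    controls: dict[str, int] = field(default_factory=dict)  # struct id -> res
    gap_open: float = 10.0
    gap_extend: float = 0.5
    pid_definition: str = "shared"
    distance_model: str = "jc69"
    cluster_k: int = 4
    bootstrap_replicates: int = 100
    bootstrap_seed: int | None = None
    bootstrap_unit: str = "codon"
    sasa_probe: float = 1.4
    sasa_points: int = 960
    exposure_sd_multiplier: float = 1.0
    motif_threshold: int = 2
    motif_window: int = 90

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        try:
            return cls(**data)
        except TypeError as err:
            raise ConfigurationError(str(err)) from err

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise ConfigurationError(f"input FASTA not found: {self.fasta}")
        if self.cds_fasta and self.bootstrap_seed is None:
            raise ConfigurationError(
                "bootstrap requires an explicit bootstrap_seed"
            )
        if self.cds_fasta and not Path(self.cds_fasta).exists():
            raise ConfigurationError(f"CDS FASTA not found: {self.cds_fasta}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a manifest of outputs.

    Stage failures abort with the stage name in the exception message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    log_lines: list[str] = []

    def emit(stage: str, path: Path) -> None:
        manifest[stage] = str(path)
        log_lines.append(f"{stage}\t{path.name}\t{_sha256(path)}")

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
        return wrap

    records = read_fasta(config.fasta)
    if not records:
        raise ConfigurationError(f"{config.fasta}: no sequences")

    @stage("config_echo")
    def _():
        p = out / "config.json"
        p.write_text(json.dumps(asdict(config), indent=2, sort_keys=True) + "\n")
        emit("config_echo", p)

    @stage("composition")
    def _():
        p = out / "composition.tsv"
        with open(p, "w") as fh:
            fh.write("id\tlength\tcys_count\tcys_pct\tmet_count\tmet_pct"
                     "\tkr_ratio\tala_cys_ratio\n")
            for rec in records:
                row = composition.composition_row(rec)
                fh.write(
                    f"{row.id}\t{row.length}\t{row.cys_count}\t{row.cys_pct}"
                    f"\t{row.met_count}\t{row.met_pct}"
                    f"\t{'' if row.kr_ratio is None else row.kr_ratio}"
                    f"\t{'' if row.ala_cys_ratio is None else row.ala_cys_ratio}\n"
                )
        emit("composition", p)
        if config.groups:
            rows = [(composition.composition_row(rec),
                     config.groups.get(rec.id, "other")) for rec in records]
            gs = out / "group_summaries.tsv"
            with open(gs, "w") as fh:
                fh.write("group\tn\tmean_cys_pct\tmean_met_pct\n")
                for g in sorted({g for _, g in rows}):
                    s = composition.group_means(rows, g)
                    fh.write(f"{s.group}\t{s.n}\t{s.mean_cys_pct}"
                             f"\t{s.mean_met_pct}\n")
            emit("group_summaries", gs)

    @stage("refractivity")
    def _():
        p = out / "refractivity.tsv"
        with open(p, "w") as fh:
            fh.write("id\tdndc_mL_per_g\n")
            for rec in records:
                pr = refractivity.protein_dndc(rec.seq, record_id=rec.id,
                                               ignore_unknown=True)
                fh.write(f"{rec.id}\t{pr.dndc:.6f}\n")
        emit("refractivity", p)

    @stage("clustering")
    def _():
        D = alignment.dissimilarity_matrix(
            records, gap_open=config.gap_open, gap_extend=config.gap_extend,
            definition=config.pid_definition)
        pd_path = out / "dissimilarity.phylip"
        D.to_phylip(pd_path)
        emit("dissimilarity_matrix", pd_path)
        dend = trees.ward_cluster(D)
        nw = out / "dendrogram.nwk"
        trees.write_newick(dend, nw)
        emit("dendrogram", nw)
        k = min(config.cluster_k, len(records))
        cut = trees.cut_dendrogram(dend, k)
        cp = out / "clusters.tsv"
        with open(cp, "w") as fh:
            fh.write("id\tcluster\n")
            for rec in records:
                fh.write(f"{rec.id}\t{cut[rec.id]}\n")
        emit("clusters", cp)

    if config.cds_fasta:
        @stage("nj_tree")
        def _():
            cds_records = read_fasta(config.cds_fasta, moltype="cds")
            cds = {r.id: r.seq for r in cds_records}
            msa = alignment.progressive_msa(
                records, gap_open=config.gap_open,
                gap_extend=config.gap_extend)
            ap = out / "protein_alignment.fasta"
            with open(ap, "w") as fh:
                for sid, row in zip(msa.ids, msa.rows):
                    fh.write(f">{sid}\n")
                    for i in range(0, len(row), 60):
                        fh.write(row[i:i + 60] + "\n")
            emit("protein_alignment", ap)
            codon_msa = alignment.codon_thread(msa, cds)
            model = trees.NucDistanceModel(model=config.distance_model)
            tree = trees.bootstrap_supports(
                codon_msa, model, replicates=config.bootstrap_replicates,
                seed=config.bootstrap_seed, unit=config.bootstrap_unit)
            np_ = out / "nj_tree.nwk"
            trees.write_newick(tree, np_)
            emit("nj_tree", np_)

    @stage("motif_classification")
    def _():
        p = out / "subfamily_calls.tsv"
        with open(p, "w") as fh:
            fh.write("id\tdc_pair_count\tcall\n")
            for rec in records:
                call = motif_classify.classify_subfamily(
                    rec, threshold=config.motif_threshold,
                    window_end=config.motif_window)
                fh.write(f"{rec.id}\t{call.evidence}\t{call.call}\n")
        emit("subfamily_calls", p)

    if config.structures:
        @stage("exposure")
        def _():
            reports = []
            pending = []
            for spath in config.structures:
                sid = Path(spath).stem
                model = sx.read_structure(spath)
                res = model.residue_numbers()
                boundary = config.boundaries.get(
                    sid, (res[0] + res[-1]) // 2)
                control = config.controls.get(sid)
                pending.append((sid, model, boundary, control))
            controls = []
            sasas = {}
            for sid, model, boundary, control in pending:
                sasa = sx.shrake_rupley(model, probe=config.sasa_probe,
                                        points=config.sasa_points)
                sasas[sid] = sasa
                controls.append((sid, sx.control_cys_sasa(model, sasa, control)))
            mean, sd, excluded = sx.buried_control_baseline(controls)
            for sid, model, boundary, control in pending:
                ntd, ctd = sx.domain_cys_sasa(model, sasas[sid], boundary)
                cls = sx.classify_exposure(
                    ntd, ctd, mean, sd,
                    sd_multiplier=config.exposure_sd_multiplier)
                reports.append(sx.ExposureReport(
                    sid, boundary, ntd, ctd,
                    dict(controls).get(sid), mean, sd, cls))
            p = out / "exposure.tsv"
            with open(p, "w") as fh:
                fh.write("id\tboundary\tntd_cys_sasa\tctd_cys_sasa"
                         "\tcontrol_sasa\tbaseline_mean\tbaseline_sd\tclass\n")
                for r in reports:
                    c = "" if r.control_sasa is None else f"{r.control_sasa:.3f}"
                    fh.write(f"{r.protein_id}\t{r.boundary}"
                             f"\t{r.ntd_cys_sasa:.3f}\t{r.ctd_cys_sasa:.3f}"
                             f"\t{c}\t{r.baseline_mean:.3f}"
                             f"\t{r.baseline_sd:.3f}\t{r.exposure_class}\n")
            emit("exposure", p)
            summary = motif_classify.exclusivity_test(reports)
            ep = out / "exclusivity.tsv"
            with open(ep, "w") as fh:
                fh.write("class\tcount\n")
                for cls in sorted(summary.counts):
                    fh.write(f"{cls}\t{summary.counts[cls]}\n")
                fh.write(f"exceptions\t{','.join(summary.exceptions) or '-'}\n")
            emit("exclusivity", ep)

    log = out / "run_log.tsv"
    log.write_text("stage\tfile\tsha256_16\n" + "\n".join(log_lines) + "\n")
    manifest["log"] = str(log)
    return manifest
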