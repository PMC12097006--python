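"""Stage orchestration, run state, annotation assembly.

A run is a deterministic chain of stages over an input directory of
standard-format files (the external aligners/classifiers/binners are
never executed here — their outputs are consumed).  Every stage stores
its result as a JSON artifact under the output directory, so a later
run can start from any stored stage boundary and produce the same
annotation file as an uninterrupted run.  Stage timing is recorded and
reported per stage and in total.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import binroute, evaluation, familydb, krakenroute, seek, swissprot
from .taxdb import TaxDb

logger = logging.getLogger(__name__)

# Ordered stage registry.  The first four are stubs: they validate the
# externally produced inputs they would otherwise create.
STAGES = [
    "sra_fetch", "qc", "preprocess", "assembly",
    "gene_prediction_import", "clustering_import",
    "seek_screen", "pfam_annotate",
    "taxonomy_route", "binning", "quantify",
    "annotate",
]

_SEEK_ONLY = {"seek_screen", "pfam_annotate"}
_TAX_ONLY = {"taxonomy_route", "binning", "quantify"}

ANNOTATION_COLUMNS = [
    "protein_id", "contig_id", "start", "end", "strand",
    "has_start_codon", "has_stop_codon",
    "dist_to_contig_start", "dist_to_contig_end", "protein_length",
    "candidate_set", "spd_profiles",
    "best_sprot_hit", "sprot_pident", "sprot_evalue",
    "predicted_family", "family_mean_length", "length_difference",
    "motifs", "signal_peptide", "tm_count",
]
TAXONOMY_COLUMNS = ["bin_id", "taxa", "bin_reads", "bin_relative_abundance"]


@dataclass
class PipelineConfig:
    """Run configuration; a YAML config file overrides constructor
    defaults, CLI flags override the file."""

    input_dir: str = "."
    output_dir: str = "protfam_out"
    mode: str = "both"               # seek | taxonomy | both
    route: str = "kraken"            # kraken | binning
    analysis_type: int = 3           # 1 | 2 | 3
    start_stage: str = "sra_fetch"
    end_stage: str = "annotate"
    evalue_cutoff: float = seek.DEFAULT_TYPE2_EVALUE
    kraken_threshold: str = "0"      # comma list; first drives binning
    min_contig_len: int = binroute.DEFAULT_MIN_CONTIG_LEN
    motifs: list[str] = field(default_factory=list)
    threads: int = 1
    filtering_threads: int = 1
    name_threshold_pct: float = 0.0
    seed: int = 0
    bracken_read_length: int = krakenroute.BRACKEN_READ_LENGTH
    bracken_min_reads: int = krakenroute.BRACKEN_MIN_READS

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def validate(self) -> None:
        if self.mode not in ("seek", "taxonomy", "both"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.route not in ("kraken", "binning"):
            raise ValueError(
                f"unknown route: {self.route!r} (the read-classifier and "
                "binner routes cannot be combined in a single run)")
        if self.analysis_type not in (1, 2, 3):
            raise ValueError("analysis_type must be 1, 2 or 3")
        for s in (self.start_stage, self.end_stage):
            if s not in STAGES:
                raise ValueError(f"unknown stage: {s!r}")


@dataclass
class RunState:
    """Completed stages, their artifacts and elapsed seconds."""

    output_dir: str
    completed_stages: list[str] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)
    elapsed: dict[str, float] = field(default_factory=dict)
    reused: list[str] = field(default_factory=list)

    @property
    def path(self) -> Path:
        return Path(self.output_dir) / "state.json"

    def save(self) -> None:
        payload = asdict(self)
        with open(self.path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, output_dir) -> "RunState":
        p = Path(output_dir) / "state.json"
        if not p.exists():
            return cls(output_dir=str(output_dir))
        with open(p) as fh:
            data = json.load(fh)
        data["output_dir"] = str(output_dir)
        return cls(**data)


def plan_stages(config: PipelineConfig,
                state: RunState | None = None) -> list[str]:
    """Ordered stage subset for a run.

    Mode prunes the seek-only/taxonomy-only stages; start/end slice the
    chain.  Starting past a stage requires its stored artifact (or a
    stub) from a previous run — missing prerequisites raise with the
    missing artifact names.
    """
    config.validate()
    active = [s for s in STAGES
              if not (s in _SEEK_ONLY and config.mode == "taxonomy")
              and not (s in _TAX_ONLY and config.mode == "seek")]
    start = active.index(config.start_stage) if config.start_stage in active else 0
    end = (active.index(config.end_stage) if config.end_stage in active
           else len(active) - 1)
    if start > end:
        raise ValueError("start_stage is after end_stage")
    plan = active[start:end + 1]
    stubs = {"sra_fetch", "qc", "preprocess", "assembly"}
    if state is not None:
        missing = [s for s in active[:start]
                   if s not in stubs and s not in state.completed_stages]
        if missing:
            raise ValueError(
                "cannot start at "
                f"{config.start_stage!r}: missing stored artifacts for "
                + ", ".join(missing))
    return plan


def required_inputs(config: PipelineConfig) -> set[str]:
    """Input files (by fixture key) a planned run will read."""
    req = {"contigs", "genes"}
    if config.mode in ("seek", "both"):
        req.add("spd_domtbl")  # type 2 still excludes profile-positive proteins
        if config.analysis_type in (2, 3):
            req.add("sfpd_diamond")
        req |= {"sprot_diamond", "topology", "swissprot"}
    if config.mode in ("taxonomy", "both"):
        req |= {"sam", "nodes", "names"}
        if config.route == "kraken":
            req |= {"kraken_per_read", "kraken_report", "bracken"}
        else:
            req |= {"bins", "tpd_domtbl", "tfpd_diamond", "proteins_nr"}
    return req


_INPUT_FILES = {
    "swissprot": "swissprot.dat", "pfam_hmm": "pfam.hmm",
    "proteins_nr": "proteins_nr.fasta", "contigs": "contigs.fasta",
    "genes": "genes.faa", "sam": "reads.sam",
    "kraken_per_read": "kraken_per_read.tsv",
    "kraken_report": "kraken_report.tsv", "bracken": "bracken_report.tsv",
    "bins": "bins.tsv", "spd_domtbl": "spd_domtblout.tsv",
    "tpd_domtbl": "tpd_domtblout.tsv", "sfpd_diamond": "sfpd_diamond.tsv",
    "tfpd_diamond": "tfpd_diamond.tsv", "sprot_diamond": "swissprot_diamond.tsv",
    "topology": "phobius.tsv", "nodes": "nodes.dmp", "names": "names.dmp",
    "gold": "gold_standard.tsv",
}


class PipelineRun:
    """Executes a planned stage chain over an input directory."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.indir = Path(config.input_dir)
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        (self.outdir / "stages").mkdir(exist_ok=True)
        self.state = RunState.load(self.outdir)

    # -- artifact helpers ---------------------------------------------------
    def _input(self, key: str) -> Path:
        p = self.indir / _INPUT_FILES[key]
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
        return p

    def _artifact_path(self, stage: str) -> Path:
        return self.outdir / "stages" / f"{stage}.json"

    def _store(self, stage: str, payload: Any) -> None:
        p = self._artifact_path(stage)
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        self.state.artifacts[stage] = str(p)

    def _load(self, stage: str) -> Any:
        with open(self._artifact_path(stage)) as fh:
            return json.load(fh)

    # -- stage bodies -------------------------------------------------------
    def _stage_stub(self, stage: str) -> None:
        # validation stub for externally produced raw data
        self._store(stage, {"stub": True, "stage": stage})

    def _stage_gene_prediction_import(self) -> None:
        contigs = {}
        with open(self._input("contigs")) as fh:
            for header, s in familydb._read_fasta(fh):
                contigs[header.split()[0]] = s
        with open(self._input("genes")) as fh:
            pred = list(familydb._read_fasta(fh))
        calls = seek.annotate_gene_geometry(pred, contigs)
        self._store("gene_prediction_import", {
            "genes": [asdict(c) for c in calls],
            "contig_lengths": {c: len(s) for c, s in contigs.items()},
        })

    def _stage_clustering_import(self) -> None:
        # representative mapping accepted as optional TSV; identity here
        rep_path = self.indir / "representatives.tsv"
        mapping = {}
        if rep_path.exists():
            with open(rep_path) as fh:
                for line in fh:
                    pid, rep = line.rstrip("\n").split("\t")
                    mapping[pid] = rep
        self._store("clustering_import", {"representatives": mapping})

    def _stage_seek_screen(self) -> None:
        genes = self._load("gene_prediction_import")["genes"]
        proteins = {g["gene_id"] for g in genes}
        spd_hits = []
        if self.config.analysis_type in (1, 2, 3):
            with open(self._input("spd_domtbl")) as fh:
                spd_hits = seek.parse_domtblout(fh)
        set1 = seek.select_type1(proteins, spd_hits)
        set2: set[str] = set()
        if self.config.analysis_type in (2, 3):
            with open(self._input("sfpd_diamond")) as fh:
                sfpd_hits = seek.parse_alignment_tabular(fh)
            set2 = seek.select_type2(proteins, set1, sfpd_hits,
                                     self.config.evalue_cutoff)
        if self.config.analysis_type == 1:
            candidates = set1
        elif self.config.analysis_type == 2:
            candidates = set2
        else:
            candidates = set1 | set2
        spd_profiles: dict[str, list[str]] = {}
        for h in spd_hits:
            spd_profiles.setdefault(h.protein_id, [])
            if h.profile_accession not in spd_profiles[h.protein_id]:
                spd_profiles[h.protein_id].append(h.profile_accession)
        self._store("seek_screen", {
            "set1": sorted(set1), "set2": sorted(set2),
            "candidates": sorted(candidates),
            "spd_profiles": spd_profiles,
        })

    def _stage_pfam_annotate(self) -> None:
        genes = self._load("gene_prediction_import")["genes"]
        screen = self._load("seek_screen")
        candidates = set(screen["candidates"])
        with open(self._input("swissprot")) as fh:
            entries = swissprot.parse_flatfile(fh)
        kb = swissprot.build_family_kb(entries)
        acc2fam = {}
        for fam in kb:
            for acc in fam.member_accessions:
                acc2fam[acc] = fam
        with open(self._input("sprot_diamond")) as fh:
            sprot_hits = seek.parse_alignment_tabular(fh)
        with open(self._input("topology")) as fh:
            topo = seek.parse_topology(fh)
        ann: dict[str, dict[str, Any]] = {}
        for g in genes:
            pid = g["gene_id"]
            if pid not in candidates:
                continue
            plen = len(g["protein_seq"])
            own = [h for h in sprot_hits if h.query_id == pid]
            top = seek.best_hit(own)
            pred = seek.predict_family(pid, own, acc2fam, plen)
            motif_hits = seek.find_motifs(g["protein_seq"], self.config.motifs)
            sp, tm = topo.get(pid, (False, 0))
            ann[pid] = {
                "best_sprot_hit": top.subject_id if top else "",
                "sprot_pident": top.pident if top else None,
                "sprot_evalue": top.evalue if top else None,
                "predicted_family": pred.predicted_family_name if pred else "",
                "family_mean_length": pred.family_mean_length if pred else None,
                "length_difference": pred.length_difference if pred else None,
                "motifs": ";".join(
                    f"{m}@{','.join(map(str, pos))}" for m, pos in motif_hits),
                "signal_peptide": sp, "tm_count": tm,
            }
        self._store("pfam_annotate", ann)

    def _stage_taxonomy_route(self) -> None:
        taxdb = TaxDb(self._input("nodes"), self._input("names"))
        if self.config.route == "kraken":
            with open(self._input("kraken_per_read")) as pr, \
                 open(self._input("kraken_report")) as rp, \
                 open(self._input("bracken")) as br:
                cls, profile = krakenroute.parse_kraken_outputs(pr, rp, br)
            specs = krakenroute.parse_threshold_list(self.config.kraken_threshold)
            primary = specs[0] if specs else krakenroute.ThresholdSpec("absolute", 0)
            filtered = krakenroute.apply_threshold(profile, primary)
            for i, spec in enumerate(specs[1:], 1):
                extra = krakenroute.apply_threshold(profile, spec)
                with open(self.outdir / f"filtered_species_{i}.tsv", "w") as fh:
                    fh.write("species\ttaxid\treads\tfraction\n")
                    for nm, t, rd, fr in extra.records:
                        fh.write(f"{nm}\t{t}\t{rd}\t{fr:.8f}\n")
            read_map = krakenroute.parse_read_map(self._input("sam"))
            contig_taxa = krakenroute.assign_contig_species(
                read_map, cls, filtered.taxids(), taxdb)
            self._store("taxonomy_route", {
                "route": "kraken",
                "profile": filtered.records,
                "contig_species": {c.contig_id: c.species_taxid
                                   for c in contig_taxa},
            })
        else:
            genes = self._load("gene_prediction_import")["genes"]
            gene_index: dict[str, list[str]] = {}
            for g in genes:
                gene_index.setdefault(g["contig_id"], []).append(g["gene_id"])
            with open(self._input("tpd_domtbl")) as fh:
                tpd = seek.parse_domtblout(fh)
            with open(self._input("tfpd_diamond")) as fh:
                tfpd = seek.parse_alignment_tabular(fh)
            header_index: dict[str, list[str]] = {}
            with open(self._input("proteins_nr")) as fh:
                for header, _s in familydb._read_fasta(fh):
                    sid = header.split()[0]
                    header_index[sid] = familydb.extract_header_taxa(header)
            ptaxa = binroute.protein_taxa(tpd, tfpd, header_index, taxdb)
            self._store("taxonomy_route", {
                "route": "binning",
                "gene_index": gene_index,
                "protein_taxa": ptaxa,
            })

    def _stage_binning(self) -> None:
        tax = self._load("taxonomy_route")
        if tax["route"] == "kraken":
            contig_taxa = [
                krakenroute.ContigTaxonomy(c, t, {})
                for c, t in sorted(tax["contig_species"].items())]
            profile = krakenroute.AbundanceProfile(
                records=[tuple(r) for r in tax["profile"]])
            bins = krakenroute.bin_by_species(contig_taxa, profile)
            self._store("binning", {
                "bins": [{"bin_id": f"species_{b.species_taxid}",
                          "species_taxid": b.species_taxid,
                          "species_name": b.species_name,
                          "contigs": sorted(b.contig_ids),
                          "reads": b.reads, "fraction": b.fraction}
                         for b in bins]})
        else:
            genes = self._load("gene_prediction_import")
            lengths = genes["contig_lengths"]
            long_enough = binroute.filter_contigs_by_length(
                lengths, self.config.min_contig_len)
            with open(self._input("bins")) as fh:
                raw_bins = binroute.read_bin_tsv(fh)
            raw_bins = {b: cs & long_enough for b, cs in raw_bins.items()}
            raw_bins = {b: cs for b, cs in raw_bins.items() if cs}
            assignments = binroute.build_bin_assignments(
                raw_bins, tax["gene_index"], tax["protein_taxa"])
            self._store("binning", {
                "bins": [{"bin_id": a.bin_id, "contigs": sorted(a.contig_ids),
                          "taxa": a.taxa}
                         for a in assignments]})

    def _stage_quantify(self) -> None:
        tax = self._load("taxonomy_route")
        data = self._load("binning")
        if tax["route"] == "kraken":
            # species bins inherit the estimated abundances directly
            self._store("quantify", data)
            return
        assignments = [
            binroute.BinAssignment(bin_id=b["bin_id"],
                                   contig_ids=set(b["contigs"]),
                                   taxa=[tuple(t) for t in b["taxa"]])
            for b in data["bins"]]
        total = sum(1 for _ in krakenroute.parse_read_map(self._input("sam")))
        binroute.quantify_bins(assignments, self._input("sam"), total)
        taxdb = TaxDb(self._input("nodes"), self._input("names"))
        rows = binroute.postfilter_merge(assignments, taxdb=taxdb)
        binroute.write_species_report(rows, self.outdir / "species_report.tsv")
        self._store("quantify", {
            "bins": [{"bin_id": a.bin_id, "contigs": sorted(a.contig_ids),
                      "taxa": a.taxa, "mapped_reads": a.mapped_reads,
                      "relative_abundance": a.relative_abundance}
                     for a in assignments],
            "total_reads": total})

    def _stage_annotate(self) -> None:
        genes = self._load("gene_prediction_import")["genes"]
        rows: list[dict[str, Any]] = []
        screen = (self._load("seek_screen")
                  if self._artifact_path("seek_screen").exists() else None)
        seek_ann = (self._load("pfam_annotate")
                    if self._artifact_path("pfam_annotate").exists() else None)
        quant = (self._load("quantify")
                 if self._artifact_path("quantify").exists() else None)
        contig_bin: dict[str, dict[str, Any]] = {}
        if quant:
            for b in quant["bins"]:
                for c in b["contigs"]:
                    contig_bin[c] = b
        set1 = set(screen["set1"]) if screen else set()
        set2 = set(screen["set2"]) if screen else set()
        for g in genes:
            pid = g["gene_id"]
            row: dict[str, Any] = {
                "protein_id": pid, "contig_id": g["contig_id"],
                "start": g["start"], "end": g["end"], "strand": g["strand"],
                "has_start_codon": g["has_start_codon"],
                "has_stop_codon": g["has_stop_codon"],
                "dist_to_contig_start": g["dist_to_contig_start"],
                "dist_to_contig_end": g["dist_to_contig_end"],
                "protein_length": len(g["protein_seq"]),
            }
            if screen:
                row["candidate_set"] = ("1" if pid in set1
                                        else "2" if pid in set2 else "")
                row["spd_profiles"] = ",".join(
                    screen["spd_profiles"].get(pid, []))
            if seek_ann:
                row.update(seek_ann.get(pid, {}))
            if quant:
                b = contig_bin.get(g["contig_id"])
                if b is not None:
                    row["bin_id"] = b["bin_id"]
                    if "species_taxid" in b:     # read-classifier route
                        row["taxa"] = str(b["species_taxid"])
                        row["bin_reads"] = b["reads"]
                        row["bin_relative_abundance"] = b["fraction"]
                    else:
                        row["taxa"] = ",".join(str(t) for t, _f in b["taxa"])
                        row["bin_reads"] = b.get("mapped_reads", "")
                        row["bin_relative_abundance"] = b.get(
                            "relative_abundance", "")
            rows.append(row)
        include_seek = self.config.mode in ("seek", "both")
        include_tax = self.config.mode in ("taxonomy", "both")
        write_annotation(rows, self.outdir / "annotation.tsv",
                         include_seek=include_seek, include_tax=include_tax)
        self._store("annotate", {"rows": len(rows)})

    # -- driver -------------------------------------------------------------
    _BODIES = {
        "gene_prediction_import": _stage_gene_prediction_import,
        "clustering_import": _stage_clustering_import,
        "seek_screen": _stage_seek_screen,
        "pfam_annotate": _stage_pfam_annotate,
        "taxonomy_route": _stage_taxonomy_route,
        "binning": _stage_binning,
        "quantify": _stage_quantify,
        "annotate": _stage_annotate,
    }

    def run(self) -> RunState:
        plan = plan_stages(self.config, self.state)
        for prior in self.state.completed_stages:
            if prior not in plan and prior not in self.state.reused:
                self.state.reused.append(prior)
        for stage in plan:
            t0 = time.perf_counter()
            body = self._BODIES.get(stage)
            if body is None:
                self._stage_stub(stage)
            else:
                body(self)
            dt = time.perf_counter() - t0
            self.state.elapsed[stage] = dt
            if stage not in self.state.completed_stages:
                self.state.completed_stages.append(stage)
            logger.info("stage %-24s %8.3f s", stage, dt)
        self.state.save()
        return self.state


def run_pipeline(config: PipelineConfig) -> RunState:
    return PipelineRun(config).run()


# ---------------------------------------------------------------------------
# Annotation file
# ---------------------------------------------------------------------------

def write_annotation(rows: list[dict[str, Any]], path,
                     include_seek: bool = True,
                     include_tax: bool = True,
                     merge_previous: bool = True) -> None:
    """Write the per-protein annotation TSV with a stable column order.

    Taxonomy columns are present only when requested and stay blank for
    unbinned proteins.  When the target file already exists (a previous
    run with the same output name), its rows are merged: columns are
    unioned per protein, the row count is preserved, and a column
    carrying conflicting non-blank values raises.
    """
    cols = ["protein_id", "contig_id", "start", "end", "strand",
            "has_start_codon", "has_stop_codon", "dist_to_contig_start",
            "dist_to_contig_end", "protein_length"] + (
        ANNOTATION_COLUMNS[10:] if include_seek else [])
    if include_tax:
        cols = cols + TAXONOMY_COLUMNS
    path = Path(path)
    merged: dict[str, dict[str, str]] = {}
    old_cols: list[str] = []
    if merge_previous and path.exists():
        with open(path) as fh:
            old_cols = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                vals = line.rstrip("\n").split("\t")
                rec = dict(zip(old_cols, vals))
                merged[rec["protein_id"]] = rec
    all_cols = list(dict.fromkeys(old_cols + cols))
    out_rows: list[dict[str, str]] = []
    for row in rows:
        pid = str(row["protein_id"])
        rec = merged.pop(pid, {})
        for c in cols:
            new = _fmt(row.get(c, ""))
            old = rec.get(c, "")
            if old and new and old != new:
                raise ValueError(
                    f"annotation merge conflict for {pid}, column {c!r}")
            rec[c] = new or old
        out_rows.append(rec)
    out_rows.extend(merged.values())  # rows only present in the previous run
    with open(path, "w") as fh:
        fh.write("\t".join(all_cols) + "\n")
        for rec in out_rows:
            fh.write("\t".join(rec.get(c, "") for c in all_cols) + "\n")


def _fmt(v: Any) -> str:
    if v is None or v == "":
        return ""
    if isinstance(v, bool):
        return "yes" if v else "no"
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def timing_report(state: RunState) -> list[tuple[str, float, str]]:
    """(stage, seconds, status) per stage plus a ("total", sum, "") row.
    Stages imported from a previous run are marked "reused"."""
    rows: list[tuple[str, float, str]] = []
    for stage in state.completed_stages:
        status = "reused" if stage in state.reused else "run"
        rows.append((stage, state.elapsed.get(stage, 0.0), status))
    total = sum(state.elapsed.get(s, 0.0) for s in state.completed_stages)
    rows.append(("total", total, ""))
    return rows


# ---------------------------------------------------------------------------
# Evaluation driver
# ---------------------------------------------------------------------------

def evaluate_run(predicted: krakenroute.AbundanceProfile, gold_path,
                 key: str = "taxid",
                 universe_size: int | None = None) -> evaluation.EvalResult:
    with open(gold_path) as fh:
        gold = evaluation.read_gold_standard(fh)
    return evaluation.evaluate_profile(predicted, gold, key=key,
                                       universe_size=universe_size)
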