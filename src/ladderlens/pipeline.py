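"""End-to-end orchestration: scan -> classify -> profile -> phylo -> dnds -> struct.

A run is driven by a strict plain-text (YAML) config; every stage logs its
parameters and input/output counts, all outputs are tab-separated tables, and
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import io as llio
from .dnds import locus_mean_dnds
from .ladder import (ArchitectureCall, BreakRule, classify_architecture,
                     consensus_ladder_profile, ladder_competence, segment_modules)
from .lrr import MotifParams, detect_lrr_modules
from .phylo import assign_families, nj_tree, protein_distance
from .structure import align_structures, class_summary

logger = logging.getLogger("ladderlens")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record/path."""


@dataclass
class AlignmentJob:
    path: str
    reference: str
    label: Optional[str] = None


@dataclass
class LocusJob:
    path: str
    label: str


@dataclass
class StructJob:
    pdb_dir: str
    pairs: str                 # TSV: fileA chainA fileB chainB
    classes: Optional[str] = None  # TSV: trace_id class


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys in the YAML are rejected."""

    output_dir: str
    ectodomains: Optional[str] = None
    alignments: list[AlignmentJob] = field(default_factory=list)
    family_alignment: Optional[str] = None
    family_references: Optional[str] = None
    cds: list[LocusJob] = field(default_factory=list)
    structures: Optional[StructJob] = None
    seed: int = 0
    bootstrap: int = 1000
    min_score: float = 3.0
    min_len: int = 20
    max_len: int = 30
    break_min_run: int = 2
    break_min_fraction: float = 0.4

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "alignments" in raw:
            raw["alignments"] = [AlignmentJob(**a) for a in raw["alignments"]]
        if "cds" in raw:
            raw["cds"] = [LocusJob(**c) for c in raw["cds"]]
        if "structures" in raw and raw["structures"] is not None:
            raw["structures"] = StructJob(**raw["structures"])
        if "output_dir" not in raw:
            raise PipelineError("config: output_dir is required")
        return cls(**raw)

    def motif_params(self) -> MotifParams:
        return MotifParams(min_score=self.min_score, min_len=self.min_len,
                           max_len=self.max_len)

    def break_rule(self) -> BreakRule:
        return BreakRule(min_run=self.break_min_run,
                         min_fraction=self.break_min_fraction)


def summarize_architecture_counts(calls: Sequence[ArchitectureCall]) -> dict[str, int]:
    """Verdict -> count map over a set of architecture calls."""
    if not calls:
        raise ValueError("no architecture calls to summarize")
    counts = dict(Counter(c.verdict for c in calls))
    if counts.get("AMBIGUOUS", 0) == len(calls):
        logger.warning("all %d architecture calls are AMBIGUOUS", len(calls))
    return counts


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


@_stage("scan")
def _run_scan(config: PipelineConfig, outdir: Path) -> dict:
    records = llio.read_fasta(config.ectodomains, "protein")
    params = config.motif_params()
    annotations = {}
    rows = []
    for rec in records:
        ann = detect_lrr_modules(rec.sequence, params, record_id=rec.id)
        annotations[rec.id] = ann
        for mod in ann.modules:
            rows.append((rec.id, mod.index, mod.start, mod.end,
                         mod.ladder_position, mod.ladder_residue, mod.motif_score))
    llio.write_tsv(outdir / "modules.tsv",
                   ["record", "module_index", "start", "end", "ladder_pos",
                    "ladder_res", "score"], rows)
    logger.info("scan: %d records, %d modules total", len(records), len(rows))
    return annotations


@_stage("classify")
def _run_classify(config: PipelineConfig, annotations: dict, outdir: Path) -> list:
    rule = config.break_rule()
    calls = []
    rows = []
    for rec_id, ann in annotations.items():
        if ann.n_modules < 6:
            rows.append((rec_id, "AMBIGUOUS", ann.n_modules, "NA", "NA", "NA",
                         "too few modules to segment"))
            continue
        flags = [ladder_competence(r) for r in ann.ladder_residues]
        call = classify_architecture(flags, rule=rule)
        calls.append(call)
        diag = ";".join(f"{s.name}:frac={s.incompetent_fraction:.2f},run={s.longest_incompetent_run}"
                        for s in call.segments)
        nb, cb, ctb = call.broken_flags
        rows.append((rec_id, call.verdict, ann.n_modules, int(nb), int(cb), int(ctb), diag))
    llio.write_tsv(outdir / "arch.tsv",
                   ["record", "verdict", "n_modules", "n_broken", "central_broken",
                    "c_broken", "diagnostics"], rows)
    logger.info("classify: %d calls: %s", len(calls),
                summarize_architecture_counts(calls) if calls else {})
    return calls


@_stage("profile")
def _run_profiles(config: PipelineConfig, annotations: dict, outdir: Path) -> list:
    rows = []
    profiles = []
    for job in config.alignments:
        aln = llio.read_alignment(job.path)
        if job.reference not in annotations:
            raise PipelineError(f"stage profile: reference {job.reference!r} was not scanned")
        profile = consensus_ladder_profile(aln, annotations[job.reference], job.reference)
        call = profile.classify(config.break_rule())
        profiles.append((job.label or job.reference, profile, call))
        for e in profile.entries:
            rows.append((job.label or job.reference, e.module_index, e.modal_residue,
                         f"{e.modal_frequency:.3f}", int(e.competent),
                         e.grade if e.grade is not None else "NA", call.verdict))
    llio.write_tsv(outdir / "ladder_profile.tsv",
                   ["family", "module_index", "modal_residue", "modal_freq",
                    "competent", "grade", "verdict"], rows)
    logger.info("profile: %d families", len(profiles))
    return profiles


@_stage("phylo")
def _run_phylo(config: PipelineConfig, outdir: Path) -> dict:
    aln = llio.read_alignment(config.family_alignment)
    refs = {}
    with open(config.family_references) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                rec_id, fam = line.rstrip("\n").split("\t")[:2]
                refs[rec_id] = fam
    dm = protein_distance(aln)
    tree = nj_tree(dm)
    families = assign_families(tree, refs)
    (outdir / "tree.nwk").write_text(llio.write_newick(tree) + "\n")
    llio.write_tsv(outdir / "families.tsv", ["record", "family"],
                   sorted(families.items()))
    logger.info("phylo: %d leaves, %d references, %d assigned",
                len(families), len(refs),
                sum(1 for f in families.values() if f != "UNASSIGNED"))
    return families


@_stage("dnds")
def _run_dnds(config: PipelineConfig, outdir: Path) -> list:
    rows = []
    summaries = []
    for i, job in enumerate(config.cds):
        records = llio.read_fasta(job.path, "nucleotide")
        summary = locus_mean_dnds(records, n_boot=config.bootstrap,
                                  seed=config.seed + i, locus=job.label)
        summaries.append(summary)
        rows.append((summary.locus, summary.mean_omega, summary.ci_low,
                     summary.ci_high, summary.n_sequences, summary.n_pairs))
    llio.write_tsv(outdir / "dnds.tsv",
                   ["locus", "mean_omega", "ci_low", "ci_high", "n_seq", "n_pairs"],
                   rows)
    logger.info("dnds: %d loci", len(summaries))
    return summaries


@_stage("struct")
def _run_struct(config: PipelineConfig, outdir: Path) -> list:
    job = config.structures
    classes = {}
    if job.classes:
        with open(job.classes) as fh:
            fh.readline()
            for line in fh:
                if line.strip():
                    trace_id, cls = line.rstrip("\n").split("\t")[:2]
                    classes[trace_id] = cls
    rows = []
    labeled = []
    with open(job.pairs) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            fa, ca, fb, cb = line.rstrip("\n").split("\t")[:4]
            ta = llio.read_ca_trace(os.path.join(job.pdb_dir, fa), ca)
            tb = llio.read_ca_trace(os.path.join(job.pdb_dir, fb), cb)
            _, comp = align_structures(ta, tb)
            rows.append((ta.id, tb.id, comp.tm_a, comp.tm_b, comp.tm_avg, comp.rmsd))
            if ta.id in classes and tb.id in classes:
                labeled.append((classes[ta.id], classes[tb.id], comp.tm_avg))
    llio.write_tsv(outdir / "tm.tsv",
                   ["trace_a", "trace_b", "tm_a", "tm_b", "tm_avg", "rmsd"], rows)
    if labeled:
        llio.write_tsv(outdir / "tm_classes.tsv",
                       ["class_a", "class_b", "mean_tm", "sem", "n"],
                       [(s.class_a, s.class_b, s.mean, s.sem, s.n)
                        for s in class_summary(labeled)])
    logger.info("struct: %d pairs, %d labeled", len(rows), len(labeled))
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a bundle of in-memory results.

    Output TSVs, the newick tree and ``run.log`` land in ``config.output_dir``.
    Stage failures raise :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    bundle: dict = {}
    try:
        logger.info("config: %s", config)
        if config.ectodomains:
            annotations = _run_scan(config, outdir)
            bundle["annotations"] = annotations
            bundle["calls"] = _run_classify(config, annotations, outdir)
            if config.alignments:
                bundle["profiles"] = _run_profiles(config, annotations, outdir)
        if config.family_alignment and config.family_references:
            bundle["families"] = _run_phylo(config, outdir)
        if config.cds:
            bundle["dnds"] = _run_dnds(config, outdir)
        if config.structures:
            bundle["tm"] = _run_struct(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return bundle
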