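"""End-to-end orchestration: preprocess -> classify -> isomiR -> tiRNA ->
quant for a control and a stress library, plus cross-condition comparisons.

All result tables are TSV (fractions at 6 decimals) for diff-ability; a JSON
manifest records the package version, seed, parameters and input checksums
so a run can be replayed. Logs go to stderr; results only to files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from . import classify as _classify
from . import isomir as _isomir
from . import quant as _quant
from . import tirna as _tirna
from .preprocess import TRUSEQ_SMALL_RNA_ADAPTER, ReadSet, preprocess_reads
from .references import (DEFAULT_HIERARCHY, ReferenceSet, load_background,
                         load_mirna_annotation, load_trna_annotation)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"


@dataclass
class RunConfig:
    """Paths and parameters of one control-vs-stress run."""

    mirna_fasta: str
    mirna_gff3: str
    trna_fasta: str
    trna_tsv: str
    reads: dict[str, str]                  # condition -> FASTQ/FASTA path
    out_dir: str
    background: dict[str, str] = field(default_factory=dict)
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    min_overlap: int = 5
    min_len: int = 15
    quality_cutoff: int = 20
    clip_policy: str = "keep"
    strata: tuple[int, ...] = (18, 22, 32)
    hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY
    nta_min_reads: int = 500
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        paths = [self.mirna_fasta, self.mirna_gff3, self.trna_fasta,
                 self.trna_tsv, *self.reads.values(), *self.background.values()]
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if set(self.reads) != {"control", "stress"}:
            raise ValueError("reads must map exactly the conditions "
                             "'control' and 'stress'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("strata", "hierarchy"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["strata"] = list(self.strata)
        data["hierarchy"] = list(self.hierarchy)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def load_references(config: RunConfig) -> ReferenceSet:
    return ReferenceSet(
        mirna_loci=load_mirna_annotation(config.mirna_fasta, config.mirna_gff3),
        trna_genes=load_trna_annotation(config.trna_fasta, config.trna_tsv),
        background=load_background(config.background),
        class_hierarchy=tuple(config.hierarchy),
    )


def analyse_condition(reads: ReadSet, refs: ReferenceSet,
                      config: RunConfig) -> dict:
    """Classify + isomiR + tiRNA for one condition's read set."""
    index = _classify.build_index(refs)
    matcher = _isomir.IsomirMatcher(refs.mirna_loci)
    assignments = _classify.classify_reads(reads, refs, index=index,
                                           matcher=matcher)
    comp = _classify.composition(assignments, strata=config.strata,
                                 sample_id=reads.sample_id)
    mirna_reads = [(a.sequence, a.count) for a in assignments
                   if a.resolved_class == "miRNA"]
    calls = _isomir.call_reads(mirna_reads, refs.mirna_loci, matcher=matcher)
    profiles, discarded = _tirna.build_profiles(assignments, refs)
    return {
        "reads": reads,
        "assignments": assignments,
        "composition": comp,
        "calls": calls,
        "tirna_profiles": profiles,
        "tirna_discarded": discarded,
    }


def run_all(config: RunConfig,
            preprocessed: Mapping[str, ReadSet] | None = None,
            refs: ReferenceSet | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    ``preprocessed`` bypasses FASTQ parsing with ready ReadSets and ``refs``
    bypasses annotation files with a loaded ReferenceSet (both used by the
    simulator-driven entry points).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if preprocessed is None:
        config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if refs is None:
        stage = "references"
        try:
            refs = load_references(config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    results = {}
    for condition in ("control", "stress"):
        stage = f"preprocess[{condition}]"
        try:
            if preprocessed is not None:
                reads = preprocessed[condition]
            else:
                reads = preprocess_reads(
                    config.reads[condition], adapter=config.adapter,
                    min_overlap=config.min_overlap, min_len=config.min_len,
                    quality_cutoff=config.quality_cutoff,
                    policy=config.clip_policy, sample_id=condition)
            stage = f"analyse[{condition}]"
            results[condition] = analyse_condition(reads, refs, config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "report"
    try:
        _write_reports(results, refs, config, out)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    return out


def _write_reports(results: dict, refs: ReferenceSet, config: RunConfig,
                   out: Path) -> None:
    de_note = ("# simplified differential test (exact binomial / NB Wald); "
               "not a DESeq2 reimplementation\n")

    comp_tables = []
    for condition, res in results.items():
        t = res["composition"].table.copy()
        t.insert(0, "sample", condition)
        comp_tables.append(t)
    _write(pd.concat(comp_tables, ignore_index=True), out / "composition.tsv",
           index=False)

    length_rows = []
    for condition, res in results.items():
        for cls in [None, "miRNA", "tRNA"]:
            hist = _classify.length_histogram(res["assignments"], cls=cls)
            for length, count in hist.items():
                length_rows.append((condition, cls or "all", length, count))
    _write(pd.DataFrame(length_rows, columns=["sample", "class", "length", "count"]),
           out / "lengths.tsv", index=False)

    ratio = _classify.class_abundance_ratio(results["control"]["composition"],
                                            results["stress"]["composition"])
    _write(ratio, out / "class_ratio.tsv")

    call_tables = []
    for condition, res in results.items():
        t = res["calls"].copy()
        t.insert(0, "sample", condition)
        call_tables.append(t)
    calls_all = pd.concat(call_tables, ignore_index=True)
    _write(calls_all.groupby(["sample", "mature_id", "arm", "shift5", "shift3",
                              "tail", "category"], as_index=False)["count"].sum(),
           out / "isomir_calls.tsv", index=False)

    nta_rows = []
    profiles = {}
    for condition, res in results.items():
        prof = _isomir.nta_fractions(res["calls"], scope="per-miRNA")
        profiles[condition] = prof
        glob = _isomir.nta_fractions(res["calls"], scope="global")
        for label in _isomir.ALL_TYPE_LABELS:
            nta_rows.append((condition, label, int(glob.type_counts[label]),
                             glob.fraction(label)))
    _write(pd.DataFrame(nta_rows, columns=["sample", "tail_type", "count", "fraction"]),
           out / "nta_profile.tsv", index=False)
    _write(_isomir.compare_nta(profiles["control"], profiles["stress"],
                               min_reads=config.nta_min_reads),
           out / "nta_comparison.tsv")

    counts = pd.DataFrame({
        condition: _isomir.mirna_counts(res["calls"])
        for condition, res in results.items()
    }).fillna(0).astype(int)
    counts.index.name = "mature_id"
    _write(counts, out / "mirna_counts.tsv")
    cm = _quant.CountMatrix(counts)
    de = _quant.simple_de(cm, {c: c for c in counts.columns}, baseline="control")
    with open(out / "de_results.tsv", "w") as fh:
        fh.write(de_note)
        de.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)

    iso_counts = {}
    for condition, res in results.items():
        iso_counts[condition] = pd.Series(
            {iso: p.total_count for iso, p in res["tirna_profiles"].items()},
            dtype=float)
    logfc = _tirna.isotype_logfc(iso_counts["control"], iso_counts["stress"])
    tirna_tables = []
    for condition, res in results.items():
        t = _tirna.profiles_table(res["tirna_profiles"],
                                  logfc if condition == "stress" else None)
        t.insert(0, "sample", condition)
        tirna_tables.append(t.reset_index())
    _write(pd.concat(tirna_tables, ignore_index=True), out / "tirna_profiles.tsv",
           index=False)
    for condition, res in results.items():
        _write(_tirna.coverage_table(res["tirna_profiles"]),
               out / f"tirna_coverage_{condition}.tsv", index=False)

    shift = _isomir.length_shift_test(results["control"]["reads"],
                                      results["stress"]["reads"])
    _write(pd.DataFrame([{
        "statistic": shift.statistic, "pvalue": shift.pvalue,
        "median_ctrl": shift.median_ctrl, "median_stress": shift.median_stress,
        "shift": shift.shift}]), out / "length_shift.tsv", index=False)

    fp_tables = []
    for condition, res in results.items():
        t = _isomir.fiveprime_isomir_summary(res["calls"]).reset_index()
        t.insert(0, "sample", condition)
        fp_tables.append(t)
    _write(pd.concat(fp_tables, ignore_index=True), out / "fiveprime_summary.tsv",
           index=False)

    premod_tables = []
    for condition, res in results.items():
        t = _isomir.premodified_length_distribution(res["calls"]).reset_index()
        t.insert(0, "sample", condition)
        premod_tables.append(t)
    _write(pd.concat(premod_tables, ignore_index=True),
           out / "premodified_lengths.tsv", index=False)

    manifest = {
        "package": "srnaproc",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "adapter": config.adapter, "min_overlap": config.min_overlap,
            "min_len": config.min_len, "quality_cutoff": config.quality_cutoff,
            "strata": list(config.strata), "hierarchy": list(config.hierarchy),
            "nta_min_reads": config.nta_min_reads,
        },
        "inputs": {
            name: _sha256(path)
            for name, path in {
                "mirna_fasta": config.mirna_fasta,
                "mirna_gff3": config.mirna_gff3,
                "trna_fasta": config.trna_fasta,
                "trna_tsv": config.trna_tsv,
                **{f"reads_{c}": p for c, p in config.reads.items()},
                **{f"bg_{c}": p for c, p in config.background.items()},
            }.items() if Path(path).is_file()
        },
        "tirna_discarded": {c: results[c]["tirna_discarded"] for c in results},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
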