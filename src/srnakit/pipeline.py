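"""Pipeline orchestration: clean -> annotate -> discover -> reclassify ->
quantify -> classify, plus the summary tables behind the standard figures
(length spectrum, 5' nucleotide frequency, genome-location counts).

Configuration is a flat key = value text file; every threshold of every
stage is echoed to the run log so a run is fully auditable. All outputs are
newline-terminated TSV re-parseable by the package's own readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .expression_stats import ExpressionRecord, expression_frame, quantify
from .io_formats import (
    GenomicInterval,
    read_fasta,
    read_fastq,
    read_gff3,
    to_rna,
)
from .mirna_discovery import (
    DiscoveryParams,
    MiRNARecord,
    call_novel_mirnas,
    reclassify_reported_mirna,
)
from .read_cleaning import (
    CleaningParams,
    CleanTag,
    clean_library,
    collapse_tags,
    length_distribution,
    tags_to_frame,
    tally_frame,
)
from .synthetic_data import SimConfig, build_contaminants, build_genome, \
    simulate_libraries, write_reference_files
from .tag_annotation import FeatureIndex, ReferenceSet, TagAnnotation, \
    annotate_tags

logger = logging.getLogger("srnakit")


@dataclass
class PipelineConfig:
    # inputs
    genome_fasta: str = ""
    gff3: str = ""
    contaminant_fasta: str = ""
    known_mirna_fasta: str = ""
    sample_sheet: str = ""
    known_precursor_fasta: str = ""   # optional, enables re-classification
    output_dir: str = "srnakit_out"
    seed: int = 1
    # cleaning
    adapter3: str = ""
    adapter5: str = ""
    quality_threshold: float = 20.0
    min_length: int = 18
    max_length: int = 30
    adapter_seed: int = 8
    polya_fraction: float = 0.8
    polya_run: int = 10
    # annotation
    contaminant_mismatches: int = 0
    known_mismatches: int = 2
    # discovery
    flank: int = 180
    min_loop: int = 8
    max_duplex_mismatches: int = 4
    max_duplex_bulges: int = 2
    min_pairing_fraction: float = 0.6
    min_score_per_base: float = 0.25
    min_total_count: int = 3
    max_genome_hits: int = 10
    wc_only_class3: bool = True
    # expression
    isomir_window: int = 2
    pseudocount: float = 0.01
    test_pseudocount: float = 1.0

    def cleaning_params(self) -> CleaningParams:
        return CleaningParams(
            quality_threshold=self.quality_threshold,
            min_length=self.min_length,
            max_length=self.max_length,
            adapter_seed=self.adapter_seed,
            polya_fraction=self.polya_fraction,
            polya_run=self.polya_run,
        )

    def discovery_params(self) -> DiscoveryParams:
        return DiscoveryParams(
            flank=self.flank,
            min_loop=self.min_loop,
            max_duplex_mismatches=self.max_duplex_mismatches,
            max_duplex_bulges=self.max_duplex_bulges,
            min_pairing_fraction=self.min_pairing_fraction,
            min_score_per_base=self.min_score_per_base,
            min_total_count=self.min_total_count,
            max_genome_hits=self.max_genome_hits,
            wc_only_class3=self.wc_only_class3,
        )


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def load_config(path: str | Path, overrides: Sequence[str] = ()) -> PipelineConfig:
    """Parse a flat ``key = value`` config file with optional CLI overrides."""
    values: dict[str, str] = {}
    if path:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, _, value = line.partition("=")
                values[key.strip()] = value.strip()
    for item in overrides:
        key, _, value = item.partition("=")
        values[key.strip()] = value.strip()
    return config_from_mapping(values)


def config_from_mapping(values: Mapping[str, str]) -> PipelineConfig:
    kwargs: dict = {}
    for key, raw in values.items():
        if key not in _FIELD_TYPES:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = _coerce(key, raw)
    config = PipelineConfig(**kwargs)
    validate_config(config)
    return config


def _coerce(key: str, raw: str):
    ftype = str(_FIELD_TYPES[key])
    if "bool" in ftype:
        if raw.lower() in ("1", "true", "yes"):
            return True
        if raw.lower() in ("0", "false", "no"):
            return False
        raise ValueError(f"config key {key}: not a boolean: {raw!r}")
    if "int" in ftype:
        return int(raw)
    if "float" in ftype:
        return float(raw)
    return raw


def validate_config(config: PipelineConfig) -> None:
    if config.flank < 0:
        raise ValueError("flank must be >= 0")
    if not (0 <= config.min_pairing_fraction <= 1):
        raise ValueError("min_pairing_fraction must lie in [0, 1]")
    if config.min_length < 1 or config.max_length < config.min_length:
        raise ValueError("bad insert length bounds")
    if config.isomir_window < 0 or config.isomir_window > 2:
        raise ValueError("isomir_window must lie in 0-2")
    if config.pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")


def show_config(config: PipelineConfig) -> str:
    return "\n".join(
        f"{f.name} = {getattr(config, f.name)}" for f in fields(config))


@dataclass
class PipelineResult:
    tags: list[CleanTag]
    tallies: pd.DataFrame
    annotations: list[TagAnnotation]
    novel: list[MiRNARecord]
    reclassified: list[tuple[str, str | None]]   # (name, group or None)
    expression: list[ExpressionRecord]
    tables: dict[str, Path]


STAGES = ("clean", "annotate", "discover", "reclassify", "quantify")


def run_pipeline(config: PipelineConfig, through: str = "quantify"
                 ) -> PipelineResult:
    """Execute the pipeline up to and including stage ``through``.

    Deterministic for a fixed config: rerunning yields byte-identical tables.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    last = STAGES.index(through)
    validate_config(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir, config)

    try:
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        genome = read_fasta(config.genome_fasta)
        features = read_gff3(config.gff3)
        contaminant_set = ReferenceSet(
            "contaminants", tuple(read_fasta(config.contaminant_fasta)))
        known_set = ReferenceSet(
            "known_miRNAs", tuple(read_fasta(config.known_mirna_fasta)))
    except Exception as exc:
        raise RuntimeError(f"stage=load: {exc}") from exc

    libraries = list(sheet["sample_id"])
    groups = dict(zip(sheet["sample_id"], sheet["group"]))

    # --- clean ---------------------------------------------------------
    try:
        params = config.cleaning_params()
        inserts_by_library: dict[str, list[str]] = {}
        tallies = {}
        for _, row in sheet.iterrows():
            inserts, tally = clean_library(
                read_fastq(row["path"]), config.adapter3, config.adapter5, params)
            inserts_by_library[row["sample_id"]] = inserts
            tallies[row["sample_id"]] = tally
        tags = collapse_tags(inserts_by_library, libraries)
        for lib, tally in tallies.items():
            tally.unique_tags = sum(
                1 for t in tags if t.counts.get(lib, 0) > 0)
    except Exception as exc:
        raise RuntimeError(f"stage=clean: {exc}") from exc
    totals = {lib: tallies[lib].surviving_reads for lib in libraries}
    logger.info("cleaned %d libraries, %d unique tags", len(libraries), len(tags))

    annotations: list[TagAnnotation] = []
    novel: list[MiRNARecord] = []
    reclassified: list[tuple[str, str | None]] = []
    known_records: list[MiRNARecord] = []
    expression: list[ExpressionRecord] = []
    index = FeatureIndex(features)
    dparams = config.discovery_params()

    # --- annotate ------------------------------------------------------
    if last >= STAGES.index("annotate"):
        try:
            annotations = annotate_tags(
                tags, contaminant_set, known_set, genome, features,
                config.contaminant_mismatches, config.known_mismatches)
        except Exception as exc:
            raise RuntimeError(f"stage=annotate: {exc}") from exc

    # --- discover ------------------------------------------------------
    if last >= STAGES.index("discover"):
        try:
            tag_hits = {
                ann.tag.seq: ann.hits
                for ann in annotations if ann.tier == "genome_mapped"
            }
            tag_counts = {ann.tag.seq: ann.tag.total for ann in annotations}
            novel = call_novel_mirnas(tag_hits, tag_counts, genome, index,
                                      dparams)
        except Exception as exc:
            raise RuntimeError(f"stage=discover: {exc}") from exc
        logger.info("called %d novel miRNAs", len(novel))

    # --- reclassify ----------------------------------------------------
    if last >= STAGES.index("reclassify"):
        try:
            precursors = {}
            if config.known_precursor_fasta:
                precursors = {r.id: r.seq
                              for r in read_fasta(config.known_precursor_fasta)}
            for rec in known_set.records:
                group, new_rec = reclassify_reported_mirna(
                    rec.seq, precursors.get(rec.id), genome, index, dparams,
                    name=rec.id)
                reclassified.append((rec.id, group))
                if new_rec is not None:
                    known_records.append(new_rec)
        except Exception as exc:
            raise RuntimeError(f"stage=reclassify: {exc}") from exc

    # --- quantify ------------------------------------------------------
    if last >= STAGES.index("quantify"):
        try:
            counts = count_mirna_reads(novel, annotations, known_set,
                                       config.isomir_window, libraries)
            expression = quantify(counts, totals, groups, config.pseudocount,
                                  config.test_pseudocount)
        except Exception as exc:
            raise RuntimeError(f"stage=quantify: {exc}") from exc

    # --- report --------------------------------------------------------
    mirna_records = novel + [r for r in known_records
                             if r.stem_loop_group in (None, "II", "III")]
    tables = _write_tables(outdir, config, libraries, tags, tallies,
                           annotations, novel, reclassified, expression,
                           mirna_records)
    return PipelineResult(tags, tally_frame(tallies), annotations, novel,
                          reclassified, expression, tables)


def count_mirna_reads(novel: Sequence[MiRNARecord],
                      annotations: Sequence[TagAnnotation],
                      known_set: ReferenceSet,
                      isomir_window: int,
                      libraries: Sequence[str]) -> pd.DataFrame:
    """miRNA x library count table.

    A known miRNA's count is the sum over tags matched to its reference id.
    A novel miRNA's count sums tags whose genomic hit lies within its mature
    interval padded by the isomiR window (captures ragged-end variants).
    """
    from intervaltree import IntervalTree

    rows: dict[str, dict[str, int]] = {}
    for rec in known_set.records:
        rows[rec.id] = dict.fromkeys(libraries, 0)
    for rec in novel:
        rows[rec.name] = dict.fromkeys(libraries, 0)

    trees: dict[tuple[str, str], IntervalTree] = {}
    for rec in novel:
        target = rec.mature_interval
        if target is None:
            continue
        tree = trees.setdefault((target.chrom, target.strand), IntervalTree())
        tree.addi(target.start - isomir_window, target.end + isomir_window + 1,
                  rec.name)

    for ann in annotations:
        if ann.tier == "known_miRNA":
            for lib in libraries:
                rows[ann.matched_id][lib] += ann.tag.counts.get(lib, 0)
        elif ann.tier == "genome_mapped":
            credited: set[str] = set()
            for hit in ann.hits:
                tree = trees.get((hit.chrom, hit.strand))
                if tree is None:
                    continue
                for iv in tree.overlap(hit.start, hit.end + 1):
                    # the tag must lie fully inside the padded mature window
                    if (iv.data not in credited
                            and hit.start >= iv.begin
                            and hit.end < iv.end):
                        for lib in libraries:
                            rows[iv.data][lib] += ann.tag.counts.get(lib, 0)
                        credited.add(iv.data)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "name"
    return frame[list(libraries)]


def summarize_first_nucleotide(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    """Per mature length 18-24, the proportion of A/C/G/U at position 1."""
    if not records:
        raise ValueError("no miRNA records")
    counts: dict[int, dict[str, int]] = {
        n: {b: 0 for b in "ACGU"} for n in range(18, 25)}
    for rec in records:
        n = rec.length
        if 18 <= n <= 24:
            counts[n][to_rna(rec.mature_seq[0])] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")
    totals = df.sum(axis=1)
    return df.div(totals.where(totals > 0, 1), axis=0)


def summarize_locations(records: Sequence[MiRNARecord]) -> dict[str, int]:
    """Counts per location class; multi-location records count once by their
    first class."""
    out = {"intergenic": 0, "intron": 0, "exon": 0, "three_prime_UTR": 0}
    if not records:
        logger.warning("no miRNA records to summarize")
        return out
    for rec in records:
        cls = rec.location_classes[0] if rec.location_classes else "intergenic"
        out[cls] += 1
    return out


def simulate_inputs(sim: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a complete synthetic input set (genome, annotation,
    references, libraries, sample sheet) under ``outdir``."""
    outdir = Path(outdir)
    genome, features, truth = build_genome(sim)
    contaminants = build_contaminants(sim)
    paths = write_reference_files(outdir, genome, features, truth, contaminants)
    simulate_libraries(genome, truth, sim, outdir, contaminants, features)
    paths["sample_sheet"] = outdir / "samples.tsv"
    return paths


def config_for_simulation(sim: SimConfig, indir: str | Path,
                          outdir: str | Path) -> PipelineConfig:
    indir = Path(indir)
    return PipelineConfig(
        genome_fasta=str(indir / "genome.fasta"),
        gff3=str(indir / "annotation.gff3"),
        contaminant_fasta=str(indir / "contaminants.fasta"),
        known_mirna_fasta=str(indir / "known_mirnas.fasta"),
        sample_sheet=str(indir / "samples.tsv"),
        output_dir=str(outdir),
        seed=sim.seed,
        adapter3=sim.adapter3,
        adapter5=sim.adapter5,
    )


def _setup_log(outdir: Path, config: PipelineConfig) -> None:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers = [handler]
    logger.setLevel(logging.INFO)
    logger.info("srnakit %s", __version__)
    for line in show_config(config).splitlines():
        logger.info("config %s", line)


def _write_tables(outdir, config, libraries, tags, tallies, annotations,
                  novel, reclassified, expression, mirna_records
                  ) -> dict[str, Path]:
    tables: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame, **kw) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", **kw)
        tables[name] = path

    save("tags", tags_to_frame(tags, libraries), index=False)
    save("cleaning_report", tally_frame(tallies), index=False)

    ann_rows = []
    for ann in annotations:
        if ann.hits:
            for hit, cls in zip(ann.hits, ann.location_classes):
                ann_rows.append({
                    "sequence": ann.tag.seq, "tier": ann.tier,
                    "matched_id": ann.matched_id or "",
                    "chrom": hit.chrom, "start": hit.start, "end": hit.end,
                    "strand": hit.strand, "location": cls,
                })
        else:
            ann_rows.append({
                "sequence": ann.tag.seq, "tier": ann.tier,
                "matched_id": ann.matched_id or "",
                "chrom": "", "start": "", "end": "", "strand": "",
                "location": "",
            })
    save("annotations", pd.DataFrame(ann_rows), index=False)

    save("novel_mirnas", pd.DataFrame([
        {
            "name": r.name, "length": r.length,
            "sequence": to_rna(r.mature_seq),
            "chrom": r.interval.chrom, "start": r.interval.start,
            "end": r.interval.end, "strand": r.strand,
            "location": ";".join(r.location_classes),
            "arm": r.arm, "mismatches": r.duplex_mismatches,
            "bulges": r.duplex_bulges,
            "pairing_fraction": round(r.pairing_fraction, 3),
        }
        for r in novel
    ]), index=False)

    save("reclassification", pd.DataFrame(
        [{"name": name, "group": group or "unchanged"}
         for name, group in reclassified]), index=False)

    save("expression", expression_frame(expression), index=False)

    if tags:
        save("length_spectrum", length_distribution(tags, libraries),
             index_label="length")
    if mirna_records:
        save("first_nucleotide",
             summarize_first_nucleotide(mirna_records), index_label="length")
        loc = summarize_locations(mirna_records)
        save("locations", pd.DataFrame(
            [{"location": k, "count": v} for k, v in loc.items()]), index=False)

    with open(outdir / "precursors.fasta", "w") as fh:
        for r in novel:
            fh.write(f">{r.name} {r.interval.chrom}:{r.interval.start}-"
                     f"{r.interval.end}({r.strand})\n{r.precursor_seq}\n"
                     f"{r.structure}\n")
    tables["precursors"] = outdir / "precursors.fasta"
    return tables
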