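"""End-to-end orchestration: clean -> map -> categorize -> conserved ->
variants -> novel -> targets, with report-shaped table output.

Stage order follows the analysis convention for plant small-RNA libraries:
conserved matching precedes novel discovery so that conserved tags are
excluded from hairpin-candidate input, and only unannotated (or
dsRNA-signature) tags are folded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from ._util import ConfigError, InputError
from . import sequence_io, annotate, conserved, hairpin, targets, variants

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    # inputs
    reads: str = ""
    genome: str = ""
    gff: str = ""
    mature: str = ""
    transcripts: str = ""
    out_dir: str = "vamir_out"
    # cleaning
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = ""
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_mean_quality: float = 20.0
    max_n_fraction: float = 0.0
    min_len: int = 18
    max_len: int = 30
    # conserved matching
    max_substitutions: int = 3
    terminal_slack: int = 3
    # variants
    min_read_support: int = 1
    max_total_shift: int = 4
    # novel discovery
    mfe_threshold: float = -18.0
    min_precursor_len: int = 60
    max_precursor_len: int = 320
    max_mature_unpaired: int = 4
    max_flank: int = 280
    flank_step: int = 20
    min_novel_reads: int = 5
    # targets
    max_score: float = 4.0
    max_bulges: int = 1
    cleavage_anchor: int = 10
    # misc
    seed: int = 0
    sirna_rule: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def parameter_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    tags: list = field(default_factory=list)
    length_histogram: object = None
    category_summary: pd.DataFrame = None
    assignments: list = field(default_factory=list)
    member_abundance: pd.DataFrame = None
    family_abundance: pd.DataFrame = None
    variant_scan: object = None
    novel_candidates: list = field(default_factory=list)
    target_hits: list = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)


def _clean_stage(config: PipelineConfig) -> tuple[list, dict]:
    reads = sequence_io.read_reads(config.reads)
    counts = {"raw_reads": len(reads)}
    reads = sequence_io.trim_adapters(
        reads, config.adapter3, config.adapter5, config.min_overlap, config.max_mismatch_rate
    )
    counts["trimmed_reads"] = len(reads)
    reads = sequence_io.quality_filter(reads, config.min_mean_quality, config.max_n_fraction)
    counts["quality_filtered_reads"] = len(reads)
    reads = sequence_io.length_filter(reads, config.min_len, config.max_len)
    counts["length_filtered_reads"] = len(reads)
    tags = sequence_io.collapse_reads(reads)
    tags = sequence_io.polya_filter(tags)
    counts["unique_tags"] = len(tags)
    counts["clean_reads"] = sum(t.read_count for t in tags)
    return tags, counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages configured inputs allow; any stage failure raises
    with a stage-tagged message."""
    result = PipelineResult(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is None or isinstance(exc, ConfigError):
                    return False
                if isinstance(exc, (InputError, FileNotFoundError)):
                    raise InputError(f"[stage {name}] {exc}") from exc
                raise RuntimeError(f"[stage {name}] {exc}") from exc

        return _Ctx()

    with stage("clean"):
        tags, counts = _clean_stage(config)
        result.tags = tags
        result.stage_counts.update(counts)
        result.length_histogram = sequence_io.length_distribution(tags) if tags else None

    with stage("map"):
        genome = annotate.load_genome(config.genome)
        annotate.map_to_genome(tags, genome)
        result.stage_counts["mapped_tags"] = sum(1 for t in tags if t.loci)

    known_seqs: set[str] = set()
    if config.mature:
        with stage("conserved"):
            known = conserved.read_mature_fasta(config.mature)
            result.assignments = conserved.match_known(
                tags, known, config.max_substitutions, config.terminal_slack
            )
            known_seqs = {a.tag.sequence for a in result.assignments}
            result.member_abundance, result.family_abundance = conserved.family_abundance(
                result.assignments
            )
            result.stage_counts["conserved_tags"] = len(result.assignments)

    with stage("categorize"):
        tracks = annotate.read_gff3_tracks(config.gff) if config.gff else []
        assignments = annotate.classify_tags(
            tags, tracks, frozenset(known_seqs), sirna_rule=config.sirna_rule
        )
        result.category_summary = annotate.summarize_categories(tags, assignments)
        result.category_assignments = assignments

    if config.mature:
        with stage("variants"):
            result.variant_scan = variants.scan_variants(
                result.assignments, config.min_read_support
            )
            result.stage_counts["snp_calls"] = sum(
                1 for c in result.variant_scan.calls if c.kind == "miR-SNP"
            )
            result.stage_counts["ld_calls"] = sum(
                1 for c in result.variant_scan.calls if c.kind == "miR-LD"
            )

    with stage("novel"):
        library = {t.sequence: t.read_count for t in tags}
        criteria = hairpin.CriteriaConfig(
            config.mfe_threshold,
            config.min_precursor_len,
            config.max_precursor_len,
            config.max_mature_unpaired,
        )
        candidates = []
        for tag in tags:
            if tag.read_count < config.min_novel_reads or not tag.loci:
                continue
            if tag.sequence in known_seqs:
                continue
            if assignments[tag.sequence] != "unann":
                continue
            per_tag = []
            for locus in tag.loci:
                for wloc, wseq, off in hairpin.excise_precursor_windows(
                    locus, genome, config.max_flank, config.flank_step
                ):
                    fold_res = hairpin.fold(wseq)
                    per_tag.append(
                        hairpin.evaluate_candidate(
                            fold_res,
                            (off, off + tag.length - 1),
                            library,
                            criteria,
                            mature_tag=tag,
                            locus=wloc,
                        )
                    )
            best = hairpin.select_best_candidate(per_tag)
            if best is not None:
                candidates.append(best)
        result.novel_candidates = candidates
        result.stage_counts["novel_candidates"] = len(candidates)

    if config.transcripts:
        with stage("targets"):
            transcripts = {
                rec.id: str(rec.seq).upper().replace("U", "T")
                for rec in SeqIO.parse(config.transcripts, "fasta")
            }
            hits = []
            query_set = (
                [(a.known.id, a.known.sequence) for a in result.assignments]
                if result.assignments
                else []
            )
            for cand in result.novel_candidates:
                query_set.append((f"novel:{cand.mature_tag.sequence[:8]}", cand.mature_tag.sequence))
            seen_queries = set()
            for qid, qseq in query_set:
                if qseq in seen_queries:
                    continue
                seen_queries.add(qseq)
                hits.extend(
                    targets.scan_transcripts(
                        qseq, qid, transcripts, config.max_score, config.max_bulges
                    )
                )
            result.target_hits = hits
            result.stage_counts["target_hits"] = len(hits)

    _write_tables(result, out_dir)
    return result


def _write_tables(result: PipelineResult, out_dir: Path) -> None:
    config = result.config
    if result.category_summary is not None:
        result.category_summary.to_csv(out_dir / "category_summary.tsv", sep="\t")
    if result.length_histogram is not None:
        sequence_io.write_length_histogram(result.length_histogram, out_dir / "length_histogram.tsv")
    if result.member_abundance is not None:
        result.member_abundance.to_csv(out_dir / "member_abundance.tsv", sep="\t")
        result.family_abundance.to_csv(out_dir / "family_abundance.tsv", sep="\t")
    if result.variant_scan is not None:
        snp_rows = [
            {
                "mirna": c.wildtype_id, "wildtype_seq": c.wildtype_seq,
                "variant_seq": c.variant_seq, "position": c.snp_position,
                "change": f"{c.ref_base}>{c.alt_base}", "reads": c.read_count,
            }
            for c in result.variant_scan.calls
            if c.kind == "miR-SNP"
        ]
        ld_rows = [
            {
                "mirna": c.wildtype_id, "wildtype_seq": c.wildtype_seq,
                "variant_seq": c.variant_seq, "delta5": c.delta5,
                "delta3": c.delta3, "reads": c.read_count,
            }
            for c in result.variant_scan.calls
            if c.kind == "miR-LD"
        ]
        pd.DataFrame(snp_rows, columns=["mirna", "wildtype_seq", "variant_seq", "position", "change", "reads"]).to_csv(
            out_dir / "mir_snp.tsv", sep="\t", index=False
        )
        pd.DataFrame(ld_rows, columns=["mirna", "wildtype_seq", "variant_seq", "delta5", "delta3", "reads"]).to_csv(
            out_dir / "mir_ld.tsv", sep="\t", index=False
        )
    cand_rows = [
        {
            "sequence": c.mature_tag.sequence,
            "reads": c.mature_tag.read_count,
            "stem_loop_nt": c.stem_loop_length,
            "start": f"{c.precursor_locus.chromosome}:{c.precursor_locus.start}",
            "mfe": round(c.fold.mfe, 2),
            "arm": c.arm,
            "star_found": c.star_reads > 0,
            "star_reads": c.star_reads,
        }
        for c in result.novel_candidates
    ]
    pd.DataFrame(
        cand_rows,
        columns=["sequence", "reads", "stem_loop_nt", "start", "mfe", "arm", "star_found", "star_reads"],
    ).to_csv(out_dir / "novel_candidates.tsv", sep="\t", index=False)
    hit_rows = [
        {
            "mirna": h.mirna_id, "transcript": h.transcript_id, "start": h.start,
            "end": h.end, "score": h.score, "mismatches": h.mismatches,
            "gu_count": h.gu_count, "region": h.region,
            "cleavage_pos_anchor10": targets.predict_cleavage(h, 10).transcript_position
            if h.alignment.state_at(10) and h.alignment.state_at(10).target_pos
            else "",
        }
        for h in result.target_hits
    ]
    pd.DataFrame(
        hit_rows,
        columns=["mirna", "transcript", "start", "end", "score", "mismatches", "gu_count", "region", "cleavage_pos_anchor10"],
    ).to_csv(out_dir / "target_hits.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stage_counts": result.stage_counts,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def render_report(result: PipelineResult) -> str:
    """Human-readable run summary (markdown)."""
    config = result.config
    lines = ["# vamir run report", ""]
    lines.append(f"- pipeline version: {__version__}")
    lines.append(f"- MFE threshold: {config.mfe_threshold} kcal/mol")
    lines.append(f"- target score cutoff: {config.max_score}")
    lines.append("")
    lines.append("## Stage counts")
    for k, v in result.stage_counts.items():
        lines.append(f"- {k}: {v}")
    if result.category_summary is not None:
        lines += ["", "## Category summary", "", result.category_summary.to_string()]
    if result.family_abundance is not None and len(result.family_abundance):
        top = result.family_abundance.sort_values("reads", ascending=False).head(10)
        lines += ["", "## Top families by abundance", "", top.to_string()]
    n_snp = n_ld = 0
    if result.variant_scan is not None:
        n_snp = sum(1 for c in result.variant_scan.calls if c.kind == "miR-SNP")
        n_ld = sum(1 for c in result.variant_scan.calls if c.kind == "miR-LD")
    lines += ["", "## Variants", f"- miR-SNP types: {n_snp}", f"- miR-LD types: {n_ld}"]
    lines += [
        "",
        "## Novel candidates",
        f"- accepted hairpin candidates: {len(result.novel_candidates)}",
        f"- with sequenced miRNA*: {sum(1 for c in result.novel_candidates if c.star_reads > 0)}",
        "",
        "## Targets",
        f"- hits: {len(result.target_hits)}",
    ]
    return "\n".join(lines) + "\n"
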