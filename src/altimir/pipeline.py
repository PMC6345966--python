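"""End-to-end orchestration: stages, stage file formats and the summary.

The pipeline runs trimming -> hierarchical classification -> expression
matrix -> differential expression / clustering / ANOVA -> isomiR and
arm-usage analysis -> novel-hairpin screen -> climate association, writing
one TSV per stage plus a JSON summary whose every number is re-derivable
from the stage tables.  A fully synthetic run (reference, reads and
climate generated from one seed) is the default entry point.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import climate as clim
from . import diffexp, isomir, novel, quantify
from . import preprocess as prep
from . import simulate as sim

log = logging.getLogger(__name__)

FD_PAIRS = [("Deh_FD", "Mun_FD"), ("Mun_FD", "Chit_FD"), ("Deh_FD", "Chit_FD")]
GH_PAIRS = [("Deh_GH", "Mun_GH"), ("Mun_GH", "Chit_GH"), ("Deh_GH", "Chit_GH")]
CONDITION_PAIRS = [("Deh_FD", "Deh_GH"), ("Mun_FD", "Mun_GH"), ("Chit_FD", "Chit_GH")]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study defaults."""

    seed: int = 0
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 18
    max_len: int = 28
    min_qual: float = 20.0
    max_mismatch: int = 0
    min_reads: int = 10
    de_alpha: float = 0.05
    fc_gate: float = 1.0
    window: int = 5
    max_sub: int = 2
    flank: int = 100
    novel_min_abundance: int = 10
    n_boot: int = 1000
    r_threshold: float = 0.98
    rpm_denominator: str = "cleaned_total"  # or "mirna_total"
    library_size: int = 600_000

    def to_generator_config(self) -> sim.GeneratorConfig:
        return sim.GeneratorConfig(
            seed=self.seed, library_size=self.library_size, adapter=self.adapter
        )

    def validate(self) -> None:
        if not self.adapter:
            raise ValueError("configuration is missing the 3' adapter sequence")
        if self.rpm_denominator not in ("cleaned_total", "mirna_total"):
            raise ValueError(f"unknown rpm_denominator {self.rpm_denominator!r}")
        if self.min_len > self.max_len:
            raise ValueError("min_len exceeds max_len")


@dataclass
class PipelineResult:
    config: PipelineConfig
    index: ann.AnnotationIndex
    tags: prep.TagTable
    trim_stats: dict[str, prep.TrimStats]
    classified: list[prep.ClassificationResult]
    cleaned: dict[str, int]
    matrix: quantify.ExpressionMatrix
    detected_fd: dict[str, set[str]]
    partition: dict[tuple[str, ...], int]
    de_tables: dict[str, pd.DataFrame]
    monotone_up: set[str]
    monotone_down: set[str]
    jaccard: list[diffexp.JaccardResult]
    newick: str | None
    anova: pd.DataFrame | None
    isomir_assigned: list
    isomir_summaries: pd.DataFrame
    nta: dict[str, dict[str, float]]
    arm_table: pd.DataFrame
    novel_candidates: list
    climate_table: pd.DataFrame | None
    climate_pca: clim.ClimatePCA | None
    pc_corr: pd.DataFrame | None
    season_corr: pd.DataFrame | None
    summary: dict
    manifest: "sim.TruthManifest | None" = None


def tags_to_frame(tags: prep.TagTable) -> pd.DataFrame:
    rows = []
    for seq in sorted(tags.counts):
        row = {"tag": seq}
        for lib in tags.libraries:
            row[f"count_{lib}"] = tags.counts[seq].get(lib, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_tags(df: pd.DataFrame) -> prep.TagTable:
    libs = [c[len("count_") :] for c in df.columns if c.startswith("count_")]
    t = prep.TagTable(libraries=list(libs))
    for rec in df.to_dict("records"):
        for lib in libs:
            n = int(rec[f"count_{lib}"])
            if n:
                t.add(rec["tag"], lib, n)
    return t


def classification_to_frame(results: list[prep.ClassificationResult], libraries: list[str]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "tag": r.tag,
            "label": r.label,
            "assigned_units": ";".join(r.assigned_units),
            "ambiguous": r.ambiguous,
        }
        for lib in libraries:
            row[f"count_{lib}"] = r.counts.get(lib, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    fold_engine: novel.FoldEngine | None = None,
    write_fastq_dir: str | Path | None = None,
) -> PipelineResult:
    """Simulate the default synthetic study and analyse it end to end."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_cfg = config.to_generator_config()
    ref = sim.generate_reference(gen_cfg)
    fastq_dir = Path(write_fastq_dir) if write_fastq_dir else out / "sim"
    fastq_paths, manifest = sim.generate_libraries(gen_cfg, ref, fastq_dir)
    climate_table = sim.generate_climate(gen_cfg)
    manifest.to_json(out / "truth_manifest.json")
    result = analyse(
        config=config,
        index=ref.annotation_index(),
        pools=ref.reference_pools(),
        fastq_paths=fastq_paths,
        design=gen_cfg.design,
        out_dir=out,
        climate_table=climate_table,
        gff3_path=_write_gff(ref, out),
        fold_engine=fold_engine,
        hairpin_loci=ref.hairpin_loci,
    )
    result.manifest = manifest
    result.summary["manifest"] = str(out / "truth_manifest.json")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1, default=str))
    return result


def _write_gff(ref: sim.SyntheticReference, out: Path) -> Path:
    p = out / "genes.gff3"
    p.write_text(ref.gff3)
    return p


def analyse(
    config: PipelineConfig,
    index: ann.AnnotationIndex,
    pools: ann.ReferencePools,
    fastq_paths: dict[str, Path],
    design: dict[str, tuple[str, str]],
    out_dir: str | Path,
    climate_table: pd.DataFrame | None = None,
    gff3_path: str | Path | None = None,
    fold_engine: novel.FoldEngine | None = None,
    hairpin_loci: dict[str, tuple[str, int, int]] | None = None,
) -> PipelineResult:
    """Run every analysis stage on trimmed-and-classified libraries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann.write_annotation_tsv(index, out / "annotation.tsv")

    # --- trim + collapse -------------------------------------------------
    tags = prep.TagTable()
    trim_stats: dict[str, prep.TrimStats] = {}
    for lib in sorted(fastq_paths):
        _, stats = prep.trim_and_filter(
            fastq_paths[lib],
            lib,
            adapter=config.adapter,
            tags=tags,
            min_len=config.min_len,
            max_len=config.max_len,
            min_qual=config.min_qual,
        )
        trim_stats[lib] = stats
    libraries = sorted(fastq_paths)
    pd.DataFrame([dataclasses.asdict(s) for s in trim_stats.values()]).to_csv(
        out / "trim_stats.tsv", sep="\t", index=False
    )

    # --- hierarchical classification -------------------------------------
    classified = prep.classify_hierarchical(tags, pools, index, max_mismatch=config.max_mismatch)
    classification_to_frame(classified, libraries).to_csv(
        out / "classification.tsv", sep="\t", index=False
    )
    cleaned = prep.cleaned_totals(classified)
    label_totals: dict[str, dict[str, int]] = {}
    for r in classified:
        for lib, n in r.counts.items():
            label_totals.setdefault(r.label, {}).setdefault(lib, 0)
            label_totals[r.label][lib] += n

    # --- expression matrix -----------------------------------------------
    matrix = quantify.count_matrix(classified, libraries, index)
    denom = cleaned if config.rpm_denominator == "cleaned_total" else prep.mirna_totals(classified)
    matrix = quantify.normalize_rpm(matrix, denom)
    quantify.expression_table(matrix, index).to_csv(out / "expression.tsv", sep="\t", index=False)

    # --- detection, Venn partition, Jaccard ------------------------------
    pops = [p for p in sim.POPULATIONS]
    detected_fd = {
        p: quantify.detected_set(matrix, scope=[f"{p}_FD"], min_reads=config.min_reads)
        for p in pops
        if f"{p}_FD" in libraries
    }
    partition = quantify.membership_partition(detected_fd) if len(detected_fd) >= 2 else {}
    jac: list[diffexp.JaccardResult] = []
    names = sorted(detected_fd)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            jac.append(
                diffexp.jaccard(
                    detected_fd[a],
                    detected_fd[b],
                    n_boot=config.n_boot,
                    seed=config.seed,
                    pair=(a, b),
                )
            )
    if jac:
        pd.DataFrame(
            [
                {"pop_a": j.pair[0], "pop_b": j.pair[1], "jaccard": j.point,
                 "ci_low": j.ci_low, "ci_high": j.ci_high, "n_boot": j.n_boot}
                for j in jac
            ]
        ).to_csv(out / "jaccard.tsv", sep="\t", index=False)

    # --- differential expression -----------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    for a, b in FD_PAIRS + GH_PAIRS + CONDITION_PAIRS:
        if a in libraries and b in libraries:
            name = f"{b}_vs_{a}"
            df = diffexp.de_table(
                matrix, a, b,
                unit_family=index.unit_family,
                alpha=config.de_alpha,
                fc_gate=config.fc_gate,
            )
            de_tables[name] = df
            df.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
    mono_up: set[str] = set()
    mono_down: set[str] = set()
    if "Mun_FD_vs_Deh_FD" in de_tables and "Chit_FD_vs_Mun_FD" in de_tables:
        mono_up, mono_down = diffexp.altitude_monotone_units(
            de_tables["Mun_FD_vs_Deh_FD"], de_tables["Chit_FD_vs_Mun_FD"]
        )

    # --- clustering of commonly expressed units --------------------------
    newick = None
    per_lib_detected = [
        quantify.detected_set(matrix, scope=[lib], min_reads=config.min_reads) for lib in libraries
    ]
    common_all = set.intersection(*per_lib_detected) if per_lib_detected else set()
    if len(libraries) >= 3 and len(common_all) >= 2:
        _, _, newick = diffexp.cluster_libraries(matrix, units=sorted(common_all))
        (out / "dendrogram.nwk").write_text(newick)

    # --- two-way ANOVA (population x condition, reference accession out) --
    anova_df = None
    core_libs = [l for l in libraries if design.get(l, ("", ""))[0] in pops]
    if len(core_libs) >= 4 and matrix.rpm is not None:
        responses = np.log2(matrix.rpm[core_libs])
        anova_df = diffexp.anova_pop_tmt(responses, {l: design[l] for l in core_libs})
        anova_df.to_csv(out / "anova.tsv", sep="\t", index=False)

    # --- isomiR taxonomy ---------------------------------------------------
    # non-template tails and substituted reads are absent from the genome,
    # so the isomiR screen looks past the genome gate: every non-contaminant
    # tag is eligible
    eligible = prep.TagTable(libraries=list(tags.libraries))
    for r in classified:
        if r.label in (prep.LABEL_MIRNA, prep.LABEL_CLEAN, prep.LABEL_UNMAPPED):
            eligible.counts[r.tag] = r.counts
    assigned = isomir.assign_isomirs(eligible, index, window=config.window, max_sub=config.max_sub)
    isomir.isomir_table(assigned, libraries).to_csv(out / "isomir.tsv", sep="\t", index=False)
    summaries = []
    nta: dict[str, dict[str, float]] = {}
    for lib in libraries:
        total = cleaned.get(lib, 0)
        if total <= 0:
            continue
        summaries.extend(isomir.isomir_summary(assigned, lib, total))
        with np.errstate(all="ignore"):
            comp = isomir.nta_base_composition(assigned, lib)
        if comp:
            nta[lib] = comp
    summary_df = isomir.summary_table(summaries)
    summary_df.to_csv(out / "isomir_summary.tsv", sep="\t", index=False)
    if nta:
        pd.DataFrame(nta).T.rename_axis("library").to_csv(out / "nta_composition.tsv", sep="\t")

    # --- arm usage ---------------------------------------------------------
    arm_table = isomir.arm_usage_table(matrix, index)
    arm_table.to_csv(out / "arm_usage.tsv", sep="\t", index=False)

    # --- novel hairpin screen ---------------------------------------------
    engine = fold_engine or novel.viennarna_engine
    clean_tags = prep.TagTable(libraries=list(tags.libraries))
    for r in classified:
        if r.label == prep.LABEL_CLEAN:
            clean_tags.counts[r.tag] = r.counts
    gene_models = novel.load_gene_models(gff3_path) if gff3_path else None
    candidates = novel.discover_novel(
        clean_tags,
        pools.genome,
        engine,
        gene_models=gene_models,
        min_abundance=config.novel_min_abundance,
        flank=config.flank,
    )
    if hairpin_loci is None:
        hairpin_loci = _locate_hairpins(index, pools.genome)
    candidates = [
        c
        for c in candidates
        if not _overlaps_known(c.locus, hairpin_loci)
    ]
    _novel_frame(candidates).to_csv(out / "novel_candidates.tsv", sep="\t", index=False)

    # --- climate -----------------------------------------------------------
    pca = pc_corr = season_corr = None
    if climate_table is not None:
        climate_table.to_csv(out / "climate.tsv", sep="\t")
        pca = clim.climate_pca(climate_table)
        pca.var_explained.rename("fraction").to_csv(out / "climate_pca_variance.tsv", sep="\t")
        pca.scores.to_csv(out / "climate_pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(out / "climate_pca_loadings.tsv", sep="\t")
        site_map = {f"{p}_FD": p for p in pops if f"{p}_FD" in libraries}
        if site_map:
            pc_corr = clim.pc_expression_correlation(pca, matrix, site_map)
            pc_corr.to_csv(out / "climate_pc_correlation.tsv", sep="\t", index=False)
            season_corr = clim.season_factor_correlation(
                matrix,
                climate_table[list(clim.SEASON_FACTORS)],
                site_map,
                r_threshold=config.r_threshold,
                alpha=config.de_alpha,
            )
            season_corr.to_csv(out / "climate_season_correlation.tsv", sep="\t", index=False)

    # --- summary -----------------------------------------------------------
    summary = {
        "config": dataclasses.asdict(config),
        "libraries": libraries,
        "design": {l: list(design[l]) for l in libraries if l in design},
        "per_library": {
            lib: {
                "raw": trim_stats[lib].raw,
                "kept": trim_stats[lib].kept_reads,
                "cleaned": cleaned.get(lib, 0),
                "mirna_reads": label_totals.get(prep.LABEL_MIRNA, {}).get(lib, 0),
            }
            for lib in libraries
        },
        "detected_fd": {p: len(s) for p, s in detected_fd.items()},
        "partition": {"+".join(k): v for k, v in partition.items()},
        "de_significant": {name: int(df["significant"].sum()) for name, df in de_tables.items()},
        "monotone_up": sorted(mono_up),
        "monotone_down": sorted(mono_down),
        "isomir_category_reads": _category_totals(assigned, libraries),
        "arm_categories": _arm_category_counts(index),
        "novel_candidates": {
            "n": len(candidates),
            "n_pass": sum(1 for c in candidates if c.verdict),
            "origins": _origin_counts(candidates),
        },
        "climate_pc_variance_pct": (
            {k: round(float(v) * 100, 2) for k, v in pca.var_explained.items()} if pca else {}
        ),
    }
    return PipelineResult(
        config=config,
        index=index,
        tags=tags,
        trim_stats=trim_stats,
        classified=classified,
        cleaned=cleaned,
        matrix=matrix,
        detected_fd=detected_fd,
        partition=partition,
        de_tables=de_tables,
        monotone_up=mono_up,
        monotone_down=mono_down,
        jaccard=jac,
        newick=newick,
        anova=anova_df,
        isomir_assigned=assigned,
        isomir_summaries=summary_df,
        nta=nta,
        arm_table=arm_table,
        novel_candidates=candidates,
        climate_table=climate_table,
        climate_pca=pca,
        pc_corr=pc_corr,
        season_corr=season_corr,
        summary=summary,
    )


def _category_totals(assigned, libraries: list[str]) -> dict[str, int]:
    totals = {c: 0 for c in isomir.CATEGORIES}
    for rec, counts in assigned:
        totals[rec.category] += sum(counts.get(l, 0) for l in libraries)
    return totals


def _arm_category_counts(index: ann.AnnotationIndex) -> dict[str, int]:
    counts: dict[str, int] = {}
    for hid in index.hairpins:
        cat = ann.arm_category(hid, index)
        counts[cat] = counts.get(cat, 0) + 1
    return counts


def _origin_counts(candidates) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in candidates:
        if c.origin:
            counts[c.origin] = counts.get(c.origin, 0) + 1
    return counts


def _locate_hairpins(index: ann.AnnotationIndex, genome: dict[str, str]) -> dict[str, tuple[str, int, int]]:
    loci = {}
    for hid, seq in index.hairpins.items():
        for chrom, g in genome.items():
            i = g.find(seq)
            if i != -1:
                loci[hid] = (chrom, i, i + len(seq))
                break
    return loci


def _overlaps_known(locus, hairpin_loci: dict[str, tuple[str, int, int]]) -> bool:
    for chrom, s, e in hairpin_loci.values():
        if locus.chrom == chrom and locus.start < e and s < locus.end:
            return True
    return False


def _novel_frame(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "chrom": c.locus.chrom,
                "start": c.locus.start,
                "end": c.locus.end,
                "strand": c.locus.strand,
                "mature": c.locus.mature_tag,
                "count": c.locus.count,
                "precursor_len": len(c.precursor_seq),
                "mfe": c.mfe,
                "verdict": c.verdict,
                "failure_reasons": ";".join(c.failure_reasons),
                "origin": c.origin or "",
                "structure": c.structure or "",
            }
        )
    return pd.DataFrame(rows)
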