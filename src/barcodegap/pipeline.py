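"""End-to-end pipeline chaining all analysis stages with reproducible outputs.

Stage order: read -> optional region extraction -> haplotype table ->
distance matrix -> divergence summary + gap distributions + rank tests ->
identification (both methods) + species tabulation -> NJ/UPGMA trees +
bootstrap + monophyly -> diagnostics. Every stage writes its artifact into
the output directory; a machine-readable ``summary.json`` aggregates the
headline numbers, taken verbatim from the stage results (no recomputation).
All randomness flows from one top-level seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from . import core_io, diagnostics, distances, divergence, identification, trees

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    fasta: str
    samplemap: str
    out_dir: str
    region: tuple[int, int] | None = None  # 1-based inclusive
    collapse_scope: Literal["global", "per_species"] = "global"
    gap_policy: Literal["strict", "ignore_gap_only_columns"] = "strict"
    test_scope: Literal["all", "haplotypes"] = "all"
    id_methods: tuple[str, ...] = ("best_hit", "nearest_distance")
    tree_methods: tuple[str, ...] = ("nj", "upgma")
    bootstrap_replicates: int = 100
    seed: int = 0
    diagnostics_target: str | None = None
    max_k: int = 3
    bin_width: float = 0.005
    singleton_policy: Literal["count_as_success", "exclude"] = "count_as_success"
    marker_name: str = "barcode"

    def validate(self) -> None:
        if not Path(self.fasta).is_file():
            raise PipelineError(f"config: input FASTA not found: {self.fasta}")
        if not Path(self.samplemap).is_file():
            raise PipelineError(f"config: sample map not found: {self.samplemap}")
        if self.bootstrap_replicates < 0:
            raise PipelineError("config: bootstrap_replicates must be >= 0")
        if self.bin_width <= 0:
            raise PipelineError("config: bin_width must be positive")
        for m in self.id_methods:
            if m not in ("best_hit", "nearest_distance"):
                raise PipelineError(f"config: unknown identification method {m!r}")
        for m in self.tree_methods:
            if m not in ("nj", "upgma"):
                raise PipelineError(f"config: unknown tree method {m!r}")

    def serialize(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("# barcodegap pipeline config v1\n")
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)!r}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON).

    On a stage failure the partial outputs are retained, a ``FAILED`` marker
    naming the stage is written, and :class:`PipelineError` is raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.serialize(out / "config.txt")

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("barcodegap")
    root.addHandler(log_handler)
    summary: dict = {"seed": config.seed, "marker": config.marker_name}
    stage = "read"
    try:
        aln = core_io.read_alignment(config.fasta, config.samplemap)
        logger.info("read %d sequences x %d columns", len(aln.records),
                    aln.alignment_length)
        if config.region is not None:
            stage = "extract_region"
            region = core_io.RegionAnnotation.from_1based(*config.region)
            aln = core_io.extract_region(aln, region)
            summary["region"] = list(config.region)
        summary["n_sequences"] = len(aln.records)
        summary["n_species"] = len(aln.species)
        summary["alignment_length"] = aln.alignment_length

        stage = "haplotypes"
        haps = core_io.collapse_haplotypes(
            aln, scope=config.collapse_scope, gap_policy=config.gap_policy
        )
        core_io.write_haplotype_table(haps, out / "haplotypes.tsv")
        summary["n_haplotypes"] = len(haps)
        logger.info("collapsed to %d haplotypes (%s)", len(haps),
                    config.collapse_scope)

        stage = "distances"
        dm = distances.distance_matrix(aln)
        distances.write_distance_tsv(dm, out / "distances.tsv")
        summary["n_undefined_distances"] = dm.n_undefined_pairs

        stage = "divergence"
        if config.test_scope == "haplotypes":
            per_sp = core_io.collapse_haplotypes(aln, scope="per_species",
                                                 gap_policy=config.gap_policy)
            reps = [h.member_ids[0] for h in per_sp.haplotypes]
            test_aln = aln.subset(reps)
            test_dm = distances.distance_matrix(test_aln)
        else:
            test_dm = dm
            test_aln = aln
        species_map = test_aln.species_map
        summ = divergence.divergence_summary(test_dm, species_map)
        divergence.write_divergence_tsv(summ, out / "divergence.tsv")
        gaps = divergence.gap_distributions(test_dm, species_map,
                                            config.bin_width)
        divergence.write_gap_histogram_tsv(gaps, out / "gap_histogram.tsv")
        intra, inter = gaps.intra_values, gaps.inter_values
        summary["divergence"] = {
            "mean_interspecific": summ.mean_interspecific,
            "theta_prime": summ.theta_prime,
            "min_interspecific": summ.min_interspecific,
            "mean_intraspecific": summ.mean_intraspecific,
            "theta": summ.theta,
            "coalescent_depth": summ.coalescent_depth,
            "n_inter_pairs": summ.n_inter_pairs,
            "n_intra_pairs": summ.n_intra_pairs,
            "n_undefined_skipped": summ.n_undefined_skipped,
            "gap_overlap": gaps.overlap,
        }

        stage = "rank_tests"
        tests: dict = {}
        if intra and inter:
            wil = divergence.wilcoxon_two_sample(inter, intra)
            med = divergence.median_test(inter, intra)
            tests = {
                "wilcoxon": {"W": wil.statistic, "p_value": wil.p_value,
                             "method": wil.method},
                "median": {"statistic": med.statistic, "p_value": med.p_value,
                           "method": med.method,
                           "pooled_median": med.pooled_median},
                "n_inter": len(inter), "n_intra": len(intra),
            }
            with open(out / "tests.tsv", "w") as fh:
                fh.write("test\tstatistic\tp_value\tmethod\tn_inter\tn_intra\n")
                fh.write(f"wilcoxon\t{wil.statistic:.6g}\t{wil.p_value:.6g}\t"
                         f"{wil.method}\t{len(inter)}\t{len(intra)}\n")
                fh.write(f"median\t{med.statistic:.6g}\t{med.p_value:.6g}\t"
                         f"{med.method}\t{len(inter)}\t{len(intra)}\n")
        summary["tests"] = tests

        stage = "identification"
        ident: dict = {}
        for method in config.id_methods:
            outcomes = identification.identify_all(
                aln, method, dm=dm if method == "nearest_distance" else None
            )
            identification.write_outcomes_tsv(
                outcomes, out / f"identification_{method}.tsv"
            )
            tab = identification.tabulate_species(outcomes, aln.species_map)
            identification.write_tabulation_tsv(
                tab, out / f"species_tabulation_{method}.tsv",
                marker=config.marker_name, method=method,
            )
            ident[method] = {
                "n_samples": tab.n_samples,
                "n_species": tab.n_species,
                "correct": tab.n_correct,
                "incorrect": tab.n_incorrect,
                "ambiguous": tab.n_ambiguous,
                "pct_correct": tab.pct_correct,
                "pct_incorrect": tab.pct_incorrect,
                "pct_ambiguous": tab.pct_ambiguous,
            }
        summary["identification"] = ident

        stage = "trees"
        tree_stats: dict = {}
        for method in config.tree_methods:
            if config.bootstrap_replicates > 0:
                tree = trees.bootstrap_support(
                    aln, method=method,
                    replicates=config.bootstrap_replicates,
                    seed=config.seed,
                )
            else:
                build = trees.nj_tree if method == "nj" else trees.upgma_tree
                tree = build(dm)
            trees.tree_to_newick(tree, out / f"tree_{method}.nwk")
            report = trees.monophyly_report(
                tree, aln.species_map, rooted=(method == "upgma"),
                singleton_policy=config.singleton_policy,
            )
            trees.write_monophyly_tsv(report, out / f"monophyly_{method}.tsv")
            tree_stats[method] = {
                "discrimination_rate": report.discrimination_rate,
                "n_monophyletic": report.n_monophyletic,
                "n_species_counted": report.n_species_counted,
            }
        summary["trees"] = tree_stats

        stage = "diagnostics"
        if config.diagnostics_target is not None:
            report = diagnostics.find_minimal_combinations(
                aln, config.diagnostics_target, max_k=config.max_k
            )
            report.alignment_name = Path(config.fasta).name
            diagnostics.write_diagnostics_tsv(report, out / "diagnostics.tsv")
            summary["diagnostics"] = {
                "target": report.target_species,
                "single_sites": [s.position for s in report.single_site_diagnostics],
                "minimal_combinations": [
                    list(c.positions) for c in report.minimal_combinations
                ],
                "found": report.found,
            }

        stage = "summary"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
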