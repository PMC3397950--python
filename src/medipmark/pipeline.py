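"""End-to-end orchestration: simulate -> center -> score -> call -> annotate
-> triage -> M-index -> evaluate.

All randomness flows from one top-level seed: stage k draws its own seed as
``SeedSequence([seed, k]).generate_state(1)[0] % 2**31`` (stages are numbered
0 = tiling simulation, 1 = triage evidence, 2 = cohort simulation,
3 = bootstrap), so every stage is independently reproducible. The effective
configuration is written to the output directory as YAML on every run, and a
``FAILED`` marker names the stage when one aborts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .enrichment import (PeakCallerConfig, annotate_regions, call_regions,
                         center_log2_ratios, score_probes)
from .errors import InputError, StageError
from .evaluate import EvalConfig, evaluate_marker
from .qmsp import cohort_m_indexes
from .simulate import (CohortSimConfig, TilingSimConfig, promoter_annotation,
                       simulate_qmsp_cohort, simulate_tiling_groups,
                       simulate_triage_evidence)
from .triage import TriageConfig, run_funnel

logger = logging.getLogger(__name__)

STAGE_TILING, STAGE_EVIDENCE, STAGE_COHORT, STAGE_BOOTSTRAP = range(4)


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    In simulate mode all inputs are generated; otherwise paths to probe
    tables, promoter BED, evidence lists, pool matrix, re-expression records
    and the Cp table must be supplied.
    """

    outdir: str = "medipmark_run"
    seed: int = 0
    simulate: bool = True
    tiling: TilingSimConfig = field(default_factory=TilingSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    peaks: PeakCallerConfig = field(default_factory=PeakCallerConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    failure_cutoff: float = 36.0
    # non-simulate mode inputs
    probe_tables: dict[str, str] = field(default_factory=dict)  # group -> path
    promoters_bed: str | None = None
    expr_down_list: str | None = None
    tdmr_list: str | None = None
    reexpression_tsv: str | None = None
    pool_matrix_tsv: str | None = None
    blood_list: str | None = None
    cp_table_tsv: str | None = None

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            return obj

        return plain(dataclasses.asdict(self))


def _write_config(cfg: RunConfig, outdir: Path) -> None:
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Stage failures raise :class:`StageError` naming the stage; partial
    outputs are retained alongside a ``FAILED`` marker file.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("medipmark")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    _write_config(cfg, outdir)
    logger.info("run started: seed=%d simulate=%s", cfg.seed, cfg.simulate)
    logger.info("effective defaults: window_width=%s score_cutoff=%s "
                "failure_cutoff=%s alpha=%s m_index_scale=10000",
                cfg.peaks.window_width, cfg.peaks.score_cutoff,
                cfg.failure_cutoff, cfg.eval.alpha)

    current_stage = "setup"
    try:
        # ------------------------------------------------ tiling inputs
        current_stage = "simulate" if cfg.simulate else "load-inputs"
        if cfg.simulate:
            tiling_cfg = dataclasses.replace(
                cfg.tiling, seed=stage_seed(cfg.seed, STAGE_TILING))
            tables, truth = simulate_tiling_groups(tiling_cfg)
            promoters = promoter_annotation(tiling_cfg)
            for group, table in tables.items():
                mio.write_probe_table(table, outdir / f"probes_{group}.tsv")
            mio.write_tsv(truth, outdir / "tiling_truth.tsv")
            mio.write_promoters_bed(promoters, outdir / "promoters.bed")
            evidence = simulate_triage_evidence(
                truth, sorted(promoters["gene"]),
                seed=stage_seed(cfg.seed, STAGE_EVIDENCE))
            mio.write_gene_list(evidence["expr_down"], outdir / "expr_down.txt")
            mio.write_gene_list(evidence["tdmr"], outdir / "tdmr.txt")
            mio.write_tsv(evidence["reexpression"], outdir / "reexpression.tsv")
            mio.write_pool_matrix(evidence["pool_matrix"], outdir / "pool_matrix.tsv")
            mio.write_gene_list(evidence["blood_genes"], outdir / "blood_genes.txt")
            cohort_cfg = dataclasses.replace(
                cfg.cohort, seed=stage_seed(cfg.seed, STAGE_COHORT))
            cp_table, cohort_truth = simulate_qmsp_cohort(cohort_cfg)
            mio.write_tsv(cp_table, outdir / "cohort.tsv")
            mio.write_tsv(cohort_truth, outdir / "cohort_truth.tsv")
            # re-read through the package's own readers (closed round trip)
            tables = {g: mio.read_probe_table(outdir / f"probes_{g}.tsv")
                      for g in tables}
            promoters = mio.read_promoters_bed(outdir / "promoters.bed")
            expr_down = mio.read_gene_list(outdir / "expr_down.txt")
            tdmr = mio.read_gene_list(outdir / "tdmr.txt")
            reexpression = mio.read_reexpression(outdir / "reexpression.tsv")
            pool_matrix = mio.read_pool_matrix(outdir / "pool_matrix.tsv")
            blood = mio.read_gene_list(outdir / "blood_genes.txt")
            cp_table = mio.read_cp_table(outdir / "cohort.tsv")
        else:
            required = {
                "probe_tables": cfg.probe_tables, "promoters_bed": cfg.promoters_bed,
                "expr_down_list": cfg.expr_down_list, "tdmr_list": cfg.tdmr_list,
                "reexpression_tsv": cfg.reexpression_tsv,
                "pool_matrix_tsv": cfg.pool_matrix_tsv,
                "cp_table_tsv": cfg.cp_table_tsv,
            }
            missing = [k for k, v in required.items() if not v]
            if missing:
                raise InputError(f"missing inputs for non-simulate mode: {missing}")
            tables = {g: mio.read_probe_table(p) for g, p in cfg.probe_tables.items()}
            promoters = mio.read_promoters_bed(cfg.promoters_bed)
            expr_down = mio.read_gene_list(cfg.expr_down_list)
            tdmr = mio.read_gene_list(cfg.tdmr_list)
            reexpression = mio.read_reexpression(cfg.reexpression_tsv)
            pool_matrix = mio.read_pool_matrix(cfg.pool_matrix_tsv)
            blood = mio.read_gene_list(cfg.blood_list) if cfg.blood_list else set()
            cp_table = mio.read_cp_table(cfg.cp_table_tsv)

        # ------------------------------------------------ enrichment calling
        current_stage = "callpeaks"
        gene_sets: dict[str, set[str]] = {}
        for group, table in tables.items():
            centered = center_log2_ratios(table, cfg.peaks)
            scores = score_probes(centered, cfg.peaks)
            regions = call_regions(scores, centered, cfg.peaks)
            enriched = annotate_regions(regions, promoters)
            mio.write_regions_bed(regions, outdir / f"regions_{group}.bed")
            mio.write_tsv(enriched, outdir / f"enriched_genes_{group}.tsv")
            gene_sets[group] = set(enriched["gene"])
            logger.info("group %s: %d regions, %d enriched genes",
                        group, len(regions), len(gene_sets[group]))

        # ------------------------------------------------ triage
        current_stage = "triage"
        report = run_funnel(
            gene_sets.get("SCC", set()), gene_sets.get("AC", set()),
            gene_sets.get("Normal", set()), expr_down, tdmr, reexpression,
            pool_matrix, blood, cfg.triage,
        )
        mio.write_tsv(report, outdir / "triage.tsv")
        n_prioritized = report.attrs["funnel_counts"]["prioritized"]

        # ------------------------------------------------ M-index
        current_stage = "mindex"
        results, failure_summary = cohort_m_indexes(cp_table, cfg.failure_cutoff)
        mio.write_tsv(results, outdir / "mindex.tsv")
        logger.info("detection failures: %s", failure_summary)

        # ------------------------------------------------ evaluation
        current_stage = "evaluate"
        if n_prioritized == 0:
            logger.info("no prioritized candidate genes; evaluation stage skipped")
        else:
            eval_cfg = dataclasses.replace(
                cfg.eval, bootstrap_seed=stage_seed(cfg.seed, STAGE_BOOTSTRAP))
            report_eval = evaluate_marker(results[results["valid"]], cfg=eval_cfg)
            mio.write_tsv(report_eval["grade_summary"], outdir / "grade_summary.tsv")
            mio.write_tsv(report_eval["scheme_table"], outdir / "evaluation.tsv")
            if len(report_eval["pairwise"]):
                mio.write_tsv(report_eval["pairwise"], outdir / "pairwise_tests.tsv")
            logger.info("Kruskal-Wallis H=%.3f p=%.3g",
                        report_eval["kruskal_h"], report_eval["kruskal_p"])
        logger.info("run finished")
        return outdir
    except InputError:
        (outdir / "FAILED").write_text(current_stage + "\n")
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(current_stage + "\n")
        raise StageError(f"stage {current_stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
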