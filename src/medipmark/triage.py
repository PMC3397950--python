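"""Candidate-gene triage funnel.

Gene-level enrichment calls from the three tiling-array groups are reduced to
a prioritized candidate list through successive, order-independent filters:

1. cancer-specific selection: enriched in both SCC and AC but not Normal;
2. external-evidence integration: intersection with an expression-down list
   and/or a tissue-specific differentially-methylated-region (T-DMR) list;
3. re-expression confirmation: restored expression after demethylating
   treatment in at least ``min_lines`` cell lines at fold >= ``min_fold``;
4. pooled-MSP exclusion: genes methylated in any Normal pool (ordinal level >=
   ``positive_level``) or in blood are excluded;
5. prioritization: genes methylated in at least ``min_cancer_pools`` cancer
   (SCC/AC) pools, ranked by that count.

Every stage partitions its input into retained and excluded genes with an
explicit reason, so the funnel can be audited end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

POOL_GROUPS = ("Normal", "SCC", "AC", "Blood")

VERDICTS = (
    "cancer_specific",
    "evidence_supported",
    "confirmed_reexpressed",
    "excluded_normal_or_blood",
    "prioritized",
    "dropped",
)


@dataclass
class TriageConfig:
    """Thresholds of the funnel filters."""

    min_fold: float = 2.0          # re-expression fold-change threshold
    min_lines: int = 1             # cell lines that must reach min_fold
    positive_level: int = 1        # ordinal MSP level counting as methylated
    min_cancer_pools: int = 5      # "more than four" cancer pools
    msp_failures: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise InputError("min_fold: must be > 1")
        if self.min_lines < 1:
            raise InputError("min_lines: must be >= 1")
        if self.positive_level not in (1, 2, 3, 4):
            raise InputError("positive_level: must be in 1..4")
        if self.min_cancer_pools < 1:
            raise InputError("min_cancer_pools: must be >= 1")


def _pool_group(column: str) -> str:
    group = column.split(":", 1)[0].strip().lower().capitalize()
    if group == "Ac":
        group = "AC"
    if group == "Scc":
        group = "SCC"
    if group not in POOL_GROUPS:
        raise InputError(f"pool column {column!r}: unknown group label")
    return group


def validate_pool_matrix(pools: pd.DataFrame) -> None:
    """Check ordinal levels and group-labeled columns of a pooled-MSP matrix."""
    for col in pools.columns:
        _pool_group(col)
    bad = ~pools.isin([0, 1, 2, 3, 4]).all(axis=None)
    if bad:
        raise InputError("pool matrix entries must be ordinal levels 0..4")


def cancer_specific_genes(scc: set[str], ac: set[str], normal: set[str]) -> set[str]:
    """Genes enriched in both carcinoma groups but not in normal samples."""
    return (set(scc) & set(ac)) - set(normal)


def integrate_external_evidence(
    genes: set[str], expr_down: set[str], tdmr: set[str]
) -> dict[str, tuple[str, ...]]:
    """Retain genes present in either external list, recording which matched.

    Returns a mapping gene -> tuple of matched evidence tags (a subset of
    ``("expr_down", "tdmr")``).
    """
    out: dict[str, tuple[str, ...]] = {}
    for g in genes:
        tags = tuple(
            tag for tag, s in (("expr_down", expr_down), ("tdmr", tdmr)) if g in s
        )
        if tags:
            out[g] = tags
    return out


def reexpression_filter(
    genes: set[str], records: pd.DataFrame, min_fold: float = 2.0,
    min_lines: int = 1,
) -> set[str]:
    """Genes whose expression is restored by demethylating treatment.

    ``records`` has columns gene, cell_line, fold_change (> 0). A gene is
    retained iff fold_change >= min_fold in at least min_lines cell lines.
    Genes without any record are dropped with a warning.
    """
    if min_fold <= 1:
        raise InputError("min_fold: must be > 1")
    if min_lines < 1:
        raise InputError("min_lines: must be >= 1")
    if (records["fold_change"] <= 0).any():
        raise InputError("fold_change values must be > 0")
    counts = (
        records[records["fold_change"] >= min_fold]
        .groupby("gene")["cell_line"].nunique()
    )
    recorded = set(records["gene"])
    missing = set(genes) - recorded
    if missing:
        logger.warning("reexpression_filter: no records for %s; dropped",
                       sorted(missing))
    return {g for g in genes if counts.get(g, 0) >= min_lines}


def _methylated_counts(pools: pd.DataFrame, genes, groups, positive_level: int):
    cols = [c for c in pools.columns if _pool_group(c) in groups]
    sub = pools.loc[list(genes), cols]
    return (sub >= positive_level).sum(axis=1)


def msp_exclusion_filter(
    genes: set[str], pools: pd.DataFrame, positive_level: int = 1,
    blood_flags: set[str] | None = None,
) -> tuple[set[str], dict[str, str]]:
    """Exclude genes methylated in normal pools or in blood.

    Returns ``(retained, excluded)`` where ``excluded`` maps gene -> reason
    ("normal pool" or "blood"). Raises if a gene is absent from the matrix.
    """
    blood_flags = blood_flags or set()
    missing = sorted(set(genes) - set(pools.index))
    if missing:
        raise InputError(f"genes absent from pool matrix: {missing}")
    validate_pool_matrix(pools)
    blood_cols = [c for c in pools.columns if _pool_group(c) == "Blood"]
    normal_hits = _methylated_counts(pools, sorted(genes), {"Normal"}, positive_level)
    retained: set[str] = set()
    excluded: dict[str, str] = {}
    for g in sorted(genes):
        in_blood = g in blood_flags or (
            blood_cols and (pools.loc[g, blood_cols] >= positive_level).any()
        )
        if normal_hits[g] > 0:
            excluded[g] = "normal pool"
        elif in_blood:
            excluded[g] = "blood"
        else:
            retained.add(g)
    return retained, excluded


def prioritize_candidates(
    retained: set[str], pools: pd.DataFrame, min_cancer_pools: int = 5,
    positive_level: int = 1,
) -> list[tuple[str, int]]:
    """Rank genes by the number of cancer pools in which they are methylated.

    Genes with at least ``min_cancer_pools`` methylated SCC/AC pools are
    prioritized; output is sorted by (count desc, gene id asc).
    """
    if not retained:
        return []
    counts = _methylated_counts(pools, sorted(retained), {"SCC", "AC"},
                                positive_level)
    chosen = [(g, int(counts[g])) for g in sorted(retained)
              if counts[g] >= min_cancer_pools]
    return sorted(chosen, key=lambda t: (-t[1], t[0]))


def run_funnel(
    scc: set[str], ac: set[str], normal: set[str],
    expr_down: set[str], tdmr: set[str],
    reexpression: pd.DataFrame, pools: pd.DataFrame,
    blood_flags: set[str] | None = None,
    cfg: TriageConfig | None = None,
) -> pd.DataFrame:
    """Run the whole funnel and return a per-gene triage report.

    The report covers every gene in the cancer-specific input set with its
    evidence flags and final verdict; retained and excluded genes partition
    each stage's input, and a counts summary is attached as
    ``DataFrame.attrs["funnel_counts"]``.
    """
    cfg = cfg or TriageConfig()
    blood_flags = blood_flags or set()
    universe = set(scc) | set(ac) | set(normal)

    stage1 = cancer_specific_genes(scc, ac, normal)
    evidence = integrate_external_evidence(stage1, expr_down, tdmr)
    stage2 = set(evidence)
    stage3 = reexpression_filter(stage2, reexpression, cfg.min_fold, cfg.min_lines)
    stage3_kept = stage3 - cfg.msp_failures
    retained, excluded = msp_exclusion_filter(
        stage3_kept, pools, cfg.positive_level, blood_flags
    )
    ranked = prioritize_candidates(retained, pools, cfg.min_cancer_pools,
                                   cfg.positive_level)
    prioritized = {g for g, _ in ranked}

    max_fold = (reexpression.groupby("gene")["fold_change"].max()
                if len(reexpression) else pd.Series(dtype=float))
    cancer_counts = (
        _methylated_counts(pools, sorted(set(pools.index)), {"SCC", "AC"},
                           cfg.positive_level)
        if len(pools) else pd.Series(dtype=int)
    )
    normal_counts = (
        _methylated_counts(pools, sorted(set(pools.index)), {"Normal"},
                           cfg.positive_level)
        if len(pools) else pd.Series(dtype=int)
    )

    rows = []
    for g in sorted(universe):
        if g not in stage1:
            verdict, reason = "dropped", "not cancer specific"
        elif g not in stage2:
            verdict, reason = "dropped", "no external evidence"
        elif g not in stage3:
            verdict, reason = "dropped", "no re-expression"
        elif g in cfg.msp_failures:
            verdict, reason = "dropped", "MSP assay failure"
        elif g in excluded:
            verdict, reason = "excluded_normal_or_blood", excluded[g]
        elif g in prioritized:
            verdict, reason = "prioritized", "methylated in >= %d cancer pools" % (
                cfg.min_cancer_pools)
        else:
            verdict, reason = "confirmed_reexpressed", "below cancer-pool threshold"
        rows.append({
            "gene": g,
            "in_scc": g in scc,
            "in_ac": g in ac,
            "in_normal": g in normal,
            "in_expr_down": g in expr_down,
            "in_tdmr": g in tdmr,
            "reexpressed": g in stage3,
            "reexpression_max_fold": float(max_fold.get(g, float("nan"))),
            "methylated_cancer_pools": int(cancer_counts.get(g, 0)),
            "methylated_normal_pools": int(normal_counts.get(g, 0)),
            "methylated_in_blood": g in blood_flags,
            "verdict": verdict,
            "reason": reason,
        })
    report = pd.DataFrame(rows)
    report.attrs["funnel_counts"] = {
        "input": len(universe),
        "cancer_specific": len(stage1),
        "evidence_supported": len(stage2),
        "confirmed_reexpressed": len(stage3),
        "after_msp_exclusion": len(retained),
        "prioritized": len(prioritized),
    }
    report.attrs["ranking"] = ranked
    logger.info("funnel counts: %s", report.attrs["funnel_counts"])
    return report
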