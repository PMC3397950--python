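"""Seeded synthetic data: tiling-array probe sets and QMSP cohorts.

Two generators back every downstream stage of the pipeline:

* :func:`simulate_tiling_groups` emulates a promoter tiling array hybridized
  with MeDIP-enriched DNA from three sample groups (SCC, AC, Normal).
  Hypermethylated promoters are planted per group; probes inside a planted
  promoter carry a mean log2-ratio shift, and the noise can be smoothed over a
  configurable correlation length reflecting sonication fragment sizes of a
  few hundred bp.
* :func:`simulate_qmsp_cohort` emulates a cross-sectional QMSP cohort across
  the cervical-neoplasia grade spectrum. Per-grade M-indexes are drawn
  log-normally around configurable medians; reference-gene crossing points
  (Cp) are drawn normally and the target-gene Cp is set so that the M-index
  formula inverts exactly.

Both return their ground truth alongside the data; truth is never embedded in
the data tables themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .grades import GRADE_ORDER, DichotomyScheme

GROUPS: tuple[str, ...] = ("SCC", "AC", "Normal")

#: Per-grade (median M-index, natural-log dispersion) defaults. The medians
#: are the published ZNF582 cohort medians across the grade spectrum; the
#: dispersion default of 1.5 reflects the wide positive-scale confidence
#: intervals around those medians.
DEFAULT_GRADE_PARAMS: dict[str, tuple[float, float]] = {
    "Normal": (0.01, 1.5),
    "CIN1": (0.06, 1.5),
    "CIN2": (0.19, 1.5),
    "CIN3/CIS": (1.71, 1.5),
    "SCC": (31.95, 1.5),
}

#: Cohort sizes per grade matching the evaluable pre-validation cohort.
DEFAULT_N_PER_GRADE: dict[str, int] = {
    "Normal": 156,
    "CIN1": 55,
    "CIN2": 31,
    "CIN3/CIS": 46,
    "SCC": 39,
}

M_INDEX_SCALE = 10_000.0


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {message}")


@dataclass
class TilingSimConfig:
    """Configuration for the tiling-array simulator.

    Lengths are in bp; log2 ratios are dimensionless. ``fragment_smoothing_bp``
    is the correlation length of the noise (0 disables smoothing and gives
    i.i.d. probes).
    """

    n_chromosomes: int = 3
    chrom_length: int = 200_000
    probe_spacing: int = 100
    probe_length: int = 50
    n_promoters: int = 60
    promoter_width: int = 1000
    planted_fraction_scc: float = 0.25
    planted_fraction_ac: float = 0.25
    planted_fraction_normal: float = 0.05
    effect_size: float = 1.5
    noise_sd: float = 0.5
    baseline_mean: float = 0.0
    fragment_smoothing_bp: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_chromosomes >= 1, "n_chromosomes", "must be >= 1")
        _require(self.chrom_length > 0, "chrom_length", "must be > 0")
        _require(self.probe_spacing > 0, "probe_spacing", "must be > 0")
        _require(0 < self.probe_length <= self.probe_spacing, "probe_length",
                 "must be in (0, probe_spacing]")
        _require(self.n_promoters >= 0, "n_promoters", "must be >= 0")
        _require(self.promoter_width >= self.probe_spacing, "promoter_width",
                 "must be >= probe_spacing")
        for name in ("planted_fraction_scc", "planted_fraction_ac",
                     "planted_fraction_normal"):
            _require(0.0 <= getattr(self, name) <= 1.0, name, "must be in [0, 1]")
        _require(self.effect_size > 0, "effect_size", "must be > 0")
        _require(self.noise_sd > 0, "noise_sd", "must be > 0")
        _require(self.fragment_smoothing_bp >= 0, "fragment_smoothing_bp",
                 "must be >= 0")

    @property
    def planted_fractions(self) -> dict[str, float]:
        return {
            "SCC": self.planted_fraction_scc,
            "AC": self.planted_fraction_ac,
            "Normal": self.planted_fraction_normal,
        }


def promoter_annotation(cfg: TilingSimConfig) -> pd.DataFrame:
    """Deterministic promoter intervals (0-based half-open) implied by a config.

    Promoters are spread evenly along each chromosome, aligned to the probe
    grid, and never overlap. Returns columns chrom, start, end, gene.
    """
    per_chrom = [cfg.n_promoters // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_promoters % cfg.n_chromosomes):
        per_chrom[i] += 1
    rows = []
    idx = 0
    for c in range(cfg.n_chromosomes):
        k = per_chrom[c]
        if k == 0:
            continue
        stride = cfg.chrom_length / (k + 1)
        if stride <= cfg.promoter_width:
            raise ConfigurationError(
                "n_promoters: too many promoters for chrom_length/promoter_width"
            )
        chrom = f"chr{c + 1}"
        for j in range(k):
            start = int(round((j + 1) * stride / cfg.probe_spacing)) * cfg.probe_spacing
            end = start + cfg.promoter_width
            if end > cfg.chrom_length:
                start = cfg.chrom_length - cfg.promoter_width
                end = cfg.chrom_length
            rows.append((chrom, start, end, f"G{idx:04d}"))
            idx += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def _smooth(noise: np.ndarray, kernel_len: int) -> np.ndarray:
    """Moving-average smoothing that preserves the marginal variance."""
    if kernel_len < 2 or noise.size < 2:
        return noise
    kernel = np.ones(kernel_len) / math.sqrt(kernel_len)
    return np.convolve(noise, kernel, mode="same")


def simulate_tiling_groups(
    cfg: TilingSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-group probe tables with planted hypermethylated promoters.

    Returns ``(tables, truth)`` where ``tables`` maps group name (SCC, AC,
    Normal) to a probe table with columns probe_id, chrom, start, end,
    log2_ratio, and ``truth`` lists every planted region with columns group,
    chrom, start, end, gene. Identical configs (including seed) give
    byte-identical outputs.
    """
    promoters = promoter_annotation(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    plant_rng = np.random.default_rng(ss.spawn(1)[0])
    group_seeds = {g: s for g, s in zip(GROUPS, ss.spawn(len(GROUPS) + 1)[1:])}

    # choose planted promoters per group
    truth_rows = []
    planted: dict[str, pd.DataFrame] = {}
    for group in GROUPS:
        frac = cfg.planted_fractions[group]
        n_plant = int(round(frac * len(promoters)))
        if n_plant > 0:
            pick = np.sort(plant_rng.choice(len(promoters), size=n_plant, replace=False))
            sub = promoters.iloc[pick]
        else:
            plant_rng.choice(1)  # keep the stream position group-independent in shape
            sub = promoters.iloc[:0]
        planted[group] = sub
        for _, row in sub.iterrows():
            truth_rows.append((group, row.chrom, row.start, row.end, row.gene))
    truth = pd.DataFrame(truth_rows, columns=["group", "chrom", "start", "end", "gene"])

    # probe grid shared by all groups
    n_per_chrom = (cfg.chrom_length - cfg.probe_length) // cfg.probe_spacing + 1
    starts = np.arange(n_per_chrom) * cfg.probe_spacing
    kernel_len = int(round(cfg.fragment_smoothing_bp / cfg.probe_spacing))

    tables: dict[str, pd.DataFrame] = {}
    for group in GROUPS:
        rng = np.random.default_rng(group_seeds[group])
        frames = []
        for c in range(cfg.n_chromosomes):
            chrom = f"chr{c + 1}"
            noise = rng.standard_normal(n_per_chrom)
            noise = _smooth(noise, kernel_len) * cfg.noise_sd
            ratio = cfg.baseline_mean + noise
            mids = starts + cfg.probe_length / 2.0
            sub = planted[group]
            for _, region in sub[sub.chrom == chrom].iterrows():
                inside = (mids >= region.start) & (mids < region.end)
                ratio[inside] += cfg.effect_size
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": [f"{chrom}:{s}" for s in starts],
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + cfg.probe_length,
                        "log2_ratio": ratio,
                    }
                )
            )
        tables[group] = pd.concat(frames, ignore_index=True)
    return tables, truth


@dataclass
class CohortSimConfig:
    """Configuration for the QMSP cohort simulator.

    ``grade_params`` maps each grade to (median M-index, natural-log
    dispersion). ``failure_rate`` is the fraction of samples whose
    reference-gene Cp exceeds the detection-failure cutoff of 36 cycles.
    """

    grade_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_PARAMS)
    )
    n_per_grade: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GRADE)
    )
    cp_ref_mean: float = 30.0
    cp_ref_sd: float = 1.0
    failure_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for grade in self.n_per_grade:
            _require(grade in GRADE_ORDER, "n_per_grade", f"unknown grade {grade!r}")
            _require(self.n_per_grade[grade] >= 1, "n_per_grade",
                     f"{grade}: must be >= 1")
            _require(grade in self.grade_params, "grade_params",
                     f"missing parameters for grade {grade!r}")
        for grade, (median, sigma) in self.grade_params.items():
            _require(grade in GRADE_ORDER, "grade_params", f"unknown grade {grade!r}")
            _require(median > 0, "grade_params", f"{grade}: median must be > 0")
            _require(sigma >= 0, "grade_params", f"{grade}: dispersion must be >= 0")
        _require(self.cp_ref_sd >= 0, "cp_ref_sd", "must be >= 0")
        _require(0.0 <= self.failure_rate < 1.0, "failure_rate", "must be in [0, 1)")


def simulate_qmsp_cohort(
    cfg: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a QMSP Cp table with grade labels, plus per-sample truth.

    For each sample an M-index ``M`` is drawn log-normally around its grade
    median, ``cp_ref`` is drawn from N(cp_ref_mean, cp_ref_sd), and
    ``cp_gene = cp_ref - log2(M / 10,000)`` so that the M-index formula
    inverts exactly. A ``failure_rate`` fraction of samples instead get
    ``cp_ref`` drawn above 36 (a detection failure).

    Returns ``(cp_table, truth)``: cp_table has columns sample_id, grade,
    cp_ref, cp_gene; truth has sample_id, grade, m_true, failed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    rows = []
    truth_rows = []
    i = 0
    for grade in GRADE_ORDER:
        if grade not in cfg.n_per_grade:
            continue
        n = cfg.n_per_grade[grade]
        median, sigma = cfg.grade_params[grade]
        m = median * np.exp(sigma * rng.standard_normal(n))
        cp_ref = rng.normal(cfg.cp_ref_mean, cfg.cp_ref_sd, n)
        failed = rng.random(n) < cfg.failure_rate
        cp_ref[failed] = rng.uniform(36.5, 45.0, int(failed.sum()))
        cp_gene = cp_ref - np.log2(m / M_INDEX_SCALE)
        for j in range(n):
            sid = f"S{i:04d}"
            rows.append((sid, grade, cp_ref[j], cp_gene[j]))
            truth_rows.append((sid, grade, m[j], bool(failed[j])))
            i += 1
    cp_table = pd.DataFrame(rows, columns=["sample_id", "grade", "cp_ref", "cp_gene"])
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "grade", "m_true", "failed"])
    return cp_table, truth


def true_auc(cfg: CohortSimConfig, scheme: DichotomyScheme) -> float:
    """Closed-form AUC of the generating model for a dichotomization scheme.

    Each arm is a finite mixture of log-normals weighted by cohort sizes;
    P(LN(mu1, s1) > LN(mu2, s2)) = Phi((mu1 - mu2) / sqrt(s1^2 + s2^2)).
    """
    def arm(grades):
        gs = [g for g in grades if g in cfg.n_per_grade]
        total = sum(cfg.n_per_grade[g] for g in gs)
        return [(math.log(cfg.grade_params[g][0]), cfg.grade_params[g][1],
                 cfg.n_per_grade[g] / total) for g in gs]

    cases = arm(scheme.case_grades)
    controls = arm(scheme.control_grades)
    auc = 0.0
    for mu1, s1, w1 in cases:
        for mu0, s0, w0 in controls:
            denom = math.sqrt(s1 * s1 + s0 * s0)
            if denom == 0:
                p = 0.5 if mu1 == mu0 else float(mu1 > mu0)
            else:
                p = float(norm.cdf((mu1 - mu0) / denom))
            auc += w1 * w0 * p
    return auc


def simulate_triage_evidence(
    truth: pd.DataFrame,
    all_genes: list[str],
    seed: int = 0,
    n_pools_per_group: int = 4,
    reexpression_cell_lines: tuple[str, ...] = ("HeLa", "SiHa", "CaSki"),
) -> dict[str, object]:
    """Synthesize triage evidence consistent with tiling ground truth.

    Produces external-evidence gene lists (expression-down and T-DMR), cell
    line re-expression fold-change records, and a pooled-MSP ordinal matrix
    covering every gene planted in any group plus unplanted decoys. Cancer
    planted genes (SCC or AC) receive methylation-positive entries in cancer
    pools and strong re-expression folds; normal-planted genes are methylated
    in Normal pools so that the exclusion rule has work to do.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    cancer_genes = sorted(set(truth.loc[truth.group.isin(["SCC", "AC"]), "gene"]))
    normal_genes = sorted(set(truth.loc[truth.group == "Normal", "gene"]))
    decoys = sorted(set(all_genes) - set(cancer_genes) - set(normal_genes))

    def sample(pool, frac):
        k = int(round(frac * len(pool)))
        if k == 0:
            return []
        return sorted(rng.choice(pool, size=min(k, len(pool)), replace=False))

    expr_down = set(sample(cancer_genes, 0.6)) | set(sample(decoys, 0.1))
    tdmr = set(sample(cancer_genes, 0.5)) | set(sample(decoys, 0.2))

    reexp_rows = []
    for g in cancer_genes + sample(decoys, 0.2):
        strong = g in cancer_genes and rng.random() < 0.8
        for line in reexpression_cell_lines:
            base = rng.uniform(2.0, 8.0) if strong else rng.uniform(0.5, 1.8)
            reexp_rows.append((g, line, base))
    reexpression = pd.DataFrame(
        reexp_rows, columns=["gene", "cell_line", "fold_change"]
    )

    pool_cols = [f"{g}:{p + 1}" for g in ("Normal", "SCC", "AC")
                 for p in range(n_pools_per_group)]
    matrix_genes = sorted(set(cancer_genes) | set(normal_genes) | set(decoys))
    mat = pd.DataFrame(0, index=pd.Index(matrix_genes, name="gene"),
                       columns=pool_cols, dtype=int)
    for g in matrix_genes:
        for col in pool_cols:
            group = col.split(":")[0]
            if group in ("SCC", "AC") and g in cancer_genes:
                level = int(rng.integers(2, 5)) if rng.random() < 0.85 else 0
            elif group == "Normal" and g in normal_genes:
                level = int(rng.integers(1, 4)) if rng.random() < 0.7 else 0
            else:
                level = int(rng.integers(1, 3)) if rng.random() < 0.03 else 0
            mat.loc[g, col] = level
    blood = set(sample(matrix_genes, 0.02))
    return {
        "expr_down": expr_down,
        "tdmr": tdmr,
        "reexpression": reexpression,
        "pool_matrix": mat,
        "blood_genes": blood,
    }
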