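"""MeDIP-on-chip enrichment calling.

The analysis chain mirrors the standard promoter tiling-array workflow:

1. center each array's probe log2 ratios by subtracting the Tukey biweight
   mean (robust location, bounded influence);
2. score each probe with a one-sided two-sample Kolmogorov-Smirnov test of the
   probes in a 500 bp window around it against all remaining probes on the
   array (the window being drawn from a more *positive* log2-ratio
   distribution raises the statistic); the probe score is -log10 of the
   KS p-value;
3. call enriched regions as maximal runs of probes whose score reaches the
   cutoff (default 2.0), merging qualifying probes separated by at most
   ``merge_gap`` bp;
4. annotate regions against promoter intervals to obtain gene-level calls.

The one-sided KS p-value is an exact permutation tail probability whenever
the window is small (which it always is for 100 bp probe spacing and a 500 bp
window): by full enumeration of label assignments when the pooled sample is
small, otherwise by an exact lattice-path count over the window's ranks.
Large windows fall back to the asymptotic bound exp(-2 d^2 mn / (m + n)).
All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class PeakCallerConfig:
    """Parameters of the windowed-KS peak caller.

    ``merge_gap`` defaults to ``window_width`` when left as None. The exact
    permutation p-value is used for windows of at most
    ``small_sample_exact_limit`` probes; ``enumeration_limit`` bounds the
    number of label assignments enumerated before switching to the
    lattice-path count.
    """

    window_width: float = 500.0
    score_cutoff: float = 2.0
    min_probes_per_window: int = 2
    merge_gap: float | None = None
    biweight_c: float = 5.0
    biweight_tol: float = 1e-6
    small_sample_exact_limit: int = 10
    enumeration_limit: int = 200_000

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ConfigurationError("window_width: must be > 0")
        if self.score_cutoff < 0:
            raise ConfigurationError("score_cutoff: must be >= 0")
        if self.min_probes_per_window < 1:
            raise ConfigurationError("min_probes_per_window: must be >= 1")
        if self.merge_gap is None:
            self.merge_gap = self.window_width
        if self.merge_gap < 0:
            raise ConfigurationError("merge_gap: must be >= 0")


def biweight_mean(values, c: float = 5.0, tol: float = 1e-6,
                  max_iter: int = 100) -> float:
    """Iterated Tukey biweight location estimate.

    Starts from the median with scale fixed at the MAD; observations with
    ``|x - m| >= c * MAD`` get zero weight, others weight ``(1 - u^2)^2``.
    Returns the median when the MAD is zero (degenerate scale).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InputError("biweight_mean: empty input")
    if not np.all(np.isfinite(x)):
        raise InputError("biweight_mean: non-finite values")
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0.0:
        return m
    scale = c * mad
    for _ in range(max_iter):
        u = (x - m) / scale
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) <= tol:
            return m_new
        m = m_new
    return m


def center_log2_ratios(probes: pd.DataFrame,
                       cfg: PeakCallerConfig | None = None) -> pd.DataFrame:
    """Return a copy of the probe table with a ``centered_ratio`` column.

    Centering subtracts the biweight mean of all log2 ratios on the array, so
    the biweight mean of the centered column is ~0.
    """
    cfg = cfg or PeakCallerConfig()
    ratios = probes["log2_ratio"].to_numpy(dtype=float)
    bad = ~np.isfinite(ratios)
    if bad.any():
        ids = probes.loc[bad, "probe_id"].tolist()
        raise InputError(f"non-finite log2_ratio for probes: {ids}")
    m = biweight_mean(ratios, c=cfg.biweight_c, tol=cfg.biweight_tol)
    out = probes.copy()
    out["centered_ratio"] = ratios - m
    return out


# ---------------------------------------------------------------------------
# one-sided KS machinery
# ---------------------------------------------------------------------------

def _d_plus_stat(window_sorted: np.ndarray, cnt_bg_less: np.ndarray,
                 n_bg: int) -> tuple[float, int]:
    """D+ and its exact integer numerator K = max_i (m*C_i - n*i).

    ``cnt_bg_less[i]`` is the number of background values strictly below the
    (i+1)-th smallest window value. D+ = max(0, K) / (m * n).
    """
    m = window_sorted.size
    ks = m * cnt_bg_less.astype(np.int64) - n_bg * np.arange(m, dtype=np.int64)
    k = int(ks.max())
    d = max(k, 0) / (m * n_bg)
    return d, k


@lru_cache(maxsize=200_000)
def _exact_p_lattice(m: int, n: int, k_obs: int) -> float:
    """Exact P(D+ >= k_obs/(m n)) over all C(m+n, m) rank assignments.

    Valid for distinct pooled values. Counts the increasing rank sequences
    r_1 < ... < r_m with r_i <= u_i (the complement event D+ < d) by a
    cumulative-sum lattice-path recursion; uses int64 when the binomial
    coefficient is exactly representable, float64 otherwise.
    """
    if k_obs <= 0:
        return 1.0
    total = math.comb(m + n, m)
    big = total >= 2**62
    upper = [min((k_obs - 1 + m * i + n * (i - 1)) // m, m + n) for i in range(1, m + 1)]
    if upper[0] < 1:
        return 1.0
    dtype = np.float64 if big else np.int64
    ways = np.ones(upper[0], dtype=dtype)  # ways_1(r), r = 1..u_1
    length = upper[0]
    for i in range(1, m):
        u = upper[i]
        if u < i + 1:
            return 1.0
        csum = np.cumsum(ways)
        new = np.zeros(u, dtype=dtype)
        lim = min(u - 1, length)
        new[1:1 + lim] = csum[:lim]
        if u - 1 > length:  # ranks beyond the previous column see the full sum
            new[1 + length:] = csum[-1]
        ways, length = new, u
    count = ways.sum()
    if big:
        return float(max(min(1.0 - float(count) / total, 1.0), _P_FLOOR))
    return (total - int(count)) / total


def _exact_p_enumeration(pooled_sorted: np.ndarray, m: int, k_obs: int) -> float:
    """Exact permutation tail by full enumeration; correct under ties.

    Enumerates every assignment of m pooled values to the window and counts
    assignments whose integer D+ numerator reaches ``k_obs``.
    """
    pooled_lt = np.searchsorted(pooled_sorted, pooled_sorted, side="left")
    n_pool = pooled_sorted.size
    n = n_pool - m
    combs = np.array(list(combinations(range(n_pool), m)), dtype=np.int64)
    vals = pooled_sorted[combs]                     # (C, m) window values, sorted
    lt_pool = pooled_lt[combs]                      # pooled values strictly below
    win_lt = np.zeros_like(lt_pool)
    for i in range(1, m):
        win_lt[:, i] = (vals[:, :i] < vals[:, i:i + 1]).sum(axis=1)
    cnt_bg = lt_pool - win_lt
    ks = m * cnt_bg - n * np.arange(m, dtype=np.int64)
    k_sub = ks.max(axis=1)
    return float(np.count_nonzero(k_sub >= k_obs)) / combs.shape[0]


def _asymptotic_p(d: float, m: int, n: int) -> float:
    p = math.exp(-2.0 * d * d * m * n / (m + n))
    return max(min(p, 1.0), _P_FLOOR)


def ks_one_sided(window_values, background_values, exact_limit: int = 10,
                 enumeration_limit: int = 200_000) -> tuple[float, float]:
    """One-sided two-sample KS test for a positive shift of the window.

    Returns ``(d_plus, p_value)`` with
    ``d_plus = sup_x [F_background(x) - F_window(x)]`` (clamped at 0). The
    p-value is the exact permutation tail probability when the window has at
    most ``exact_limit`` values (full enumeration when C(m+n, m) <=
    ``enumeration_limit``, else an exact rank lattice-path count assuming
    distinct pooled values); otherwise the asymptotic one-sided bound
    ``exp(-2 d^2 m n / (m + n))``. p is clamped to (0, 1].
    """
    w = np.sort(np.asarray(window_values, dtype=float))
    bg = np.sort(np.asarray(background_values, dtype=float))
    m, n = w.size, bg.size
    if m == 0 or n == 0:
        raise InputError("ks_one_sided: both samples must be non-empty")
    cnt_bg = np.searchsorted(bg, w, side="left")
    d, k = _d_plus_stat(w, cnt_bg, n)
    if k <= 0:
        return 0.0, 1.0
    if m <= exact_limit:
        if math.comb(m + n, m) <= enumeration_limit:
            pooled = np.sort(np.concatenate([w, bg]))
            p = _exact_p_enumeration(pooled, m, k)
        elif np.unique(np.concatenate([w, bg])).size == m + n:
            p = _exact_p_lattice(m, n, k)
        else:
            logger.warning(
                "ks_one_sided: ties in a pooled sample too large to enumerate; "
                "using the asymptotic bound"
            )
            p = _asymptotic_p(d, m, n)
    else:
        p = _asymptotic_p(d, m, n)
    return float(d), float(max(p, _P_FLOOR))


# ---------------------------------------------------------------------------
# probe scoring and region calling
# ---------------------------------------------------------------------------

def _check_sorted(probes: pd.DataFrame) -> None:
    key = probes[["chrom", "start"]]
    if not key.equals(key.sort_values(["chrom", "start"], kind="stable")):
        raise InputError("probes must be sorted by (chrom, start); "
                         "use the table readers, which sort on load")


def score_probes(probes: pd.DataFrame, cfg: PeakCallerConfig | None = None) -> pd.DataFrame:
    """Windowed one-sided KS score for every probe.

    For each probe the window is every probe on the same chromosome whose
    interval midpoint lies within +/- window_width/2 of the probe's midpoint;
    the background is every other probe on the array. Probes whose window has
    fewer than ``min_probes_per_window`` members get score 0 (skip counted in
    the log). Input must be centered and sorted by (chrom, start).

    Returns a DataFrame with columns probe_id, d_plus, p_value, score aligned
    to the input rows.
    """
    cfg = cfg or PeakCallerConfig()
    if "centered_ratio" not in probes.columns:
        raise InputError("probes must carry centered_ratio; run center_log2_ratios first")
    _check_sorted(probes)

    values = probes["centered_ratio"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite centered_ratio values")
    n_total = values.size
    all_sorted = np.sort(values)
    has_ties = np.unique(all_sorted).size < n_total
    half = cfg.window_width / 2.0

    d_out = np.full(n_total, np.nan)
    p_out = np.ones(n_total)
    s_out = np.zeros(n_total)
    n_skipped = 0
    n_asymptotic = 0

    offset = 0
    for _, chrom_df in probes.groupby("chrom", sort=False, observed=True):
        mids = ((chrom_df["start"].to_numpy() + chrom_df["end"].to_numpy()) / 2.0)
        k = mids.size
        lo = np.searchsorted(mids, mids - half, side="left")
        hi = np.searchsorted(mids, mids + half, side="right")
        for j in range(k):
            a, b = lo[j], hi[j]
            m = b - a
            gi = offset + j
            if m < cfg.min_probes_per_window:
                n_skipped += 1
                continue
            w = np.sort(values[offset + a: offset + b])
            n_bg = n_total - m
            cnt_all = np.searchsorted(all_sorted, w, side="left")
            cnt_win = np.searchsorted(w, w, side="left")
            d, kint = _d_plus_stat(w, cnt_all - cnt_win, n_bg)
            d_out[gi] = d
            if kint <= 0:
                continue
            if m <= cfg.small_sample_exact_limit and not has_ties:
                p = _exact_p_lattice(m, n_bg, kint)
            else:
                p = _asymptotic_p(d, m, n_bg)
                n_asymptotic += 1
            p_out[gi] = max(p, _P_FLOOR)
            s_out[gi] = -math.log10(p_out[gi])
        offset += k

    if n_skipped:
        logger.info("score_probes: %d probes skipped (window below %d probes)",
                    n_skipped, cfg.min_probes_per_window)
    if n_asymptotic:
        logger.info("score_probes: %d probes scored with the asymptotic bound "
                    "(window > %d probes or ties present)",
                    n_asymptotic, cfg.small_sample_exact_limit)
    return pd.DataFrame(
        {
            "probe_id": probes["probe_id"].to_numpy(),
            "d_plus": d_out,
            "p_value": p_out,
            "score": s_out,
        },
        index=probes.index,
    )


def call_regions(scores: pd.DataFrame, probes: pd.DataFrame,
                 cfg: PeakCallerConfig | None = None) -> pd.DataFrame:
    """Merge qualifying probes (score >= cutoff) into enriched regions.

    Consecutive qualifying probes on the same chromosome whose inter-probe gap
    (next start minus previous end) is at most ``merge_gap`` join one region.
    Regions spanning fewer than ``min_probes_per_window`` qualifying probes
    are dropped. Returns chrom, start, end, peak_score, n_probes.
    """
    cfg = cfg or PeakCallerConfig()
    if len(scores) != len(probes):
        raise InputError("scores and probes must be aligned")
    df = probes[["chrom", "start", "end"]].copy()
    df["score"] = scores["score"].to_numpy()
    qual = df[df["score"] >= cfg.score_cutoff]
    regions = []
    cur = None
    for row in qual.itertuples(index=False):
        if (cur is not None and row.chrom == cur["chrom"]
                and row.start - cur["end"] <= cfg.merge_gap):
            cur["end"] = max(cur["end"], row.end)
            cur["peak_score"] = max(cur["peak_score"], row.score)
            cur["n_probes"] += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": row.chrom, "start": int(row.start), "end": int(row.end),
                   "peak_score": float(row.score), "n_probes": 1}
    if cur is not None:
        regions.append(cur)
    out = pd.DataFrame(regions,
                       columns=["chrom", "start", "end", "peak_score", "n_probes"])
    return out[out["n_probes"] >= cfg.min_probes_per_window].reset_index(drop=True)


def annotate_regions(regions: pd.DataFrame, promoters: pd.DataFrame) -> pd.DataFrame:
    """Gene-level enrichment: genes whose promoter overlaps a called region.

    Overlap is >= 1 bp under half-open coordinates. Returns one row per
    enriched gene with its best peak_score and the number of overlapping
    regions. Raises if a region chromosome is absent from the annotation.
    """
    unmatched = sorted(set(regions["chrom"]) - set(promoters["chrom"]))
    if unmatched:
        raise InputError(f"region chromosomes missing from annotation: {unmatched}")
    if regions.empty:
        return pd.DataFrame(columns=["gene", "peak_score", "n_regions"])
    hits = []
    for chrom, sub in regions.groupby("chrom", sort=False, observed=True):
        proms = promoters[promoters["chrom"] == chrom]
        for r in sub.itertuples(index=False):
            ov = proms[(proms["start"] < r.end) & (r.start < proms["end"])]
            for g in ov.itertuples(index=False):
                hits.append((g.gene, r.peak_score))
    if not hits:
        return pd.DataFrame(columns=["gene", "peak_score", "n_regions"])
    df = pd.DataFrame(hits, columns=["gene", "peak_score"])
    out = (df.groupby("gene")
             .agg(peak_score=("peak_score", "max"), n_regions=("peak_score", "size"))
             .reset_index()
             .sort_values("gene", kind="stable")
             .reset_index(drop=True))
    return out
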