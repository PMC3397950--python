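"""QMSP quantification: the methylation index (M-index).

The M-index normalizes a target gene's quantitative methylation-specific PCR
signal by the COL2A reference gene::

    M-index = 10,000 x 2 ** (Cp_ref - Cp_gene)

where Cp is the PCR crossing point (lower Cp = more template). A reaction
whose reference Cp exceeds 36 cycles carries too little amplifiable input and
is a *detection failure* - treated as missing, never as zero methylation. The
cutoff applies to the reference gene only: a high target Cp is a legitimate
low-methylation signal.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import InputError
from .grades import GRADE_ORDER, grade_categorical

M_INDEX_SCALE = 10_000.0
DEFAULT_FAILURE_CUTOFF = 36.0

REQUIRED_COLUMNS = ("sample_id", "grade", "cp_ref", "cp_gene")


def m_index(cp_ref, cp_gene, failure_cutoff: float = DEFAULT_FAILURE_CUTOFF):
    """M-index of one sample, or None on detection failure.

    Detection failure: ``cp_ref > failure_cutoff`` or either Cp missing
    (None/NaN). Negative Cp values are an error.
    """
    def _missing(v):
        return v is None or (isinstance(v, float) and math.isnan(v))

    if _missing(cp_ref) or _missing(cp_gene):
        return None
    cp_ref = float(cp_ref)
    cp_gene = float(cp_gene)
    if cp_ref < 0 or cp_gene < 0:
        raise InputError("Cp values must be non-negative")
    if cp_ref > failure_cutoff:
        return None
    return M_INDEX_SCALE * 2.0 ** (cp_ref - cp_gene)


def cohort_m_indexes(
    cp_table: pd.DataFrame, failure_cutoff: float = DEFAULT_FAILURE_CUTOFF
) -> tuple[pd.DataFrame, dict]:
    """Vectorized M-index over a cohort Cp table.

    ``cp_table`` needs columns sample_id, grade, cp_ref, cp_gene (missing Cp
    as NaN/empty, never 0). Returns ``(results, failure_summary)``: results
    carries one row per sample with an ordered-categorical grade, m_index
    (NaN when invalid) and a ``valid`` flag; the summary counts failures per
    grade. Duplicate sample ids and unparseable grades are errors.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in cp_table.columns]
    if missing_cols:
        raise InputError(f"cp table missing columns: {missing_cols}")
    if cp_table.empty:
        results = cp_table.copy()
        results["m_index"] = pd.Series(dtype=float)
        results["valid"] = pd.Series(dtype=bool)
        return results, {"n_total": 0, "n_failed": 0, "per_grade": {}}

    dup = cp_table["sample_id"][cp_table["sample_id"].duplicated()]
    if len(dup):
        raise InputError(f"duplicate sample_id values: {sorted(set(dup))}")

    try:
        cat = grade_categorical(cp_table["grade"])
    except InputError as exc:
        # name the offending row for easier debugging of hand-edited tables
        for i, raw in enumerate(cp_table["grade"]):
            try:
                grade_categorical([raw])
            except InputError:
                raise InputError(
                    f"row {i + 1} (sample {cp_table['sample_id'].iloc[i]!r}): {exc}"
                ) from None
        raise

    cp_ref = pd.to_numeric(cp_table["cp_ref"], errors="coerce").to_numpy(float)
    cp_gene = pd.to_numeric(cp_table["cp_gene"], errors="coerce").to_numpy(float)
    if np.nanmin(np.concatenate([cp_ref, cp_gene])) < 0:
        raise InputError("Cp values must be non-negative")

    valid = np.isfinite(cp_ref) & np.isfinite(cp_gene) & (cp_ref <= failure_cutoff)
    m = np.where(valid, M_INDEX_SCALE * 2.0 ** (cp_ref - cp_gene), np.nan)

    results = pd.DataFrame(
        {
            "sample_id": cp_table["sample_id"].to_numpy(),
            "grade": cat,
            "cp_ref": cp_ref,
            "cp_gene": cp_gene,
            "m_index": m,
            "valid": valid,
        }
    )
    per_grade = {
        g: int(((results["grade"] == g) & ~results["valid"]).sum())
        for g in GRADE_ORDER
        if (results["grade"] == g).any()
    }
    summary = {
        "n_total": int(len(results)),
        "n_failed": int((~results["valid"]).sum()),
        "per_grade": per_grade,
    }
    return results, summary
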