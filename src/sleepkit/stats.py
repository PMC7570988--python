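"""Condition-comparison statistics for the sleep-quality study design.

A small crossover cohort (each subject sleeps one night per mattress
condition A / S / SH) is compared with paired two-sided Wilcoxon signed-rank
tests using the exact null distribution at study scale (n = 10; no normal
approximation below ``EXACT_LIMIT`` pairs). Subjective-objective association
uses Spearman rank correlation. Subjects split into poor and good sleepers at
the conventional PSQI > 5 cutoff.

Zero paired differences are dropped before ranking (Wilcoxon's original
convention); ``zero_method="pratt"`` is available as the documented
alternative. No multiple-testing correction is applied by default; pass
``holm=True`` to ``condition_comparison`` for a Holm adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError

__all__ = [
    "wilcoxon_signed_rank",
    "spearman_rho",
    "split_by_psqi",
    "condition_comparison",
    "INDEX_DIRECTIONS",
]

#: largest n for which the exact signed-rank null distribution is used
EXACT_LIMIT = 25

#: +1 where a larger value means better sleep, -1 where smaller is better;
#: used to pick "the better of S/SH" per index for the paired comparison
INDEX_DIRECTIONS = {
    "depth": +1,
    "length": +1,
    "se": +1,
    "tst_min": +1,
    "sol_min": -1,
    "waso_min": -1,
    "rem_min": +1,
    "deep_min": +1,
    "rnr": +1,
    "ssi": -1,
}


def wilcoxon_signed_rank(
    paired_a,
    paired_b,
    zero_method: str = "wilcox",
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns ``(statistic, p_value)`` with the exact null distribution when
    the number of nonzero differences is at most ``EXACT_LIMIT``, otherwise
    the normal approximation.
    """
    a = np.asarray(paired_a, dtype=float).ravel()
    b = np.asarray(paired_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n_nonzero = int(np.sum(d != 0)) if zero_method == "wilcox" else d.size
    if np.all(d == 0):
        raise DegenerateInputError("all paired differences are zero")
    method = "exact" if n_nonzero <= EXACT_LIMIT else "approx"
    with warnings.catch_warnings():
        # scipy warns (and falls back) when ties preclude the exact law
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(
            a, b, zero_method=zero_method, alternative="two-sided", method=method
        )
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError("inputs must have equal length")
    if xa.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise DegenerateInputError("correlation undefined for a constant input")
    rho = sps.spearmanr(xa, ya).statistic
    return float(rho)


def split_by_psqi(records: pd.DataFrame, cutoff: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition subject records into (poor, good) sleepers.

    Poor sleepers have PSQI strictly above ``cutoff`` (default 5, the
    conventional threshold); the split is exhaustive and disjoint.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if "psqi" not in records.columns:
        raise ValueError("records need a 'psqi' column")
    poor = records[records["psqi"] > cutoff]
    good = records[records["psqi"] <= cutoff]
    return poor, good


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def condition_comparison(
    records: pd.DataFrame,
    indices: list[str] | None = None,
    baseline: str = "A",
    holm: bool = False,
) -> pd.DataFrame:
    """Per-index condition summary with a paired test against baseline.

    ``records`` holds one row per subject × condition with columns
    ``subject_id``, ``condition`` and index columns. For each index the table
    reports mean (SD) per condition and the paired two-sided Wilcoxon p-value
    between the baseline condition and, among the non-baseline conditions,
    the one with the best mean for that index (direction-aware via
    ``INDEX_DIRECTIONS``; unknown indices default to higher-is-better).
    Subjects missing either night of a pair are excluded with a warning.
    Degenerate pairs (all differences zero) yield a missing p-value.
    """
    required = {"subject_id", "condition"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    conditions = sorted(records["condition"].unique())
    if baseline not in conditions:
        raise ValueError(f"baseline condition {baseline!r} absent from records")
    others = [c for c in conditions if c != baseline]
    if not others:
        raise ValueError("need at least 2 conditions for a comparison")
    if indices is None:
        indices = [
            c
            for c in records.columns
            if c not in ("subject_id", "condition", "psqi", "source")
            and pd.api.types.is_numeric_dtype(records[c])
        ]

    rows = []
    for idx in indices:
        wide = records.pivot_table(
            index="subject_id", columns="condition", values=idx, aggfunc="first"
        )
        row: dict = {"index": idx}
        for cond in conditions:
            vals = wide[cond].dropna() if cond in wide else pd.Series(dtype=float)
            row[f"mean_{cond}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{cond}"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        direction = INDEX_DIRECTIONS.get(idx, +1)
        best = max(others, key=lambda c: direction * row[f"mean_{c}"])
        paired = wide[[baseline, best]].dropna()
        n_total = wide.shape[0]
        if len(paired) < n_total:
            warnings.warn(
                f"{idx}: {n_total - len(paired)} subject(s) unpaired between "
                f"{baseline} and {best}; excluded",
                stacklevel=2,
            )
        try:
            _, p = wilcoxon_signed_rank(paired[baseline], paired[best])
        except (DegenerateInputError, ValueError):
            p = np.nan
        row["comparator"] = best
        row["p_value"] = p
        row["n_pairs"] = len(paired)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("index")
    if holm:
        table["p_adjusted"] = _holm(table["p_value"].to_numpy())
        table["significance"] = [_stars(p) for p in table["p_adjusted"]]
    else:
        table["significance"] = [_stars(p) for p in table["p_value"]]
    return table


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (statsmodels), NaN-aware."""
    from statsmodels.stats.multitest import multipletests

    adj = np.full_like(pvals, np.nan, dtype=float)
    mask = ~np.isnan(pvals)
    if mask.any():
        adj[mask] = multipletests(pvals[mask], method="holm")[1]
    return adj
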