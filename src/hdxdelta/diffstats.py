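"""State-vs-state differential deuteration with Welch testing.

For each peptide and exposure shared by two states the pipeline reports

    delta_D = D_state - D_control,      se = sqrt(sd_a^2 + sd_b^2)

(the propagated error is the square root of the sum of the per-state
variances) and evaluates the two-sided Welch t-test — the two-sample t-test
for unequal variances and unequal sample sizes, with Welch–Satterthwaite
degrees of freedom. With the complex state as the first argument, protection
by the binding partner appears as delta_D < 0.

No multiple-testing correction is applied by default (per-peptide raw
p < alpha is the customary HDX criterion); Benjamini–Hochberg is available
via ``correction="bh"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .uptake import DeuterationSummary

__all__ = [
    "DifferentialResult",
    "delta_deuteration",
    "welch_test",
    "compare_states",
]

logger = logging.getLogger("hdxdelta")

MERGE_KEY = ["protein", "start", "end", "sequence", "exposure"]


@dataclass(frozen=True)
class DifferentialResult:
    """delta deuterated fraction between two states for one peptide/exposure."""

    protein: str
    start: int
    end: int
    sequence: str
    exposure: float
    delta_D: float
    se_delta: float
    t_stat: float
    df: float
    p_value: float
    significant: bool
    direction: str  # "protection" (delta_D < 0) or "deprotection"


def delta_deuteration(
    a: DeuterationSummary, b: DeuterationSummary
) -> tuple[float, float]:
    """``(mean_D(a) - mean_D(b), sqrt(sd_a^2 + sd_b^2))`` for one peptide.

    Raises a pairing error unless both summaries refer to the same peptide
    and exposure.
    """
    if not a.same_peptide(b) or a.exposure != b.exposure:
        raise ValueError(
            f"cannot pair {a.protein} {a.start}-{a.end}@{a.exposure}s with "
            f"{b.protein} {b.start}-{b.end}@{b.exposure}s"
        )
    return a.mean_D - b.mean_D, float(np.hypot(a.sd_D, b.sd_D))


def welch_test(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's two-sample t-test from summary statistics (array-aware).

    Returns ``(t, df, p)`` with

        t  = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2)
        df = (v1 + v2)^2 / (v1^2/(n1-1) + v2^2/(n2-1)),  v_i = sd_i^2/n_i

    and the two-sided p-value from Student's t distribution. Degenerate
    inputs with both sample variances zero are resolved by convention:
    equal means give p = 1 (t = 0), different means p = 0 (t = ±inf), with
    the pooled df ``n1 + n2 - 2`` in both cases.
    """
    mean1, sd1 = np.asarray(mean1, float), np.asarray(sd1, float)
    mean2, sd2 = np.asarray(mean2, float), np.asarray(sd2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("both groups need n >= 2")
    if (sd1 < 0).any() or (sd2 < 0).any():
        raise ValueError("standard deviations must be >= 0")

    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    diff = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    degenerate = se == 0
    pooled_df = n1 + n2 - 2
    with np.errstate(invalid="ignore"):
        t = np.where(
            degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t
        )
    df = np.where(degenerate, pooled_df, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    if t.ndim == 0:
        return float(t), float(df), float(p)
    return t, df, p


def compare_states(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_delta: float = 0.0,
    correction: str | None = None,
) -> pd.DataFrame:
    """Peptide-by-peptide differential comparison of two summary tables.

    Parameters
    ----------
    summaries_a, summaries_b:
        Deuteration summary tables (see :func:`hdxdelta.uptake.summarize_table`),
        each restricted to one state; *a* is the state of interest (e.g. the
        complex), *b* the control state, so protection shows as negative
        delta_D.
    alpha:
        Per-peptide significance level, in (0, 1).
    min_abs_delta:
        Additional magnitude threshold on \\|delta_D\\| (default 0: p-value
        only).
    correction:
        ``None`` (default, raw per-peptide p-values) or ``"bh"`` for
        Benjamini–Hochberg FDR across all peptide-exposure pairs.

    Returns
    -------
    DataFrame with one row per shared (peptide, exposure): delta_D, se_delta,
    t_stat, df, p_value, p_adjusted, significant, direction.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if correction not in (None, "none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    merged = summaries_a.merge(
        summaries_b, on=MERGE_KEY, suffixes=("_a", "_b"), how="inner"
    )
    if merged.empty:
        raise ValueError(
            "the two summary sets share no (peptide, exposure) pairs"
        )
    if (merged[["n_a", "n_b"]] == 2).any().any():
        warnings.warn(
            "two-replicate conditions present: Welch degrees of freedom are "
            "very small and the test has little power",
            stacklevel=2,
        )
    t, df, p = welch_test(
        merged["mean_D_a"].to_numpy(),
        merged["sd_D_a"].to_numpy(),
        merged["n_a"].to_numpy(),
        merged["mean_D_b"].to_numpy(),
        merged["sd_D_b"].to_numpy(),
        merged["n_b"].to_numpy(),
    )
    delta = merged["mean_D_a"] - merged["mean_D_b"]
    se = np.hypot(merged["sd_D_a"], merged["sd_D_b"])
    if correction == "bh":
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        p_adj = p
    out = pd.DataFrame(
        {
            "protein": merged["protein"],
            "start": merged["start"],
            "end": merged["end"],
            "sequence": merged["sequence"],
            "exposure": merged["exposure"],
            "state_a": merged["state_a"],
            "state_b": merged["state_b"],
            "delta_D": delta,
            "se_delta": se,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "p_adjusted": p_adj,
        }
    )
    out["significant"] = (out["p_adjusted"] < alpha) & (
        out["delta_D"].abs() >= min_abs_delta
    )
    out["direction"] = np.where(out["delta_D"] < 0, "protection", "deprotection")
    out = out.sort_values(["protein", "start", "end", "exposure"]).reset_index(
        drop=True
    )
    logger.info(
        "compared %d peptide-exposure pairs, %d significant at alpha=%g",
        len(out),
        int(out["significant"].sum()),
        alpha,
    )
    return out
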