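"""Heterogeneity, directionality filtering, confounder exclusion, plot data.

Cochran's Q and the I² index quantify disagreement among per-variant causal
estimates; Steiger filtering removes instruments that explain more variance
in the outcome than in the exposure (a signature of reverse causation); the
confounder filter excludes instruments associated with known fracture risk
factors at a Bonferroni-corrected threshold; and the plot-data exporters
produce the funnel- and scatter-plot tables used to inspect pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult, _ivw_core, extract_arrays

logger = logging.getLogger(__name__)


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class HeterogeneityStats:
    Q: float
    df: int
    p_q: float
    i2: float


@dataclass(frozen=True)
class SteigerRow:
    variant_id: str
    r2_exposure: float
    r2_outcome: float
    keep: bool
    steiger_p: float


def cochran_q(rows) -> HeterogeneityStats:
    """Cochran's Q of the Wald ratios about the fixed-effect IVW estimate."""
    bx, sx, by, sy, _ = extract_arrays(rows)
    if len(bx) < 2:
        raise DiagnosticsError("cochran_q requires >= 2 variants")
    _, _, q, i2 = _ivw_core(bx, by, sy)
    df = len(bx) - 1
    return HeterogeneityStats(Q=q, df=df, p_q=float(stats.chi2.sf(q, df)), i2=i2)


def effective_n(n_cases: float, n_controls: float) -> float:
    """Effective sample size 4/(1/cases + 1/controls) for a binary GWAS."""
    if n_cases <= 0 or n_controls <= 0:
        raise DiagnosticsError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def steiger_filter(
    rows,
    n_exp: float,
    n_out_cases: float | None = None,
    n_out_controls: float | None = None,
    n_out_total: float | None = None,
    binary_outcome: bool = True,
) -> tuple[pd.DataFrame, list[SteigerRow]]:
    """Remove variants more strongly correlated with the outcome than exposure.

    Per-variant variance explained is ``r2 = z^2/(n + z^2)`` on each side;
    for a binary outcome the effective sample size 4/(1/cases+1/controls)
    replaces n (set ``binary_outcome=False`` to use the naive total instead).
    A variant is kept only when ``r2_exposure > r2_outcome`` strictly; ties
    drop.  The per-variant p tests the difference of the implied correlations
    via Fisher's z transform.
    """
    if n_exp <= 0:
        raise DiagnosticsError("n_exp must be positive")
    if binary_outcome:
        if n_out_cases is None or n_out_controls is None:
            raise DiagnosticsError(
                "binary (ln-OR) outcome requires the case/control split for "
                "the Steiger effective sample size")
        n_eff = effective_n(n_out_cases, n_out_controls)
    else:
        if n_out_total is None:
            raise DiagnosticsError("continuous outcome requires n_out_total")
        n_eff = float(n_out_total)

    bx, sx, by, sy, ids = extract_arrays(rows)
    table: list[SteigerRow] = []
    keep_mask = []
    for vid, zx, zy in zip(ids, bx / sx, by / sy):
        r2x = zx * zx / (n_exp + zx * zx)
        r2y = zy * zy / (n_eff + zy * zy)
        rx, ry = np.sqrt(r2x), np.sqrt(r2y)
        denom = np.sqrt(1.0 / max(n_exp - 3.0, 1.0) + 1.0 / max(n_eff - 3.0, 1.0))
        zdiff = (np.arctanh(rx) - np.arctanh(ry)) / denom
        p = float(2 * stats.norm.sf(abs(zdiff)))
        keep = bool(r2x > r2y)
        table.append(SteigerRow(vid, float(r2x), float(r2y), keep, p))
        keep_mask.append(keep)
    df = _as_frame(rows)
    kept = df.loc[np.asarray(keep_mask, bool)].reset_index(drop=True)
    n_drop = len(table) - int(np.sum(keep_mask))
    if n_drop:
        logger.info("steiger_filter: dropped %d of %d variants", n_drop, len(table))
    return kept, table


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows.reset_index(drop=True)
    bx, sx, by, sy, ids = extract_arrays(rows)
    return pd.DataFrame({"SNP": ids, "BETA_EXP": bx, "SE_EXP": sx,
                         "BETA_OUT": by, "SE_OUT": sy})


def steiger_frame(table: list[SteigerRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"SNP": r.variant_id, "R2_EXP": r.r2_exposure, "R2_OUT": r.r2_outcome,
          "KEEP": r.keep, "P_STEIGER": r.steiger_p} for r in table],
        columns=["SNP", "R2_EXP", "R2_OUT", "KEEP", "P_STEIGER"])


def confounder_filter(
    instruments,
    confounder_assoc: pd.DataFrame,
    n_tests: int,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude instruments associated with confounder traits.

    ``confounder_assoc`` has columns SNP, TRAIT, P (BETA/SE optional).  The
    exclusion threshold is ``alpha / n_tests`` — e.g. 0.05/732 ≈ 6.83e-5 when
    correcting over 732 unique exposure variants; a variant is excluded when
    *any* of its confounder associations falls strictly below the threshold.
    Variants absent from the table are kept and logged.

    Returns (kept instruments frame, exclusion log frame with SNP/TRAIT/P).
    """
    if n_tests < 1:
        raise DiagnosticsError("n_tests must be >= 1")
    threshold = alpha / n_tests
    df = _as_frame(instruments)
    snp_col = "SNP" if "SNP" in df.columns else df.columns[0]
    assoc = confounder_assoc
    missing = set(df[snp_col].astype(str)) - set(assoc["SNP"].astype(str))
    if missing:
        logger.info("confounder_filter: %d variants absent from the "
                    "confounder table (kept)", len(missing))
    hits = assoc[assoc["P"].astype(float) < threshold]
    excluded_ids = set(hits["SNP"].astype(str))
    kept = df[~df[snp_col].astype(str).isin(excluded_ids)].reset_index(drop=True)
    log = hits.loc[hits["SNP"].astype(str).isin(set(df[snp_col].astype(str))),
                   [c for c in ("SNP", "TRAIT", "P") if c in hits.columns]]
    log = log.reset_index(drop=True)
    log.attrs["threshold"] = threshold
    return kept, log


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """The corrected per-test significance threshold alpha/n_tests."""
    if n_tests < 1:
        raise DiagnosticsError("n_tests must be >= 1")
    return alpha / n_tests


def export_plot_data(rows, results: list[MRResult] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Funnel- and scatter-plot data tables.

    Funnel: per-variant Wald ratio against its precision |beta_exp|/se_out.
    Scatter: the harmonized effect pairs plus one fitted line per supplied
    method result (slope = estimate; intercept 0 except for Egger, whose
    intercept comes from its extras).
    """
    bx, sx, by, sy, ids = extract_arrays(rows)
    funnel = pd.DataFrame({
        "SNP": ids,
        "WALD_RATIO": by / bx,
        "PRECISION": np.abs(bx) / sy,
    }, columns=["SNP", "WALD_RATIO", "PRECISION"])
    scatter = pd.DataFrame({
        "SNP": ids, "BETA_EXP": bx, "SE_EXP": sx,
        "BETA_OUT": by, "SE_OUT": sy,
    }, columns=["SNP", "BETA_EXP", "SE_EXP", "BETA_OUT", "SE_OUT"])
    lines = []
    for res in results or []:
        intercept = res.extras.get("intercept", 0.0) if res.method == "egger" else 0.0
        lines.append({"METHOD": res.method, "SLOPE": res.estimate,
                      "INTERCEPT": intercept})
    scatter.attrs["lines"] = pd.DataFrame(
        lines, columns=["METHOD", "SLOPE", "INTERCEPT"])
    return funnel, scatter
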