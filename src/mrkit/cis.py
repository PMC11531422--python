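"""Correlated cis-instrument analysis.

Variants within or near the gene encoding a measured protein (cis-SNPs) give
instruments less prone to horizontal pleiotropy, but they typically sit in
linkage disequilibrium with each other, so their Wald ratios are not
independent.  This module provides per-variant Wald-ratio results and a
generalized (correlation-aware) fixed-effect IVW: with outcome-error
covariance ``Omega_ij = se_out_i * se_out_j * rho_ij``,

    theta_hat = (b' Omega^-1 b)^-1 * b' Omega^-1 y,
    SE        = sqrt((b' Omega^-1 b)^-1),

where b and y are the exposure and outcome beta vectors.  With rho = I this
reduces exactly to ordinary fixed-effect IVW.

The named cis instrument set for the SHBG protein — rs6761, rs1799941 and
rs858519, with HapMap proxies rs12150660 (for rs1799941) and rs727428 (for
rs858519) — ships as identifiers only; their effect sizes live in
access-restricted datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult, extract_arrays, wald_ratio, Z95

logger = logging.getLogger(__name__)

#: Cis-SNP ids for SHBG and the HapMap proxies used when an outcome dataset
#: lacks them (identifiers only; no effect sizes are distributed).
SHBG_CIS_SNPS = ("rs6761", "rs1799941", "rs858519")
SHBG_CIS_PROXIES = {"rs1799941": "rs12150660", "rs858519": "rs727428"}

_CONDITION_MAX = 1e8


class LDMatrixError(ValueError):
    pass


@dataclass
class LDMatrix:
    """Signed pairwise correlation (r, not r²) over a named variant set."""

    variant_ids: list[str]
    rho: np.ndarray

    def __post_init__(self):
        self.rho = np.asarray(self.rho, float)
        k = len(self.variant_ids)
        if self.rho.shape != (k, k):
            raise LDMatrixError(
                f"rho shape {self.rho.shape} does not match {k} variant ids")
        if not np.allclose(self.rho, self.rho.T, atol=1e-10):
            raise LDMatrixError("rho is not symmetric within 1e-10")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-10):
            raise LDMatrixError("rho diagonal must be exactly 1")
        eig = np.linalg.eigvalsh(self.rho)
        if eig.min() < -1e-8:
            raise LDMatrixError(
                f"rho is not positive semi-definite (min eigenvalue {eig.min():.3g})")
        if eig.min() < 0:
            # repair tiny numerical negatives by eigenvalue clipping
            logger.warning("LDMatrix: clipping %d slightly negative "
                           "eigenvalues (min %.3g)", (eig < 0).sum(), eig.min())
            vals, vecs = np.linalg.eigh(self.rho)
            vals = np.clip(vals, 0.0, None)
            self.rho = vecs @ np.diag(vals) @ vecs.T
            np.fill_diagonal(self.rho, 1.0)

    def reorder(self, variant_ids: list[str]) -> "LDMatrix":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return LDMatrix(list(variant_ids), self.rho[np.ix_(idx, idx)])

    @classmethod
    def read(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns.astype(str)), df.to_numpy(float))

    def write(self, path) -> None:
        pd.DataFrame(self.rho, index=self.variant_ids,
                     columns=self.variant_ids).to_csv(path, sep="\t")


def cis_wald_table(rows, outcome_scale: str = "sd") -> list[MRResult]:
    """One Wald-ratio MRResult per cis variant, input order preserved."""
    bx, sx, by, sy, ids = extract_arrays(rows)
    results = []
    for vid, b, s, y, t in zip(ids, bx, sx, by, sy):
        est, se = wald_ratio(b, s, y, t)
        res = MRResult(
            method="wald_ratio", n_snp=1, estimate=est, se=se,
            ci_low=est - Z95 * se, ci_high=est + Z95 * se,
            pvalue=float(2 * stats.norm.sf(abs(est / se))),
            extras={"variant_id": vid})
        if outcome_scale == "lnor":
            res.or_estimate = float(np.exp(res.estimate))
            res.or_ci_low = float(np.exp(res.ci_low))
            res.or_ci_high = float(np.exp(res.ci_high))
        results.append(res)
    return results


def correlated_ivw(rows, ld: LDMatrix, outcome_scale: str = "sd",
                   flipped_ids: set[str] | None = None) -> MRResult:
    """Fixed-effect IVW with generalized least squares over correlated variants.

    ``ld`` must cover exactly the (usable) row variants; it is reordered to
    match.  The signs in rho refer to the alleles as originally reported; for
    variants whose harmonization flipped the outcome orientation
    (``flipped_ids``) the corresponding rows/columns of rho are re-signed so
    correlations stay consistent with the harmonized betas.
    """
    bx, sx, by, sy, ids = extract_arrays(rows)
    if len(bx) < 2:
        raise LDMatrixError("correlated_ivw requires >= 2 variants")
    if set(ids) != set(ld.variant_ids):
        raise LDMatrixError(
            f"LD matrix variants {ld.variant_ids} do not match rows {ids}")
    ld = ld.reorder(list(ids))
    rho = ld.rho.copy()
    if flipped_ids:
        sign = np.array([-1.0 if v in flipped_ids else 1.0 for v in ids])
        rho = rho * np.outer(sign, sign)
        np.fill_diagonal(rho, 1.0)

    off = rho[~np.eye(len(ids), dtype=bool)]
    if np.any(np.isclose(np.abs(off), 1.0, atol=1e-12)):
        raise LDMatrixError(
            "a variant pair has |rho| = 1: Omega is singular; prune one of "
            "the pair")
    omega = np.outer(sy, sy) * rho
    cond = np.linalg.cond(omega)
    if cond > _CONDITION_MAX:
        raise LDMatrixError(
            f"Omega condition number {cond:.3g} exceeds {_CONDITION_MAX:.0e}; "
            "prune near-duplicate variants")
    omega_inv = np.linalg.inv(omega)
    btob = float(bx @ omega_inv @ bx)
    theta = float(bx @ omega_inv @ by) / btob
    se = float(np.sqrt(1.0 / btob))
    res = MRResult(
        method="correlated_ivw", n_snp=len(bx), estimate=theta, se=se,
        ci_low=theta - Z95 * se, ci_high=theta + Z95 * se,
        pvalue=float(2 * stats.norm.sf(abs(theta / se))),
        extras={"condition_number": float(cond)})
    if outcome_scale == "lnor":
        res.or_estimate = float(np.exp(theta))
        res.or_ci_low = float(np.exp(res.ci_low))
        res.or_ci_high = float(np.exp(res.ci_high))
    return res
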