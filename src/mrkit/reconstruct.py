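"""Standardized effect reconstruction and instrument-strength summaries.

Many GWAS report only a p-value, an allele frequency and a sample size for
each variant.  For a continuous trait analysed on the standard-deviation
scale, the per-allele effect and its standard error can be recovered from
those three quantities alone: with z the signed normal quantile of the
two-sided p-value and p the effect-allele frequency,

    beta_std = z / sqrt(2 p (1-p) (n + z^2))
    se_std   = 1 / sqrt(2 p (1-p) (n + z^2))

This is the reconstruction used for BMD outcome effects and (via the
beta/se z-score) for re-expressing natural-log-scale hormone effects in SD
units.  The per-variant variance explained follows from the same algebra:

    r2 = (2 beta^2 p(1-p)) / (2 beta^2 p(1-p) + 2 se^2 n p(1-p))
       = beta^2 / (beta^2 + n se^2)                      (the 2p(1-p) cancels)
       = z^2 / (n + z^2)         for any reconstructed (beta_std, se_std).

The simplified form is what the implementation evaluates; the cancellation of
the 2p(1-p) factor makes r2 a function of (z, n) only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Conventional strong-instrument threshold on the per-variant F statistic.
F_STRONG = 10.0

_P_MIN = 1e-300


class ReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class ReconstructedEffect:
    """A per-variant effect re-expressed in SD units of the trait."""

    variant_id: str
    z: float
    beta_std: float
    se_std: float
    r2: float
    f_stat: float


def reconstruct_from_p(
    pvalue: float,
    direction: int,
    eaf: float,
    n: float,
    variant_id: str = "",
) -> ReconstructedEffect:
    """Recover a standardized effect from (p, sign, EAF, N).

    ``direction`` is the sign of the reported effect (+1 or -1); ``eaf`` the
    effect-allele frequency; ``n`` the association sample size.  p-values at
    or below 1e-300 are refused outright — choose and apply an explicit
    minimum-p convention upstream rather than relying on silent clipping.
    """
    if not 0 < pvalue <= 1:
        if pvalue == 0:
            raise ReconstructionError(
                "p-value of exactly 0: cap p at an explicit minimum "
                "(e.g. 1e-300) before reconstruction; no silent capping is done")
        raise ReconstructionError(f"p-value {pvalue} outside (0, 1]")
    if pvalue < _P_MIN:
        raise ReconstructionError(
            f"p-value {pvalue} below {_P_MIN}: apply an explicit minimum-p "
            "convention upstream")
    if direction not in (1, -1):
        raise ReconstructionError(f"direction must be +1 or -1, got {direction}")
    if not 0 < eaf < 1:
        raise ReconstructionError(f"EAF {eaf} outside (0,1)")
    if n < 2:
        raise ReconstructionError(f"sample size {n} < 2")
    z = float(direction) * float(stats.norm.isf(pvalue / 2.0))
    return _from_z(z, eaf, n, variant_id)


def standardize_log_effect(
    beta_ln: float,
    se_ln: float,
    eaf: float,
    n: float,
    variant_id: str = "",
) -> ReconstructedEffect:
    """Re-express a natural-log-scale effect in SD units.

    Only the z-score ``beta_ln/se_ln`` carries through; the log-scale
    magnitude is discarded, so the result is invariant to rescaling beta and
    SE by a common positive factor.
    """
    if not se_ln > 0:
        raise ReconstructionError(f"SE {se_ln} must be > 0")
    z = beta_ln / se_ln
    return _from_z(z, eaf, n, variant_id)


def _from_z(z: float, eaf: float, n: float, variant_id: str) -> ReconstructedEffect:
    denom = np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z * z))
    beta_std = z / denom
    se_std = 1.0 / denom
    r2 = variance_explained(beta_std, se_std, eaf, n)
    return ReconstructedEffect(
        variant_id=variant_id, z=float(z), beta_std=float(beta_std),
        se_std=float(se_std), r2=float(r2), f_stat=float(z * z))


def variance_explained(beta_std: float, se_std: float, eaf: float, n: float) -> float:
    """Per-variant fraction of trait variance explained.

    Evaluates the simplified form beta^2/(beta^2 + n se^2); the 2p(1-p)
    factors of the full expression cancel exactly (see module docstring), so
    ``eaf`` does not enter the value and is accepted only for interface
    symmetry with the full formula.
    """
    if not se_std > 0:
        raise ReconstructionError(f"SE {se_std} must be > 0")
    b2 = beta_std * beta_std
    return b2 / (b2 + n * se_std * se_std)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F via the t-statistic approximation, (beta/se)^2."""
    if not se > 0:
        raise ReconstructionError(f"SE {se} must be > 0")
    return (beta / se) ** 2


def total_variance_explained(effects: Iterable[ReconstructedEffect]) -> float:
    """Summed r2 over independent (pre-pruned) instruments."""
    total = float(sum(e.r2 for e in effects))
    if total >= 0.5:
        logger.warning(
            "total variance explained %.3f >= 0.5: instruments are unlikely "
            "to be independent", total)
    return total


def strong_instruments(effects: Iterable[ReconstructedEffect],
                       f_min: float = F_STRONG) -> list[ReconstructedEffect]:
    """Subset with F above the conventional strong-instrument threshold."""
    return [e for e in effects if e.f_stat > f_min]
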