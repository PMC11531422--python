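"""Cross-cohort meta-analysis, cohort bookkeeping and MR power calculations.

Per-variant outcome associations estimated separately in several case–control
cohorts are combined by fixed-effect inverse-variance meta-analysis before
entering the MR estimators.  Power for a binary-outcome MR follows the mRnd
approach: with case fraction K, causal odds ratio OR, instrument variance
explained R² and total sample size N, the approximate risk difference per SD

    b = K * (OR / (1 + K*(OR - 1)) - 1)

has sampling variance v = (K(1-K) - b²)/(N R²), giving a non-centrality
parameter NCP = b²/v for a 1-df chi-square test; power is the upper-tail
probability of the non-central chi-square beyond the central (1-alpha)
quantile.  A documented alternative uses the log-OR scale directly:
NCP = (ln OR)² * N * R² * K(1-K).  The detectable-OR solver inverts either
formula by bisection on ln OR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sumstats import InstrumentSet, SummaryRecord, harmonize

logger = logging.getLogger(__name__)


class PowerError(ValueError):
    pass


class CohortError(ValueError):
    pass


@dataclass
class PowerSpec:
    """Design parameters of a binary-outcome MR power calculation."""

    n_total: int
    n_cases: int
    r2: float
    alpha: float = 0.05
    or_alt: float | None = None

    def __post_init__(self):
        if not 0 < self.n_cases < self.n_total:
            raise PowerError("need 0 < n_cases < n_total")
        if not 0 < self.r2 < 1:
            raise PowerError(f"r2 {self.r2} outside (0,1)")
        if not 0 < self.alpha < 1:
            raise PowerError(f"alpha {self.alpha} outside (0,1)")
        if self.or_alt is not None and self.or_alt <= 0:
            raise PowerError("or_alt must be > 0")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def power_binary(spec: PowerSpec, or_alt: float | None = None,
                 formula: str = "risk_difference") -> float:
    """Power to detect the alternative odds ratio at significance alpha.

    ``formula='risk_difference'`` is the mRnd form (module docstring);
    ``formula='log_or'`` is the documented log-scale alternative.  Both are
    continuous in OR and return exactly alpha at OR = 1.
    """
    orx = or_alt if or_alt is not None else spec.or_alt
    if orx is None or orx <= 0:
        raise PowerError("power_binary needs a positive alternative OR")
    k = spec.case_fraction
    if formula == "risk_difference":
        b = k * (orx / (1.0 + k * (orx - 1.0)) - 1.0)
        v = (k * (1.0 - k) - b * b) / (spec.n_total * spec.r2)
        ncp = b * b / v
    elif formula == "log_or":
        ncp = (np.log(orx) ** 2) * spec.n_total * spec.r2 * k * (1.0 - k)
    else:
        raise PowerError(f"unknown power formula {formula!r}")
    crit = stats.chi2.ppf(1.0 - spec.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def detectable_or(spec: PowerSpec, target_power: float = 0.80,
                  direction: str = "protective",
                  formula: str = "risk_difference",
                  tol: float = 1e-8) -> float:
    """Odds ratio detectable at ``target_power``, by bisection on ln OR.

    ``direction='harmful'`` searches OR > 1, ``'protective'`` OR < 1; the
    search bracket is ln OR in (0, 5] or [-5, 0).  The returned OR satisfies
    ``power_binary(OR) = target_power`` within ``tol``.
    """
    if not 0 < target_power < 1:
        raise PowerError(f"target power {target_power} outside (0,1)")
    if direction not in ("harmful", "protective"):
        raise PowerError(f"direction must be harmful or protective, got {direction!r}")
    sign = 1.0 if direction == "harmful" else -1.0

    def gap(log_or: float) -> float:
        return power_binary(spec, float(np.exp(log_or)), formula) - target_power

    lo, hi = sign * 1e-9, sign * 5.0
    # the risk-difference variance K(1-K) - b^2 can turn negative at extreme
    # ORs; pull the far bracket end back inside the formula's valid domain
    for _ in range(200):
        if np.isfinite(gap(hi)):
            break
        hi *= 0.95
    else:
        raise PowerError("no valid bracket for the power formula")
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise PowerError(
            f"target power {target_power} unreachable for OR in "
            f"[e^-5, e^5] ({direction}); power at bracket ends: "
            f"{g_lo + target_power:.4f}, {g_hi + target_power:.4f}")
    root = optimize.brentq(gap, lo, hi, xtol=tol * 1e-2, rtol=8.9e-16)
    # polish until the power gap itself is inside tolerance
    if abs(gap(root)) > tol:
        root = optimize.brentq(gap, root - 1e-6, root + 1e-6, xtol=1e-15)
    return float(np.exp(root))


# ---------------------------------------------------------------------------
# cohort bookkeeping


@dataclass
class CohortTable:
    """Per-cohort case/control counts with validation n = cases + controls."""

    frame: pd.DataFrame  # COHORT, CASES, CONTROLS, TOTAL, MEDIAN_AGE

    def __post_init__(self):
        f = self.frame
        bad = f[f["CASES"] + f["CONTROLS"] != f["TOTAL"]]
        if len(bad):
            raise CohortError(
                f"cohort rows where cases+controls != total: "
                f"{bad['COHORT'].tolist()}")

    def totals(self, include: Sequence[str]) -> tuple[int, int, int]:
        """(total_n, total_cases, total_controls) over the included cohorts."""
        if not include:
            raise CohortError("include must name at least one cohort")
        known = set(self.frame["COHORT"])
        unknown = [c for c in include if c not in known]
        if unknown:
            raise CohortError(f"unknown cohort name(s) {unknown}; known: "
                              f"{sorted(known)}")
        sub = self.frame[self.frame["COHORT"].isin(set(include))]
        return (int(sub["TOTAL"].sum()), int(sub["CASES"].sum()),
                int(sub["CONTROLS"].sum()))

    @classmethod
    def read(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t"))


#: Forearm-fracture cohort composition: cases, controls, totals and the
#: median age at fracture in each contributing biobank.
FRACTURE_COHORTS_TSV = """\
COHORT\tCASES\tCONTROLS\tTOTAL\tMEDIAN_AGE
UKBB\t11564\t226008\t237572\t60.5
UFO\t850\t856\t1706\t61.4
HUNT\t4447\t31581\t36028\t64
EstBB\t3526\t70091\t73617\t58
"""

#: The three cohorts forming the non-overlapping two-sample outcome set.
TWO_SAMPLE_COHORTS = ("EstBB", "HUNT", "UFO")


def fracture_cohort_table() -> CohortTable:
    """The packaged forearm-fracture cohort composition table."""
    return CohortTable(pd.read_csv(StringIO(FRACTURE_COHORTS_TSV), sep="\t"))


def cohort_totals(table: CohortTable, include: Sequence[str]) -> tuple[int, int, int]:
    """Functional wrapper over :meth:`CohortTable.totals`."""
    return table.totals(include)


# ---------------------------------------------------------------------------
# fixed-effect meta-analysis


@dataclass
class CohortAssoc:
    """One cohort's per-variant outcome associations on the ln-OR scale."""

    cohort_name: str
    instruments: InstrumentSet

    def __post_init__(self):
        if self.instruments.records and self.instruments.trait_scale != "lnor":
            raise CohortError(
                f"{self.cohort_name}: cohort associations must be ln-OR scale")
        for r in self.instruments:
            if r.n_cases is not None and r.n_cases >= r.n_total:
                raise CohortError(f"{self.cohort_name}/{r.variant_id}: "
                                  "n_cases >= n_total")


def meta_fixed(assocs: Sequence[CohortAssoc],
               reference: str | None = None) -> CohortAssoc:
    """Combine cohorts per variant by fixed-effect inverse-variance weighting.

    Alleles are first harmonized to the reference cohort's orientation
    (default: the first cohort) using the same rules as exposure/outcome
    harmonization; a variant whose alleles cannot be reconciled is dropped
    with a log entry.  Variants present in a single cohort are carried
    through unchanged and flagged.  Combined sample and case counts are the
    sums over contributing cohorts.
    """
    if len(assocs) < 2:
        raise CohortError("meta_fixed requires >= 2 cohorts")
    names = [a.cohort_name for a in assocs]
    ref = assocs[0] if reference is None else next(
        a for a in assocs if a.cohort_name == reference)

    # per variant: list of aligned (beta, se, n, ncase, eaf)
    per_variant: dict[str, list[tuple]] = {}
    meta_template: dict[str, SummaryRecord] = {}
    for a in assocs:
        if a is ref:
            aligned = {r.variant_id: r for r in a.instruments}
        else:
            rows = harmonize(ref.instruments, a.instruments)
            aligned = {}
            for row in rows:
                if not row.usable:
                    if row.action == "dropped_ambiguous":
                        logger.info("meta_fixed: %s ambiguous in %s, skipped "
                                    "for that cohort", row.variant_id,
                                    a.cohort_name)
                    continue
                src = a.instruments.get(row.variant_id)
                aligned[row.variant_id] = SummaryRecord(
                    variant_id=row.variant_id,
                    effect_allele=row.effect_allele,
                    other_allele=_other_allele(ref, row.variant_id),
                    eaf=row.eaf_out, beta=row.beta_out, se=row.se_out,
                    pvalue=src.pvalue if src else 1.0,
                    n_total=src.n_total if src else 0,
                    n_cases=src.n_cases if src else None,
                    trait_scale="lnor")
            # variants in this cohort but not in the reference: extend the key set
            ref_ids = {r.variant_id for r in ref.instruments}
            for r in a.instruments:
                if r.variant_id not in ref_ids:
                    aligned.setdefault(r.variant_id, r)
        for vid, rec in aligned.items():
            per_variant.setdefault(vid, []).append(rec)
            meta_template.setdefault(vid, rec)

    combined: list[SummaryRecord] = []
    n_single = 0
    for vid, recs in per_variant.items():
        if len(recs) == 1:
            n_single += 1
            combined.append(recs[0])
            continue
        w = np.array([1.0 / (r.se ** 2) for r in recs])
        betas = np.array([r.beta for r in recs])
        beta = float((w * betas).sum() / w.sum())
        se = float(1.0 / np.sqrt(w.sum()))
        p = float(2 * stats.norm.sf(abs(beta / se)))
        n_total = int(sum(r.n_total for r in recs))
        n_cases_vals = [r.n_cases for r in recs if r.n_cases is not None]
        eafs = np.array([r.eaf for r in recs])
        ns = np.array([r.n_total for r in recs], float)
        tmpl = meta_template[vid]
        combined.append(SummaryRecord(
            variant_id=vid, effect_allele=tmpl.effect_allele,
            other_allele=tmpl.other_allele,
            eaf=float((eafs * ns).sum() / ns.sum()),
            beta=beta, se=se, pvalue=max(p, 1e-300), n_total=n_total,
            n_cases=int(sum(n_cases_vals)) if n_cases_vals else None,
            trait_scale="lnor"))
    if n_single:
        logger.info("meta_fixed: %d variants present in a single cohort "
                    "carried through unchanged", n_single)
    name = "meta(" + "+".join(names) + ")"
    return CohortAssoc(cohort_name=name, instruments=InstrumentSet(
        trait_name=name, records=combined,
        selection_meta={"meta": "fixed-effect IVW", "cohorts": names,
                        "single_cohort_variants": n_single}))


def _other_allele(ref: CohortAssoc, variant_id: str) -> str:
    rec = ref.instruments.get(variant_id)
    return rec.other_allele if rec else "N"
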