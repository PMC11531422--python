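"""GWAS summary-statistic data model, I/O, instrument selection and harmonization.

Summary statistics are the per-variant association results of a genome-wide
association study: an effect allele, an effect size per copy of that allele,
its standard error, the effect-allele frequency (EAF), a p-value and a sample
size.  Two-sample Mendelian randomization consumes two such tables — one for
the exposure (here a circulating hormone measured in SD units) and one for the
outcome (a binary fracture phenotype on the log-odds scale, or a continuous
BMD phenotype in SD units) — and requires that both are expressed with respect
to the *same* effect allele for every variant.  Aligning them is called
harmonization; the rules implemented here are the standard ones: direct
allele match, allele swap (sign flip), strand flip (reverse complement), and
allele-frequency-based inference for palindromic (A/T, C/G) variants whose
strand cannot be resolved from the alleles alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_NUCLEOTIDES = frozenset("ACGT")
#: Allele pairs that are their own reverse complement; strand is ambiguous.
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column names of the summary-statistics TSV dialect.
REQUIRED_COLUMNS = ("SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N")
OPTIONAL_COLUMNS = ("NCASE", "INFO", "CHR", "POS")

#: Fixed column order of the harmonized TSV.
HARMONIZED_COLUMNS = (
    "SNP", "EA", "BETA_EXP", "SE_EXP", "BETA_OUT", "SE_OUT",
    "EAF_EXP", "EAF_OUT", "PALINDROMIC", "ACTION", "PROXY_OF",
)

#: Harmonization outcomes.  dropped_* rows carry no usable outcome estimate.
ACTIONS = (
    "kept", "sign_flipped", "strand_flipped",
    "dropped_ambiguous", "dropped_missing", "proxied",
)


class SumstatsError(ValueError):
    """Fatal configuration or content error in a summary-statistics input."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n_total: int
    n_cases: int | None = None
    trait_scale: str = "sd"  # one of {"sd", "ln", "lnor"}
    info: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_NUCLEOTIDES:
            raise SumstatsError(f"{self.variant_id}: invalid effect allele "
                                f"{self.effect_allele!r} (biallelic SNPs only)")
        if self.other_allele not in VALID_NUCLEOTIDES:
            raise SumstatsError(f"{self.variant_id}: invalid other allele "
                                f"{self.other_allele!r} (biallelic SNPs only)")
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.variant_id}: identical alleles")
        if not 0.0 < self.eaf < 1.0:
            raise SumstatsError(f"{self.variant_id}: EAF {self.eaf} outside (0,1)")
        if not self.se > 0:
            raise SumstatsError(f"{self.variant_id}: SE {self.se} must be > 0")
        if not 0.0 < self.pvalue <= 1.0:
            raise SumstatsError(f"{self.variant_id}: p {self.pvalue} outside (0,1]")
        if self.n_total < 1:
            raise SumstatsError(f"{self.variant_id}: non-positive N")
        if self.trait_scale not in ("sd", "ln", "lnor"):
            raise SumstatsError(f"unknown trait scale {self.trait_scale!r}")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS

    def check_p_beta_consistency(self, rtol: float = 0.10) -> bool:
        """True when |beta/se| agrees with the normal quantile of p within rtol.

        A mismatch usually indicates a units problem or a truncated p-value
        column; the loader warns but keeps the row.
        """
        z_from_p = float(stats.norm.isf(self.pvalue / 2.0))
        z_obs = abs(self.beta / self.se)
        if z_from_p == 0.0:
            return z_obs < 1e-8
        return abs(z_obs - z_from_p) <= rtol * z_from_p


@dataclass
class InstrumentSet:
    """An ordered, uniquely-keyed collection of instruments for one trait."""

    trait_name: str
    records: list[SummaryRecord]
    selection_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SumstatsError(
                f"{self.trait_name}: duplicated variant ids {dupes[:5]}")
        scales = {r.trait_scale for r in self.records}
        if len(scales) > 1:
            raise SumstatsError(f"{self.trait_name}: mixed trait scales {scales}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def trait_scale(self) -> str:
        return self.records[0].trait_scale if self.records else "sd"

    def get(self, variant_id: str) -> SummaryRecord | None:
        for r in self.records:
            if r.variant_id == variant_id:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.variant_id, "EA": r.effect_allele, "OA": r.other_allele,
                "EAF": r.eaf, "BETA": r.beta, "SE": r.se, "P": r.pvalue,
                "N": r.n_total, "NCASE": r.n_cases, "INFO": r.info,
            }
            for r in self.records
        ]
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["NCASE", "INFO"])
        return df


@dataclass(frozen=True)
class HarmonizedRow:
    """An exposure/outcome pair aligned to the exposure's effect allele."""

    variant_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float | None
    se_out: float | None
    eaf_exp: float
    eaf_out: float | None
    palindromic: bool
    action: str
    proxy_of: str | None = None

    @property
    def usable(self) -> bool:
        return not self.action.startswith("dropped")


@dataclass
class ProxyMap:
    """Substitutes for instruments missing from an outcome dataset.

    Maps a missing variant id to a proxy variant in high LD with it; proxies
    are trusted as supplied (no reference-panel validation is attempted).
    """

    mapping: dict[str, str]
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target, proxy in self.mapping.items():
            if target == proxy:
                raise SumstatsError(f"proxy map: {target} maps to itself")
        if set(self.mapping) & set(self.mapping.values()):
            bad = sorted(set(self.mapping) & set(self.mapping.values()))
            raise SumstatsError(f"proxy ids overlap target ids: {bad[:5]}")

    def get(self, variant_id: str) -> str | None:
        return self.mapping.get(variant_id)

    @classmethod
    def read(cls, path) -> "ProxyMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("TARGET", "PROXY"):
            if col not in df.columns:
                raise SumstatsError(f"proxy file missing column {col}")
        notes = {}
        if "NOTE" in df.columns:
            notes = dict(zip(df["TARGET"], df["NOTE"].fillna("")))
        return cls(mapping=dict(zip(df["TARGET"], df["PROXY"])), notes=notes)


# ---------------------------------------------------------------------------
# readers / writers


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_scale: str = "sd",
) -> InstrumentSet:
    """Read a tab-delimited summary-statistics file into an :class:`InstrumentSet`.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    dialect
        Mapping from canonical column names (``SNP``, ``EA``, ...) to the
        column names actually present in the file.  Omitted entries default
        to the canonical names; column order in the file is irrelevant.
    trait_name, trait_scale
        Attached to the returned set; ``trait_scale`` is one of ``sd``,
        ``ln``, ``lnor``.

    Rows violating a per-record invariant (bad allele, EAF outside (0,1),
    non-positive SE, ...) are dropped with a logged count, not raised.
    """
    dialect = dict(dialect or {})
    colmap = {canon: dialect.get(canon, canon)
              for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        raise SumstatsError(f"{path}: empty summary-statistics file")
    for canon in REQUIRED_COLUMNS:
        if colmap[canon] not in df.columns:
            raise SumstatsError(
                f"{path}: missing required column {colmap[canon]!r} "
                f"(canonical {canon})")
    has_ncase = colmap["NCASE"] in df.columns
    has_info = colmap["INFO"] in df.columns

    records: list[SummaryRecord] = []
    n_dropped = 0
    n_inconsistent = 0
    for _, row in df.iterrows():
        try:
            ncase = row[colmap["NCASE"]] if has_ncase else None
            info = row[colmap["INFO"]] if has_info else None
            rec = SummaryRecord(
                variant_id=str(row[colmap["SNP"]]),
                effect_allele=str(row[colmap["EA"]]).upper(),
                other_allele=str(row[colmap["OA"]]).upper(),
                eaf=float(row[colmap["EAF"]]),
                beta=float(row[colmap["BETA"]]),
                se=float(row[colmap["SE"]]),
                pvalue=float(row[colmap["P"]]),
                n_total=int(row[colmap["N"]]),
                n_cases=None if ncase is None or pd.isna(ncase) else int(ncase),
                trait_scale=trait_scale,
                info=None if info is None or pd.isna(info) else float(info),
            )
            rec.validate()
        except (SumstatsError, ValueError, TypeError):
            n_dropped += 1
            continue
        if not rec.check_p_beta_consistency():
            n_inconsistent += 1
        records.append(rec)
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows of %d", path, n_dropped, len(df))
    if n_inconsistent:
        logger.warning("%s: %d rows with |beta/se| inconsistent with P beyond "
                       "10%% relative tolerance (kept)", path, n_inconsistent)
    return InstrumentSet(trait_name=trait_name, records=records)


def write_sumstats(instruments: InstrumentSet, path) -> None:
    """Write an instrument set back to the canonical TSV dialect."""
    df = instruments.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def select_instruments(
    instruments: InstrumentSet,
    p_max: float = 5e-8,
    maf_min: float = 0.001,
    info_min: float | None = None,
) -> InstrumentSet:
    """Apply genome-wide-significance, MAF and imputation-quality filters.

    Keeps records with ``pvalue < p_max`` (strict), minor allele frequency
    ``min(eaf, 1-eaf) > maf_min`` (strict), and — when both an info threshold
    and a per-record info score are available — ``info > info_min``.
    Independence pruning is *not* recomputed: inputs are assumed to be
    pre-pruned published instrument lists (pairwise r² < 0.05).
    """
    for thr, name in ((p_max, "p_max"), (maf_min, "maf_min")):
        if not 0.0 < thr < 1.0:
            raise SumstatsError(f"{name}={thr} outside (0,1)")
    kept = []
    for rec in instruments:
        if not rec.pvalue < p_max:
            continue
        if not min(rec.eaf, 1.0 - rec.eaf) > maf_min:
            continue
        if info_min is not None and rec.info is not None and not rec.info > info_min:
            continue
        kept.append(rec)
    if not kept:
        logger.warning("%s: no instruments survive selection", instruments.trait_name)
    meta = dict(instruments.selection_meta)
    meta.update({"p_max": p_max, "maf_min": maf_min, "info_min": info_min,
                 "independence_r2": "assumed pre-pruned (<0.05)"})
    return InstrumentSet(trait_name=instruments.trait_name, records=kept,
                         selection_meta=meta)


# ---------------------------------------------------------------------------
# harmonization


def _complemented(rec: SummaryRecord) -> SummaryRecord:
    return replace(rec,
                   effect_allele=COMPLEMENT[rec.effect_allele],
                   other_allele=COMPLEMENT[rec.other_allele])


def _flipped(rec: SummaryRecord) -> SummaryRecord:
    """Swap effect/other allele, negating beta and reflecting EAF."""
    return replace(rec,
                   effect_allele=rec.other_allele,
                   other_allele=rec.effect_allele,
                   beta=-rec.beta,
                   eaf=1.0 - rec.eaf)


def harmonize(
    exposure: InstrumentSet,
    outcome: InstrumentSet,
    proxies: ProxyMap | None = None,
    palindrome_window: float = 0.08,
) -> list[HarmonizedRow]:
    """Align outcome associations to the exposure's effect alleles.

    Every exposure instrument yields exactly one row whose ``action`` records
    what happened:

    * ``kept`` — alleles already matched (including a palindromic variant
      whose frequencies agreed on orientation);
    * ``sign_flipped`` — outcome alleles were swapped relative to the
      exposure, or a palindromic variant's frequencies sat on opposite sides
      of 0.5; the outcome beta is negated and its EAF reflected;
    * ``strand_flipped`` — a non-palindromic reverse-complement mismatch,
      resolved by complementing the outcome alleles first;
    * ``dropped_ambiguous`` — palindromic with either EAF within
      ``palindrome_window`` of 0.5 (default window 0.42–0.58), where
      frequency cannot resolve the strand;
    * ``proxied`` — variant absent from the outcome but a proxy from
      ``proxies`` was present; the proxy's outcome association is used;
    * ``dropped_missing`` — absent from the outcome with no usable proxy, or
      an allele mismatch no rule resolves.
    """
    out_index = {r.variant_id: r for r in outcome}
    # duplicate detection is enforced by InstrumentSet construction
    rows: list[HarmonizedRow] = []
    for exp in exposure:
        rec = out_index.get(exp.variant_id)
        proxy_of = None
        action_prefix = None
        if rec is None and proxies is not None:
            proxy_id = proxies.get(exp.variant_id)
            if proxy_id is not None and proxy_id in out_index:
                # The proxy's own alleles stand in for the target's; the
                # orientation rules below are applied to the proxy record.
                rec = out_index[proxy_id]
                proxy_of = exp.variant_id
                action_prefix = "proxied"
        if rec is None:
            rows.append(_dropped_row(exp, "dropped_missing"))
            continue
        row = _orient(exp, rec, palindrome_window, proxy_of, action_prefix)
        rows.append(row)
    return rows


def _dropped_row(exp: SummaryRecord, action: str) -> HarmonizedRow:
    return HarmonizedRow(
        variant_id=exp.variant_id, effect_allele=exp.effect_allele,
        beta_exp=exp.beta, se_exp=exp.se, beta_out=None, se_out=None,
        eaf_exp=exp.eaf, eaf_out=None, palindromic=exp.is_palindromic,
        action=action)


def _orient(
    exp: SummaryRecord,
    out: SummaryRecord,
    window: float,
    proxy_of: str | None,
    action_prefix: str | None,
) -> HarmonizedRow:
    exp_alleles = (exp.effect_allele, exp.other_allele)
    action: str | None = None

    if exp.is_palindromic and proxy_of is None:
        if frozenset(exp_alleles) != frozenset((out.effect_allele, out.other_allele)):
            return _dropped_row(exp, "dropped_missing")
        near_half = (abs(exp.eaf - 0.5) < window) or (abs(out.eaf - 0.5) < window)
        if near_half:
            return _dropped_row(exp, "dropped_ambiguous")
        same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
        # Align the outcome record label-wise to the exposure effect allele
        # first; frequency then decides whether that alignment is the true
        # orientation or its strand-flipped mirror.
        if (out.effect_allele, out.other_allele) != exp_alleles:
            out = _flipped(out)
        if same_side:
            action = "kept"
        else:
            out = _flipped(out)
            action = "sign_flipped"
    else:
        if (out.effect_allele, out.other_allele) == exp_alleles:
            action = "kept"
        elif (out.other_allele, out.effect_allele) == exp_alleles:
            out = _flipped(out)
            action = "sign_flipped"
        else:
            comp = _complemented(out)
            if (comp.effect_allele, comp.other_allele) == exp_alleles:
                out = comp
                action = "strand_flipped"
            elif (comp.other_allele, comp.effect_allele) == exp_alleles:
                out = _flipped(comp)
                action = "strand_flipped"
            else:
                return _dropped_row(exp, "dropped_missing")

    if action_prefix == "proxied":
        action = "proxied"
    return HarmonizedRow(
        variant_id=exp.variant_id, effect_allele=exp.effect_allele,
        beta_exp=exp.beta, se_exp=exp.se,
        beta_out=out.beta, se_out=out.se,
        eaf_exp=exp.eaf, eaf_out=out.eaf,
        palindromic=exp.is_palindromic, action=action, proxy_of=proxy_of)


def harmonized_frame(rows: Iterable[HarmonizedRow]) -> pd.DataFrame:
    """Harmonized rows as a DataFrame in the documented column order."""
    recs = [
        {
            "SNP": r.variant_id, "EA": r.effect_allele,
            "BETA_EXP": r.beta_exp, "SE_EXP": r.se_exp,
            "BETA_OUT": r.beta_out, "SE_OUT": r.se_out,
            "EAF_EXP": r.eaf_exp, "EAF_OUT": r.eaf_out,
            "PALINDROMIC": r.palindromic, "ACTION": r.action,
            "PROXY_OF": r.proxy_of,
        }
        for r in rows
    ]
    return pd.DataFrame(recs, columns=list(HARMONIZED_COLUMNS))


def usable_frame(rows: Iterable[HarmonizedRow]) -> pd.DataFrame:
    """Frame of rows usable by the estimators (dropped_* excluded)."""
    df = harmonized_frame(r for r in rows if r.usable)
    return df.reset_index(drop=True)


def write_harmonized(rows: Iterable[HarmonizedRow], path) -> None:
    """Write harmonized rows as TSV; dropped rows keep empty outcome fields."""
    df = harmonized_frame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_harmonized(path) -> list[HarmonizedRow]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in HARMONIZED_COLUMNS:
        if col not in df.columns:
            raise SumstatsError(f"{path}: missing harmonized column {col}")
    rows = []
    for _, r in df.iterrows():
        rows.append(HarmonizedRow(
            variant_id=str(r["SNP"]), effect_allele=str(r["EA"]),
            beta_exp=float(r["BETA_EXP"]), se_exp=float(r["SE_EXP"]),
            beta_out=None if pd.isna(r["BETA_OUT"]) else float(r["BETA_OUT"]),
            se_out=None if pd.isna(r["SE_OUT"]) else float(r["SE_OUT"]),
            eaf_exp=float(r["EAF_EXP"]),
            eaf_out=None if pd.isna(r["EAF_OUT"]) else float(r["EAF_OUT"]),
            palindromic=bool(r["PALINDROMIC"]),
            action=str(r["ACTION"]),
            proxy_of=None if pd.isna(r["PROXY_OF"]) else str(r["PROXY_OF"]),
        ))
    return rows


def action_counts(rows: Iterable[HarmonizedRow]) -> dict[str, int]:
    counts = {a: 0 for a in ACTIONS}
    for r in rows:
        counts[r.action] = counts.get(r.action, 0) + 1
    return counts
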