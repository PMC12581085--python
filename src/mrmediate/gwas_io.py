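"""Reading, validating, harmonising and instrument-selecting GWAS summary statistics.

A trait's association results live in a :class:`SummaryStats`: a pandas frame
with one row per variant plus trait metadata (name, unit, ancestry). All
estimators downstream consume a :class:`HarmonisedSet`, the per-SNP table of
exposure/outcome effect pairs aligned to a common effect allele.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import FormatError, InputError

logger = logging.getLogger(__name__)

#: Canonical internal column names -> default file header names.
DEFAULT_DIALECT = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

#: Columns that must be present in every summary-statistics file.
MANDATORY = ("variant_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "pvalue")

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Harmonisation provenance codes.
FLAG_UNCHANGED = "unchanged"
FLAG_FLIPPED = "allele_flipped"
FLAG_DROPPED_PALINDROMIC = "dropped_palindromic"
FLAG_DROPPED_MISSING = "dropped_missing"
FLAG_DROPPED_INCOMPATIBLE = "dropped_incompatible"


@dataclass
class LoadReport:
    """Row-level accounting for one summary-statistics load."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    reasons: Counter = field(default_factory=Counter)


@dataclass
class SummaryStats:
    """One trait's per-variant GWAS associations plus metadata.

    ``table`` uses the canonical columns of :data:`DEFAULT_DIALECT` keys;
    ``variant_id`` values are unique. ``n_case``/``n_control`` columns are
    present for binary (log-OR) traits.
    """

    trait_name: str
    table: pd.DataFrame
    unit: str = "SD"
    ancestry: str = "European"
    load_report: LoadReport | None = None

    def __post_init__(self):
        if self.table["variant_id"].duplicated().any():
            dup = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise InputError(f"duplicate variant_id {dup!r} in trait {self.trait_name!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> pd.DataFrame:
        return self.table

    def subset(self, variant_ids) -> "SummaryStats":
        keep = self.table["variant_id"].isin(set(variant_ids))
        return SummaryStats(self.trait_name, self.table.loc[keep].reset_index(drop=True),
                            unit=self.unit, ancestry=self.ancestry)

    def exclude(self, variant_ids) -> "SummaryStats":
        keep = ~self.table["variant_id"].isin(set(variant_ids))
        return SummaryStats(self.trait_name, self.table.loc[keep].reset_index(drop=True),
                            unit=self.unit, ancestry=self.ancestry)

    def significant_ids(self, p_threshold: float = 5e-8) -> list[str]:
        t = self.table
        return list(t.loc[t["pvalue"] < p_threshold, "variant_id"])

    def to_tsv(self, path, dialect: dict | None = None) -> None:
        dialect = {**DEFAULT_DIALECT, **(dialect or {})}
        out = self.table.rename(columns=dialect)
        out.to_csv(path, sep="\t", index=False)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    """Apply per-variant invariants; drop and count offending rows."""
    report = LoadReport(n_read=len(df))
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    checks = {
        "non_positive_se": ~(df["se"] > 0),
        "invalid_allele": ~(df["effect_allele"].isin(_VALID_ALLELES)
                            & df["other_allele"].isin(_VALID_ALLELES)),
        "identical_alleles": df["effect_allele"] == df["other_allele"],
        "pvalue_out_of_range": ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        "position_below_one": ~(df["pos"] >= 1),
        "non_finite_beta": ~np.isfinite(df["beta"]),
    }
    if "eaf" in df.columns:
        eaf = df["eaf"]
        checks["eaf_out_of_range"] = eaf.notna() & ~((eaf > 0) & (eaf < 1))

    bad = pd.Series(False, index=df.index)
    for reason, mask in checks.items():
        mask = mask.fillna(True) if mask.dtype == object else mask
        fresh = mask & ~bad
        if fresh.any():
            report.reasons[reason] += int(fresh.sum())
        bad |= mask
    kept = df.loc[~bad].reset_index(drop=True)
    report.n_kept = len(kept)
    report.n_dropped = report.n_read - report.n_kept
    return kept, report


def read_summary_stats(path, dialect: dict | None = None, *, trait_name: str | None = None,
                       unit: str = "SD", ancestry: str = "European") -> SummaryStats:
    """Read a tab-separated summary-statistics file into a validated SummaryStats.

    ``dialect`` maps canonical column names (see :data:`DEFAULT_DIALECT`) to
    the file's header names; unmapped columns fall back to the defaults. Rows
    violating per-variant invariants (se <= 0, malformed alleles, p outside
    (0, 1], ...) are dropped and counted in ``load_report``.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    try:
        raw = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise InputError(f"empty summary-statistics file: {path}") from None
    if raw.empty:
        raise InputError(f"empty summary-statistics file: {path}")

    rename = {v: k for k, v in dialect.items() if v in raw.columns}
    missing = [dialect[c] for c in MANDATORY if dialect[c] not in raw.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s) {missing} in {path}")
    df = raw.rename(columns=rename)
    keep_cols = [c for c in DEFAULT_DIALECT if c in df.columns]
    extra = [c for c in ("n_case", "n_control") if c in df.columns]
    df = df[keep_cols + extra]
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)

    clean, report = _validate_rows(df)
    name = trait_name if trait_name is not None else str(path)
    ss = SummaryStats(name, clean, unit=unit, ancestry=ancestry)
    ss.load_report = report
    if report.n_dropped:
        logger.info("%s: dropped %d/%d rows (%s)", name, report.n_dropped,
                    report.n_read, dict(report.reasons))
    return ss


# ---------------------------------------------------------------------------
# LD matrices

@dataclass
class LDMatrix:
    """Squared-correlation matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise InputError("LD matrix shape does not match variant list")
        if not np.allclose(self.r2, self.r2.T):
            raise InputError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise InputError("LD matrix diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise InputError("LD r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id) -> bool:
        return variant_id in self._index

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids,
                     columns=self.variant_ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Instrument selection (greedy LD clumping)

def select_instruments(ss: SummaryStats, p_threshold: float = 5e-8,
                       r2_max: float = 0.001, window_kb: float = 10_000,
                       ld: LDMatrix | None = None) -> SummaryStats:
    """Select genome-wide-significant, mutually independent instruments.

    Variants with p < ``p_threshold`` are visited in order of ascending
    p-value (ties broken by variant_id) and retained greedily: a candidate is
    kept iff its r² with every already-retained variant within ``window_kb``
    (centre ± window, boundary inclusive) is below ``r2_max``. Without an LD
    matrix, distance-only pruning applies: retained variants on the same
    chromosome must be more than ``window_kb`` apart.
    """
    if not (0 < p_threshold < 1):
        raise InputError("p_threshold must lie in (0, 1)")
    if not (0 <= r2_max <= 1):
        raise InputError("r2_max must lie in [0, 1]")

    sig = ss.table.loc[ss.table["pvalue"] < p_threshold]
    if sig.empty:
        return SummaryStats(ss.trait_name, sig.reset_index(drop=True),
                            unit=ss.unit, ancestry=ss.ancestry)
    if ld is not None:
        missing = [v for v in sig["variant_id"] if v not in ld]
        if missing:
            raise InputError(f"LD matrix missing significant variant(s): {missing}")

    sig = sig.sort_values(["pvalue", "variant_id"], kind="mergesort")
    window_bp = window_kb * 1000.0
    retained: list[tuple[str, str, float]] = []  # (id, chrom, pos)
    for row in sig.itertuples(index=False):
        ok = True
        for rid, rchrom, rpos in retained:
            if row.chrom != rchrom or abs(row.pos - rpos) > window_bp:
                continue
            if ld is None or ld.lookup(row.variant_id, rid) >= r2_max:
                ok = False
                break
        if ok:
            retained.append((row.variant_id, row.chrom, row.pos))

    keep_ids = {v for v, _, _ in retained}
    out = ss.table.loc[ss.table["variant_id"].isin(keep_ids)].reset_index(drop=True)
    return SummaryStats(ss.trait_name, out, unit=ss.unit, ancestry=ss.ancestry)


# ---------------------------------------------------------------------------
# Harmonisation

@dataclass
class HarmonisedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    ``table`` columns: variant_id, beta_exp, se_exp, beta_out, se_out, eaf,
    flag (retained SNPs only); ``provenance`` records the decision for every
    SNP shared between the two traits, including dropped ones.
    """

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    provenance: pd.DataFrame | None = None

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
                t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))

    def drop(self, variant_ids) -> "HarmonisedSet":
        keep = ~self.table["variant_id"].isin(set(variant_ids))
        return HarmonisedSet(self.exposure_name, self.outcome_name,
                             self.table.loc[keep].reset_index(drop=True),
                             self.provenance)

    def subset(self, variant_ids) -> "HarmonisedSet":
        keep = self.table["variant_id"].isin(set(variant_ids))
        return HarmonisedSet(self.exposure_name, self.outcome_name,
                             self.table.loc[keep].reset_index(drop=True),
                             self.provenance)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonise(exposure: SummaryStats, outcome: SummaryStats,
              palindrome_eaf_band: tuple[float, float] = (0.40, 0.60)) -> HarmonisedSet:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Swapped allele labels flip the outcome beta sign (and complement its eaf);
    strand flips are resolved by base complement for unambiguous SNPs and by
    allele frequency for palindromic (A/T, C/G) SNPs, which are dropped when
    either trait's eaf falls inside ``palindrome_eaf_band`` or is missing.
    """
    lo, hi = palindrome_eaf_band
    ex = exposure.table.set_index("variant_id")
    ou = outcome.table.set_index("variant_id")
    shared = ex.index.intersection(ou.index)

    rows, prov = [], []
    for vid in shared:
        e, o = ex.loc[vid], ou.loc[vid]
        ea_x, oa_x = e["effect_allele"], e["other_allele"]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        eaf_x = e.get("eaf", np.nan)
        eaf_y = o.get("eaf", np.nan)
        beta_out, eaf_out = float(o["beta"]), eaf_y

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                flag = FLAG_DROPPED_INCOMPATIBLE
                warnings.warn(f"{vid}: irreconcilable alleles "
                              f"{ea_x}/{oa_x} vs {ea_y}/{oa_y}; dropped")
            elif pd.isna(eaf_x) or pd.isna(eaf_y):
                flag = FLAG_DROPPED_PALINDROMIC
            elif lo < eaf_x < hi or lo < eaf_y < hi:
                flag = FLAG_DROPPED_PALINDROMIC
            else:
                # Nominal label alignment, then strand check by eaf agreement.
                if ea_y == oa_x:
                    beta_out, eaf_out = -beta_out, 1.0 - eaf_y
                if (eaf_x < 0.5) != (eaf_out < 0.5):
                    beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                flag = FLAG_UNCHANGED if beta_out == float(o["beta"]) else FLAG_FLIPPED
        else:
            pair = (ea_y, oa_y)
            comp = (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y])
            if pair == (ea_x, oa_x) or comp == (ea_x, oa_x):
                flag = FLAG_UNCHANGED
            elif pair == (oa_x, ea_x) or comp == (oa_x, ea_x):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_y if pd.notna(eaf_y) else np.nan
                flag = FLAG_FLIPPED
            else:
                flag = FLAG_DROPPED_INCOMPATIBLE
                warnings.warn(f"{vid}: irreconcilable alleles "
                              f"{ea_x}/{oa_x} vs {ea_y}/{oa_y}; dropped")

        prov.append((vid, flag))
        if flag in (FLAG_UNCHANGED, FLAG_FLIPPED):
            rows.append({"variant_id": vid, "beta_exp": float(e["beta"]),
                         "se_exp": float(e["se"]), "beta_out": beta_out,
                         "se_out": float(o["se"]),
                         "eaf": float(eaf_x) if pd.notna(eaf_x) else np.nan,
                         "flag": flag})

    for vid in ex.index.difference(ou.index).union(ou.index.difference(ex.index)):
        prov.append((vid, FLAG_DROPPED_MISSING))

    table = pd.DataFrame(rows, columns=["variant_id", "beta_exp", "se_exp",
                                        "beta_out", "se_out", "eaf", "flag"])
    provenance = pd.DataFrame(prov, columns=["variant_id", "flag"])
    return HarmonisedSet(exposure.trait_name, outcome.trait_name, table, provenance)


# ---------------------------------------------------------------------------
# Instrument strength

@dataclass
class InstrumentStrength:
    """Per-SNP and mean F statistics with the weak-instrument verdict."""

    f_per_snp: pd.Series
    mean_f: float
    weak: bool  # True unless mean F strictly exceeds 10


def instrument_strength(h: HarmonisedSet) -> InstrumentStrength:
    """Per-SNP F = (beta_exp/se_exp)^2; instruments are weak unless mean F > 10."""
    if h.n_snp == 0:
        raise InputError("instrument_strength requires a non-empty HarmonisedSet")
    bx, sx, _, _ = h.arrays()
    f = (bx / sx) ** 2
    mean_f = float(np.mean(f))
    return InstrumentStrength(pd.Series(f, index=h.table["variant_id"].to_numpy()),
                              mean_f, weak=not mean_f > 10)
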