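"""Multivariable MR: joint instrument assembly and multivariable IVW.

Assembles the union of genome-wide-significant variants across exposures,
prunes it to mutual independence, harmonises every trait to a common effect
allele, and regresses outcome betas on the exposure-beta matrix (no
intercept, inverse outcome-variance weights) so each coefficient is that
exposure's direct effect conditional on the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._exceptions import CollinearityError, InputError, UnderIdentifiedError
from .estimators import MREstimate, _wls
from .gwas_io import LDMatrix, SummaryStats, harmonise, select_instruments


@dataclass
class MVMRDataset:
    """Per-SNP effects of m exposures and one outcome, jointly harmonised.

    ``table`` columns: variant_id, then beta_<name>/se_<name> per exposure,
    then beta_out/se_out.
    """

    exposure_names: list[str]
    outcome_name: str
    table: pd.DataFrame

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def m(self) -> int:
        return len(self.exposure_names)

    def exposure_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.table[f"beta_{n}"].to_numpy(float) for n in self.exposure_names])

    def outcome_arrays(self):
        return (self.table["beta_out"].to_numpy(float),
                self.table["se_out"].to_numpy(float))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def assemble_mvmr(exposures: list[SummaryStats], outcome: SummaryStats,
                  p_threshold: float = 5e-8, r2_max: float = 0.001,
                  window_kb: float = 10_000, ld: LDMatrix | None = None,
                  exclude_ids=()) -> MVMRDataset:
    """Union-then-prune instrument assembly across exposures.

    Significant variants from every exposure are pooled; greedy pruning
    orders candidates by each variant's minimum p across exposures; the
    pruned set is harmonised to the first exposure's allele coding and
    intersected with the outcome (and every other exposure).
    """
    if len(exposures) < 2:
        raise InputError("assemble_mvmr requires at least 2 exposures")
    exclude_ids = set(exclude_ids)

    # Pool significant variants, scoring each by its minimum p across exposures.
    frames = []
    for ss in exposures:
        t = ss.table
        sig = t.loc[(t["pvalue"] < p_threshold)
                    & ~t["variant_id"].isin(exclude_ids),
                    ["variant_id", "chrom", "pos", "effect_allele",
                     "other_allele", "eaf", "beta", "se", "pvalue"]]
        frames.append(sig)
    pooled = pd.concat(frames, ignore_index=True)
    pooled = (pooled.sort_values(["pvalue", "variant_id"], kind="mergesort")
              .drop_duplicates("variant_id", keep="first"))
    union = SummaryStats("mvmr_union", pooled.reset_index(drop=True))
    pruned = select_instruments(union, p_threshold=p_threshold, r2_max=r2_max,
                                window_kb=window_kb, ld=ld)
    ids = set(pruned.table["variant_id"])

    # Harmonise every trait to the first exposure's allele coding.
    ref = exposures[0].subset(ids & set(exposures[0].table["variant_id"]))
    merged = ref.table[["variant_id", "beta", "se"]].rename(
        columns={"beta": f"beta_{exposures[0].trait_name}",
                 "se": f"se_{exposures[0].trait_name}"})
    for ss in exposures[1:]:
        h = harmonise(ref, ss)
        part = h.table[["variant_id", "beta_out", "se_out"]].rename(
            columns={"beta_out": f"beta_{ss.trait_name}",
                     "se_out": f"se_{ss.trait_name}"})
        merged = merged.merge(part, on="variant_id", how="inner")
    h_out = harmonise(ref, outcome)
    merged = merged.merge(h_out.table[["variant_id", "beta_out", "se_out"]],
                          on="variant_id", how="inner")
    merged = merged.sort_values("variant_id", kind="mergesort").reset_index(drop=True)

    names = [ss.trait_name for ss in exposures]
    if len(merged) <= len(names):
        raise UnderIdentifiedError(
            f"{len(merged)} SNPs cannot identify {len(names)} exposures")
    return MVMRDataset(names, outcome.trait_name, merged)


class MultivariableIVW(BaseEstimator):
    """No-intercept weighted least squares of outcome betas on exposure betas.

    Weights are 1/se_out^2; SEs use multiplicative inflation floored at 1;
    p-values are two-sided normal. Fitted attributes: ``coef_`` (m,),
    ``se_`` (m,), ``estimates_`` (dict exposure name -> MREstimate).
    """

    def fit(self, d: MVMRDataset, y=None) -> "MultivariableIVW":
        X = d.exposure_matrix()
        by, sy = d.outcome_arrays()
        n, m = X.shape
        if n <= m:
            raise UnderIdentifiedError(f"{n} SNPs cannot identify {m} exposures")
        # An exposure with no instrument signal at all contributes nothing to
        # the fit: give it a zero coefficient and leave the others alone.
        zero_cols = np.flatnonzero(~X.any(axis=0))
        active = np.flatnonzero(X.any(axis=0))
        Xa = X[:, active]
        if Xa.size and np.linalg.matrix_rank(Xa) < len(active):
            # name the exposures involved in the deficiency via pairwise correlation
            bad = []
            with np.errstate(invalid="ignore"):
                for ii, i in enumerate(active):
                    for j in active[ii + 1:]:
                        c = np.corrcoef(X[:, i], X[:, j])[0, 1]
                        if abs(c) > 1 - 1e-10:
                            bad += [d.exposure_names[i], d.exposure_names[j]]
            bad = list(dict.fromkeys(bad)) or [d.exposure_names[i] for i in active]
            raise CollinearityError(
                f"exposure-beta matrix is rank deficient ({', '.join(bad)})",
                exposures=bad)
        coef = np.zeros(m)
        se = np.full(m, np.inf)
        if len(active):
            coef_a, se_a, _, _ = _wls(Xa, by, 1.0 / sy ** 2)
            coef[active], se[active] = coef_a, se_a
        self.coef_, self.se_, self.n_snp_ = coef, se, n
        self.estimates_ = {
            name: MREstimate.from_beta_se("mvmr_ivw", coef[k], se[k], n)
            for k, name in enumerate(d.exposure_names)}
        return self


def mvmr_ivw(d: MVMRDataset) -> dict[str, MREstimate]:
    """One-shot multivariable IVW fit; see :class:`MultivariableIVW`."""
    return MultivariableIVW().fit(d).estimates_
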