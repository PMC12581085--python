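"""MR-PRESSO: pleiotropy residual sum and outlier test by parametric simulation.

The global test compares the observed leave-one-out residual sum of squares
against a null distribution simulated under no pleiotropy; per-SNP outlier
tests compare each observed squared residual with its simulated counterpart
(Bonferroni-adjusted across instruments); the distortion test asks whether
removing the flagged SNPs moved the IVW slope more than removing an equally
sized random subset would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._exceptions import DegenerateCorrectionError, InputError
from .estimators import MREstimate, _arrays, ivw
from .gwas_io import HarmonisedSet


@dataclass(frozen=True)
class PressoResult:
    """Global, outlier and distortion test results."""

    rss_obs: float
    global_p: float
    outlier_pvalues: pd.Series  # Bonferroni-adjusted, indexed by variant_id
    outlier_ids: tuple[str, ...]
    corrected: MREstimate
    distortion_p: float | None


def _loo_slopes(bx, by, sy):
    """Leave-one-out fixed-IVW slopes, vectorised over the omitted SNP."""
    w = bx ** 2 / sy ** 2
    wr = bx * by / sy ** 2
    return (wr.sum() - wr) / (w.sum() - w)


class MRPresso(BaseEstimator):
    """Simulation-based pleiotropy outlier detection (seeded, deterministic).

    Parameters
    ----------
    n_sim : number of parametric null datasets.
    outlier_alpha : flagging threshold on the Bonferroni-adjusted per-SNP p.
    random_state : seed for all simulation draws (mandatory).
    corrected_model : IVW model used for the outlier-corrected estimate.
    """

    def __init__(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                 random_state: int | None = None,
                 corrected_model: str = "random_multiplicative"):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.random_state = random_state
        self.corrected_model = corrected_model

    def fit(self, h: HarmonisedSet, y=None) -> "MRPresso":
        if self.random_state is None:
            raise InputError("MRPresso requires an explicit random_state")
        bx, sx, by, sy = _arrays(h)
        n = len(bx)
        if n < 4:
            raise InputError(f"MR-PRESSO requires at least 4 SNPs, got {n}")
        ids = list(h.table["variant_id"]) if isinstance(h, HarmonisedSet) \
            else list(range(n))
        rng = np.random.default_rng(self.random_state)

        slopes = _loo_slopes(bx, by, sy)
        resid = by - slopes * bx
        rss_obs = float((resid ** 2).sum())

        # Parametric null: outcome betas centred on the leave-one-out fit.
        m = self.n_sim
        bx_s = rng.normal(bx, sx, size=(m, n))
        by_s = rng.normal(slopes * bx, sy, size=(m, n))
        w_s = bx_s ** 2 / sy ** 2
        wr_s = bx_s * by_s / sy ** 2
        slopes_s = (wr_s.sum(axis=1, keepdims=True) - wr_s) / \
                   (w_s.sum(axis=1, keepdims=True) - w_s)
        resid_s = by_s - slopes_s * bx_s
        rss_s = (resid_s ** 2).sum(axis=1)

        global_p = (1 + int((rss_s >= rss_obs).sum())) / (m + 1)

        raw = (1 + (resid_s ** 2 >= resid ** 2).sum(axis=0)) / (m + 1)
        adj = np.minimum(1.0, raw * n)
        outlier_p = pd.Series(adj, index=pd.Index(ids, name="variant_id"))
        flagged = [vid for vid, p in outlier_p.items() if p < self.outlier_alpha]
        if len(flagged) == n:
            raise DegenerateCorrectionError("every instrument flagged as an outlier")

        keep = ~np.isin(np.asarray(ids, dtype=object), np.asarray(flagged, dtype=object))
        sub = h.subset([ids[i] for i in np.flatnonzero(keep)]) \
            if isinstance(h, HarmonisedSet) else None
        corrected = ivw(sub if sub is not None else
                        {"beta_exp": bx[keep], "se_exp": sx[keep],
                         "beta_out": by[keep], "se_out": sy[keep]},
                        model=self.corrected_model)

        distortion_p = None
        if flagged:
            full = ivw(h, model="fixed").beta
            d_obs = (full - corrected.beta) / abs(corrected.beta)
            k = len(flagged)
            non_out = np.flatnonzero(keep)
            d_null = np.empty(m)
            w_all = bx ** 2 / sy ** 2
            wr_all = bx * by / sy ** 2
            for i in range(m):
                # pseudo-outliers drawn from the non-flagged instruments
                drop = rng.choice(non_out, size=min(k, len(non_out)), replace=False)
                mask = np.ones(n, bool)
                mask[drop] = False
                sub_beta = wr_all[mask].sum() / w_all[mask].sum()
                d_null[i] = (full - sub_beta) / abs(sub_beta)
            distortion_p = (1 + int((np.abs(d_null) >= abs(d_obs)).sum())) / (m + 1)

        self.rss_obs_, self.global_p_ = rss_obs, global_p
        self.outlier_pvalues_ = outlier_p
        self.outlier_ids_ = tuple(flagged)
        self.corrected_ = corrected
        self.distortion_p_ = distortion_p
        self.result_ = PressoResult(rss_obs, global_p, outlier_p,
                                    tuple(flagged), corrected, distortion_p)
        return self


def presso(h: HarmonisedSet, n_sim: int = 1000, seed: int | None = None,
           outlier_alpha: float = 0.05) -> PressoResult:
    """One-shot MR-PRESSO run; see :class:`MRPresso`."""
    return MRPresso(n_sim=n_sim, outlier_alpha=outlier_alpha,
                    random_state=seed).fit(h).result_
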