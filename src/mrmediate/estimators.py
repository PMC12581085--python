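"""Univariable two-sample MR estimators and heterogeneity diagnostics.

Each estimator is a scikit-learn-style class: construct with hyperparameters,
call ``fit`` on a :class:`~mrmediate.gwas_io.HarmonisedSet` (or a frame with
``beta_exp``/``se_exp``/``beta_out``/``se_out`` columns), then read fitted
attributes (``beta_``, ``se_``, ``estimate_``). Module-level functions wrap
the classes for one-shot use.

Conventions: causal effects are per SD of exposure (log-OR per SD for binary
outcomes); 95% intervals use the normal multiplier 1.96; two-sided p-values
are normal-approximation except MR-Egger, which uses t with n_snp - 2 df.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import InputError, UndefinedRatioError
from .gwas_io import HarmonisedSet

Z95 = 1.96

_MIN_P = 1e-300


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its normal-approximation interval."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int,
                     df: int | None = None) -> "MREstimate":
        """Build an estimate; p two-sided normal, or t with ``df`` if given."""
        beta, se = float(beta), float(se)
        if se > 0:
            z = abs(beta) / se
            p = 2 * (stats.t.sf(z, df) if df else stats.norm.sf(z))
        else:
            p = 1.0 if beta == 0 else _MIN_P
        return cls(method, beta, se, beta - Z95 * se, beta + Z95 * se,
                   max(float(p), _MIN_P), int(n_snp))


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its chi-square reference."""

    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (causal effect) and intercept (directional pleiotropy)."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    Q: float
    Q_pvalue: float


@dataclass(frozen=True)
class ORResult:
    """An estimate exponentiated onto the odds-ratio scale."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    display: str


def _arrays(h) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(h, HarmonisedSet):
        return h.arrays()
    return (np.asarray(h["beta_exp"], float), np.asarray(h["se_exp"], float),
            np.asarray(h["beta_out"], float), np.asarray(h["se_out"], float))


def _require(h, n_min: int, what: str):
    bx, sx, by, sy = _arrays(h)
    if len(bx) < n_min:
        raise InputError(f"{what} requires at least {n_min} SNPs, got {len(bx)}")
    return bx, sx, by, sy


# ---------------------------------------------------------------------------
# Wald ratio

def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               second_order: bool = False) -> MREstimate:
    """Per-SNP causal estimate beta_out / beta_exp.

    First-order delta SE is se_out/|beta_exp|; with ``second_order`` the
    exposure's sampling error is propagated too:
    se^2 = se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4.
    """
    if beta_exp == 0:
        raise UndefinedRatioError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    if second_order:
        var = se_out ** 2 / beta_exp ** 2 + beta_out ** 2 * se_exp ** 2 / beta_exp ** 4
        se = float(np.sqrt(var))
    else:
        se = se_out / abs(beta_exp)
    return MREstimate.from_beta_se("wald", beta, se, 1)


# ---------------------------------------------------------------------------
# IVW

def _ivw_core(bx, by, sy):
    """Fixed-effect IVW slope, SE and Q from first-order weights."""
    w = bx ** 2 / sy ** 2
    r = by / bx
    sw = w.sum()
    beta = float((w * r).sum() / sw)
    se_fixed = float(1.0 / np.sqrt(sw))
    q = float((w * (r - beta) ** 2).sum())
    return beta, se_fixed, q, w, r


class IVW(BaseEstimator):
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios.

    ``model="fixed"`` uses se = 1/sqrt(sum w); ``"random_multiplicative"``
    (the headline model) inflates it by max(1, sqrt(Q/(n_snp-1))).
    """

    def __init__(self, model: str = "random_multiplicative"):
        self.model = model

    def fit(self, h, y=None) -> "IVW":
        if self.model not in ("fixed", "random_multiplicative"):
            raise InputError(f"unknown IVW model {self.model!r}")
        n_min = 1 if self.model == "fixed" else 2
        bx, sx, by, sy = _require(h, n_min, f"IVW ({self.model})")
        if np.any(bx == 0):
            raise UndefinedRatioError("IVW requires non-zero exposure betas")
        beta, se, q, _, _ = _ivw_core(bx, by, sy)
        n = len(bx)
        if self.model == "random_multiplicative":
            se *= max(1.0, float(np.sqrt(q / (n - 1))))
        self.beta_, self.se_, self.q_, self.n_snp_ = beta, se, q, n
        self.estimate_ = MREstimate.from_beta_se(
            "ivw_fixed" if self.model == "fixed" else "ivw_random", beta, se, n)
        return self


def ivw(h, model: str = "random_multiplicative") -> MREstimate:
    """One-shot IVW estimate; see :class:`IVW`."""
    return IVW(model=model).fit(h).estimate_


# ---------------------------------------------------------------------------
# MR-Egger

def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, floor_scale: bool = True):
    """Weighted least squares with multiplicative SE inflation floored at 1."""
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    rss = float(resid @ resid)
    dof = X.shape[0] - X.shape[1]
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    scale = rss / dof if dof > 0 else np.nan
    if floor_scale:
        scale = max(1.0, scale)
    se = np.sqrt(np.diag(xtx_inv) * scale)
    return coef, se, rss, rank


class MREggerRegression(BaseEstimator):
    """Weighted regression of outcome on exposure betas with a free intercept.

    SNPs are oriented so every exposure beta is positive; a non-zero
    intercept indicates directional horizontal pleiotropy. Inference uses t
    with n_snp - 2 df and multiplicative SE inflation floored at 1.
    """

    def fit(self, h, y=None) -> "MREggerRegression":
        bx, sx, by, sy = _require(h, 3, "MR-Egger")
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        w = 1.0 / sy ** 2
        X = np.column_stack([np.ones_like(bx), bx])
        (a, b), (se_a, se_b), rss, _ = _wls(X, by, w)
        n = len(bx)
        q = rss  # weighted RSS about the Egger fit
        self.n_snp_ = n
        self.beta_, self.se_ = float(b), float(se_b)
        self.intercept_, self.intercept_se_ = float(a), float(se_a)
        self.intercept_pvalue_ = max(_MIN_P, 2 * stats.t.sf(abs(a) / se_a, n - 2))
        self.q_ = float(q)
        self.q_pvalue_ = float(stats.chi2.sf(q, n - 2))
        self.estimate_ = MREstimate.from_beta_se("egger_slope", b, se_b, n, df=n - 2)
        self.result_ = EggerResult(self.estimate_, self.intercept_,
                                   self.intercept_se_, self.intercept_pvalue_,
                                   self.q_, self.q_pvalue_)
        return self


def mr_egger(h) -> EggerResult:
    """One-shot MR-Egger regression; see :class:`MREggerRegression`."""
    return MREggerRegression().fit(h).result_


def _parametric_bootstrap(bx, sx, by, sy, n_boot, seed, statistic):
    """Seeded parametric bootstrap over per-SNP betas.

    Outcome-side noise is drawn in antithetic pairs (+z, -z), so the bootstrap
    SE is exactly invariant under negating every outcome beta; ``n_boot`` is
    rounded up to the next even number.
    """
    rng = np.random.default_rng(seed)
    n_pair = (n_boot + 1) // 2
    out = np.empty(2 * n_pair)
    tiny = np.finfo(float).tiny
    for i in range(n_pair):
        bxs = bx + rng.standard_normal(len(bx)) * sx
        zy = rng.standard_normal(len(by)) * sy
        bxs[bxs == 0] = tiny
        out[2 * i] = statistic(bxs, by + zy)
        out[2 * i + 1] = statistic(bxs, by - zy)
    return out


# ---------------------------------------------------------------------------
# Weighted median

def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Value at cumulative normalised weight 0.5, interpolating between the
    centred cumulative weights of adjacent order statistics."""
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of Wald ratios; consistent when >50% of weight is valid.

    The SE comes from a seeded parametric bootstrap: per-SNP betas are
    resampled from normal(beta, se), the median recomputed, and the standard
    deviation over ``n_boot`` draws reported.
    """

    def __init__(self, n_boot: int = 5000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, h, y=None) -> "WeightedMedianEstimator":
        if self.random_state is None:
            raise InputError("WeightedMedianEstimator requires an explicit random_state")
        bx, sx, by, sy = _require(h, 3, "weighted median")
        w = bx ** 2 / sy ** 2
        beta = _weighted_median(by / bx, w)
        n = len(bx)
        boots = _parametric_bootstrap(
            bx, sx, by, sy, self.n_boot, self.random_state,
            lambda bxs, bys: _weighted_median(bys / bxs, bxs ** 2 / sy ** 2))
        se = float(np.std(boots, ddof=1))
        self.beta_, self.se_, self.n_snp_ = beta, se, n
        self.estimate_ = MREstimate.from_beta_se("weighted_median", beta, se, n)
        return self


def weighted_median(h, n_boot: int = 5000, seed: int | None = None) -> MREstimate:
    """One-shot weighted-median estimate; see :class:`WeightedMedianEstimator`."""
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(h).estimate_


# ---------------------------------------------------------------------------
# Weighted mode

def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    # Silverman-style rule on the ratio spread, using the smaller of SD and
    # scaled MAD so a single outlier does not inflate the bandwidth.
    n = len(ratios)
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = min(sd, mad) if mad > 0 else sd
    if s == 0:
        return 0.0
    return factor * 0.9 * s * n ** (-1 / 5)


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    if bandwidth == 0:
        return float(ratios[np.argmax(weights)])
    w = weights / weights.sum()
    grid = np.linspace(ratios.min() - 3 * bandwidth, ratios.max() + 3 * bandwidth, 2048)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :])
                                        / bandwidth) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


class WeightedModeEstimator(BaseEstimator):
    """Mode of the inverse-variance-weighted kernel density over Wald ratios.

    Consistent when the largest weight-share of SNPs is valid (ZEMPA). The
    normal-kernel bandwidth is ``bandwidth_factor`` times a rule-of-thumb on
    the ratio spread; SE by seeded parametric bootstrap.
    """

    def __init__(self, bandwidth_factor: float = 1.0, n_boot: int = 5000,
                 random_state: int | None = None):
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, h, y=None) -> "WeightedModeEstimator":
        if self.random_state is None:
            raise InputError("WeightedModeEstimator requires an explicit random_state")
        bx, sx, by, sy = _require(h, 3, "weighted mode")
        r = by / bx
        w = bx ** 2 / sy ** 2
        if np.ptp(r) == 0:
            beta = float(r[0])
        else:
            beta = _weighted_mode(r, w, _mode_bandwidth(r, self.bandwidth_factor))

        def stat(bxs, bys):
            rs = bys / bxs
            if np.ptp(rs) == 0:
                return rs[0]
            return _weighted_mode(rs, bxs ** 2 / sy ** 2,
                                  _mode_bandwidth(rs, self.bandwidth_factor))

        boots = _parametric_bootstrap(bx, sx, by, sy, self.n_boot,
                                      self.random_state, stat)
        se = float(np.std(boots, ddof=1))
        n = len(bx)
        self.beta_, self.se_, self.n_snp_ = beta, se, n
        self.estimate_ = MREstimate.from_beta_se("weighted_mode", beta, se, n)
        return self


def weighted_mode(h, bandwidth_factor: float = 1.0, n_boot: int = 5000,
                  seed: int | None = None) -> MREstimate:
    """One-shot weighted-mode estimate; see :class:`WeightedModeEstimator`."""
    return WeightedModeEstimator(bandwidth_factor=bandwidth_factor, n_boot=n_boot,
                                 random_state=seed).fit(h).estimate_


# ---------------------------------------------------------------------------
# Heterogeneity and influence

def cochrans_q(h, pooled: MREstimate) -> HeterogeneityStats:
    """Cochran's Q of per-SNP Wald ratios about the pooled estimate."""
    bx, sx, by, sy = _require(h, 2, "Cochran's Q")
    w = bx ** 2 / sy ** 2
    r = by / bx
    q = float((w * (r - pooled.beta) ** 2).sum())
    df = len(bx) - 1
    return HeterogeneityStats(q, df, float(stats.chi2.sf(q, df)))


def leave_one_out(h: HarmonisedSet, model: str = "random_multiplicative"
                  ) -> list[tuple[str, MREstimate]]:
    """Re-estimate IVW with each SNP omitted in turn."""
    if h.n_snp < 3:
        raise InputError(f"leave-one-out requires at least 3 SNPs, got {h.n_snp}")
    out = []
    ids = list(h.table["variant_id"])
    for vid in ids:
        out.append((vid, ivw(h.drop([vid]), model=model)))
    return out


# ---------------------------------------------------------------------------
# Presentation scale

def _round_half_away(x: float, ndigits: int = 2) -> float:
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def to_odds_ratio(e: MREstimate) -> ORResult:
    """Exponentiate a log-OR estimate onto the odds-ratio scale.

    Display values round to 2 decimals, half away from zero.
    """
    o, lo, hi = np.exp([e.beta, e.ci_low, e.ci_high])
    disp = (f"{_round_half_away(o):.2f} ({_round_half_away(lo):.2f} "
            f"to {_round_half_away(hi):.2f})")
    return ORResult(float(o), float(lo), float(hi), disp)
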