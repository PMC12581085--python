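"""Synthetic GWAS summary statistics with a known exposure→mediator→outcome chain.

The generator works entirely on the summary level: per-variant true effects
are drawn for an exposure, a mediator and an outcome linked by a causal
triad (direct effect θ_xy_direct, mediated path θ_xm·θ_my, optional per-SNP
pleiotropy α_j), then observed effects are the truth plus sampling noise
with the standard-error profile of a GWAS of the configured sample size:
se_j = 1/sqrt(2·n·maf_j(1−maf_j)) for standardised traits, with the
effective sample size 4/(1/n_case + 1/n_control) for binary (log-OR) traits.

The exposure's instruments carry heritability ``exposure_h2`` spread over
``n_snps`` variants; the mediator gets its own ``n_med_snps`` instruments
(heritability ``mediator_h2``) so that its direct effect is identifiable in
multivariable MR; ``n_null_snps`` background variants have no true effect
anywhere. All variants are placed more than one pruning window apart so
distance-only clumping treats them as independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._exceptions import InputError
from .gwas_io import LDMatrix, SummaryStats

_MIN_P = 1e-300
_CHROM_COUNT = 22
_SLOT_BP = 20_000_000  # > default 10,000 kb window, so slots never clump


@dataclass
class SimConfig:
    """Study conditions for one simulated triad.

    Defaults mirror the design this generator emulates: a standardised
    continuous exposure measured in ~300k samples with ~100 independent
    genome-wide-significant instruments of comfortably strong mean F, a
    standardised continuous mediator (~450k samples), and a binary outcome
    on the log-OR scale with FinnGen-like case/control counts. The default
    causal chain (θ_xm = 0.47, θ_my = 0.22, total = 0.38) is a realistic
    body-composition-mediated triad.
    """

    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 298_142
    n_med: int = 450_243
    n_out: int | tuple[int, int] = (8_125, 381_977)
    exposure_h2: float = 0.02
    mediator_h2: float = 0.04
    n_med_snps: int = 100
    theta_xm: float = 0.47
    theta_my: float = 0.22
    theta_xy_direct: float = 0.38 - 0.47 * 0.22
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_null_snps: int = 100
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_snps < 1:
            bad.append("n_snps")
        if self.n_med_snps < 0:
            bad.append("n_med_snps")
        if self.n_null_snps < 0:
            bad.append("n_null_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            bad.append("maf_range")
        for name in ("n_exp", "n_med"):
            if getattr(self, name) < 1:
                bad.append(name)
        if isinstance(self.n_out, tuple):
            if len(self.n_out) != 2 or min(self.n_out) < 1:
                bad.append("n_out")
        elif self.n_out < 1:
            bad.append("n_out")
        if not (0 < self.exposure_h2 < 1):
            bad.append("exposure_h2")
        if self.n_med_snps and not (0 < self.mediator_h2 < 1):
            bad.append("mediator_h2")
        if self.pleiotropy_sd < 0:
            bad.append("pleiotropy_sd")
        if bad:
            raise InputError(f"invalid SimConfig field(s): {bad}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown SimConfig field(s): {sorted(unknown)}")
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        if isinstance(raw.get("n_out"), list):
            raw["n_out"] = tuple(raw["n_out"])
        return cls(**raw)


@dataclass(frozen=True)
class TriadTruth:
    """Analytic ground truth of the simulated causal chain."""

    true_total: float
    true_direct: float
    true_indirect: float
    true_proportion: float

    @classmethod
    def from_config(cls, cfg: SimConfig) -> "TriadTruth":
        indirect = cfg.theta_xm * cfg.theta_my
        total = cfg.theta_xy_direct + indirect
        return cls(total, cfg.theta_xy_direct, indirect,
                   indirect / total if total != 0 else np.nan)


def _effective_n(n) -> float:
    if isinstance(n, tuple):
        n_case, n_control = n
        return 4.0 / (1.0 / n_case + 1.0 / n_control)
    return float(n)


def _positions(n_total: int):
    idx = np.arange(n_total)
    chrom = (idx % _CHROM_COUNT + 1).astype(str)
    pos = (idx // _CHROM_COUNT + 1) * _SLOT_BP
    return chrom, pos


def _emit_trait(rng, name, unit, ids, chrom, pos, maf, true_beta, n,
                swap_fraction=0.10, n_case=None, n_control=None) -> SummaryStats:
    """Observed summary statistics for one trait: truth + sampling noise,
    with a fraction of records emitted with swapped allele labels."""
    n_eff = _effective_n(n)
    se = 1.0 / np.sqrt(2.0 * n_eff * maf * (1.0 - maf))
    beta = true_beta + rng.normal(0.0, se)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), _MIN_P)

    ea = np.full(len(ids), "A", dtype=object)
    oa = np.full(len(ids), "C", dtype=object)
    eaf = maf.copy()
    swap = rng.random(len(ids)) < swap_fraction
    ea[swap], oa[swap] = oa[swap], ea[swap]
    beta = np.where(swap, -beta, beta)
    eaf = np.where(swap, 1.0 - eaf, eaf)

    table = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": p,
        "n": int(round(n_eff)) if n_case is None else n_case + n_control,
    })
    if n_case is not None:
        table["n_case"] = n_case
        table["n_control"] = n_control
    return SummaryStats(name, table, unit=unit)


def simulate_triad(cfg: SimConfig) -> tuple[SummaryStats, SummaryStats,
                                            SummaryStats, TriadTruth]:
    """Draw one exposure/mediator/outcome triad of summary statistics."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_x, n_m, n_0 = cfg.n_snps, cfg.n_med_snps, cfg.n_null_snps
    total_snps = n_x + n_m + n_0
    ids = np.array([f"rs{i + 1:06d}" for i in range(total_snps)], dtype=object)
    chrom, pos = _positions(total_snps)
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, total_snps) if hi > lo else np.full(total_snps, lo)

    # Per-variant true effects (standardised per-allele scale).
    gamma = np.zeros(total_snps)   # on the exposure
    gamma[:n_x] = rng.normal(
        0.0, np.sqrt(cfg.exposure_h2 / n_x / (2.0 * maf[:n_x] * (1.0 - maf[:n_x]))))
    gamma_m = np.zeros(total_snps)  # mediator-specific
    if n_m:
        sl = slice(n_x, n_x + n_m)
        gamma_m[sl] = rng.normal(
            0.0, np.sqrt(cfg.mediator_h2 / n_m / (2.0 * maf[sl] * (1.0 - maf[sl]))))
    alpha = np.zeros(total_snps)    # pleiotropic direct effects on the outcome
    if cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0:
        alpha[:n_x] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n_x)

    true_exp = gamma
    true_med = cfg.theta_xm * gamma + gamma_m
    true_out = (cfg.theta_xy_direct * gamma
                + cfg.theta_my * true_med + alpha)

    binary = isinstance(cfg.n_out, tuple)
    exposure = _emit_trait(rng, "exposure", "SD", ids, chrom, pos, maf,
                           true_exp, cfg.n_exp)
    mediator = _emit_trait(rng, "mediator", "SD", ids, chrom, pos, maf,
                           true_med, cfg.n_med)
    outcome = _emit_trait(rng, "outcome", "logOR" if binary else "SD",
                          ids, chrom, pos, maf, true_out, cfg.n_out,
                          n_case=cfg.n_out[0] if binary else None,
                          n_control=cfg.n_out[1] if binary else None)
    return exposure, mediator, outcome, TriadTruth.from_config(cfg)


def expected_instrument_f(cfg: SimConfig) -> float:
    """Analytic expectation of the mean instrument F: 1 + n_exp·h²/n_snps."""
    return 1.0 + cfg.n_exp * cfg.exposure_h2 / cfg.n_snps


def simulate_ld_block(n_snps: int, decay_r2: float, seed: int
                      ) -> tuple[LDMatrix, SummaryStats]:
    """A single LD block with geometrically decaying r² and matching betas.

    r²(i, j) = decay_r2^|i−j|; variants sit 100 kb apart on one chromosome;
    every emitted variant is genome-wide significant, making the block a
    direct fixture for the clumping rule.
    """
    if not 0 <= decay_r2 < 1:
        raise InputError("decay_r2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_snps)
    corr = np.sqrt(decay_r2) ** np.abs(idx[:, None] - idx[None, :])
    r2 = corr ** 2
    ids = [f"ld{i + 1:03d}" for i in range(n_snps)]
    ld = LDMatrix(ids, r2)

    z = np.linalg.cholesky(corr + 1e-12 * np.eye(n_snps)) @ rng.standard_normal(n_snps)
    se = np.full(n_snps, 0.01)
    beta = 0.08 + 0.01 * z  # ~8 SE from zero: comfortably genome-wide significant
    p = np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), _MIN_P)
    table = pd.DataFrame({
        "variant_id": ids, "chrom": "1", "pos": (idx + 1) * 100_000,
        "effect_allele": "A", "other_allele": "C",
        "eaf": np.full(n_snps, 0.3), "beta": beta, "se": se, "pvalue": p,
        "n": 100_000,
    })
    return ld, SummaryStats("ld_block", table)


def write_truth(path, truth: TriadTruth) -> None:
    """Write the ground-truth sidecar as plain YAML key: value text."""
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in vars(truth).items()}, fh,
                       sort_keys=True)


def read_truth(path) -> TriadTruth:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return TriadTruth(**raw)
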