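"""Two-step MR mediation: indirect effects, mediated proportions, qualification.

The decomposition is the product-of-coefficients form: the effect of the
exposure on a mediator (β₁, univariable IVW) times the mediator's direct
effect on the outcome conditional on the exposure (β₂, multivariable IVW)
gives the indirect effect; dividing by the total exposure→outcome effect
gives the proportion mediated. Standard errors propagate by the delta
method.

Two reporting modes exist for the proportion. ``exact`` divides the
unrounded indirect effect by the total and carries both variance terms of
the ratio. ``table2_convention`` rounds the indirect effect to two decimals
before dividing and treats the total as fixed — the convention that
reproduces published two-step MR tables reporting coefficients at
two-decimal precision (ties round half-to-even).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

from ._exceptions import InputError
from .estimators import Z95, MREstimate, ivw
from .gwas_io import SummaryStats, harmonise, select_instruments
from .mvmr import assemble_mvmr, mvmr_ivw


@dataclass(frozen=True)
class BonferroniLayers:
    """Per-layer significance thresholds of the study design."""

    alpha_outcomes: float = 0.05 / 16
    alpha_mediators: float = 0.05 / 24
    alpha_mediator_outcome: float = 0.05 / 96


@dataclass(frozen=True)
class IndirectEffect:
    value: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ProportionMediated:
    percent: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class QualificationResult:
    """Per-criterion verdicts for one candidate mediator."""

    bw_mediator: bool        # exposure→mediator association significant
    mediator_outcome: bool   # mediator→outcome (adjusted) significant
    direction: bool          # indirect effect agrees in sign with the total

    @property
    def qualified(self) -> bool:
        return self.bw_mediator and self.mediator_outcome and self.direction


@dataclass
class MediationResult:
    """Full decomposition for one (mediator, outcome) pair."""

    outcome: str
    mediator: str
    total: MREstimate
    beta1: MREstimate
    beta2: MREstimate
    indirect: IndirectEffect
    proportion: ProportionMediated | None
    criteria: QualificationResult
    qualified: bool
    estimable: bool = True
    n_excluded_overlap: int | None = None


def indirect_effect(beta1: MREstimate, beta2: MREstimate) -> IndirectEffect:
    """Product of coefficients β₁β₂ with delta-method SE.

    se² = β₁²·se₂² + β₂²·se₁² (first-order, independence across samples).
    """
    if not (np.isfinite(beta1.beta) and np.isfinite(beta2.beta)):
        raise InputError("indirect_effect requires finite inputs")
    value = beta1.beta * beta2.beta
    se = float(np.sqrt(beta1.beta ** 2 * beta2.se ** 2
                       + beta2.beta ** 2 * beta1.se ** 2))
    return IndirectEffect(value, se, value - Z95 * se, value + Z95 * se)


def _round2(x: float) -> Decimal:
    return Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)


def proportion_mediated(indirect: IndirectEffect, total: MREstimate,
                        reporting: str = "table2_convention") -> ProportionMediated:
    """Proportion of the total effect carried through the mediator, as a %.

    ``table2_convention``: round the indirect effect (and its CI bounds) to
    two decimals, divide by the total point estimate, express as a
    percentage rounded to two decimals. ``exact``: unrounded ratio with the
    full two-term delta-method variance.
    """
    if total.beta == 0:
        raise InputError("proportion undefined: total effect is zero")
    if reporting == "table2_convention":
        t = Decimal(repr(total.beta))
        pct = float((100 * _round2(indirect.value) / t)
                    .quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))
        bounds = sorted(
            float((100 * _round2(b) / t).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_EVEN))
            for b in (indirect.ci_low, indirect.ci_high))
        return ProportionMediated(pct, bounds[0], bounds[1])
    if reporting == "exact":
        p = indirect.value / total.beta
        var = (indirect.se ** 2 / total.beta ** 2
               + indirect.value ** 2 * total.se ** 2 / total.beta ** 4)
        se = float(np.sqrt(var))
        return ProportionMediated(100 * p, 100 * (p - Z95 * se), 100 * (p + Z95 * se))
    raise InputError(f"unknown reporting mode {reporting!r}")


def qualify_mediator(beta1: MREstimate, beta2: MREstimate, total: MREstimate,
                     layers: BonferroniLayers = BonferroniLayers()) -> QualificationResult:
    """Apply the three mediator-qualification criteria (strict inequalities)."""
    return QualificationResult(
        bw_mediator=beta1.pvalue < layers.alpha_mediators,
        mediator_outcome=beta2.pvalue < layers.alpha_mediator_outcome,
        direction=np.sign(beta1.beta * beta2.beta) == np.sign(total.beta),
    )


# ---------------------------------------------------------------------------
# Pair-level mediation pipeline (shared by run_study and overlap_sensitivity)

@dataclass
class MediationSettings:
    p_threshold: float = 5e-8
    r2_max: float = 0.001
    window_kb: float = 10_000
    palindrome_eaf_band: tuple[float, float] = (0.40, 0.60)
    ivw_model: str = "random_multiplicative"
    reporting: str = "table2_convention"
    layers: BonferroniLayers = field(default_factory=BonferroniLayers)
    ld: object = None


def run_mediation_pair(exposure: SummaryStats, mediator: SummaryStats,
                       outcome: SummaryStats,
                       settings: MediationSettings = MediationSettings(),
                       exclude_ids=()) -> MediationResult:
    """Full two-step decomposition for one (mediator, outcome) pair.

    Total effect and β₁ come from univariable IVW on the exposure's
    instruments; β₂ from multivariable IVW on the pooled exposure+mediator
    instruments. ``exclude_ids`` removes variants from every instrument set
    before selection (used by the overlap-SNP sensitivity analysis).
    """
    s = settings
    exp_sel = select_instruments(exposure.exclude(exclude_ids), s.p_threshold,
                                 s.r2_max, s.window_kb, s.ld)
    if len(exp_sel) == 0:
        raise InputError("no exposure instruments after selection/exclusion")
    h_total = harmonise(exp_sel, outcome, s.palindrome_eaf_band)
    total = ivw(h_total, model=s.ivw_model)
    h_med = harmonise(exp_sel, mediator, s.palindrome_eaf_band)
    beta1 = ivw(h_med, model=s.ivw_model)

    d = assemble_mvmr([exposure.exclude(exclude_ids),
                       mediator.exclude(exclude_ids)], outcome,
                      p_threshold=s.p_threshold, r2_max=s.r2_max,
                      window_kb=s.window_kb, ld=s.ld)
    beta2 = mvmr_ivw(d)[mediator.trait_name]

    ind = indirect_effect(beta1, beta2)
    prop = proportion_mediated(ind, total, reporting=s.reporting)
    crit = qualify_mediator(beta1, beta2, total, s.layers)
    return MediationResult(outcome.trait_name, mediator.trait_name, total,
                           beta1, beta2, ind, prop, crit, crit.qualified)


def overlap_sensitivity(exposure: SummaryStats, mediator: SummaryStats,
                        outcome: SummaryStats,
                        settings: MediationSettings = MediationSettings()
                        ) -> MediationResult:
    """Re-run the mediation after excluding variants genome-wide significant
    for both the exposure and the mediator (shared-instrument sensitivity)."""
    shared = (set(exposure.significant_ids(settings.p_threshold))
              & set(mediator.significant_ids(settings.p_threshold)))
    try:
        res = run_mediation_pair(exposure, mediator, outcome, settings,
                                 exclude_ids=shared)
    except InputError:
        import warnings
        warnings.warn("overlap exclusion emptied an instrument set; "
                      "sensitivity result non-estimable")
        na = MREstimate("ivw_random", np.nan, np.nan, np.nan, np.nan, 1.0, 0)
        res = MediationResult(outcome.trait_name, mediator.trait_name, na, na,
                              na, IndirectEffect(np.nan, np.nan, np.nan, np.nan),
                              None, QualificationResult(False, False, False),
                              False, estimable=False)
    res.n_excluded_overlap = len(shared)
    return res
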