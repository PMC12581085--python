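"""Config-driven study orchestration: total effects, two-step mediation, reports.

``run_study`` reproduces the full analysis funnel: instrument selection for
the exposure, univariable IVW total effects on every outcome, step-1 IVW
effects on every mediator, step-2 multivariable IVW for each (significant
outcome, significant mediator) pair, qualification, mediation decomposition,
and the toggled sensitivity analyses. Report tables are written as TSV; all
randomness derives from the configured seed, so a rerun produces
byte-identical report files (the human-readable run log additionally carries
a wall-clock timestamp and is exempt from that contract).
"""

from __future__ import annotations

import datetime
import json
import zlib
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._exceptions import InputError, MRError
from .estimators import (MREstimate, cochrans_q, ivw, leave_one_out, mr_egger,
                         to_odds_ratio, weighted_median, weighted_mode)
from .gwas_io import (SummaryStats, harmonise, instrument_strength,
                      read_summary_stats, select_instruments)
from .mediation import (BonferroniLayers, MediationSettings, MediationResult,
                        indirect_effect, overlap_sensitivity,
                        proportion_mediated, qualify_mediator)
from .mvmr import assemble_mvmr, mvmr_ivw
from .presso import presso


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class TraitSpec:
    name: str
    path: str | None = None
    category: str | None = None


@dataclass
class SensitivityToggles:
    egger: bool = True
    median: bool = True
    mode: bool = False
    presso: bool = True
    loo: bool = True
    overlap_exclusion: bool = True


@dataclass
class StudyConfig:
    exposure: TraitSpec = field(default_factory=lambda: TraitSpec("exposure"))
    outcomes: list[TraitSpec] = field(default_factory=list)
    mediators: list[TraitSpec] = field(default_factory=list)
    p_threshold: float = 5e-8
    r2_max: float = 0.001
    window_kb: float = 10_000
    palindrome_eaf_band: tuple[float, float] = (0.40, 0.60)
    ivw_model: str = "random_multiplicative"
    reporting: str = "table2_convention"
    n_boot: int = 2000
    presso_n_sim: int = 1000
    sensitivity: SensitivityToggles = field(default_factory=SensitivityToggles)
    seed: int | None = None

    def __post_init__(self):
        if not self.outcomes and not self.mediators:
            return  # bare default config; validated again at run time
        self._validate()

    def _validate(self):
        if not self.outcomes:
            raise InputError("StudyConfig needs at least one outcome")
        s = self.sensitivity
        stochastic = s.median or s.mode or s.presso
        if stochastic and self.seed is None:
            raise InputError("StudyConfig needs a seed when stochastic "
                             "sensitivity methods are enabled")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kw = dict(raw)
        if "exposure" in kw:
            kw["exposure"] = TraitSpec(**kw["exposure"])
        for key in ("outcomes", "mediators"):
            if key in kw:
                kw[key] = [TraitSpec(**t) for t in kw[key]]
        if "sensitivity" in kw:
            kw["sensitivity"] = SensitivityToggles(**kw["sensitivity"])
        if "palindrome_eaf_band" in kw:
            kw["palindrome_eaf_band"] = tuple(kw["palindrome_eaf_band"])
        try:
            return cls(**kw)
        except TypeError as exc:
            raise InputError(f"invalid study config: {exc}") from None

    def to_yaml(self) -> str:
        d = asdict(self)
        d["palindrome_eaf_band"] = list(self.palindrome_eaf_band)
        return yaml.safe_dump(d, sort_keys=False)

    def mediation_settings(self, layers: BonferroniLayers) -> MediationSettings:
        return MediationSettings(self.p_threshold, self.r2_max, self.window_kb,
                                 self.palindrome_eaf_band, self.ivw_model,
                                 self.reporting, layers)


@dataclass
class StudyReport:
    """All result tables of one study run."""

    bw_cvd_table: pd.DataFrame
    bw_mediator_table: pd.DataFrame
    mediator_cvd_table: pd.DataFrame
    mediation_table: pd.DataFrame
    sensitivity_block: pd.DataFrame
    sankey_edges: pd.DataFrame
    instrument_qc: pd.DataFrame
    events: list[dict]


# ---------------------------------------------------------------------------
# Display helpers

def _round_half_away(x: float, nd: int = 2) -> float:
    q = Decimal(1).scaleb(-nd)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_effect(e: MREstimate, scale: str = "beta") -> str:
    """Render an estimate as ``x.xx (x.xx to x.xx)``, 2-decimal half-away."""
    vals = (e.beta, e.ci_low, e.ci_high)
    if scale == "or":
        vals = tuple(np.exp(v) for v in vals)
    elif scale != "beta":
        raise InputError(f"unknown scale {scale!r}")
    b, lo, hi = (_round_half_away(v) for v in vals)
    return f"{b:.2f} ({lo:.2f} to {hi:.2f})"


@dataclass(frozen=True)
class BonferroniResult:
    threshold: float
    display_threshold: float  # rounded to 4 decimals for captions
    flags: tuple[bool, ...]


def apply_bonferroni(pvalues, n_tests: int) -> BonferroniResult:
    """Flag p-values below 0.05/n_tests (strict inequality)."""
    if n_tests < 1:
        raise InputError("n_tests must be >= 1")
    thr = 0.05 / n_tests
    flags = tuple(bool(p < thr) for p in pvalues)
    return BonferroniResult(thr, float(round(thr, 4)), flags)


def _pair_seed(base: int, *labels: str) -> int:
    """Deterministic per-pair seed below 2^31."""
    h = zlib.crc32("|".join(labels).encode())
    return (base * 1_000_003 + h) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# Study runner

def _load_traits(cfg: StudyConfig, data: dict | None):
    if data is not None:
        exposure = data["exposure"]
        outcomes = dict(data["outcomes"])
        mediators = dict(data.get("mediators", {}))
        return exposure, outcomes, mediators
    exposure = read_summary_stats(cfg.exposure.path, trait_name=cfg.exposure.name)
    outcomes = {t.name: read_summary_stats(t.path, trait_name=t.name)
                for t in cfg.outcomes}
    mediators = {t.name: read_summary_stats(t.path, trait_name=t.name)
                 for t in cfg.mediators}
    return exposure, outcomes, mediators


def run_study(cfg: StudyConfig, outdir, data: dict | None = None) -> StudyReport:
    """Execute the full study design and write the report directory.

    ``data`` may supply in-memory SummaryStats ({"exposure": ss,
    "outcomes": {name: ss}, "mediators": {name: ss}}) instead of the config's
    file paths. Per-pair failures are logged as events and the run continues.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events: list[dict] = []

    def log(event: str, **kw):
        events.append({"event": event, **kw})

    exposure, outcomes, mediators = _load_traits(cfg, data)
    categories = {t.name: t.category for t in cfg.outcomes + cfg.mediators}
    log("config", seed=cfg.seed, p_threshold=cfg.p_threshold,
        r2_max=cfg.r2_max, window_kb=cfg.window_kb,
        n_outcomes=len(outcomes), n_mediators=len(mediators))

    exp_sel = select_instruments(exposure, cfg.p_threshold, cfg.r2_max,
                                 cfg.window_kb)
    log("instrument_selection", trait=exposure.trait_name,
        n_selected=len(exp_sel), n_total=len(exposure))
    if len(exp_sel) == 0:
        raise InputError("no genome-wide-significant exposure instruments")

    f_exp = (exp_sel.table["beta"] / exp_sel.table["se"]) ** 2
    qc = pd.DataFrame([{"trait": exposure.trait_name,
                        "n_instruments": len(exp_sel),
                        "mean_f": float(f_exp.mean()),
                        "min_f": float(f_exp.min()),
                        "weak": not float(f_exp.mean()) > 10}])

    n_out_tests = len(outcomes)
    n_med_tests = max(len(mediators), 1)

    # --- total effects: exposure -> each outcome -----------------------------
    bw_rows, h_by_outcome, total_by_outcome = [], {}, {}
    for name, ss in outcomes.items():
        try:
            h = harmonise(exp_sel, ss, cfg.palindrome_eaf_band)
            est = ivw(h, model=cfg.ivw_model)
            fixed = ivw(h, model="fixed")
        except MRError as exc:
            log("pair_failed", stage="total_effect", outcome=name, reason=str(exc))
            continue
        h_by_outcome[name], total_by_outcome[name] = h, est
        dropped = h.provenance.loc[h.provenance["flag"].str.startswith("dropped")]
        for row in dropped.itertuples(index=False):
            log("snp_dropped", stage="harmonise", outcome=name,
                variant_id=row.variant_id, reason=row.flag)
        orr = to_odds_ratio(est)
        bw_rows.append({"outcome": name, "category": categories.get(name),
                        "n_snp": est.n_snp, "beta": est.beta, "se": est.se,
                        "ci_low": est.ci_low, "ci_high": est.ci_high,
                        "pvalue": est.pvalue, "beta_fixed": fixed.beta,
                        "se_fixed": fixed.se, "or_display": orr.display,
                        "beta_display": format_effect(est)})
    bw_cvd = pd.DataFrame(bw_rows)
    if not bw_cvd.empty:
        bonf_out = apply_bonferroni(bw_cvd["pvalue"], n_out_tests)
        bw_cvd["significant"] = bonf_out.flags
        bw_cvd["alpha"] = bonf_out.threshold
    sig_outcomes = list(bw_cvd.loc[bw_cvd.get("significant", pd.Series(dtype=bool)),
                                   "outcome"]) if not bw_cvd.empty else []

    # --- step 1: exposure -> each mediator -----------------------------------
    med_rows, beta1_by_med = [], {}
    for name, ss in mediators.items():
        try:
            h = harmonise(exp_sel, ss, cfg.palindrome_eaf_band)
            est = ivw(h, model=cfg.ivw_model)
        except MRError as exc:
            log("pair_failed", stage="step1", mediator=name, reason=str(exc))
            continue
        beta1_by_med[name] = est
        med_rows.append({"mediator": name, "category": categories.get(name),
                         "n_snp": est.n_snp, "beta": est.beta, "se": est.se,
                         "ci_low": est.ci_low, "ci_high": est.ci_high,
                         "pvalue": est.pvalue, "beta_display": format_effect(est)})
    bw_med = pd.DataFrame(med_rows)
    if not bw_med.empty:
        bonf_med = apply_bonferroni(bw_med["pvalue"], n_med_tests)
        bw_med["significant"] = bonf_med.flags
        bw_med["alpha"] = bonf_med.threshold
    sig_mediators = list(bw_med.loc[bw_med.get("significant", pd.Series(dtype=bool)),
                                    "mediator"]) if not bw_med.empty else []

    # --- step 2: MVMR for (significant outcome, significant mediator) pairs --
    pairs = [(o, m) for o in sig_outcomes for m in sig_mediators]
    n_pair_tests = max(len(pairs), 1)
    layers = BonferroniLayers(alpha_outcomes=0.05 / n_out_tests,
                              alpha_mediators=0.05 / n_med_tests,
                              alpha_mediator_outcome=0.05 / n_pair_tests)
    pair_rows, med_results = [], []
    for out_name, med_name in pairs:
        try:
            d = assemble_mvmr([exposure, mediators[med_name]],
                              outcomes[out_name], cfg.p_threshold,
                              cfg.r2_max, cfg.window_kb)
            est = mvmr_ivw(d)
            beta2 = est[med_name]
        except MRError as exc:
            log("pair_failed", stage="mvmr", outcome=out_name,
                mediator=med_name, reason=str(exc))
            continue
        pair_rows.append({"outcome": out_name, "mediator": med_name,
                          "n_snp": beta2.n_snp, "beta": beta2.beta,
                          "se": beta2.se, "ci_low": beta2.ci_low,
                          "ci_high": beta2.ci_high, "pvalue": beta2.pvalue,
                          "beta_exposure_adjusted": est[exposure.trait_name].beta,
                          "beta_display": format_effect(beta2)})

        total = total_by_outcome[out_name]
        beta1 = beta1_by_med[med_name]
        ind = indirect_effect(beta1, beta2)
        crit = qualify_mediator(beta1, beta2, total, layers)
        prop = (proportion_mediated(ind, total, cfg.reporting)
                if total.beta != 0 else None)
        med_results.append(MediationResult(out_name, med_name, total, beta1,
                                           beta2, ind, prop, crit,
                                           crit.qualified))
    mediator_cvd = pd.DataFrame(pair_rows)
    if not mediator_cvd.empty:
        bonf_pair = apply_bonferroni(mediator_cvd["pvalue"], n_pair_tests)
        mediator_cvd["significant"] = bonf_pair.flags
        mediator_cvd["alpha"] = bonf_pair.threshold

    # --- mediation table (qualified pairs only, Table-2 shape) ----------------
    mediation_rows = []
    for r in med_results:
        if not r.qualified:
            log("pair_not_qualified", outcome=r.outcome, mediator=r.mediator,
                bw_mediator=r.criteria.bw_mediator,
                mediator_outcome=r.criteria.mediator_outcome,
                direction=r.criteria.direction)
            continue
        mediation_rows.append({
            "outcome": r.outcome, "mediator": r.mediator,
            "total_effect": format_effect(r.total),
            "beta1": format_effect(r.beta1),
            "beta2": format_effect(r.beta2),
            "indirect": r.indirect.value, "indirect_se": r.indirect.se,
            "proportion_pct": r.proportion.percent,
            "proportion_display": (f"{r.proportion.percent:.2f}% "
                                   f"({r.proportion.ci_low:.2f}% to "
                                   f"{min(r.proportion.ci_high, 100.0):.2f}%)"),
        })
    mediation = pd.DataFrame(mediation_rows)

    # --- sensitivity analyses -------------------------------------------------
    sens_rows = []
    tog = cfg.sensitivity
    for name, h in h_by_outcome.items():
        pair_id = f"{exposure.trait_name}->{name}"
        est = total_by_outcome[name]
        try:
            q = cochrans_q(h, ivw(h, model="fixed"))
            sens_rows.append({"pair": pair_id, "method": "cochrans_q",
                              "value": q.Q, "se": np.nan, "pvalue": q.pvalue})
        except MRError as exc:
            log("sensitivity_failed", pair=pair_id, method="cochrans_q",
                reason=str(exc))
        methods = []
        if tog.egger:
            methods.append(("egger", lambda hh: mr_egger(hh)))
        if tog.median:
            methods.append(("weighted_median",
                            lambda hh: weighted_median(
                                hh, n_boot=cfg.n_boot,
                                seed=_pair_seed(cfg.seed or 0, pair_id, "median"))))
        if tog.mode:
            methods.append(("weighted_mode",
                            lambda hh: weighted_mode(
                                hh, n_boot=cfg.n_boot,
                                seed=_pair_seed(cfg.seed or 0, pair_id, "mode"))))
        for label, fn in methods:
            try:
                res = fn(h)
            except MRError as exc:
                log("sensitivity_failed", pair=pair_id, method=label,
                    reason=str(exc))
                continue
            if label == "egger":
                sens_rows.append({"pair": pair_id, "method": "egger_slope",
                                  "value": res.slope.beta, "se": res.slope.se,
                                  "pvalue": res.slope.pvalue})
                sens_rows.append({"pair": pair_id, "method": "egger_intercept",
                                  "value": res.intercept, "se": res.intercept_se,
                                  "pvalue": res.intercept_pvalue})
            else:
                sens_rows.append({"pair": pair_id, "method": label,
                                  "value": res.beta, "se": res.se,
                                  "pvalue": res.pvalue})
        if tog.presso:
            try:
                pr = presso(h, n_sim=cfg.presso_n_sim,
                            seed=_pair_seed(cfg.seed or 0, pair_id, "presso"))
                sens_rows.append({"pair": pair_id, "method": "presso_global",
                                  "value": pr.rss_obs, "se": np.nan,
                                  "pvalue": pr.global_p})
                sens_rows.append({"pair": pair_id, "method": "presso_corrected",
                                  "value": pr.corrected.beta,
                                  "se": pr.corrected.se,
                                  "pvalue": pr.corrected.pvalue})
                for vid in pr.outlier_ids:
                    log("presso_outlier", pair=pair_id, variant_id=vid)
            except MRError as exc:
                log("sensitivity_failed", pair=pair_id, method="presso",
                    reason=str(exc))
        if tog.loo:
            try:
                loo = leave_one_out(h, model=cfg.ivw_model)
                betas = np.array([e.beta for _, e in loo])
                worst = loo[int(np.argmax(np.abs(betas - est.beta)))]
                sens_rows.append({"pair": pair_id, "method": "loo_max_shift",
                                  "value": worst[1].beta, "se": worst[1].se,
                                  "pvalue": worst[1].pvalue})
            except MRError as exc:
                log("sensitivity_failed", pair=pair_id, method="loo",
                    reason=str(exc))
    if tog.overlap_exclusion:
        settings = cfg.mediation_settings(layers)
        for r in med_results:
            if not r.qualified:
                continue
            ov = overlap_sensitivity(exposure, mediators[r.mediator],
                                     outcomes[r.outcome], settings)
            if not ov.estimable:
                log("overlap_non_estimable", outcome=r.outcome,
                    mediator=r.mediator, n_excluded=ov.n_excluded_overlap)
                continue
            sens_rows.append({"pair": f"{r.mediator}->{r.outcome}",
                              "method": "overlap_excluded_proportion",
                              "value": (ov.proportion.percent
                                        if ov.proportion else np.nan),
                              "se": np.nan, "pvalue": np.nan})
            log("overlap_exclusion", outcome=r.outcome, mediator=r.mediator,
                n_excluded=ov.n_excluded_overlap)
    sensitivity = pd.DataFrame(sens_rows)

    # --- sankey edge list ------------------------------------------------------
    edges = []
    for row in bw_cvd.itertuples(index=False):
        if getattr(row, "significant", False):
            edges.append({"source": exposure.trait_name, "target": row.outcome,
                          "effect": row.beta, "width": abs(row.beta)})
    qualified = {(r.outcome, r.mediator) for r in med_results if r.qualified}
    for r in med_results:
        if not r.qualified:
            continue
        edges.append({"source": exposure.trait_name, "target": r.mediator,
                      "effect": r.beta1.beta, "width": abs(r.beta1.beta)})
        edges.append({"source": r.mediator, "target": r.outcome,
                      "effect": r.beta2.beta, "width": abs(r.beta2.beta)})
    sankey = (pd.DataFrame(edges).drop_duplicates()
              if edges else pd.DataFrame(columns=["source", "target",
                                                  "effect", "width"]))

    report = StudyReport(bw_cvd, bw_med, mediator_cvd, mediation,
                         sensitivity, sankey, qc, events)
    _write_report(report, cfg, outdir)
    return report


def _write_report(report: StudyReport, cfg: StudyConfig, outdir: Path) -> None:
    tables = {
        "bw_cvd_table.tsv": report.bw_cvd_table,
        "bw_mediator_table.tsv": report.bw_mediator_table,
        "mediator_cvd_table.tsv": report.mediator_cvd_table,
        "mediation_table.tsv": report.mediation_table,
        "sensitivity.tsv": report.sensitivity_block,
        "sankey_edges.tsv": report.sankey_edges,
        "instrument_qc.tsv": report.instrument_qc,
    }
    for fname, df in tables.items():
        df.to_csv(outdir / fname, sep="\t", index=False)
    with open(outdir / "events.jsonl", "w") as fh:
        for ev in report.events:
            fh.write(json.dumps(ev, sort_keys=True, default=str) + "\n")
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"# run at {datetime.datetime.now().isoformat()}\n")
        fh.write(f"seed: {cfg.seed}\n")
        fh.write(f"p_threshold: {cfg.p_threshold}\n")
        fh.write(f"r2_max: {cfg.r2_max}\nwindow_kb: {cfg.window_kb}\n")
        for ev in report.events:
            fh.write(json.dumps(ev, sort_keys=True, default=str) + "\n")
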