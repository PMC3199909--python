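"""End-to-end study orchestration.

Order of stages: generate (or load) -> split -> calibrate -> outfit filter +
refit -> DIF screen (report only by default) -> 30-item CAT on the
calibration group -> cutoff at target specificity -> fixed-length comparison
table -> decision-rule CAT on the validation group -> validity and
efficiency reports.  The cutoff is fixed before any validation datum is
touched.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cat as cat_mod
from . import dif as dif_mod
from . import evaluation as eval_mod
from . import pcm as pcm_mod
from . import synth as synth_mod
from .data import ItemBank, ResponseMatrix, validate_persons

log = logging.getLogger("psychocat")

__all__ = ["StudyConfig", "StudyReport", "run_full_study", "load_external_study"]


@dataclass
class StudyConfig:
    """Every tunable of the full study, with screening-design defaults."""

    # cohort
    n_persons: int = 2041
    n_calibration: int = 1650
    design: str = "four_block"
    # synthetic bank
    n_core: int = 118
    n_short: int = 25
    n_categories: int = 3
    location_low: float = -2.0
    location_high: float = 3.0
    spread: float = 1.0
    # synthetic population
    theta_shift: float = -4.0
    lognorm_mu: float = 0.5
    lognorm_sigma: float = 0.6
    treatment_intercept: float = synth_mod.TREATMENT_INTERCEPT
    treatment_slope: float = synth_mod.TREATMENT_SLOPE
    # calibration
    quadrature_nodes: int = 61
    max_iter: int = 500
    tol: float = 1.0e-6
    outfit_threshold: float = 1.7
    # DIF screen
    dif_alpha: float = 0.05
    dif_r2_threshold: float = 0.035
    remove_dif_items: bool = False
    # CAT
    cutoff_cat_items: int = 30
    fixed_n_set: tuple[int, ...] = (5, 10, 20, 30)
    precision_halfwidth: float = 0.5
    decision_confidence: float = 0.95
    decision_max_items: int = 100
    target_specificity: float = 0.90
    exclude_core_items: bool = False
    # external data (synthetic when unset)
    responses_path: str | None = None
    persons_path: str | None = None
    bank_path: str | None = None
    # master seed
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_n_set"] = list(self.fixed_n_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "fixed_n_set" in d:
            d["fixed_n_set"] = tuple(d["fixed_n_set"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudyReport:
    config: dict
    calibration_summary: dict
    dif_table: list[dict]
    prior: dict
    cutoff: float
    table3: list[dict]
    validation_clinical: dict
    validation_treated: dict
    efficiency: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_external_study(
    responses_path: str | Path,
    persons_path: str | Path,
    bank_path: str | Path | None = None,
    design: str = "four_block",
) -> tuple[ItemBank | None, pd.DataFrame, ResponseMatrix]:
    """Load user-supplied CSVs under the synth serialization contracts.

    ``theta_true`` may be absent; truth-requiring diagnostics are then
    skipped downstream.
    """
    persons = pd.read_csv(persons_path)
    validate_persons(persons)
    bank = ItemBank.from_csv(bank_path) if bank_path else None
    responses = ResponseMatrix.from_csv(
        Path(responses_path),
        design=design,
        person_ids=persons["id"].to_numpy(int),
        item_ids=bank.ids if bank is not None else None,
    )
    if bank is not None:
        responses.validate_against(bank)
    return bank, persons, responses


def moment_matched_prior(theta_hat: np.ndarray, shift: float,
                         grid: np.ndarray) -> tuple[cat_mod.GridPrior, dict]:
    """Shifted-lognormal prior whose mean/variance match the estimates."""
    excess = np.asarray(theta_hat, float) - shift
    excess = excess[excess > 1e-6]
    m, v = float(excess.mean()), float(excess.var())
    sigma2 = float(np.log1p(v / m**2))
    sigma = max(np.sqrt(sigma2), 1e-3)
    mu = float(np.log(m) - sigma2 / 2)
    prior = cat_mod.lognormal_prior(grid, shift=shift, mu=mu, sigma=sigma)
    return prior, {"shift": shift, "mu": mu, "sigma": sigma}


def _fixed_prefix_scores(traces: list[cat_mod.CatTrace], k: int) -> np.ndarray:
    """theta after the first min(k, n) items of each stored trajectory.

    Valid because item selection does not depend on the stopping rule: a
    fixed-k run with the same seed administers a prefix of a longer run.
    """
    return np.array([t.theta_path[min(k, t.n_items) - 1] for t in traces])


def run_full_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0])
        for name, child in zip(
            ("synth", "split", "cat_calib", "cat_precision", "cat_valid", "eval"),
            ss.spawn(6),
        )
    }

    # ---- stage 1: data -----------------------------------------------------
    if config.responses_path:
        bank, persons, responses = load_external_study(
            config.responses_path, config.persons_path, config.bank_path,
            design=config.design,
        )
        if bank is None:
            raise ValueError("external studies require a bank file for category counts")
        log.info("stage=data source=external persons=%d items=%d",
                 len(persons), len(bank))
    else:
        bank, persons, responses = synth_mod.generate_study(
            n_persons=config.n_persons,
            bank_kwargs=dict(
                n_core=config.n_core, n_short=config.n_short,
                n_categories=config.n_categories,
                location_low=config.location_low,
                location_high=config.location_high, spread=config.spread,
            ),
            population_kwargs=dict(
                theta_shift=config.theta_shift, lognorm_mu=config.lognorm_mu,
                lognorm_sigma=config.lognorm_sigma,
                treatment_intercept=config.treatment_intercept,
                treatment_slope=config.treatment_slope,
            ),
            design=config.design,
            seed=seeds["synth"],
        )
        log.info("stage=synth persons=%d items=%d seed=%d",
                 len(persons), len(bank), seeds["synth"])
    if out is not None:
        bank.to_csv(out / "bank.csv")
        persons.to_csv(out / "persons.csv", index=False)
        responses.to_csv(out / "responses.csv")

    # ---- stage 2: split ----------------------------------------------------
    split = eval_mod.split_sample(persons["id"], config.n_calibration,
                                  seed=seeds["split"])
    resp_cal = responses.subset_persons(split.calibration_ids)
    persons_idx = persons.set_index("id")
    pers_cal = persons_idx.loc[split.calibration_ids].reset_index()
    pers_val = persons_idx.loc[split.validation_ids].reset_index()
    log.info("stage=split calibration=%d validation=%d",
             len(split.calibration_ids), len(split.validation_ids))

    # ---- stage 3: calibration + outfit filter ------------------------------
    calib = pcm_mod.fit_pcm(
        resp_cal, bank, quadrature_nodes=config.quadrature_nodes,
        max_iter=config.max_iter, tol=config.tol,
    )
    calib.outfit = pcm_mod.outfit(
        pcm_mod.apply_category_maps(resp_cal, calib.category_maps),
        calib.bank, calib.person_theta,
    )
    filt = pcm_mod.filter_items(calib, responses=resp_cal,
                                threshold=config.outfit_threshold)
    fitted = filt.calibration
    log.info("stage=calibrate loglik=%.2f psi=%.3f removed=%d converged=%s",
             fitted.loglik, fitted.psi, len(filt.removed), fitted.converged)
    # downstream stages score on the (possibly collapsed) calibrated scale
    resp_cal = pcm_mod.apply_category_maps(resp_cal, fitted.category_maps)
    responses = pcm_mod.apply_category_maps(responses, fitted.category_maps)

    # ---- stage 4: DIF screen ----------------------------------------------
    resp_cal_kept = resp_cal.subset_items(fitted.bank.ids)
    dif_table = dif_mod.dif_screen(
        resp_cal_kept, fitted.bank, fitted.person_theta, pers_cal,
        alpha=config.dif_alpha, r2_threshold=config.dif_r2_threshold,
    )
    flagged_ids = dif_table.loc[dif_table["flagged"], "item_id"].tolist()
    log.info("stage=dif screened=%d flagged=%d", len(dif_table), len(flagged_ids))

    pool_bank = fitted.bank.copy()
    if config.remove_dif_items and flagged_ids:
        pool_bank.retained &= ~np.isin(pool_bank.ids, flagged_ids)
    if config.exclude_core_items:
        pool_bank.retained &= np.asarray(pool_bank.blocks) != "A"
    pool_bank = pool_bank.retained_bank()

    # ---- stage 5: prior + cutoff from 30-item CAT on calibration -----------
    grid_upper = max(6.0, float(fitted.person_theta.max()) + 2.0)
    grid = cat_mod.default_grid(config.theta_shift, grid_upper,
                                config.quadrature_nodes)
    prior, prior_params = moment_matched_prior(
        fitted.person_theta, config.theta_shift, grid
    )

    resp_cal_pool = resp_cal.subset_items(pool_bank.ids)
    k_max = max(config.cutoff_cat_items, max(config.fixed_n_set))
    traces_cal = cat_mod.simulate_cat_cohort(
        resp_cal_pool, pool_bank,
        cat_mod.StoppingRule.fixed_n(k_max), prior, seed=seeds["cat_calib"],
    )
    scores_30 = _fixed_prefix_scores(traces_cal, config.cutoff_cat_items)
    clin_cal = pers_cal["clinical"].to_numpy(bool)
    cutoff = eval_mod.choose_cutoff(scores_30, clin_cal,
                                    config.target_specificity)
    log.info("stage=cutoff value=%.4f target_specificity=%.2f",
             cutoff, config.target_specificity)

    # ---- stage 6: fixed-length comparison table ----------------------------
    table3 = []
    for k in sorted(config.fixed_n_set):
        sc = _fixed_prefix_scores(traces_cal, k)
        rep = eval_mod.evaluate_decisions(
            sc, clin_cal, cutoff, group="calibration", criterion="clinical",
            seed=seeds["eval"],
        )
        table3.append({
            "rule": f"fixed_{k}", "n_items": k,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "auc": rep.auc, "auc_ci": list(rep.auc_ci),
        })
    traces_prec = cat_mod.simulate_cat_cohort(
        resp_cal_pool, pool_bank,
        cat_mod.StoppingRule.precision(config.precision_halfwidth,
                                       cutoff=cutoff,
                                       max_items=config.decision_max_items),
        prior, seed=seeds["cat_calib"],
    )
    sc_prec = np.array([t.theta_hat for t in traces_prec])
    rep_prec = eval_mod.evaluate_decisions(
        sc_prec, clin_cal, cutoff, group="calibration", criterion="clinical",
        seed=seeds["eval"],
    )
    table3.append({
        "rule": "precision", "n_items": float(np.mean([t.n_items for t in traces_prec])),
        "sensitivity": rep_prec.sensitivity, "specificity": rep_prec.specificity,
        "auc": rep_prec.auc, "auc_ci": list(rep_prec.auc_ci),
    })
    log.info("stage=table3 rows=%d", len(table3))

    # ---- stage 7: decision-rule CAT on validation --------------------------
    resp_val_pool = responses.subset_persons(split.validation_ids).subset_items(
        pool_bank.ids
    )
    rule = cat_mod.StoppingRule.decision(
        cutoff, confidence=config.decision_confidence,
        max_items=config.decision_max_items,
    )
    traces_val = cat_mod.simulate_cat_cohort(
        resp_val_pool, pool_bank, rule, prior, seed=seeds["cat_valid"]
    )

    # full-pool posterior scores, for reports and the efficiency summary
    tables = cat_mod._BankTables(pool_bank, grid=prior.grid)
    full_scores = np.empty(resp_val_pool.n_persons)
    for n in range(resp_val_pool.n_persons):
        row = resp_val_pool.values[n]
        admin = [
            (int(resp_val_pool.item_ids[j]), int(row[j]))
            for j in np.flatnonzero(~np.isnan(row))
        ]
        full_scores[n], _, _ = cat_mod.posterior_update(admin, pool_bank, prior)

    decisions = np.array([t.decision for t in traces_val])
    theta_val = np.array([t.theta_hat for t in traces_val])
    # undecided persons are classified by the side of their point estimate
    positive = np.where(decisions == "undecided", theta_val >= cutoff,
                        decisions == "above")

    clin_val = pers_val["clinical"].to_numpy(bool)
    treat_val = pers_val["treated"].to_numpy(bool)
    eff = eval_mod.efficiency_summary(
        traces_val, full_scores, pers_val["criterion_score"].to_numpy(float)
    )
    report_clin = eval_mod.evaluate_decisions(
        theta_val, clin_val, cutoff, group="validation", criterion="clinical",
        efficiency=eff, seed=seeds["eval"],
    )
    try:
        report_treat = eval_mod.evaluate_decisions(
            theta_val, treat_val, cutoff, group="validation", criterion="treated",
            seed=seeds["eval"],
        ).to_dict()
    except ValueError as exc:  # tiny cohorts may have a single treated class
        log.warning("stage=validate treated criterion degenerate: %s", exc)
        report_treat = {"criterion": "treated", "error": str(exc)}
    log.info("stage=validate auc=%.3f sens=%.3f spec=%.3f decided=%.2f",
             report_clin.auc, report_clin.sensitivity,
             report_clin.specificity, eff["decided_fraction"])

    report = StudyReport(
        config=config.to_dict(),
        calibration_summary={
            "n_items_fitted": len(calib.bank),
            "n_items_removed": len(filt.removed),
            "removed_items": [
                {"item_id": i, "outfit": o} for i, o in filt.removed
            ],
            "psi": fitted.psi,
            "loglik": fitted.loglik,
            "converged": bool(fitted.converged),
            "latent_mu": fitted.latent_mu,
            "latent_sigma": fitted.latent_sigma,
        },
        dif_table=dif_table.to_dict("records"),
        prior=prior_params,
        cutoff=float(cutoff),
        table3=table3,
        validation_clinical=report_clin.to_dict(),
        validation_treated=report_treat,
        efficiency=eff,
        provenance={
            "seed": config.seed,
            "stage_seeds": seeds,
            "runtime_s": round(time.time() - t0, 2),
        },
    )

    if out is not None:
        _write_intermediates(out, fitted, filt, dif_table, traces_val,
                             theta_val, clin_val, report)
    return report


def _write_intermediates(out: Path, fitted, filt, dif_table, traces_val,
                         theta_val, clin_val, report) -> None:
    calibration = {
        "item_ids": fitted.bank.ids.tolist(),
        "thresholds": [t.tolist() for t in fitted.bank.thresholds],
        "threshold_se": [s.tolist() for s in fitted.threshold_se],
        "locations": fitted.bank.locations.tolist(),
        "outfit": None if fitted.outfit is None else np.asarray(fitted.outfit).tolist(),
        "psi": fitted.psi,
        "removed_items": filt.removed,
        "latent_mu": fitted.latent_mu,
        "latent_sigma": fitted.latent_sigma,
        "loglik": fitted.loglik,
        "converged": bool(fitted.converged),
        "n_iterations": fitted.n_iterations,
    }
    (out / "calibration.json").write_text(
        json.dumps(calibration, indent=2, default=_jsonable)
    )
    dif_table.to_csv(out / "dif.csv", index=False)
    pd.DataFrame([t.to_record() for t in traces_val]).to_csv(
        out / "cat_traces.csv", index=False
    )
    (out / "cat_traces.json").write_text(json.dumps(
        [
            {**t.to_record(), "theta_path": t.theta_path, "se_path": t.se_path,
             "responses": t.responses, "administered": t.administered}
            for t in traces_val
        ],
        default=_jsonable,
    ))
    roc, _, _ = eval_mod.roc_and_auc(theta_val, clin_val, n_boot=1)
    roc.to_csv(out / "roc.csv", index=False)
    report.to_json(out / "study_report.json")
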