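"""End-to-end study workflow at synthetic scale.

Mirrors the published analysis sequence: fit the original model on a
derivation trial cohort; externally validate it (discrimination,
calibration, benefit quintiles, c-for-benefit) on an independent trial
cohort; update the model (likelihood-ratio test for adding the nonlinear
glucose term, test for dropping prior stroke, refit on the pooled data with
a derivation-vs-validation cohort indicator); then validate the updated
model on an all-treated registry cohort using the reperfusion surrogate
(three benefit classes cut at 1% and 10%, surrogate c-for-benefit) and
report the intercept recalibration offset for the registry.

A master seed fans out to fixed per-stage seeds through
``numpy.random.SeedSequence([master_seed, stage_id])``, so adding a stage
never perturbs earlier ones, and rerunning a config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benefit as bn
from . import cohort as ch
from . import fitting as ft
from . import validation as vl
from .model import FittedOrdinalModel, original_spec, updated_spec

__all__ = ["StudyConfig", "StageError", "run_study", "default_study_config"]

# fixed stage ids for seed fan-out; never renumber
STAGE_IDS = {
    "generate_derivation": 0,
    "generate_validation": 1,
    "generate_registry": 2,
    "first_validation_bootstrap": 4,
    "first_validation_matching": 5,
    "registry_validation_bootstrap": 7,
    "registry_matching": 8,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class StudyConfig:
    """Scenario + analysis settings of one synthetic study run."""

    derivation: ch.CohortSpec
    validation: ch.CohortSpec
    registry: ch.CohortSpec
    bootstrap_B: int = 2000
    imputation_policy: str = "single_regression"
    imputation_threshold: float = 0.05
    glucose_form: str = "piecewise_linear"
    master_seed: int = 0
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.bootstrap_B < 40:
            raise ValueError("bootstrap_B must be >= 40")
        if self.registry.design != "registry":
            raise ValueError("registry cohort spec must have design='registry'")
        for spec in (self.derivation, self.validation):
            if spec.design != "rct":
                raise ValueError("derivation and validation specs must be RCTs")

    def to_dict(self) -> dict:
        return {
            "derivation": self.derivation.to_dict(),
            "validation": self.validation.to_dict(),
            "registry": self.registry.to_dict(),
            "bootstrap_B": self.bootstrap_B,
            "imputation_policy": self.imputation_policy,
            "imputation_threshold": self.imputation_threshold,
            "glucose_form": self.glucose_form,
            "master_seed": self.master_seed,
            "make_figures": self.make_figures,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("derivation", "validation", "registry"):
            d[key] = ch.CohortSpec.from_dict(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed; independent of other stages."""
    ss = np.random.SeedSequence([int(master_seed), STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def default_study_config(
    n_derivation: int = 2000,
    n_validation: int = 2000,
    n_registry: int = 2000,
    master_seed: int = 0,
    bootstrap_B: int = 2000,
    **overrides,
) -> StudyConfig:
    """A ready-to-run scenario with the default generator settings.

    Missingness mimics the motivating cohorts: collateral grade missing in
    a third of patients, a few percent elsewhere.
    """
    missing = {"collateral_grade": 0.33, "glucose": 0.03, "sbp": 0.03, "aspects": 0.03}
    mk = lambda n, stage, design, label, **kw: ch.CohortSpec(  # noqa: E731
        n=n,
        design=design,
        label=label,
        seed=stage_seed(master_seed, stage),
        missingness=dict(missing),
        **kw,
    )
    return StudyConfig(
        derivation=mk(n_derivation, "generate_derivation", "rct", "derivation"),
        validation=mk(n_validation, "generate_validation", "rct", "validation"),
        registry=mk(
            n_registry, "generate_registry", "registry", "registry", p_reperf=0.6
        ),
        master_seed=master_seed,
        bootstrap_B=bootstrap_B,
        **overrides,
    )


def _prepare(cohort_spec: ch.CohortSpec, config: StudyConfig) -> pd.DataFrame:
    raw = ch.generate_cohort(cohort_spec).df
    if cohort_spec.missingness:
        masked = ch.inject_missingness(
            raw, cohort_spec.missingness, seed=cohort_spec.seed + 1
        )
        completed = ch.impute(
            ch.drop_missing_outcomes(masked),
            policy=config.imputation_policy,
            threshold=config.imputation_threshold,
        )
        # latent potential outcomes pass through untouched for oracle use
        return completed
    return raw


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_study(config: StudyConfig, outdir) -> dict:
    """Execute the full derive / validate / update / re-validate workflow.

    Writes all artifacts (cohort CSVs, model JSONs, validation tables,
    benefit tables, matched-pair audits, the report bundle) under
    ``outdir``; returns the report bundle as a dict. Rerunning with the same
    config produces bit-identical artifacts. Any stage failure raises
    :class:`StageError` after persisting the artifacts produced so far.
    """
    out = Path(outdir)
    (out / "cohorts").mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    report: dict = {
        "config_fingerprint": config.fingerprint(),
        "master_seed": config.master_seed,
        "stage_seeds": {k: stage_seed(config.master_seed, k) for k in STAGE_IDS},
    }
    _json_dump(config.to_dict(), out / "config.json")

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            _json_dump(report, out / "report.json")
            raise StageError(name, exc) from exc

    # -- cohorts ----------------------------------------------------------
    def gen(label: str, spec: ch.CohortSpec) -> pd.DataFrame:
        df = _prepare(spec, config)
        ch.write_cohort_csv(df, out / "cohorts" / f"{label}.csv")
        return df

    deriv = stage("generate_derivation", lambda: gen("derivation", config.derivation))
    valid = stage("generate_validation", lambda: gen("validation", config.validation))
    registry = stage("generate_registry", lambda: gen("registry", config.registry))
    report["n"] = {"derivation": len(deriv), "validation": len(valid), "registry": len(registry)}

    # -- derive -----------------------------------------------------------
    def fit_original() -> FittedOrdinalModel:
        m = ft.fit_model(deriv, original_spec())
        m.to_json(out / "models" / "original.json")
        return m

    model_orig = stage("fit_original", fit_original)

    # -- first external validation ---------------------------------------
    def first_validation() -> dict:
        rep = vl.validate_external(
            model_orig,
            valid,
            B=config.bootstrap_B,
            seed=stage_seed(config.master_seed, "first_validation_bootstrap"),
            label="validation",
        )
        rep.to_json(out / "validation_first.json")
        rep.to_csv(out / "validation_first.csv")

        scored = valid.copy()
        scored["benefit"] = model_orig.predicted_benefit(valid)["benefit"].to_numpy()
        quint = bn.benefit_group_calibration(scored, grouping="quintiles")
        quint.to_csv(out / "benefit_quintiles_first.csv")
        pairs = bn.match_by_predicted_benefit(
            scored, seed=stage_seed(config.master_seed, "first_validation_matching")
        )
        pairs.to_csv(out / "pairs_first.csv")
        cfb = bn.c_for_benefit(pairs)
        return {
            "validation": rep.to_dict(),
            "c_for_benefit": cfb,
            "n_pairs": len(pairs),
            "benefit_quintiles": quint.table.to_dict(orient="records"),
        }

    report["first_validation"] = stage("first_validation", first_validation)

    # -- model updating ---------------------------------------------------
    def update() -> tuple[FittedOrdinalModel, dict]:
        combined = pd.concat([deriv, valid], ignore_index=True)
        upd_spec = updated_spec(config.glucose_form)

        base = ft.refit_with_cohort_adjustment(combined, original_spec())
        with_glucose = ft.refit_with_cohort_adjustment(
            combined,
            dataclasses.replace(
                original_spec(), include_glucose=True, glucose=upd_spec.glucose
            ),
        )
        lr_glucose = ft.lr_test(with_glucose, base)

        updated_full = ft.refit_with_cohort_adjustment(combined, upd_spec)
        with_prior = ft.refit_with_cohort_adjustment(
            combined,
            dataclasses.replace(
                upd_spec,
                include_prior_stroke=True,
                interactions=upd_spec.interactions,
            ),
        )
        lr_prior = ft.lr_test(with_prior, updated_full)

        updated_full.to_json(out / "models" / "updated.json")
        tests = {
            "add_glucose": dataclasses.asdict(lr_glucose),
            "drop_prior_stroke": dataclasses.asdict(lr_prior),
        }
        _json_dump(tests, out / "lr_tests.json")
        return updated_full, tests

    model_upd, lr_results = stage("model_updating", update)
    report["lr_tests"] = lr_results

    # -- second validation: registry --------------------------------------
    def registry_validation() -> dict:
        # predictions at the validation-cohort baseline level
        m = model_upd.with_cohort_baseline("validation")
        recal = ft.recalibrate_intercepts(m, registry)
        delta = float(recal.diagnostics["intercept_shift"])
        _json_dump({"delta": delta}, out / "recalibration.json")

        rep = vl.validate_external(
            m,
            registry,
            B=config.bootstrap_B,
            seed=stage_seed(config.master_seed, "registry_validation_bootstrap"),
            label="registry",
        )
        rep.to_json(out / "validation_registry.json")
        rep.to_csv(out / "validation_registry.csv")

        scored = registry.copy()
        scored["benefit"] = m.predicted_benefit(registry)["benefit"].to_numpy()
        classes = bn.registry_surrogate_benefit(scored, grouping="classes")
        classes.to_csv(out / "benefit_classes_registry.csv")
        pairs = bn.match_by_predicted_benefit(
            scored,
            seed=stage_seed(config.master_seed, "registry_matching"),
            arm_col="etici_success",
        )
        pairs.to_csv(out / "pairs_registry.csv")
        cfb = bn.c_for_benefit(pairs)
        med = float(np.median(scored["benefit"]))
        return {
            "validation": rep.to_dict(),
            "recalibration_delta": delta,
            "c_for_benefit_surrogate": cfb,
            "n_pairs": len(pairs),
            "median_predicted_benefit": med,
            "benefit_classes": classes.table.to_dict(orient="records"),
        }

    report["registry_validation"] = stage("registry_validation", registry_validation)

    if config.make_figures:
        stage("figures", lambda: _make_figures(model_orig, valid, out))

    _json_dump(report, out / "report.json")
    return report


def _make_figures(model: FittedOrdinalModel, valid: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = model.prob_good(valid)
    y = (valid["mrs_90d"].to_numpy().astype(int) <= 2).astype(int)
    curve = vl.calibration_curve(p, y)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.plot(curve.mean_predicted, curve.observed, "o-")
    ax.set_xlabel("Predicted P(mRS 0-2)")
    ax.set_ylabel("Observed proportion")
    ax.set_title("Calibration, first validation")
    fig.tight_layout()
    fig.savefig(out / "calibration_first.png", dpi=120)
    plt.close(fig)
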