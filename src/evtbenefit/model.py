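"""Cumulative-logit (proportional-odds) model of the 90-day modified Rankin Scale.

The model predicts the full 7-level mRS distribution from eleven baseline
characteristics, with endovascular treatment (EVT) entering both as a main
effect and through interactions with onset-to-groin time, collateral grade
and (in the original configuration) prior stroke. Orientation: the linear
predictor eta enters ``P(mRS <= j) = expit(alpha_j + eta)``, so positive
coefficients mean better outcomes and the probability of functional
independence is literally ``P(mRS <= 2)``.

Individual treatment benefit is the difference in the probability of
functional independence (mRS 0-2) with and without EVT, evaluated by
forcing the treatment indicator (and all its interactions) to 1 and 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .splines import GlucoseTerm, spline_basis

__all__ = [
    "OCCLUSION_LEVELS",
    "N_MRS_LEVELS",
    "MissingPredictorError",
    "InvalidModelError",
    "UnsupportedOperationError",
    "PredictorProfile",
    "ModelSpec",
    "FittedOrdinalModel",
    "BenefitPrediction",
    "original_spec",
    "updated_spec",
    "design_matrix",
    "build_design_row",
]

OCCLUSION_LEVELS = ("ICA/ICA-T", "M1", "M2")
N_MRS_LEVELS = 7

ALLOWED_INTERACTIONS = ("evt:onset_to_groin", "evt:collateral_grade", "evt:prior_stroke")


class MissingPredictorError(ValueError):
    """A predictor required by the model specification is absent or NaN."""


class InvalidModelError(ValueError):
    """Model parameters violate a structural invariant (e.g. cutpoint order)."""


class UnsupportedOperationError(RuntimeError):
    """Operation not defined for this model specification."""


def _check_binary(name: str, value) -> int:
    if value not in (0, 1, 0.0, 1.0, False, True):
        raise ValueError(f"{name} must be 0/1, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class PredictorProfile:
    """One patient's baseline predictors plus treatment/reperfusion indicators.

    Units: age in years, sbp in mmHg, glucose in mg/dL, onset_to_groin in
    minutes from symptom onset (or last seen well) to groin puncture.
    """

    age: float
    nihss: int
    sbp: float
    glucose: float
    iv_alteplase: int
    diabetes: int
    prestroke_mrs: int
    aspects: int
    occlusion_location: str
    collateral_grade: int
    onset_to_groin: float
    prior_stroke: Optional[int] = None
    evt: int = 0
    etici_success: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.nihss <= 42:
            raise ValueError(f"nihss out of [0, 42]: {self.nihss}")
        if self.prestroke_mrs not in range(6):
            raise ValueError(f"prestroke_mrs out of 0..5: {self.prestroke_mrs}")
        if self.aspects not in range(11):
            raise ValueError(f"aspects out of 0..10: {self.aspects}")
        if self.collateral_grade not in range(4):
            raise ValueError(f"collateral_grade out of 0..3: {self.collateral_grade}")
        if self.occlusion_location not in OCCLUSION_LEVELS:
            raise ValueError(
                f"occlusion_location must be one of {OCCLUSION_LEVELS}, "
                f"got {self.occlusion_location!r}"
            )
        if not self.onset_to_groin > 0:
            raise ValueError("onset_to_groin must be positive")
        _check_binary("iv_alteplase", self.iv_alteplase)
        _check_binary("diabetes", self.diabetes)
        _check_binary("evt", self.evt)
        if self.prior_stroke is not None:
            _check_binary("prior_stroke", self.prior_stroke)
        if self.etici_success is not None:
            _check_binary("etici_success", self.etici_success)

    def as_row(self) -> dict:
        return dataclasses.asdict(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.as_row()])


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the linear predictor (terms, glucose form, interactions).

    Coefficient *values* are never part of a spec; they live in fitted
    models or in generator configurations.
    """

    name: str = "custom"
    include_glucose: bool = False
    glucose: GlucoseTerm = field(default_factory=GlucoseTerm)
    include_prior_stroke: bool = False
    include_evt: bool = True
    interactions: tuple[str, ...] = ()
    cohort_adjustment: bool = False
    intercept_only: bool = False

    def __post_init__(self) -> None:
        if self.intercept_only and (self.interactions or self.include_glucose):
            raise ValueError("intercept_only spec cannot carry terms")
        for term in self.interactions:
            if term not in ALLOWED_INTERACTIONS:
                raise ValueError(f"unknown interaction {term!r}")
            if not self.include_evt:
                raise ValueError("interactions require the evt term")
        if "evt:prior_stroke" in self.interactions and not self.include_prior_stroke:
            raise ValueError("evt:prior_stroke interaction requires prior_stroke main term")

    def design_columns(self, cohort_levels: Optional[Sequence[str]] = None) -> list[str]:
        if self.intercept_only:
            if self.cohort_adjustment:
                if cohort_levels is None:
                    raise ValueError("cohort_adjustment spec needs cohort_levels")
                return [f"cohort[{lvl}]" for lvl in list(cohort_levels)[1:]]
            return []
        cols = ["age", "nihss", "sbp"]
        if self.include_glucose:
            cols += self.glucose.column_names
        cols += [
            "iv_alteplase",
            "diabetes",
            "prestroke_mrs",
            "aspects",
            "occ_ica_icat",
            "occ_m2",
            "collateral_grade",
            "onset_to_groin",
        ]
        if self.include_prior_stroke:
            cols.append("prior_stroke")
        if self.cohort_adjustment:
            if cohort_levels is None:
                raise ValueError("cohort_adjustment spec needs cohort_levels")
            cols += [f"cohort[{lvl}]" for lvl in list(cohort_levels)[1:]]
        if self.include_evt:
            cols.append("evt")
            cols += list(self.interactions)
        return cols

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interactions"] = list(self.interactions)
        d["glucose"] = {
            "form": self.glucose.form,
            "knot": self.glucose.knot,
            "rcs_knots": list(self.glucose.rcs_knots),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        g = d.get("glucose")
        if isinstance(g, dict):
            d["glucose"] = GlucoseTerm(
                form=g.get("form", "piecewise_linear"),
                knot=float(g.get("knot", 120.0)),
                rcs_knots=tuple(g.get("rcs_knots", (90.0, 120.0, 180.0))),
            )
        d["interactions"] = tuple(d.get("interactions", ()))
        return cls(**d)


def original_spec() -> ModelSpec:
    """Original model: prior stroke in, glucose out, three EVT interactions."""
    return ModelSpec(
        name="original",
        include_glucose=False,
        include_prior_stroke=True,
        interactions=("evt:onset_to_groin", "evt:collateral_grade", "evt:prior_stroke"),
    )


def updated_spec(glucose_form: str = "piecewise_linear") -> ModelSpec:
    """Updated model: nonlinear glucose in, prior stroke out, two interactions."""
    return ModelSpec(
        name="updated",
        include_glucose=True,
        glucose=GlucoseTerm(form=glucose_form),
        include_prior_stroke=False,
        interactions=("evt:onset_to_groin", "evt:collateral_grade"),
    )


def _column(data: pd.DataFrame, name: str) -> np.ndarray:
    if name not in data.columns:
        raise MissingPredictorError(f"required predictor column {name!r} is absent")
    col = data[name]
    if col.isna().any():
        raise MissingPredictorError(
            f"predictor {name!r} has {int(col.isna().sum())} missing values; impute first"
        )
    return col.to_numpy()


def design_matrix(
    data: pd.DataFrame,
    spec: ModelSpec,
    cohort_levels: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list[str]]:
    """Build the (n, p) design matrix for ``spec`` from a cohort table.

    Categorical occlusion location is coded as two indicators (ICA/ICA-T and
    M2) against the M1 reference; collateral grade enters as a single linear
    0-3 score; interaction columns are the product of their parents.
    """
    n = len(data)
    cols: list[np.ndarray] = []
    names = spec.design_columns(cohort_levels)

    base = {
        "age": lambda: _column(data, "age").astype(float),
        "nihss": lambda: _column(data, "nihss").astype(float),
        "sbp": lambda: _column(data, "sbp").astype(float),
        "iv_alteplase": lambda: _column(data, "iv_alteplase").astype(float),
        "diabetes": lambda: _column(data, "diabetes").astype(float),
        "prestroke_mrs": lambda: _column(data, "prestroke_mrs").astype(float),
        "aspects": lambda: _column(data, "aspects").astype(float),
        "collateral_grade": lambda: _column(data, "collateral_grade").astype(float),
        "onset_to_groin": lambda: _column(data, "onset_to_groin").astype(float),
        "prior_stroke": lambda: _column(data, "prior_stroke").astype(float),
        "evt": lambda: _column(data, "evt").astype(float),
    }

    glucose_cols: Optional[np.ndarray] = None
    if spec.include_glucose:
        glucose_cols = spline_basis(_column(data, "glucose"), spec.glucose)

    occ = None
    cohort_dummies: dict[str, np.ndarray] = {}
    if spec.cohort_adjustment:
        labels = _column(data, "cohort").astype(str)
        known = set(str(x) for x in cohort_levels)
        bad = set(labels) - known
        if bad:
            raise ValueError(f"cohort labels {sorted(bad)} not in model levels {sorted(known)}")
        for lvl in list(cohort_levels)[1:]:
            cohort_dummies[f"cohort[{lvl}]"] = (labels == str(lvl)).astype(float)

    built: dict[str, np.ndarray] = {}

    def get(name: str) -> np.ndarray:
        if name in built:
            return built[name]
        if name in base:
            v = base[name]()
        elif name == "occ_ica_icat" or name == "occ_m2":
            nonlocal occ
            if occ is None:
                occ = _column(data, "occlusion_location").astype(str)
                bad = set(occ) - set(OCCLUSION_LEVELS)
                if bad:
                    raise ValueError(f"unknown occlusion_location values {sorted(bad)}")
            v = (occ == ("ICA/ICA-T" if name == "occ_ica_icat" else "M2")).astype(float)
        elif name.startswith("glucose"):
            idx = spec.glucose.column_names.index(name)
            v = glucose_cols[:, idx]
        elif name.startswith("cohort["):
            v = cohort_dummies[name]
        elif ":" in name:
            a, b = name.split(":")
            v = get(a) * get(b)
        else:  # pragma: no cover - guarded by design_columns
            raise KeyError(name)
        built[name] = v
        return v

    for name in names:
        cols.append(get(name))
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


def build_design_row(profile: PredictorProfile, spec: ModelSpec) -> np.ndarray:
    """Design row for a single patient, deterministic column order per spec."""
    if spec.include_prior_stroke and profile.prior_stroke is None:
        raise MissingPredictorError("predictor 'prior_stroke' is required by this spec")
    if spec.cohort_adjustment:
        raise ValueError("single-profile rows do not support cohort adjustment")
    X, _ = design_matrix(profile.to_frame(), spec)
    return X[0]


@dataclass(frozen=True)
class BenefitPrediction:
    """Predicted probability of functional independence with/without EVT."""

    p_good_treated: float
    p_good_control: float

    @property
    def benefit(self) -> float:
        return self.p_good_treated - self.p_good_control


@dataclass
class FittedOrdinalModel:
    """A fitted (or externally specified) cumulative-logit model.

    ``cutpoints`` are the six strictly increasing thresholds alpha_1..alpha_6
    on the cumulative logits; ``coefficients`` align with
    ``spec.design_columns(cohort_levels)``. ``covariance`` is the estimated
    variance matrix of (alpha, beta) from the inverse observed information,
    or None for models constructed from given parameters.
    """

    spec: ModelSpec
    cutpoints: np.ndarray
    coefficients: np.ndarray
    coef_names: list[str]
    covariance: Optional[np.ndarray] = None
    loglik: float = np.nan
    n_obs: int = 0
    converged: bool = True
    cohort_levels: Optional[tuple[str, ...]] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.cutpoints.shape != (N_MRS_LEVELS - 1,):
            raise InvalidModelError(
                f"expected {N_MRS_LEVELS - 1} cutpoints, got {self.cutpoints.shape}"
            )
        expected = self.spec.design_columns(self.cohort_levels)
        if list(self.coef_names) != expected:
            raise InvalidModelError(
                f"coefficient names {list(self.coef_names)} do not match spec "
                f"columns {expected}"
            )
        if self.coefficients.shape != (len(expected),):
            raise InvalidModelError("coefficient vector length does not match spec columns")

    # -- evaluation -------------------------------------------------------

    def _require_monotone(self) -> None:
        if not np.all(np.diff(self.cutpoints) > 0):
            raise InvalidModelError(f"cutpoints not strictly increasing: {self.cutpoints}")

    def _design(self, data: pd.DataFrame) -> np.ndarray:
        X, _ = design_matrix(data, self.spec, self.cohort_levels)
        return X

    def linear_predictor(self, data) -> np.ndarray:
        if isinstance(data, PredictorProfile):
            data = data.to_frame()
        return self._design(data) @ self.coefficients

    def cumulative_probs(self, data) -> np.ndarray:
        """P(mRS <= j) for j = 0..5, shape (n, 6), nondecreasing in j."""
        self._require_monotone()
        eta = self.linear_predictor(data)
        return expit(self.cutpoints[None, :] + eta[:, None])

    def category_probs(self, data) -> np.ndarray:
        """Probabilities of mRS 0..6, shape (n, 7); rows sum to 1."""
        cum = self.cumulative_probs(data)
        n = cum.shape[0]
        full = np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))])
        return np.diff(full, axis=1)

    def prob_good(self, data) -> np.ndarray:
        """Probability of functional independence, P(mRS <= 2)."""
        self._require_monotone()
        eta = self.linear_predictor(data)
        return expit(self.cutpoints[2] + eta)

    def predicted_benefit(self, data) -> pd.DataFrame:
        """Per-patient benefit: P(mRS 0-2 | evt=1) - P(mRS 0-2 | evt=0).

        The profile's own recorded evt value is ignored; treatment (and its
        interactions, rebuilt from the design) is forced to 1 then 0.
        Returns columns ``p_good_treated``, ``p_good_control``, ``benefit``.
        """
        if not self.spec.include_evt or self.spec.intercept_only:
            raise UnsupportedOperationError(
                "treatment benefit is undefined for a spec without the evt term"
            )
        if isinstance(data, PredictorProfile):
            data = data.to_frame()
        out = {}
        for arm, key in ((1, "p_good_treated"), (0, "p_good_control")):
            forced = data.copy()
            forced["evt"] = arm
            out[key] = self.prob_good(forced)
        res = pd.DataFrame(out, index=data.index)
        res["benefit"] = res["p_good_treated"] - res["p_good_control"]
        return res

    def predict_benefit_profile(self, profile: PredictorProfile) -> BenefitPrediction:
        row = self.predicted_benefit(profile.to_frame()).iloc[0]
        return BenefitPrediction(float(row["p_good_treated"]), float(row["p_good_control"]))

    # -- derived models ---------------------------------------------------

    def shift_cutpoints(self, delta: float) -> "FittedOrdinalModel":
        """Return a copy with all cutpoints shifted by ``delta`` (recalibration)."""
        return dataclasses.replace(
            self,
            cutpoints=self.cutpoints + float(delta),
            coefficients=self.coefficients.copy(),
            diagnostics={**self.diagnostics, "intercept_shift": float(delta)},
        )

    def with_cohort_baseline(self, label: str) -> "FittedOrdinalModel":
        """Absorb a cohort-adjustment offset into the cutpoints.

        Produces a plain (non-adjusted) model whose predictions correspond to
        the named cohort level; indicator rows/cols are dropped from the
        covariance (ignoring their sampling covariance with the rest).
        """
        if not self.spec.cohort_adjustment:
            raise UnsupportedOperationError("model has no cohort adjustment")
        levels = list(self.cohort_levels)
        if label not in levels:
            raise ValueError(f"unknown cohort label {label!r}; levels: {levels}")
        keep = [i for i, nm in enumerate(self.coef_names) if not nm.startswith("cohort[")]
        offset = 0.0
        if label != levels[0]:
            j = self.coef_names.index(f"cohort[{label}]")
            offset = float(self.coefficients[j])
        new_spec = dataclasses.replace(self.spec, cohort_adjustment=False)
        cov = None
        if self.covariance is not None:
            n_alpha = N_MRS_LEVELS - 1
            idx = list(range(n_alpha)) + [n_alpha + i for i in keep]
            cov = self.covariance[np.ix_(idx, idx)]
        return FittedOrdinalModel(
            spec=new_spec,
            cutpoints=self.cutpoints + offset,
            coefficients=self.coefficients[keep],
            coef_names=[self.coef_names[i] for i in keep],
            covariance=cov,
            loglik=self.loglik,
            n_obs=self.n_obs,
            converged=self.converged,
            diagnostics={**self.diagnostics, "cohort_baseline": label},
        )

    # -- uncertainty ------------------------------------------------------

    def se(self) -> Optional[pd.Series]:
        """Standard errors of the coefficients (excludes cutpoints)."""
        if self.covariance is None:
            return None
        n_alpha = N_MRS_LEVELS - 1
        var = np.diag(self.covariance)[n_alpha:]
        return pd.Series(np.sqrt(np.maximum(var, 0.0)), index=self.coef_names)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "cutpoints": self.cutpoints.tolist(),
            "coefficients": self.coefficients.tolist(),
            "coef_names": list(self.coef_names),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "loglik": None if np.isnan(self.loglik) else float(self.loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "cohort_levels": None if self.cohort_levels is None else list(self.cohort_levels),
            "diagnostics": {k: v for k, v in self.diagnostics.items() if _json_safe(v)},
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedOrdinalModel":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            cutpoints=np.asarray(d["cutpoints"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            coef_names=list(d["coef_names"]),
            covariance=None if d.get("covariance") is None else np.asarray(d["covariance"]),
            loglik=np.nan if d.get("loglik") is None else float(d["loglik"]),
            n_obs=int(d.get("n_obs", 0)),
            converged=bool(d.get("converged", True)),
            cohort_levels=None
            if d.get("cohort_levels") is None
            else tuple(d["cohort_levels"]),
            diagnostics=dict(d.get("diagnostics", {})),
        )

    @classmethod
    def from_json(cls, path) -> "FittedOrdinalModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
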