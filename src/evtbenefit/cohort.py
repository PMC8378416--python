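"""Synthetic trial and registry cohorts for the EVT-benefit analysis.

The real derivation and validation cohorts are individual-patient trial and
registry data that are not publicly released, so every stage of the
analysis is exercised on synthetic cohorts with the same statistical
structure: eleven baseline covariates drawn from configurable marginal laws
(independently by default, optionally tied through a Gaussian copula), a
7-level mRS outcome drawn from a proportional-odds model with
treatment-by-time and treatment-by-collateral interactions and a nonlinear
glucose effect, 1:1 randomized (trial) or all-treated with a reperfusion
surrogate (registry) designs, MCAR missingness at per-field rates, and the
mean/mode vs single-regression imputation rule with a 5% threshold.

Both potential outcomes (under evt=0 and evt=1) are drawn with a shared
uniform (comonotone coupling) and retained in underscore-prefixed columns,
so individual-level benefit is well defined in fixtures; all cohort-level
statistics depend only on the marginals.

All defaults are synthetic-but-plausible values chosen for this generator;
none is an estimate from real patients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from ._glm import logistic_fit, softmax_fit, softmax_predict
from .model import (
    N_MRS_LEVELS,
    OCCLUSION_LEVELS,
    FittedOrdinalModel,
    ModelSpec,
    updated_spec,
)

__all__ = [
    "CovariateLaws",
    "TrueOutcomeModel",
    "CohortSpec",
    "Cohort",
    "default_true_model",
    "generate_cohort",
    "inject_missingness",
    "impute",
    "drop_missing_outcomes",
    "read_cohort_csv",
    "write_cohort_csv",
]

# Field typing used by imputation (and CSV round-trips)
CONTINUOUS_FIELDS = ("age", "sbp", "glucose", "onset_to_groin")
COUNT_FIELDS = {"nihss": (0, 42), "aspects": (0, 10)}
BINARY_FIELDS = ("iv_alteplase", "diabetes", "prior_stroke")
ORDINAL_FIELDS = {"prestroke_mrs": 6, "collateral_grade": 4}
NOMINAL_FIELDS = ("occlusion_location",)

PREDICTOR_COLUMNS = (
    "age",
    "nihss",
    "sbp",
    "glucose",
    "iv_alteplase",
    "diabetes",
    "prestroke_mrs",
    "aspects",
    "occlusion_location",
    "collateral_grade",
    "onset_to_groin",
    "prior_stroke",
)


@dataclass(frozen=True)
class CovariateLaws:
    """Marginal laws of the baseline covariates (synthetic defaults).

    Continuous laws are truncated normals or a clipped log-normal (glucose,
    median ~115 mg/dL); categorical laws are multinomials; onset-to-groin is
    uniform within the 6.5 h treatment window. Optional pairwise latent
    correlations (``copula_corr``) tie covariates through a Gaussian copula.
    """

    age_mean: float = 68.0
    age_sd: float = 13.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    nihss_mean: float = 16.0
    nihss_sd: float = 5.0
    sbp_mean: float = 145.0
    sbp_sd: float = 24.0
    sbp_bounds: tuple[float, float] = (80.0, 260.0)
    glucose_log_median: float = 115.0
    glucose_log_sd: float = 0.22
    glucose_bounds: tuple[float, float] = (40.0, 400.0)
    p_iv_alteplase: float = 0.85
    p_diabetes: float = 0.15
    prestroke_mrs_probs: tuple[float, ...] = (0.75, 0.12, 0.06, 0.04, 0.02, 0.01)
    aspects_probs: tuple[float, ...] = (
        0.01, 0.01, 0.02, 0.03, 0.05, 0.07, 0.10, 0.14, 0.18, 0.21, 0.18,
    )
    occlusion_probs: tuple[float, ...] = (0.25, 0.60, 0.15)  # ICA/ICA-T, M1, M2
    collateral_probs: tuple[float, ...] = (0.07, 0.25, 0.40, 0.28)
    onset_to_groin_bounds: tuple[float, float] = (60.0, 390.0)
    p_prior_stroke: float = 0.10
    copula_corr: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for name in ("prestroke_mrs_probs", "aspects_probs", "occlusion_probs", "collateral_probs"):
            probs = np.asarray(getattr(self, name), dtype=float)
            if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-8):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        for name in ("p_iv_alteplase", "p_diabetes", "p_prior_stroke"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} out of [0, 1]")
        lo, hi = self.onset_to_groin_bounds
        if not 0 < lo < hi:
            raise ValueError("onset_to_groin bounds must satisfy 0 < lo < hi")
        for a, b, r in self.copula_corr:
            if a not in PREDICTOR_COLUMNS or b not in PREDICTOR_COLUMNS:
                raise ValueError(f"copula_corr names unknown: {(a, b)}")
            if not -1 < r < 1:
                raise ValueError("copula correlations must be in (-1, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["copula_corr"] = [list(t) for t in self.copula_corr]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateLaws":
        d = dict(d)
        for key, val in d.items():
            if isinstance(val, list) and key != "copula_corr":
                d[key] = tuple(val)
        d["copula_corr"] = tuple(tuple(t) for t in d.get("copula_corr", ()))
        return cls(**d)


@dataclass(frozen=True)
class TrueOutcomeModel:
    """Generating proportional-odds model: spec + cutpoints + coefficients.

    Coefficient names must be design columns of ``spec``; unnamed columns
    get coefficient 0.
    """

    spec: ModelSpec
    cutpoints: tuple[float, ...]
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cutpoints, dtype=float)
        if cuts.shape != (N_MRS_LEVELS - 1,) or not np.all(np.diff(cuts) > 0):
            raise ValueError("cutpoints must be 6 strictly increasing values")
        cols = self.spec.design_columns()
        unknown = set(self.coefficients) - set(cols)
        if unknown:
            raise ValueError(f"coefficients for unknown design columns: {sorted(unknown)}")

    def as_model(self) -> FittedOrdinalModel:
        cols = self.spec.design_columns()
        beta = np.array([float(self.coefficients.get(c, 0.0)) for c in cols])
        return FittedOrdinalModel(
            spec=self.spec,
            cutpoints=np.asarray(self.cutpoints, dtype=float),
            coefficients=beta,
            coef_names=cols,
            converged=True,
        )

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "cutpoints": list(self.cutpoints),
            "coefficients": dict(self.coefficients),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueOutcomeModel":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            cutpoints=tuple(d["cutpoints"]),
            coefficients=dict(d.get("coefficients", {})),
        )


def default_true_model() -> TrueOutcomeModel:
    """Default generating model: updated structure with both interactions.

    Orientation: positive coefficients mean better outcomes. Glucose slopes
    are -0.003047 per mg/dL below 120 and -0.002020 above (odds ratios 0.97
    and 0.98 per 10 mg/dL for a *worse* outcome orientation, sign-flipped
    here). Cutpoints are set so the control arm sees a realistic mRS spread
    (~30% functional independence) under the default covariate laws.
    """
    return TrueOutcomeModel(
        spec=updated_spec(),
        cutpoints=(1.34, 2.26, 2.93, 3.58, 4.19, 5.52),
        coefficients={
            "age": -0.035,
            "nihss": -0.09,
            "sbp": -0.006,
            "glucose": -0.003047,
            "glucose_hinge": 0.001027,  # slope above 120 = -0.002020
            "iv_alteplase": 0.35,
            "diabetes": -0.35,
            "prestroke_mrs": -0.45,
            "aspects": 0.12,
            "occ_ica_icat": -0.55,
            "occ_m2": 0.20,
            "collateral_grade": 0.35,
            "onset_to_groin": -0.0015,
            "evt": 0.75,
            "evt:onset_to_groin": -0.002,
            "evt:collateral_grade": 0.15,
        },
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generative scenario: design, laws, true model, missingness, seed."""

    n: int
    design: str = "rct"  # "rct" (1:1) or "registry" (all treated)
    laws: CovariateLaws = field(default_factory=CovariateLaws)
    true_model: TrueOutcomeModel = field(default_factory=default_true_model)
    missingness: dict = field(default_factory=dict)
    p_reperf: Optional[float] = None
    reperf_coefficients: Optional[dict] = None  # logistic law for etici_success
    label: str = "cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.design not in ("rct", "registry"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "registry" and self.p_reperf is None:
            raise ValueError("registry design requires p_reperf")
        if self.p_reperf is not None and not 0.0 <= self.p_reperf <= 1.0:
            raise ValueError("p_reperf out of [0, 1]")
        for fld, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {fld!r} out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "design": self.design,
            "laws": self.laws.to_dict(),
            "true_model": self.true_model.to_dict(),
            "missingness": dict(self.missingness),
            "p_reperf": self.p_reperf,
            "reperf_coefficients": self.reperf_coefficients,
            "label": self.label,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["laws"] = CovariateLaws.from_dict(d.get("laws", {}))
        if "true_model" in d:
            d["true_model"] = TrueOutcomeModel.from_dict(d["true_model"])
        return cls(**d)


@dataclass
class Cohort:
    """A generated patient table plus its generation metadata.

    ``df`` holds the predictor columns, treatment/reperfusion indicators,
    ``mrs_90d``, ``cohort`` label, and latent potential outcomes
    ``_mrs_evt0`` / ``_mrs_evt1`` kept for oracle checks.
    """

    df: pd.DataFrame
    spec: CohortSpec


# ---------------------------------------------------------------------------
# generation


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    laws = spec.laws
    n = spec.n
    cols = list(PREDICTOR_COLUMNS)
    k = len(cols)
    R = np.eye(k)
    for a, b, r in laws.copula_corr:
        ia, ib = cols.index(a), cols.index(b)
        R[ia, ib] = R[ib, ia] = r
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("copula correlation matrix is not positive definite") from exc
    Z = rng.standard_normal((n, k)) @ L.T
    U = norm.cdf(Z)
    u = {c: U[:, i] for i, c in enumerate(cols)}
    z = {c: Z[:, i] for i, c in enumerate(cols)}

    lo, hi = laws.age_bounds
    a, b = (lo - laws.age_mean) / laws.age_sd, (hi - laws.age_mean) / laws.age_sd
    age = truncnorm.ppf(u["age"], a, b, loc=laws.age_mean, scale=laws.age_sd)

    nihss = np.clip(np.rint(laws.nihss_mean + laws.nihss_sd * z["nihss"]), 0, 42).astype(int)
    sbp = np.clip(
        laws.sbp_mean + laws.sbp_sd * z["sbp"], laws.sbp_bounds[0], laws.sbp_bounds[1]
    )
    glucose = np.clip(
        laws.glucose_log_median * np.exp(laws.glucose_log_sd * z["glucose"]),
        laws.glucose_bounds[0],
        laws.glucose_bounds[1],
    )

    def categorical(name: str, probs) -> np.ndarray:
        edges = np.cumsum(np.asarray(probs, dtype=float))[:-1]
        return np.searchsorted(edges, u[name], side="right")

    prestroke = categorical("prestroke_mrs", laws.prestroke_mrs_probs)
    aspects = categorical("aspects", laws.aspects_probs)
    occ_idx = categorical("occlusion_location", laws.occlusion_probs)
    collateral = categorical("collateral_grade", laws.collateral_probs)
    o_lo, o_hi = laws.onset_to_groin_bounds
    onset = o_lo + (o_hi - o_lo) * u["onset_to_groin"]

    return pd.DataFrame(
        {
            "age": age,
            "nihss": nihss,
            "sbp": sbp,
            "glucose": glucose,
            "iv_alteplase": (u["iv_alteplase"] < laws.p_iv_alteplase).astype(int),
            "diabetes": (u["diabetes"] < laws.p_diabetes).astype(int),
            "prestroke_mrs": prestroke.astype(int),
            "aspects": aspects.astype(int),
            "occlusion_location": np.asarray(OCCLUSION_LEVELS, dtype=object)[occ_idx],
            "collateral_grade": collateral.astype(int),
            "onset_to_groin": onset,
            "prior_stroke": (u["prior_stroke"] < laws.p_prior_stroke).astype(int),
        }
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from ``spec``; deterministic given ``spec.seed``.

    Potential outcomes under both arms come from the true model's cumulative
    probabilities through one shared uniform per patient (comonotone
    coupling); the observed outcome is the assigned arm's.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_cov, rng_out, rng_assign = (np.random.default_rng(s) for s in ss.spawn(3))

    df = _draw_covariates(spec, rng_cov)
    model = spec.true_model.as_model()

    v = rng_out.uniform(size=spec.n)
    potential = {}
    for arm in (0, 1):
        arm_df = df.copy()
        arm_df["evt"] = arm
        cum = model.cumulative_probs(arm_df)  # (n, 6), P(Y <= j)
        potential[arm] = (v[:, None] > cum).sum(axis=1).astype(int)

    df["_mrs_evt0"] = potential[0]
    df["_mrs_evt1"] = potential[1]

    if spec.design == "rct":
        evt = np.zeros(spec.n, dtype=int)
        evt[rng_assign.permutation(spec.n)[: spec.n // 2]] = 1
        df["evt"] = evt
        df["mrs_90d"] = np.where(evt == 1, potential[1], potential[0])
    else:
        df["evt"] = 1
        if spec.reperf_coefficients:
            cols = sorted(spec.reperf_coefficients)
            lin = sum(
                float(spec.reperf_coefficients[c])
                * (df[c].to_numpy(dtype=float) if c != "intercept" else 1.0)
                for c in cols
            )
            p_r = 1.0 / (1.0 + np.exp(-np.asarray(lin, dtype=float)))
        else:
            p_r = np.full(spec.n, float(spec.p_reperf))
        etici = (rng_assign.uniform(size=spec.n) < p_r).astype(int)
        df["etici_success"] = etici
        # unsuccessful procedures behave like untreated patients
        df["mrs_90d"] = np.where(etici == 1, potential[1], potential[0])

    df["cohort"] = spec.label
    return Cohort(df=df, spec=spec)


# ---------------------------------------------------------------------------
# missingness


def inject_missingness(
    df: pd.DataFrame, rates: dict, seed: int = 0
) -> pd.DataFrame:
    """Blank each value independently with its field's MCAR rate.

    The outcome is only blanked if ``mrs_90d`` itself appears in ``rates``
    (missing-outcome patients are excluded upstream, not imputed).
    """
    out = df.copy()
    rng = np.random.default_rng(seed)
    for fld in sorted(rates):
        rate = rates[fld]
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {fld!r} out of [0, 1]")
        if fld not in out.columns:
            raise ValueError(f"field {fld!r} not in cohort")
        mask = rng.uniform(size=len(out)) < rate
        if mask.any():
            col = out[fld]
            if col.dtype.kind in "iub":
                out[fld] = col.astype(float)
            out.loc[mask, fld] = np.nan
    return out


def drop_missing_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Exclude patients with a missing 90-day mRS (never imputed)."""
    return df[df["mrs_90d"].notna()].copy()


# ---------------------------------------------------------------------------
# imputation


class UnimputableFieldError(ValueError):
    """A field has no observed values to impute from."""


def _encode_for_regression(df: pd.DataFrame, exclude: str) -> tuple[np.ndarray, list[str]]:
    cols = []
    names = []
    for c in PREDICTOR_COLUMNS:
        if c == exclude or c not in df.columns:
            continue
        if c == "occlusion_location":
            v = df[c].astype(str)
            cols.append((v == "ICA/ICA-T").astype(float).to_numpy())
            names.append("occ_ica_icat")
            cols.append((v == "M2").astype(float).to_numpy())
            names.append("occ_m2")
        else:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack([np.ones(len(df))] + cols)
    return X, ["intercept"] + names


def _mode(series: pd.Series):
    counts = series.value_counts()
    top = counts.max()
    # deterministic tie-break: smallest value
    return sorted(counts[counts == top].index)[0]


def impute(
    df: pd.DataFrame,
    policy: str = "mean_mode",
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Complete missing predictor values.

    ``mean_mode``: continuous fields get the observed mean, categorical and
    binary fields the observed mode. ``single_regression``: fields missing
    in at most ``threshold`` of rows are still mean/mode-filled; fields
    above the threshold are predicted deterministically (no noise draw) from
    the other covariates — linear least squares for continuous fields,
    multinomial-logistic for categorical ones — fitted on rows where the
    target is observed, with the remaining covariates mean/mode-filled first.
    """
    if policy not in ("mean_mode", "single_regression"):
        raise ValueError(f"unknown imputation policy {policy!r}")
    if "mrs_90d" in df.columns and df["mrs_90d"].isna().any():
        raise ValueError("outcome has missing values; drop_missing_outcomes first")

    out = df.copy()
    fields = [c for c in PREDICTOR_COLUMNS if c in out.columns]
    miss_frac = {c: float(out[c].isna().mean()) for c in fields}
    for c in fields:
        if out[c].notna().sum() == 0:
            raise UnimputableFieldError(f"field {c!r} has zero observed values")

    def simple_fill(col: str, series: pd.Series):
        observed = series.dropna()
        if col in CONTINUOUS_FIELDS:
            return float(observed.mean())
        return _mode(observed)

    # pass 1: mean/mode everywhere (also the regression covariate backbone)
    simple = out.copy()
    for c in fields:
        if miss_frac[c] > 0:
            simple[c] = simple[c].fillna(simple_fill(c, out[c]))

    regression_fields = [
        c for c in fields if policy == "single_regression" and miss_frac[c] > threshold
    ]
    for c in fields:
        if miss_frac[c] == 0:
            continue
        mask = out[c].isna()
        if c not in regression_fields:
            out.loc[mask, c] = simple_fill(c, df[c])
        else:
            X, _ = _encode_for_regression(simple, exclude=c)
            obs = ~mask.to_numpy()
            if c in CONTINUOUS_FIELDS or c in COUNT_FIELDS:
                t = out.loc[obs, c].to_numpy(dtype=float)
                coef = np.linalg.lstsq(X[obs], t, rcond=None)[0]
                pred = X[mask.to_numpy()] @ coef
                if c in COUNT_FIELDS:
                    lo, hi = COUNT_FIELDS[c]
                    pred = np.clip(np.rint(pred), lo, hi)
                out.loc[mask, c] = pred
            elif c in BINARY_FIELDS:
                t = out.loc[obs, c].to_numpy(dtype=float).astype(int)
                beta = logistic_fit(X[obs], t)
                pred = (X[mask.to_numpy()] @ beta > 0).astype(int)
                out.loc[mask, c] = pred
            elif c in ORDINAL_FIELDS:
                n_classes = ORDINAL_FIELDS[c]
                t = out.loc[obs, c].to_numpy(dtype=float).astype(int)
                classes = np.unique(t)
                remap = {v: i for i, v in enumerate(classes)}
                B = softmax_fit(X[obs], np.array([remap[v] for v in t]), len(classes))
                pred = classes[softmax_predict(X[mask.to_numpy()], B)]
                out.loc[mask, c] = pred
            elif c in NOMINAL_FIELDS:
                t = out.loc[obs, c].astype(str).to_numpy()
                classes = np.array(sorted(set(t)), dtype=object)
                remap = {v: i for i, v in enumerate(classes)}
                B = softmax_fit(X[obs], np.array([remap[v] for v in t]), len(classes))
                pred = classes[softmax_predict(X[mask.to_numpy()], B)]
                out.loc[mask, c] = pred

    # restore integer dtypes
    for c in fields:
        if c in COUNT_FIELDS or c in BINARY_FIELDS or c in ORDINAL_FIELDS:
            out[c] = np.rint(out[c].to_numpy(dtype=float)).astype(int)
    for c in ("evt", "etici_success", "mrs_90d"):
        if c in out.columns and out[c].notna().all():
            out[c] = out[c].astype(int)
    return out


# ---------------------------------------------------------------------------
# CSV schema


def write_cohort_csv(df: pd.DataFrame, path, include_latent: bool = False) -> None:
    """Write the documented cohort CSV (missing values as empty cells)."""
    cols = [c for c in df.columns if include_latent or not c.startswith("_")]
    df[cols].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become NaN."""
    df = pd.read_csv(path)
    for c in df.columns:
        if c in ("occlusion_location", "cohort"):
            continue
        if df[c].notna().all() and c not in CONTINUOUS_FIELDS and c != "onset_to_groin":
            if np.allclose(df[c].to_numpy(dtype=float) % 1, 0):
                df[c] = df[c].astype(int)
    return df
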