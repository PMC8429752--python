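"""Candidate winter-survival models and their comparison.

Nine candidate models are considered: three thermal predictors (LTDD;
MinDTmean; DTmean paired with exposure days) crossed with three
functional forms (linear, exponential, sigmoid).  Models are fitted by
nonlinear least squares to interval survival proportions, compared by
AIC (ties broken by R^2, then parsimony), and the selected model is
validated against independent field observations by ordinary least
squares of observed on predicted survival.

The biological expectation — and the empirical winner for chill-killed
pests — is the exponential decay of survival with accumulated cold,
S = a * exp(b * LTDD) with a in (0, 1] the survival at zero cold load
and b <= 0 the per-degree-day decay rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FitFailureError, InvalidInputError

__all__ = [
    "PREDICTORS",
    "FORMS",
    "SurvivalObservation",
    "ModelSpec",
    "FittedSurvivalModel",
    "ValidationResult",
    "all_model_specs",
    "aic",
    "fit_survival_model",
    "compare_models",
    "predict_survival",
    "validate_field",
]

PREDICTORS = ("LTDD", "MinDTmean", "DTmean_days")
FORMS = ("linear", "exponential", "sigmoid")


@dataclass
class SurvivalObservation:
    """One exposure-window survival count with its thermal predictors.

    ``predictors`` maps predictor names to values: LTDD (degC·day),
    MinDTmean (degC), DTmean (degC), exposure_days (days).
    ``n_survived`` may be fractional for idealised noise-free data.
    """

    site_id: str
    stage: str  # larva | pupa | adult
    setting: str  # lab | field_plant | field_jar
    exposure_start: object
    exposure_end: object
    n_exposed: float
    n_survived: float
    predictors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_exposed <= 0:
            raise InvalidInputError("n_exposed must be > 0")
        if not 0 <= self.n_survived <= self.n_exposed:
            raise InvalidInputError("n_survived must be in [0, n_exposed]")

    @property
    def proportion(self) -> float:
        return float(self.n_survived) / float(self.n_exposed)


@dataclass(frozen=True)
class ModelSpec:
    """(predictor, functional form) pair identifying one candidate model."""

    predictor: str
    form: str

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTORS:
            raise InvalidInputError(f"unknown predictor {self.predictor!r}")
        if self.form not in FORMS:
            raise InvalidInputError(f"unknown form {self.form!r}")

    @property
    def n_coefficients(self) -> int:
        two_cov = self.predictor == "DTmean_days"
        if self.form == "linear":
            return 3 if two_cov else 2
        if self.form == "exponential":
            return 3 if two_cov else 2
        return 4 if two_cov else 3  # sigmoid

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        if self.predictor == "DTmean_days":
            if self.form == "linear":
                return ("a", "b1", "b2")
            if self.form == "exponential":
                return ("a", "b1", "b2")
            return ("a", "b1", "b2", "c")
        if self.form == "sigmoid":
            return ("a", "c", "d")
        return ("a", "b")


def all_model_specs() -> list[ModelSpec]:
    """The full 3 x 3 candidate set."""
    return [ModelSpec(p, f) for p in PREDICTORS for f in FORMS]


def _design(observations, predictor: str) -> np.ndarray:
    """Predictor matrix: one column, or (DTmean, exposure_days) for the pair."""
    rows = []
    for obs in observations:
        p = obs.predictors
        try:
            if predictor == "DTmean_days":
                rows.append((float(p["DTmean"]), float(p["exposure_days"])))
            else:
                rows.append((float(p[predictor]),))
        except KeyError as exc:
            raise InvalidInputError(f"observation missing predictor {exc}") from exc
    X = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("non-finite predictor value")
    return X


def _model_value(spec: ModelSpec, coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Raw (unclipped) model response for design X (n x 1 or n x 2)."""
    if spec.predictor == "DTmean_days":
        lin = coef[1] * X[:, 0] + coef[2] * X[:, 1]
        if spec.form == "linear":
            return coef[0] + lin
        if spec.form == "exponential":
            with np.errstate(over="ignore"):
                return coef[0] * np.exp(np.clip(lin, -700, 700))
        return coef[0] / (1.0 + np.exp(np.clip(-(lin - coef[3]), -700, 700)))
    x = X[:, 0]
    if spec.form == "linear":
        return coef[0] + coef[1] * x
    if spec.form == "exponential":
        with np.errstate(over="ignore"):
            return coef[0] * np.exp(np.clip(coef[1] * x, -700, 700))
    a, c, d = coef
    return a / (1.0 + np.exp(np.clip(-(x - c) / d, -700, 700)))


@dataclass
class FittedSurvivalModel:
    """Least-squares fit of one candidate model."""

    spec: ModelSpec
    coefficients: dict
    r2: float
    aic: float
    n_obs: int
    residual_ss: float
    coef_se: dict = field(default_factory=dict)

    def _coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in self.spec.coefficient_names])

    def predict(self, predictors) -> np.ndarray | float:
        """Predicted survival proportion(s), clipped to [0, 1].

        ``predictors`` is a mapping of predictor name to scalar or array.
        """
        scalar = True
        if self.spec.predictor == "DTmean_days":
            t = np.atleast_1d(np.asarray(predictors["DTmean"], dtype=float))
            d = np.atleast_1d(np.asarray(predictors["exposure_days"], dtype=float))
            scalar = np.ndim(predictors["DTmean"]) == 0
            X = np.column_stack([t, d])
        else:
            try:
                x = np.asarray(predictors[self.spec.predictor], dtype=float)
            except KeyError as exc:
                raise InvalidInputError(f"missing predictor {exc}") from exc
            scalar = x.ndim == 0
            X = np.atleast_1d(x).reshape(-1, 1)
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("non-finite predictor value")
        out = np.clip(_model_value(self.spec, self._coef_array(), X), 0.0, 1.0)
        return float(out[0]) if scalar else out

    def to_json(self) -> str:
        return json.dumps(
            {
                "predictor": self.spec.predictor,
                "form": self.spec.form,
                "coefficients": self.coefficients,
                "r2": self.r2,
                "aic": self.aic,
                "n_obs": self.n_obs,
                "residual_ss": self.residual_ss,
                "coef_se": self.coef_se,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedSurvivalModel":
        d = json.loads(text)
        return cls(
            spec=ModelSpec(d["predictor"], d["form"]),
            coefficients=d["coefficients"],
            r2=d["r2"],
            aic=d["aic"],
            n_obs=d["n_obs"],
            residual_ss=d["residual_ss"],
            coef_se=d.get("coef_se", {}),
        )


def predict_survival(model: FittedSurvivalModel, predictors) -> np.ndarray | float:
    """Functional alias for :meth:`FittedSurvivalModel.predict`."""
    return model.predict(predictors)


def aic(residual_ss: float, n_obs: int, k_coefficients: int) -> float:
    """Least-squares AIC: n*ln(RSS/n) + 2k.

    The constant from the error-variance parameter is identical across
    models fitted to the same data, so it is omitted; only differences
    matter for ranking.  RSS = 0 returns -inf as a perfect-fit sentinel.
    """
    if residual_ss < 0:
        raise InvalidInputError("residual_ss must be >= 0")
    if n_obs <= k_coefficients:
        raise InvalidInputError("need n_obs > k_coefficients")
    if residual_ss == 0:
        return float("-inf")
    return n_obs * math.log(residual_ss / n_obs) + 2 * k_coefficients


def _starts(spec: ModelSpec, X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
            n_starts: int = 5) -> list[np.ndarray]:
    """Coarse-grid starting points spanning plausible coefficient ranges."""
    a0 = float(np.clip(y.max(), 0.05, 1.0))
    span = float(np.ptp(X[:, 0])) or 1.0
    mid = float(np.median(X[:, 0]))
    starts: list[np.ndarray] = []
    if spec.predictor == "DTmean_days":
        base = {
            "linear": [a0, 0.0, 0.0],
            "exponential": [a0, 0.0, 0.0],
            "sigmoid": [a0, 0.0, 0.0, 0.0],
        }[spec.form]
        starts.append(np.array(base))
        for _ in range(n_starts - 1):
            jitter = rng.normal(0, 0.1, size=len(base))
            starts.append(np.array(base) + jitter)
        return starts
    if spec.form == "linear":
        b0 = (y[-1] - y[0]) / (X[-1, 0] - X[0, 0]) if span else 0.0
        grid = [[a0, b0], [a0, 0.0], [0.5, -1.0 / span], [1.0, -2.0 / span], [a0, 1.0 / span]]
    elif spec.form == "exponential":
        grid = [[a0, -1.0 / span], [a0, -3.0 / span], [a0, 0.0], [1.0, -5.0 / span], [0.5, -0.5 / span]]
    else:  # sigmoid
        grid = [
            [a0, mid, -span / 4],
            [a0, mid, span / 4],
            [a0, mid - span / 4, -span / 8],
            [1.0, mid + span / 4, -span / 2],
            [a0, mid, -span / 20],
        ]
    return [np.asarray(g, dtype=float) for g in grid[:n_starts]]


def fit_survival_model(
    observations,
    spec: ModelSpec,
    seed: int = 0,
) -> FittedSurvivalModel:
    """Fit one candidate model to survival proportions by least squares.

    Multi-start Levenberg–Marquardt (5 deterministic starts seeded by
    ``seed``) guards against local minima in the nonlinear forms; the
    best converged attempt by RSS wins.  R^2 is computed on the fitted
    response scale; AIC per :func:`aic`.
    """
    from scipy.optimize import least_squares

    observations = list(observations)
    k = spec.n_coefficients
    if len(observations) < k + 3:
        raise InvalidInputError(
            f"need at least {k + 3} observations for {k} coefficients, got {len(observations)}"
        )
    X = _design(observations, spec.predictor)
    y = np.array([obs.proportion for obs in observations])
    order = np.lexsort(tuple(X.T) + (y,))  # order-invariant internal sort
    X, y = X[order], y[order]
    rng = np.random.default_rng(seed)

    def resid(coef):
        return _model_value(spec, coef, X) - y

    best = None
    for x0 in _starts(spec, X, y, rng):
        try:
            sol = least_squares(resid, x0, method="lm", xtol=1e-10, ftol=1e-10,
                                gtol=1e-10, max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-10:
            best = (rss, sol)
    if best is None:
        raise FitFailureError(f"all starts failed for {spec}", best_attempt=None)
    rss, sol = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    # heteroscedasticity-robust (sandwich) SEs: survival proportions have
    # binomial variance p(1-p)/n that varies strongly along the curve, so
    # the constant-variance NLS covariance would be miscalibrated
    dof = max(len(y) - k, 1)
    se = np.full(k, np.nan)
    try:
        bread = np.linalg.inv(sol.jac.T @ sol.jac)
        meat = sol.jac.T @ (sol.fun[:, None] ** 2 * sol.jac)
        cov = bread @ meat @ bread * len(y) / dof
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        pass
    return FittedSurvivalModel(
        spec=spec,
        coefficients={n: float(v) for n, v in zip(spec.coefficient_names, sol.x)},
        r2=float(r2),
        aic=aic(rss, len(y), k),
        n_obs=len(y),
        residual_ss=rss,
        coef_se={n: float(v) for n, v in zip(spec.coefficient_names, se)},
    )


def compare_models(observations, specs=None, seed: int = 0) -> list[FittedSurvivalModel]:
    """Fit every candidate spec and rank ascending by AIC.

    Ties break toward higher R^2, then fewer coefficients.  Specs whose
    fit fails are dropped; if all fail, FitFailureError is raised.
    """
    if specs is None:
        specs = all_model_specs()
    fitted: list[FittedSurvivalModel] = []
    failures = []
    for spec in specs:
        try:
            fitted.append(fit_survival_model(observations, spec, seed=seed))
        except (FitFailureError, InvalidInputError) as exc:
            failures.append((spec, exc))
    if not fitted:
        raise FitFailureError(f"all {len(failures)} fits failed", best_attempt=failures)
    fitted.sort(key=lambda m: (m.aic, -m.r2, m.spec.n_coefficients))
    return fitted


@dataclass
class ValidationResult:
    """OLS of observed on predicted survival for independent field data."""

    slope: float
    intercept: float
    r2: float
    n: int
    slope_stderr: float = float("nan")

    @property
    def bias(self) -> float:
        """Deviation of the regression slope from the 1:1 line."""
        return abs(self.slope - 1.0)


def validate_field(
    model: FittedSurvivalModel,
    field_observations,
    exclude_zero_ltdd: bool = True,
) -> ValidationResult:
    """Regress observed field survival on model predictions.

    Field records from sites whose exposure window accumulated no cold
    (LTDD = 0) are excluded by default: winters warm enough for
    uninterrupted development produce survival unrelated to cold load.
    """
    obs = list(field_observations)
    if exclude_zero_ltdd:
        obs = [
            o for o in obs
            if not (o.setting.startswith("field") and o.predictors.get("LTDD", 1.0) == 0.0)
        ]
    if len(obs) < 3:
        raise InvalidInputError("need at least 3 field observations")
    X = _design(obs, model.spec.predictor)
    if model.spec.predictor == "DTmean_days":
        pred = model.predict({"DTmean": X[:, 0], "exposure_days": X[:, 1]})
    else:
        pred = model.predict({model.spec.predictor: X[:, 0]})
    observed = np.array([o.proportion for o in obs])
    from scipy.stats import linregress

    fit = linregress(pred, observed)
    return ValidationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(obs),
        slope_stderr=float(fit.stderr),
    )
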