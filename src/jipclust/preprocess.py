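"""Feature encoding: Yeo-Johnson power transforms for numeric variables,
log transform for ESR, one-hot encoding for categoricals, binary joint
flags — with all fitted parameters frozen for reuse on external cohorts.

The encoder is a scikit-learn style transformer: ``fit`` estimates the
per-variable Yeo-Johnson lambda, the post-transform mean/SD and the
categorical level lists on a training cohort; ``transform`` applies those
frozen parameters and never refits, so external cohorts are projected into
exactly the training feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort, joint_flag_columns

NUMERIC_VARS = ["age", "hb", "ht", "leuko", "thrombo", "esr"]
CATEGORICAL_LEVELS = {
    "sex": ["female", "male"],
    "rf": [1, 0],
    "acpa": [1, 0],
}


class DegenerateInputError(ValueError):
    """Input without enough variation to fit a transform."""


class UnseenLevelError(ValueError):
    """A categorical value outside the frozen level list."""


def fit_yeo_johnson(values, bounds: tuple[float, float] = (-5.0, 5.0),
                    tol: float = 1e-5) -> float:
    """Maximum-likelihood Yeo-Johnson lambda by bounded Brent search.

    Requires at least 10 finite values with nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise DegenerateInputError("need >= 10 finite values")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant input")
    res = optimize.minimize_scalar(
        lambda lmb: -stats.yeojohnson_llf(lmb, x),
        bounds=bounds, method="bounded",
        options={"xatol": tol})
    return float(res.x)


def apply_yeo_johnson(y, lmbda: float):
    """Yeo-Johnson transform (scalar or array).

    y >= 0: ((y+1)^l - 1)/l          (l != 0),  ln(y+1)      (l == 0)
    y <  0: -(((-y+1)^(2-l) - 1)/(2-l)) (l != 2), -ln(-y+1)  (l == 2)
    """
    if not np.isfinite(lmbda):
        raise ValueError("lambda must be finite")
    y = np.asarray(y, dtype=float)
    out = stats.yeojohnson(y.ravel(), lmbda=lmbda)
    out = np.asarray(out).reshape(y.shape)
    return float(out) if out.ndim == 0 else out


def one_hot(value, levels) -> np.ndarray:
    """One-hot vector over an ordered level list; unseen values are an
    error (the encoding never silently extends)."""
    levels = list(levels)
    if value not in levels:
        raise UnseenLevelError(f"value {value!r} not in levels {levels}")
    vec = np.zeros(len(levels))
    vec[levels.index(value)] = 1.0
    return vec


@dataclass
class TransformParams:
    """Frozen fit parameters: Yeo-Johnson lambdas, post-transform means/SDs,
    categorical level lists, joint-flag column order."""

    lambdas: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    levels: dict[str, list]
    joint_cols: list[str]
    esr_log: bool = True

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TransformParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class FeatureMatrix:
    """Modality-blocked design matrix: a standardized numeric block and a
    binary categorical block (one-hot groups + joint flags)."""

    numeric: np.ndarray
    categorical: np.ndarray
    numeric_cols: list[str]
    categorical_cols: list[str]
    row_ids: list
    params: TransformParams

    @property
    def values(self) -> np.ndarray:
        return np.hstack([self.numeric, self.categorical])

    @property
    def columns(self) -> list[str]:
        return self.numeric_cols + self.categorical_cols

    @property
    def n_numeric(self) -> int:
        return self.numeric.shape[1]

    def __len__(self) -> int:
        return self.numeric.shape[0]


class ClinicalFeatureEncoder(BaseEstimator, TransformerMixin):
    """Mixed-type feature encoder with frozen transform parameters.

    Numeric variables are Yeo-Johnson transformed (ESR: ln(esr+1) instead,
    matching its log-normal shape) and standardized; sex/RF/ACPA are
    one-hot encoded against their frozen level lists, with two-level
    variables reduced to a single indicator column; the 88 tender/swollen
    joint flags pass through as binary columns in atlas order.
    """

    def __init__(self, yj_bounds=(-5.0, 5.0)):
        self.yj_bounds = yj_bounds

    def fit(self, cohort: Cohort, y=None):
        df = cohort.df
        lambdas, means, sds = {}, {}, {}
        for var in NUMERIC_VARS:
            x = df[var].to_numpy(dtype=float)
            if var == "esr":
                if (x < 0).any():
                    raise ValueError("esr must be non-negative")
                t = np.log(x + 1.0)
            else:
                lambdas[var] = fit_yeo_johnson(x, bounds=self.yj_bounds)
                t = apply_yeo_johnson(x, lambdas[var])
            means[var] = float(t.mean())
            sd = float(t.std(ddof=0))
            if sd == 0:
                raise DegenerateInputError(f"{var}: zero variance")
            sds[var] = sd
        self.params_ = TransformParams(
            lambdas=lambdas, means=means, sds=sds,
            levels={k: list(v) for k, v in CATEGORICAL_LEVELS.items()},
            joint_cols=joint_flag_columns(cohort.atlas))
        return self

    def transform(self, cohort: Cohort) -> FeatureMatrix:
        return apply_transform(cohort, self.params_)

    def fit_transform(self, cohort: Cohort, y=None) -> FeatureMatrix:
        return self.fit(cohort).transform(cohort)


def transform_esr(esr, params: TransformParams):
    """ln(esr+1), standardized with the frozen mean/SD."""
    esr = np.asarray(esr, dtype=float)
    if (esr < 0).any():
        raise ValueError("esr must be non-negative")
    t = np.log(esr + 1.0)
    return (t - params.means["esr"]) / params.sds["esr"]


def fit_transform(cohort: Cohort) -> FeatureMatrix:
    """Fit encoder parameters on this cohort and return its feature matrix
    (with the frozen params attached)."""
    return ClinicalFeatureEncoder().fit_transform(cohort)


def apply_transform(cohort: Cohort, params: TransformParams) -> FeatureMatrix:
    """Encode a cohort with previously frozen parameters (never refits)."""
    df = cohort.df
    num_cols, num_blocks = [], []
    for var in NUMERIC_VARS:
        x = df[var].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"{var}: missing values; run "
                             "filter_complete_cases first")
        if var == "esr":
            t = transform_esr(x, params)
        else:
            t = apply_yeo_johnson(x, params.lambdas[var])
            t = (t - params.means[var]) / params.sds[var]
        num_cols.append(var)
        num_blocks.append(t[:, None])

    cat_cols, cat_blocks = [], []
    for var, levels in params.levels.items():
        vals = df[var].tolist()
        block = np.zeros((len(df), len(levels)))
        for i, v in enumerate(vals):
            if isinstance(v, (float, np.floating)) and float(v).is_integer():
                v = int(v)
            block[i] = one_hot(v, levels)
        if len(levels) == 2:
            # two-level variables keep a single indicator column: the
            # complement column carries no information but doubles the
            # variable's weight in downstream losses and distances
            block = block[:, :1]
            cat_cols.append(f"{var}={levels[0]}")
        else:
            cat_cols += [f"{var}={lev}" for lev in levels]
        cat_blocks.append(block)
    joint = df[params.joint_cols].to_numpy(dtype=float)
    if np.isnan(joint).any():
        raise ValueError("missing joint flags; run filter_complete_cases")
    cat_cols += list(params.joint_cols)
    cat_blocks.append(joint)

    return FeatureMatrix(
        numeric=np.hstack(num_blocks),
        categorical=np.hstack(cat_blocks),
        numeric_cols=num_cols, categorical_cols=cat_cols,
        row_ids=cohort.patient_ids, params=params)
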