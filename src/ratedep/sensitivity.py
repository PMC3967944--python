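"""Multivariable regression of log-APD on the randomized parameters.

Design matrix X: one column per registry parameter, z-scored log(scale
factor) for G/K/p columns, z-scored raw mV shift for V columns.  Output Y:
z-scored natural log of APD (ms).  Ordinary least squares gives the
standardized sensitivity vector B per rate: positive B means increasing the
parameter prolongs the APD.  R^2 is the squared Pearson correlation between
X B and Y.  For cross-rate comparison, B_fast is rescaled by
sigma_logAPD,fast / sigma_logAPD,slow, putting both sensitivity vectors in
units of the slow-rate output spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import ParameterDescriptor
from .population import PopulationResult, PopulationSample


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_included, n_params), z-scored
    parameter_names: list[str]
    trial_ids: list[int]
    column_means: np.ndarray  # of the transformed (pre-z-score) columns
    column_sds: np.ndarray


@dataclass
class SensitivityResult:
    rate_hz: float
    parameter_names: list[str]
    coefficients: np.ndarray  # standardized B
    intercept: float
    standard_errors: np.ndarray
    r_squared: float
    sigma_log_apd: float  # SD of log-APD across included trials
    n_included: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.parameter_names, name="B")


def _transform_columns(
    samples: list[PopulationSample], registry: list[ParameterDescriptor]
) -> np.ndarray:
    cols = []
    for d in registry:
        raw = np.array(
            [s.perturbation.get(d.name, 0.0 if d.category == "V" else 1.0)
             for s in samples]
        )
        cols.append(raw if d.category == "V" else np.log(raw))
    return np.column_stack(cols)


def build_design_matrix(
    samples: list[PopulationSample],
    registry: list[ParameterDescriptor],
    included_ids: list[int],
    apds: dict[int, float],
) -> tuple[DesignMatrix, np.ndarray, float]:
    """Standardized design + z-scored log-APD output + sigma of log-APD.

    ``apds`` maps trial id -> APD (ms) at the rate being fit.
    """
    if len(included_ids) < 10:
        raise ValueError("need at least 10 included trials")
    by_id = {s.trial_id: s for s in samples}
    kept = [by_id[i] for i in included_ids]
    raw = _transform_columns(kept, registry)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    zero = np.nonzero(sds <= 0)[0]
    if len(zero):
        names = [registry[i].name for i in zero]
        raise ValueError(f"zero-variance design column(s): {names}")
    X = (raw - means) / sds
    if len(kept) < len(registry):
        warnings.warn(
            f"{len(kept)} trials < {len(registry)} parameters: regression underdetermined",
            stacklevel=2,
        )
    y_log = np.log(np.array([apds[i] for i in included_ids]))
    sigma = float(y_log.std())
    if sigma <= 0:
        raise ValueError("log-APD has zero variance")
    y = (y_log - y_log.mean()) / sigma
    design = DesignMatrix(
        X=X,
        parameter_names=[d.name for d in registry],
        trial_ids=list(included_ids),
        column_means=means,
        column_sds=sds,
    )
    return design, y, sigma


def regress(
    design: DesignMatrix, y: np.ndarray, sigma_log_apd: float, rate_hz: float
) -> SensitivityResult:
    """OLS fit of the standardized outputs on the standardized design."""
    Xc = sm.add_constant(design.X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, Xc).fit()
    yhat = fit.fittedvalues
    r2 = float(np.corrcoef(yhat, y)[0, 1] ** 2)
    return SensitivityResult(
        rate_hz=rate_hz,
        parameter_names=list(design.parameter_names),
        coefficients=np.asarray(fit.params[1:]),
        intercept=float(fit.params[0]),
        standard_errors=np.asarray(fit.bse[1:]),
        r_squared=r2,
        sigma_log_apd=sigma_log_apd,
        n_included=len(design.trial_ids),
    )


def scale_fast_sensitivities(
    slow: SensitivityResult, fast: SensitivityResult
) -> np.ndarray:
    """B_fast * sigma_fast / sigma_slow (elementwise); slow B unchanged."""
    if slow.parameter_names != fast.parameter_names:
        raise ValueError("slow/fast results cover different parameters")
    if slow.n_included != fast.n_included:
        raise ValueError("slow/fast results come from different trial sets")
    if slow.sigma_log_apd == 0:
        raise ValueError("sigma of slow log-APD is zero")
    return fast.coefficients * (fast.sigma_log_apd / slow.sigma_log_apd)


def fit_population(
    result: PopulationResult, registry: list[ParameterDescriptor]
) -> tuple[SensitivityResult, SensitivityResult, np.ndarray]:
    """Both-rate regression of an exclusion-filtered population.

    Returns (slow fit, fast fit, scaled fast coefficients).
    """
    if not result.exclusions_applied:
        raise ValueError("apply_exclusions before fitting")
    ids = result.included_ids()
    frame = result.apd_frame()
    apd_slow = frame["APD_slow"].to_dict()
    apd_fast = frame["APD_fast"].to_dict()
    d_s, y_s, sig_s = build_design_matrix(result.samples, registry, ids, apd_slow)
    d_f, y_f, sig_f = build_design_matrix(result.samples, registry, ids, apd_fast)
    slow = regress(d_s, y_s, sig_s, result.protocol_slow.rate_hz)
    fast = regress(d_f, y_f, sig_f, result.protocol_fast.rate_hz)
    return slow, fast, scale_fast_sensitivities(slow, fast)
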