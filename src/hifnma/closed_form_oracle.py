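"""Exact solutions of the fixed-effects NMA likelihood under flat priors.

Because the fixed-effects model is a Gaussian linear model in the basic
parameters, its flat-prior posterior has a closed form: weighted least
squares on the edge-incidence design matrix.  These exact results —
inverse-variance pooling on a single edge, GLS on a general connected
network, and the Bucher adjusted indirect comparison for a two-edge star —
serve as the independent validation oracle for the MCMC engine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import EvidenceNetwork, assert_connected
from .trial_data import (
    OutcomeSpec,
    Z975,
    ci_to_se,
    se_to_ci,
    to_reporting_scale,
    ValidationError,
)

logger = logging.getLogger("hifnma")

#: data row for the engine and the oracle: observed contrast on the analysis
#: scale, its SE, and the two arms.
DataRow = tuple[float, float, str, str]

COND_WARN_THRESHOLD = 1e8


@dataclass(frozen=True)
class GLSResult:
    """Flat-prior posterior: point estimates and covariance of the basic
    parameters (treatment-vs-reference effects, analysis scale)."""

    parameters: tuple[str, ...]
    estimates: np.ndarray
    covariance: np.ndarray
    reference: str

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance)
        if not np.allclose(cov, cov.T):
            raise ValidationError("covariance must be symmetric")
        if np.any(np.diag(cov) <= 0):
            raise ValidationError("covariance diagonal must be strictly positive")

    def contrast(self, treatment: str, comparator: str) -> tuple[float, float]:
        """Estimate and SE of ``d_treatment - d_comparator`` (analysis scale)."""
        k = len(self.parameters)
        vec = np.zeros(k)
        if treatment != self.reference:
            vec[self.parameters.index(treatment)] = 1.0
        if comparator != self.reference:
            vec[self.parameters.index(comparator)] -= 1.0
        est = float(vec @ self.estimates)
        var = float(vec @ self.covariance @ vec)
        return est, float(np.sqrt(var)) if var > 0 else 0.0


def pool_fixed_effect(
    ys: Sequence[float], ses: Sequence[float]
) -> tuple[float, float]:
    """Inverse-variance fixed-effect pooling of independent estimates.

    pooled = Σ(y/se²)/Σ(1/se²), se = sqrt(1/Σ(1/se²)).
    """
    ys = np.asarray(ys, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if ys.size == 0 or ys.shape != ses.shape:
        raise ValidationError("ys and ses must be equal-length and non-empty")
    if np.any(ses <= 0):
        raise ValidationError("all standard errors must be positive")
    w = 1.0 / ses**2
    return float(np.sum(w * ys) / np.sum(w)), float(np.sqrt(1.0 / np.sum(w)))


def design_matrix(
    net: EvidenceNetwork, data: Sequence[DataRow]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Edge-incidence design over non-reference nodes: returns (X, y, se, params).

    Row i has +1 in the treatment column and -1 in the comparator column
    (reference columns omitted, fixing d_reference = 0).
    """
    params = tuple(n for n in net.nodes if n != net.reference)
    index = {p: j for j, p in enumerate(params)}
    nodeset = set(net.nodes)
    X = np.zeros((len(data), len(params)))
    y = np.empty(len(data))
    se = np.empty(len(data))
    for i, (yi, sei, t, c) in enumerate(data):
        if t not in nodeset or c not in nodeset:
            raise ValidationError(f"data row {i}: arms ({t!r}, {c!r}) not in network")
        if sei <= 0:
            raise ValidationError(f"data row {i}: se must be positive")
        if t != net.reference:
            X[i, index[t]] = 1.0
        if c != net.reference:
            X[i, index[c]] = -1.0
        y[i], se[i] = yi, sei
    return X, y, se, params


def gls_fe_nma(net: EvidenceNetwork, data: Sequence[DataRow]) -> GLSResult:
    """Weighted least squares solution of the fixed-effects NMA.

    estimates = (XᵀWX)⁻¹XᵀWy with W = diag(1/se²).  For a star network this
    reduces edgewise to :func:`pool_fixed_effect`.
    """
    assert_connected(net)
    X, y, se, params = design_matrix(net, data)
    w = 1.0 / se**2
    A = (X.T * w) @ X
    b = X.T @ (w * y)
    cond = np.linalg.cond(A)
    if cond > COND_WARN_THRESHOLD:
        warnings.warn(
            f"normal matrix condition number {cond:.3g} exceeds "
            f"{COND_WARN_THRESHOLD:.0e}; estimates may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        # Cholesky solve: small dense SPD systems, stability over speed
        L = np.linalg.cholesky(A)
        est = np.linalg.solve(L.T, np.linalg.solve(L, b))
        cov = np.linalg.inv(A)
        cov = (cov + cov.T) / 2.0
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular normal matrix: some basic parameter has no evidence path "
            "to the reference"
        ) from exc
    return GLSResult(parameters=params, estimates=est, covariance=cov, reference=net.reference)


def bucher_indirect(
    a_vs_c: tuple[float, float, float],
    b_vs_c: tuple[float, float, float],
    scale: str,
) -> tuple[float, float, float]:
    """Bucher adjusted indirect comparison of A vs B via common comparator C.

    On the analysis scale d_AB = d_AC − d_BC with variances summed; the
    returned (est, lower, upper) are on the reporting scale of ``scale``.
    """
    est_a, lo_a, hi_a = a_vs_c
    est_b, lo_b, hi_b = b_vs_c
    se_a = ci_to_se(lo_a, hi_a, scale)
    se_b = ci_to_se(lo_b, hi_b, scale)
    if scale == "log":
        if est_a <= 0 or est_b <= 0:
            raise ValidationError("log-scale estimates must be positive")
        d = np.log(est_a) - np.log(est_b)
    else:
        d = est_a - est_b
    se = float(np.sqrt(se_a**2 + se_b**2))
    lo, hi = se_to_ci(se, float(d), scale)
    point = float(np.exp(d)) if scale == "log" else float(d)
    return point, lo, hi


def gls_league_table(
    result: GLSResult, spec: OutcomeSpec, analysis_set_id: str = ""
) -> pd.DataFrame:
    """League table (same schema as the MCMC engine's) from a GLS fit.

    Intervals are symmetric normal-theory 95% intervals on the analysis
    scale, mapped to the reporting scale; ``method`` column = "gls".
    """
    nodes = (result.reference,) + result.parameters
    rows = []
    for t in nodes:
        for c in nodes:
            if t == c:
                est, lo, hi = 0.0, 0.0, 0.0
            else:
                est, se = result.contrast(t, c)
                lo, hi = est - Z975 * se, est + Z975 * se
            rows.append(
                {
                    "treatment": t,
                    "comparator": c,
                    "median": to_reporting_scale(est, spec),
                    "ci2_5": to_reporting_scale(lo, spec),
                    "ci97_5": to_reporting_scale(hi, spec),
                    "scale": spec.reporting_scale,
                    "outcome_id": spec.outcome_id,
                    "analysis_set": analysis_set_id,
                    "method": "gls",
                }
            )
    return pd.DataFrame(rows)
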