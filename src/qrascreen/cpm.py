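"""Crash prediction model (safety performance function).

The CPM is a log-linear negative-binomial regression of annual segment crash
frequency on traffic and geometric covariates, with segment length as a fixed
multiplicative exposure:

    E[count] = LM * ADT^a * exp(b0 + b_CI * CI + b_MR * MR)

where LM is segment length (m), ADT average daily traffic (pcu/day), CI the
congestion index and MR the merging ratio. The default coefficients are the
Shanghai urban-expressway calibration (a = 0.8410, b0 = -12.17, b_CI = 2.822,
b_MR = 0.792). Fitting uses maximum-likelihood NB2 (variance = mu + mu^2/theta)
with log(LM) as the offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import Segment

__all__ = ["CpmCoefficients", "SHANGHAI_COEFFICIENTS", "predict_crash_frequency", "fit_cpm"]


@dataclass(frozen=True)
class CpmCoefficients:
    """Coefficients of the log-linear NB crash prediction model."""

    adt_exponent: float = 0.8410
    intercept: float = -12.17
    ci_coef: float = 2.822
    mr_coef: float = 0.792
    dispersion: float | None = None  # NB2 theta (variance = mu + mu^2/theta)

    def __post_init__(self) -> None:
        for name in ("adt_exponent", "intercept", "ci_coef", "mr_coef"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.dispersion is not None and self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def as_dict(self) -> dict:
        return {
            "adt_exponent": self.adt_exponent,
            "intercept": self.intercept,
            "ci_coef": self.ci_coef,
            "mr_coef": self.mr_coef,
            "dispersion": self.dispersion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CpmCoefficients":
        return cls(**{k: d[k] for k in
                      ("adt_exponent", "intercept", "ci_coef", "mr_coef") if k in d}
                   | ({"dispersion": d["dispersion"]} if d.get("dispersion") is not None else {}))


#: Default calibration for the Shanghai urban expressway network.
SHANGHAI_COEFFICIENTS = CpmCoefficients()


def predict_crash_frequency(
    segment: Segment, coef: CpmCoefficients = SHANGHAI_COEFFICIENTS
) -> float:
    """Predicted annual crash frequency for one segment.

    Returns ``LM * ADT^a * exp(b0 + b_CI*CI + b_MR*MR)``. Raises for
    nonpositive ADT or negative LM; LM = 0 yields 0 by linear exposure.
    """
    if segment.adt <= 0:
        raise ValueError(f"segment {segment.segment_id}: ADT must be > 0")
    if segment.seg_length_m < 0:
        raise ValueError(f"segment {segment.segment_id}: LM must be >= 0")
    return (
        segment.seg_length_m
        * segment.adt ** coef.adt_exponent
        * math.exp(
            coef.intercept
            + coef.ci_coef * segment.congestion_index
            + coef.mr_coef * segment.merging_ratio
        )
    )


class CpmFitError(RuntimeError):
    """Raised when the NB fit cannot be carried out or does not converge."""


def fit_cpm(
    segments: Sequence[Segment],
    annual_counts: Sequence[float],
    return_details: bool = False,
) -> CpmCoefficients | tuple[CpmCoefficients, dict]:
    """Fit the NB2 crash prediction model by maximum likelihood.

    ``annual_counts`` are observed annual crash counts, one per segment
    (nonnegative integers; pass the per-year mean rounded or pool years as
    separate observations by repeating segments). log(LM) enters as a fixed
    exposure offset with coefficient 1.

    Returns fitted :class:`CpmCoefficients` including the NB2 dispersion
    theta. With ``return_details=True`` also returns a dict of convergence
    diagnostics: standard errors per coefficient, the log-likelihood and the
    converged flag. Raises :class:`CpmFitError` on degenerate designs,
    all-zero counts, or non-convergence.
    """
    if len(segments) < 10:
        raise CpmFitError("need at least 10 segments to fit the CPM")
    y = np.asarray(annual_counts, dtype=float)
    if len(y) != len(segments):
        raise CpmFitError("annual_counts length must match segments")
    if (y < 0).any():
        raise CpmFitError("counts must be nonnegative")
    if y.sum() == 0:
        raise CpmFitError("all observed counts are zero; the model is not identifiable")

    log_adt = np.array([math.log(s.adt) for s in segments])
    ci = np.array([s.congestion_index for s in segments])
    mr = np.array([s.merging_ratio for s in segments])
    offset = np.array([math.log(s.seg_length_m) for s in segments])

    for name, col in (("log(ADT)", log_adt), ("CI", ci), ("MR", mr)):
        if np.ptp(col) == 0:
            raise CpmFitError(f"covariate {name} has zero variance; coefficient unidentifiable")

    X = sm.add_constant(np.column_stack([log_adt, ci, mr]))
    model = sm.NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
    try:
        res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels raises a zoo of numeric errors
        raise CpmFitError(f"NB fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise CpmFitError("NB fit did not converge")

    const, a, b_ci, b_mr, alpha = res.params
    theta = 1.0 / alpha if alpha > 0 else float("inf")
    coef = CpmCoefficients(
        adt_exponent=float(a),
        intercept=float(const),
        ci_coef=float(b_ci),
        mr_coef=float(b_mr),
        dispersion=float(theta) if math.isfinite(theta) else None,
    )
    if not return_details:
        return coef
    se = res.bse
    details = {
        "stderr": {
            "intercept": float(se[0]),
            "adt_exponent": float(se[1]),
            "ci_coef": float(se[2]),
            "mr_coef": float(se[3]),
        },
        "loglike": float(res.llf),
        "converged": bool(res.mle_retvals.get("converged", False)),
        "n_obs": len(y),
    }
    return coef, details
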