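"""Amyloid-PET SUVR from simulated aggregate burden, and sigmoid
SUVR-versus-age trajectory fitting.

The standardized uptake value ratio (SUVR) — tracer uptake in a target
region relative to the cerebellum — is modelled as a saturating
function of the weighted aggregate load

    beta_L = o + O + F + c4 * P        (summed over both isoforms)
    SUVR   = c0 + c1 * beta_L^c2 / (c3^c2 + beta_L^c2)

with c0 the amyloid-free baseline (1.0) and c4 > 1 expressing the
tracer's higher affinity for plaques. Clinical SUVR-age trajectories
are fitted with a 4-parameter logistic, optionally anchored by a
heavily weighted pseudo-observation (the baseline SUVR of 1.5 at age
70), which supports back-extrapolation below the observed age range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .params import ParameterSet

__all__ = [
    "SUVRConstants",
    "abeta_load",
    "suvr_from_load",
    "invert_suvr",
    "SUVRSigmoidModel",
    "SUVRSigmoidResults",
    "fit_sigmoid",
    "suvr_trajectory",
]


@dataclass(frozen=True)
class SUVRConstants:
    """Calibrated constants of the saturating uptake relation."""

    c0: float = 1.0
    c1: float = 4.65
    c2: float = 3.3
    c3: float = 630000.0
    c4: float = 1.95

    def __post_init__(self):
        if self.c0 < 1.0:
            raise ValueError("c0 is the no-amyloid baseline and must be >= 1")
        if self.c4 <= 1.0:
            raise ValueError("c4 must exceed 1 (tracer prefers plaque)")
        if self.c1 <= 0 or self.c2 <= 0 or self.c3 <= 0:
            raise ValueError("c1, c2, c3 must be positive")

    @classmethod
    def from_parameter_set(cls, params: ParameterSet) -> "SUVRConstants":
        s = params.section("imaging.suvr")
        return cls(**{k: float(s[k]) for k in ("c0", "c1", "c2", "c3", "c4")})


def abeta_load(aggregates: dict[str, float] | Sequence[float],
               k: SUVRConstants = SUVRConstants()) -> float:
    """Weighted aggregate load beta_L = o + O + F + c4*P.

    ``aggregates`` is either a mapping with keys o, O, F, P (already
    summed over isoforms) or a sequence (o, O, F, P). Values are lumped
    ISF concentrations in nM.
    """
    if isinstance(aggregates, dict):
        o, O, F, P = (aggregates[s] for s in ("o", "O", "F", "P"))
    else:
        o, O, F, P = aggregates
    for v in (o, O, F, P):
        if v < 0:
            raise ValueError("aggregate concentrations must be >= 0")
    return o + O + F + k.c4 * P


def suvr_from_load(beta_L, k: SUVRConstants = SUVRConstants()):
    """Saturating uptake: c0 + c1*bL^c2 / (c3^c2 + bL^c2).

    Strictly increasing in the load and bounded in [c0, c0 + c1).
    Accepts scalars or arrays.
    """
    bl = np.asarray(beta_L, dtype=float)
    if np.any(bl < 0):
        raise ValueError("amyloid load must be >= 0")
    x = bl ** k.c2
    out = k.c0 + k.c1 * x / (k.c3 ** k.c2 + x)
    return float(out) if np.isscalar(beta_L) else out


def invert_suvr(suvr: float, k: SUVRConstants = SUVRConstants()) -> float:
    """Numeric inverse of the uptake relation on (c0, c0 + c1)."""
    if not k.c0 < suvr < k.c0 + k.c1:
        raise ValueError(f"SUVR {suvr} outside the invertible range "
                         f"({k.c0}, {k.c0 + k.c1})")
    hi = k.c3
    while suvr_from_load(hi, k) < suvr:
        hi *= 10.0
    return brentq(lambda b: suvr_from_load(b, k) - suvr, 0.0, hi,
                  xtol=1e-12, rtol=1e-14)


# ---------------------------------------------------------------------------
# sigmoid trajectory fitting

def _logistic4(age, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (age - midpoint)))


class SigmoidFitError(RuntimeError):
    pass


class SUVRSigmoidModel:
    """4-parameter logistic model of an SUVR-versus-age trajectory.

    Parameters
    ----------
    ages, suvr : array-like
        Observed trajectory points (at least 4 for the 4-parameter fit).
    anchor : (age, suvr), optional
        Pseudo-observation appended with ``anchor_weight`` times the
        weight of a regular point — a soft constraint, e.g. the
        baseline SUVR of 1.5 at age 70.
    """

    def __init__(self, ages, suvr, anchor: tuple[float, float] | None = None,
                 anchor_weight: float = 10.0):
        self.ages = np.asarray(ages, dtype=float)
        self.suvr = np.asarray(suvr, dtype=float)
        if self.ages.size != self.suvr.size:
            raise ValueError("ages and suvr must have equal length")
        if self.ages.size < 4:
            raise SigmoidFitError("need at least 4 points for a 4-parameter fit")
        if np.ptp(self.ages) == 0:
            raise SigmoidFitError("degenerate input: all ages identical")
        self.anchor = anchor
        self.anchor_weight = float(anchor_weight)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_col: str = "age",
                       suvr_col: str = "suvr", **kw) -> "SUVRSigmoidModel":
        return cls(df[age_col].to_numpy(), df[suvr_col].to_numpy(), **kw)

    def fit(self, p0: Sequence[float] | None = None) -> "SUVRSigmoidResults":
        x, y = self.ages, self.suvr
        w = np.ones_like(x)
        if self.anchor is not None:
            x = np.append(x, self.anchor[0])
            y = np.append(y, self.anchor[1])
            w = np.append(w, self.anchor_weight)
        sigma = 1.0 / np.sqrt(w)
        if p0 is None:
            lo, hi = float(y.min()), float(y.max())
            p0 = [lo, hi if hi > lo else lo + 0.5, float(np.median(x)), 0.1]
        try:
            popt, pcov = curve_fit(
                _logistic4, x, y, p0=p0, sigma=sigma, absolute_sigma=False,
                maxfev=20000,
                bounds=([0.0, 0.0, 0.0, 1e-4], [10.0, 20.0, 200.0, 5.0]),
            )
        except RuntimeError as exc:
            raise SigmoidFitError(f"sigmoid fit did not converge: {exc}") from exc
        cond = np.linalg.cond(pcov) if np.all(np.isfinite(pcov)) else np.inf
        return SUVRSigmoidResults(
            model=self, params=popt, cov=pcov, condition_number=float(cond))


@dataclass
class SUVRSigmoidResults:
    """Fitted logistic parameters with uncertainties and diagnostics."""

    model: SUVRSigmoidModel
    params: np.ndarray          # lower, upper, midpoint, slope
    cov: np.ndarray
    condition_number: float = np.nan
    param_names: tuple = ("lower", "upper", "midpoint_age", "slope")

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def predict(self, ages):
        """Evaluate the fitted sigmoid; ages below the observed range
        give the back-extrapolated prodromal trajectory."""
        return _logistic4(np.asarray(ages, dtype=float), *self.params)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.suvr - self.predict(self.model.ages)

    def to_dict(self) -> dict:
        return {**dict(zip(self.param_names, map(float, self.params))),
                "bse": dict(zip(self.param_names, map(float, self.bse))),
                "rss": float(np.sum(self.residuals ** 2)),
                "n_obs": int(self.model.ages.size),
                "condition_number": self.condition_number}

    def summary(self) -> str:
        lines = ["SUVR sigmoid fit (4-parameter logistic)",
                 f"  n obs: {self.model.ages.size}"
                 + (f" + anchor {self.model.anchor} (weight {self.model.anchor_weight})"
                    if self.model.anchor else ""),
                 "  param           estimate     std err"]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"  {name:<14}{est:>10.4f}{se:>12.4f}")
        lines.append(f"  RSS: {np.sum(self.residuals ** 2):.5g}")
        return "\n".join(lines)


def fit_sigmoid(points, anchor=None, anchor_weight: float = 10.0) -> SUVRSigmoidResults:
    """Convenience wrapper: fit a list of (age, SUVR) pairs."""
    pts = np.asarray(points, dtype=float)
    return SUVRSigmoidModel(pts[:, 0], pts[:, 1], anchor=anchor,
                            anchor_weight=anchor_weight).fit()


def suvr_trajectory(result, k: SUVRConstants = SUVRConstants(),
                    isoform: str = "both") -> pd.DataFrame:
    """Compose aggregate load and the uptake relation over a lifespan run.

    ``result`` is a LifespanResult; returns a frame with columns age,
    beta_L and suvr. ``isoform`` selects "both" (default) or a single
    isoform's aggregates.
    """
    load = result.abeta_load_series(k, isoform=isoform)
    return pd.DataFrame({
        "age": result.ages,
        "beta_L": load,
        "suvr": suvr_from_load(load, k),
    })
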