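"""Observed-vs-simulated agreement statistics for crop-model evaluation.

Given paired observed (Oᵢ) and simulated (Sᵢ) values the module reports the
standard crop-modelling battery:

    R²    = squared Pearson correlation of O and S
    RMSE  = √( Σ(Sᵢ − Oᵢ)² / n )
    MAE   = Σ|Sᵢ − Oᵢ| / n
    bias  = Σ(Sᵢ − Oᵢ) / n          (positive = over-simulation)
    S = a + b·O                      (1:1 regression slope/intercept)

Note the R² here is the *correlation* form: it is blind to additive or
multiplicative bias and therefore differs from the regression R²
(1 − SSE/SST) whenever the simulation is biased.  The latter is exposed as
``nse`` (Nash–Sutcliffe efficiency, computed against the observed mean),
which can be negative for badly biased simulations; the correlation form is
the default reported ``r_squared``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairedSeries", "EvalMetrics", "evaluate"]


@dataclass(frozen=True)
class PairedSeries:
    """Equal-length observed/simulated vectors with a variable label."""

    observed: np.ndarray
    simulated: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        obs = np.asarray(self.observed, dtype=float)
        sim = np.asarray(self.simulated, dtype=float)
        if obs.shape != sim.shape or obs.ndim != 1:
            raise ValueError("observed and simulated must be equal-length 1-D vectors")
        if len(obs) < 2:
            raise ValueError("need n >= 2 pairs")
        if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(sim))):
            raise ValueError("non-finite values present")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "simulated", sim)

    def __len__(self):
        return len(self.observed)


@dataclass(frozen=True)
class EvalMetrics:
    r_squared: float
    rmse: float
    mae: float
    bias: float
    slope: float
    intercept: float
    nse: float
    n: int

    def summary(self) -> str:
        return (
            f"n = {self.n}\n"
            f"R²        = {self.r_squared:.3f}\n"
            f"RMSE      = {self.rmse:.3f}\n"
            f"MAE       = {self.mae:.3f}\n"
            f"bias      = {self.bias:+.3f}\n"
            f"S = a + bO: a = {self.intercept:.3f}, b = {self.slope:.3f}\n"
            f"NSE       = {self.nse:.3f}"
        )

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared, "rmse": self.rmse, "mae": self.mae,
            "bias": self.bias, "slope": self.slope, "intercept": self.intercept,
            "nse": self.nse, "n": self.n,
        }


def evaluate(pairs: PairedSeries) -> EvalMetrics:
    """All agreement statistics for one observed/simulated pairing.

    Raises if the observed vector is constant (correlation, slope and NSE are
    then undefined).
    """
    obs, sim = pairs.observed, pairs.simulated
    n = len(obs)
    if np.ptp(obs) == 0:
        raise ValueError(
            "constant observed vector: R², regression slope/intercept and NSE "
            "are undefined"
        )
    do = obs - obs.mean()
    ds = sim - sim.mean()
    denom = np.sqrt((do**2).sum() * (ds**2).sum())
    r_squared = float((do @ ds) ** 2 / denom**2) if denom > 0 else 0.0
    err = sim - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    bias = float(np.mean(err))
    slope = float((do @ ds) / (do @ do))
    intercept = float(sim.mean() - slope * obs.mean())
    nse = float(1.0 - (err**2).sum() / (do**2).sum())
    return EvalMetrics(r_squared, rmse, mae, bias, slope, intercept, nse, n)
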