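"""Temperature and CO₂ sensitivity statistics over a pluggable yield model.

The headline statistics are simple and exact:

    yield loss (% per °C)      = (Y_ambient − Y_{+1°C}) / Y_ambient × 100
    yield change (% per 100ppm) = (Y_CO₂+n − Y_CO₂) / Y_CO₂ × 100

Driving them requires simulated yields over a ΔT × CO₂ grid.  A full
process-based crop simulator is out of scope here, so the module provides a
*surrogate* response surface — multiplicative linear loss in ΔT, saturating
(logarithmic) CO₂ benefit, additive Gaussian noise:

    Y(ΔT, C) = Y₀ · (1 − r·ΔT) · (1 + g·ln(C / C_ref)) + ε,  floored at 0.

It is a documented stand-in for exercising and testing the sensitivity
statistics, calibrated so its loss rate matches reported semi-arid wheat
responses (≈4.5 %/°C Islamabad-like, ≈6 %/°C Chakwal-like); it makes no claim
to emulate process-model dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weather import WeatherSeries

__all__ = [
    "SurrogateYieldModel",
    "SensitivityGrid",
    "surrogate_preset",
    "yield_loss_per_degC",
    "yield_change_per_co2",
    "run_grid",
    "apply_delta_t",
    "DEFAULT_DELTA_T",
    "DEFAULT_CO2_LEVELS",
]

#: Default temperature-increase grid, 0..+8 °C.
DEFAULT_DELTA_T = tuple(float(d) for d in range(0, 9))

#: Default CO₂ grid, 350..800 ppm.
DEFAULT_CO2_LEVELS = (350.0, 450.0, 550.0, 650.0, 800.0)


@dataclass(frozen=True)
class SurrogateYieldModel:
    """Surrogate wheat-yield response surface (see module docstring).

    Parameters
    ----------
    baseline_yield : t/ha at ΔT = 0 and C = co2_reference.
    temp_loss_rate : fractional yield loss per °C (0.045 = 4.5 %/°C).
    co2_response : fractional gain per log-unit CO₂.
    co2_reference : ppm at which the CO₂ term is neutral.
    noise_sd : additive Gaussian noise, t/ha.
    """

    baseline_yield: float = 4.0
    temp_loss_rate: float = 0.045
    co2_response: float = 0.08
    co2_reference: float = 350.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_yield <= 0:
            raise ValueError("baseline_yield must be > 0")
        if not 0 <= self.temp_loss_rate < 1:
            raise ValueError("temp_loss_rate must lie in [0, 1)")
        if self.co2_reference <= 0:
            raise ValueError("co2_reference must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def expected_yield(self, delta_t, co2) -> np.ndarray:
        """Noise-free response surface, floored at zero."""
        delta_t = np.asarray(delta_t, dtype=float)
        co2 = np.asarray(co2, dtype=float)
        y = (
            self.baseline_yield
            * (1.0 - self.temp_loss_rate * delta_t)
            * (1.0 + self.co2_response * np.log(co2 / self.co2_reference))
        )
        return np.maximum(y, 0.0)

    def simulate(self, delta_t, co2, replicates: int = 1,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        """Replicate yields at one (ΔT, CO₂) cell."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        mu = self.expected_yield(delta_t, co2)
        y = mu + rng.normal(0.0, self.noise_sd, size=replicates)
        return np.maximum(y, 0.0)


def surrogate_preset(site_name: str, **overrides) -> SurrogateYieldModel:
    """Site-calibrated surrogates: ≈4.5 %/°C (islamabad), ≈6 %/°C (chakwal),
    both with a 4.0 t/ha baseline."""
    presets = {
        "islamabad": dict(baseline_yield=4.0, temp_loss_rate=0.045, co2_response=0.08),
        "chakwal": dict(baseline_yield=4.0, temp_loss_rate=0.060, co2_response=0.07),
    }
    key = site_name.strip().lower()
    if key not in presets:
        raise KeyError(f"unknown site {site_name!r}; available: {sorted(presets)}")
    kw = presets[key] | overrides
    return SurrogateYieldModel(**kw)


# ---------------------------------------------------------------------------
# the sensitivity statistics
# ---------------------------------------------------------------------------

def yield_loss_per_degC(y_ambient, y_perturbed=None) -> float:
    """Percentage yield loss per °C of warming.

    Two call forms:

    * ``yield_loss_per_degC(y0, y1)`` — the +1 °C contrast,
      (y0 − y1) / y0 × 100;
    * ``yield_loss_per_degC(pairs)`` with ``pairs`` a sequence of
      (ΔT, yield) tuples including ΔT = 0 — each increment's loss is divided
      by its ΔT and the per-°C rates are averaged.
    """
    if y_perturbed is None:
        pairs = sorted((float(d), float(y)) for d, y in y_ambient)
        if not pairs or pairs[0][0] != 0.0:
            raise ValueError("pairs must include the ambient (ΔT = 0) yield")
        y0 = pairs[0][1]
        if y0 <= 0:
            raise ValueError("ambient yield must be > 0")
        rates = [
            (y0 - y) / y0 * 100.0 / d for d, y in pairs[1:] if d > 0
        ]
        if not rates:
            raise ValueError("no perturbed (ΔT > 0) entries")
        return float(np.mean(rates))
    y0 = float(y_ambient)
    if y0 <= 0:
        raise ValueError("ambient yield must be > 0")
    return (y0 - float(y_perturbed)) / y0 * 100.0


def yield_change_per_co2(y_base: float, y_elevated: float) -> float:
    """Percentage yield change under elevated CO₂:
    (Y_elevated − Y_base) / Y_base × 100."""
    y_base = float(y_base)
    if y_base <= 0:
        raise ValueError("baseline yield must be > 0")
    return (float(y_elevated) - y_base) / y_base * 100.0


# ---------------------------------------------------------------------------
# grid simulation
# ---------------------------------------------------------------------------

class SensitivityGrid:
    """Replicate yields on a complete ΔT × CO₂ grid plus summary statistics."""

    def __init__(self, data: pd.DataFrame, model: SurrogateYieldModel):
        required = {"delta_t", "co2", "replicate", "yield_t_ha"}
        if not required <= set(data.columns):
            raise ValueError(f"grid frame needs columns {sorted(required)}")
        counts = data.groupby(["delta_t", "co2"]).size()
        if counts.nunique() != 1:
            raise ValueError("incomplete grid: unequal replicate counts per cell")
        if (data["yield_t_ha"] < 0).any():
            raise ValueError("negative yields in grid")
        self.data = data.reset_index(drop=True)
        self.model = model
        self.delta_t_values = np.sort(data["delta_t"].unique())
        self.co2_levels = np.sort(data["co2"].unique())

    def cell_means(self) -> pd.DataFrame:
        return (
            self.data.groupby(["delta_t", "co2"])["yield_t_ha"]
            .mean()
            .reset_index()
        )

    def boxplot_summary(self) -> pd.DataFrame:
        """Five-number summary (min, q1, median, q3, max) per grid cell."""
        g = self.data.groupby(["delta_t", "co2"])["yield_t_ha"]
        out = g.agg(
            minimum="min",
            q1=lambda s: s.quantile(0.25),
            median="median",
            q3=lambda s: s.quantile(0.75),
            maximum="max",
        ).reset_index()
        return out

    def loss_per_degC(self, co2: float | None = None) -> float:
        """Average per-°C loss rate along the ΔT axis at one CO₂ level
        (default: the model's reference, or the lowest level present)."""
        if co2 is None:
            ref = self.model.co2_reference
            co2 = ref if ref in self.co2_levels else self.co2_levels[0]
        means = self.cell_means()
        col = means[means["co2"] == co2].sort_values("delta_t")
        pairs = list(zip(col["delta_t"], col["yield_t_ha"]))
        return yield_loss_per_degC(pairs)

    def change_per_100ppm(self, delta_t: float = 0.0) -> float:
        """Average yield change per 100 ppm CO₂ along the CO₂ axis at one
        ΔT (default ambient)."""
        means = self.cell_means()
        row = means[means["delta_t"] == delta_t].sort_values("co2")
        co2 = row["co2"].to_numpy()
        y = row["yield_t_ha"].to_numpy()
        base_c, base_y = co2[0], y[0]
        if base_y <= 0:
            raise ValueError("non-positive baseline yield")
        rates = [
            yield_change_per_co2(base_y, yi) / ((ci - base_c) / 100.0)
            for ci, yi in zip(co2[1:], y[1:])
        ]
        if not rates:
            raise ValueError("need at least two CO₂ levels")
        return float(np.mean(rates))

    def summary(self) -> dict:
        return {
            "loss_pct_per_degC": self.loss_per_degC(),
            "change_pct_per_100ppm": self.change_per_100ppm(),
            "n_cells": int(len(self.delta_t_values) * len(self.co2_levels)),
            "replicates": int(len(self.data)
                              // (len(self.delta_t_values) * len(self.co2_levels))),
        }


def run_grid(
    model: SurrogateYieldModel,
    delta_t_values=DEFAULT_DELTA_T,
    co2_levels=DEFAULT_CO2_LEVELS,
    replicates: int = 1,
    seed: int | None = None,
) -> SensitivityGrid:
    """Simulate *replicates* yields at every (ΔT, CO₂) combination.

    Reproducible from ``seed`` (default: the model's own seed).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    delta_t_values = [float(d) for d in delta_t_values]
    co2_levels = [float(c) for c in co2_levels]
    if not delta_t_values or not co2_levels:
        raise ValueError("empty grid axis")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    rows = []
    for d in delta_t_values:
        for c in co2_levels:
            y = model.simulate(d, c, replicates=replicates, rng=rng)
            for r, yi in enumerate(y):
                rows.append(
                    {"delta_t": d, "co2": c, "replicate": r, "yield_t_ha": float(yi)}
                )
    return SensitivityGrid(pd.DataFrame(rows), model)


def apply_delta_t(series: WeatherSeries, delta: float) -> WeatherSeries:
    """Uniform warming scenario: shift Tmax and Tmin by *delta* °C, rainfall
    untouched."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    return series.with_offset(float(delta))
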