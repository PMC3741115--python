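"""Closed-form well-mixed predictions for the volume-mean dopamine level.

These formulas balance the total quantal source against the uniform
first-order uptake and ignore diffusion entirely.  Under periodic
boundaries diffusion only redistributes mass, so the predictions are exact
for *volume means*; they say nothing about local values near release
sites — do not use them for that.

All formulas use the realized integer site count ``round(ρ·V)`` (52 sites
at ρ = 2e-4 /µm³ in the 64-µm cube), which is what a finite simulation
volume actually contains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import (
    GridSpec,
    LITRE_PER_UM3,
    NM_PER_MOLAR,
    ParameterError,
    SimulationParams,
    _round_half_up,
)

__all__ = [
    "MeanFieldInputs",
    "steady_state_mean",
    "phasic_delta_mean",
    "blocked_uptake_slope",
    "time_to_level",
]


@dataclass(frozen=True)
class MeanFieldInputs:
    """Parameters entering the well-mixed balance."""

    site_density: float      # sites / µm³ tissue
    f_tonic: float           # Hz
    f_phasic: float          # Hz (rate of the phasic cohort during the window)
    phasic_fraction: float   # fraction of sites firing phasically
    release_prob: float
    quantal_moles: float     # mol per event
    alpha: float             # extracellular volume fraction
    uptake_rate: float       # 1/s
    duration: float = 0.15   # s, length of the phasic window
    volume: float = 64.0**3  # µm³, used only to realize an integer site count

    @classmethod
    def from_params(
        cls,
        params: SimulationParams,
        f_phasic: float | None = None,
        phasic_fraction: float = 0.5,
        duration: float = 0.15,
    ) -> "MeanFieldInputs":
        return cls(
            site_density=params.site_density,
            f_tonic=params.f_tonic,
            f_phasic=params.f_phasic if f_phasic is None else f_phasic,
            phasic_fraction=phasic_fraction,
            release_prob=params.release_prob,
            quantal_moles=params.quantal_moles,
            alpha=params.alpha,
            uptake_rate=params.uptake_rate,
            duration=duration,
            volume=params.grid.volume,
        )

    @property
    def realized_density(self) -> float:
        """Integer site count divided by the volume, sites/µm³."""
        return _round_half_up(self.site_density * self.volume) / self.volume


def blocked_uptake_slope(inputs: MeanFieldInputs) -> float:
    """Growth rate (nM/s) of the volume mean when reuptake is fully blocked.

    ρ·f_tonic·p·Q / α, converted from mol per µm³ of extracellular water
    per second to nM/s.  With tonic release continuing this is the slope of
    the linear accumulation ramp.
    """
    rho = inputs.realized_density
    molar_per_s = (rho * inputs.f_tonic * inputs.release_prob * inputs.quantal_moles
                   / (inputs.alpha * LITRE_PER_UM3))
    return molar_per_s * NM_PER_MOLAR


def steady_state_mean(inputs: MeanFieldInputs) -> float:
    """Volume-mean steady-state concentration (nM) under tonic firing.

    ρ·f_tonic·p·Q / (α·k): the source rate divided by the clearance rate.
    Defaults give 26.2 nM; the Parkinsonian-like density 0.61e-4 gives 8.0.
    """
    if inputs.uptake_rate <= 0:
        raise ParameterError("no steady state without uptake (k must be > 0)")
    return blocked_uptake_slope(inputs) / inputs.uptake_rate


def phasic_delta_mean(inputs: MeanFieldInputs) -> float:
    """Volume-mean concentration change (nM) after the phasic window.

    A fraction φ of sites switches from f_tonic to f_phasic for ``duration``
    seconds; the well-mixed ODE dC/dt = source − k·C relaxes toward the new
    fixed point, giving

        ΔC = φ · (f_phasic − f_tonic)/f_tonic · C_ss · (1 − e^(−k·T)).

    Negative for a pause (f_phasic = 0).
    """
    if inputs.f_tonic <= 0:
        raise ParameterError("phasic change is defined relative to tonic firing > 0")
    if inputs.duration < 0:
        raise ParameterError("duration must be non-negative")
    css = steady_state_mean(inputs)
    rel = inputs.phasic_fraction * (inputs.f_phasic - inputs.f_tonic) / inputs.f_tonic
    return rel * css * (1.0 - math.exp(-inputs.uptake_rate * inputs.duration))


def time_to_level(inputs: MeanFieldInputs, target_nm: float,
                  baseline_nm: float | None = None) -> float:
    """Seconds for the blocked-reuptake ramp to climb from baseline to target.

    Used for the projection that a complete reuptake block drives the mean
    from its ~26-nM baseline to micromolar levels within tens of seconds.
    """
    slope = blocked_uptake_slope(inputs)
    if slope <= 0:
        raise ParameterError("no release: the level never rises")
    base = steady_state_mean(inputs) if baseline_nm is None else baseline_nm
    return (target_nm - base) / slope
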