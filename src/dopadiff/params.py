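"""Model constants, voxel-grid geometry and derived quantities.

All concentrations in this package are expressed in nM referred to the
*extracellular fluid* volume: a voxel holds tissue of volume ``spacing**3``
µm³ of which only the fraction ``alpha`` is extracellular water, and the
dopamine released into it is diluted in that water.  With this convention a
uniform first-order uptake ``k`` balances the quantal source exactly as in
the well-mixed limit (see :mod:`dopadiff.meanfield`).

Units used throughout: µm for length, s for time, mol for amount, nM for
concentration, Hz for rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "GridSpec",
    "SimulationParams",
    "ParameterError",
    "StabilityError",
    "stability_max_dt",
    "quantal_increment",
    "default_params",
]

#: litres per cubic micrometre
LITRE_PER_UM3 = 1e-15
#: nanomolar per (mol / litre)
NM_PER_MOLAR = 1e9


class ParameterError(ValueError):
    """Raised for physically inadmissible or inconsistent parameter values."""


class StabilityError(ParameterError):
    """Raised when a time step exceeds the explicit-Euler stability bound."""


Boundary = Literal["periodic", "reflecting"]


@dataclass(frozen=True)
class GridSpec:
    """Uniform cubic voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    spacing
        Edge length of one voxel in µm (voxels are cubes).
    boundary
        ``"periodic"`` (default) or ``"reflecting"`` (zero-flux).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 1.0
    boundary: Boundary = "periodic"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ParameterError(f"grid shape must be three positive ints, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if self.spacing <= 0:
            raise ParameterError("voxel spacing must be positive")
        if self.boundary not in ("periodic", "reflecting"):
            raise ParameterError(f"unknown boundary condition {self.boundary!r}")

    @property
    def n_voxels(self) -> int:
        return self.shape[0] * self.shape[1] * self.shape[2]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.spacing**3

    @property
    def volume(self) -> float:
        """Total tissue volume in µm³."""
        return self.n_voxels * self.voxel_volume

    @property
    def edge_lengths(self) -> tuple[float, float, float]:
        return tuple(n * self.spacing for n in self.shape)


def stability_max_dt(d_eff: float, spacing: float) -> float:
    """Largest stable time step for the explicit 7-point diffusion stencil.

    The forward-Euler step of the 3-D discrete Laplacian is stable for
    ``dt <= spacing**2 / (6 * D_eff)``; the engine refuses any larger step.
    """
    if d_eff <= 0 or spacing <= 0:
        raise ParameterError("d_eff and spacing must be positive")
    return spacing**2 / (6.0 * d_eff)


def quantal_increment(quantal_moles: float, alpha: float, voxel_volume: float) -> float:
    """Concentration jump (nM) in one voxel's extracellular water per vesicle.

    One quantum of ``quantal_moles`` mol is diluted into the extracellular
    fraction ``alpha`` of a voxel of ``voxel_volume`` µm³.
    """
    if quantal_moles <= 0 or voxel_volume <= 0:
        raise ParameterError("quantal_moles and voxel_volume must be positive")
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must lie in (0, 1]")
    litres = alpha * voxel_volume * LITRE_PER_UM3
    return quantal_moles / litres * NM_PER_MOLAR


@dataclass(frozen=True)
class SimulationParams:
    """All physical constants of the volume-transmission model.

    Defaults are the measured/assumed values for layer 3 of macaque
    prefrontal area 10: sparse dopaminergic boutons (2 per 10^4 µm³ of
    neuropil), tonic midbrain firing at 5.6 Hz with release probability
    0.5, a vesicle of 6.5e-20 L at 0.25 M dopamine, slow cortical reuptake
    (k = 1.5 /s, ten-fold slower than striatum) and hindered extracellular
    diffusion (D_eff = 322 µm²/s, i.e. free 763 µm²/s over tortuosity²).
    """

    site_density: float = 2e-4        # potential release sites per µm³ tissue
    alpha: float = 0.23               # extracellular volume fraction
    tortuosity: float = 1.54          # geometric hindrance (metadata; engine uses d_eff)
    d_free: float = 763.0             # free diffusion coefficient, µm²/s
    d_eff: float = 322.0              # effective diffusion coefficient, µm²/s
    vesicle_volume: float = 6.5e-20   # L
    vesicle_conc: float = 0.25        # mol/L
    quantal_moles: float = 1.625e-20  # mol released per event (= volume × conc)
    f_tonic: float = 5.6              # Hz
    f_phasic: float = 15.0            # Hz (burst); 26 Hz is the stronger protocol
    pause_rate: float = 0.0           # Hz (reward-omission pause)
    release_prob: float = 0.5         # per action potential
    uptake_rate: float = 1.5          # 1/s, uniform first-order clearance
    kd_high: float = 10.0             # nM, high-affinity receptor state
    kd_low: float = 1500.0            # nM, low-affinity (resting) state
    dt: float = 5e-4                  # s, just under the stability bound
    seed: int = 0
    uptake_block_time: float | None = None  # t (s) after which k = 0; None = never
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ParameterError("alpha must lie in (0, 1]")
        for name in ("site_density", "f_tonic", "f_phasic", "pause_rate",
                     "uptake_rate", "kd_high", "kd_low"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0 <= self.release_prob <= 1:
            raise ParameterError("release_prob must lie in [0, 1]")
        if self.d_eff <= 0 or self.d_free <= 0:
            raise ParameterError("diffusion coefficients must be positive")
        if self.d_eff > self.d_free:
            raise ParameterError("effective diffusivity cannot exceed the free one")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if not math.isclose(self.quantal_moles,
                            self.vesicle_volume * self.vesicle_conc, rel_tol=1e-6):
            raise ParameterError(
                "quantal_moles inconsistent with vesicle_volume × vesicle_conc "
                f"({self.quantal_moles} vs {self.vesicle_volume * self.vesicle_conc})"
            )
        if self.dt > self.max_stable_dt * (1 + 1e-12):
            raise StabilityError(
                f"dt={self.dt} exceeds the explicit-Euler stability bound "
                f"{self.max_stable_dt:.3e} s"
            )
        if self.uptake_block_time is not None and self.uptake_block_time < 0:
            raise ParameterError("uptake_block_time must be non-negative")

    # -- derived quantities ------------------------------------------------

    @property
    def max_stable_dt(self) -> float:
        return stability_max_dt(self.d_eff, self.grid.spacing)

    @property
    def quantal_increment_nm(self) -> float:
        """nM added to one voxel's extracellular water per release event."""
        return quantal_increment(self.quantal_moles, self.alpha, self.grid.voxel_volume)

    @property
    def n_sites(self) -> int:
        """Realized integer number of release sites in the grid."""
        return _round_half_up(self.site_density * self.grid.volume)

    @property
    def uptake_length(self) -> float:
        """Screening length sqrt(D_eff / k) in µm (inf if k = 0)."""
        if self.uptake_rate == 0:
            return math.inf
        return math.sqrt(self.d_eff / self.uptake_rate)

    def with_(self, **changes) -> "SimulationParams":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **changes)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def default_params(**overrides) -> SimulationParams:
    """The standard parameter set; keyword overrides are applied on top."""
    return SimulationParams(**overrides) if overrides else SimulationParams()
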