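"""Canned simulation protocols and their firing schedules.

The study protocols all share a 4-s tonic run-in (5.6 Hz, release
probability 0.5) that brings the volume to steady state, followed by a
phasic manipulation of part of the release-site population:

=========  =============================================  =================
name       phasic manipulation                            site density
=========  =============================================  =================
A          15 Hz for 150 ms, then 0 Hz for 150 ms         2e-4 /µm³
B          26 Hz for 150 ms                               2e-4 /µm³
C          pause (0 Hz) for 150 ms                        2e-4 /µm³
D          as A, Parkinsonian-like depleted innervation   0.61e-4 /µm³
E          tonic only, reuptake blocked from t = 1 s      2e-4 /µm³
=========  =============================================  =================

For A–D the phasic cohort is 10, 25 or 50% of sites firing in synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterError, SimulationParams
from .release import FiringSchedule

__all__ = ["ProtocolSpec", "PROTOCOLS", "get_protocol", "build_schedules",
           "table1_conditions", "MPTP_DENSITY", "TONIC_DURATION"]

#: depleted release-site density (≈70% loss), sites/µm³
MPTP_DENSITY = 0.61e-4
#: length of the tonic run-in to steady state, s (six uptake time constants)
TONIC_DURATION = 4.0
#: length of the phasic window, s
PHASIC_DURATION = 0.15


@dataclass(frozen=True)
class ProtocolSpec:
    """One simulation condition."""

    name: str
    site_density: float = 2e-4
    phasic_fraction: float = 0.5
    phasic_rate: float = 15.0        # Hz during the phasic window
    phasic_duration: float = PHASIC_DURATION
    pause_duration: float = 0.0      # 0-Hz window appended after the phasic one
    uptake_blocked: bool = False
    block_time: float = 1.0          # s, only if uptake_blocked
    tonic_duration: float = TONIC_DURATION
    t_end: float | None = None
    n_seeds: int = 10

    def __post_init__(self) -> None:
        for f in ("phasic_duration", "pause_duration", "tonic_duration"):
            if getattr(self, f) < 0:
                raise ParameterError(f"{f} must be non-negative")
        if not 0 <= self.phasic_fraction <= 1:
            raise ParameterError("phasic_fraction must lie in [0, 1]")

    @property
    def horizon(self) -> float:
        if self.t_end is not None:
            return self.t_end
        if self.uptake_blocked:
            return self.block_time + 2.5
        return self.tonic_duration + self.phasic_duration + self.pause_duration + 0.5


PROTOCOLS: dict[str, ProtocolSpec] = {
    "A": ProtocolSpec("A", phasic_rate=15.0, pause_duration=0.15),
    "B": ProtocolSpec("B", phasic_rate=26.0),
    "C": ProtocolSpec("C", phasic_rate=0.0),
    "D": ProtocolSpec("D", site_density=MPTP_DENSITY, phasic_rate=15.0,
                      pause_duration=0.15),
    "E": ProtocolSpec("E", phasic_fraction=0.0, uptake_blocked=True,
                      tonic_duration=3.5, t_end=3.5),
}


def get_protocol(name: str, **overrides) -> ProtocolSpec:
    try:
        spec = PROTOCOLS[name.upper()]
    except KeyError:
        raise ParameterError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOLS)}"
        ) from None
    if overrides:
        from dataclasses import replace

        spec = replace(spec, **overrides)
    return spec


def build_schedules(spec: ProtocolSpec, params: SimulationParams,
                    t_end: float | None = None) -> dict[str, FiringSchedule]:
    """Firing schedules per cohort for one protocol.

    The tonic cohort fires at f_tonic throughout.  The phasic cohort fires
    tonically until ``tonic_duration``, then at ``phasic_rate`` for
    ``phasic_duration``, optionally pauses, and returns to tonic.
    """
    p = params.release_prob
    t_end = spec.horizon if t_end is None else t_end
    tonic = FiringSchedule.constant(params.f_tonic, t_end, p)
    t0 = spec.tonic_duration
    segs = [(0.0, t0, params.f_tonic)]
    t = t0
    if spec.phasic_duration > 0 and t < t_end:
        t1 = min(t + spec.phasic_duration, t_end)
        segs.append((t, t1, spec.phasic_rate))
        t = t1
    if spec.pause_duration > 0 and t < t_end:
        t1 = min(t + spec.pause_duration, t_end)
        segs.append((t, t1, 0.0))
        t = t1
    if t < t_end:
        segs.append((t, t_end, params.f_tonic))
    return {"tonic": tonic, "phasic": FiringSchedule(tuple(segs), p)}


def table1_conditions() -> list[ProtocolSpec]:
    """The full condition grid of the summary table.

    Nine normal-density cells (15/26/0 Hz × 10/25/50%) plus the three
    depleted-density 15-Hz cells.
    """
    conds = []
    for rate, base in ((15.0, "A"), (26.0, "B"), (0.0, "C")):
        for frac in (0.10, 0.25, 0.50):
            conds.append(ProtocolSpec(f"{base}-{int(frac*100)}", phasic_rate=rate,
                                      phasic_fraction=frac))
    for frac in (0.10, 0.25, 0.50):
        conds.append(ProtocolSpec(f"D-{int(frac*100)}", site_density=MPTP_DENSITY,
                                  phasic_rate=15.0, phasic_fraction=frac))
    return conds
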