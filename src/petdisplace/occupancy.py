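"""Time-dependent drug-occupancy profiles for the displacement model.

Two parametric forms of the occupancy time-course d(t) are supported:

* ``numerical_ramp`` -- occupancy rises smoothly (cubic smoothstep) from 0
  at the drug-administration time ``t_b`` to its maximum ``d_max`` at
  ``t_e``, and stays there.  On [t_b, t_e] the profile is
  ``d_max * (1 + 2*(t_e - t)/(t_e - t_b)) * ((t - t_b)/(t_e - t_b))**2``,
  which equals ``d_max * (3*tau**2 - 2*tau**3)`` with
  ``tau = (t - t_b)/(t_e - t_b)``: continuous, nondecreasing, with zero
  slope at both ends.
* ``single_step`` -- occupancy jumps instantaneously from 0 to ``d_max``
  at the step time ``t_s`` (appropriate for fast-acting drugs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OccupancyProfile", "occupancy_value"]

_KINDS = ("numerical_ramp", "single_step")


@dataclass(frozen=True)
class OccupancyProfile:
    """Occupancy time-course d(t), fraction of target sites occupied.

    Parameters
    ----------
    kind : {"numerical_ramp", "single_step"}
    d_max : float
        Maximal occupancy, in the open interval (0, 1).
    t_b : float
        Drug administration time, minutes from scan start.
    t_e : float, optional
        Ramp end (numerical_ramp only); must satisfy ``t_e > t_b``.
    t_s : float, optional
        Step time (single_step only); must satisfy ``t_s > t_b``.
    """

    kind: str
    d_max: float
    t_b: float
    t_e: float | None = None
    t_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not (0.0 < self.d_max < 1.0):
            raise ValueError(f"d_max must be in (0, 1), got {self.d_max}")
        if not np.isfinite(self.t_b):
            raise ValueError("t_b must be finite")
        if self.kind == "numerical_ramp":
            if self.t_e is None or not self.t_e > self.t_b:
                raise ValueError("numerical_ramp requires t_e > t_b")
            if self.t_s is not None:
                raise ValueError("t_s is not a numerical_ramp parameter")
        else:
            if self.t_s is None or not self.t_s > self.t_b:
                raise ValueError("single_step requires t_s > t_b")
            if self.t_e is not None:
                raise ValueError("t_e is not a single_step parameter")

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate d(t) at time(s) ``t`` (minutes)."""
        t_arr = np.asarray(t, dtype=float)
        if self.kind == "numerical_ramp":
            tau = np.clip((t_arr - self.t_b) / (self.t_e - self.t_b), 0.0, 1.0)
            out = self.d_max * (3.0 * tau**2 - 2.0 * tau**3)
        else:
            out = np.where(t_arr > self.t_s, self.d_max, 0.0)
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(out)
        return out

    @property
    def timing(self) -> float:
        """The fitted timing parameter: ``t_e`` for the ramp, ``t_s`` for the step."""
        return self.t_e if self.kind == "numerical_ramp" else self.t_s


def occupancy_value(profile: OccupancyProfile, t) -> np.ndarray | float:
    """Occupancy d(t) at time ``t`` minutes (functional form of ``profile(t)``)."""
    return profile(t)
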