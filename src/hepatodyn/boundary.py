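"""Time-dependent boundary conditions: plasma metabolite and hormone
profiles clamping the external species of a model.

Periodic 24 h profiles are interpolated with a periodic cubic spline
(smooth forcing keeps the stiff integrator from restarting at knots);
aperiodic overlays (boluses, infusions) use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, interp1d


class BoundaryError(ValueError):
    pass


@dataclass
class BoundaryProfile:
    times: np.ndarray  # hours
    values: dict  # species id -> concentration series (mM)
    periodic: bool = False
    period: float = 24.0

    _interp: object = field(default=None, repr=False, compare=False)
    _ids: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise BoundaryError("profile needs at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise BoundaryError("profile times must be strictly increasing")
        self.values = {k: np.asarray(v, float) for k, v in self.values.items()}
        for sid, v in self.values.items():
            if v.shape != self.times.shape:
                raise BoundaryError(f"species {sid!r}: length mismatch with time grid")
            if np.any(v < 0):
                raise BoundaryError(f"species {sid!r}: negative concentration in profile")
        if self.periodic:
            t0, t1 = self.times[0], self.times[-1]
            if not np.isclose(t1 - t0, self.period):
                raise BoundaryError(
                    f"periodic profile must span one period ({self.period} h)")
            for sid, v in self.values.items():
                if not np.isclose(v[0], v[-1], rtol=1e-6, atol=1e-9):
                    raise BoundaryError(
                        f"species {sid!r}: endpoints differ on a periodic profile")

    # ------------------------------------------------------------- constructors
    @classmethod
    def constant(cls, concentrations: dict, t_span=(0.0, 24.0)) -> "BoundaryProfile":
        t = np.array([t_span[0], t_span[1]], float)
        vals = {k: np.full(2, float(v)) for k, v in concentrations.items()}
        return cls(t, vals, periodic=False)

    # ------------------------------------------------------------- evaluation
    @property
    def species_ids(self) -> list:
        return list(self.values)

    def _build(self):
        ids = self.species_ids
        Y = np.column_stack([self.values[s] for s in ids]) if ids else np.zeros((len(self.times), 0))
        if self.periodic:
            Yp = Y.copy()
            Yp[-1] = Yp[0]  # enforce exact closure for the periodic spline
            self._interp = CubicSpline(self.times, Yp, axis=0, bc_type="periodic")
        else:
            self._interp = interp1d(self.times, Y, axis=0, bounds_error=False,
                                    fill_value=(Y[0], Y[-1]))
        self._ids = ids

    def values_at(self, t) -> np.ndarray:
        """Interpolated concentrations at time ``t`` (array ordered as
        ``species_ids``).  Negative spline undershoot is clipped to 0."""
        if self._interp is None:
            self._build()
        if self.periodic:
            t = self.times[0] + np.mod(np.asarray(t) - self.times[0], self.period)
        return np.clip(self._interp(t), 0.0, None)

    def value_at(self, species_id: str, t):
        if self._interp is None:
            self._build()
        col = self._ids.index(species_id)
        out = self.values_at(t)
        return out[..., col]

    def mean_values(self) -> dict:
        """Time-averaged concentration of each species over the profile span
        (trapezoidal; for a periodic profile this is the 24 h mean)."""
        span = self.times[-1] - self.times[0]
        return {s: float(np.trapezoid(v, self.times) / span)
                for s, v in self.values.items()}

    def supports(self, t_span) -> bool:
        if self.periodic:
            return True
        return t_span[0] >= self.times[0] - 1e-9 and t_span[1] <= self.times[-1] + 1e-9

    # ------------------------------------------------------------- composition
    def with_species(self, extra: dict) -> "BoundaryProfile":
        """Return a profile extended with constant-valued species."""
        vals = dict(self.values)
        for sid, v in extra.items():
            vals[sid] = np.full_like(self.times, float(v))
        return BoundaryProfile(self.times.copy(), vals, self.periodic, self.period)

    def overlay(self, species_id: str, times, series,
                mode: str = "replace") -> "BoundaryProfile":
        """Overlay an aperiodic time series onto one species.

        The result is aperiodic on the union grid; other species are
        resampled from their interpolants.  ``mode`` is ``replace`` or
        ``add``.
        """
        times = np.asarray(times, float)
        grid = np.unique(np.concatenate([self.times, times]))
        if self.periodic:
            tmax = max(times[-1], self.times[-1])
            ext = np.arange(self.times[0], tmax + 1e-9, 0.25)
            grid = np.unique(np.concatenate([ext, times]))
        base = self.values_at(grid)
        vals = {s: base[:, i] for i, s in enumerate(self.species_ids)}
        overlay_vals = np.interp(grid, times, series, left=series[0], right=series[-1])
        if mode == "add":
            vals[species_id] = vals.get(species_id, 0.0) + overlay_vals
        else:
            vals[species_id] = overlay_vals
        return BoundaryProfile(grid, vals, periodic=False)

    def restricted(self, ids) -> "BoundaryProfile":
        missing = [s for s in ids if s not in self.values]
        if missing:
            raise BoundaryError(f"boundary profile lacks species {missing}")
        return BoundaryProfile(self.times.copy(),
                               {s: self.values[s] for s in ids},
                               self.periodic, self.period)
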