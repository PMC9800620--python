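"""Electrochemical performance metrics for microbial electrolysis cells.

The raw signal is a current trace sampled by a potentiostat (typically every
30 s).  From it this module computes:

* a rebinned trace (groups of ten 30-s readings averaged into 5-min values),
* the peak current over a window (highest 5-min average),
* the total charge, the time integral of current ``Q = int_{t1}^{t2} I(t) dt``,
* the coulombic efficiency,

  ``CE = Q / (F * V * sum_s b_s * dC_s)``

  where ``F`` is Faraday's constant, ``V`` the liquid volume (L), ``dC_s`` the
  consumed concentration of substrate ``s`` (mol/L) and ``b_s`` the number of
  electrons liberated when ``s`` is fully oxidised to CO2,
* the lag time before substantial current production (current density first
  exceeding a threshold, by default 1 A/m2).

Integration uses the trapezoid rule on the raw samples; the 5-min rebinned
series is used only for peak current and lag time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Faraday's constant, C per mol of electrons.
FARADAY = 96485.3

#: Electrons liberated per mol of substrate fully oxidised to CO2, from the
#: balanced half-reactions, e.g. C2H3O2- + 2H2O -> 2CO2 + 7H+ + 8e-.
ELECTRONS_PER_MOL = {
    "acetate": 8,
    "propionate": 14,
    "butyrate": 20,
}

SECONDS_PER_DAY = 86400.0


@dataclass
class CurrentTrace:
    """A timestamped current signal with reactor geometry.

    Attributes
    ----------
    time
        Sample times in seconds, strictly increasing.
    current
        Current in amperes at each sample time.
    electrode_area
        Projected anode area in m2 (> 0), used for current densities.
    volume
        Liquid volume of the reactor in litres (> 0).
    """

    time: np.ndarray
    current: np.ndarray
    electrode_area: float
    volume: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("time must be a non-empty 1-d array")
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have the same length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.electrode_area <= 0:
            raise ValueError("electrode_area must be positive")
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    @property
    def current_density(self) -> np.ndarray:
        """Current density in A/m2."""
        return self.current / self.electrode_area

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


@dataclass(frozen=True)
class TimeWindow:
    """Integration window [t1, t2] in seconds."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t2 > self.t1:
            raise ValueError("window requires t2 > t1")


@dataclass(frozen=True)
class SubstrateDelta:
    """Consumed substrate over a window: concentration change and stoichiometry.

    ``delta_conc`` is the consumed concentration (mol/L, positive for
    consumption).  ``electrons_per_mol`` defaults to the balanced-half-reaction
    value for the named substrate but may be overridden.
    """

    substrate: str
    delta_conc: float
    electrons_per_mol: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.delta_conc < 0:
            raise ValueError("delta_conc is the consumed amount; must be >= 0")
        if self.electrons_per_mol is None:
            object.__setattr__(
                self, "electrons_per_mol", electron_count(self.substrate)
            )


def electron_count(substrate: str) -> int:
    """Electrons liberated per mol of *substrate* oxidised to CO2 (b).

    Known substrates: acetate (8), propionate (14), butyrate (20).
    """
    try:
        return ELECTRONS_PER_MOL[substrate.lower()]
    except KeyError:
        known = ", ".join(sorted(ELECTRONS_PER_MOL))
        raise ValueError(f"unknown substrate {substrate!r}; known: {known}") from None


def rebin_current(trace: CurrentTrace, group_size: int = 10) -> CurrentTrace:
    """Average consecutive groups of samples into coarser bins.

    With 30-s sampling and the default ``group_size`` of 10 this produces the
    5-min average series.  Bin timestamps are the midpoint of the samples in
    the group; a trailing partial group is averaged over its available samples
    (so end-of-cycle peaks are preserved).
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n = trace.time.size
    if n == 0:
        raise ValueError("empty trace")
    edges = np.arange(0, n, group_size)
    t_binned = np.array([trace.time[s : s + group_size].mean() for s in edges])
    i_binned = np.array([trace.current[s : s + group_size].mean() for s in edges])
    return CurrentTrace(t_binned, i_binned, trace.electrode_area, trace.volume)


def _window_or_span(trace: CurrentTrace, window: TimeWindow | None) -> TimeWindow:
    if window is None:
        t0, t1 = trace.span
        return TimeWindow(t0, t1)
    t0, t1 = trace.span
    if window.t1 < t0 - 1e-9 or window.t2 > t1 + 1e-9:
        raise ValueError(
            f"window [{window.t1}, {window.t2}] outside trace span [{t0}, {t1}]"
        )
    return window


def peak_current(
    trace: CurrentTrace,
    window: TimeWindow | None = None,
    group_size: int = 10,
    rebin: bool = True,
) -> float:
    """Highest binned-average current (A) within *window*.

    The trace is rebinned first (``group_size`` samples per bin) unless it is
    already binned, in which case pass ``rebin=False``.
    """
    binned = rebin_current(trace, group_size) if rebin else trace
    window = _window_or_span(binned, window)
    mask = (binned.time >= window.t1) & (binned.time <= window.t2)
    if not mask.any():
        raise ValueError("window contains no binned samples")
    return float(binned.current[mask].max())


def total_charge(trace: CurrentTrace, window: TimeWindow | None = None) -> float:
    """Total charge in coulombs: trapezoidal integral of I(t) over the window.

    Window boundaries falling between samples are handled by linear
    interpolation of the current at t1 and t2.
    """
    window = _window_or_span(trace, window)
    inside = (trace.time > window.t1) & (trace.time < window.t2)
    t = np.concatenate(([window.t1], trace.time[inside], [window.t2]))
    i_bounds = np.interp([window.t1, window.t2], trace.time, trace.current)
    i = np.concatenate(([i_bounds[0]], trace.current[inside], [i_bounds[1]]))
    if t.size < 2:
        raise ValueError("window must contain at least two samples")
    return float(np.trapezoid(i, t))


def coulombic_efficiency(
    trace: CurrentTrace,
    window: TimeWindow | None,
    deltas: list[SubstrateDelta],
) -> float:
    """Fraction of electrons from consumed substrate recovered as current.

    ``CE = int I dt / (F * V * sum b * dC)``.  Dimensionless; values above 1
    indicate inconsistent inputs and are reported as-is, not clipped.
    """
    if not deltas:
        raise ValueError("at least one substrate delta is required")
    denom_mol = sum(d.electrons_per_mol * d.delta_conc for d in deltas)
    if denom_mol <= 0:
        raise ValueError("all substrate deltas are zero: CE undefined")
    charge = total_charge(trace, window)
    return charge / (FARADAY * trace.volume * denom_mol)


def lag_time(
    trace: CurrentTrace,
    threshold_density: float = 1.0,
    group_size: int = 10,
    rebin: bool = True,
) -> float | None:
    """Days from trace start until current density first exceeds the threshold.

    The 5-min (binned) average current density is compared against
    ``threshold_density`` (A/m2, default 1).  Returns the time in days of the
    first crossing bin, or ``None`` if the trace never crosses.
    """
    binned = rebin_current(trace, group_size) if rebin else trace
    above = binned.current_density > threshold_density
    if not above.any():
        return None
    t_cross = binned.time[int(np.argmax(above))]
    return float((t_cross - binned.time[0]) / SECONDS_PER_DAY)
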