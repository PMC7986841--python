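"""Gradient-coil source fields and waveform harmonic machinery.

The switched gradient waveforms over one representative interval Delta are
partitioned into subsignals (periodic trains such as an EPI readout, and
aperiodic transition lobes), each expanded in a truncated Fourier series.
Per-harmonic quasi-static eddy solutions (see :mod:`implantheat.eddy`) are
then superposed in the time domain to recover the instantaneous induced
current density in the implant.

Two coil descriptions are supported: an idealized uniform-gradient map
(linear field over the bore, matching the stated coil sensitivities) and a
filamentary model evaluated with the Biot-Savart law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MU_0 = 4e-7 * np.pi

#: Gradient coil sensitivities, T/(m A), for the x, y, z axis coils.
DEFAULT_SENSITIVITIES = (56.1e-6, 56.1e-6, 57.8e-6)


@dataclass
class CoilModel:
    """Gradient-coil field model.

    ``uniform-gradient`` mode returns the idealized linear field of each axis
    coil (B_z = G*u with u the coil axis coordinate; concomitant components
    are not modeled).  ``filamentary`` mode sums the Biot-Savart field of
    straight line segments carrying unit current, scaled to the requested
    gradient through the coil sensitivity.
    """

    mode: str = "uniform-gradient"
    sensitivities: tuple[float, float, float] = DEFAULT_SENSITIVITIES
    filaments: list[tuple[np.ndarray, np.ndarray]] | None = None
    linear_region: float = 0.5

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sensitivities):
            raise ValueError("sensitivities must be > 0")
        if self.mode not in ("uniform-gradient", "filamentary"):
            raise ValueError(f"unknown coil mode {self.mode!r}")
        if self.mode == "filamentary" and not self.filaments:
            raise ValueError("filamentary mode requires a nonempty filament list")


def biot_savart_segments(segments, points: np.ndarray, current: float = 1.0) -> np.ndarray:
    """B field (T) of straight current segments at ``points`` (n, 3).

    ``segments`` is an iterable of (start, end) arrays.  Uses the exact
    finite-segment formula.
    """
    points = np.atleast_2d(points)
    B = np.zeros_like(points, dtype=float)
    for a, b in segments:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        dl = b - a
        L = np.linalg.norm(dl)
        if L == 0:
            continue
        u = dl / L
        ap = points - a
        bp = points - b
        ra = np.linalg.norm(ap, axis=1)
        rb = np.linalg.norm(bp, axis=1)
        # perpendicular vector from the segment line to the point
        proj = ap @ u
        perp = ap - proj[:, None] * u
        d2 = np.einsum("ij,ij->i", perp, perp)
        with np.errstate(divide="ignore", invalid="ignore"):
            cos_a = proj / ra
            cos_b = (bp @ u) / rb
            factor = np.where(d2 > 0, (cos_a - cos_b) / d2, 0.0)
        direction = np.cross(np.broadcast_to(u, points.shape), perp)
        B += MU_0 * current / (4 * np.pi) * factor[:, None] * direction
    return B


def circular_loop(radius: float, z: float = 0.0, n_segments: int = 360):
    """Filament approximation of a circular loop in the plane z=const."""
    phi = np.linspace(0, 2 * np.pi, n_segments + 1)
    pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), np.full_like(phi, z)])
    return [(pts[i], pts[i + 1]) for i in range(n_segments)]


def demo_z_winding(radius: float = 0.36, spacing: float = 0.35, n_segments: int = 360):
    """Generic demonstration z-gradient winding: an anti-Helmholtz (Maxwell)
    pair of loops with opposed currents, for filamentary-mode exercises."""
    upper = circular_loop(radius, +spacing, n_segments)
    lower = [(b, a) for a, b in circular_loop(radius, -spacing, n_segments)]
    return upper + lower


def source_field(coil: CoilModel, points: np.ndarray, axis: int,
                 gradient: float = 1.0) -> np.ndarray:
    """Magnetic flux density (T) at ``points`` for one axis coil at a given
    gradient strength (T/m).

    Uniform mode: B = z_hat * gradient * u, u the axis coordinate; a warning
    is emitted for points outside the linear region.  Filamentary mode: the
    Biot-Savart sum scaled by gradient/sensitivity amperes.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if coil.mode == "uniform-gradient":
        u = points[:, axis]
        if np.any(np.abs(points).max(axis=1) > coil.linear_region):
            warnings.warn("points outside the gradient linear region", stacklevel=2)
        B = np.zeros_like(points)
        B[:, 2] = gradient * u
        return B
    current = gradient / coil.sensitivities[axis]
    return biot_savart_segments(coil.filaments, points, current)


def vector_potential(coil: CoilModel, points: np.ndarray, axis: int,
                     gradient: float = 1.0) -> np.ndarray:
    """Magnetic vector potential A (T m) for one axis coil, uniform mode.

    Gauges (divergence free, reproducing B_z = G*u):
      x coil: A = (0, G x^2 / 2, 0)
      y coil: A = (-G y^2 / 2, 0, 0)
      z coil: A = G z (-y/2, x/2, 0)   (symmetric gauge)
    The z-coil gauge carries the Maxwell-consistent concomitant components;
    x/y gauges are exact for the idealized linear map.
    """
    if coil.mode != "uniform-gradient":
        raise NotImplementedError(
            "vector potential is defined for the uniform-gradient mode; "
            "filamentary mode serves field evaluation only"
        )
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    A = np.zeros_like(points)
    if axis == 0:
        A[:, 1] = gradient * x**2 / 2
    elif axis == 1:
        A[:, 0] = -gradient * y**2 / 2
    elif axis == 2:
        A[:, 0] = -gradient * z * y / 2
        A[:, 1] = gradient * z * x / 2
    else:
        raise ValueError("axis must be 0, 1 or 2")
    return A


# ---------------------------------------------------------------------------
# Subsignal splitting
# ---------------------------------------------------------------------------

@dataclass
class Subsignal:
    """One contiguous segment of a gradient channel over Delta."""

    samples: np.ndarray
    start: int  # sample offset within Delta
    classification: str  # "periodic" | "aperiodic"
    period: int | None = None  # samples, for periodic segments

    def __post_init__(self) -> None:
        if self.classification not in ("periodic", "aperiodic"):
            raise ValueError("classification must be periodic or aperiodic")


def split_into_subsignals(
    channel: np.ndarray,
    boundaries: list[int] | None = None,
    periodic_flags: list[bool] | None = None,
    min_repeats: int = 3,
    rtol: float = 1e-9,
) -> list[Subsignal]:
    """Partition one gradient channel into periodic/aperiodic subsignals.

    With ``boundaries`` (sorted interior split indices) and optional
    ``periodic_flags`` the segmentation is manual.  Otherwise the longest
    exactly-repeating run is detected from the autocorrelation-candidate
    periods; the run (if it covers at least ``min_repeats`` periods) becomes
    a periodic subsignal and the remaining head/tail are aperiodic.
    Concatenating the returned segments reproduces the input exactly.
    """
    x = np.asarray(channel, dtype=float)
    n = x.size
    if boundaries is not None:
        edges = [0, *boundaries, n]
        if any(e1 >= e2 for e1, e2 in zip(edges, edges[1:])) or edges[0] != 0 or edges[-1] != n:
            raise ValueError("boundaries must be strictly increasing interior indices")
        flags = periodic_flags or [False] * (len(edges) - 1)
        if len(flags) != len(edges) - 1:
            raise ValueError("periodic_flags length must match segment count")
        return [
            Subsignal(x[a:b], a, "periodic" if f else "aperiodic")
            for a, b, f in zip(edges, edges[1:], flags)
        ]

    scale = np.abs(x).max(initial=0.0)
    if scale == 0.0:
        return [Subsignal(x, 0, "aperiodic")]

    best = None  # (run_length, -period, i0, i1, p)
    for p in _candidate_periods(x):
        match = np.abs(x[p:] - x[:-p]) <= rtol * scale
        i0, i1 = _longest_true_run(match)
        run = i1 - i0
        if run >= (min_repeats - 1) * p:
            key = (run + p, -p)
            if best is None or key > best[0]:
                best = (key, i0, i1 + p, p)
    if best is None:
        return [Subsignal(x, 0, "aperiodic")]
    _, i0, i1, p = best
    out: list[Subsignal] = []
    if i0 > 0:
        out.append(Subsignal(x[:i0], 0, "aperiodic"))
    out.append(Subsignal(x[i0:i1], i0, "periodic", period=p))
    if i1 < n:
        out.append(Subsignal(x[i1:], i1, "aperiodic"))
    return out


def _candidate_periods(x: np.ndarray, n_candidates: int = 8) -> list[int]:
    """Candidate periods from the peaks of the (biased) autocorrelation."""
    n = x.size
    xc = x - x.mean()
    if not np.any(xc):
        return []
    m = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(xc, m)) ** 2
    ac = np.fft.irfft(spec, m)[: n // 2]
    if ac.size < 3:
        return []
    peaks = np.where((ac[1:-1] > ac[:-2]) & (ac[1:-1] >= ac[2:]))[0] + 1
    peaks = peaks[ac[peaks] > 0.1 * ac[0]]
    order = np.argsort(ac[peaks])[::-1]
    return [int(p) for p in peaks[order][:n_candidates]]


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    if not mask.any():
        return 0, 0
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    k = int(np.argmax(ends - starts))
    return int(starts[k]), int(ends[k])


# ---------------------------------------------------------------------------
# Truncated Fourier expansion
# ---------------------------------------------------------------------------

@dataclass
class Harmonics:
    """Truncated Fourier expansion of one subsignal.

    The subsignal is represented as
    ``x(t) = Re( sum_k c_k exp(2j pi f_k t) )`` with t measured from the
    subsignal start; f_k = 0 carries the (real) mean.  ``energy_captured``
    is the retained fraction of the mean-square (Parseval bookkeeping).
    """

    frequencies: np.ndarray
    coefficients: np.ndarray
    n_samples: int
    dt: float
    energy_captured: float
    start: int = 0

    def reconstruct(self, t: np.ndarray | None = None) -> np.ndarray:
        if t is None:
            t = np.arange(self.n_samples) * self.dt
        phase = np.exp(2j * np.pi * np.outer(self.frequencies, t))
        return np.real(self.coefficients @ phase)


@dataclass
class HarmonicSet:
    """Per-axis, per-subsignal harmonic expansions of a gradient timeline."""

    per_axis: list[list[Harmonics]]  # [axis][subsignal]
    dt: float
    delta_interval: float
    subsignals: list[list[Subsignal]] = field(default_factory=lambda: [[], [], []])

    def all_frequencies(self) -> np.ndarray:
        freqs = [h.frequencies for per in self.per_axis for h in per]
        return np.unique(np.concatenate(freqs)) if freqs else np.array([])


def harmonic_decompose(
    subsignal: Subsignal | np.ndarray,
    dt: float,
    energy_fraction: float = 0.999,
    max_frequency: float = 100e3,
) -> Harmonics:
    """Truncated FFT expansion of one subsignal.

    Bins are retained in order of descending energy until ``energy_fraction``
    of the mean-square is captured, after discarding bins above
    ``max_frequency``.  The inverse transform of the retained coefficients
    reproduces the subsignal with RMS error <= sqrt(1 - energy_fraction)
    times the signal RMS (up to the frequency cap).
    """
    if isinstance(subsignal, Subsignal):
        x = subsignal.samples
        start = subsignal.start
    else:
        x = np.asarray(subsignal, dtype=float)
        start = 0
    n = x.size
    if n < 2:
        raise ValueError("subsignal must have at least 2 samples")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, dt)
    # one-sided coefficients: x = Re(sum c_k e^{2j pi f t}), DC weight 1
    coeff = spec / n
    weight = np.full(n // 2 + 1, 2.0)
    weight[0] = 1.0
    if n % 2 == 0:
        weight[-1] = 1.0
    coeff = coeff * weight
    energy = np.abs(spec) ** 2 * weight / n**2  # per-bin mean-square share
    total = energy.sum()
    keep = freqs <= max_frequency
    order = np.argsort(energy)[::-1]
    order = order[keep[order]]
    if total == 0:
        sel = order[:1]
        captured = 1.0
    else:
        csum = np.cumsum(energy[order])
        k = int(np.searchsorted(csum, energy_fraction * total)) + 1
        sel = np.sort(order[:k])
        captured = float(csum[min(k, csum.size) - 1] / total)
    return Harmonics(
        frequencies=freqs[sel],
        coefficients=coeff[sel],
        n_samples=n,
        dt=dt,
        energy_captured=captured,
        start=start,
    )


def decompose_timeline(
    timeline,
    energy_fraction: float = 0.999,
    max_frequency: float = 100e3,
    boundaries=None,
) -> HarmonicSet:
    """Split and decompose all three gradient channels of a timeline."""
    per_axis: list[list[Harmonics]] = []
    subs_all: list[list[Subsignal]] = []
    for axis in range(3):
        subs = split_into_subsignals(
            timeline.gradients[axis],
            boundaries=None if boundaries is None else boundaries[axis],
        )
        per_axis.append(
            [
                harmonic_decompose(s, timeline.dt, energy_fraction, max_frequency)
                for s in subs
            ]
        )
        subs_all.append(subs)
    return HarmonicSet(
        per_axis=per_axis,
        dt=timeline.dt,
        delta_interval=timeline.delta_interval,
        subsignals=subs_all,
    )
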