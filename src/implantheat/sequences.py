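"""Pulse-sequence waveform synthesis for TSE, EPI, GRE and TrueFISP.

Synthesizes the sampled RF envelope and the three gradient channels over one
representative interval Delta: the whole-slice acquisition frame for
single-shot EPI, and one TR for the other sequences.  Gradient lobes are
trapezoids obeying the per-sequence slew-rate limit, with amplitudes fixed by
the standard moment relations (readout amplitude from bandwidth and FOV,
slice-selection from the RF time-bandwidth product, phase encoding from the
k-space step).  RF pulses are apodized sinc pulses whose amplitude is set by
area-proportional flip-angle scaling.

The module also implements the whole-body-SAR duty-cycle bookkeeping: the
dead time appended after each acquisition to hold the time-averaged SARwb at
the 2 W/kg limit, and the resulting acquisition counts per exam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

#: Gyromagnetic ratio of 1H over 2*pi, Hz/T.
GAMMA_BAR = 42.577478518e6

#: Default waveform sample interval, s (>= 250 samples over the shortest 1 ms pulse).
DEFAULT_DT = 4e-6

#: Default gradient amplitude ceiling, T/m.
DEFAULT_GMAX = 40e-3


class InfeasibleGradientError(ValueError):
    """A gradient lobe cannot honor the slew limit within its time slot."""


@dataclass(frozen=True)
class SequenceParams:
    """Parameter set of one sequence, SI units (s, Hz, m, T/(m s)).

    ``flip_angles`` and ``rf_durations`` are tuples (excitation[, refocusing])
    in degrees and seconds.  ``matrix`` is (readout, phase), ``fov`` is
    (readout, phase) in meters.
    """

    kind: str
    flip_angles: tuple[float, ...]
    rf_durations: tuple[float, ...]
    time_bandwidth: float
    TE: float
    TR: float
    matrix: tuple[int, int]
    fov: tuple[float, float]
    slice_thickness: float
    readout_bandwidth: float
    slices_per_TR: int = 1
    echo_train_length: int = 1
    max_slew: float = 200.0
    dead_time: float = 0.0
    apodization: float = 0.5
    g_max: float = DEFAULT_GMAX

    def __post_init__(self) -> None:
        if self.TE >= self.TR:
            raise ValueError("TE must be < TR")
        if self.max_slew <= 0:
            raise ValueError("max_slew must be > 0")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")

    def with_(self, **kwargs) -> "SequenceParams":
        return replace(self, **kwargs)


#: Clinical parameter presets for the four analyzed sequences.
TSE = SequenceParams(
    kind="TSE", flip_angles=(90.0, 180.0), rf_durations=(1.6e-3, 1.6e-3),
    time_bandwidth=4.0, TE=6e-3, TR=260e-3, matrix=(128, 128),
    fov=(0.45, 0.45), slice_thickness=10e-3, readout_bandwidth=69e3,
    slices_per_TR=2, echo_train_length=16, max_slew=180.0,
)
EPI = SequenceParams(
    kind="EPI", flip_angles=(90.0,), rf_durations=(1.6e-3,),
    time_bandwidth=4.0, TE=21e-3, TR=43e-3, matrix=(64, 64),
    fov=(0.182, 0.182), slice_thickness=8e-3, readout_bandwidth=150e3,
    slices_per_TR=1, max_slew=167.0,
)
GRE = SequenceParams(
    kind="GRE", flip_angles=(20.0,), rf_durations=(10e-3,),
    time_bandwidth=10.0, TE=20e-3, TR=500e-3, matrix=(256, 256),
    fov=(0.14, 0.14), slice_thickness=4e-3, readout_bandwidth=20.83e3,
    slices_per_TR=11, max_slew=130.0,
)
TRUEFISP = SequenceParams(
    kind="TrueFISP", flip_angles=(45.0,), rf_durations=(1e-3,),
    time_bandwidth=4.0, TE=3.2e-3, TR=6.4e-3, matrix=(256, 256),
    fov=(0.18, 0.12), slice_thickness=4e-3, readout_bandwidth=126.3e3,
    slices_per_TR=1, max_slew=200.0,
)
PRESETS = {p.kind: p for p in (TSE, EPI, GRE, TRUEFISP)}


def truefisp_variant(which: int) -> SequenceParams:
    """TrueFISP variants: 1 = RF duration 1 -> 1.5 ms at fixed time-bandwidth
    product; 2 = readout bandwidth extended to 200 kHz at fixed RF duration."""
    if which == 1:
        return TRUEFISP.with_(rf_durations=(1.5e-3,))
    if which == 2:
        return TRUEFISP.with_(readout_bandwidth=200e3)
    raise ValueError("variant must be 1 or 2")


@dataclass
class SequenceTimeline:
    """Sampled waveforms over one representative interval Delta.

    ``gradients`` has shape (3, n) for the x, y, z gradient channels (T/m);
    ``rf_envelope`` is the nonnegative B1 magnitude (T).  ``schedule`` lists
    (active, dead) duration pairs covering the exam.
    """

    dt: float
    rf_envelope: np.ndarray
    gradients: np.ndarray
    delta_interval: float
    acquisition_duration: float
    schedule: list[tuple[float, float]] = field(default_factory=list)
    params: SequenceParams | None = None

    @property
    def n_samples(self) -> int:
        return self.rf_envelope.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def slew_rates(self) -> np.ndarray:
        return np.diff(self.gradients, axis=1) / self.dt

    def schedule_period(self) -> tuple[float, float]:
        """(active, dead) of one schedule entry; (Delta, 0) if no schedule."""
        if self.schedule:
            return self.schedule[0]
        return self.delta_interval, 0.0

    # -- I/O ----------------------------------------------------------------
    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["dt"] = self.dt
            fh.attrs["delta_interval"] = self.delta_interval
            fh.attrs["acquisition_duration"] = self.acquisition_duration
            fh.create_dataset("rf_envelope", data=self.rf_envelope)
            fh.create_dataset("gradients", data=self.gradients)
            fh.create_dataset("schedule", data=np.asarray(self.schedule, dtype=float))
            if self.params is not None:
                fh.attrs["params_json"] = json.dumps(
                    {k: v for k, v in self.params.__dict__.items()}
                )

    @classmethod
    def from_hdf5(cls, path: str) -> "SequenceTimeline":
        with h5py.File(path, "r") as fh:
            params = None
            if "params_json" in fh.attrs:
                raw = json.loads(fh.attrs["params_json"])
                for key in ("flip_angles", "rf_durations", "matrix", "fov"):
                    raw[key] = tuple(raw[key])
                params = SequenceParams(**raw)
            return cls(
                dt=float(fh.attrs["dt"]),
                rf_envelope=fh["rf_envelope"][()],
                gradients=fh["gradients"][()],
                delta_interval=float(fh.attrs["delta_interval"]),
                acquisition_duration=float(fh.attrs["acquisition_duration"]),
                schedule=[tuple(row) for row in fh["schedule"][()]],
                params=params,
            )

    def to_csv(self, path: str) -> None:
        data = np.column_stack(
            [self.times, self.rf_envelope, self.gradients.T]
        )
        np.savetxt(
            path, data, delimiter=",",
            header="t_s,b1_T,gx_T_per_m,gy_T_per_m,gz_T_per_m", comments="",
        )


READ, PHASE, SLICE = 0, 1, 2  # gradient channel assignment (x, y, z)


class _Assembler:
    """Accumulates lobes and pulses onto sampled channels."""

    def __init__(self, duration: float, dt: float):
        self.dt = dt
        self.n = int(round(duration / dt))
        self.rf = np.zeros(self.n)
        self.g = np.zeros((3, self.n))

    def add_trap(self, channel: int, t0: float, amp: float, flat: float,
                 ramp: float, name: str) -> float:
        """Render one trapezoid; returns its end time."""
        dur = 2 * ramp + flat
        i0 = int(round(t0 / self.dt))
        i1 = int(round((t0 + dur) / self.dt))
        if i0 < 0 or i1 > self.n:
            raise InfeasibleGradientError(
                f"lobe '{name}' [{t0:.6f}, {t0 + dur:.6f}] s does not fit the interval"
            )
        t = (np.arange(i0, i1) - i0) * self.dt
        knots_t = [0.0, ramp, ramp + flat, dur]
        knots_v = [0.0, amp, amp, 0.0]
        self.g[channel, i0:i1] += np.interp(t, knots_t, knots_v)
        return t0 + dur

    def add_rf(self, t0: float, flip_deg: float, duration: float,
               tbw: float, apod: float) -> float:
        """Render one apodized-sinc RF pulse; returns its end time."""
        i0 = int(round(t0 / self.dt))
        i1 = int(round((t0 + duration) / self.dt))
        if i0 < 0 or i1 > self.n:
            raise InfeasibleGradientError(
                f"RF pulse at {t0:.6f} s does not fit the interval"
            )
        t = ((np.arange(i0, i1) - i0) + 0.5) * self.dt - duration / 2
        shape = np.sinc(tbw * t / duration) * ((1 - apod) + apod * np.cos(2 * np.pi * t / duration))
        area = shape.sum() * self.dt  # signed area of the unit-amplitude shape
        flip = np.deg2rad(flip_deg)
        amp = flip / (2 * np.pi * GAMMA_BAR * area) if flip != 0 else 0.0
        self.rf[i0:i1] += np.abs(amp * shape)
        return t0 + duration


def _lobe_for_moment(moment: float, slew: float, g_max: float, dt: float,
                     name: str) -> tuple[float, float, float]:
    """(amp, flat, ramp) of the shortest trapezoid with a given zeroth moment."""
    m = abs(moment)
    if m == 0:
        return 0.0, 0.0, dt
    amp = np.sqrt(m * slew)
    if amp <= g_max:
        ramp = max(amp / slew, dt)
        amp = m / ramp  # keep the moment exact if ramp was clamped to dt
        flat = 0.0
    else:
        amp = g_max
        ramp = max(amp / slew, dt)
        flat = m / amp - ramp
        if flat < 0:
            raise InfeasibleGradientError(f"lobe '{name}': moment infeasible")
    # quantize to the sample grid, preserving the moment via the amplitude
    ramp = max(dt, np.ceil(ramp / dt - 1e-9) * dt)
    flat = round(flat / dt) * dt
    amp = m / (ramp + flat)
    if amp / ramp > slew * (1 + 1e-9):
        ramp += dt
        amp = m / (ramp + flat)
    return np.sign(moment) * amp, flat, ramp


@dataclass
class _Dims:
    """Derived lobe dimensions shared by the sequence builders."""

    g_read: float
    ramp_read: float
    flat_read: float
    g_ss: float
    ramp_ss: float
    dky: float  # phase-encode moment per k-space line, T s / m


def _dims(p: SequenceParams, dt: float) -> _Dims:
    g_read = p.readout_bandwidth / (GAMMA_BAR * p.fov[0])
    if g_read > p.g_max:
        raise InfeasibleGradientError("readout lobe: amplitude exceeds g_max")
    ramp_read = max(dt, np.ceil(g_read / p.max_slew / dt) * dt)
    flat_read = round(p.matrix[0] / p.readout_bandwidth / dt) * dt
    g_ss = p.time_bandwidth / (GAMMA_BAR * p.rf_durations[0] * p.slice_thickness)
    if g_ss > p.g_max:
        raise InfeasibleGradientError("slice-selection lobe: amplitude exceeds g_max")
    ramp_ss = max(dt, np.ceil(g_ss / p.max_slew / dt) * dt)
    dky = 1.0 / (GAMMA_BAR * p.fov[1])
    return _Dims(g_read, ramp_read, flat_read, g_ss, ramp_ss, dky)


def pe_moment(params: SequenceParams, line_index: int) -> float:
    """Zeroth moment (T s/m) of the phase-encode lobe for one k-space line.

    ``line_index`` runs from -matrix_phase/2 to matrix_phase/2 - 1; moments
    grow linearly across lines.
    """
    return line_index / (GAMMA_BAR * params.fov[1])


def _slice_select(asm: _Assembler, p: SequenceParams, d: _Dims, t: float,
                  flip: float, rf_dur: float, refocus: bool) -> float:
    """Excitation/refocusing block: slice gradient plateau + centered RF."""
    ramp_ss = max(asm.dt, np.ceil((d.g_ss * rf_dur / p.rf_durations[0]) / p.max_slew / asm.dt) * asm.dt)
    g_ss = p.time_bandwidth / (GAMMA_BAR * rf_dur * p.slice_thickness)
    end = asm.add_trap(SLICE, t, g_ss, rf_dur, ramp_ss, "slice-selection")
    asm.add_rf(t + ramp_ss, flip, rf_dur, p.time_bandwidth, p.apodization)
    if refocus:
        m = -g_ss * (rf_dur + ramp_ss) / 2
        amp, flat, ramp = _lobe_for_moment(m, p.max_slew, p.g_max, asm.dt, "slice refocus")
        end = asm.add_trap(SLICE, end, amp, flat, ramp, "slice refocus")
    return end


def build_sequence(params: SequenceParams, dt: float = DEFAULT_DT,
                   exam_duration: float = 360.0,
                   pe_line: int | None = None) -> SequenceTimeline:
    """Synthesize the representative interval Delta for one sequence.

    ``pe_line`` selects the representative phase-encode line (default: the
    k-space edge, -matrix_phase/2, the largest-moment and hence most
    conservative encoding step).
    """
    p = params
    d = _dims(p, dt)
    if pe_line is None:
        pe_line = -p.matrix[1] // 2
    builder = {
        "TSE": _build_tse, "EPI": _build_epi,
        "GRE": _build_gre, "TrueFISP": _build_fisp,
    }.get(p.kind)
    if builder is None:
        raise ValueError(f"unknown sequence kind {p.kind!r}")
    timeline = builder(p, d, dt, pe_line)
    _check_slew(timeline, p.max_slew)
    active = timeline.acquisition_duration
    n_periods = max(1, int(np.ceil(exam_duration / (active + p.dead_time))))
    timeline.schedule = [(active, p.dead_time)] * n_periods
    return timeline


def _check_slew(tl: SequenceTimeline, max_slew: float) -> None:
    worst = np.abs(tl.slew_rates()).max(initial=0.0)
    if worst > max_slew * (1 + 1e-6):
        raise InfeasibleGradientError(
            f"synthesized waveform violates slew limit: {worst:.1f} > {max_slew} T/(m s)"
        )


def _pe_pair(asm, p, d, t_start, t_end, line, name):
    """Phase-encode blip at t_start and rewinder ending near t_end."""
    m = pe_moment(p, line)
    amp, flat, ramp = _lobe_for_moment(m, p.max_slew, p.g_max, asm.dt, name)
    if m != 0:
        asm.add_trap(PHASE, t_start, amp, flat, ramp, name)
        asm.add_trap(PHASE, t_end - (2 * ramp + flat), -amp, flat, ramp, name + " rewind")


def _build_tse(p: SequenceParams, d: _Dims, dt: float, pe_line: int) -> SequenceTimeline:
    """One TR: per slice, a 90deg excitation then an echo train of 180deg
    refocusing pulses, each followed by a phase-encoded readout."""
    asm = _Assembler(p.TR, dt)
    esp = p.TE  # echo spacing
    slot = p.TR / p.slices_per_TR
    n_shots = p.matrix[1] // p.echo_train_length
    read_dur = 2 * d.ramp_read + d.flat_read
    for s in range(p.slices_per_TR):
        t0 = s * slot
        exc_dur = p.rf_durations[0] + 2 * d.ramp_ss
        t = _slice_select(asm, p, d, t0, p.flip_angles[0], p.rf_durations[0], refocus=True)
        exc_center = t0 + exc_dur / 2
        # readout prephaser (+half moment: the first 180 inverts it)
        m_pre = d.g_read * (d.flat_read + d.ramp_read) / 2
        amp, flat, ramp = _lobe_for_moment(m_pre, p.max_slew, p.g_max, dt, "readout prephaser")
        asm.add_trap(READ, t, amp, flat, ramp, "readout prephaser")
        for e in range(p.echo_train_length):
            rf_dur = p.rf_durations[-1]
            ref_dur = rf_dur + 2 * d.ramp_ss
            t_ref = exc_center + (e + 0.5) * esp - ref_dur / 2
            _slice_select(asm, p, d, t_ref, p.flip_angles[-1], rf_dur, refocus=False)
            t_echo = exc_center + (e + 1) * esp
            t_read = t_echo - read_dur / 2
            asm.add_trap(READ, t_read, d.g_read, d.flat_read, d.ramp_read, "readout")
            line = e * n_shots + pe_line  # shot-0 interleaved line ordering
            _pe_pair(asm, p, d, t_ref + ref_dur, t_read + read_dur + (t_read - (t_ref + ref_dur)),
                     line, f"phase encode echo {e}")
    acq = n_shots * p.TR
    return SequenceTimeline(dt, asm.rf, asm.g, p.TR, acq, params=p)


def _build_epi(p: SequenceParams, d: _Dims, dt: float, pe_line: int) -> SequenceTimeline:
    """One single-shot acquisition frame: excitation followed by the
    alternating-readout trapezoid train with phase blips at the reversals."""
    n_lines = p.matrix[1]
    lobe_dur = 2 * d.ramp_read + d.flat_read
    exc_dur = p.rf_durations[0] + 2 * d.ramp_ss
    m_ss_ref = d.g_ss * (p.rf_durations[0] + d.ramp_ss) / 2
    _, flat_r, ramp_r = _lobe_for_moment(m_ss_ref, p.max_slew, p.g_max, dt, "slice refocus")
    m_pre = d.g_read * (d.flat_read + d.ramp_read) / 2
    _, flat_p, ramp_p = _lobe_for_moment(m_pre, p.max_slew, p.g_max, dt, "readout prephaser")
    pre_dur = max(2 * ramp_p + flat_p, 2 * ramp_r + flat_r)
    frame = exc_dur + pre_dur + n_lines * lobe_dur + 10 * dt
    delta = round(np.ceil(frame / dt)) * dt

    asm = _Assembler(delta, dt)
    t = _slice_select(asm, p, d, 0.0, p.flip_angles[0], p.rf_durations[0], refocus=True)
    amp, flat, ramp = _lobe_for_moment(-m_pre, p.max_slew, p.g_max, dt, "readout prephaser")
    asm.add_trap(READ, exc_dur, amp, flat, ramp, "readout prephaser")
    m_pe0 = pe_moment(p, pe_line)
    if m_pe0 != 0:
        amp, flat, ramp = _lobe_for_moment(m_pe0, p.max_slew, p.g_max, dt, "phase prephaser")
        asm.add_trap(PHASE, exc_dur, amp, flat, ramp, "phase prephaser")
    t = exc_dur + pre_dur
    m_blip = pe_moment(p, 1)  # one k-space line per blip
    amp_b, flat_b, ramp_b = _lobe_for_moment(m_blip, p.max_slew, p.g_max, dt, "phase blip")
    blip_dur = 2 * ramp_b + flat_b
    for k in range(n_lines):
        sign = 1 if k % 2 == 0 else -1
        t_end = asm.add_trap(READ, t, sign * d.g_read, d.flat_read, d.ramp_read, "EPI readout")
        if k < n_lines - 1:
            asm.add_trap(PHASE, t_end - blip_dur / 2, amp_b, flat_b, ramp_b, "phase blip")
        t = t_end
    return SequenceTimeline(dt, asm.rf, asm.g, delta, delta, params=p)


def _build_gre(p: SequenceParams, d: _Dims, dt: float, pe_line: int) -> SequenceTimeline:
    """One TR of a spoiled multislice gradient echo: per slice, a low-flip
    excitation, phase encoding, prephased readout, then spoiler + rewinder."""
    asm = _Assembler(p.TR, dt)
    slot = p.TR / p.slices_per_TR
    read_dur = 2 * d.ramp_read + d.flat_read
    m_read = d.g_read * (d.flat_read + d.ramp_read)
    for s in range(p.slices_per_TR):
        t0 = s * slot
        t = _slice_select(asm, p, d, t0, p.flip_angles[0], p.rf_durations[0], refocus=True)
        amp, flat, ramp = _lobe_for_moment(-m_read / 2, p.max_slew, p.g_max, dt, "readout prephaser")
        t_pre_end = asm.add_trap(READ, t, amp, flat, ramp, "readout prephaser")
        _pe_pair(asm, p, d, t, t_pre_end + read_dur + (t_pre_end - t), pe_line, "phase encode")
        t_read_end = asm.add_trap(READ, t_pre_end, d.g_read, d.flat_read, d.ramp_read, "readout")
        amp, flat, ramp = _lobe_for_moment(m_read, p.max_slew, p.g_max, dt, "spoiler")
        end = asm.add_trap(READ, t_read_end, amp, flat, ramp, "spoiler")
        if end > t0 + slot:
            raise InfeasibleGradientError("GRE slice block exceeds its TR slot")
    return SequenceTimeline(dt, asm.rf, asm.g, p.TR, p.TR, params=p)


def _build_fisp(p: SequenceParams, d: _Dims, dt: float, pe_line: int) -> SequenceTimeline:
    """One TR of balanced SSFP: symmetric slice lobes around the excitation,
    fully balanced readout and phase encoding."""
    asm = _Assembler(p.TR, dt)
    rf_dur = p.rf_durations[0]
    m_ss_half = d.g_ss * (rf_dur + d.ramp_ss) / 2
    amp_h, flat_h, ramp_h = _lobe_for_moment(-m_ss_half, p.max_slew, p.g_max, dt, "slice balance")
    half_dur = 2 * ramp_h + flat_h
    t = asm.add_trap(SLICE, 0.0, amp_h, flat_h, ramp_h, "slice balance (pre)")
    t = _slice_select(asm, p, d, t, p.flip_angles[0], rf_dur, refocus=False)
    t = asm.add_trap(SLICE, t, amp_h, flat_h, ramp_h, "slice balance (post)")
    m_pre = d.g_read * (d.flat_read + d.ramp_read) / 2
    amp, flat, ramp = _lobe_for_moment(-m_pre, p.max_slew, p.g_max, dt, "readout balance")
    pre_dur = 2 * ramp + flat
    t_pre_end = asm.add_trap(READ, t, amp, flat, ramp, "readout balance (pre)")
    read_dur = 2 * d.ramp_read + d.flat_read
    _pe_pair(asm, p, d, t, t_pre_end + read_dur + pre_dur, pe_line, "phase encode")
    t = asm.add_trap(READ, t_pre_end, d.g_read, d.flat_read, d.ramp_read, "readout")
    asm.add_trap(READ, t, amp, flat, ramp, "readout balance (post)")
    return SequenceTimeline(dt, asm.rf, asm.g, p.TR, p.TR, params=p)


# ---------------------------------------------------------------------------
# SAR duty-cycle bookkeeping
# ---------------------------------------------------------------------------

def rf_mean_square_b1(timeline: SequenceTimeline, include_dead: bool = True) -> float:
    """Time-averaged <B1^2> (T^2) of the timeline.

    Averaged over one schedule period (acquisition + dead time) when
    ``include_dead`` is true, else over the active interval only.  Quadratic
    in the RF amplitude and linear in the duty cycle.
    """
    if timeline.n_samples == 0:
        raise ValueError("empty timeline")
    energy = float(np.sum(timeline.rf_envelope**2)) * timeline.dt
    mean_active = energy / timeline.delta_interval
    if not include_dead:
        return mean_active
    active, dead = timeline.schedule_period()
    return mean_active * active / (active + dead)


def dead_time_for_sar(sar_unscaled: float, t_active: float,
                      sar_limit: float = 2.0) -> float:
    """Dead time (s) after each acquisition holding time-averaged SARwb at
    ``sar_limit``: max(0, t_active * (sar_unscaled/sar_limit - 1))."""
    if sar_unscaled <= 0 or t_active <= 0 or sar_limit <= 0:
        raise ValueError("sar_unscaled, t_active and sar_limit must be > 0")
    return max(0.0, t_active * (sar_unscaled / sar_limit - 1.0))


def count_acquisitions(total_time: float, t_active: float, dead_time: float) -> int:
    """Number of acquisitions fitting an exam: round(total / (active + dead))."""
    if total_time < 0 or dead_time < 0 or t_active <= 0:
        raise ValueError("times must be >= 0 and t_active > 0")
    return int(round(total_time / (t_active + dead_time)))
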