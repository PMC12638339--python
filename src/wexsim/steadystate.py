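"""Steady-state simulation of free-running bSSFP (with any excitation pulse)
and FISS over off-resonance and flip-angle grids.

bSSFP: each TR holds one excitation with alternating (0/180 deg) RF phase,
the pulse placed symmetrically in the TR, free precession with relaxation on
either side, and the echo sampled at TE = TR/2 (measured from the pulse
center). The receiver is demodulated by the excitation phase so the
on-resonance pass-band signal is coherent across excitations.

FISS: the bSSFP train is broken into modules of ``readouts_per_module`` (NR)
full-alpha excitations bracketed by alpha/2 catalyzation/restoration pulses;
after each module the transverse magnetization is nulled (perfect RF +
gradient spoiling) and the module base phase is advanced by a quadratic
117-degree law. With perfect spoiling the result is insensitive to the
spoiling increment (property-tested).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .bloch import ResponseMap, TissueParams, equilibrium, free_precess, rotate_segment
from .calibration import calibrate_amplitude
from .pulses import PulseKind, PulseParams, RFPulse, RFSegment, make_pulse

__all__ = [
    "Scheme",
    "PhaseCycling",
    "SequenceParams",
    "simulate_bssfp",
    "simulate_fiss",
    "steady_state_map",
    "default_alpha_grid",
]


class Scheme(str, enum.Enum):
    BSSFP = "BSSFP"
    FISS = "FISS"


class PhaseCycling(str, enum.Enum):
    ALTERNATING = "ALTERNATING"
    NONE = "NONE"


@dataclass
class SequenceParams:
    """Timing and scheme parameters of one free-running acquisition."""

    tr: float
    te: float | None = None  # defaults to TR/2
    n_excitations: int = 1000
    scheme: Scheme = Scheme.BSSFP
    readouts_per_module: int = 4
    spoil_increment: float = 117.0  # degrees, quadratic law across modules
    phase_cycling: PhaseCycling = PhaseCycling.ALTERNATING

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        self.phase_cycling = PhaseCycling(self.phase_cycling)
        if self.te is None:
            self.te = self.tr / 2.0
        if not (0 < self.te < self.tr):
            raise ValueError(f"require 0 < te < tr, got te={self.te}, tr={self.tr}")
        if self.n_excitations < 1:
            raise ValueError("n_excitations must be >= 1")
        if self.readouts_per_module < 1:
            raise ValueError("readouts_per_module must be >= 1")


def _apply_pulse_norelax(m, pulse: RFPulse, df):
    n = len(pulse.segments)
    for i, seg in enumerate(pulse.segments):
        m = rotate_segment(m, seg, df)
        if pulse.gap and i + 1 < n:
            m = free_precess(m, pulse.gap, df, tissue=None)
    return m


def _fixed_point(propagate, df_size: int) -> np.ndarray:
    """Exact fixed point of an affine per-period Bloch map.

    One period of any pulse/precession/relaxation sequence acts on the
    magnetization as ``m -> A m + b``; A and b are recovered by propagating
    the zero vector and the three basis vectors, and the steady state is the
    solution of ``(I - A) m = b`` (A is a contraction whenever T2 is finite).
    """
    basis = np.zeros((4, df_size, 3))
    basis[1, :, 0] = 1.0
    basis[2, :, 1] = 1.0
    basis[3, :, 2] = 1.0
    out = propagate(basis)
    b = out[0]
    a_cols = out[1:] - b[None]  # (3, ndf, 3): a_cols[j] = A @ e_j
    a = np.stack(a_cols, axis=-1)  # (ndf, 3, 3)
    eye = np.eye(3)[None]
    return np.linalg.solve(eye - a, b[..., None])[..., 0]


def simulate_bssfp(
    pulse: RFPulse,
    seq: SequenceParams,
    tissue: TissueParams,
    delta_f,
    return_history: bool = False,
    init: str = "steady",
):
    """Steady-state complex Mxy at TE for a bSSFP train.

    ``delta_f`` may be a scalar or an array (vectorized). Relaxation acts
    during free precession; the RF pulse itself is a relaxation-free rotation
    of its stated duration. The train starts at the exact periodic fixed
    point of the (two-TR, for alternating cycling) Bloch map
    (``init="steady"``; ``init="equilibrium"`` starts from (0,0,1) instead,
    which after 1000 excitations still carries a ~1% transient because the
    effective relaxation time T1* is of order a second). Returns the
    demodulated TE signal of the final excitation, or the full
    per-excitation history if ``return_history``.
    """
    if seq.scheme is not Scheme.BSSFP:
        raise ValueError("simulate_bssfp requires scheme=BSSFP")
    df = np.atleast_1d(np.asarray(delta_f, dtype=float))
    gap = (seq.tr - pulse.total_duration) / 2.0
    if gap < 0:
        raise ValueError(
            f"pulse ({pulse.total_duration*1e3:.2f} ms) does not fit in TR "
            f"({seq.tr*1e3:.2f} ms)"
        )
    alternating = seq.phase_cycling is PhaseCycling.ALTERNATING

    def one_tr(m, phase):
        m = _apply_pulse_norelax(m, pulse.with_extra_phase(phase) if phase else pulse, df)
        m = free_precess(m, gap, df, tissue)
        sig = (m[..., 0] + 1j * m[..., 1]) * np.exp(-1j * phase)
        return free_precess(m, gap, df, tissue), sig

    if init == "steady":

        def period(m):
            m, _ = one_tr(m, 0.0)
            if alternating:
                m, _ = one_tr(m, math.pi)
            return m

        m = _fixed_point(period, df.size)
    elif init == "equilibrium":
        m = equilibrium(df.shape)
    else:
        raise ValueError(f"unknown init {init!r}")

    history = np.zeros((seq.n_excitations, df.size), dtype=complex)
    for n in range(seq.n_excitations):
        phase = math.pi * n if alternating else 0.0
        m, history[n] = one_tr(m, phase)
    if return_history:
        return history
    sig = history[-1]
    return sig[0] if np.isscalar(delta_f) or np.ndim(delta_f) == 0 else sig


def simulate_fiss(
    seq: SequenceParams,
    tissue: TissueParams,
    delta_f,
    alpha: float,
    rect_duration: float = 0.3e-3,
    init: str = "steady",
):
    """Steady-state complex Mxy at TE for a FISS train.

    Each module: an alpha/2 catalyzation pulse TR/2 before the first full
    excitation, NR alternating-phase alpha excitations sampled at TE, an
    alpha/2 restoration pulse TR/2 after the last, then perfect spoiling
    (Mxy set to zero) and the quadratic base-phase advance. With perfect
    spoiling the state entering each module is purely longitudinal, so the
    module-to-module map is scalar-affine in Mz; ``init="steady"`` starts
    from its exact fixed point (``init="equilibrium"`` from Mz = 1). Modules
    are run until ``seq.n_excitations`` total alpha pulses have occurred; the
    returned signal is the mean demodulated TE sample of the final module.
    """
    if seq.scheme is not Scheme.FISS:
        raise ValueError("simulate_fiss requires scheme=FISS")
    df = np.atleast_1d(np.asarray(delta_f, dtype=float))
    nr = seq.readouts_per_module
    n_modules = max(1, math.ceil(seq.n_excitations / nr))
    alpha_rad = math.radians(alpha)
    amp = alpha_rad / rect_duration
    full = RFSegment(rect_duration, amp)
    half = RFSegment(rect_duration, amp / 2.0)
    half_gap = (seq.tr - rect_duration) / 2.0
    if half_gap < 0:
        raise ValueError("rect pulse does not fit in TR")
    spoil = math.radians(seq.spoil_increment)
    signals = np.zeros((nr, df.size), dtype=complex)

    def run_module(m, base):
        # catalyzation alpha/2, opposite phase to the first alpha pulse
        m = rotate_segment(m, replace(half, phase_intercept=base + math.pi), df)
        m = free_precess(m, half_gap, df, tissue)
        for r in range(nr):
            phase = base + math.pi * r
            m = rotate_segment(m, replace(full, phase_intercept=phase), df)
            m = free_precess(m, half_gap, df, tissue)
            signals[r] = (m[..., 0] + 1j * m[..., 1]) * np.exp(-1j * phase)
            m = free_precess(m, half_gap, df, tissue)
        # restoration alpha/2 continuing the alternation
        m = rotate_segment(m, replace(half, phase_intercept=base + math.pi * nr), df)
        m = free_precess(m, half_gap, df, tissue)
        # perfect RF + gradient spoiling: null the transverse magnetization
        m = m.copy()
        m[..., 0] = 0.0
        m[..., 1] = 0.0
        return m

    if init == "steady":
        # affine scalar map mz -> a*mz + c across one module
        zero = np.zeros((df.size, 3))
        one = np.zeros((df.size, 3))
        one[:, 2] = 1.0
        c = run_module(zero, 0.0)[..., 2]
        a = run_module(one, 0.0)[..., 2] - c
        mz_star = c / (1.0 - a)
        m = np.zeros((df.size, 3))
        m[:, 2] = mz_star
    elif init == "equilibrium":
        m = equilibrium(df.shape)
    else:
        raise ValueError(f"unknown init {init!r}")

    base = 0.0
    for k in range(n_modules):
        # quadratic RF spoiling: base phase advanced by k * increment each module
        base = base + k * spoil
        m = run_module(m, base)
    sig = signals.mean(axis=0)
    return sig[0] if np.isscalar(delta_f) or np.ndim(delta_f) == 0 else sig


def default_alpha_grid(center: float = 50.0, half_range: float = 20.0, step: float = 5.0):
    """Flip-angle grid center-20 .. center+20 deg in 5-deg steps (9 points)."""
    n = int(round(2 * half_range / step)) + 1
    return center - half_range + step * np.arange(n)


def steady_state_map(
    protocol: str,
    seq: SequenceParams,
    tissue: TissueParams,
    alpha_grid=None,
    delta_f_grid=None,
    pulse_params: PulseParams | None = None,
    alpha_half_range: float = 20.0,
    alpha_step: float = 5.0,
) -> ResponseMap:
    """|Mxy| steady-state map over excitation angle x off-resonance.

    ``protocol`` is one of ``bssfp``, ``fiss``, ``borr``, ``libre``,
    ``libor``. The angle axis is the scanner-interface excitation angle,
    i.e. a B1-amplitude sweep: for water-excitation protocols the default
    grid spans the calibrated interface angle +- 20 deg in 5-deg steps (the
    nominal 50-deg water rotation is achieved at the center of the range),
    probing robustness to B1 inhomogeneity; for rectangular-pulse protocols
    interface and nominal angles coincide. Row amplitudes scale linearly
    with the axis value.
    """
    from .calibration import default_delta_f_grid
    from .pulses import table_pulse_params

    protocol = protocol.lower()
    params = pulse_params if pulse_params is not None else table_pulse_params(protocol)
    if params.kind is PulseKind.RECT:
        center = params.nominal_alpha
    else:
        center = calibrate_amplitude(params).interface_angle
    angles = np.asarray(
        default_alpha_grid(center=center, half_range=alpha_half_range, step=alpha_step)
        if alpha_grid is None
        else alpha_grid,
        dtype=float,
    )
    dfg = np.asarray(
        default_delta_f_grid() if delta_f_grid is None else delta_f_grid, dtype=float
    )
    if angles.size == 0 or dfg.size == 0:
        raise ValueError("grids must be non-empty")

    active = params.tau if params.kind is PulseKind.RECT else 2 * params.tau
    values = np.zeros((angles.size, dfg.size), dtype=complex)
    for i, angle in enumerate(angles):
        if protocol == "fiss":
            values[i] = simulate_fiss(seq, tissue, dfg, angle, rect_duration=params.tau)
        else:
            pulse = make_pulse(params, math.radians(angle) / active)
            values[i] = simulate_bssfp(pulse, seq, tissue, dfg)
    return ResponseMap(
        delta_f=dfg,
        values=values,
        axis2=angles,
        axis2_name="excitation_angle_deg",
        metadata={
            "protocol": protocol,
            "tr_s": seq.tr,
            "scheme": seq.scheme.value,
            "center_angle_deg": float(center),
        },
    )
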