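"""Bloch-equation engine: exact rotations through RF segments, relaxation and
free precession, and single-pulse frequency responses.

Magnetization is a length-3 vector (or an ``(..., 3)`` array) in units of the
equilibrium magnetization M0. Rotations are right-handed; a positive
on-resonance pulse with phase 0 tips +z toward +y. All reported quantities
downstream are |Mxy|, so only self-consistency of the handedness matters.

RF segments are piecewise-constant in amplitude with a linear phase ramp
(carrier offset). Each segment is evolved exactly by transforming into the
frame rotating with the carrier, where the effective field
``(omega_1, 0, 2*pi*delta_f - phase_slope)`` is constant, applying a single
axis-angle rotation, and transforming back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pulses import RFPulse, RFSegment, sample_waveform

__all__ = [
    "TissueParams",
    "ResponseMap",
    "rotate_segment",
    "free_precess",
    "apply_pulse",
    "single_pulse_response",
    "ode_oracle",
    "equilibrium",
    "WATER_BLOOD_1p5T",
    "FAT_1p5T",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class TissueParams:
    """Relaxation times (seconds) and chemical shift (Hz) of a compartment."""

    t1: float
    t2: float
    chemical_shift: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.t2 <= self.t1):
            raise ValueError(f"require 0 < t2 <= t1, got t1={self.t1}, t2={self.t2}")


#: Blood-like relaxation at 1.5 T (T1 1390 ms, T2 300 ms), on-resonance water.
WATER_BLOOD_1p5T = TissueParams(t1=1.390, t2=0.300, chemical_shift=0.0)

#: Lipid compartment at 1.5 T: main fat peak -220 Hz; T1/T2 290/80 ms are
#: typical literature values for fat (assumed; single-peak model).
FAT_1p5T = TissueParams(t1=0.290, t2=0.080, chemical_shift=-220.0)


def equilibrium(shape=()) -> np.ndarray:
    """Equilibrium magnetization (0, 0, 1) broadcast to ``shape + (3,)``."""
    m = np.zeros(tuple(np.atleast_1d(shape)) + (3,)) if shape != () else np.zeros(3)
    m[..., 2] = 1.0
    return m


def _rotate(m: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Right-handed rotation of ``m`` about ``axis`` by ``angle`` (Rodrigues).

    ``axis`` need not be normalized; broadcasts over leading dimensions.
    """
    norm = np.linalg.norm(axis, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(norm > 0, axis / np.where(norm > 0, norm, 1.0), 0.0)
    ang = np.asarray(angle)[..., None]
    c = np.cos(ang)
    s = np.sin(ang)
    kxm = np.cross(k, m)
    kdotm = np.sum(k * m, axis=-1, keepdims=True)
    return m * c + kxm * s + k * kdotm * (1.0 - c)


def _rot_z(m: np.ndarray, angle) -> np.ndarray:
    ang = np.asarray(angle)
    c, s = np.cos(ang), np.sin(ang)
    out = np.empty_like(m)
    out[..., 0] = m[..., 0] * c - m[..., 1] * s
    out[..., 1] = m[..., 0] * s + m[..., 1] * c
    out[..., 2] = m[..., 2]
    return out


def rotate_segment(m: np.ndarray, seg: RFSegment, delta_f) -> np.ndarray:
    """Evolve ``m`` through one piecewise-constant RF segment (no relaxation).

    ``delta_f`` is the spin off-resonance in Hz (scalar or array broadcasting
    against the leading dimensions of ``m``). Exact axis-angle solution in the
    carrier frame; preserves the norm of ``m`` to machine precision.
    """
    m = np.asarray(m, dtype=float)
    df = np.asarray(delta_f, dtype=float)
    wz = TWO_PI * df - seg.phase_slope  # effective z-field in the carrier frame
    axis = np.stack(
        [
            np.broadcast_to(seg.amplitude, wz.shape),
            np.zeros_like(wz),
            wz,
        ],
        axis=-1,
    )
    angle = np.sqrt(seg.amplitude**2 + wz**2) * seg.duration
    out = _rot_z(m, -seg.phase_intercept)
    out = _rotate(out, axis, angle)
    return _rot_z(out, seg.phase_intercept + seg.phase_slope * seg.duration)


def free_precess(
    m: np.ndarray,
    duration: float,
    delta_f,
    tissue: TissueParams | None = None,
) -> np.ndarray:
    """Free precession for ``duration`` seconds at off-resonance ``delta_f`` Hz.

    The transverse component rotates by ``2*pi*delta_f*duration`` and, when
    ``tissue`` is given, decays by exp(-duration/T2) while Mz relaxes toward 1
    with exp(-duration/T1). ``tissue=None`` disables relaxation.
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    m = np.asarray(m, dtype=float)
    out = _rot_z(m, TWO_PI * np.asarray(delta_f, dtype=float) * duration)
    if tissue is not None:
        e1 = math.exp(-duration / tissue.t1)
        e2 = math.exp(-duration / tissue.t2)
        out = out.copy()
        out[..., 0] *= e2
        out[..., 1] *= e2
        out[..., 2] = 1.0 + (out[..., 2] - 1.0) * e1
    return out


def apply_pulse(m: np.ndarray, pulse: RFPulse, delta_f) -> np.ndarray:
    """Evolve ``m`` through all segments of a pulse (relaxation disabled).

    The inter-subpulse gap, if any, is free precession without relaxation.
    """
    n = len(pulse.segments)
    for i, seg in enumerate(pulse.segments):
        m = rotate_segment(m, seg, delta_f)
        if pulse.gap and i + 1 < n:
            m = free_precess(m, pulse.gap, delta_f, tissue=None)
    return m


@dataclass
class ResponseMap:
    """Complex transverse magnetization over off-resonance x secondary grid.

    ``values`` has shape ``(len(axis2), len(delta_f))``; ``axis2`` is a
    singleton ``[0.0]`` for plain single-pulse responses, a flip-angle grid
    for steady-state maps, or a phase-offset grid for the phase sweep.
    """

    delta_f: np.ndarray
    values: np.ndarray
    axis2: np.ndarray | None = None
    axis2_name: str = "index"
    metadata: dict | None = None

    def __post_init__(self) -> None:
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.axis2 is None:
            self.axis2 = np.zeros(self.values.shape[0])
        self.axis2 = np.asarray(self.axis2, dtype=float)
        if self.values.shape != (self.axis2.size, self.delta_f.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grids "
                f"({self.axis2.size}, {self.delta_f.size})"
            )

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def slice(self, index: int = 0) -> np.ndarray:
        """Complex response along off-resonance at one axis2 index."""
        return self.values[index]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: (delta_f, axis2, re, im, abs)."""
        a2, df = np.meshgrid(self.axis2, self.delta_f, indexing="ij")
        v = self.values
        return pd.DataFrame(
            {
                "delta_f_hz": df.ravel(),
                self.axis2_name: a2.ravel(),
                "re": v.real.ravel(),
                "im": v.imag.ravel(),
                "abs": np.abs(v).ravel(),
            }
        )

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, index=False)

    def to_hdf5(self, path, name: str = "response") -> None:
        import h5py

        with h5py.File(path, "a") as fh:
            if name in fh:
                del fh[name]
            grp = fh.create_group(name)
            grp.create_dataset("delta_f_hz", data=self.delta_f)
            grp.create_dataset(self.axis2_name, data=self.axis2)
            grp.create_dataset("values", data=self.values)
            for k, v in (self.metadata or {}).items():
                grp.attrs[k] = v


def single_pulse_response(pulse: RFPulse, delta_f_grid) -> ResponseMap:
    """Complex Mxy after one pulse from equilibrium, per off-resonance value.

    Relaxation is disabled (pulse durations are far shorter than T2).
    """
    df = np.asarray(delta_f_grid, dtype=float)
    if df.size == 0:
        raise ValueError("delta_f_grid must be non-empty")
    m = equilibrium(df.shape)
    m = apply_pulse(m, pulse, df)
    values = (m[..., 0] + 1j * m[..., 1])[None, :]
    return ResponseMap(
        delta_f=df,
        values=values,
        axis2=np.array([0.0]),
        axis2_name="slice",
        metadata={"kind": pulse.kind.value},
    )


def ode_oracle(pulse: RFPulse, delta_f: float, dt: float = 5e-7) -> np.ndarray:
    """Fine-step RK4 integration of the Bloch equations over the waveform.

    Test oracle for :func:`rotate_segment` / :func:`apply_pulse`: integrates
    dM/dt = Omega(t) x M with Omega(t) = (w1*cos(phi(t)), w1*sin(phi(t)),
    2*pi*delta_f) using the exact in-segment phase law, with fixed step
    ``dt`` (<= 1 us). Relaxation disabled, start at equilibrium.
    """
    if dt > 1e-6:
        raise ValueError("oracle step must be <= 1 us")
    wz = TWO_PI * delta_f

    # (t_start, duration, amplitude, intercept, slope) including gaps
    pieces = []
    t0 = 0.0
    n = len(pulse.segments)
    for i, seg in enumerate(pulse.segments):
        pieces.append((t0, seg.duration, seg.amplitude, seg.phase_intercept, seg.phase_slope))
        t0 += seg.duration
        if pulse.gap and i + 1 < n:
            pieces.append((t0, pulse.gap, 0.0, 0.0, 0.0))
            t0 += pulse.gap

    def omega(t_local, piece):
        _, _, amp, icpt, slope = piece
        phi = icpt + slope * t_local
        return np.array([amp * math.cos(phi), amp * math.sin(phi), wz])

    m = np.array([0.0, 0.0, 1.0])
    for piece in pieces:
        _, dur, _, _, _ = piece
        nsteps = max(1, math.ceil(dur / dt))
        h = dur / nsteps
        t = 0.0
        for _ in range(nsteps):
            k1 = np.cross(omega(t, piece), m)
            k2 = np.cross(omega(t + h / 2, piece), m + h / 2 * k1)
            k3 = np.cross(omega(t + h / 2, piece), m + h / 2 * k2)
            k4 = np.cross(omega(t + h, piece), m + h * k3)
            m = m + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
    return m
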