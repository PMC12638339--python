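"""Synthetic fat-fraction vial phantom and protocol image simulation.

Emulates the physical validation phantom: vials of water/oil mixtures
spanning fat fractions 0..100% on a square canvas, imaged with each
protocol's steady-state signal. A pixel with fat fraction FF and local B0
offset b0 gets the noiseless signal

    s = FF * |Mxy_fat(b0 + fat_shift)| + (1 - FF) * |Mxy_water(b0)|

where each compartment's Mxy is the protocol's steady-state transverse
magnetization at the compartment's off-resonance and relaxation times.
Complex Gaussian noise is then added and the magnitude taken, giving Rician
magnitude statistics; background noise SD is measured empirically from the
background ROI, as in the scanner analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bloch import FAT_1p5T, TissueParams, WATER_BLOOD_1p5T
from .calibration import calibrate_amplitude
from .pulses import PulseKind, PulseParams, make_pulse, table_pulse_params
from .steadystate import Scheme, SequenceParams, simulate_bssfp, simulate_fiss

__all__ = [
    "PhantomSpec",
    "Phantom",
    "ProtocolDef",
    "ROIStats",
    "build_phantom",
    "simulate_protocol_image",
    "roi_report",
    "default_protocols",
]


@dataclass
class PhantomSpec:
    """Geometry and acquisition-noise description of the digital phantom."""

    fat_fractions: tuple = tuple(round(0.1 * i, 1) for i in range(11))
    canvas_n: int = 96
    vial_radius: int = 9
    b0_offset: float | np.ndarray = 0.0  # Hz, scalar or full-canvas map
    noise_sd: float = 0.01  # complex-channel SD, units of M0
    seed: int = 0
    guard: int = 3  # background exclusion margin around vials, pixels
    centers: tuple | None = None  # optional explicit (row, col) centers

    def __post_init__(self) -> None:
        for ff in self.fat_fractions:
            if not (0.0 <= ff <= 1.0):
                raise ValueError(f"fat fraction {ff} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Phantom:
    """Built phantom: fat-fraction and B0 images plus ROI masks."""

    spec: PhantomSpec
    fat_fraction: np.ndarray  # NaN outside vials
    b0: np.ndarray
    vial_masks: dict  # label -> bool mask
    background_mask: np.ndarray


def _auto_centers(n_vials: int, canvas_n: int, radius: int) -> list[tuple[int, int]]:
    per_row = 4
    n_rows = math.ceil(n_vials / per_row)
    centers = []
    for i in range(n_vials):
        r, c = divmod(i, per_row)
        row = int(round((r + 1) * canvas_n / (n_rows + 1)))
        col = int(round((c + 1) * canvas_n / (per_row + 1)))
        centers.append((row, col))
    return centers


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the vial layout; deterministic given the spec.

    Raises ``ValueError`` if any two vials (plus guard margin) overlap. The
    background mask excludes every vial with a guard margin.
    """
    n = spec.canvas_n
    ffs = spec.fat_fractions
    centers = (
        list(spec.centers) if spec.centers is not None else _auto_centers(len(ffs), n, spec.vial_radius)
    )
    if len(centers) != len(ffs):
        raise ValueError("number of centers must match number of fat fractions")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = math.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < 2 * spec.vial_radius:
                raise ValueError(f"vials {i} and {j} overlap (center distance {d:.1f})")
    rr, cc = np.mgrid[0:n, 0:n]
    ff_img = np.full((n, n), np.nan)
    masks: dict = {}
    guard_union = np.zeros((n, n), dtype=bool)
    for i, (ff, (r0, c0)) in enumerate(zip(ffs, centers)):
        dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
        mask = dist2 <= spec.vial_radius**2
        ff_img[mask] = ff
        masks[f"ff_{int(round(ff * 100))}"] = mask
        guard_union |= dist2 <= (spec.vial_radius + spec.guard) ** 2
    b0 = np.broadcast_to(np.asarray(spec.b0_offset, dtype=float), (n, n)).copy()
    return Phantom(
        spec=spec,
        fat_fraction=ff_img,
        b0=b0,
        vial_masks=masks,
        background_mask=~guard_union,
    )


@dataclass
class ProtocolDef:
    """One imaging protocol: pulse parameters, sequence, tissue compartments."""

    name: str
    pulse_params: PulseParams
    seq: SequenceParams
    water: TissueParams = WATER_BLOOD_1p5T
    fat: TissueParams = FAT_1p5T


def default_protocols() -> dict[str, ProtocolDef]:
    """The five table protocols with their default sequences."""
    out = {}
    for name in ("bssfp", "fiss", "borr", "libre", "libor"):
        params = table_pulse_params(name)
        from .pulses import TABLE_PARAMS

        tr = TABLE_PARAMS[name]["tr"]
        scheme = Scheme.FISS if name == "fiss" else Scheme.BSSFP
        out[name] = ProtocolDef(
            name=name,
            pulse_params=params,
            seq=SequenceParams(tr=tr, scheme=scheme),
        )
    return out


def _steady_signal(protocol: ProtocolDef, tissue: TissueParams, delta_f: np.ndarray) -> np.ndarray:
    """|Mxy| of a compartment at the given total off-resonance values."""
    if protocol.seq.scheme is Scheme.FISS:
        sig = simulate_fiss(
            protocol.seq, tissue, delta_f, protocol.pulse_params.nominal_alpha,
            rect_duration=protocol.pulse_params.tau,
        )
    elif protocol.pulse_params.kind is PulseKind.RECT:
        pulse = make_pulse(
            protocol.pulse_params,
            math.radians(protocol.pulse_params.nominal_alpha) / protocol.pulse_params.tau,
        )
        sig = simulate_bssfp(pulse, protocol.seq, tissue, delta_f)
    else:
        cal = calibrate_amplitude(protocol.pulse_params)
        sig = simulate_bssfp(cal.pulse, protocol.seq, tissue, delta_f)
    return np.abs(np.atleast_1d(sig))


def simulate_protocol_image(
    phantom: Phantom,
    protocol: ProtocolDef,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Noisy magnitude image of the phantom under one protocol.

    Steady-state signals are computed once per unique B0 value per
    compartment (fat sees ``b0 + fat chemical shift``); complex Gaussian
    noise of SD ``noise_sd`` per channel is added i.i.d. per pixel and the
    magnitude returned. Bit-reproducible under a fixed seed.
    """
    sd = phantom.spec.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(phantom.spec.seed if seed is None else seed)
    b0_vals = np.unique(phantom.b0)
    water_sig = dict(zip(b0_vals, _steady_signal(protocol, protocol.water, b0_vals)))
    fat_sig = dict(
        zip(b0_vals, _steady_signal(protocol, protocol.fat, b0_vals + protocol.fat.chemical_shift))
    )
    n = phantom.spec.canvas_n
    img = np.zeros((n, n))
    ff = np.nan_to_num(phantom.fat_fraction, nan=0.0)
    inside = ~np.isnan(phantom.fat_fraction)
    for b0 in b0_vals:
        sel = phantom.b0 == b0
        img[sel] = np.where(
            inside[sel],
            ff[sel] * fat_sig[b0] + (1.0 - ff[sel]) * water_sig[b0],
            0.0,
        )
    if sd > 0:
        noise = rng.normal(scale=sd, size=(n, n, 2))
        img = np.hypot(img + noise[..., 0], noise[..., 1])
    return img


@dataclass(frozen=True)
class ROIStats:
    """Per-ROI signal statistics."""

    label: str
    mean_signal: float
    background_sd: float

    @property
    def snr(self) -> float:
        return self.mean_signal / self.background_sd


def roi_report(
    images: dict[str, np.ndarray],
    phantom: Phantom,
) -> pd.DataFrame:
    """SNR per vial and water-fat CNR per protocol.

    SNR is the ROI mean over the empirical background SD of the same image;
    CNR(water-fat) = SNR(FF=0) - SNR(FF=100).
    """
    rows = []
    for name, img in images.items():
        if img.shape != phantom.fat_fraction.shape:
            raise ValueError(f"image shape mismatch for protocol {name!r}")
        bg_sd = float(img[phantom.background_mask].std())
        snrs = {}
        for label, mask in phantom.vial_masks.items():
            mean = float(img[mask].mean())
            snrs[label] = mean / bg_sd
            rows.append(
                {
                    "protocol": name,
                    "roi": label,
                    "mean_signal": mean,
                    "background_sd": bg_sd,
                    "snr": snrs[label],
                }
            )
        if "ff_0" in snrs and "ff_100" in snrs:
            rows.append(
                {
                    "protocol": name,
                    "roi": "cnr_water_fat",
                    "mean_signal": np.nan,
                    "background_sd": bg_sd,
                    "snr": snrs["ff_0"] - snrs["ff_100"],
                }
            )
    return pd.DataFrame(rows)
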