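"""Midbrain-like digital phantom and multi-echo gradient-echo simulation.

The phantom carries a ground-truth susceptibility map chi (ppm), an effective
transverse relaxation rate map R2* (Hz) and a proton-density magnitude M0 on
one voxel grid, together with bilateral SN ellipsoids (partitioned into the
four nigral territories), subthalamic nuclei and red nuclei, inside an
ellipsoidal brain mask.  Susceptibility sources outside the brain mask stand
in for air/tissue interfaces and generate the background field the
reconstruction has to remove.

The forward model is the standard dipole convolution: the B0 field shift (in
ppm of B0) is ``F^-1[ D(k) F[chi] ]`` with the unit-free kernel
``D(k) = 1/3 - k_z^2/|k|^2`` (k_z the component along the B0 axis, D(0)=0).
The complex gradient-echo signal per voxel is

    S(TE) = M0 * exp(-R2* TE) * exp(i (2 pi f TE + phi0)),
    f [Hz] = gamma_bar * B0 * field_ppm * 1e-6,

with gamma_bar = 42.577 MHz/T, plus independent circular complex Gaussian
noise per echo (so magnitudes are Rician-distributed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.fft import irfftn, rfftn

from .roi import LABEL_CODES, ROILabelMap, derive_sn_subdivisions

__all__ = [
    "GAMMA_BAR_HZ_PER_T",
    "PhantomTruth",
    "EchoSeries",
    "default_geometry",
    "nigral_value_presets",
    "build_phantom",
    "forward_field",
    "default_echo_times",
    "simulate_echoes",
]

#: Reduced gyromagnetic ratio of the proton, Hz per tesla.
GAMMA_BAR_HZ_PER_T = 42.577e6


@dataclass
class PhantomTruth:
    """Ground-truth voxel maps of the digital midbrain phantom."""

    chi: np.ndarray  # susceptibility, ppm (nonzero outside brain = background sources)
    r2s: np.ndarray  # relaxation rate, Hz
    m0: np.ndarray  # proton-density magnitude, arbitrary units >= 0
    labels: ROILabelMap
    brain_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        shp = self.chi.shape
        for name in ("r2s", "m0", "brain_mask"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} grid {getattr(self, name).shape} != chi grid {shp}")
        if self.labels.data.shape != shp:
            raise ValueError("label grid mismatch")
        if ((self.labels.data > 0) & ~self.brain_mask).any():
            raise ValueError("labelled voxels fall outside the brain mask")
        self.b0_dir = _unit_b0(self.b0_dir)


@dataclass
class EchoSeries:
    """Complex multi-echo gradient-echo signal with acquisition metadata."""

    signal: np.ndarray  # complex, shape grid + (n_echoes,)
    echo_times: np.ndarray  # seconds, strictly increasing
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_tesla: float = 3.0
    b0_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.ndim != 1 or te.size < 2:
            raise ValueError("need at least 2 echo times")
        if (te <= 0).any() or (np.diff(te) <= 0).any():
            raise ValueError("echo times must be positive and strictly increasing")
        if self.signal.shape[-1] != te.size:
            raise ValueError("signal last axis must match number of echoes")
        self.echo_times = te
        self.b0_dir = _unit_b0(self.b0_dir)

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)


def _unit_b0(b0_dir: np.ndarray) -> np.ndarray:
    v = np.asarray(b0_dir, dtype=float)
    if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError("b0_dir must be a 3-vector of unit norm")
    return v


# ---------------------------------------------------------------------------
# Forward dipole model
# ---------------------------------------------------------------------------


def dipole_kernel(
    shape: tuple[int, ...],
    voxel_size: tuple[float, float, float],
    b0_dir: np.ndarray,
    rfft: bool = True,
) -> np.ndarray:
    """Fourier-domain dipole kernel D(k) = 1/3 - (k.b0)^2/|k|^2, D(0) = 0."""
    b0 = _unit_b0(b0_dir)
    ks = [np.fft.fftfreq(n, d=h) for n, h in zip(shape, voxel_size)]
    if rfft:
        ks[-1] = np.fft.rfftfreq(shape[-1], d=voxel_size[-1])
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    k_par = kx * b0[0] + ky * b0[1] + kz * b0[2]
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 / 3.0 - np.where(k2 > 0, k_par**2 / np.where(k2 > 0, k2, 1.0), 0.0)
    d = np.asarray(d)
    d[tuple([0] * d.ndim)] = 0.0  # zero-frequency convention
    return d


def forward_field(
    chi: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    b0_dir: np.ndarray = (0.0, 0.0, 1.0),
    pad_factor: int = 2,
) -> np.ndarray:
    """B0 field shift (ppm) induced by a susceptibility distribution (ppm).

    The grid is zero-padded ``pad_factor``-fold per axis before the FFT to
    suppress circular wrap-around of the long-range dipole field.
    """
    chi = np.asarray(chi, dtype=np.float64)
    if not np.isfinite(chi).all():
        raise ValueError("chi must be finite")
    b0 = _unit_b0(np.asarray(b0_dir, dtype=float))
    shape = chi.shape
    padded = tuple(int(n * pad_factor) for n in shape)
    buf = np.zeros(padded, dtype=np.float64)
    buf[tuple(slice(0, n) for n in shape)] = chi
    d = dipole_kernel(padded, tuple(voxel_size), b0, rfft=True)
    out = irfftn(d * rfftn(buf), s=padded)
    return np.ascontiguousarray(out[tuple(slice(0, n) for n in shape)])


# ---------------------------------------------------------------------------
# Phantom geometry and values
# ---------------------------------------------------------------------------


def default_geometry(shape: tuple[int, int, int]) -> dict:
    """Placement of the midbrain structures, in fractions of the grid.

    Axis 0 = left-right, axis 1 = anterior-posterior (posterior = larger
    index), axis 2 = inferior-superior (inferior = smaller index).
    """
    return {
        "brain_semiaxes": (0.42, 0.42, 0.42),
        # per-hemisphere SN: centre offset from grid centre (fractions), semiaxes
        "sn_center": (0.16, 0.04, -0.06),
        "sn_semiaxes": (0.055, 0.105, 0.135),
        # red nucleus: posterior-medial, overlapping the superior SN slices
        "rn_center": (0.07, 0.12, 0.03),
        "rn_semiaxes": (0.045, 0.05, 0.07),
        # STN: anterior-lateral-superior of the SN
        "stn_center": (0.22, -0.07, 0.06),
        "stn_semiaxes": (0.045, 0.05, 0.045),
        # background (outside-brain) susceptibility blobs: centre, sigma, amplitude
        "background_blobs": [
            ((0.0, -0.46, -0.40), 0.10, 4.0),  # sinus-like air pocket, anterior-inferior
            ((0.30, 0.40, 0.35), 0.12, 2.0),
        ],
    }


def nigral_value_presets() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-structure (chi ppm, R2* Hz) assignments for the two phantom classes.

    The "HV" preset carries healthy-volunteer-like nigral values and the "PD"
    preset carries Parkinson-like values with the posteroventral territory
    raised the most, mirroring the posteroventral-first iron accumulation.
    """
    hv = {
        "anterodorsal": (0.121, 27.0),
        "posterodorsal": (0.097, 24.5),
        "anteroventral": (0.140, 28.5),
        "posteroventral": (0.103, 25.4),
        "STN": (0.089, 28.0),
        "red_nucleus": (0.130, 30.0),
        "tissue": (0.0, 16.0),
    }
    pd_ = {
        "anterodorsal": (0.125, 27.4),
        "posterodorsal": (0.106, 25.1),
        "anteroventral": (0.150, 29.2),
        "posteroventral": (0.120, 27.2),
        "STN": (0.093, 28.3),
        "red_nucleus": (0.130, 30.0),
        "tissue": (0.0, 16.0),
    }
    return {"HV": hv, "PD": pd_}


def _ellipsoid(shape, center_frac, semiaxes_frac) -> np.ndarray:
    idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij", sparse=True)
    c = [(n - 1) / 2.0 + f * n for n, f in zip(shape, center_frac)]
    a = [max(f * n, 1.0) for n, f in zip(shape, semiaxes_frac)]
    r2 = sum(((i - ci) / ai) ** 2 for i, ci, ai in zip(idx, c, a))
    return r2 <= 1.0


def build_phantom(
    geometry: dict | None = None,
    values: dict[str, tuple[float, float]] | None = None,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    m0_brain: float = 100.0,
    chi_texture_sd: float = 0.002,
    b0_dir: np.ndarray = (0.0, 0.0, 1.0),
) -> PhantomTruth:
    """Build the midbrain phantom with ground-truth chi/R2*/M0 maps.

    ``values`` maps structure names (the four nigral territories, STN,
    red_nucleus, tissue) to (chi ppm, R2* Hz); defaults to the "HV" preset.
    ``chi_texture_sd`` adds smooth seeded texture to the brain-tissue chi so
    the map is not piecewise constant.  Deterministic given ``seed``.
    """
    if min(shape) < 32:
        raise ValueError("grid must be at least 32 voxels per axis")
    geo = default_geometry(shape) if geometry is None else geometry
    vals = nigral_value_presets()["HV"] if values is None else values
    rng = np.random.default_rng(seed)

    brain = _ellipsoid(shape, (0.0, 0.0, 0.0), geo["brain_semiaxes"])

    def mirror(center):
        return (-center[0], center[1], center[2])

    sn_r = _ellipsoid(shape, geo["sn_center"], geo["sn_semiaxes"])
    sn_l = _ellipsoid(shape, mirror(geo["sn_center"]), geo["sn_semiaxes"])
    rn_r = _ellipsoid(shape, geo["rn_center"], geo["rn_semiaxes"])
    rn_l = _ellipsoid(shape, mirror(geo["rn_center"]), geo["rn_semiaxes"])
    stn_r = _ellipsoid(shape, geo["stn_center"], geo["stn_semiaxes"])
    stn_l = _ellipsoid(shape, mirror(geo["stn_center"]), geo["stn_semiaxes"])

    structures = [sn_l, sn_r, rn_l, rn_r, stn_l, stn_r]
    names = ["SN_L", "SN_R", "RN_L", "RN_R", "STN_L", "STN_R"]
    occupancy = np.zeros(shape, dtype=np.int8)
    for s in structures:
        occupancy += s.astype(np.int8)
    if (occupancy > 1).any():
        clash = [n for n, s in zip(names, structures) if (s & (occupancy > 1)).any()]
        raise ValueError(f"ROI shapes overlap with conflicting labels: {clash}")
    for n, s in zip(names, structures):
        if (s & ~brain).any():
            raise ValueError(f"ROI {n} extends outside the brain mask")

    labels = derive_sn_subdivisions(sn_l, sn_r, rn_l | rn_r, voxel_size)
    data = labels.data
    data[rn_l] = LABEL_CODES["red_nucleus_L"]
    data[rn_r] = LABEL_CODES["red_nucleus_R"]
    data[stn_l] = LABEL_CODES["STN_L"]
    data[stn_r] = LABEL_CODES["STN_R"]

    chi_tissue, r2s_tissue = vals.get("tissue", (0.0, 16.0))
    chi = np.zeros(shape, dtype=np.float64)
    r2s = np.zeros(shape, dtype=np.float64)
    chi[brain] = chi_tissue
    r2s[brain] = r2s_tissue
    m0 = np.where(brain, m0_brain, 0.0)

    if chi_texture_sd > 0:
        tex = rng.standard_normal(shape)
        tex = ndimage.gaussian_filter(tex, sigma=2.0)
        tex *= chi_texture_sd / max(tex.std(), 1e-12)
        chi[brain] += tex[brain]

    for base in ("anterodorsal", "posterodorsal", "anteroventral", "posteroventral"):
        c, r = vals[base]
        for side in ("L", "R"):
            sel = data == LABEL_CODES[f"{base}_{side}"]
            chi[sel] = c
            r2s[sel] = r
    for base, masks in (("STN", (stn_l, stn_r)), ("red_nucleus", (rn_l, rn_r))):
        c, r = vals[base]
        for m in masks:
            chi[m] = c
            r2s[m] = r
    # iron-rich structures appear slightly darker on the T2*-weighted magnitude
    m0[data > 0] = m0_brain * 0.9

    # background sources live strictly outside the brain: a ~2-voxel standoff
    # emulates the skull/CSF gap between parenchyma and air cavities
    exclusion = ndimage.binary_dilation(brain, iterations=2)
    for center, sigma_frac, amp in geo.get("background_blobs", []):
        idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij", sparse=True)
        c = [(n - 1) / 2.0 + f * n for n, f in zip(shape, center)]
        s2 = (sigma_frac * min(shape)) ** 2
        blob = amp * np.exp(-sum((i - ci) ** 2 for i, ci in zip(idx, c)) / (2 * s2))
        blob[exclusion] = 0.0
        chi += blob

    # keep only labels inside the brain (blob masking never touches labels)
    lab = ROILabelMap(data, dict(LABEL_CODES), tuple(voxel_size))
    return PhantomTruth(chi, r2s, m0, lab, brain, tuple(voxel_size), np.asarray(b0_dir, float))


# ---------------------------------------------------------------------------
# Echo simulation
# ---------------------------------------------------------------------------


def default_echo_times(n_echoes: int = 8, te1: float = 0.003, delta_te: float = 0.004) -> np.ndarray:
    """Echo times in seconds: 8 echoes, TE1 = 3 ms, dTE = 4 ms by default."""
    return te1 + delta_te * np.arange(n_echoes)


def simulate_echoes(
    phantom: PhantomTruth,
    echo_times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    b0_tesla: float = 3.0,
    phi0_map: np.ndarray | None = None,
) -> EchoSeries:
    """Simulate the multi-echo complex gradient-echo signal of a phantom.

    Noise is circular complex Gaussian with per-channel SD ``noise_sd`` added
    independently per echo; deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    te = default_echo_times() if echo_times is None else np.asarray(echo_times, dtype=float)
    field_ppm = forward_field(phantom.chi, phantom.voxel_size, phantom.b0_dir)
    f_hz = GAMMA_BAR_HZ_PER_T * b0_tesla * field_ppm * 1e-6
    phi0 = 0.0 if phi0_map is None else phi0_map[..., None]

    tex = te[None, None, None, :]
    sig = (
        phantom.m0[..., None]
        * np.exp(-phantom.r2s[..., None] * tex)
        * np.exp(1j * (2 * np.pi * f_hz[..., None] * tex + phi0))
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + noise_sd * (
            rng.standard_normal(sig.shape) + 1j * rng.standard_normal(sig.shape)
        )
    return EchoSeries(sig, te, phantom.voxel_size, b0_tesla, phantom.b0_dir)
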