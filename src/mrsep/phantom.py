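"""Numerical brain phantom and spatiospectral encoding.

A 2-D slice phantom with smooth concentric gray-matter / white-matter / CSF
tissue-fraction maps, an elliptical lesion (choline raised by a factor of
three, other metabolites reduced, MM level raised), per-voxel per-molecule
frequency jitter, and a smooth B0 inhomogeneity field. Regional spectral
parameters are blended with the tissue fractions as weights and fed through
the parametric signal model to produce ground-truth metabolite and MM
spatiotemporal matrices.

Encoding follows the (k, t)-space forward model

    d = Omega { F  B (.) (X_met + X_mm) },

with B(r, t) = exp(i 2 pi df0(r) t) the B0-induced linear phase, F the
unitary centered 2-D spatial DFT per time point and Omega a boolean (k, t)
sampling mask. Complex white Gaussian noise is prescribed by an SNR defined
against the maximum NAA spectral-magnitude peak in the field of view; with
the unitary DFT convention, adding the noise in (x, t) or (k, t) space is
equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import SpectralAxis
from .basis import MetaboliteBasis
from .params import ParamDistributions, default_distributions
from .seeds import rng_for
from .synth import _met_term_batch, _mm_term_batch

__all__ = [
    "PhantomSpec", "Phantom", "EncodedData",
    "build_phantom", "synthetic_fractions",
    "forward_encode", "adjoint_encode", "add_noise",
]

# Regional mean concentration multipliers relative to the distribution means:
# (GM, WM, CSF) per metabolite, loosely following literature contrast
# (NAA higher in WM, Cho higher in WM, near-zero metabolites in CSF).
_REGIONAL_MET = {
    "NAA":  (1.00, 0.90, 0.05),
    "Cr":   (1.05, 0.85, 0.05),
    "Cho":  (0.90, 1.10, 0.05),
    "Glu":  (1.10, 0.75, 0.05),
    "Gln":  (1.05, 0.80, 0.05),
    "mI":   (1.00, 0.95, 0.05),
    "GABA": (1.10, 0.80, 0.05),
    "GSH":  (1.00, 0.90, 0.05),
    "Lac":  (1.00, 1.00, 0.30),
}
# MM level multiplier per tissue (GM, WM, CSF).
_REGIONAL_MM = (1.05, 1.00, 0.05)


@dataclass
class PhantomSpec:
    """Geometry and variability settings of the synthetic phantom."""

    nx: int = 32
    ny: int = 32
    jitter_std_hz: float = 5.0     # per-voxel per-molecule frequency jitter
    b0_std_hz: float = 10.0        # marginal std of the smooth B0 field
    lesion: bool = True
    lesion_center: tuple[float, float] = (0.30, 0.62)  # fractional (x, y)
    lesion_radii: tuple[float, float] = (0.12, 0.09)   # fractional semi-axes
    lesion_cho_factor: float = 3.0
    lesion_other_factor: float = 0.7
    lesion_mm_factor: float = 1.5


@dataclass
class Phantom:
    """Ground-truth phantom state."""

    spec: PhantomSpec
    axis: SpectralAxis
    basis: MetaboliteBasis
    tissue_fractions: np.ndarray   # (ny, nx, 3) GM/WM/CSF, sum to 1 in-brain
    brain_mask: np.ndarray         # (ny, nx) bool
    lesion_mask: np.ndarray        # (ny, nx) bool
    b0_map: np.ndarray             # (ny, nx) Hz
    x_met: np.ndarray              # (ny, nx, T) complex
    x_mm: np.ndarray               # (ny, nx, T) complex
    conc_maps: dict[str, np.ndarray] = field(default_factory=dict)
    mm_amp_maps: np.ndarray | None = None   # (ny, nx, 13)
    met_df_maps: np.ndarray | None = None   # (ny, nx, M) per-molecule jitter, Hz
    seed: int = 0

    @property
    def grid(self) -> tuple[int, int]:
        return self.x_met.shape[:2]

    @property
    def x_total(self) -> np.ndarray:
        return self.x_met + self.x_mm


@dataclass
class EncodedData:
    """Measured (k, t)-space samples."""

    d: np.ndarray          # (ny, nx, T) complex; zero outside the mask support
    omega_mask: np.ndarray  # (ny, nx) or (ny, nx, T) bool
    snr: float
    noise_seed: int = 0
    noise_std: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.d.view(float))):
            raise ValueError("encoded data must be finite")

    @property
    def d_vector(self) -> np.ndarray:
        """Measured samples restricted to the mask support, flattened."""
        return self.d[np.broadcast_to(np.atleast_3d(self.omega_mask), self.d.shape)]


def synthetic_fractions(nx: int, ny: int) -> tuple[np.ndarray, np.ndarray]:
    """Concentric smooth GM/WM/CSF pattern; returns (fractions, brain_mask).

    Cortical GM forms the outer band of an elliptical brain, WM fills the
    interior and a small central CSF compartment mimics the ventricles.
    Fractions vary smoothly (sigmoids of the elliptical radius) and sum to 1
    inside the brain mask; the background is all-zero.
    """
    y, x = np.mgrid[0:ny, 0:nx]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.sqrt(((x - cx) / (0.44 * nx)) ** 2 + ((y - cy) / (0.46 * ny)) ** 2)
    brain = r <= 1.0
    sig = lambda u, w: 1.0 / (1.0 + np.exp(-u / w))
    csf_c = sig(0.22 - r, 0.05)                 # central ventricle-like CSF
    gm = sig(r - 0.72, 0.06) * (1 - csf_c)      # outer cortical band
    csf_rim = sig(r - 0.95, 0.025)              # thin CSF rim at the brain edge
    csf = np.clip(csf_c + csf_rim, 0, 1)
    gm = np.clip(gm * (1 - csf_rim), 0, 1)
    wm = np.clip(1.0 - gm - csf, 0, 1)
    frac = np.stack([gm, wm, csf], axis=-1)
    frac[~brain] = 0.0
    s = frac.sum(axis=-1, keepdims=True)
    frac = np.divide(frac, s, out=np.zeros_like(frac), where=s > 0)
    return frac, brain


def _smooth_b0(nx: int, ny: int, std_hz: float, rng: np.random.Generator,
               mask: np.ndarray) -> np.ndarray:
    """Low-order 2-D polynomial field rescaled to the target in-mask std."""
    if std_hz == 0:
        return np.zeros((ny, nx))
    y, x = np.mgrid[0:ny, 0:nx]
    u = 2.0 * x / max(nx - 1, 1) - 1.0
    v = 2.0 * y / max(ny - 1, 1) - 1.0
    terms = [u, v, u * v, u ** 2, v ** 2, u ** 2 * v, u * v ** 2]
    coef = rng.normal(size=len(terms))
    f = sum(c * t for c, t in zip(coef, terms))
    f = f - f[mask].mean()
    s = f[mask].std()
    return f * (std_hz / s) if s > 0 else f


def build_phantom(spec: PhantomSpec, basis: MetaboliteBasis, axis: SpectralAxis,
                  seed: int, dists: ParamDistributions | None = None,
                  fractions: np.ndarray | None = None) -> Phantom:
    """Build the phantom and synthesize its ground-truth components.

    Per-voxel parameters are the tissue-fraction-weighted blends of regional
    values; the lesion override multiplies Cho by ``lesion_cho_factor``, the
    other metabolites by ``lesion_other_factor`` and the MM amplitudes by
    ``lesion_mm_factor``. Reproducible bit-for-bit from (spec, seed).
    """
    dists = dists or default_distributions([*basis.names])
    ny, nx = spec.ny, spec.nx
    if fractions is None:
        frac, brain = synthetic_fractions(nx, ny)
    else:
        frac = np.asarray(fractions, dtype=float)
        if frac.shape != (ny, nx, 3):
            raise ValueError("fractions must have shape (ny, nx, 3)")
        s = frac.sum(axis=-1)
        brain = s > 0
        if not np.allclose(s[brain], 1.0, atol=1e-6):
            raise ValueError("tissue fractions must sum to 1 inside the support")

    y, x = np.mgrid[0:ny, 0:nx]
    lx, ly = spec.lesion_center[0] * nx, spec.lesion_center[1] * ny
    rx, ryy = spec.lesion_radii[0] * nx, spec.lesion_radii[1] * ny
    lesion = (((x - lx) / rx) ** 2 + ((y - ly) / ryy) ** 2 <= 1.0) & brain
    if not spec.lesion:
        lesion = np.zeros_like(lesion)

    rng_jit = rng_for(seed, "phantom", "jitter")
    rng_b0 = rng_for(seed, "phantom", "b0")

    names = basis.names
    m = len(names)
    n_vox = ny * nx
    fr = frac.reshape(n_vox, 3)
    les = lesion.reshape(n_vox)

    # metabolite parameter maps
    conc = np.zeros((n_vox, m))
    for j, name in enumerate(names):
        mult = np.asarray(_REGIONAL_MET.get(name, (1.0, 1.0, 0.05)))
        base = dists.met_conc[name].mean * (fr @ mult)
        factor = np.where(les, spec.lesion_cho_factor if name == "Cho"
                          else spec.lesion_other_factor, 1.0)
        conc[:, j] = base * factor
    t2 = np.full((n_vox, m), dists.met_t2star.mean)
    # mild tissue dependence of linewidth: CSF-free voxels slightly longer T2*
    t2 *= (1.0 + 0.15 * (fr[:, 1:2] - fr[:, 0:1]))
    t2 = np.clip(t2, dists.met_t2star.lo, dists.met_t2star.hi)
    met_df = rng_jit.normal(0.0, spec.jitter_std_hz, size=(n_vox, m))
    met_phase = np.zeros((n_vox, m))

    # MM parameter maps
    k = dists.n_mm
    mm_mult = fr @ np.asarray(_REGIONAL_MM)
    mm_mult = mm_mult * np.where(les, spec.lesion_mm_factor, 1.0)
    amp_means = dists.mm_global_scale * np.asarray([d.mean for d in dists.mm_amp])
    mm_amp = mm_mult[:, None] * amp_means[None, :]
    mm_w = np.broadcast_to(np.asarray([d.mean for d in dists.mm_width_hz]),
                           (n_vox, k)).copy()
    base_hz = (np.asarray(dists.mm_positions_ppm) - axis.ref_ppm) * axis.field_mhz
    mm_df = base_hz[None, :] + rng_jit.normal(0.0, spec.jitter_std_hz, size=(n_vox, k))
    mm_phase = np.zeros((n_vox, k))

    phi0 = np.zeros(n_vox)
    x_met = _met_term_batch(axis, basis, phi0, conc, t2, met_df, met_phase)
    x_mm = _mm_term_batch(axis, phi0, mm_amp, mm_w, mm_df, mm_phase)
    inb = brain.reshape(n_vox)
    x_met[~inb] = 0.0
    x_mm[~inb] = 0.0

    b0 = _smooth_b0(nx, ny, spec.b0_std_hz, rng_b0, brain)

    conc_maps = {name: (conc[:, j] * inb).reshape(ny, nx)
                 for j, name in enumerate(names)}
    return Phantom(spec=spec, axis=axis, basis=basis,
                   tissue_fractions=frac, brain_mask=brain, lesion_mask=lesion,
                   b0_map=b0, x_met=x_met.reshape(ny, nx, -1),
                   x_mm=x_mm.reshape(ny, nx, -1),
                   conc_maps=conc_maps,
                   mm_amp_maps=(mm_amp * inb[:, None]).reshape(ny, nx, k),
                   met_df_maps=met_df.reshape(ny, nx, m),
                   seed=int(seed))


def _b_phase(b0_map: np.ndarray, axis: SpectralAxis) -> np.ndarray:
    """B(r, t) = exp(i 2 pi df0(r) t), shape (ny, nx, T)."""
    return np.exp(2j * np.pi * b0_map[..., None] * axis.time[None, None, :])


def forward_encode(x_total: np.ndarray, b0_map: np.ndarray | None,
                   omega_mask: np.ndarray, axis: SpectralAxis) -> np.ndarray:
    """Apply ``Omega { F B (.) x }``; linear in ``x_total``.

    F is the unitary centered 2-D DFT over the spatial axes, applied per time
    point; the mask may be spatial (ny, nx) or full (ny, nx, T).
    """
    x = np.asarray(x_total, dtype=np.complex128)
    if b0_map is not None:
        x = x * _b_phase(np.asarray(b0_map, dtype=float), axis)
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(0, 1)),
                                    axes=(0, 1), norm="ortho"), axes=(0, 1))
    mask = np.broadcast_to(np.atleast_3d(omega_mask), k.shape)
    return np.where(mask, k, 0.0)


def adjoint_encode(d: np.ndarray, b0_map: np.ndarray | None,
                   omega_mask: np.ndarray, axis: SpectralAxis) -> np.ndarray:
    """Adjoint of :func:`forward_encode` (conjugate B phase, inverse DFT)."""
    d = np.asarray(d, dtype=np.complex128)
    mask = np.broadcast_to(np.atleast_3d(omega_mask), d.shape)
    k = np.where(mask, d, 0.0)
    x = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k, axes=(0, 1)),
                                     axes=(0, 1), norm="ortho"), axes=(0, 1))
    if b0_map is not None:
        x = x * np.conj(_b_phase(np.asarray(b0_map, dtype=float), axis))
    return x


def naa_peak_amplitude(phantom: Phantom) -> float:
    """Maximum NAA-only spectral magnitude over the field of view.

    The SNR reference: the noise-free NAA signal of every voxel is
    transformed with the unitary DFT and the global magnitude maximum taken.
    """
    if "NAA" not in phantom.basis.names:
        raise ValueError("phantom basis does not contain NAA")
    j = phantom.basis.index("NAA")
    ny, nx, t = phantom.x_met.shape
    dists = default_distributions([*phantom.basis.names])
    conc = phantom.conc_maps["NAA"].reshape(-1, 1)
    n_vox = conc.shape[0]
    t2 = np.full((n_vox, 1), dists.met_t2star.mean)
    naa_basis = MetaboliteBasis(names=["NAA"], fids=phantom.basis.fids[j][None],
                                axis=phantom.axis)
    fid = _met_term_batch(phantom.axis, naa_basis, np.zeros(n_vox), conc, t2,
                          np.zeros((n_vox, 1)), np.zeros((n_vox, 1)))
    spec = np.fft.fft(fid, axis=-1) / np.sqrt(t)
    return float(np.abs(spec).max())


def add_noise(d: np.ndarray, snr: float | None, phantom: Phantom,
              noise_seed: int, omega_mask: np.ndarray) -> EncodedData:
    """Add complex white Gaussian noise at the prescribed SNR.

    ``snr = None`` (or ``inf``) returns the data unchanged. Otherwise the
    per-complex-sample noise std is ``sigma = peak_NAA / snr`` where
    ``peak_NAA`` is :func:`naa_peak_amplitude`; with the unitary DFT
    convention this sigma is identical in (x, t), (k, t) and image-spectral
    domains.
    """
    d = np.asarray(d, dtype=np.complex128)
    if snr is None or np.isinf(snr):
        return EncodedData(d=d.copy(), omega_mask=np.asarray(omega_mask, bool),
                           snr=float("inf"), noise_seed=int(noise_seed),
                           noise_std=0.0)
    if snr <= 0:
        raise ValueError("snr must be positive")
    sigma = naa_peak_amplitude(phantom) / float(snr)
    rng = rng_for(noise_seed, "noise")
    noise = (rng.normal(0.0, sigma / np.sqrt(2.0), size=d.shape)
             + 1j * rng.normal(0.0, sigma / np.sqrt(2.0), size=d.shape))
    mask = np.broadcast_to(np.atleast_3d(omega_mask), d.shape)
    return EncodedData(d=np.where(mask, d + noise, 0.0),
                       omega_mask=np.asarray(omega_mask, bool), snr=float(snr),
                       noise_seed=int(noise_seed), noise_std=float(sigma))
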