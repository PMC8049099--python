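"""Parametric FID synthesis and training-set generation.

The signal model for one voxel is the two-component sum

    rho(t) = sum_m c_m e^{i(phi0 + phi_m)} v_m(t) e^{-t/T2*_m + i 2 pi df_m t}
           + sum_l b_l e^{i(phi0 + psi_l)} e^{-t^2 pi^2 W_l^2 / (4 ln 2) + i 2 pi df_l t},

a Lorentzian-decayed metabolite basis expansion plus Gaussian-lineshape MM
resonances. The Gaussian time envelope is parameterized so that W_l is the
spectral full width at half maximum in Hz; likewise the Lorentzian FWHM is
1/(pi T2*).

Training sets are real matrices of shape (N, 2T) — real part then imaginary
part concatenated — scaled by one shared positive scalar so the whole set
lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axes import SpectralAxis
from .basis import MetaboliteBasis
from .params import ComponentParams, ParamDistributions, sample_parameter_arrays
from .seeds import rng_for

__all__ = [
    "synthesize_fid",
    "synthesize_batch",
    "TrainingSet",
    "generate_training_set",
    "fids_to_real",
    "real_to_fids",
]

_GAUSS = np.pi ** 2 / (4.0 * np.log(2.0))  # W^2 t^2 coefficient


def fids_to_real(fids: np.ndarray) -> np.ndarray:
    """Pack complex FIDs (..., T) into the concatenated-real form (..., 2T)."""
    fids = np.asarray(fids)
    return np.concatenate([fids.real, fids.imag], axis=-1)


def real_to_fids(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fids_to_real`; exact round trip."""
    x = np.asarray(x)
    if x.shape[-1] % 2:
        raise ValueError("last axis must have even length 2T")
    t = x.shape[-1] // 2
    return x[..., :t] + 1j * x[..., t:]


def _met_term_batch(axis: SpectralAxis, basis: MetaboliteBasis, phi0: np.ndarray,
                    conc: np.ndarray, t2star: np.ndarray, df_hz: np.ndarray,
                    phase: np.ndarray) -> np.ndarray:
    """Metabolite sum for stacked parameters; conc etc. have shape (n, M)."""
    t = axis.time  # (T,)
    out = np.zeros((conc.shape[0], axis.n_points), dtype=np.complex128)
    for m in range(conc.shape[1]):
        amp = conc[:, m] * np.exp(1j * (phi0 + phase[:, m]))  # (n,)
        env = np.exp(np.outer(-1.0 / t2star[:, m], t)
                     + 2j * np.pi * np.outer(df_hz[:, m], t))  # (n, T)
        out += amp[:, None] * basis.fids[m][None, :] * env
    return out


def _mm_term_batch(axis: SpectralAxis, phi0: np.ndarray, amp: np.ndarray,
                   width_hz: np.ndarray, df_hz: np.ndarray,
                   phase: np.ndarray) -> np.ndarray:
    """MM Gaussian-group sum for stacked parameters of shape (n, L_mm)."""
    t = axis.time
    t2 = t ** 2
    out = np.zeros((amp.shape[0], axis.n_points), dtype=np.complex128)
    for l in range(amp.shape[1]):
        a = amp[:, l] * np.exp(1j * (phi0 + phase[:, l]))
        env = np.exp(-_GAUSS * np.outer(width_hz[:, l] ** 2, t2)
                     + 2j * np.pi * np.outer(df_hz[:, l], t))
        out += a[:, None] * env
    return out


def synthesize_fid(params: ComponentParams, basis: MetaboliteBasis | None,
                   axis: SpectralAxis, which: str = "both") -> np.ndarray:
    """Evaluate the parametric model for one voxel on the axis grid.

    Parameters
    ----------
    params:
        Spectral parameters; the component(s) requested must be populated
        (an empty component contributes zero when ``which='both'``).
    basis:
        Metabolite basis; may be None when only the MM term is requested.
    which:
        'metabolite', 'mm' or 'both'.
    """
    if which not in ("metabolite", "mm", "both"):
        raise ValueError(f"unknown component selector {which!r}")
    params.validate()
    out = np.zeros(axis.n_points, dtype=np.complex128)
    if which in ("metabolite", "both") and params.has_met:
        if basis is None:
            raise ValueError("metabolite synthesis requires a basis")
        if len(basis) != params.met_conc.size:
            raise ValueError("basis size does not match metabolite parameters")
        out += _met_term_batch(axis, basis, np.array([params.phi0]),
                               params.met_conc[None], params.met_t2star[None],
                               params.met_df_hz[None], params.met_phase[None])[0]
    elif which == "metabolite" and not params.has_met:
        raise ValueError("metabolite parameters are empty")
    if which in ("mm", "both") and params.has_mm:
        out += _mm_term_batch(axis, np.array([params.phi0]), params.mm_amp[None],
                              params.mm_width_hz[None], params.mm_df_hz[None],
                              params.mm_phase[None])[0]
    elif which == "mm" and not params.has_mm:
        raise ValueError("MM parameters are empty")
    return out


def synthesize_batch(arrays: dict[str, np.ndarray], basis: MetaboliteBasis | None,
                     axis: SpectralAxis, which: str) -> np.ndarray:
    """Vectorized model evaluation for stacked parameter arrays."""
    n = arrays["phi0"].shape[0]
    out = np.zeros((n, axis.n_points), dtype=np.complex128)
    if which in ("metabolite", "both") and "met_conc" in arrays:
        if basis is None:
            raise ValueError("metabolite synthesis requires a basis")
        out += _met_term_batch(axis, basis, arrays["phi0"], arrays["met_conc"],
                               arrays["met_t2star"], arrays["met_df_hz"],
                               arrays["met_phase"])
    if which in ("mm", "both") and "mm_amp" in arrays:
        out += _mm_term_batch(axis, arrays["phi0"], arrays["mm_amp"],
                              arrays["mm_width_hz"], arrays["mm_df_hz"],
                              arrays["mm_phase"])
    return out


@dataclass
class TrainingSet:
    """Normalized component-specific training matrix.

    ``samples`` is (N, 2T) real with every entry in [-1, 1];
    ``samples * norm_scale`` reproduces the raw synthesized signals exactly.
    """

    samples: np.ndarray
    component_tag: str
    norm_scale: float
    seed: int
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2 * self.axis.n_points:
            raise ValueError("samples must be (N, 2T) for the stored axis")
        if not self.norm_scale > 0:
            raise ValueError("norm_scale must be positive")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def raw(self) -> np.ndarray:
        """De-normalized (N, 2T) signals."""
        return self.samples * self.norm_scale

    def fids(self) -> np.ndarray:
        """De-normalized complex FIDs, shape (N, T)."""
        return real_to_fids(self.raw())

    def split(self, n_train: int) -> tuple["TrainingSet", "TrainingSet"]:
        """Deterministic head/tail split sharing the normalization scale."""
        if not 0 < n_train < self.n:
            raise ValueError("n_train must be in (0, N)")
        mk = lambda s: TrainingSet(s, self.component_tag, self.norm_scale,
                                   self.seed, self.axis)
        return mk(self.samples[:n_train]), mk(self.samples[n_train:])


def generate_training_set(n: int, component: str, dists: ParamDistributions,
                          basis: MetaboliteBasis | None, axis: SpectralAxis,
                          rng_seed: int) -> TrainingSet:
    """Synthesize ``n`` component-specific spectra and normalize to [-1, 1].

    One shared ``norm_scale`` (the maximum absolute real/imaginary value over
    the whole set) scales the matrix; per-sample amplitude information is
    preserved. Bit-reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if component not in ("metabolite", "macromolecule"):
        raise ValueError(f"component must be 'metabolite' or 'macromolecule', got {component!r}")
    rng = rng_for(rng_seed, "params", component)
    arrays = sample_parameter_arrays(dists, component, rng, n,
                                     field_mhz=axis.field_mhz, ref_ppm=axis.ref_ppm)
    which = "metabolite" if component == "metabolite" else "mm"
    fids = synthesize_batch(arrays, basis, axis, which)
    x = fids_to_real(fids)
    scale = float(np.abs(x).max())
    if scale == 0:
        raise ValueError("all-zero training set; check distributions")
    x /= scale
    # flush amplitudes below machine-noise level (decayed Gaussian tails) to
    # exact zero: numerically irrelevant, and avoids float32 subnormals that
    # severely slow the training arithmetic
    x[np.abs(x) < 1e-12] = 0.0
    return TrainingSet(samples=x, component_tag=component,
                       norm_scale=scale, seed=int(rng_seed), axis=axis)
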