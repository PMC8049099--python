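"""Spectral parameters and their sampling distributions.

The parametric FID model has, per voxel, a global zeroth-order phase phi0 and

* per metabolite m: concentration coefficient c_m (unitless, NAA mean = 1),
  Lorentzian decay constant T2*_m (s), frequency shift df_m (Hz) and a
  molecule phase phi_m (rad);
* per macromolecule (MM) group l: amplitude b_l (unitless), Gaussian
  full-width-at-half-maximum W_l (Hz), resonance offset df_l (Hz) and a group
  phase psi_l (rad).

Training spectra are generated by drawing every parameter from a truncated
(rejection-sampled) Gaussian. The phase standard deviations (25 deg global,
10 deg per molecule), the bounds (T2* in [5, 200] ms, c in [0, 2], W in
[5, 70] Hz, b >= 0), the 13 MM resonance positions and the 20%-of-mean rule
for the MM amplitude/width spreads are fixed study conditions; the remaining
means are package defaults documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seeds import rng_for

__all__ = [
    "BoundedGaussian",
    "ComponentParams",
    "ParamDistributions",
    "MM_POSITIONS_PPM",
    "default_distributions",
    "sample_parameters",
]

#: Mean chemical-shift positions (ppm) of the 13 modeled MM resonance groups.
MM_POSITIONS_PPM: tuple[float, ...] = (
    0.9, 1.21, 1.38, 1.63, 2.01, 2.09, 2.25, 2.61, 2.96, 3.11, 3.67, 3.8, 3.96,
)

# Default MM group amplitudes (relative, before mm_global_scale) and Gaussian
# FWHM linewidths in Hz; package defaults standing in for unpublished
# literature tables, spreads are 20% of these means.
_MM_AMP_MEANS = (0.72, 0.28, 0.38, 0.18, 0.50, 0.45, 0.31, 0.18, 0.36, 0.25,
                 0.58, 0.45, 0.46)
_MM_WIDTH_MEANS = (38.0, 33.0, 30.0, 28.0, 45.0, 40.0, 35.0, 30.0, 29.0, 33.0,
                   48.0, 28.0, 50.0)

# Default metabolite concentration coefficient means relative to NAA = 1.
_MET_CONC_MEANS = {
    "NAA": 1.00, "Cr": 0.65, "Cho": 0.25, "Glu": 0.75, "Gln": 0.25,
    "mI": 0.45, "GABA": 0.12, "GSH": 0.18, "Lac": 0.08,
}


@dataclass(frozen=True)
class BoundedGaussian:
    """Gaussian with hard bounds enforced by rejection sampling."""

    mean: float
    std: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be >= 0")
        if not self.lo < self.hi:
            raise ValueError(f"lower bound {self.lo} must be < upper bound {self.hi}")

    def sample(self, rng: np.random.Generator, size: int | tuple = (),
               max_tries: int = 1000):
        """Draw within bounds; out-of-range values are redrawn (never clipped)."""
        scalar = size == ()
        shape = (1,) if scalar else size
        x = np.asarray(rng.normal(self.mean, self.std, size=shape), dtype=float)
        for _ in range(max_tries):
            bad = (x < self.lo) | (x > self.hi)
            if not bad.any():
                break
            x[bad] = rng.normal(self.mean, self.std, size=int(bad.sum()))
        else:
            raise RuntimeError(
                f"rejection sampling did not converge in {max_tries} rounds for "
                f"N({self.mean}, {self.std}) on [{self.lo}, {self.hi}]")
        return float(x[0]) if scalar else x


@dataclass
class ParamDistributions:
    """Sampling distributions for every model parameter of one study."""

    met_conc: dict[str, BoundedGaussian] = field(default_factory=dict)
    met_t2star: BoundedGaussian = BoundedGaussian(0.060, 0.015, 0.005, 0.200)
    met_shift_hz: BoundedGaussian = BoundedGaussian(0.0, 5.0, -15.0, 15.0)
    phi0_std_deg: float = 25.0
    met_phase_std_deg: float = 10.0
    mm_positions_ppm: tuple[float, ...] = MM_POSITIONS_PPM
    mm_amp: tuple[BoundedGaussian, ...] = ()
    mm_width_hz: tuple[BoundedGaussian, ...] = ()
    mm_shift_jitter_hz: BoundedGaussian = BoundedGaussian(0.0, 5.0, -15.0, 15.0)
    mm_phase_std_deg: float = 10.0
    #: Scalar applied to all b_l draws (metabolite-to-MM signal ratio knob).
    mm_global_scale: float = 0.74

    def __post_init__(self) -> None:
        if len(self.mm_amp) != len(self.mm_positions_ppm) or \
                len(self.mm_width_hz) != len(self.mm_positions_ppm):
            raise ValueError("mm_amp/mm_width_hz must match mm_positions_ppm length")

    @property
    def met_names(self) -> list[str]:
        return list(self.met_conc)

    @property
    def n_mm(self) -> int:
        return len(self.mm_positions_ppm)


def default_distributions(met_names: list[str] | None = None) -> ParamDistributions:
    """Package-default study conditions.

    Concentration spreads are 20% of the means (bounded to [0, 2]); MM
    amplitude and width spreads are 20% of their means per the stated rule.
    """
    names = list(_MET_CONC_MEANS) if met_names is None else list(met_names)
    conc = {}
    for n in names:
        m = _MET_CONC_MEANS[n]
        conc[n] = BoundedGaussian(m, 0.20 * m, 0.0, 2.0)
    amp = tuple(BoundedGaussian(m, 0.20 * m, 0.0, np.inf) for m in _MM_AMP_MEANS)
    width = tuple(BoundedGaussian(m, 0.20 * m, 5.0, 70.0) for m in _MM_WIDTH_MEANS)
    return ParamDistributions(met_conc=conc, mm_amp=amp, mm_width_hz=width)


@dataclass
class ComponentParams:
    """One voxel's spectral parameters (either or both components filled).

    Metabolite arrays are aligned with ``met_names``; MM arrays with the 13
    resonance groups. ``mm_df_hz`` is the absolute frequency offset of each
    group (position + jitter), in Hz relative to the reference.
    """

    phi0: float = 0.0
    met_names: list[str] = field(default_factory=list)
    met_conc: np.ndarray = field(default_factory=lambda: np.zeros(0))
    met_t2star: np.ndarray = field(default_factory=lambda: np.zeros(0))
    met_df_hz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    met_phase: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mm_amp: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mm_width_hz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mm_df_hz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mm_phase: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for name in ("met_conc", "met_t2star", "met_df_hz", "met_phase",
                     "mm_amp", "mm_width_hz", "mm_df_hz", "mm_phase"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        arrays = [self.met_conc, self.met_t2star, self.met_df_hz, self.met_phase,
                  self.mm_amp, self.mm_width_hz, self.mm_df_hz, self.mm_phase,
                  np.asarray([self.phi0])]
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("all spectral parameters must be finite")
        if self.met_conc.size and (self.met_conc < 0).any():
            raise ValueError("concentration coefficients must be >= 0")
        if self.mm_amp.size and (self.mm_amp < 0).any():
            raise ValueError("MM amplitudes must be >= 0")
        if self.met_t2star.size and (self.met_t2star <= 0).any():
            raise ValueError("T2* must be positive")
        if self.mm_width_hz.size and (self.mm_width_hz <= 0).any():
            raise ValueError("MM linewidths must be positive")

    @property
    def has_met(self) -> bool:
        return bool(self.met_conc.size)

    @property
    def has_mm(self) -> bool:
        return bool(self.mm_amp.size)

    def with_phi0(self, phi0: float) -> "ComponentParams":
        return replace(self, phi0=phi0)


def _deg(rng: np.random.Generator, std_deg: float, size) -> np.ndarray:
    return np.deg2rad(rng.normal(0.0, std_deg, size=size))


def sample_parameters(dists: ParamDistributions, component: str,
                      rng_seed: int | np.random.Generator,
                      field_mhz: float = 127.7, ref_ppm: float = 4.7,
                      max_tries: int = 1000) -> ComponentParams:
    """Draw one voxel's parameters for ``component`` in {'metabolite',
    'macromolecule', 'both'}; deterministic given the seed."""
    batch = sample_parameter_batch(dists, component, rng_seed, n=1,
                                   field_mhz=field_mhz, ref_ppm=ref_ppm,
                                   max_tries=max_tries)
    return batch[0]


def sample_parameter_batch(dists: ParamDistributions, component: str,
                           rng_seed: int | np.random.Generator, n: int,
                           field_mhz: float = 127.7, ref_ppm: float = 4.7,
                           max_tries: int = 1000) -> list[ComponentParams]:
    """Vectorized draw of ``n`` independent parameter sets."""
    arrays = sample_parameter_arrays(dists, component, rng_seed, n,
                                     field_mhz=field_mhz, ref_ppm=ref_ppm,
                                     max_tries=max_tries)
    out = []
    for i in range(n):
        out.append(ComponentParams(
            phi0=float(arrays["phi0"][i]),
            met_names=dists.met_names if "met_conc" in arrays else [],
            met_conc=arrays.get("met_conc", np.zeros((n, 0)))[i],
            met_t2star=arrays.get("met_t2star", np.zeros((n, 0)))[i],
            met_df_hz=arrays.get("met_df_hz", np.zeros((n, 0)))[i],
            met_phase=arrays.get("met_phase", np.zeros((n, 0)))[i],
            mm_amp=arrays.get("mm_amp", np.zeros((n, 0)))[i],
            mm_width_hz=arrays.get("mm_width_hz", np.zeros((n, 0)))[i],
            mm_df_hz=arrays.get("mm_df_hz", np.zeros((n, 0)))[i],
            mm_phase=arrays.get("mm_phase", np.zeros((n, 0)))[i],
        ))
    return out


def sample_parameter_arrays(dists: ParamDistributions, component: str,
                            rng_seed: int | np.random.Generator, n: int,
                            field_mhz: float = 127.7, ref_ppm: float = 4.7,
                            max_tries: int = 1000) -> dict[str, np.ndarray]:
    """Stacked parameter arrays (shape ``(n, ...)``) for batch synthesis."""
    if component not in ("metabolite", "macromolecule", "both"):
        raise ValueError(f"unknown component tag {component!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else rng_for(int(rng_seed), "params", component)

    out: dict[str, np.ndarray] = {
        "phi0": _deg(rng, dists.phi0_std_deg, n)}
    if component in ("metabolite", "both"):
        names = dists.met_names
        m = len(names)
        conc = np.empty((n, m))
        for j, name in enumerate(names):
            conc[:, j] = dists.met_conc[name].sample(rng, n, max_tries)
        out["met_conc"] = conc
        out["met_t2star"] = np.column_stack(
            [dists.met_t2star.sample(rng, n, max_tries) for _ in range(m)])
        out["met_df_hz"] = np.column_stack(
            [dists.met_shift_hz.sample(rng, n, max_tries) for _ in range(m)])
        out["met_phase"] = _deg(rng, dists.met_phase_std_deg, (n, m))
    if component in ("macromolecule", "both"):
        k = dists.n_mm
        amp = np.column_stack([d.sample(rng, n, max_tries) for d in dists.mm_amp])
        out["mm_amp"] = dists.mm_global_scale * amp
        out["mm_width_hz"] = np.column_stack(
            [d.sample(rng, n, max_tries) for d in dists.mm_width_hz])
        base = (np.asarray(dists.mm_positions_ppm) - ref_ppm) * field_mhz
        jitter = np.column_stack(
            [dists.mm_shift_jitter_hz.sample(rng, n, max_tries) for _ in range(k)])
        out["mm_df_hz"] = base[None, :] + jitter
        out["mm_phase"] = _deg(rng, dists.mm_phase_std_deg, (n, k))
    return out
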