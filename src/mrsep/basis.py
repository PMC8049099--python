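"""Metabolite basis signals.

Each metabolite contributes a decay-free complex time-domain basis FID

    v_m(t) = sum_k a_{m,k} exp(i 2 pi f(ppm_{m,k}) t),

a sum of pure complex exponentials at the metabolite's proton chemical-shift
positions with fixed relative amplitudes. Lineshape (decay), frequency jitter
and phase are applied on top of the basis by the parametric signal model, so
the basis itself carries only the resonance structure.

The built-in table is a simplified analytic multiplet set: singlets for the
dominant NAA/Cr/Cho peaks and few-line multiplets for the coupled spin
systems, with amplitudes proportional to proton counts. Amplitudes are
globally normalized so the dominant NAA methyl resonance (2.01 ppm) has unit
amplitude. Quantum-mechanical basis sets (J-evolution, TE-specific patterns)
are out of scope; a user-supplied basis stored in the package HDF5 container
is accepted anywhere a basis is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import SpectralAxis

__all__ = ["MetaboliteBasis", "build_default_basis", "SUPPORTED_METABOLITES", "RESONANCE_TABLE"]

# (ppm position, relative amplitude ~ proton count) per metabolite.
# Positions from standard 1H chemical-shift tables for brain metabolites.
RESONANCE_TABLE: dict[str, list[tuple[float, float]]] = {
    "NAA":  [(2.008, 3.0), (2.49, 0.8), (2.67, 0.8)],
    "Cr":   [(3.027, 3.0), (3.913, 2.0)],
    "Cho":  [(3.185, 9.0), (3.501, 2.0)],
    "Glu":  [(2.04, 1.0), (2.11, 1.0), (2.35, 2.0), (3.74, 1.0)],
    "Gln":  [(2.13, 2.0), (2.45, 2.0), (3.75, 1.0)],
    "mI":   [(3.52, 4.0), (3.61, 1.0), (4.05, 1.0)],
    "GABA": [(1.89, 2.0), (2.28, 2.0), (3.01, 2.0)],
    "GSH":  [(2.15, 2.0), (2.55, 2.0), (2.95, 2.0), (3.77, 1.0)],
    "Lac":  [(1.31, 3.0), (4.10, 1.0)],
}

SUPPORTED_METABOLITES: tuple[str, ...] = tuple(RESONANCE_TABLE)

# All basis amplitudes are divided by this so the NAA 2.01 ppm line has
# amplitude 1; relative (within- and across-metabolite) ratios are preserved.
_NAA_MAIN_AMPLITUDE = max(a for _, a in RESONANCE_TABLE["NAA"])


@dataclass
class MetaboliteBasis:
    """Ordered set of complex basis FIDs sharing one :class:`SpectralAxis`."""

    names: list[str]
    fids: np.ndarray  # complex, shape (n_metabolites, T)
    axis: SpectralAxis
    scheme_tag: str = "analytic-multiplet"
    # per-metabolite (ppm, amplitude) lines; kept for provenance/export
    lines: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fids = np.asarray(self.fids, dtype=np.complex128)
        if self.fids.shape != (len(self.names), self.axis.n_points):
            raise ValueError("fids must have shape (len(names), axis.n_points)")
        if not np.all(np.isfinite(self.fids.view(float))):
            raise ValueError("basis FIDs must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"metabolite {name!r} not in basis {self.names}") from None


def build_default_basis(axis: SpectralAxis,
                        names: list[str] | tuple[str, ...] | None = None) -> MetaboliteBasis:
    """Build the simplified analytic multiplet basis on ``axis``.

    Parameters
    ----------
    axis:
        Grid the basis FIDs are evaluated on.
    names:
        Metabolites to include, drawn from :data:`SUPPORTED_METABOLITES`.
        Defaults to all nine.

    Returns
    -------
    MetaboliteBasis
        Deterministic, decay-free basis (constant modulus per line sum).
    """
    if names is None:
        names = list(SUPPORTED_METABOLITES)
    names = list(names)
    unknown = [n for n in names if n not in RESONANCE_TABLE]
    if unknown:
        raise ValueError(
            f"unknown metabolite name(s) {unknown}; supported: {list(SUPPORTED_METABOLITES)}")

    t = axis.time
    fids = np.zeros((len(names), axis.n_points), dtype=np.complex128)
    lines: dict[str, list[tuple[float, float]]] = {}
    for i, name in enumerate(names):
        table = RESONANCE_TABLE[name]
        lines[name] = [(p, a / _NAA_MAIN_AMPLITUDE) for p, a in table]
        for ppm, amp in lines[name]:
            f_hz = axis.ppm_to_hz(ppm)
            fids[i] += amp * np.exp(2j * np.pi * f_hz * t)
    return MetaboliteBasis(names=names, fids=fids, axis=axis, lines=lines)
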