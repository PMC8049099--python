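"""HDF5 / NIfTI / CSV / YAML containers.

One HDF5 container family with a schema version attribute holds every
package artifact:

* axis:      /axis/{n_points,bandwidth,field_mhz,ref_ppm}
* basis:     /basis/{names,fids,scheme_tag}
* training:  /train/{samples,component_tag,norm_scale,seed}
* models:    /model/{layer_dims,activation,component_tag,model_order,
              norm_scale,seed,final_train_loss,final_test_error,
              weights_i,biases_i,nonlinear}
* phantom:   /phantom/{x_met,x_mm,b0,fractions,lesion,seed}
* encoded:   /encoded/{d,mask,snr,noise_seed,noise_std}
* recon:     /recon/{x_met,x_mm,s,history_*}

Every writer stamps a provenance block (schema version, package version,
seed where applicable) in the root attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .axes import SpectralAxis
from .basis import MetaboliteBasis
from .network import MLP
from .params import BoundedGaussian, ParamDistributions
from .phantom import EncodedData, Phantom, PhantomSpec
from .representation import DAEModel
from .synth import TrainingSet

SCHEMA_VERSION = "1"

__all__ = [
    "save_axis", "load_axis", "save_basis", "load_basis",
    "save_training_set", "load_training_set", "save_model", "load_model",
    "save_phantom", "load_phantom", "save_recon", "load_recon",
    "spectrum_to_csv", "distributions_to_yaml", "distributions_from_yaml",
]


def _stamp(f: h5py.File, seed: int | None = None) -> None:
    f.attrs["schema_version"] = SCHEMA_VERSION
    f.attrs["package"] = "mrsep"
    if seed is not None:
        f.attrs["seed"] = int(seed)


def save_axis(g: h5py.Group, axis: SpectralAxis) -> None:
    grp = g.require_group("axis")
    grp.attrs["n_points"] = axis.n_points
    grp.attrs["bandwidth"] = axis.bandwidth
    grp.attrs["field_mhz"] = axis.field_mhz
    grp.attrs["ref_ppm"] = axis.ref_ppm


def load_axis(g: h5py.Group) -> SpectralAxis:
    grp = g["axis"]
    return SpectralAxis(int(grp.attrs["n_points"]), float(grp.attrs["bandwidth"]),
                        float(grp.attrs["field_mhz"]), float(grp.attrs["ref_ppm"]))


def save_basis(path: str, basis: MetaboliteBasis) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f)
        save_axis(f, basis.axis)
        grp = f.create_group("basis")
        grp.create_dataset("names", data=np.array(basis.names, dtype="S"))
        grp.create_dataset("fids", data=basis.fids)
        grp.attrs["scheme_tag"] = basis.scheme_tag
        grp.attrs["lines"] = json.dumps(basis.lines)


def load_basis(path: str) -> MetaboliteBasis:
    with h5py.File(path, "r") as f:
        axis = load_axis(f)
        grp = f["basis"]
        names = [n.decode() for n in grp["names"][()]]
        lines = json.loads(grp.attrs.get("lines", "{}"))
        lines = {k: [tuple(x) for x in v] for k, v in lines.items()}
        return MetaboliteBasis(names=names, fids=grp["fids"][()], axis=axis,
                               scheme_tag=str(grp.attrs.get("scheme_tag", "")),
                               lines=lines)


def save_training_set(path: str, ts: TrainingSet) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, ts.seed)
        save_axis(f, ts.axis)
        grp = f.create_group("train")
        grp.create_dataset("samples", data=ts.samples)
        grp.attrs["component_tag"] = ts.component_tag
        grp.attrs["norm_scale"] = ts.norm_scale
        grp.attrs["seed"] = ts.seed


def load_training_set(path: str) -> TrainingSet:
    with h5py.File(path, "r") as f:
        axis = load_axis(f)
        grp = f["train"]
        return TrainingSet(samples=grp["samples"][()],
                           component_tag=str(grp.attrs["component_tag"]),
                           norm_scale=float(grp.attrs["norm_scale"]),
                           seed=int(grp.attrs["seed"]), axis=axis)


def save_model(path: str, model: DAEModel) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, model.seed)
        save_axis(f, model.axis)
        grp = f.create_group("model")
        grp.attrs["layer_dims"] = model.net.dims
        grp.attrs["activation"] = model.net.activation
        grp.attrs["component_tag"] = model.component_tag
        grp.attrs["model_order"] = model.model_order
        grp.attrs["norm_scale"] = model.norm_scale
        grp.attrs["seed"] = model.seed
        grp.attrs["final_train_loss"] = model.final_train_loss
        grp.attrs["final_test_error"] = model.final_test_error
        grp.create_dataset("nonlinear", data=np.asarray(model.net.nonlinear))
        for i, (w, b) in enumerate(zip(model.net.weights, model.net.biases)):
            grp.create_dataset(f"weights_{i}", data=w)
            grp.create_dataset(f"biases_{i}", data=b)


def load_model(path: str) -> DAEModel:
    with h5py.File(path, "r") as f:
        axis = load_axis(f)
        grp = f["model"]
        dims = [int(d) for d in grp.attrs["layer_dims"]]
        n_layers = len(dims) - 1
        net = MLP(dims=dims, activation=str(grp.attrs["activation"]),
                  weights=[grp[f"weights_{i}"][()] for i in range(n_layers)],
                  biases=[grp[f"biases_{i}"][()] for i in range(n_layers)],
                  nonlinear=[bool(b) for b in grp["nonlinear"][()]])
        return DAEModel(net=net, component_tag=str(grp.attrs["component_tag"]),
                        model_order=int(grp.attrs["model_order"]),
                        norm_scale=float(grp.attrs["norm_scale"]), axis=axis,
                        seed=int(grp.attrs["seed"]),
                        final_train_loss=float(grp.attrs["final_train_loss"]),
                        final_test_error=float(grp.attrs["final_test_error"]))


def save_phantom(path: str, phantom: Phantom,
                 encoded: EncodedData | None = None) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, phantom.seed)
        save_axis(f, phantom.axis)
        grp = f.create_group("phantom")
        grp.create_dataset("x_met", data=phantom.x_met)
        grp.create_dataset("x_mm", data=phantom.x_mm)
        grp.create_dataset("b0", data=phantom.b0_map)
        grp.create_dataset("fractions", data=phantom.tissue_fractions)
        grp.create_dataset("lesion", data=phantom.lesion_mask)
        grp.create_dataset("brain_mask", data=phantom.brain_mask)
        grp.attrs["seed"] = phantom.seed
        grp.attrs["spec"] = json.dumps(vars(phantom.spec))
        bgrp = f.create_group("basis")
        bgrp.create_dataset("names", data=np.array(phantom.basis.names, dtype="S"))
        bgrp.create_dataset("fids", data=phantom.basis.fids)
        for name, img in phantom.conc_maps.items():
            grp.create_dataset(f"conc/{name}", data=img)
        if phantom.mm_amp_maps is not None:
            grp.create_dataset("mm_amp_maps", data=phantom.mm_amp_maps)
        if encoded is not None:
            egrp = f.create_group("encoded")
            egrp.create_dataset("d", data=encoded.d)
            egrp.create_dataset("mask", data=encoded.omega_mask)
            egrp.attrs["snr"] = encoded.snr
            egrp.attrs["noise_seed"] = encoded.noise_seed
            egrp.attrs["noise_std"] = encoded.noise_std


def load_phantom(path: str) -> tuple[Phantom, EncodedData | None]:
    with h5py.File(path, "r") as f:
        axis = load_axis(f)
        grp = f["phantom"]
        spec_dict = json.loads(grp.attrs["spec"])
        for key in ("lesion_center", "lesion_radii"):
            if key in spec_dict:
                spec_dict[key] = tuple(spec_dict[key])
        spec = PhantomSpec(**spec_dict)
        bgrp = f["basis"]
        basis = MetaboliteBasis(names=[n.decode() for n in bgrp["names"][()]],
                                fids=bgrp["fids"][()], axis=axis)
        conc = {}
        if "conc" in grp:
            conc = {k: grp[f"conc/{k}"][()] for k in grp["conc"]}
        phantom = Phantom(spec=spec, axis=axis, basis=basis,
                          tissue_fractions=grp["fractions"][()],
                          brain_mask=grp["brain_mask"][()],
                          lesion_mask=grp["lesion"][()], b0_map=grp["b0"][()],
                          x_met=grp["x_met"][()], x_mm=grp["x_mm"][()],
                          conc_maps=conc,
                          mm_amp_maps=grp["mm_amp_maps"][()]
                          if "mm_amp_maps" in grp else None,
                          seed=int(grp.attrs["seed"]))
        encoded = None
        if "encoded" in f:
            egrp = f["encoded"]
            encoded = EncodedData(d=egrp["d"][()], omega_mask=egrp["mask"][()],
                                  snr=float(egrp.attrs["snr"]),
                                  noise_seed=int(egrp.attrs["noise_seed"]),
                                  noise_std=float(egrp.attrs["noise_std"]))
        return phantom, encoded


def save_recon(path: str, x_met: np.ndarray, x_mm: np.ndarray, state) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f)
        grp = f.create_group("recon")
        grp.create_dataset("x_met", data=x_met)
        grp.create_dataset("x_mm", data=x_mm)
        grp.create_dataset("s", data=state.s)
        grp.create_dataset("history_rel_change", data=np.asarray(state.rel_changes))
        grp.create_dataset("history_primal", data=np.asarray(state.primal_residuals))
        grp.create_dataset("history_objective", data=np.asarray(state.objectives))


def load_recon(path: str) -> dict:
    with h5py.File(path, "r") as f:
        grp = f["recon"]
        return {k: grp[k][()] for k in grp}


def spectrum_to_csv(path: str, fid: np.ndarray, axis: SpectralAxis) -> None:
    """CSV export with columns frequency_hz, ppm, real, imag, magnitude."""
    import pandas as pd
    spec = axis.spectrum(np.asarray(fid))
    pd.DataFrame({
        "frequency_hz": axis.freq_hz,
        "ppm": axis.ppm,
        "real": spec.real,
        "imag": spec.imag,
        "magnitude": np.abs(spec),
    }).to_csv(path, index=False)


def _bg_to_dict(bg: BoundedGaussian) -> dict:
    out = {"mean": bg.mean, "std": bg.std}
    if np.isfinite(bg.lo):
        out["lo"] = bg.lo
    if np.isfinite(bg.hi):
        out["hi"] = bg.hi
    return out


def _bg_from_dict(d: dict) -> BoundedGaussian:
    return BoundedGaussian(float(d["mean"]), float(d["std"]),
                           float(d.get("lo", -np.inf)), float(d.get("hi", np.inf)))


def distributions_to_yaml(path: str, dists: ParamDistributions) -> None:
    doc = {
        "met_conc": {k: _bg_to_dict(v) for k, v in dists.met_conc.items()},
        "met_t2star": _bg_to_dict(dists.met_t2star),
        "met_shift_hz": _bg_to_dict(dists.met_shift_hz),
        "phi0_std_deg": dists.phi0_std_deg,
        "met_phase_std_deg": dists.met_phase_std_deg,
        "mm_positions_ppm": list(dists.mm_positions_ppm),
        "mm_amp": [_bg_to_dict(d) for d in dists.mm_amp],
        "mm_width_hz": [_bg_to_dict(d) for d in dists.mm_width_hz],
        "mm_shift_jitter_hz": _bg_to_dict(dists.mm_shift_jitter_hz),
        "mm_phase_std_deg": dists.mm_phase_std_deg,
        "mm_global_scale": dists.mm_global_scale,
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def distributions_from_yaml(path: str) -> ParamDistributions:
    with open(path) as f:
        doc = yaml.safe_load(f)
    return ParamDistributions(
        met_conc={k: _bg_from_dict(v) for k, v in doc["met_conc"].items()},
        met_t2star=_bg_from_dict(doc["met_t2star"]),
        met_shift_hz=_bg_from_dict(doc["met_shift_hz"]),
        phi0_std_deg=float(doc["phi0_std_deg"]),
        met_phase_std_deg=float(doc["met_phase_std_deg"]),
        mm_positions_ppm=tuple(doc["mm_positions_ppm"]),
        mm_amp=tuple(_bg_from_dict(d) for d in doc["mm_amp"]),
        mm_width_hz=tuple(_bg_from_dict(d) for d in doc["mm_width_hz"]),
        mm_shift_jitter_hz=_bg_from_dict(doc["mm_shift_jitter_hz"]),
        mm_phase_std_deg=float(doc["mm_phase_std_deg"]),
        mm_global_scale=float(doc["mm_global_scale"]),
    )


def fractions_from_nifti(path: str) -> np.ndarray:
    """Load a (ny, nx, 3) tissue-fraction map from a NIfTI file."""
    import nibabel as nib
    data = np.asanyarray(nib.load(path).dataobj, dtype=float)
    if data.ndim == 4 and data.shape[2] == 1:
        data = data[:, :, 0, :]
    if data.ndim != 3 or data.shape[-1] != 3:
        raise ValueError("expected a (ny, nx, 3) fraction image")
    return data


def maps_to_nifti(path: str, maps: dict[str, np.ndarray]) -> None:
    """Stack molecular maps into a (ny, nx, n_mol) NIfTI image."""
    import nibabel as nib
    names = sorted(maps)
    stack = np.stack([maps[n] for n in names], axis=-1)
    img = nib.Nifti1Image(stack.astype(np.float32), affine=np.eye(4))
    img.header["descrip"] = (",".join(names))[:79].encode()
    nib.save(img, path)
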