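"""Component-specific low-dimensional spectral models.

Two deep autoencoders (DAEs) with the fully-connected shape
``2T-1000-250-100-L-100-250-1000-2T`` are trained with a mixed objective:
an unsupervised reconstruction term on the network's own component and a
supervised suppression term that drives the network's output on the *other*
component toward zero,

    theta_met = argmin (1/N) sum_n [ ||x_met^n - N_met(x_met^n)||^2
                                     + ||N_met(x_mm^n)||^2 ],

and symmetrically for the MM network. The result is a representation that
approximates its own component accurately while nearly annihilating the
other — the property the separation reconstruction relies on.

A linear counterpart (rank-L principal subspace of the training Casorati
matrix) is provided for comparison; it approximates its own component well
but, unlike the DAE, also captures much of the other component's energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .axes import SpectralAxis
from .network import MLP, AdamState
from .seeds import rng_for
from .synth import TrainingSet, fids_to_real, real_to_fids

__all__ = [
    "DAEModel", "SubspaceModel", "TrainConfig",
    "mixed_loss", "train_dae", "dae_apply", "dae_jacobian",
    "fit_subspace", "relative_l2_error", "representation_sweep",
]


@dataclass
class TrainConfig:
    """Stochastic-training settings (defaults follow the study recipe)."""

    batch_size: int = 500
    learning_rate: float = 1e-3   # initial learning rate
    epochs: int = 300
    optimizer: str = "adam"
    seed: int = 0
    suppression_weight: float = 1.0  # relative weight of the cross-component term
    lr_schedule: str = "cosine"   # 'cosine' decay of the initial rate, or 'constant'

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is implemented")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")


@dataclass
class DAEModel:
    """Trained component-specific autoencoder.

    ``net`` maps concatenated-real 2T vectors on the normalized [-1, 1] scale;
    ``norm_scale`` is the training set's scale, used to bridge physical-scale
    FIDs into the network's domain.
    """

    net: MLP
    component_tag: str
    model_order: int
    norm_scale: float
    axis: SpectralAxis
    seed: int = 0
    final_train_loss: float = float("nan")
    final_test_error: float = float("nan")
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return self.axis.n_points

    @property
    def layer_dims(self) -> list[int]:
        return self.net.dims

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Apply the network to normalized-scale 2T real vectors."""
        return self.net(x)


@dataclass
class SubspaceModel:
    """Rank-L principal subspace of a component's training matrix."""

    basis_vectors: np.ndarray  # (2T, L), orthonormal columns
    component_tag: str
    model_order: int

    def project(self, x: np.ndarray) -> np.ndarray:
        """Orthogonal projection of (..., 2T) vectors onto the subspace."""
        v = self.basis_vectors
        return (np.asarray(x) @ v) @ v.T


def _dae_dims(n_points: int, model_order: int) -> list[int]:
    t2 = 2 * n_points
    return [t2, 1000, 250, 100, model_order, 100, 250, 1000, t2]


def mixed_loss(model: DAEModel | MLP, own_batch: np.ndarray,
               other_batch: np.ndarray, suppression_weight: float = 1.0) -> float:
    """Mixed reconstruction + cross-component suppression loss.

    ``(1/N) sum_n [ ||x_own^n - N(x_own^n)||^2 + w ||N(x_other^n)||^2 ]`` with
    squared l2 for both terms and N the (shared) batch size.
    """
    net = model.net if isinstance(model, DAEModel) else model
    own = np.asarray(own_batch, dtype=np.float32)
    other = np.asarray(other_batch, dtype=np.float32)
    if own.shape != other.shape:
        raise ValueError("own and other batches must have identical shapes")
    if own.shape[-1] != net.dims[0]:
        raise ValueError(f"batch dimension {own.shape[-1]} != network input {net.dims[0]}")
    n = own.shape[0]
    rec = net(own) - own
    sup = net(other)
    return float((np.sum(rec.astype(np.float64) ** 2)
                  + suppression_weight * np.sum(sup.astype(np.float64) ** 2)) / n)


def train_dae(own: TrainingSet, other: TrainingSet, model_order: int,
              cfg: TrainConfig | None = None,
              activation: str = "relu",
              test_fraction: float = 1.0 / 3.0,
              eval_every: int = 0,
              verbose: bool = False) -> DAEModel:
    """Train a component-specific DAE with the mixed objective.

    The last ``test_fraction`` of ``own`` is held out; the returned model
    records the final training loss and the held-out relative l2 error.
    Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if own.samples.shape[1] != other.samples.shape[1]:
        raise ValueError("training sets must share the 2T dimension")
    n_pairs = min(own.n, other.n)
    n_test = int(round(n_pairs * test_fraction))
    n_train = n_pairs - n_test
    if n_train < 1:
        raise ValueError("not enough samples to train after the held-out split")

    x_own = own.samples[:n_train].astype(np.float32)
    x_other = other.samples[:n_train].astype(np.float32)
    x_test = own.samples[n_train:n_pairs].astype(np.float32)

    rng = rng_for(cfg.seed, "init", own.component_tag)
    net = MLP.create(_dae_dims(own.axis.n_points, model_order), activation, rng)
    adam = AdamState(lr=cfg.learning_rate)
    shuffle_rng = rng_for(cfg.seed, "shuffle", own.component_tag)

    w = np.float32(cfg.suppression_weight)
    history: list[float] = []
    eval_history: list[tuple[int, float]] = []
    steps_per_epoch = -(-n_train // cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    step_no = 0
    t2 = x_own.shape[1]
    xb = np.empty((2 * cfg.batch_size, t2), dtype=np.float32)
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n_train)
        total = 0.0
        for start in range(0, n_train, cfg.batch_size):
            if cfg.lr_schedule == "cosine":
                adam.lr = cfg.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * step_no / max(total_steps - 1, 1)))
            step_no += 1
            idx = order[start:start + cfg.batch_size]
            nb = len(idx)
            buf = xb if nb == cfg.batch_size else np.empty((2 * nb, t2),
                                                           dtype=np.float32)
            np.take(x_own, idx, axis=0, out=buf[:nb])
            np.take(x_other, idx, axis=0, out=buf[nb:])
            y, caches = net.forward(buf, cache=True)
            resid = y
            resid[:nb] -= buf[:nb]  # targets: own inputs, zeros for other
            batch_loss = float(np.dot(resid.ravel(), resid.ravel()))
            if w != 1.0:
                resid[nb:] *= w
            resid *= np.float32(2.0 / nb)
            dws, dbs, _ = net.backward(caches, resid)
            adam.step(net, dws, dbs)
            total += batch_loss / nb
        epoch_loss = total / max(1, -(-n_train // cfg.batch_size))
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        history.append(epoch_loss)
        if eval_every and n_test and ((epoch + 1) % eval_every == 0):
            err = relative_l2_error(x_test, net(x_test))
            eval_history.append((epoch + 1, err))
            if verbose:
                print(f"[{own.component_tag} DAE] epoch {epoch + 1:4d} "
                      f"held-out rel l2 {err:.4f}", flush=True)
        elif verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
            print(f"[{own.component_tag} DAE] epoch {epoch:4d} loss {epoch_loss:.5f}",
                  flush=True)

    test_err = float("nan")
    if n_test:
        test_err = relative_l2_error(x_test, net(x_test))
    model = DAEModel(net=net, component_tag=own.component_tag,
                     model_order=model_order, norm_scale=own.norm_scale,
                     axis=own.axis, seed=cfg.seed,
                     final_train_loss=history[-1], final_test_error=test_err,
                     loss_history=history)
    model.eval_history = eval_history
    return model


def dae_apply(model: DAEModel, fids: np.ndarray) -> np.ndarray:
    """Run complex FIDs (..., T) through the network.

    Bridges the physical scale into the network's normalized domain: divide
    by ``norm_scale``, pack real/imaginary, apply, unpack, multiply back.
    """
    fids = np.asarray(fids)
    if fids.shape[-1] != model.n_points:
        raise ValueError(f"FID length {fids.shape[-1]} != model T {model.n_points}")
    x = fids_to_real(fids) / model.norm_scale
    y = model.net(x).astype(np.float64) * model.norm_scale
    return real_to_fids(y)


def dae_jacobian(model: DAEModel, x: np.ndarray) -> np.ndarray:
    """Jacobian (2T x 2T) of the network map at a normalized-scale input."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return model.net.jacobian(x).astype(np.float64)


def fit_subspace(training: TrainingSet, model_order: int) -> SubspaceModel:
    """Top-L right singular subspace of the training sample matrix."""
    n, t2 = training.samples.shape
    if model_order > min(n, t2):
        raise ValueError(f"model order {model_order} exceeds min(N, 2T) = {min(n, t2)}")
    # right singular vectors of the (N, 2T) Casorati matrix
    _, _, vt = np.linalg.svd(np.asarray(training.samples, dtype=np.float64),
                             full_matrices=False)
    return SubspaceModel(basis_vectors=vt[:model_order].T,
                         component_tag=training.component_tag,
                         model_order=model_order)


def relative_l2_error(x_true: np.ndarray, x_hat: np.ndarray) -> float:
    """Frobenius-ratio error ``||X_true - X_hat||_F / ||X_true||_F``."""
    x_true = np.asarray(x_true)
    x_hat = np.asarray(x_hat)
    if x_true.shape != x_hat.shape:
        raise ValueError("shapes must match")
    denom = np.linalg.norm(x_true.ravel())
    if denom == 0:
        raise ValueError("reference signal has zero norm")
    return float(np.linalg.norm((x_true - x_hat).ravel()) / denom)


def representation_sweep(met_models: dict[int, DAEModel],
                         mm_models: dict[int, DAEModel],
                         met_train: TrainingSet, mm_train: TrainingSet,
                         met_test: TrainingSet, mm_test: TrainingSet,
                         orders: list[int]) -> pd.DataFrame:
    """Approximation-error table over model orders.

    For each order L and each model family (DAE / subspace, per component),
    the relative l2 error on both the own-component and cross-component test
    sets. Test samples are evaluated on the model's own normalized scale.
    """
    rows = []
    for L in orders:
        met_sub = fit_subspace(met_train, L)
        mm_sub = fit_subspace(mm_train, L)
        # test matrices rescaled to each model family's normalization
        met_x = met_test.raw()
        mm_x = mm_test.raw()
        for model_tag, met_map, mm_map in (
            ("dae",
             (lambda x: met_models[L].net(x / met_models[L].norm_scale)
              * met_models[L].norm_scale) if L in met_models else None,
             (lambda x: mm_models[L].net(x / mm_models[L].norm_scale)
              * mm_models[L].norm_scale) if L in mm_models else None),
            ("subspace", met_sub.project, mm_sub.project),
        ):
            for comp_model, fn in (("metabolite", met_map), ("macromolecule", mm_map)):
                if fn is None:
                    continue
                for comp_test, xt in (("metabolite", met_x), ("macromolecule", mm_x)):
                    err = relative_l2_error(xt, np.asarray(fn(xt), dtype=np.float64))
                    rows.append({"L": L, "model": model_tag,
                                 "model_component": comp_model,
                                 "test_component": comp_test,
                                 "rel_l2_error": err})
    return pd.DataFrame(rows)
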