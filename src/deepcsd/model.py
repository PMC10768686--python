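"""Patch CNN, voxel MLP, reproducibility loss and training.

The estimator maps a 3x3x3 neighborhood of signal-SH vectors (45 channels)
to the 45 fODF SH coefficients of the center voxel.  Training combines

* a fit loss: mean over samples of the summed squared coefficient error
  against the full-direction CSD label, and
* a pairing loss: the same functional applied to predictions for
  corresponding voxels of a registered scan/rescan pair, whose expectation
  is zero for a perfectly reproducible estimator,

weighted ``alpha`` and ``beta``; ``beta = 0`` whenever no paired data
participate.  A single shared network is forwarded on all three patch
groups per step, and at inference only single patches are needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import sh
from .errors import InvalidArgumentError
from .nn import Adam, BatchNorm, Dense, Param, PatchConv3, ReLU

N_COEF = 45  # order-8 even SH


@dataclass(frozen=True)
class LossWeights:
    """Eq.-style loss weights: total = alpha * fit + beta * pairing."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidArgumentError("loss weights must be non-negative")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture selector and seeds; layer sizes are fixed by design."""

    architecture: str = "patch_cnn"  # "patch_cnn" | "voxel_mlp"
    seed: int = 0
    hidden_dense: int = 200
    batchnorm: bool = True
    shortcut: str = "center"  # "center" | "avgpool"

    def __post_init__(self) -> None:
        if self.architecture not in ("patch_cnn", "voxel_mlp"):
            raise InvalidArgumentError(f"unknown architecture {self.architecture!r}")
        if self.shortcut not in ("center", "avgpool"):
            raise InvalidArgumentError(f"unknown shortcut mode {self.shortcut!r}")


@dataclass(frozen=True)
class OptimConfig:
    lr: float = 1e-3
    batch_size: int = 128
    epochs: int = 50
    patience: int = 5


@dataclass
class TripletBatch:
    """One training step's data: labeled patches plus a scan/rescan pair.

    ``paired_u[i]`` and ``paired_v[i]`` are the same voxel location in the
    two volumes of one registered pair.
    """

    labeled_x: np.ndarray            # (B, 3, 3, 3, 45) or (B, 45) for MLP
    labels: np.ndarray               # (B, 45), center-voxel fODF SH
    paired_u: np.ndarray | None = None
    paired_v: np.ndarray | None = None


# ---------------------------------------------------------------------------
# losses

def loss_fit(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean over samples of the coefficient-summed squared error."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise InvalidArgumentError("pred and truth shapes differ")
    return float(np.mean(np.sum((truth - pred) ** 2, axis=-1)))


def loss_pair(pred_u: np.ndarray, pred_v: np.ndarray) -> float:
    """Reproducibility loss: squared prediction gap between paired voxels."""
    return loss_fit(pred_u, pred_v)


def loss_total(loss1: float, loss2: float, weights: LossWeights) -> float:
    if loss1 < 0 or loss2 < 0:
        raise InvalidArgumentError("losses must be non-negative")
    return weights.alpha * loss1 + weights.beta * loss2


# ---------------------------------------------------------------------------
# architectures

class _NormalizationMixin:
    """Fixed affine input/output normalization.

    Signal-SH inputs and fODF-SH labels have strongly heterogeneous
    per-coefficient scales; standardizing both (with the output mapped
    back to raw coefficients inside the model) conditions the optimization
    without changing what the network predicts or how the loss is defined.
    Statistics are computed once from the training volumes and serialized
    with the weights.
    """

    norm: dict | None = None

    def set_normalization(self, in_mean, in_std, out_mean, out_std) -> None:
        self.norm = {"in_mean": np.asarray(in_mean, dtype=np.float64),
                     "in_std": np.asarray(in_std, dtype=np.float64),
                     "out_mean": np.asarray(out_mean, dtype=np.float64),
                     "out_std": np.asarray(out_std, dtype=np.float64)}

    def _norm_in(self, x: np.ndarray) -> np.ndarray:
        if self.norm is None:
            return x
        return (x - self.norm["in_mean"]) / self.norm["in_std"]

    def _denorm_out(self, y: np.ndarray) -> np.ndarray:
        if self.norm is None:
            return y
        return y * self.norm["out_std"] + self.norm["out_mean"]

    def _scale_dy(self, dy: np.ndarray) -> np.ndarray:
        if self.norm is None:
            return dy
        return dy * self.norm["out_std"]


def compute_normalization(labeled_volumes) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-coefficient mean/std of signal inputs and fODF labels over WM."""
    xs, ys = [], []
    for sig, lab, mask in labeled_volumes:
        m = np.asarray(mask, dtype=bool)
        xs.append(sig.data[m])
        ys.append(lab.data[m])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return x.mean(0), x.std(0) + 1e-8, y.mean(0), y.std(0) + 1e-8


class PatchCNN(_NormalizationMixin):
    """3D residual patch CNN: 3x3x3x45 in, 45 SH coefficients out.

    conv1 (1^3 kernel, 45 filters) -> conv2 (3^3, padding 1, 45) ->
    conv3 (3^3, padding 0, 45), a shortcut adding the conv1 activation at
    the patch center to the conv3 output, then two dense layers.  Batch
    norm follows each affine before its ReLU; the output layer is linear
    because SH coefficients are signed.
    """

    input_kind = "patch"

    def __init__(self, config: NetworkConfig):
        if config.architecture != "patch_cnn":
            raise InvalidArgumentError("config.architecture must be 'patch_cnn'")
        self.config = config
        rng = np.random.default_rng(config.seed)
        H = config.hidden_dense
        self.conv1 = Dense(N_COEF, N_COEF, rng)
        self.conv2 = PatchConv3(N_COEF, N_COEF, rng)
        self.conv3 = Dense(27 * N_COEF, N_COEF, rng)
        self.dense1 = Dense(N_COEF, H, rng)
        self.dense2 = Dense(H, N_COEF, rng)
        self.bn1 = BatchNorm(N_COEF)
        self.bn2 = BatchNorm(N_COEF)
        self.bn3 = BatchNorm(N_COEF)
        self.bn4 = BatchNorm(H)
        self.r1, self.r2, self.r3, self.r4 = ReLU(), ReLU(), ReLU(), ReLU()
        self._cache: dict = {}

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 5 or x.shape[1:] != (3, 3, 3, N_COEF):
            raise InvalidArgumentError(f"expected (N, 3, 3, 3, {N_COEF}) patches, got {x.shape}")
        N = x.shape[0]
        bn = self.config.batchnorm
        xf = self._norm_in(x).reshape(N * 27, N_COEF)
        h1 = self.conv1.forward(xf)
        if bn:
            h1 = self.bn1.forward(h1, train)
        h1 = self.r1.forward(h1).reshape(N, 27, N_COEF)

        h2 = self.conv2.forward(h1.reshape(N, 27 * N_COEF)).reshape(N * 27, N_COEF)
        if bn:
            h2 = self.bn2.forward(h2, train)
        h2 = self.r2.forward(h2).reshape(N, 27 * N_COEF)

        h3 = self.conv3.forward(h2)
        if bn:
            h3 = self.bn3.forward(h3, train)
        short = h1.mean(axis=1) if self.config.shortcut == "avgpool" else h1[:, 13, :]
        h3 = self.r3.forward(h3 + short)

        h4 = self.dense1.forward(h3)
        if bn:
            h4 = self.bn4.forward(h4, train)
        h4 = self.r4.forward(h4)
        out = self.dense2.forward(h4)
        self._cache = {"N": N}
        return self._denorm_out(out)

    def backward(self, dy: np.ndarray) -> None:
        N = self._cache["N"]
        bn = self.config.batchnorm
        d = self.dense2.backward(self._scale_dy(dy))
        d = self.r4.backward(d)
        if bn:
            d = self.bn4.backward(d)
        d = self.dense1.backward(d)
        d = self.r3.backward(d)
        dshort = d.copy()
        if bn:
            d = self.bn3.backward(d)
        d = self.conv3.backward(d)              # (N, 27*45)
        d = self.r2.backward(d.reshape(N * 27, N_COEF))
        if bn:
            d = self.bn2.backward(d)
        dh1 = self.conv2.backward(d.reshape(N, 27 * N_COEF)).reshape(N, 27, N_COEF)
        if self.config.shortcut == "avgpool":
            dh1 = dh1 + dshort[:, None, :] / 27.0
        else:
            dh1[:, 13, :] += dshort
        d = self.r1.backward(dh1.reshape(N * 27, N_COEF))
        if bn:
            d = self.bn1.backward(d)
        self.conv1.backward(d)

    # -- bookkeeping -------------------------------------------------------
    def layers(self) -> dict:
        return {"conv1": self.conv1, "conv2": self.conv2, "conv3": self.conv3,
                "dense1": self.dense1, "dense2": self.dense2,
                "bn1": self.bn1, "bn2": self.bn2, "bn3": self.bn3, "bn4": self.bn4}

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers().values():
            out.extend(layer.params())
        return out

    def freeze_all_but_dense(self) -> None:
        """Finetuning mechanism: only the two dense head layers stay trainable."""
        for name, layer in self.layers().items():
            trainable = name in ("dense1", "dense2", "bn4")
            for p in layer.params():
                p.trainable = trainable


class VoxelMLP(_NormalizationMixin):
    """Voxel-wise baseline: 45 -> 400 -> 45 -> 200 -> 45, ReLU hidden, linear out."""

    input_kind = "voxel"
    LAYER_SIZES = (400, 45, 200, 45)

    def __init__(self, config: NetworkConfig):
        if config.architecture != "voxel_mlp":
            raise InvalidArgumentError("config.architecture must be 'voxel_mlp'")
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = (N_COEF,) + self.LAYER_SIZES
        self.dense = [Dense(sizes[i], sizes[i + 1], rng) for i in range(4)]
        self.relu = [ReLU() for _ in range(3)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != N_COEF:
            raise InvalidArgumentError(f"expected (N, {N_COEF}) inputs, got {x.shape}")
        h = self._norm_in(x)
        for i in range(3):
            h = self.relu[i].forward(self.dense[i].forward(h))
        return self._denorm_out(self.dense[3].forward(h))

    def backward(self, dy: np.ndarray) -> None:
        d = self.dense[3].backward(self._scale_dy(dy))
        for i in (2, 1, 0):
            d = self.dense[i].backward(self.relu[i].backward(d))

    def layers(self) -> dict:
        return {f"dense{i + 1}": l for i, l in enumerate(self.dense)}

    def params(self) -> list[Param]:
        out = []
        for l in self.dense:
            out.extend(l.params())
        return out

    def freeze_all_but_dense(self) -> None:
        for i, l in enumerate(self.dense):
            for p in l.params():
                p.trainable = i >= 2


def build_patch_cnn(config: NetworkConfig | None = None) -> PatchCNN:
    return PatchCNN(config or NetworkConfig(architecture="patch_cnn"))


def build_voxel_mlp(config: NetworkConfig | None = None) -> VoxelMLP:
    cfg = config or NetworkConfig(architecture="voxel_mlp")
    return VoxelMLP(cfg)


# ---------------------------------------------------------------------------
# patch extraction and triplet sampling

def interior_mask(mask: np.ndarray) -> np.ndarray:
    """Mask voxels whose full 3x3x3 neighborhood lies inside the volume."""
    m = np.zeros_like(np.asarray(mask, dtype=bool))
    m[1:-1, 1:-1, 1:-1] = np.asarray(mask, dtype=bool)[1:-1, 1:-1, 1:-1]
    return m


def extract_patches(field_data: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Gather 3x3x3 neighborhoods around interior voxel coordinates."""
    coords = np.asarray(coords)
    n = coords.shape[0]
    out = np.empty((n, 3, 3, 3, field_data.shape[-1]))
    for di in range(3):
        for dj in range(3):
            for dk in range(3):
                out[:, di, dj, dk] = field_data[coords[:, 0] + di - 1,
                                                coords[:, 1] + dj - 1,
                                                coords[:, 2] + dk - 1]
    return out


def sample_triplets(labeled_volumes: Sequence[tuple[sh.SHField, sh.SHField, np.ndarray]],
                    paired_volumes: Sequence[tuple[sh.SHField, sh.SHField, np.ndarray]],
                    batch_size: int, seed: int, n_batches: int,
                    input_kind: str = "patch",
                    paired_batch_size: int | None = None) -> list[TripletBatch]:
    """Deterministic stream of triplet batches.

    ``labeled_volumes``: (signal field, label field, WM mask) triples —
    labels are the full-direction CSD coefficients of the center voxel.
    ``paired_volumes``: (scan signal field, rescan signal field, WM mask)
    from registered pairs; patches are drawn at identical coordinates in
    both.  Direction-dropout augmentation enters by listing augmented
    signal fields (sharing one label field) among ``labeled_volumes``.
    """
    rng = np.random.default_rng(seed)
    lab_pool = []
    for vol_i, (sig, lab, mask) in enumerate(labeled_volumes):
        coords = np.argwhere(interior_mask(mask))
        if coords.shape[0] == 0:
            raise InvalidArgumentError("a labeled volume has no interior WM voxels")
        lab_pool.append(coords)
    pair_pool = []
    for sig_u, sig_v, mask in paired_volumes:
        coords = np.argwhere(interior_mask(mask))
        if coords.shape[0] == 0:
            raise InvalidArgumentError("a paired volume has no interior WM voxels")
        pair_pool.append(coords)

    def grab(field: sh.SHField, coords: np.ndarray) -> np.ndarray:
        if input_kind == "patch":
            return extract_patches(field.data, coords)
        return field.data[coords[:, 0], coords[:, 1], coords[:, 2]]

    batches = []
    for _ in range(n_batches):
        vi = int(rng.integers(len(labeled_volumes)))
        sig, lab, _ = labeled_volumes[vi]
        coords = lab_pool[vi][rng.integers(lab_pool[vi].shape[0], size=batch_size)]
        labeled_x = grab(sig, coords)
        labels = lab.data[coords[:, 0], coords[:, 1], coords[:, 2]]
        pu = pv = None
        if paired_volumes:
            nb = paired_batch_size or batch_size
            pi = int(rng.integers(len(paired_volumes)))
            su, sv, _ = paired_volumes[pi]
            pcoords = pair_pool[pi][rng.integers(pair_pool[pi].shape[0], size=nb)]
            pu = grab(su, pcoords)
            pv = grab(sv, pcoords)
        batches.append(TripletBatch(labeled_x, labels, pu, pv))
    return batches


# ---------------------------------------------------------------------------
# training

def _mean_val_acc(model, val_x: np.ndarray, val_labels: np.ndarray) -> float:
    pred = model.forward(val_x, train=False)
    u, v = pred[:, 1:], val_labels[:, 1:]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 0) & (nv > 0)
    if not np.any(ok):
        return float("nan")
    return float(np.mean(np.einsum("ij,ij->i", u[ok], v[ok]) / (nu[ok] * nv[ok])))


def train(model, triplet_stream: Iterable[TripletBatch], weights: LossWeights,
          optim_config: OptimConfig | None = None,
          validation: tuple[np.ndarray, np.ndarray] | None = None) -> dict:
    """Train the shared network on a triplet stream.

    Each step forwards labeled, scan and rescan patches through the same
    network (one concatenated batch, so batch-norm statistics pool all
    three groups), backpropagates ``alpha * fit + beta * pairing``, and
    records both terms.  With ``validation=(inputs, labels)`` the model is
    scored by mean ACC after each epoch and the best parameters are
    restored at the end (early stopping on ``patience`` stale epochs).
    """
    if optim_config is None:
        optim_config = OptimConfig()
    batches = list(triplet_stream)
    if not batches:
        raise InvalidArgumentError("empty triplet stream")
    opt = Adam(model.params(), lr=optim_config.lr)
    history: dict = {"loss1": [], "loss2": [], "total": [], "val_acc": []}
    best = (-np.inf, None)
    stale = 0
    for epoch in range(optim_config.epochs):
        for tb in batches:
            nl = tb.labeled_x.shape[0]
            use_pair = weights.beta > 0 and tb.paired_u is not None
            if use_pair:
                x = np.concatenate([tb.labeled_x, tb.paired_u, tb.paired_v], axis=0)
            else:
                x = tb.labeled_x
            pred = model.forward(x, train=True)
            pred_l = pred[:nl]
            l1 = loss_fit(pred_l, tb.labels)
            dy = np.zeros_like(pred)
            dy[:nl] = weights.alpha * 2.0 * (pred_l - tb.labels) / nl
            if use_pair:
                npair = tb.paired_u.shape[0]
                pu, pv = pred[nl:nl + npair], pred[nl + npair:]
                l2 = loss_pair(pu, pv)
                g = weights.beta * 2.0 * (pu - pv) / npair
                dy[nl:nl + npair] = g
                dy[nl + npair:] = -g
            else:
                l2 = 0.0
            total = loss_total(l1, l2, weights)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (loss1={l1}, loss2={l2}); aborting"
                )
            history["loss1"].append(l1)
            history["loss2"].append(l2)
            history["total"].append(total)
            opt.zero_grad()
            model.backward(dy)
            opt.step()
        if validation is not None:
            va = _mean_val_acc(model, *validation)
            history["val_acc"].append(va)
            if va > best[0]:
                best = (va, [p.value.copy() for p in model.params()])
                stale = 0
            else:
                stale += 1
                if stale >= optim_config.patience:
                    break
    if validation is not None and best[1] is not None:
        for p, v in zip(model.params(), best[1]):
            p.value[...] = v
    return history


#: step-decay learning-rate schedules: (lr, epochs) stages, Adam restarted
#: per stage.  The deeper patch network needs the hot first stage; the MLP
#: diverges occasionally above 3e-3, hence its gentler schedule.
CNN_SCHEDULE: tuple[tuple[float, int], ...] = ((1e-2, 40), (3e-3, 25), (1e-3, 15))
MLP_SCHEDULE: tuple[tuple[float, int], ...] = ((3e-3, 40), (1e-3, 30))


def train_staged(model, triplet_stream: Iterable[TripletBatch], weights: LossWeights,
                 schedule: Sequence[tuple[float, int]] = CNN_SCHEDULE,
                 batch_size: int = 128,
                 validation: tuple[np.ndarray, np.ndarray] | None = None) -> dict:
    """Run :func:`train` over a step-decay schedule, merging histories."""
    batches = list(triplet_stream)
    history: dict = {"loss1": [], "loss2": [], "total": [], "val_acc": []}
    for lr, epochs in schedule:
        h = train(model, batches, weights,
                  OptimConfig(lr=lr, batch_size=batch_size, epochs=epochs, patience=epochs),
                  validation=validation)
        for key in history:
            history[key].extend(h[key])
    return history


def predict_volume(model, signal_field: sh.SHField, mask: np.ndarray,
                   chunk: int = 2048) -> sh.SHField:
    """Voxelwise inference over a mask (reflect padding at volume borders)."""
    if signal_field.spec.max_order != 8:
        raise InvalidArgumentError("signal field must be order 8")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != signal_field.shape:
        raise InvalidArgumentError("mask shape does not match field")
    out = np.zeros(signal_field.shape + (N_COEF,))
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        return sh.SHField(out, signal_field.spec, kind="fodf")
    if model.input_kind == "patch":
        padded = np.pad(signal_field.data, ((1, 1), (1, 1), (1, 1), (0, 0)), mode="reflect")
        for lo in range(0, coords.shape[0], chunk):
            sel = coords[lo:lo + chunk]
            patches = extract_patches(padded, sel + 1)
            out[sel[:, 0], sel[:, 1], sel[:, 2]] = model.forward(patches, train=False)
    else:
        for lo in range(0, coords.shape[0], chunk):
            sel = coords[lo:lo + chunk]
            x = signal_field.data[sel[:, 0], sel[:, 1], sel[:, 2]]
            out[sel[:, 0], sel[:, 1], sel[:, 2]] = model.forward(x, train=False)
    return sh.SHField(out, signal_field.spec, kind="fodf")


# ---------------------------------------------------------------------------
# serialization

def save_model(model, path: str | Path, extra_meta: dict | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar describing the run."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for lname, layer in model.layers().items():
        if isinstance(layer, Dense):
            arrays[f"{lname}.W"] = layer.W.value
            arrays[f"{lname}.b"] = layer.b.value
        elif isinstance(layer, BatchNorm):
            arrays[f"{lname}.gamma"] = layer.gamma.value
            arrays[f"{lname}.beta"] = layer.beta.value
            arrays[f"{lname}.running_mean"] = layer.running_mean
            arrays[f"{lname}.running_var"] = layer.running_var
    if model.norm is not None:
        for key, arr in model.norm.items():
            arrays[f"norm.{key}"] = arr
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"config": asdict(model.config), "order": 8, "basis_convention": sh.CONVENTION,
            "n_coeffs": N_COEF}
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = NetworkConfig(**meta["config"])
    model = build_patch_cnn(config) if config.architecture == "patch_cnn" else build_voxel_mlp(config)
    with np.load(path.with_suffix(".npz")) as data:
        for lname, layer in model.layers().items():
            if isinstance(layer, Dense):
                layer.W.value[...] = data[f"{lname}.W"]
                layer.b.value[...] = data[f"{lname}.b"]
            elif isinstance(layer, BatchNorm):
                layer.gamma.value[...] = data[f"{lname}.gamma"]
                layer.beta.value[...] = data[f"{lname}.beta"]
                layer.running_mean[...] = data[f"{lname}.running_mean"]
                layer.running_var[...] = data[f"{lname}.running_var"]
        if "norm.in_mean" in data:
            model.set_normalization(data["norm.in_mean"], data["norm.in_std"],
                                    data["norm.out_mean"], data["norm.out_std"])
    return model
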