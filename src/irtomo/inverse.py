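"""The deep inverse-scattering solver.

Architecture (three heads over one encoder):

* InverseScatterEncoder — blocks of attention-augmented 1D convolutions
  (channel-wise concatenation of a convolution and multi-head self-attention),
  batch-normalisation, ReLU and max-pooling, closed by a fully connected
  layer onto the latent code.  The attention path carries the global spectral
  context (scattering wiggles span the whole spectrum) that purely local
  convolutions miss.
* two absorption decoders — mirrored 1D blocks with nearest-neighbour
  unpooling rebuilding the 737-channel molecular absorption of cell wall and
  interior; softplus output enforces alpha >= 0.
* a parameter head (phase 1) predicting (a_cw, a_int, n0_int, n0_cw) through
  bounded transforms — a_int is predicted as a fraction of a_cw so the
  ordering a_int < a_cw holds structurally — or a ShapeNet (phase 2): 3D
  transpose convolutions decoding the voxelised refractive-index map.

Training runs in two phases: phase 1 fits encoder + absorption decoders +
parameter head (MSE+Pearson spectral loss, range-weighted parameter MSE);
phase 2 swaps the parameter head for a ShapeNet pre-trained as the decoder of
a 3D convolutional autoencoder over rasterised concentric spheres, trained
with a distance-transform Hausdorff surrogate while the encoder fine-tunes at
a reduced learning rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from . import nn
from .specsim import A_CW_RANGE, N0_RANGE, SpectralDataset, rasterize

__all__ = [
    "ModelConfig",
    "small_config",
    "LossWeights",
    "TrainConfig",
    "InverseScatterModel",
    "TrainedModel",
    "pearson_mse_loss",
    "weighted_param_mse",
    "hausdorff_distance",
    "voxel_point_set",
    "shape_loss",
    "ShapeAutoencoder",
    "pretrain_shape_autoencoder",
    "train",
    "evaluate",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters (all tunable; capacity sized to the
    737-channel input)."""

    n_channels: int = 737
    encoder_channels: tuple[int, ...] = (32, 64, 128, 192, 256)
    kernel: int = 7
    pool: int = 2
    attention_blocks: tuple[int, ...] = (2, 3, 4)   # 0-based block indices
    attention_heads: int = 4
    use_attention: bool = True
    latent_dim: int = 128
    decoder_channels: tuple[int, ...] = (128, 96, 64, 32)
    param_head_hidden: int = 64
    voxel_grid: int = 32
    shapenet_channels: tuple[int, ...] = (32, 16, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 8:
            raise ValueError("latent_dim must be >= 8")
        if self.voxel_grid not in (16, 32, 64):
            raise ValueError("voxel_grid must be one of 16, 32, 64")


def small_config(voxel_grid: int = 16, seed: int = 0,
                 use_attention: bool = True) -> ModelConfig:
    """A reduced configuration for CPU-scale runs (tests, small studies)."""
    return ModelConfig(
        encoder_channels=(12, 16, 24, 32, 48),
        attention_blocks=(3, 4),
        latent_dim=64,
        decoder_channels=(32, 24, 16, 8),
        param_head_hidden=48,
        voxel_grid=voxel_grid,
        shapenet_channels=(24, 12, 6) if voxel_grid == 16 else (32, 16, 8),
        seed=seed,
        use_attention=use_attention,
    )


@dataclass(frozen=True)
class LossWeights:
    """lambda_pearson weighs the (1 - r) spectral-shape term; parameter
    weights default to inverse squared sampling-range widths so radii and
    refractive indices carry equal importance; shape_weight scales the
    phase-2 Hausdorff surrogate."""

    lambda_pearson: float = 1.0
    param_weights: tuple[float, float, float, float] = (
        1.0 / (A_CW_RANGE[1] - A_CW_RANGE[0]) ** 2,
        1.0 / (A_CW_RANGE[1] - A_CW_RANGE[0]) ** 2,
        1.0 / (N0_RANGE[1] - N0_RANGE[0]) ** 2,
        1.0 / (N0_RANGE[1] - N0_RANGE[0]) ** 2,
    )
    shape_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_pearson < 0 or self.shape_weight < 0 or \
                any(w < 0 for w in self.param_weights):
            raise ValueError("loss weights must be >= 0")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class _EncoderBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, heads: int,
                 with_attention: bool, rng: np.random.Generator):
        self.with_attention = with_attention
        if with_attention:
            c_att = max(heads, (c_out // 4 // heads) * heads)
            self.att = nn.MultiheadSelfAttention1d(c_in, c_att, heads, rng)
            self.conv = nn.Conv1d(c_in, c_out - c_att, kernel, rng)
        else:
            self.conv = nn.Conv1d(c_in, c_out, kernel, rng)
        self.bn = nn.BatchNorm(c_out)

    def __call__(self, x):
        y = self.conv(x)
        if self.with_attention:
            y = nn.concat([y, self.att(x)], axis=1)
        return nn.maxpool1d(nn.relu(self.bn(y)), 2)


class _AbsorptionDecoder(nn.Module):
    """latent -> (B, 737) non-negative absorption spectrum."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        n_up = len(cfg.decoder_channels)
        self.l0 = int(np.ceil(cfg.n_channels / 2**n_up))
        self.c0 = cfg.decoder_channels[0]
        self.n_out = cfg.n_channels
        self.fc = nn.Linear(cfg.latent_dim, self.c0 * self.l0, rng)
        chans = list(cfg.decoder_channels) + [cfg.decoder_channels[-1]]
        self.blocks = [
            (nn.Conv1d(chans[i], chans[i + 1], cfg.kernel, rng),
             nn.BatchNorm(chans[i + 1]))
            for i in range(n_up)
        ]
        self.head = nn.Conv1d(chans[-1], 1, cfg.kernel, rng)

    def __call__(self, z):
        B = z.shape[0]
        x = nn.reshape(self.fc(z), (B, self.c0, self.l0))
        for conv, bn in self.blocks:
            x = nn.relu(bn(conv(nn.upsample1d(x, 2))))
        x = nn.softplus(self.head(x))
        start = (x.shape[2] - self.n_out) // 2
        x = nn.narrow(x, 2, start, self.n_out)
        return nn.reshape(x, (B, self.n_out))


class _ShapeNet(nn.Module):
    """latent -> (B, G, G, G) non-negative refractive-index field via 3D
    transpose convolutions; output bounded to [0, 2) by a scaled sigmoid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        chans = list(cfg.shapenet_channels)
        n_up = int(np.log2(cfg.voxel_grid)) - 1
        while len(chans) < n_up:
            chans.append(chans[-1])
        self.grid = cfg.voxel_grid
        self.c0 = chans[0]
        self.fc = nn.Linear(cfg.latent_dim, self.c0 * 8, rng)
        layers = []
        for i in range(n_up):
            c_in = chans[i]
            c_out = chans[i + 1] if i + 1 < n_up else chans[-1]
            layers.append(nn.ConvTranspose3d(c_in, c_out, 4, rng))
        self.layers = layers
        self.head = nn.Conv3d(chans[-1], 1, 3, rng, pad=1)

    def __call__(self, z):
        B = z.shape[0]
        x = nn.reshape(self.fc(z), (B, self.c0, 2, 2, 2))
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = nn.relu(x)
        x = nn.mul(nn.sigmoid(self.head(x)), 2.0)
        return nn.reshape(x, (B, self.grid, self.grid, self.grid))


class InverseScatterModel(nn.Module):
    """Encoder + two absorption decoders + parameter head + ShapeNet."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        chans = (1,) + cfg.encoder_channels
        self.enc_blocks = [
            _EncoderBlock(chans[i], chans[i + 1], cfg.kernel,
                          cfg.attention_heads,
                          cfg.use_attention and i in cfg.attention_blocks, rng)
            for i in range(len(cfg.encoder_channels))
        ]
        l_out = cfg.n_channels
        for _ in cfg.encoder_channels:
            l_out //= cfg.pool
        self.flat_dim = cfg.encoder_channels[-1] * l_out
        self.fc_latent = nn.Linear(self.flat_dim, cfg.latent_dim, rng)
        self.dec_int = _AbsorptionDecoder(cfg, rng)
        self.dec_cw = _AbsorptionDecoder(cfg, rng)
        self.param_fc1 = nn.Linear(cfg.latent_dim, cfg.param_head_hidden, rng)
        self.param_fc2 = nn.Linear(cfg.param_head_hidden, 4, rng)
        self.shapenet = _ShapeNet(cfg, rng)
        # input standardisation buffers, set from the training set
        self.x_mean = np.zeros(cfg.n_channels)
        self.x_sd = np.ones(cfg.n_channels)

    def buffers(self):
        return [self.x_mean, self.x_sd]

    def encoder_parameters(self) -> list[nn.Tensor]:
        out = []
        for b in self.enc_blocks:
            out.extend(b.parameters())
        out.extend(self.fc_latent.parameters())
        return out

    # -- forward paths ------------------------------------------------------
    def encoder_forward(self, spectra: np.ndarray) -> nn.Tensor:
        x = np.atleast_2d(np.asarray(spectra, dtype=float))
        if x.shape[1] != self.cfg.n_channels:
            raise ValueError(
                f"expected {self.cfg.n_channels} channels, got {x.shape[1]}")
        if not np.all(np.isfinite(x)):
            raise ValueError("spectrum contains non-finite values")
        x = (x - self.x_mean) / self.x_sd
        t = nn.Tensor(x[:, None, :])
        for block in self.enc_blocks:
            t = block(t)
        t = nn.reshape(t, (x.shape[0], self.flat_dim))
        return self.fc_latent(t)

    def decode_absorptions(self, latent: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        return self.dec_int(latent), self.dec_cw(latent)

    def decode_parameters(self, latent: nn.Tensor) -> nn.Tensor:
        """(B, 4) physical parameters: a_cw in [1.25, 20] um, a_int < a_cw,
        n0 in [1.3, 1.6] — all enforced by the output transforms."""
        u = self.param_fc2(nn.relu(self.param_fc1(latent)))
        lo_a, hi_a = A_CW_RANGE
        lo_n, hi_n = N0_RANGE
        a_cw = nn.add(nn.mul(nn.sigmoid(nn.narrow(u, 1, 0, 1)), hi_a - lo_a), lo_a)
        a_int = nn.mul(a_cw, nn.sigmoid(nn.narrow(u, 1, 1, 1)))
        n0_int = nn.add(nn.mul(nn.sigmoid(nn.narrow(u, 1, 2, 1)), hi_n - lo_n), lo_n)
        n0_cw = nn.add(nn.mul(nn.sigmoid(nn.narrow(u, 1, 3, 1)), hi_n - lo_n), lo_n)
        return nn.concat([a_cw, a_int, n0_int, n0_cw], axis=1)

    def shapenet_forward(self, latent: nn.Tensor) -> nn.Tensor:
        return self.shapenet(latent)

    def predict(self, spectra: np.ndarray, with_voxels: bool = False) -> dict:
        """Inference: returns numpy arrays, model in evaluation mode."""
        self.set_training(False)
        z = self.encoder_forward(spectra)
        a_int, a_cw = self.decode_absorptions(z)
        params = self.decode_parameters(z)
        out = {
            "alpha_int": a_int.data,
            "alpha_cw": a_cw.data,
            "params": params.data,
        }
        if with_voxels:
            out["voxels"] = self.shapenet_forward(z).data
        return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def pearson_mse_loss(pred: nn.Tensor, true: np.ndarray,
                     lambda_pearson: float = 1.0) -> nn.Tensor:
    """MSE + lambda * (1 - r), row-wise over a (B, L) batch, averaged.

    Zero iff pred == true (for lambda > 0).  Rows with constant truth have
    no defined r; the Pearson term is skipped for them with a warning.
    """
    t = np.atleast_2d(np.asarray(true, dtype=float))
    if pred.shape != t.shape or t.shape[1] < 3:
        raise ValueError("pred/true must be equal (B, L>=3) shapes")
    diff = pred - nn.Tensor(t)
    loss = nn.meant(nn.mul(diff, diff))
    if lambda_pearson > 0:
        tc = t - t.mean(axis=1, keepdims=True)
        t_ss = np.sum(tc * tc, axis=1)
        valid = t_ss > 0
        if not np.all(valid):
            warnings.warn("constant target row(s): Pearson term skipped")
        if np.any(valid):
            w_valid = valid.astype(float) / max(1, int(valid.sum()))
            pc = pred - nn.meant(pred, axis=1, keepdims=True)
            cov = nn.sumt(nn.mul(pc, nn.Tensor(tc)), axis=1)
            p_ss = nn.add(nn.sumt(nn.mul(pc, pc), axis=1), 1e-30)
            r = nn.mul(cov, nn.powt(nn.mul(p_ss, np.where(valid, t_ss, 1.0)),
                                    -0.5))
            one_minus_r = nn.add(nn.mul(r, -1.0), 1.0)
            loss = nn.add(loss, nn.mul(nn.sumt(nn.mul(one_minus_r,
                                                      nn.Tensor(w_valid))),
                                       lambda_pearson))
    return loss


def weighted_param_mse(pred: nn.Tensor, true: np.ndarray,
                       weights: tuple[float, ...]) -> nn.Tensor:
    t = np.atleast_2d(np.asarray(true, dtype=float))
    diff = pred - nn.Tensor(t)
    w = np.asarray(weights, dtype=float)
    return nn.meant(nn.sumt(nn.mul(nn.mul(diff, diff), nn.Tensor(w)), axis=1))


def hausdorff_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Exact Hausdorff distance between two non-empty point sets in R^3:
    max of the two directed sup-inf Euclidean distances."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("point sets must be non-empty")
    d_xy = cKDTree(y).query(x)[0].max()
    d_yx = cKDTree(x).query(y)[0].max()
    return float(max(d_xy, d_yx))


def voxel_point_set(grid: np.ndarray, threshold: float,
                    voxel_size: float = 1.0) -> np.ndarray:
    """Coordinates (in physical units) of voxels whose value exceeds the
    threshold."""
    return np.argwhere(np.asarray(grid) > threshold) * voxel_size


def shape_loss(pred: nn.Tensor, truth: np.ndarray, threshold: float = 0.65,
               voxel_size: float = 1.0) -> tuple[nn.Tensor, float]:
    """Differentiable Hausdorff surrogate plus the exact metric.

    The surrogate is a distance-transform-weighted squared error
    mean((p - t)^2 (1 + DT_t^2 + DT_p^2)): misplacements far from the true
    (resp. predicted) surface are penalised quadratically in their distance,
    which tracks the Hausdorff objective while staying differentiable in the
    voxel values (the DT maps are recomputed each call but treated as
    constants).  The exact set Hausdorff distance on the thresholded voxel
    sets is returned alongside as the reported metric; an empty thresholded
    set falls back to the grid-diagonal penalty.
    """
    t = np.asarray(truth, dtype=float)
    if pred.shape != t.shape:
        raise ValueError("pred and truth must share the grid")
    batched = t.ndim == 4
    tb = t if batched else t[None]
    pb = pred.data if batched else pred.data[None]
    g = tb.shape[-1]
    diag = np.sqrt(3.0) * g * voxel_size
    wt = np.empty_like(tb)
    exact = 0.0
    for i in range(tb.shape[0]):
        occ_t = tb[i] > threshold
        occ_p = pb[i] > threshold
        dt_t = distance_transform_edt(~occ_t) if occ_t.any() else np.full(tb[i].shape, g)
        dt_p = distance_transform_edt(~occ_p) if occ_p.any() else np.full(tb[i].shape, g)
        wt[i] = 1.0 + dt_t**2 + dt_p**2
        if occ_t.any() and occ_p.any():
            exact += hausdorff_distance(np.argwhere(occ_p) * voxel_size,
                                        np.argwhere(occ_t) * voxel_size)
        else:
            exact += diag
    exact /= tb.shape[0]
    wt_full = wt if batched else wt[0]
    diff = pred - nn.Tensor(t)
    surrogate = nn.meant(nn.mul(nn.mul(diff, diff), nn.Tensor(wt_full)))
    return surrogate, exact


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    encoder_lr_factor_phase2: float = 0.1
    shape_threshold: float = 0.65
    log_every: int = 100


@dataclass
class TrainedModel:
    model: InverseScatterModel
    config: ModelConfig
    train_config: TrainConfig
    log: list[dict]
    seed: int
    dataset_hash: str | None = None

    def save(self, path: str) -> None:
        arrays = self.model.state()
        meta = json.dumps({
            "config": asdict(self.config),
            "train_config": {k: (asdict(v) if k == "weights" else v)
                             for k, v in self.train_config.__dict__.items()},
            "log": self.log,
            "seed": self.seed,
            "dataset_hash": self.dataset_hash,
        })
        np.savez_compressed(path, meta=np.array(meta),
                            **{f"arr_{i}": a for i, a in enumerate(arrays)})

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
        cfg_d = meta["config"]
        for key in ("encoder_channels", "attention_blocks", "decoder_channels",
                    "shapenet_channels"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = ModelConfig(**cfg_d)
        tc_d = meta["train_config"]
        tc_d["weights"] = LossWeights(
            lambda_pearson=tc_d["weights"]["lambda_pearson"],
            param_weights=tuple(tc_d["weights"]["param_weights"]),
            shape_weight=tc_d["weights"]["shape_weight"])
        model = InverseScatterModel(cfg)
        model.load_state(arrays)
        return cls(model, cfg, TrainConfig(**tc_d), meta["log"], meta["seed"],
                   meta["dataset_hash"])


def _batch_voxels(dataset: SpectralDataset, idx: np.ndarray,
                  grid: int) -> np.ndarray:
    out = np.empty((idx.size, grid, grid, grid))
    for j, i in enumerate(idx):
        out[j] = rasterize(dataset.sample(int(i)), grid).grid
    return out


def train(dataset: SpectralDataset, config: ModelConfig | None = None,
          train_config: TrainConfig | None = None, phase: int = 1,
          model: InverseScatterModel | None = None,
          shapenet_init: list[np.ndarray] | None = None) -> TrainedModel:
    """Two-phase training on a simulated dataset.

    Phase 1: encoder + absorption decoders + parameter head,
    loss = pearson_mse(alpha_int) + pearson_mse(alpha_cw) + weighted param MSE.
    Phase 2: parameter head replaced by the ShapeNet (optionally initialised
    from a pre-trained autoencoder decoder); the encoder fine-tunes at
    ``encoder_lr_factor_phase2 * lr``; loss swaps the parameter term for the
    Hausdorff surrogate.

    Deterministic given (seed, config, dataset); raises on divergence.
    """
    tc = train_config or TrainConfig()
    if model is None:
        cfg = config or ModelConfig()
        model = InverseScatterModel(cfg)
        sd = dataset.spectra.std(axis=0)
        model.x_mean[...] = dataset.spectra.mean(axis=0)
        model.x_sd[...] = np.where(sd > 1e-12, sd, 1.0)
    else:
        cfg = model.cfg
    if len(dataset) < 1:
        raise ValueError("dataset must be non-empty")
    if phase not in (1, 2):
        raise ValueError("phase must be 1 or 2")
    if phase == 2 and shapenet_init is not None:
        params = model.shapenet.parameters()
        if len(shapenet_init) != len(params):
            raise ValueError("shapenet_init does not match the ShapeNet")
        for p, a in zip(params, shapenet_init):
            p.data[...] = a

    rng = np.random.default_rng(tc.seed)
    w = tc.weights
    enc_params = model.encoder_parameters()
    dec_params = model.dec_int.parameters() + model.dec_cw.parameters()
    if phase == 1:
        head_params = (model.param_fc1.parameters()
                       + model.param_fc2.parameters())
        opts = [nn.Adam(enc_params + dec_params + head_params, lr=tc.lr)]
    else:
        opts = [
            nn.Adam(dec_params + model.shapenet.parameters(), lr=tc.lr),
            nn.Adam(enc_params, lr=tc.lr * tc.encoder_lr_factor_phase2),
        ]

    log: list[dict] = []
    n = len(dataset)
    bs = min(tc.batch_size, n)
    targets_p = dataset.params[:, :4]
    step = 0
    for epoch in range(tc.epochs):
        model.set_training(True)
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            z = model.encoder_forward(dataset.spectra[idx])
            a_int, a_cw = model.decode_absorptions(z)
            loss = nn.add(
                pearson_mse_loss(a_int, dataset.alpha_int[idx], w.lambda_pearson),
                pearson_mse_loss(a_cw, dataset.alpha_cw[idx], w.lambda_pearson))
            if phase == 1:
                pp = model.decode_parameters(z)
                loss = nn.add(loss, weighted_param_mse(pp, targets_p[idx],
                                                       w.param_weights))
            else:
                vox = model.shapenet_forward(z)
                truth_vox = _batch_voxels(dataset, idx, cfg.voxel_grid)
                surr, _ = shape_loss(vox, truth_vox, tc.shape_threshold)
                loss = nn.add(loss, nn.mul(surr, w.shape_weight))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss at epoch {epoch}, "
                    f"step {step})")
            for o in opts:
                o.zero_grad()
            loss.backward()
            for o in opts:
                o.step()
            ep_loss += loss.item()
            n_batches += 1
            step += 1
        log.append({"epoch": epoch, "phase": phase,
                    "loss": ep_loss / max(1, n_batches)})
    return TrainedModel(model, cfg, tc, log, tc.seed, dataset.config_hash)


# ---------------------------------------------------------------------------
# shape autoencoder pretraining
# ---------------------------------------------------------------------------


class ShapeAutoencoder(nn.Module):
    """3D conv encoder + ShapeNet decoder over rasterised concentric spheres."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed + 1)
        self.cfg = cfg
        chans = list(reversed(cfg.shapenet_channels))
        n_down = int(np.log2(cfg.voxel_grid)) - 1
        while len(chans) < n_down:
            chans.append(chans[-1])
        self.enc_layers = [
            nn.Conv3d(1 if i == 0 else chans[i - 1], chans[i], 4, rng,
                      stride=2, pad=1)
            for i in range(n_down)
        ]
        self.fc = nn.Linear(chans[n_down - 1] * 8, cfg.latent_dim, rng)
        self.flat = chans[n_down - 1] * 8
        self.decoder = _ShapeNet(cfg, rng)

    def encode(self, vox: np.ndarray) -> nn.Tensor:
        v = np.asarray(vox, dtype=float)
        t = nn.Tensor(v[:, None])
        for i, layer in enumerate(self.enc_layers):
            t = layer(t)
            t = nn.relu(t)
        t = nn.reshape(t, (v.shape[0], self.flat))
        return self.fc(t)

    def __call__(self, vox: np.ndarray) -> nn.Tensor:
        return self.decoder(self.encode(vox))


def pretrain_shape_autoencoder(spheres: np.ndarray, cfg: ModelConfig,
                               epochs: int = 30, batch_size: int = 16,
                               lr: float = 2e-3, occupied_weight: float = 5.0,
                               seed: int = 0) -> tuple[ShapeAutoencoder, list[np.ndarray], list[dict]]:
    """Train a 3D autoencoder to reproduce rasterised concentric spheres and
    extract its decoder weights as the ShapeNet initialisation.

    Reconstruction uses an occupancy-weighted MSE (occupied voxels weighted
    1 + occupied_weight): on the fixed-scale grid small spheres occupy a few
    percent of the voxels and an unweighted loss collapses to the empty map.

    Returns (autoencoder, decoder weight arrays, loss log).
    """
    spheres = np.asarray(spheres, dtype=float)
    ae = ShapeAutoencoder(cfg)
    opt = nn.Adam(ae.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    n = spheres.shape[0]
    bs = min(batch_size, n)
    log = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep = 0.0
        nb = 0
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            out = ae(spheres[idx])
            target = spheres[idx]
            diff = out - nn.Tensor(target)
            w = 1.0 + occupied_weight * (target > 0)
            loss = nn.meant(nn.mul(nn.mul(diff, diff), nn.Tensor(w)))
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep += loss.item()
            nb += 1
        log.append({"epoch": epoch, "loss": ep / max(1, nb)})
    decoder_weights = [p.data.copy() for p in ae.decoder.parameters()]
    return ae, decoder_weights, log


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(model: InverseScatterModel, dataset: SpectralDataset,
             batch_size: int = 256) -> dict:
    """Held-out performance: R^2 per physical parameter, per-record Pearson r
    of the decoded absorption spectra (median and mean)."""
    from .metrics import UndefinedStatistic, pearson_r, r2_score

    n = len(dataset)
    preds_p = np.empty((n, 4))
    r_int = np.full(n, np.nan)
    r_cw = np.full(n, np.nan)
    model.set_training(False)
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        out = model.predict(dataset.spectra[sl])
        preds_p[sl] = out["params"]
        for j in range(sl.stop - sl.start):
            for name, pred_a, true_a in (
                    ("int", out["alpha_int"][j], dataset.alpha_int[sl][j]),
                    ("cw", out["alpha_cw"][j], dataset.alpha_cw[sl][j])):
                try:
                    r = pearson_r(true_a, pred_a)
                except UndefinedStatistic:
                    continue
                (r_int if name == "int" else r_cw)[sl.start + j] = r
    names = ("a_cw", "a_int", "n0_int", "n0_cw")
    report = {f"r2_{nm}": r2_score(dataset.params[:, i], preds_p[:, i])
              for i, nm in enumerate(names)}
    report["r_alpha_int_median"] = float(np.nanmedian(r_int))
    report["r_alpha_cw_median"] = float(np.nanmedian(r_cw))
    report["r_alpha_int_mean"] = float(np.nanmean(r_int))
    report["r_alpha_cw_mean"] = float(np.nanmean(r_cw))
    report["n"] = n
    return report
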