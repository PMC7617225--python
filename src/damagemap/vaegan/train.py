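"""Training loop, checkpointing and latent-table extraction for the VAE-GAN.

Per batch the discriminator takes one update (real vs reconstruction,
standard adversarial loss) and the encoder+generator take one joint update
minimizing

    w_kl * KL + w_pix * pixel MSE + w_feat * feature similarity + w_gan * gan_gen

The reported reconstruction terms are per-element means; the default weights
(w_pix = w_feat = 4096 = 64*64) restore the canonical per-sample
sum-over-dimensions scaling of the reconstruction terms relative to the
per-sample KL — with all-unit weights on mean-scaled terms the KL dominates
and the posterior collapses, erasing the latent structure clustering needs.
All modules use Adam at learning rate 1e-4;
the reference training schedule is 500 epochs (use far fewer for smoke
runs). Optional augmentation expands the patch set with flips and 90-degree
rotations, which preserve texture statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layers import Adam
from .model import VAEGAN, VAEGANSpec, _as_batch, _sigmoid, _softplus, kl_divergence

LOSS_KEYS = ("kl", "pixel_mse", "feature_similarity", "gan_gen", "gan_disc")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 500
    batch_size: int = 32
    loss_weights: tuple[float, float, float, float] = (1.0, 4096.0, 4096.0, 1.0)  # kl, pix, feat, gan
    seed: int = 0
    augmentation: bool = True
    checkpoint_every: int = 0  # epochs; 0 disables intermediate checkpoints
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")


def augment_patches(patches: np.ndarray) -> np.ndarray:
    """Flips and 90-degree rotations: 8 texture-preserving views per patch."""
    p = np.asarray(patches)
    views = [p, p[:, ::-1, :], p[:, :, ::-1]]
    for k in (1, 2, 3):
        views.append(np.rot90(p, k=k, axes=(1, 2)))
    views.append(np.rot90(p[:, ::-1, :], k=1, axes=(1, 2)))
    views.append(np.rot90(p[:, :, ::-1], k=1, axes=(1, 2)))
    return np.concatenate(views, axis=0)


def _train_step(model: VAEGAN, x: np.ndarray, opts: dict[str, Adam],
                weights: tuple[float, float, float, float],
                rng: np.random.Generator) -> dict[str, float]:
    w_kl, w_pix, w_feat, w_gan = weights
    n = x.shape[0]

    # ---- encoder/generator forward ----
    h = model.enc_trunk.forward(x, train=True)
    mu = model.mu_head.forward(h, train=True)
    logvar = model.logvar_head.forward(h, train=True)
    eps = rng.standard_normal(mu.shape).astype(np.float32)
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    xhat = model.gen.forward(z, train=True)

    # ---- discriminator update (real vs detached reconstruction) ----
    opts["disc"].zero_grad()
    logit_real, _ = model.discriminate(x, train=True)
    g_real = (-_sigmoid(-logit_real) / n).astype(np.float32)
    last = (x.shape[0], 1, model.spec.input_size // 2 ** len(model.spec.disc_channels),
            model.spec.input_size // 2 ** len(model.spec.disc_channels))
    model._disc_backward(g_real, None, last)
    loss_disc_real = float(np.mean(_softplus(-logit_real)))
    # fake pass gradient
    logit_fake_d, _ = model.discriminate(xhat, train=True)
    g_fake = (_sigmoid(logit_fake_d) / n).astype(np.float32)
    model._disc_backward(g_fake, None, last)
    loss_disc = loss_disc_real + float(np.mean(_softplus(logit_fake_d)))
    opts["disc"].step()

    # ---- encoder + generator update ----
    opts["enc"].zero_grad()
    opts["gen"].zero_grad()
    model.disc.zero_grad()
    # constant targets from the (just-updated) discriminator on the real batch
    _, feat_real = model.discriminate(x, train=True)
    feat_real = feat_real.copy()
    logit_fake, feat_fake = model.discriminate(xhat, train=True)

    pixel_mse = float(np.mean((x.astype(np.float64) - xhat) ** 2))
    feat_mse = float(np.mean((feat_real.astype(np.float64) - feat_fake) ** 2))
    gan_gen = float(np.mean(_softplus(-logit_fake)))
    kl = kl_divergence(mu, logvar)

    g_logit = (-w_gan * _sigmoid(-logit_fake) / n).astype(np.float32)
    g_feat = (w_feat * 2.0 * (feat_fake - feat_real) / feat_fake.size).astype(np.float32)
    g_xhat = model._disc_backward(g_logit, g_feat, last)
    model.disc.zero_grad()  # discriminator params are frozen in this phase
    g_xhat = g_xhat + w_pix * 2.0 * (xhat - x) / xhat.size
    g_z = model.gen.backward(g_xhat.astype(np.float32))
    # reparameterization: z = mu + sigma * eps
    g_mu = g_z + w_kl * (mu / n)
    g_logvar = g_z * eps * 0.5 * sigma + w_kl * 0.5 * (np.exp(logvar) - 1.0) / n
    g_h = model.mu_head.backward(g_mu.astype(np.float32))
    g_h = g_h + model.logvar_head.backward(g_logvar.astype(np.float32))
    model.enc_trunk.backward(g_h)
    opts["enc"].step()
    opts["gen"].step()

    losses = dict(kl=kl, pixel_mse=pixel_mse, feature_similarity=feat_mse,
                  gan_gen=gan_gen, gan_disc=loss_disc)
    for k, v in losses.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"training diverged: non-finite {k}={v}")
    return losses


def train(model: VAEGAN, patches: np.ndarray, cfg: TrainConfig | None = None
          ) -> pd.DataFrame:
    """Train in place; returns the per-epoch loss history (five terms).

    Deterministic for a fixed seed and backend: data order, reparameterization
    noise and initialization all derive from seeded generators.
    """
    cfg = cfg or TrainConfig()
    x_all = _as_batch(np.asarray(patches, dtype=np.float32))
    if cfg.augmentation:
        x_all = _as_batch(augment_patches(x_all[:, 0]))
    if x_all.shape[0] < 2 * cfg.batch_size:
        raise ValueError(
            f"need at least 2*batch_size={2 * cfg.batch_size} patches "
            f"(after augmentation), got {x_all.shape[0]}"
        )
    rng = np.random.default_rng(cfg.seed)
    opts = {
        "enc": Adam(model.encoder_params(), lr=cfg.learning_rate),
        "gen": Adam(model.generator_params(), lr=cfg.learning_rate),
        "disc": Adam(model.discriminator_params(), lr=cfg.learning_rate),
    }
    history = []
    n = x_all.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = {k: 0.0 for k in LOSS_KEYS}
        nb = 0
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = x_all[order[start : start + cfg.batch_size]]
            losses = _train_step(model, batch, opts, cfg.loss_weights, rng)
            for k in LOSS_KEYS:
                sums[k] += losses[k]
            nb += 1
        history.append({"epoch": epoch, **{k: sums[k] / max(nb, 1) for k in LOSS_KEYS}})
        if cfg.checkpoint_every and cfg.checkpoint_dir and (epoch + 1) % cfg.checkpoint_every == 0:
            save_model(model, Path(cfg.checkpoint_dir) / f"checkpoint_epoch{epoch + 1:04d}.npz")
    return pd.DataFrame(history)


def encode_table(model: VAEGAN, patches: dict[int, np.ndarray]) -> pd.DataFrame:
    """Latent table: one row per cell with mu and log sigma^2 vectors.

    Uses the posterior mean only (no sampling), in eval mode, so repeated
    calls are bit-identical.
    """
    cell_ids = list(patches.keys())
    x = np.stack([patches[c] for c in cell_ids]).astype(np.float32)
    mu, logvar = model.encode(x, train=False)
    d = model.spec.latent_dim
    df = pd.DataFrame({"cell_id": cell_ids})
    for k in range(d):
        df[f"mu_{k}"] = mu[:, k].astype(np.float64)
    for k in range(d):
        df[f"logvar_{k}"] = logvar[:, k].astype(np.float64)
    return df


# ---------------------------------------------------------------------------
# checkpoint I/O: flat npz of parameters + JSON architecture sidecar


def _param_dict(model: VAEGAN) -> dict[str, np.ndarray]:
    out = {}
    for i, p in enumerate(model.all_params()):
        out[f"p{i:04d}"] = p.data
    bn = [l for seq in (model.enc_trunk, model.gen, model.disc) for l in seq.layers
          if hasattr(l, "running_mean")]
    for i, l in enumerate(bn):
        out[f"rm{i:04d}"] = l.running_mean
        out[f"rv{i:04d}"] = l.running_var
    return out


def save_model(model: VAEGAN, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **_param_dict(model))
    from dataclasses import asdict

    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(asdict(model.spec), fh, indent=2)
        fh.write("\n")


def load_model(path: str | Path) -> VAEGAN:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        spec = VAEGANSpec(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in json.load(fh).items()})
    model = VAEGAN(spec, seed=0)
    data = np.load(path)
    for i, p in enumerate(model.all_params()):
        p.data = data[f"p{i:04d}"]
    bn = [l for seq in (model.enc_trunk, model.gen, model.disc) for l in seq.layers
          if hasattr(l, "running_mean")]
    for i, l in enumerate(bn):
        l.running_mean = data[f"rm{i:04d}"]
        l.running_var = data[f"rv{i:04d}"]
    return model
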