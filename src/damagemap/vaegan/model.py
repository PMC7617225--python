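"""VAE-GAN for 64x64 nucleus patches: encoder, generator, discriminator.

The encoder maps a patch to a 16-dimensional diagonal Gaussian (mu,
log sigma^2); the generator decodes a latent vector back to a [0, 1] image;
the discriminator scores real vs reconstructed patches and, crucially,
supplies the *learned similarity metric*: reconstruction quality is measured
as the mean squared distance between the feature maps its fourth
convolutional layer produces for the input and for the reconstruction, in
addition to the plain pixel-wise MSE. The variational KL term and the
non-saturating adversarial terms complete the objective.

Architecture (kernel 4, stride 2, padding 1 throughout):

* encoder: 3 conv layers (32/64/128 channels) with batch normalization,
  two dense layers (256/128), then linear (mu, log sigma^2) heads.
* generator: mirrored — dense 16->256->8192, three transposed conv layers
  (64/32/1 channels), sigmoid output.
* discriminator: 5 conv layers (32/64/128/256/1); feature tap after the
  fourth; spatial mean of the last map is the real/fake logit. Batch
  normalization on the middle layers (none on the first, per common GAN
  practice, and none on the logit layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Flatten,
    LeakyReLU,
    Param,
    ReLU,
    Reshape,
    Sequential,
    Sigmoid,
)


@dataclass
class VAEGANSpec:
    latent_dim: int = 16
    input_size: int = 64
    enc_channels: tuple[int, ...] = (32, 64, 128)
    dense_dims: tuple[int, ...] = (256, 128)
    disc_channels: tuple[int, ...] = (32, 64, 128, 256, 1)
    similarity_tap: int = 4  # 1-based conv-layer index feeding the similarity metric

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 1 <= self.similarity_tap <= len(self.disc_channels):
            raise ValueError("similarity_tap out of range")
        if self.input_size % (2 ** len(self.enc_channels)) != 0:
            raise ValueError("input_size must be divisible by 2^n_conv_layers")


def _as_batch(patches: np.ndarray) -> np.ndarray:
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None, :, :]
    return x


class VAEGAN:
    """Model handle holding the three sub-networks and their specs."""

    def __init__(self, spec: VAEGANSpec | None = None, seed: int = 0):
        self.spec = spec or VAEGANSpec()
        rng = np.random.default_rng(seed)
        s = self.spec
        side = s.input_size // 2 ** len(s.enc_channels)  # spatial size after encoder convs
        self._bottleneck = (s.enc_channels[-1], side, side)
        flat = s.enc_channels[-1] * side * side

        enc_layers: list = []
        c_prev = 1
        for c in s.enc_channels:
            enc_layers += [Conv2d(c_prev, c, rng), BatchNorm2d(c), ReLU()]
            c_prev = c
        enc_layers.append(Flatten())
        d_prev = flat
        for d in s.dense_dims:
            enc_layers += [Dense(d_prev, d, rng), ReLU()]
            d_prev = d
        self.enc_trunk = Sequential(enc_layers)
        self.mu_head = Dense(d_prev, s.latent_dim, rng)
        self.logvar_head = Dense(d_prev, s.latent_dim, rng)

        gen_layers: list = [Dense(s.latent_dim, s.dense_dims[0], rng), ReLU(),
                            Dense(s.dense_dims[0], flat, rng), ReLU(),
                            Reshape(self._bottleneck)]
        rev = list(s.enc_channels[::-1][1:]) + [1]
        c_prev = s.enc_channels[-1]
        for i, c in enumerate(rev):
            gen_layers.append(ConvTranspose2d(c_prev, c, rng))
            if i < len(rev) - 1:
                gen_layers += [BatchNorm2d(c), ReLU()]
            c_prev = c
        gen_layers.append(Sigmoid())
        self.gen = Sequential(gen_layers)

        disc_layers: list = []
        self._tap_layer_idx = None
        c_prev = 1
        for i, c in enumerate(s.disc_channels):
            disc_layers.append(Conv2d(c_prev, c, rng))
            last = i == len(s.disc_channels) - 1
            if not last:
                if i > 0:
                    disc_layers.append(BatchNorm2d(c))
                disc_layers.append(LeakyReLU(0.2))
            if i + 1 == s.similarity_tap:
                self._tap_layer_idx = len(disc_layers) - 1  # after activation of tap conv
            c_prev = c
        self.disc = Sequential(disc_layers)

    # -- parameter plumbing -------------------------------------------------

    def encoder_params(self) -> list[Param]:
        return self.enc_trunk.params() + self.mu_head.params() + self.logvar_head.params()

    def generator_params(self) -> list[Param]:
        return self.gen.params()

    def discriminator_params(self) -> list[Param]:
        return self.disc.params()

    def all_params(self) -> list[Param]:
        return self.encoder_params() + self.generator_params() + self.discriminator_params()

    def param_checksum(self) -> float:
        return float(sum(np.sum(np.abs(p.data.astype(np.float64))) for p in self.all_params()))

    # -- forward passes -----------------------------------------------------

    def encode(self, patches: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Map patches to (mu, log sigma^2); deterministic (no sampling)."""
        x = _as_batch(patches)
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"expected {self.spec.input_size}x{self.spec.input_size} patches, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        h = self.enc_trunk.forward(x, train=train)
        return self.mu_head.forward(h, train=train), self.logvar_head.forward(h, train=train)

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.gen.forward(np.asarray(z, dtype=np.float32), train=train)

    def discriminate(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Returns (logit per sample, tap-layer feature maps)."""
        outs = self.disc.forward_taps(_as_batch(x), train=train)
        feat = outs[self._tap_layer_idx]
        logit = outs[-1].mean(axis=(1, 2, 3))
        return logit, feat

    def _disc_backward(self, g_logit: np.ndarray, g_feat: np.ndarray | None, last_shape: tuple):
        n, c, h, w = last_shape
        g_last = np.broadcast_to(
            g_logit[:, None, None, None].astype(np.float32), last_shape
        ) / (c * h * w)
        taps = {self._tap_layer_idx: g_feat} if g_feat is not None else None
        return self.disc.backward(np.ascontiguousarray(g_last), tap_grads=taps)


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Mean over batch of KL(N(mu, diag sigma^2) || N(0, I)), closed form."""
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    per_sample = 0.5 * np.sum(mu**2 + np.exp(logvar) - logvar - 1.0, axis=-1)
    return float(np.mean(per_sample))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def loss_terms(model: VAEGAN, batch: np.ndarray, seed: int = 0) -> dict[str, float]:
    """All five loss terms on a batch, without touching gradients.

    kl: closed-form divergence of the encoder posterior from N(0, I);
    pixel_mse: input vs reconstruction; feature_similarity: MSE between
    discriminator tap features of input and reconstruction; gan_gen /
    gan_disc: non-saturating adversarial losses.
    """
    x = _as_batch(batch)
    if x.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    rng = np.random.default_rng(seed)
    mu, logvar = model.encode(x, train=True)
    z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape).astype(np.float32)
    xhat = model.decode(z, train=True)
    logit_real, feat_real = model.discriminate(x, train=True)
    logit_fake, feat_fake = model.discriminate(xhat, train=True)
    out = dict(
        kl=kl_divergence(mu, logvar),
        pixel_mse=float(np.mean((x.astype(np.float64) - xhat) ** 2)),
        feature_similarity=float(np.mean((feat_real.astype(np.float64) - feat_fake) ** 2)),
        gan_gen=float(np.mean(_softplus(-logit_fake))),
        gan_disc=float(np.mean(_softplus(-logit_real)) + np.mean(_softplus(logit_fake))),
    )
    for k, v in out.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss term {k}={v}")
    return out
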