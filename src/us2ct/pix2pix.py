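"""Conditional adversarial image translation (pix2pix).

A UNet generator with skip connections maps a [−1, 1] single-channel input
image to a [−1, 1] CT-like image; a PatchGAN discriminator classifies
(input, candidate) pairs patch-wise.  The generator objective is the
non-saturating adversarial term plus λ·L1 reconstruction (λ = 100); both
networks train with Adam (lr 2·10⁻⁴, β₁ 0.5, β₂ 0.999) at batch size 1.

Two scale presets exist: ``full_256`` is the canonical topology
(C64-C128-C256-C512×5 encoder, mirrored decoder with dropout 0.5 in the
first three blocks, 70×70-receptive-field discriminator); ``desk_64`` is a
6-level UNet on 64×64 images used for CPU-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from us2ct.nn import Adam, Conv, ConvT, Dropout, InstanceNorm, LeakyReLU, Param, ReLU, Tanh, bce_with_logits

PRESETS = {
    "full_256": dict(
        image_size=256,
        enc_channels=(64, 128, 256, 512, 512, 512, 512, 512),
        disc_channels=(64, 128, 256, 512),
        disc_strides=(2, 2, 2, 1),
    ),
    "desk_64": dict(
        image_size=64,
        enc_channels=(16, 32, 64, 128, 128, 128),
        disc_channels=(16, 32, 64),
        disc_strides=(2, 2, 1),
    ),
}


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    lambda_l1: float = 100.0
    steps: int = 50_000
    batch_size: int = 1
    seed: int = 0
    scale_preset: str = "full_256"
    use_jitter: bool = True
    adversarial: bool = True       # False → pure L1 regression training

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.beta1, self.beta2, self.lambda_l1 + 1e-12) <= 0:
            raise ValueError("optimizer settings must be positive")
        if self.scale_preset not in PRESETS:
            raise ValueError(f"unknown preset {self.scale_preset!r}")


class UNet:
    """Encoder-decoder with skip connections down to a 1×1 bottleneck."""

    def __init__(self, enc_channels, in_ch=1, out_ch=1, rng=None,
                 n_dropout=3, drop_p=0.5):
        rng = rng or np.random.default_rng()
        self.enc_channels = tuple(enc_channels)
        self.in_ch, self.out_ch = in_ch, out_ch
        n = len(self.enc_channels)
        self.n_levels = n

        self.enc_acts, self.enc_convs, self.enc_norms = [], [], []
        prev = in_ch
        for i, ch in enumerate(self.enc_channels):
            self.enc_acts.append(LeakyReLU(0.2) if i > 0 else None)
            self.enc_convs.append(Conv(prev, ch, rng=rng))
            # no norm on the first level (canonical) nor at the 1×1 bottleneck
            self.enc_norms.append(InstanceNorm(ch) if 0 < i < n - 1 else None)
            prev = ch

        self.dec_acts, self.dec_convs, self.dec_norms, self.dec_drops = [], [], [], []
        for j in range(n - 1):
            cin = self.enc_channels[n - 1] if j == 0 else 2 * self.enc_channels[n - 1 - j]
            cout = self.enc_channels[n - 2 - j]
            self.dec_acts.append(ReLU())
            self.dec_convs.append(ConvT(cin, cout, rng=rng))
            self.dec_norms.append(InstanceNorm(cout))
            self.dec_drops.append(Dropout(drop_p) if j < n_dropout else None)

        self.final_act = ReLU()
        self.final_conv = ConvT(2 * self.enc_channels[0], out_ch, rng=rng)
        self.tanh = Tanh()

    @property
    def params(self):
        out = []
        for layer in (
            *self.enc_convs, *filter(None, self.enc_norms),
            *self.dec_convs, *self.dec_norms, self.final_conv,
        ):
            out.extend(layer.params)
        return out

    def forward(self, x, train=True, rng=None):
        size = x.shape[2]
        if size != (1 << self.n_levels) or x.shape[3] != size:
            raise ValueError(
                f"input size {x.shape[2:]} must be square 2^{self.n_levels}"
            )
        n = self.n_levels
        e = []
        h = x
        for i in range(n):
            if i > 0:
                h = self.enc_acts[i].forward(h)
            h = self.enc_convs[i].forward(h)
            if self.enc_norms[i] is not None:
                h = self.enc_norms[i].forward(h)
            e.append(h)
        self._e = e
        h = e[-1]
        for j in range(n - 1):
            h = self.dec_acts[j].forward(h)
            h = self.dec_convs[j].forward(h)
            h = self.dec_norms[j].forward(h)
            if self.dec_drops[j] is not None:
                h = self.dec_drops[j].forward(h, train=train, rng=rng)
            h = np.concatenate([e[n - 2 - j], h], axis=1)
        h = self.final_act.forward(h)
        h = self.final_conv.forward(h)
        return self.tanh.forward(h)

    def backward(self, dout):
        n = self.n_levels
        d = self.tanh.backward(dout)
        d = self.final_conv.backward(d)
        d = self.final_act.backward(d)
        dskips = [None] * n
        for j in reversed(range(n - 1)):
            skip_ch = self.enc_channels[n - 2 - j]
            dskip, dh = d[:, :skip_ch], d[:, skip_ch:]
            dskips[n - 2 - j] = dskip
            if self.dec_drops[j] is not None:
                dh = self.dec_drops[j].backward(dh)
            dh = self.dec_norms[j].backward(dh)
            dh = self.dec_convs[j].backward(dh)
            dh = self.dec_acts[j].backward(dh)
            d = dh
        g = d  # gradient at the bottleneck e[n-1]
        for i in reversed(range(n)):
            if self.enc_norms[i] is not None:
                g = self.enc_norms[i].backward(g)
            g = self.enc_convs[i].backward(g)
            if i > 0:
                g = self.enc_acts[i].backward(g)
                g = g + dskips[i - 1]
        return g


class PatchDiscriminator:
    """Markovian patch classifier over concatenated (input, candidate)."""

    def __init__(self, channels, strides, in_ch=2, rng=None):
        rng = rng or np.random.default_rng()
        self.layers = []
        prev = in_ch
        for i, (ch, s) in enumerate(zip(channels, strides)):
            self.layers.append(Conv(prev, ch, stride=s, rng=rng))
            if i > 0:
                self.layers.append(InstanceNorm(ch))
            self.layers.append(LeakyReLU(0.2))
            prev = ch
        self.layers.append(Conv(prev, 1, stride=1, rng=rng))

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x, train=True):
        h = x
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h

    def backward(self, dout):
        d = dout
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


def build_generator(scale_preset: str = "full_256", rng=None) -> UNet:
    p = PRESETS[scale_preset]
    return UNet(p["enc_channels"], rng=rng)


def build_discriminator(scale_preset: str = "full_256", rng=None) -> PatchDiscriminator:
    p = PRESETS[scale_preset]
    return PatchDiscriminator(p["disc_channels"], p["disc_strides"], rng=rng)


def generator_loss(disc_logits_on_fake, fake, target, lambda_l1):
    """Non-saturating adversarial term + λ·mean-absolute-error.

    Returns (total, adversarial_component, l1_component).
    """
    adv, _ = bce_with_logits(disc_logits_on_fake, 1.0)
    l1 = float(np.mean(np.abs(fake - target)))
    return adv + lambda_l1 * l1, adv, l1


@dataclass
class ModelState:
    generator: UNet
    discriminator: PatchDiscriminator
    config: TrainConfig
    step: int = 0
    loss_history: dict = field(
        default_factory=lambda: {"d": [], "g_adv": [], "g_l1": []}
    )


def _as_batch(image: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(image, dtype=np.float32)[None, None]


def init_model(config: TrainConfig) -> ModelState:
    rng = np.random.default_rng(config.seed)
    return ModelState(
        generator=build_generator(config.scale_preset, rng=rng),
        discriminator=build_discriminator(config.scale_preset, rng=rng),
        config=config,
    )


def train(pairs, config: TrainConfig, rng: np.random.Generator) -> ModelState:
    """Alternating discriminator/generator updates over random pair draws.

    ``pairs`` is the training split (list of TrainingPair); jitter
    augmentation is applied per draw when ``config.use_jitter``.  Raises on
    an empty dataset or a non-finite loss.
    """
    from us2ct.pairs import jitter as jitter_fn

    if len(pairs) == 0:
        raise ValueError("cannot train on an empty dataset")
    state = init_model(config)
    gen, disc = state.generator, state.discriminator
    opt_g = Adam(gen.params, config.learning_rate, config.beta1, config.beta2)
    opt_d = Adam(disc.params, config.learning_rate, config.beta1, config.beta2)

    for _ in range(config.steps):
        pair = pairs[int(rng.integers(len(pairs)))]
        if config.use_jitter:
            pair = jitter_fn(pair, rng)
        x = _as_batch(pair.input_image)
        y = _as_batch(pair.target_image)

        fake = gen.forward(x, train=True, rng=rng)

        if config.adversarial:
            # one discriminator pass on the fake pair serves both players:
            # the generator's adversarial gradient and the discriminator's
            # fake-label loss share the same activations
            logits_f = disc.forward(np.concatenate([x, fake], axis=1), train=True)
            adv, dl_adv = bce_with_logits(logits_f, 1.0)
            opt_g.zero_grad()
            opt_d.zero_grad()
            dfake = disc.backward(dl_adv)[:, 1:]
            opt_d.zero_grad()  # discard discriminator grads from the G pass
        else:
            adv = 0.0
            opt_g.zero_grad()
            dfake = np.zeros_like(fake)

        l1 = float(np.mean(np.abs(fake - y)))
        dfake = dfake + config.lambda_l1 * np.sign(fake - y) / fake.size
        gen.backward(dfake.astype(np.float32))
        opt_g.step()

        if config.adversarial:
            # discriminator update: 0.5·[BCE(D(x,y),1) + BCE(D(x,G(x)),0)];
            # the fake-pass caches are still valid (D untouched since)
            loss_f, dl_f = bce_with_logits(logits_f, 0.0)
            disc.backward(0.5 * dl_f)
            logits_r = disc.forward(np.concatenate([x, y], axis=1), train=True)
            loss_r, dl_r = bce_with_logits(logits_r, 1.0)
            disc.backward(0.5 * dl_r)
            opt_d.step()
            d_loss = 0.5 * (loss_r + loss_f)
        else:
            d_loss = 0.0

        if not (np.isfinite(d_loss) and np.isfinite(adv) and np.isfinite(l1)):
            raise RuntimeError(
                f"non-finite loss at step {state.step}: d={d_loss} adv={adv} l1={l1}"
            )
        state.loss_history["d"].append(d_loss)
        state.loss_history["g_adv"].append(adv)
        state.loss_history["g_l1"].append(l1)
        state.step += 1
    return state


def translate(model: ModelState | UNet, input_image: np.ndarray) -> np.ndarray:
    """Deterministic inference: [−1,1] input image → [−1,1] output image
    (dropout off)."""
    gen = model.generator if isinstance(model, ModelState) else model
    out = gen.forward(_as_batch(input_image), train=False)
    return out[0, 0].astype(np.float64)


def save_model(state: ModelState, path) -> None:
    """Serialize parameters (npz) with a JSON sidecar of the TrainConfig."""
    path = Path(path)
    arrays = {}
    for prefix, net in (("g", state.generator), ("d", state.discriminator)):
        for i, p in enumerate(net.params):
            arrays[f"{prefix}{i}"] = p.value
    np.savez_compressed(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"config": asdict(state.config), "step": state.step}))


def load_model(path) -> ModelState:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = TrainConfig(**meta["config"])
    state = init_model(config)
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as data:
        for prefix, net in (("g", state.generator), ("d", state.discriminator)):
            for i, p in enumerate(net.params):
                p.value[...] = data[f"{prefix}{i}"]
    state.step = meta["step"]
    return state
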