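"""U-shaped encoder-decoder density regressor with scSE attention.

Five encoder stages each halve the spatial size; five decoder blocks
upsample (non-trainable 2x interpolation), concatenate the symmetric
encoder feature map, convolve, and apply concurrent spatial/channel
squeeze-and-excitation combined by an elementwise maximum.  The output
head is a 1x1 convolution with identity activation producing a single
channel at the input resolution.

Two presets are provided: ``standard`` (decoder widths 256/128/64/32/16)
and ``tiny`` (< 100k parameters, for desk-scale training and tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, avg_pool2, concat, conv2d, maximum, upsample2x

__all__ = ["NetworkConfig", "DensityNet", "build_model", "scse_block", "INNER_BLOCKS"]

_PRESET_ENCODER = {
    "standard": [24, 32, 48, 96, 136],
    "tiny": [8, 12, 16, 24, 32],
}
_PRESET_DECODER = {
    "standard": [256, 128, 64, 32, 16],
    "tiny": [32, 24, 16, 12, 8],
}

#: The six designated inner blocks tapped for deep-feature analysis:
#: the bottleneck plus its adjacent encoder and decoder blocks.
INNER_BLOCKS = ("enc4", "enc5", "bottleneck", "dec1", "dec2", "dec3")


@dataclass
class NetworkConfig:
    encoder_preset: str = "tiny"
    decoder_channels: list[int] | None = None
    scse: bool = True
    upsample_mode: str = "bilinear"
    learning_rate: float = 1e-2
    scheduler_factor: float = 0.2
    scheduler_patience: int = 10
    seed: int = 0

    def resolved_decoder(self) -> list[int]:
        ch = self.decoder_channels or _PRESET_DECODER[self.encoder_preset]
        if len(ch) != 5:
            raise ValueError("decoder must have exactly five blocks")
        if any(a <= b for a, b in zip(ch, ch[1:])):
            raise ValueError("decoder channel widths must be strictly decreasing")
        return list(ch)


class _Param:
    """Named trainable parameter."""

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.tensor = Tensor(data, requires_grad=True)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class _SCSE:
    """Concurrent spatial and channel squeeze-and-excitation.

    Channel branch: global average pool -> linear halving C -> ReLU ->
    linear back to C -> sigmoid.  Spatial branch: 1x1 conv to a single
    channel -> sigmoid.  Combined per entry by maximum.  For C == 1 the
    channel bottleneck is undefined; the channel branch degrades to
    identity weights.
    """

    def __init__(self, rng: np.random.Generator, c: int, prefix: str):
        self.c = c
        self.params: list[_Param] = []
        if c >= 2:
            mid = max(c // 2, 1)
            self.w1 = _Param(f"{prefix}.w1", _he(rng, (c, mid), c))
            self.b1 = _Param(f"{prefix}.b1", np.zeros(mid))
            self.w2 = _Param(f"{prefix}.w2", _he(rng, (mid, c), mid))
            self.b2 = _Param(f"{prefix}.b2", np.zeros(c))
            self.params += [self.w1, self.b1, self.w2, self.b2]
        self.ws = _Param(f"{prefix}.ws", _he(rng, (1, c, 1, 1), c))
        self.bs = _Param(f"{prefix}.bs", np.zeros(1))
        self.params += [self.ws, self.bs]

    def __call__(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        if self.c >= 2:
            z = x.mean(axis=(2, 3))  # (B, C)
            z = (z @ self.w1.tensor + self.b1.tensor).relu()
            z = (z @ self.w2.tensor + self.b2.tensor).sigmoid()
            ch_w = z.reshape(b, c, 1, 1)
        else:
            ch_w = Tensor(np.ones((b, c, 1, 1)))
        sp = conv2d(x, self.ws.tensor, self.bs.tensor).sigmoid()  # (B, 1, H, W)
        return x * maximum(ch_w, sp)


def scse_block(
    x: np.ndarray, rng: np.random.Generator | None = None, module: _SCSE | None = None
) -> np.ndarray:
    """Functional scSE on a (C, H, W) array with fresh (or given) weights."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a C x H x W feature map")
    if module is None:
        module = _SCSE(rng or np.random.default_rng(0), arr.shape[0], "scse")
    out = module(Tensor(arr[None]))
    return out.data[0]


class DensityNet:
    """The full encoder-decoder model."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        enc_ch = _PRESET_ENCODER[config.encoder_preset]
        dec_ch = config.resolved_decoder()
        self.encoder_channels = enc_ch
        self.decoder_channels = dec_ch
        rng = np.random.default_rng(config.seed)
        self.params: list[_Param] = []

        self.enc_w, self.enc_b = [], []
        cin = 3
        for i, cout in enumerate(enc_ch):
            w = _Param(f"enc{i + 1}.w", _he(rng, (cout, cin, 3, 3), cin * 9))
            b = _Param(f"enc{i + 1}.b", np.zeros(cout))
            self.enc_w.append(w)
            self.enc_b.append(b)
            self.params += [w, b]
            cin = cout

        self.dec_w, self.dec_b, self.dec_scse = [], [], []
        prev = enc_ch[-1]  # bottleneck channels
        for j, cout in enumerate(dec_ch):
            skip = enc_ch[4 - j]
            cin_j = prev + skip
            w = _Param(f"dec{j + 1}.w", _he(rng, (cout, cin_j, 3, 3), cin_j * 9))
            b = _Param(f"dec{j + 1}.b", np.zeros(cout))
            self.dec_w.append(w)
            self.dec_b.append(b)
            self.params += [w, b]
            if config.scse:
                s = _SCSE(rng, cout, f"dec{j + 1}.scse")
                self.dec_scse.append(s)
                self.params += s.params
            else:
                self.dec_scse.append(None)
            prev = cout

        self.head_w = _Param("head.w", _he(rng, (1, dec_ch[-1], 1, 1), dec_ch[-1]))
        self.head_b = _Param("head.b", np.zeros(1))
        self.params += [self.head_w, self.head_b]

    # -- parameter plumbing ---------------------------------------------
    def n_parameters(self) -> int:
        return sum(p.tensor.data.size for p in self.params)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.tensor.data.copy() for p in self.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params:
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name} in state dict")
            p.tensor.data = np.array(state[p.name], dtype=float)

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor, return_features: bool = False):
        """Map (B, 3, H, W) in [0, 1] to a (B, 1, H, W) density map.

        ``return_features`` additionally returns the post-ReLU activations
        of the six designated inner blocks.
        """
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        if t.data.ndim != 4 or t.data.shape[1] != 3:
            raise ValueError("input must be (B, 3, H, W)")
        h, w = t.data.shape[2], t.data.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"spatial size ({h}, {w}) must be divisible by 32 (five halvings)"
            )
        feats: dict[str, Tensor] = {}
        skips = []
        cur = t
        for i in range(5):
            cur = conv2d(cur, self.enc_w[i].tensor, self.enc_b[i].tensor).relu()
            skips.append(cur)
            if f"enc{i + 1}" in INNER_BLOCKS:
                feats[f"enc{i + 1}"] = cur
            cur = avg_pool2(cur)
        feats["bottleneck"] = cur
        for j in range(5):
            cur = upsample2x(cur, mode=self.config.upsample_mode)
            cur = concat([cur, skips[4 - j]], axis=1)
            cur = conv2d(cur, self.dec_w[j].tensor, self.dec_b[j].tensor).relu()
            if self.dec_scse[j] is not None:
                cur = self.dec_scse[j](cur)
            if f"dec{j + 1}" in INNER_BLOCKS:
                feats[f"dec{j + 1}"] = cur
        out = conv2d(cur, self.head_w.tensor, self.head_b.tensor)  # identity head
        if return_features:
            return out, feats
        return out

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Inference on (B, H, W, 3) uint8 tiles -> (B, H, W) density maps."""
        x = _to_input(images)
        return self.forward(x).data[:, 0]

    # -- feature geometry -------------------------------------------------
    def feature_dim(self, block_id: str, input_size: int) -> int:
        """Flattened length D of a block's activation for a square input."""
        c, scale = self._block_geometry(block_id)
        side = input_size // scale
        return side * side * c

    def _block_geometry(self, block_id: str) -> tuple[int, int]:
        if block_id not in INNER_BLOCKS:
            raise KeyError(
                f"unknown block id {block_id!r}; valid ids: {list(INNER_BLOCKS)}"
            )
        if block_id.startswith("enc"):
            i = int(block_id[3:])
            return self.encoder_channels[i - 1], 2 ** (i - 1)
        if block_id == "bottleneck":
            return self.encoder_channels[-1], 32
        j = int(block_id[3:])
        return self.decoder_channels[j - 1], 2 ** (5 - j)


def _to_input(images: np.ndarray) -> np.ndarray:
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[-1] == 3:
        arr = np.moveaxis(arr, -1, 1)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr


def build_model(config: NetworkConfig | None = None, **kwargs) -> DensityNet:
    """Instantiate the network from a configuration."""
    if config is None:
        config = NetworkConfig(**kwargs)
    if config.encoder_preset not in _PRESET_ENCODER:
        raise ValueError(
            f"unknown encoder preset {config.encoder_preset!r}; "
            f"choose from {sorted(_PRESET_ENCODER)}"
        )
    return DensityNet(config)


def extract_features(
    model: DensityNet,
    tiles: np.ndarray | list[np.ndarray],
    block_id: str,
    state: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Flattened post-ReLU activations of one inner block, one row per tile.

    ``state`` optionally loads an epoch checkpoint before extraction
    (the model's current weights are restored afterwards).
    """
    model._block_geometry(block_id)  # validate id early
    saved = None
    if state is not None:
        saved = model.state_dict()
        model.load_state_dict(state)
    try:
        rows = []
        for tile in tiles:
            x = _to_input(np.asarray(tile))
            _, feats = model.forward(x, return_features=True)
            rows.append(feats[block_id].data[0].ravel())
        return np.vstack(rows)
    finally:
        if saved is not None:
            model.load_state_dict(saved)
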