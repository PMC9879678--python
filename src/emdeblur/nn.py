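"""Layers, parameter containers and SGD for the deblurring networks.

Thin object layer over :mod:`emdeblur.autograd`.  Modules register
parameters by attribute assignment; ``parameters()`` walks nested modules
and lists.  Initialization is He-style with a caller-supplied RNG so every
network build is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, upsample2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping, stable under attribute order."""
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            if isinstance(obj, Parameter):
                out[prefix] = obj.data
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = self.state_dict()
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"checkpoint incompatible with model: {sorted(missing)[:5]}")

        def walk(obj, prefix):
            if isinstance(obj, Parameter):
                if obj.data.shape != state[prefix].shape:
                    raise ValueError(f"shape mismatch at {prefix}")
                obj.data = np.array(state[prefix], dtype=obj.data.dtype)
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")

        walk(self, "")

    def zero_all_weights(self):
        """Set every parameter to zero (identity-map probes in tests)."""
        for p in self.parameters():
            p.data = np.zeros_like(p.data)

    def astype(self, dtype) -> "Module":
        """Cast all parameters in place (float32 halves training cost)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 init_scale: float = 1.0):
        fan_in = in_ch * kernel * kernel
        std = init_scale * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization with optional affine."""

    def __init__(self, channels: int, affine: bool = True, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1))) if affine else None
        self.beta = Parameter(np.zeros((1, channels, 1, 1))) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        y = centered * (var + self.eps) ** -0.5
        if self.gamma is not None:
            y = y * self.gamma + self.beta
        return y


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Upsample(Module):
    """x2^k spatial upsampling; ``transposed`` = zero-stuffing + 3x3 conv."""

    def __init__(self, in_ch: int, out_ch: int, factor: int, mode: str,
                 rng: np.random.Generator, init_scale: float = 1.0):
        if mode not in ("bilinear", "nearest", "transposed"):
            raise ValueError(f"unknown upsample mode {mode!r}")
        self.mode = mode
        self.factor = factor
        self.conv = Conv2d(in_ch, out_ch, 3, rng, init_scale=init_scale)

    def forward(self, x: Tensor) -> Tensor:
        stuff = "zeros" if self.mode == "transposed" else self.mode
        return self.conv(upsample2d(x, self.factor, stuff))


class ResidualBlock(Module):
    """Lightweight residual block: conv-ReLU-conv plus skip, no norms.

    The normalization-free variant keeps reconstruction detail and halves
    the block's cost relative to the classic norm-act-conv design.  The
    closing conv starts small so stacked blocks leave feature magnitudes
    near their input scale — without normalization layers this is what
    keeps a deep decoder's activations (and the Tanh head) unsaturated.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.conv2 = Conv2d(channels, channels, 3, rng, init_scale=0.2)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).relu())


class SGD:
    """Momentum SGD; ``lr`` may change every step (warm-up schedules)."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data = p.data - lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"velocity": [v.copy() for v in self.velocity]}

    def load_state(self, state: dict):
        self.velocity = [np.array(v) for v in state["velocity"]]
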