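"""Layer abstractions over the autodiff engine.

Mirrors the familiar ``torch.nn`` surface at the scale this package needs:
``Module`` with recursive parameter discovery, ``Conv2d`` /
``ConvTranspose2d`` / ``BatchNorm2d`` / ``PReLU`` / ``ReLU`` / ``Dropout2d``
/ ``Sequential``, plus ``state_dict`` round-tripping for checkpoints.

Weight initialisation is He-normal and driven by an explicit
``numpy.random.Generator`` so model construction is fully seeded.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: recursive parameters(), train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}.{name}" if prefix else name)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        sub = f"{prefix}.{name}.{i}" if prefix else f"{name}.{i}"
                        yield from item.named_modules(sub)

    def named_parameters(self):
        for mod_name, mod in self.named_modules():
            for name, val in vars(mod).items():
                if isinstance(val, Parameter):
                    yield (f"{mod_name}.{name}" if mod_name else name), val

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self):
        for mod_name, mod in self.named_modules():
            for name in getattr(mod, "_buffers", ()):
                full = f"{mod_name}.{name}" if mod_name else name
                yield full, getattr(mod, name)

    # -- modes ---------------------------------------------------------
    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        mismatches = []
        for name, p in own.items():
            if name not in state:
                mismatches.append(f"missing parameter {name}")
            elif state[name].shape != p.data.shape:
                mismatches.append(
                    f"{name}: checkpoint {state[name].shape} vs model {p.data.shape}")
        if mismatches:
            raise ValueError("checkpoint/architecture mismatch: " + "; ".join(mismatches))
        for name, p in own.items():
            p.data = state[name].astype(p.data.dtype).copy()
        for mod_name, mod in self.named_modules():
            for bname in getattr(mod, "_buffers", ()):
                full = f"{mod_name}.{bname}" if mod_name else bname
                if full in state:
                    setattr(mod, bname, state[full].copy())
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


from contextlib import contextmanager


@contextmanager
def no_grad(module: "Module"):
    """Temporarily drop requires_grad on all parameters so forward passes
    skip graph construction (cheaper inference)."""
    params = module.parameters()
    flags = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p, f in zip(params, flags):
            p.requires_grad = f


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 *, stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, (out_channels, in_channels, kernel_size, kernel_size)
        ).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation)


class ConvTranspose2d(Module):
    """Learned ×stride upsampling: zero-insertion followed by a convolution
    with the spatially flipped, channel-transposed kernel (IOHW weight)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 *, stride: int = 2, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, (in_channels, out_channels, kernel_size, kernel_size)
        ).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x):
        xz = ad.zero_insert(x, self.stride)
        w = ad.flip_kernel(self.weight)
        pad = self.kernel_size - 1 - self.padding
        y = ad.conv2d(xz, w, None, stride=1, padding=pad)
        if self.bias is not None:
            y = ad.add(y, _reshape_bias(self.bias))
        return y


def _reshape_bias(b: Parameter):
    # broadcastable view of a (C,) bias that still routes gradients
    out = ad.Tensor(b.data.reshape(1, -1, 1, 1))
    out._parents = (b,)
    out._backward = lambda g: ((b, g.reshape(b.data.shape)),)
    return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, *, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.num_features = num_features
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones((1, num_features, 1, 1), dtype=dtype))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1), dtype=dtype))
        self.running_mean = np.zeros((1, num_features, 1, 1), dtype=dtype)
        self.running_var = np.ones((1, num_features, 1, 1), dtype=dtype)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x):
        if self.training:
            out, mu, var = ad.batch_norm(x, self.gamma, self.beta, eps=self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            out, _, _ = ad.batch_norm(x, self.gamma, self.beta,
                                      mean=self.running_mean,
                                      var=self.running_var, eps=self.eps)
        return out


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class PReLU(Module):
    def __init__(self, num_channels: int, init: float = 0.25, dtype=np.float32):
        super().__init__()
        self.alpha = Parameter(np.full(num_channels, init, dtype=dtype))

    def forward(self, x):
        return ad.prelu(x, self.alpha)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class Dropout2d(Module):
    """Inverted elementwise dropout; ``keep_prob`` is the KEEP probability
    (any drop-rate caller converts explicitly). ``mc_active`` keeps it
    stochastic in evaluation mode for Monte-Carlo uncertainty passes."""

    def __init__(self, keep_prob: float = 0.5, seed: int = 0):
        super().__init__()
        if not 0.0 < keep_prob <= 1.0:
            raise ValueError(f"keep_prob must lie in (0, 1], got {keep_prob}")
        self.keep_prob = keep_prob
        self.rng = np.random.default_rng(seed)
        self.mc_active = False

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        active = self.training or self.mc_active
        return ad.dropout(x, self.keep_prob, self.rng, training=active)
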