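"""Weight initialization schemes."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, Module


class ConfigurationError(ValueError):
    pass


def he_normal_(module: Module, rng: np.random.Generator) -> None:
    """In-place He-normal init: conv weights ~ N(0, 2/fan_in), biases zero.

    BatchNorm scales reset to 1 and shifts to 0. Traversal order is the
    registration order of submodules, so the draw sequence is deterministic
    for a fixed seed.
    """
    if isinstance(module, (Conv2d, ConvTranspose2d)):
        std = np.sqrt(2.0 / module.fan_in)
        module.weight.data[...] = rng.normal(0.0, std, module.weight.shape)
        if module.bias is not None:
            module.bias.data[...] = 0.0
    elif isinstance(module, BatchNorm2d):
        module.gamma.data[...] = 1.0
        module.beta.data[...] = 0.0
    for child in module._children.values():
        he_normal_(child, rng)


def init_weights(model: Module, scheme: str = "he_normal",
                 seed: int = 0) -> Module:
    """Initialize all parameters of ``model`` in place and return it."""
    if scheme != "he_normal":
        raise ConfigurationError(f"unknown initialization scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    he_normal_(model, rng)
    return model
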