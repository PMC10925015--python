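"""Parameter containers and initialisation helpers for the encoders."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def glorot(rng: np.random.Generator, *shape: int) -> Tensor:
    """Glorot/Xavier uniform initialisation."""
    fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], shape[0])
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def ones(*shape: int) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


class Module:
    """Lightweight parameter registry.

    Any :class:`Tensor` attribute (or Module / list of either) is a child;
    traversal order follows attribute insertion order, so two instances built
    by the same constructor share a naming scheme — which is what checkpoint
    round-tripping relies on.
    """

    def _children(self):
        for name, value in self.__dict__.items():
            if isinstance(value, (Tensor, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Tensor, Module)):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for _, child in self._children():
            if isinstance(child, Tensor):
                if child.requires_grad:
                    params.append(child)
            else:
                params.extend(child.parameters())
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, child in self._children():
            key = f"{prefix}{name}"
            if isinstance(child, Tensor):
                state[key] = child.data
            else:
                state.update(child.state_dict(prefix=f"{key}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray],
                        prefix: str = "") -> None:
        for name, child in self._children():
            key = f"{prefix}{name}"
            if isinstance(child, Tensor):
                child.data = np.array(state[key], dtype=np.float64)
            else:
                child.load_state_dict(state, prefix=f"{key}.")


ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "identity": lambda t: t,
}


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = glorot(rng, d_in, d_out)
        self.b = zeros(d_out)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b
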