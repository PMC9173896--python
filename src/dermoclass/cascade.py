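"""Cascade-forward neural network for binary lesion classification.

A cascade-forward network augments a one-hidden-layer perceptron with
direct input-to-output connections, so the scalar network output is

    y = f_in( sum_i w_i x_i )
        + f_out( b_out + sum_j v_j * f_h( b_j + sum_i W_ji x_i ) )

where the first term is the direct (input -> output) path and the
second the usual hidden-layer path.  Because this sum is unbounded, the
classifier applies a final logistic squash to y and thresholds the
resulting score at 0.5 (melanoma when score >= threshold; the tie at
exactly the threshold goes to melanoma).

Weights are not trained by gradient descent here: the parameter vector
is optimized by a population metaheuristic (see the mrfo module), so
this module also provides a lossless flatten/unflatten between the
structured parameters and a flat search vector with the fixed ordering
(direct weights, hidden weights row-major, output weights, hidden
biases, output bias).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CascadeNetParams",
    "ParamLayout",
    "forward",
    "predict",
    "flatten",
    "unflatten",
    "zero_params",
    "random_params",
    "save_params",
    "load_params",
]

_ACTIVATIONS = {
    "identity": lambda z: z,
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
    "tanh": np.tanh,
}


@dataclass(frozen=True)
class CascadeNetParams:
    direct_weights: np.ndarray  # (n_inputs,)
    hidden_weights: np.ndarray  # (n_hidden, n_inputs)
    output_weights: np.ndarray  # (n_hidden,)
    hidden_biases: np.ndarray  # (n_hidden,)
    output_bias: float
    activations: tuple[str, str, str] = ("identity", "logistic", "logistic")

    def __post_init__(self) -> None:
        n = self.direct_weights.shape[0]
        k = self.output_weights.shape[0]
        if self.hidden_weights.shape != (k, n):
            raise ValueError("hidden_weights shape inconsistent")
        if self.hidden_biases.shape != (k,):
            raise ValueError("hidden_biases shape inconsistent")
        for name in self.activations:
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")

    @property
    def n_inputs(self) -> int:
        return self.direct_weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.output_weights.shape[0]


@dataclass(frozen=True)
class ParamLayout:
    """Dimensions needed to rebuild CascadeNetParams from a flat vector."""

    n_inputs: int
    n_hidden: int
    activations: tuple[str, str, str] = ("identity", "logistic", "logistic")

    @property
    def size(self) -> int:
        n, k = self.n_inputs, self.n_hidden
        return n + k * n + k + k + 1


def network_output(params: CascadeNetParams, x: np.ndarray) -> np.ndarray:
    """Raw (unsquashed) cascade output y for one vector or a batch."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.n_inputs:
        raise ValueError(
            f"input length {x.shape[1]} != n_inputs {params.n_inputs}"
        )
    f_in, f_h, f_out = (_ACTIVATIONS[a] for a in params.activations)
    direct = f_in(x @ params.direct_weights)
    hidden = f_h(x @ params.hidden_weights.T + params.hidden_biases)
    indirect = f_out(params.output_bias + hidden @ params.output_weights)
    return direct + indirect


def forward(params: CascadeNetParams, x: np.ndarray) -> float | np.ndarray:
    """Classification score in (0, 1): logistic squash of the raw output."""
    y = network_output(params, x)
    score = 1.0 / (1.0 + np.exp(-np.clip(y, -500, 500)))
    if np.asarray(x).ndim == 1:
        return float(score[0])
    return score


def predict(
    params: CascadeNetParams,
    x: np.ndarray | Sequence[np.ndarray],
    threshold: float = 0.5,
) -> np.ndarray:
    """Labels from scores; melanoma iff score >= threshold."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    scores = forward(params, x)
    return np.where(scores >= threshold, "melanoma", "benign")


def flatten(params: CascadeNetParams) -> tuple[np.ndarray, ParamLayout]:
    layout = ParamLayout(params.n_inputs, params.n_hidden, params.activations)
    vec = np.concatenate(
        [
            params.direct_weights,
            params.hidden_weights.ravel(),
            params.output_weights,
            params.hidden_biases,
            [params.output_bias],
        ]
    )
    return vec, layout


def unflatten(vector: np.ndarray, layout: ParamLayout) -> CascadeNetParams:
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (layout.size,):
        raise ValueError(
            f"vector length {vector.shape} does not match layout size {layout.size}"
        )
    n, k = layout.n_inputs, layout.n_hidden
    pos = 0

    def take(count: int) -> np.ndarray:
        nonlocal pos
        out = vector[pos : pos + count]
        pos += count
        return out

    return CascadeNetParams(
        direct_weights=take(n).copy(),
        hidden_weights=take(k * n).reshape(k, n).copy(),
        output_weights=take(k).copy(),
        hidden_biases=take(k).copy(),
        output_bias=float(take(1)[0]),
        activations=layout.activations,
    )


def zero_params(n_inputs: int, n_hidden: int) -> CascadeNetParams:
    layout = ParamLayout(n_inputs, n_hidden)
    return unflatten(np.zeros(layout.size), layout)


def random_params(
    n_inputs: int, n_hidden: int, seed: int = 0, scale: float = 1.0
) -> CascadeNetParams:
    layout = ParamLayout(n_inputs, n_hidden)
    rng = np.random.default_rng(seed)
    return unflatten(rng.normal(0.0, scale, layout.size), layout)


def save_params(params: CascadeNetParams, path) -> None:
    """Serialize as structured text (JSON) so model files are diffable."""
    import json

    payload = {
        "n_inputs": params.n_inputs,
        "n_hidden": params.n_hidden,
        "activations": list(params.activations),
        "values": flatten(params)[0].tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_params(path) -> CascadeNetParams:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    layout = ParamLayout(
        payload["n_inputs"], payload["n_hidden"], tuple(payload["activations"])
    )
    return unflatten(np.array(payload["values"]), layout)
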