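"""Declarative description of the cell-counting CNN architecture.

The network maps one grayscale well image to posterior probabilities of the
four occupancy categories (0, 1, 2, >2 cells).  Apart from the input and
output it has 18 layers: a local-response-normalization (LRN) layer applied
directly to the image, four 2x2 max-pooling stages, eight 5x5 convolutions
(channel plan 32-32 / 64-64-64 / 32-32-32, with the first convolution of the
middle and last blocks striding by 2), four LRN layers, and two fully
connected layers (32 then 512 units) feeding a 4-way softmax.  At the native
511x511 input resolution the weight tensors (biases excluded) hold exactly
468,768 elements.

Spatial sizes follow "same" (ceil) arithmetic: a stride-``s`` stage maps side
``n`` to ``ceil(n / s)``.  The same channel plan can therefore be instantiated
at any input side >= 64 (``scaled_spec``), which is how the desk-scale tests
and examples train the architecture on small synthetic wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple


class LayerKind(str, Enum):
    INPUT = "input"
    LRN = "lrn"
    MAX_POOL = "max_pool"
    CONV = "conv"
    FULLY_CONNECTED = "fully_connected"
    OUTPUT = "output"


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network, as it would appear in an architecture table.

    Parameters
    ----------
    kind : LayerKind
    name : str
        e.g. ``"conv3"`` or ``"lrn2"``; used in error messages.
    out_channels : int
        Channel count of the output feature map; for fully connected and
        output layers this is the unit count and ``spatial_size`` is 1.
    spatial_size : int
        Side of the (square) output feature map.
    kernel : tuple, optional
        ``(kh, kw, in_channels, out_channels)`` for convolutions.
    weight_shape : tuple, optional
        Element count of the weight tensor as a shape product; for fully
        connected layers ``(out, in...)``.
    stride : int
    fan_in : int
        Number of input nodes feeding one unit; sets the He-initialization
        variance 2 / fan_in.
    """

    kind: LayerKind
    name: str
    out_channels: int
    spatial_size: int
    kernel: Optional[Tuple[int, int, int, int]] = None
    weight_shape: Optional[Tuple[int, ...]] = None
    stride: int = 1

    @property
    def fan_in(self) -> int:
        if self.kind is LayerKind.CONV:
            kh, kw, cin, _ = self.kernel
            return kh * kw * cin
        if self.kind in (LayerKind.FULLY_CONNECTED, LayerKind.OUTPUT):
            return int(math.prod(self.weight_shape[1:]))
        return 0

    @property
    def n_nodes(self) -> int:
        return self.out_channels * self.spatial_size * self.spatial_size

    @property
    def n_weights(self) -> int:
        shape = self.kernel if self.kind is LayerKind.CONV else self.weight_shape
        if shape is None:
            return 0
        return int(math.prod(shape))

    def __post_init__(self) -> None:
        if self.kind is LayerKind.CONV:
            if self.kernel is None:
                raise ValueError(f"{self.name}: convolution layer needs a kernel shape")
            if self.kernel[3] != self.out_channels:
                raise ValueError(
                    f"{self.name}: kernel out-channels {self.kernel[3]} != "
                    f"declared out_channels {self.out_channels}"
                )
        if self.kind in (LayerKind.FULLY_CONNECTED, LayerKind.OUTPUT):
            if self.weight_shape is None:
                raise ValueError(f"{self.name}: fully connected layer needs weight_shape")
            if self.weight_shape[0] != self.out_channels:
                raise ValueError(
                    f"{self.name}: weight_shape[0] {self.weight_shape[0]} != "
                    f"unit count {self.out_channels}"
                )


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer list plus the hyperparameters shared by all instances."""

    layers: Tuple[LayerSpec, ...]
    dropout_rate: float = 0.3
    lrn_depth_radius: int = 2
    lrn_alpha: float = 1e-4
    lrn_beta: float = 0.75
    lrn_bias: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers or self.layers[0].kind is not LayerKind.INPUT:
            raise ValueError("spec must start with an input layer")
        if self.layers[-1].kind is not LayerKind.OUTPUT:
            raise ValueError("spec must end with an output layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        prev = self.layers[0]
        for layer in self.layers[1:]:
            if layer.kind is LayerKind.CONV and layer.kernel[2] != prev.out_channels:
                raise ValueError(
                    f"shape mismatch between {prev.name} (out {prev.out_channels} ch) "
                    f"and {layer.name} (kernel expects {layer.kernel[2]} ch)"
                )
            if layer.kind in (LayerKind.FULLY_CONNECTED, LayerKind.OUTPUT):
                expected = int(math.prod(layer.weight_shape[1:]))
                if expected != prev.n_nodes:
                    raise ValueError(
                        f"shape mismatch between {prev.name} ({prev.n_nodes} nodes) and "
                        f"{layer.name} (weights expect {expected} inputs)"
                    )
            prev = layer

    @property
    def input_side(self) -> int:
        return self.layers[0].spatial_size

    @property
    def n_categories(self) -> int:
        return self.layers[-1].out_channels

    def count_weights(self) -> int:
        """Total number of weight elements, biases excluded."""
        return sum(layer.n_weights for layer in self.layers)

    def count_parameters(self) -> int:
        """Weights plus biases (one bias per conv/fc output channel)."""
        biases = sum(
            layer.out_channels
            for layer in self.layers
            if layer.kind in (LayerKind.CONV, LayerKind.FULLY_CONNECTED, LayerKind.OUTPUT)
        )
        return self.count_weights() + biases


def _ceil_div(n: int, s: int) -> int:
    return -(-n // s)


#: (kind, name, out_channels, stride) for the spatial stages, in order.
_STAGE_PLAN = (
    ("lrn", "lrn1", None, 1),
    ("max_pool", "maxpool1", None, 2),
    ("conv", "conv1", 32, 1),
    ("conv", "conv2", 32, 1),
    ("max_pool", "maxpool2", None, 2),
    ("lrn", "lrn2", None, 1),
    ("conv", "conv3", 64, 2),
    ("conv", "conv4", 64, 1),
    ("conv", "conv5", 64, 1),
    ("max_pool", "maxpool3", None, 2),
    ("lrn", "lrn3", None, 1),
    ("conv", "conv6", 32, 2),
    ("conv", "conv7", 32, 1),
    ("conv", "conv8", 32, 1),
    ("max_pool", "maxpool4", None, 2),
    ("lrn", "lrn4", None, 1),
)


def build_spec(
    input_side: int = 511,
    kernel_size: int = 5,
    fc1_units: int = 32,
    fc2_units: int = 512,
    n_categories: int = 4,
    dropout_rate: float = 0.3,
) -> NetworkSpec:
    """Instantiate the architecture for a given (square) input side.

    The channel plan, kernel size, strides and fully-connected widths are
    fixed; only the spatial sizes and hence the first fully-connected weight
    shape depend on ``input_side``.  ``input_side=511`` reproduces the native
    architecture exactly.
    """
    if input_side < 64:
        raise ValueError("input_side must be >= 64 for six stride-2 stages")
    layers = [LayerSpec(LayerKind.INPUT, "input", 1, input_side)]
    side, channels = input_side, 1
    for kind, name, out_ch, stride in _STAGE_PLAN:
        if kind == "conv":
            side = _ceil_div(side, stride)
            kernel = (kernel_size, kernel_size, channels, out_ch)
            layers.append(
                LayerSpec(LayerKind.CONV, name, out_ch, side, kernel=kernel, stride=stride)
            )
            channels = out_ch
        elif kind == "max_pool":
            side = _ceil_div(side, stride)
            layers.append(
                LayerSpec(LayerKind.MAX_POOL, name, channels, side, stride=stride)
            )
        else:  # lrn
            layers.append(LayerSpec(LayerKind.LRN, name, channels, side))
    layers.append(
        LayerSpec(
            LayerKind.FULLY_CONNECTED,
            "fc1",
            fc1_units,
            1,
            weight_shape=(fc1_units, channels, side, side),
        )
    )
    layers.append(
        LayerSpec(
            LayerKind.FULLY_CONNECTED, "fc2", fc2_units, 1, weight_shape=(fc2_units, fc1_units)
        )
    )
    layers.append(
        LayerSpec(
            LayerKind.OUTPUT, "output", n_categories, 1, weight_shape=(n_categories, fc2_units)
        )
    )
    return NetworkSpec(tuple(layers), dropout_rate=dropout_rate)


def table_spec() -> NetworkSpec:
    """The native 511x511 architecture (468,768 weight elements)."""
    return build_spec(input_side=511)


def scaled_spec(input_side: int, **kwargs) -> NetworkSpec:
    """Same channel plan at a smaller input side, for desk-scale training."""
    return build_spec(input_side=input_side, **kwargs)


def count_weights(spec: NetworkSpec) -> int:
    """Number of weight elements in ``spec``, excluding biases."""
    return spec.count_weights()
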