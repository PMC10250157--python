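"""The 11-entry architecture catalog and model-level operations.

Every architecture is a 1-D convolutional classifier over one-hot encoded
windows: a stack of convolutional blocks (50 filters of size 9, ReLU,
optionally followed by size-2 stride-1 max or average pooling), then a
flatten (or global average pool), a 100-unit ReLU dense layer, 30% dropout,
and a 2-class softmax head.  Convolutions use length-preserving padding and
pooling uses stride 1, so all variants keep the full window length through
the conv stack; that makes the conv-block parameter shapes of the 2- and
3-block variants agree layerwise, which is what permits the weight-averaged
ensemble entries (MODEL4 = mean of trained MODEL1 and MODEL2, MODEL5 = mean
of trained MODEL1 and MODEL3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from . import nn
from .errors import AveragingError, CatalogError, ModelFormatError, ShapeError

FORMAT_VERSION = 1

Pooling = Literal["max", "average", "none", "global_average"]


@dataclass
class ArchitectureSpec:
    """Hyperparameters of one catalog entry."""

    name: str
    n_conv_blocks: int
    pooling: Pooling
    filters: int = 50
    kernel_size: int = 9
    pool_size: int = 2
    pool_stride: int = 1
    dense_units: int = 100
    dropout_rate: float = 0.3
    n_classes: int = 2
    input_len: int = 400
    conv_activation: str = "relu"
    conv_stride: int = 1

    def __post_init__(self) -> None:
        if self.filters <= 0:
            raise ShapeError("filters must be positive")
        if self.kernel_size % 2 == 0:
            raise ShapeError("kernel_size must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ShapeError("dropout_rate must lie in [0, 1)")


# (n_conv_blocks, pooling); filters/kernel inherited from the winning grid point
_CATALOG: dict[str, tuple[int, Pooling]] = {
    "C1": (1, "none"),
    "C11M": (1, "max"),
    "MODEL1": (3, "max"),
    "MODEL2": (2, "max"),
    "MODEL3": (3, "average"),
    "NPOOL13": (3, "none"),
    "NPOOL12": (2, "none"),
    "AVEPOOL12": (2, "average"),
    "MEANPOOL13": (3, "global_average"),
    # ensemble entries: same topology as their deeper source (MODEL1);
    # their weights come from average_weights over trained sources
    "MODEL4": (3, "max"),
    "MODEL5": (3, "max"),
}

CATALOG_NAMES = tuple(_CATALOG)

# which trained sources the ensemble entries average
ENSEMBLE_SOURCES = {"MODEL4": ("MODEL1", "MODEL2"), "MODEL5": ("MODEL1", "MODEL3")}


@dataclass
class ModelWeights:
    """Named parameter tensors plus free-text provenance."""

    tensors: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = ""

    def copy(self) -> "ModelWeights":
        return ModelWeights(
            {k: v.copy() for k, v in self.tensors.items()}, self.provenance
        )


def catalog_spec(name: str, input_len: int = 400) -> ArchitectureSpec:
    key = name.upper()
    if key not in _CATALOG:
        raise CatalogError(
            f"unknown architecture {name!r}; valid names: {', '.join(CATALOG_NAMES)}"
        )
    n_blocks, pooling = _CATALOG[key]
    return ArchitectureSpec(name=key, n_conv_blocks=n_blocks, pooling=pooling, input_len=input_len)


def build_network(spec: ArchitectureSpec) -> nn.Network:
    """Materialize the layer stack for a spec (uninitialized parameters)."""
    layers: list[nn.Layer] = []
    c_in = 4
    out_len = spec.input_len
    for i in range(spec.n_conv_blocks):
        layers.append(
            nn.Conv1D(c_in, spec.filters, spec.kernel_size, name=f"conv{i + 1}", stride=spec.conv_stride)
        )
        layers.append(nn.Activation(spec.conv_activation))
        out_len = -(-out_len // spec.conv_stride)
        if spec.pooling == "max":
            layers.append(nn.MaxPool1D(spec.pool_size))
        elif spec.pooling == "average":
            layers.append(nn.AvgPool1D(spec.pool_size))
        c_in = spec.filters
    if spec.pooling == "global_average":
        layers.append(nn.GlobalAvgPool1D())
        dense_in = spec.filters
    else:
        layers.append(nn.Flatten())
        dense_in = out_len * spec.filters
    layers.append(nn.Dense(dense_in, spec.dense_units, name="dense"))
    layers.append(nn.Activation("relu"))
    layers.append(nn.Dropout(spec.dropout_rate))
    layers.append(nn.Dense(spec.dense_units, spec.n_classes, name="out"))
    return nn.Network(layers)


def build_architecture(
    name: str, input_len: int = 400, seed: int = 0
) -> tuple[ArchitectureSpec, ModelWeights]:
    """Create a catalog architecture with seeded, reproducible initialization."""
    spec = catalog_spec(name, input_len)
    net = build_network(spec)
    net.init(seed)
    weights = ModelWeights(
        {k: v.copy() for k, v in net.parameters().items()},
        provenance=f"random init (seed={seed})",
    )
    return spec, weights


def network_with_weights(spec: ArchitectureSpec, weights: ModelWeights) -> nn.Network:
    net = build_network(spec)
    expected = set(net.parameters())
    got = set(weights.tensors)
    if expected != got:
        raise ShapeError(
            f"weight keys {sorted(got)} do not match architecture {spec.name} "
            f"(expected {sorted(expected)})"
        )
    net.set_parameters(weights.tensors)
    return net


def average_weights(
    a: ModelWeights, b: ModelWeights, target: ArchitectureSpec
) -> ModelWeights:
    """Elementwise mean of shape-matched layers; deeper-only layers copied.

    The target architecture is the deeper of the two sources; any tensor
    present with identical shape in both sources is averaged, tensors present
    only in the target's source are copied unchanged.
    """
    target_net = build_network(target)
    target_keys = target_net.parameters()
    matched = [
        k
        for k in target_keys
        if k in a.tensors and k in b.tensors and a.tensors[k].shape == b.tensors[k].shape
    ]
    if not matched:
        raise AveragingError("no structurally matching layers between the two models")
    out: dict[str, np.ndarray] = {}
    copied: list[str] = []
    for k in target_keys:
        if k in matched:
            out[k] = ((a.tensors[k] + b.tensors[k]) / 2.0).astype(np.float32)
        elif k in a.tensors:
            out[k] = a.tensors[k].copy()
            copied.append(k)
        elif k in b.tensors:
            out[k] = b.tensors[k].copy()
            copied.append(k)
        else:
            raise AveragingError(f"target layer {k} missing from both sources")
    prov = (
        f"average of [{a.provenance or 'a'}] and [{b.provenance or 'b'}]; "
        f"averaged={sorted(matched)}; copied={sorted(copied)}"
    )
    return ModelWeights(out, provenance=prov)


@dataclass
class PredictionBatch:
    """Softmax outputs for a batch, class order (false_site, true_site)."""

    probabilities: np.ndarray  # (n, 2)
    predicted_labels: np.ndarray  # (n,) int, 1 = true_site

    def __len__(self) -> int:
        return self.probabilities.shape[0]


def predict(
    spec: ArchitectureSpec,
    weights: ModelWeights,
    x: np.ndarray,
    batch_size: int = 128,
) -> PredictionBatch:
    """Run inference (dropout disabled) on an (n, L, 4) one-hot tensor."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1] != spec.input_len or x.shape[2] != 4:
        raise ShapeError(
            f"expected inputs of shape (n, {spec.input_len}, 4), got {x.shape}"
        )
    net = network_with_weights(spec, weights)
    probs = np.empty((x.shape[0], spec.n_classes), dtype=np.float32)
    for start in range(0, x.shape[0], batch_size):
        logits = net.forward(x[start : start + batch_size], train=False)
        probs[start : start + batch_size] = nn.softmax(logits)
    return PredictionBatch(probabilities=probs, predicted_labels=probs.argmax(axis=1))


# ---------------------------------------------------------------------------
# persistence: a directory bundle with a JSON manifest + NPZ weights


def save_model(spec: ArchitectureSpec, weights: ModelWeights, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "spec": asdict(spec),
        "provenance": weights.provenance,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(path / "weights.npz", **weights.tensors)


def load_model(path: str | Path) -> tuple[ArchitectureSpec, ModelWeights]:
    path = Path(path)
    manifest_path = path / "manifest.json"
    weights_path = path / "weights.npz"
    if not manifest_path.exists() or not weights_path.exists():
        raise ModelFormatError(f"{path} is not a model bundle (missing manifest or weights)")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"corrupt manifest in {path}: {exc}") from exc
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"model bundle format version {version} unsupported (expected {FORMAT_VERSION})"
        )
    spec = ArchitectureSpec(**manifest["spec"])
    with np.load(weights_path) as npz:
        tensors = {k: npz[k].astype(np.float32) for k in npz.files}
    weights = ModelWeights(tensors, provenance=manifest.get("provenance", ""))
    # validate shapes against the spec before handing the bundle back
    network_with_weights(spec, weights)
    return spec, weights
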