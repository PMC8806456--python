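"""The feature multi-connection (FMC) architecture family.

An AlexNet-style five-convolution backbone in which the conv3/conv4/conv5
feature maps can be re-routed forward: either as extra inputs to later
convolutions or directly into a *merged layer* that concatenates them,
reduces each channel by global Lp pooling and projects the pooled vector
to a configurable width before the dense classifier head.

Seven wirings are supported: ``base`` (plain backbone, no merged layer),
the ablation variants ``A``–``E`` which each forward a different subset of
conv outputs, and ``FMC``, the full pattern in which every convolution from
conv3 onward receives the concatenation of all preceding conv3+ outputs and
the merged layer receives all three.  Every variant keeps exactly five conv
layers with identical per-layer output widths — the connectivity, not the
depth or width, is what varies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

VARIANTS = ("base", "A", "B", "C", "D", "E", "FMC")

#: merged-layer inputs per variant, in concatenation order
MERGE_SOURCES = {
    "A": ("conv5",),
    "B": ("conv5", "conv3"),
    "C": ("conv4", "conv5"),
    "D": ("conv4", "conv5"),
    "E": ("conv3", "conv4", "conv5"),
    "FMC": ("conv3", "conv4", "conv5"),
}

#: extra (skip) inputs to conv layers, prepended to the normal input
CONV_SKIP_SOURCES = {
    "A": {"conv5": ("conv4", "conv3")},   # conv5 sees concat(conv4, conv3)
    "FMC": {"conv5": ("conv3", "conv4")},  # conv5 sees concat(conv3, conv4)
}

#: (kernel, stride, pad) for conv1/conv2/conv3-5 and (kernel, stride) for pools
_GEOMETRY = {
    "full": {
        "input_size": 227,
        "conv": [(11, 4, 0), (5, 1, 2), (3, 1, 1), (3, 1, 1), (3, 1, 1)],
        "pool": (3, 2),
        "conv_widths": (96, 256, 384, 384, 256),
        "merged_width": 1024,
        "dense_widths": (4096, 4096),
    },
    "tiny": {
        "input_size": 64,
        "conv": [(5, 2, 2), (5, 1, 2), (3, 1, 1), (3, 1, 1), (3, 1, 1)],
        "pool": (2, 2),
        "conv_widths": (16, 32, 48, 48, 32),
        "merged_width": 128,
        "dense_widths": (64, 64),
    },
}

#: LRN hyperparameters: k=2, n=5, alpha=0.0004, beta=0.75
@dataclass(frozen=True)
class LrnParams:
    k: float = 2.0
    n: int = 5
    alpha: float = 0.0004
    beta: float = 0.75

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("LRN neighborhood size n must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("LRN alpha and beta must be positive")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one member of the architecture family."""

    variant: str = "FMC"
    size_profile: str = "tiny"
    conv_widths: tuple[int, ...] | None = None
    merged_width: int | None = None
    reduction_p: float = 2.0
    dense_widths: tuple[int, ...] | None = None
    input_size: int | None = None
    n_channels: int = 3
    n_classes: int = 2
    lrn: LrnParams = field(default_factory=LrnParams)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.size_profile not in _GEOMETRY:
            raise ValueError(f"unknown size_profile {self.size_profile!r}")
        if self.reduction_p < 1:
            raise ValueError("reduction exponent p must be >= 1")
        if self.merged_width is not None and self.merged_width < 1:
            raise ValueError("merged_width must be >= 1")

    def resolved(self) -> "ArchitectureSpec":
        """Fill profile defaults for any field left as None."""
        g = _GEOMETRY[self.size_profile]
        return dataclasses.replace(
            self,
            conv_widths=tuple(self.conv_widths or g["conv_widths"]),
            merged_width=self.merged_width or g["merged_width"],
            dense_widths=tuple(self.dense_widths or g["dense_widths"]),
            input_size=self.input_size or g["input_size"],
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("conv_widths", "dense_widths"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        for k in ("conv_widths", "dense_widths"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        if isinstance(d.get("lrn"), dict):
            d["lrn"] = LrnParams(**d["lrn"])
        return cls(**d)


# ---------------------------------------------------------------------------
# functional layer operations (spec-facing, unbatched feature maps are fine)

def lrn(a: np.ndarray, params: LrnParams = LrnParams()) -> np.ndarray:
    """Local response normalization of an (..., C) feature map (pure numpy)."""
    return nn.lrn(Tensor(np.asarray(a, dtype=float)),
                  k=params.k, n=params.n, alpha=params.alpha, beta=params.beta).data


def concat_merge(features: list[np.ndarray]) -> np.ndarray:
    """Concatenate feature maps along channels; spatial dims must agree."""
    features = [np.asarray(f) for f in features]
    shapes = [f.shape[:-1] for f in features]
    if len(set(shapes)) > 1:
        raise ValueError(f"cannot merge feature maps with spatial dims {shapes}")
    return np.concatenate(features, axis=-1)


def lp_reduce(f_total: np.ndarray, p: float = 2.0) -> np.ndarray:
    """Reduce an (H,W,C) map to a length-C vector: out_c = (sum_xy |f|^p)^(1/p)."""
    if p < 1:
        raise ValueError(f"reduction exponent p must be >= 1, got {p}")
    f = np.asarray(f_total, dtype=float)
    return (np.abs(f) ** p).sum(axis=(0, 1)) ** (1.0 / p)


# ---------------------------------------------------------------------------
# model graph

class WiringError(ValueError):
    pass


class ModelGraph:
    """A built network: named parameters plus the variant's forward wiring.

    Parameters are ``nn.Tensor`` objects keyed like ``conv1.weight`` /
    ``merged.proj.weight`` / ``fc1.bias`` / ``classifier.weight``; the same
    keys appear in checkpoints.  ``forward`` returns the 2-logit output and a
    dict of intermediate activations (conv3/conv4/conv5 post-activation maps,
    the merged concat map and pooled vector) used by evaluation and CAM.
    """

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator | None = None,
                 dtype=nn.DEFAULT_DTYPE):
        self.spec = spec.resolved()
        self.dtype = dtype
        rng = rng or np.random.default_rng(0)
        s = self.spec
        g = _GEOMETRY[s.size_profile]
        self.conv_geometry = g["conv"]
        self.pool_geometry = g["pool"]

        self.conv_in_channels = self._conv_inputs()
        self.spatial_dims = self._spatial_dims()
        self._check_skip_spatial()

        self.params: dict[str, Tensor] = {}
        for i, (cin, cout) in enumerate(zip(self.conv_in_channels, s.conv_widths), start=1):
            k = self.conv_geometry[i - 1][0]
            self._add_param(f"conv{i}.weight", nn.he_normal(rng, (k, k, cin, cout), k * k * cin, dtype))
            self._add_param(f"conv{i}.bias", np.zeros(cout, dtype=dtype))

        if s.variant == "base":
            pk, ps = self.pool_geometry
            side = (self.spatial_dims["conv5"] - pk) // ps + 1
            fc_in = side * side * s.conv_widths[4]
        else:
            merged_channels = sum(s.conv_widths[_conv_index(src)] for src in MERGE_SOURCES[s.variant])
            self.merged_channels = merged_channels
            self._add_param("merged.proj.weight",
                            nn.he_normal(rng, (merged_channels, s.merged_width), merged_channels, dtype))
            self._add_param("merged.proj.bias", np.zeros(s.merged_width, dtype=dtype))
            fc_in = s.merged_width

        widths = list(s.dense_widths)
        for i, w in enumerate(widths, start=1):
            self._add_param(f"fc{i}.weight", nn.he_normal(rng, (fc_in, w), fc_in, dtype))
            self._add_param(f"fc{i}.bias", np.zeros(w, dtype=dtype))
            fc_in = w
        self._add_param("classifier.weight", nn.he_normal(rng, (fc_in, s.n_classes), fc_in, dtype))
        self._add_param("classifier.bias", np.zeros(s.n_classes, dtype=dtype))

    # -- construction helpers ------------------------------------------------

    def _add_param(self, name: str, value: np.ndarray):
        self.params[name] = Tensor(value, requires_grad=True, name=name)

    def _conv_inputs(self) -> list[int]:
        s = self.spec
        ins = [s.n_channels]
        for i in range(2, 6):
            normal = s.conv_widths[i - 2]
            skips = CONV_SKIP_SOURCES.get(s.variant, {}).get(f"conv{i}")
            if skips:
                ins.append(sum(s.conv_widths[_conv_index(src)] for src in skips))
            else:
                ins.append(normal)
        return ins

    def _spatial_dims(self) -> dict[str, int]:
        s = self.spec
        pk, ps = self.pool_geometry
        size = s.input_size
        dims = {}
        for i, (k, stride, pad) in enumerate(self.conv_geometry, start=1):
            size = (size + 2 * pad - k) // stride + 1
            dims[f"conv{i}"] = size
            if i in (1, 2):  # pools after conv1/conv2 (LRN+pool per AlexNet convention)
                size = (size - pk) // ps + 1
                dims[f"pool{i}"] = size
        return dims

    def _check_skip_spatial(self):
        s = self.spec
        if s.variant == "base":
            return
        names = set(MERGE_SOURCES[s.variant])
        for skips in CONV_SKIP_SOURCES.get(s.variant, {}).values():
            names.update(skips)
        sizes = {n: self.spatial_dims[n] for n in names}
        if len(set(sizes.values())) > 1:
            raise WiringError(
                f"skip wiring requires equal spatial dims, got {sizes} "
                f"(variant {s.variant}, input {s.input_size})")

    # -- forward -------------------------------------------------------------

    def forward(self, x: np.ndarray | Tensor) -> tuple[Tensor, dict[str, Tensor]]:
        """Run the network; returns (logits, named activations)."""
        s = self.spec
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        if x.data.ndim != 4 or x.data.shape[1] != s.input_size or x.data.shape[3] != s.n_channels:
            raise ValueError(
                f"expected input (N,{s.input_size},{s.input_size},{s.n_channels}), got {x.data.shape}")
        p = self.params
        acts: dict[str, Tensor] = {}
        pk, ps = self.pool_geometry
        lp = s.lrn

        def conv(i, inp):
            k, stride, pad = self.conv_geometry[i - 1]
            return nn.relu(nn.conv2d(inp, p[f"conv{i}.weight"], p[f"conv{i}.bias"], stride, pad))

        h = conv(1, x)
        h = nn.maxpool2d(nn.lrn(h, lp.k, lp.n, lp.alpha, lp.beta), pk, ps)
        h = conv(2, h)
        h = nn.maxpool2d(nn.lrn(h, lp.k, lp.n, lp.alpha, lp.beta), pk, ps)
        acts["conv3"] = conv(3, h)
        acts["conv4"] = conv(4, acts["conv3"])
        skips = CONV_SKIP_SOURCES.get(s.variant, {}).get("conv5")
        conv5_in = nn.concat_channels([acts[n] for n in skips]) if skips else acts["conv4"]
        acts["conv5"] = conv(5, conv5_in)

        if s.variant == "base":
            h = nn.maxpool2d(acts["conv5"], pk, ps)
            h = nn.flatten(h)
        else:
            merged = nn.concat_channels([acts[n] for n in MERGE_SOURCES[s.variant]])
            acts["merged"] = merged
            pooled = nn.lp_pool(merged, s.reduction_p)
            acts["pooled"] = pooled
            h = nn.relu(nn.dense(pooled, p["merged.proj.weight"], p["merged.proj.bias"]))
            acts["merged_out"] = h
        for i in range(1, len(s.dense_widths) + 1):
            h = nn.relu(nn.dense(h, p[f"fc{i}.weight"], p[f"fc{i}.bias"]))
        logits = nn.dense(h, p["classifier.weight"], p["classifier.bias"])
        return logits, acts

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Positive-class probabilities for a batch of input tensors."""
        logits, _ = self.forward(x)
        return nn.pair_sigmoid(logits).data

    # -- introspection / state ----------------------------------------------

    def conv_layer_names(self) -> list[str]:
        return [f"conv{i}" for i in range(1, 6)]

    def skip_edges(self) -> list[tuple[str, str]]:
        """All non-sequential (skip) edges as (source, destination) pairs."""
        s = self.spec
        edges = []
        for dst, srcs in CONV_SKIP_SOURCES.get(s.variant, {}).items():
            for src in srcs:
                if _conv_index(src) + 2 != _conv_index(dst) + 1:
                    edges.append((src, dst))
        if s.variant != "base":
            for src in MERGE_SOURCES[s.variant]:
                if src != "conv5":
                    edges.append((src, "merged"))
        return edges

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k!r}")
            if self.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}: {self.params[k].data.shape} vs {v.shape}")
            self.params[k].data = np.asarray(v, dtype=self.dtype).copy()


def _conv_index(name: str) -> int:
    return int(name[4:]) - 1


def build_architecture(spec: ArchitectureSpec, rng: np.random.Generator | None = None,
                       dtype=nn.DEFAULT_DTYPE) -> ModelGraph:
    """Build a ModelGraph for the given architecture specification."""
    return ModelGraph(spec, rng=rng, dtype=dtype)


def summarize_depth_width(model: ModelGraph) -> dict:
    """Structural summary: layer list, conv count and widths, skip edges.

    Sufficient for asserting that a variant changes connectivity only —
    never the depth (number of conv layers) or width (per-conv channels).
    """
    s = model.spec
    layers = []
    for i in range(1, 6):
        layers.append({"name": f"conv{i}", "type": "conv",
                       "out_channels": int(s.conv_widths[i - 1])})
    if s.variant != "base":
        layers.append({"name": "merged", "type": "merged",
                       "out_channels": int(s.merged_width)})
    for i, w in enumerate(s.dense_widths, start=1):
        layers.append({"name": f"fc{i}", "type": "dense", "out_channels": int(w)})
    layers.append({"name": "classifier", "type": "dense", "out_channels": int(s.n_classes)})
    total_edges = 5 + len(s.dense_widths) + 1 + (1 if s.variant != "base" else 0)
    return {
        "variant": s.variant,
        "conv_layer_count": 5,
        "conv_output_channels": [int(w) for w in s.conv_widths],
        "layers": layers,
        "skip_edges": [list(e) for e in model.skip_edges()],
        "n_edges": total_edges + len(model.skip_edges()),
    }


def summary_to_json(summary: dict) -> str:
    return json.dumps(summary, indent=2, sort_keys=True)


def summary_from_json(text: str) -> dict:
    return json.loads(text)
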