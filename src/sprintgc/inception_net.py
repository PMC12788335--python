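"""The per-timestep ground-contact classifier: stacked inception blocks.

Each block runs four parallel convolutional branches with kernel sizes
k in {1, 3, 5, 7} over the (N, C, L) input:

* the k = 1 branch is a single pointwise convolution C_in -> 32;
* the k in {3, 5, 7} branches first apply a pointwise bottleneck
  C_in -> 32, then a kernel-k temporal convolution 32 -> 32.

Branch outputs are concatenated (4 x 32 = 128 channels) and batch-
normalized; a pointwise residual projection C_in -> 128 (also batch-
normalized) is added and the sum passes through ReLU:

    R(x) = BN(W_r * x)
    I(x) = BN([b1(x) || b3(x) || b5(x) || b7(x)])
    y    = ReLU(I(x) + R(x))

There is deliberately no activation or normalization inside the branches.
The first block sees the two resultant channels (C_in = 2); every later
block sees 128. After the last block a pointwise 128 -> 1 convolution with
bias and a sigmoid yield one contact probability per timestep. All
convolutions are same-padded, so the sequence length is preserved
throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from sprintgc.errors import ValidationError
from sprintgc.nn import Adam, BatchNorm1d, Conv1dSame, Parameter, relu, sigmoid


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and optimizer hyperparameters.

    Defaults are the grid-search optimum of the detection study: 18 blocks
    and learning rate 0.01 (window 100 / stride 15 live in the windowing
    configuration, not here).
    """

    n_blocks: int = 18
    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    branch_filters: int = 32
    concat_channels: int = 128
    in_channels: int = 2
    lr: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValidationError("kernel sizes must be odd")

    @property
    def consistent(self) -> bool:
        """concat_channels must equal |kernels| x branch_filters."""
        return len(self.kernel_sizes) * self.branch_filters == self.concat_channels

    def validate(self) -> None:
        if not self.consistent:
            raise ValidationError(
                f"concat_channels {self.concat_channels} != "
                f"{len(self.kernel_sizes)} kernels x {self.branch_filters} filters"
            )


class InceptionBlock:
    """One inception block with residual projection; see module docstring."""

    def __init__(self, in_channels: int, spec: ModelSpec, rng: np.random.Generator, name: str):
        self.in_channels = in_channels
        self.spec = spec
        bf = spec.branch_filters
        self.branches: list[list[Conv1dSame]] = []
        for k in spec.kernel_sizes:
            if k == 1:
                layers = [Conv1dSame(in_channels, bf, 1, rng=rng, name=f"{name}.b1")]
            else:
                layers = [
                    Conv1dSame(in_channels, bf, 1, rng=rng, name=f"{name}.b{k}.bottleneck"),
                    Conv1dSame(bf, bf, k, rng=rng, name=f"{name}.b{k}.conv"),
                ]
            self.branches.append(layers)
        cc = spec.concat_channels
        self.bn_inception = BatchNorm1d(cc, name=f"{name}.bn_inc")
        self.residual_conv = Conv1dSame(in_channels, cc, 1, rng=rng, name=f"{name}.res")
        self.bn_residual = BatchNorm1d(cc, name=f"{name}.bn_res")
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValidationError(
                f"block expects {self.in_channels} input channels, got {x.shape[1]}"
            )
        outs = []
        for layers in self.branches:
            h = x
            for conv in layers:
                h = conv.forward(h, cache=training)
            outs.append(h)
        concat = np.concatenate(outs, axis=1)
        i_out = self.bn_inception.forward(concat, training)
        r_out = self.bn_residual.forward(self.residual_conv.forward(x, cache=training), training)
        y, mask = relu(i_out + r_out)
        self._mask = mask if training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ds = np.where(self._mask, dy, 0.0).astype(np.float32)
        self._mask = None
        dx = self.residual_conv.backward(self.bn_residual.backward(ds))
        dconcat = self.bn_inception.backward(ds)
        bf = self.spec.branch_filters
        for bi, layers in enumerate(self.branches):
            dh = dconcat[:, bi * bf : (bi + 1) * bf, :]
            for conv in reversed(layers):
                dh = conv.backward(dh)
            dx += dh
        return dx

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for layers in self.branches:
            for conv in layers:
                ps += conv.parameters()
        ps += self.bn_inception.parameters()
        ps += self.residual_conv.parameters()
        ps += self.bn_residual.parameters()
        return ps

    def batchnorms(self) -> list[BatchNorm1d]:
        return [self.bn_inception, self.bn_residual]


class GroundContactNet:
    """Stacked inception blocks with a pointwise sigmoid classifier head."""

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.blocks: list[InceptionBlock] = []
        cin = spec.in_channels
        for b in range(spec.n_blocks):
            self.blocks.append(InceptionBlock(cin, spec, rng, name=f"block{b}"))
            cin = spec.concat_channels
        self.head = Conv1dSame(spec.concat_channels, 1, 1, bias=True, rng=rng, name="head")
        self.training = True

    # -- mode -----------------------------------------------------------
    def train(self) -> "GroundContactNet":
        self.training = True
        return self

    def eval(self) -> "GroundContactNet":
        self.training = False
        return self

    # -- forward / backward ---------------------------------------------
    def forward_logits(self, X: np.ndarray) -> np.ndarray:
        """(N, 2, T) features -> (N, T) pre-sigmoid logits."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != self.spec.in_channels:
            raise ValidationError(
                f"expected (N, {self.spec.in_channels}, T) input, got {X.shape}"
            )
        h = X
        for block in self.blocks:
            h = block.forward(h, self.training)
        z = self.head.forward(h, cache=self.training)
        return z[:, 0, :]

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits[:, None, :].astype(np.float32))
        for block in reversed(self.blocks):
            dh = block.backward(dh)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(N, 2, T) -> (N, T) contact probabilities in (0, 1), eval mode."""
        was_training = self.training
        self.eval()
        z = self.forward_logits(X)
        self.training = was_training
        return sigmoid(z)

    # -- parameters & persistence ---------------------------------------
    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for block in self.blocks:
            ps += block.parameters()
        ps += self.head.parameters()
        return ps

    def batchnorms(self) -> list[BatchNorm1d]:
        return [bn for block in self.blocks for bn in block.batchnorms()]

    def make_optimizer(self) -> Adam:
        return Adam(self.parameters(), lr=self.spec.lr)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.parameters()}
        for i, bn in enumerate(self.batchnorms()):
            state[f"running_mean.{i}"] = bn.running_mean.copy()
            state[f"running_var.{i}"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data = np.asarray(state[p.name], dtype=np.float32).copy()
        for i, bn in enumerate(self.batchnorms()):
            bn.running_mean = np.asarray(state[f"running_mean.{i}"], dtype=np.float32).copy()
            bn.running_var = np.asarray(state[f"running_var.{i}"], dtype=np.float32).copy()
            bn.n_updates = max(bn.n_updates, 1)  # restored stats count as set

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        np.savez(path, __spec__=json.dumps(asdict(self.spec)), **self.state_dict())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GroundContactNet":
        with np.load(Path(path), allow_pickle=False) as z:
            raw = json.loads(str(z["__spec__"]))
            raw["kernel_sizes"] = tuple(raw["kernel_sizes"])
            spec = ModelSpec(**raw)
            model = cls(spec)
            model.load_state_dict({k: z[k] for k in z.files if k != "__spec__"})
        return model

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def count_channels(spec: ModelSpec) -> list[dict]:
    """Per-block channel ledger: (C_in, branch, concat, residual) widths.

    Each row carries ``consistent=False`` when the concatenated width does
    not equal |kernels| x branch_filters == concat_channels.
    """
    rows = []
    concat = len(spec.kernel_sizes) * spec.branch_filters
    cin = spec.in_channels
    for b in range(spec.n_blocks):
        rows.append(
            {
                "block": b + 1,
                "c_in": cin,
                "branch_channels": spec.branch_filters,
                "concat_channels": concat,
                "residual_channels": spec.concat_channels,
                "consistent": concat == spec.concat_channels,
            }
        )
        cin = spec.concat_channels
    return rows
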