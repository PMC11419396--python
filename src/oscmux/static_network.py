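"""The non-dynamical letter classifier.

Architecture: a 56x56 image is reduced to 64 first-layer inputs by sliding a
single 28x28 weight kernel per hidden node over the four quadrants with a
stride of 28 and summing (quadrant weight sharing); then a fully connected
64 -> 32 layer and a 3-node softmax output.

Hidden activations use a shifted sigmoid

    h = sigma(z) = 1 / (1 + exp(-a (z - b)))

with fixed slope a = 2 and shift b = 2.5: small inputs give h ~ 0 and inputs
well above 2.5 give h ~ 1, so trained hidden activations are approximately
binary.  The shift is never trained; only the weights are.

Training minimises the softmax cross-entropy with per-image Adam updates
(stochastic gradient descent, one pass over the 132-image set per epoch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import GLYPH_SIZE, IMAGE_SIZE, LabeledDataset, StimulusImage

N_HIDDEN1 = 64
N_HIDDEN2 = 32
N_CLASSES = 3
N_PIXELS = GLYPH_SIZE * GLYPH_SIZE  # inputs per kernel


@dataclass(frozen=True)
class SigmoidParams:
    """Fixed constants of the shifted sigmoid (never trained)."""

    a: float = 2.0
    b: float = 2.5

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"sigmoid slope a must be > 0, got {self.a}")


def shifted_sigmoid(z, params: SigmoidParams = SigmoidParams()):
    """sigma(z) = 1 / (1 + exp(-a (z - b))); strictly increasing, sigma(b)=0.5.

    Saturates gracefully (exp overflow at very negative z yields exactly 0).
    """
    with np.errstate(over="ignore"):
        return 1.0 / (
            1.0 + np.exp(-params.a * (np.asarray(z, dtype=float) - params.b))
        )


def softmax(z: np.ndarray) -> np.ndarray:
    """Class probabilities; max-subtracted for overflow safety."""
    z = np.asarray(z, dtype=float)
    e = np.exp(z - z.max())
    return e / e.sum()


@dataclass
class NetworkWeights:
    """The three trainable weight blocks.

    kernels1 : (64, 28, 28) — one quadrant-shared kernel per layer-1 node
    W2       : (64, 32)
    W3       : (32, 3)
    """

    kernels1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    sigmoid: SigmoidParams = SigmoidParams()

    def validate(self) -> None:
        shapes = {
            "kernels1": (self.kernels1.shape, (N_HIDDEN1, GLYPH_SIZE, GLYPH_SIZE)),
            "W2": (self.W2.shape, (N_HIDDEN1, N_HIDDEN2)),
            "W3": (self.W3.shape, (N_HIDDEN2, N_CLASSES)),
        }
        for name, (got, want) in shapes.items():
            if got != want:
                raise ValueError(f"{name} has shape {got}, expected {want}")
        for name in ("kernels1", "W2", "W3"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite entries in {name}")


@dataclass
class ActivationRecord:
    """Full forward-pass state for one image."""

    z1: np.ndarray
    h1: np.ndarray
    z2: np.ndarray
    h2: np.ndarray
    z_out: np.ndarray
    probs: np.ndarray


def glorot_init(n_in: int, n_out: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform on [-x, x] with x = sqrt(6 / (n_in + n_out))."""
    if n_in < 1 or n_out < 1:
        raise ValueError("n_in and n_out must be >= 1")
    x = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-x, x, size=(n_in, n_out))


def init_weights(seed: int) -> NetworkWeights:
    """Glorot-initialised weights; deterministic per seed."""
    rng = np.random.default_rng(seed)
    k = np.ascontiguousarray(
        glorot_init(N_PIXELS, N_HIDDEN1, rng).T.reshape(
            N_HIDDEN1, GLYPH_SIZE, GLYPH_SIZE
        )
    )
    w2 = glorot_init(N_HIDDEN1, N_HIDDEN2, rng)
    w3 = glorot_init(N_HIDDEN2, N_CLASSES, rng)
    return NetworkWeights(kernels1=k, W2=w2, W3=w3)


def _quadrant_sum(pixels: np.ndarray) -> np.ndarray:
    """Sum of the four 28x28 quadrants (weight sharing collapses them)."""
    if pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
        raise ValueError(f"image must be 56x56, got {pixels.shape}")
    g = GLYPH_SIZE
    return (
        pixels[:g, :g] + pixels[:g, g:] + pixels[g:, :g] + pixels[g:, g:]
    )


def layer1_input(image: StimulusImage | np.ndarray, kernels1: np.ndarray) -> np.ndarray:
    """z1[j] = sum over quadrants of <kernel j, quadrant>.

    Because the kernel is shared across quadrants, this equals the kernel
    dotted with the quadrant sum — making z1 exactly invariant to which
    quadrant a (noiseless) letter occupies.
    """
    pixels = image.pixels if isinstance(image, StimulusImage) else np.asarray(image)
    qsum = _quadrant_sum(pixels).ravel()
    return kernels1.reshape(N_HIDDEN1, -1) @ qsum


def forward_static(
    image: StimulusImage | np.ndarray, weights: NetworkWeights
) -> ActivationRecord:
    """Static forward pass: h1 = sigma(z1), h2 = sigma(h1 W2), probs = softmax(h2 W3)."""
    weights.validate()
    sp = weights.sigmoid
    z1 = layer1_input(image, weights.kernels1)
    h1 = shifted_sigmoid(z1, sp)
    z2 = h1 @ weights.W2
    h2 = shifted_sigmoid(z2, sp)
    z_out = h2 @ weights.W3
    return ActivationRecord(z1, h1, z2, h2, z_out, softmax(z_out))


@dataclass
class TrainConfig:
    """Adam defaults; ``batch_size=1`` is per-image stochastic gradient descent."""

    epochs: int = 20
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _gradients(
    image: StimulusImage, label: int, weights: NetworkWeights
) -> tuple[float, dict[str, np.ndarray], ActivationRecord]:
    """Cross-entropy loss and analytic gradients for one image."""
    rec = forward_static(image, weights)
    a = weights.sigmoid.a
    loss = -float(np.log(rec.probs[label]))

    d_out = rec.probs.copy()
    d_out[label] -= 1.0                      # dL/dz_out
    g_w3 = np.outer(rec.h2, d_out)
    d_h2 = weights.W3 @ d_out
    d_z2 = d_h2 * a * rec.h2 * (1.0 - rec.h2)
    g_w2 = np.outer(rec.h1, d_z2)
    d_h1 = weights.W2 @ d_z2
    d_z1 = d_h1 * a * rec.h1 * (1.0 - rec.h1)
    qsum = _quadrant_sum(image.pixels).ravel()
    g_k = np.outer(d_z1, qsum).reshape(weights.kernels1.shape)
    return loss, {"kernels1": g_k, "W2": g_w2, "W3": g_w3}, rec


class _Adam:
    """Adam optimiser state for one named set of weight blocks."""

    def __init__(self, blocks: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in blocks.items()}
        self.v = {k: np.zeros_like(v) for k, v in blocks.items()}

    def step(self, blocks: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bias1 = 1.0 - c.beta1 ** self.t
        bias2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            blocks[k] -= (
                c.learning_rate
                * (self.m[k] / bias1)
                / (np.sqrt(self.v[k] / bias2) + c.eps)
            )


def evaluate(weights: NetworkWeights, dataset: LabeledDataset) -> tuple[float, float]:
    """(accuracy, mean cross-entropy loss) over a dataset."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    correct = 0
    losses = []
    for image, label in dataset.items:
        rec = forward_static(image, weights)
        losses.append(-np.log(rec.probs[label]))
        correct += int(np.argmax(rec.probs) == label)
    return correct / len(dataset), float(np.mean(losses))


def train_network(
    dataset: LabeledDataset, config: TrainConfig = TrainConfig()
) -> tuple[NetworkWeights, list[float]]:
    """Train with per-image Adam updates; returns weights and per-epoch mean loss.

    Only the three weight blocks are updated; the sigmoid constants stay
    fixed.  The per-epoch loss is the mean cross-entropy over the dataset
    re-evaluated after the epoch.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    weights = init_weights(config.seed)
    blocks = {"kernels1": weights.kernels1, "W2": weights.W2, "W3": weights.W3}
    opt = _Adam(blocks, config)
    rng = np.random.default_rng(config.seed + 1)

    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        for i0 in range(0, len(order), config.batch_size):
            batch = order[i0 : i0 + config.batch_size]
            summed: dict[str, np.ndarray] | None = None
            for i in batch:
                image, label = dataset.items[i]
                loss, grads, _ = _gradients(image, label, weights)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                if summed is None:
                    summed = {k: g.copy() for k, g in grads.items()}
                else:
                    for k, g in grads.items():
                        summed[k] += g
            assert summed is not None
            for k in summed:
                summed[k] /= len(batch)
            opt.step(blocks, summed)
        _, mean_loss = evaluate(weights, dataset)
        trace.append(mean_loss)
    return weights, trace
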