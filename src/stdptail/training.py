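"""Unsupervised training loop, class assignment, inference and metrics.

Training presents the dataset in its randomized order with plasticity on
and records a snapshot of the flattened plastic weight vector at every
iteration boundary (an iteration = a fixed number of images).  The
snapshot sequence is the learning trajectory whose final-iteration
increments feed the tail-index / BG-index analysis.

Evaluation freezes the network (learning rate zero, thresholds fixed),
assigns each excitatory neuron the class it responds to most strongly,
and predicts by the class whose assigned neurons fire most on average.
The generalization error is the absolute difference between training and
test accuracy in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import LabeledImageSet, image_rates, partition_iterations
from .lif import NeuronParams, NetworkTopology, run_presentation, BoostDivergence
from .stdp import STDPConfig

__all__ = [
    "TrainSchedule",
    "WeightTrajectory",
    "TrainRun",
    "train",
    "assign_classes",
    "predict",
    "class_responses",
    "accuracy",
    "training_loss",
    "cross_entropy_loss",
    "class_probabilities_from_counts",
    "generalization_error",
    "UNRESPONSIVE",
]

UNRESPONSIVE = -1  # sentinel class for neurons that never spike


@dataclass
class TrainSchedule:
    """Presentation protocol: images per iteration and timing constants."""

    images_per_iteration: int = 60
    max_iterations: int | None = None
    duration: float = 350.0
    dt: float = 0.5
    rest_interval: float = 150.0
    gain_divisor: float = 4.0
    min_spikes: int = 5
    boost_hz: float = 32.0
    boost_cap: int = 20

    @property
    def rate_ceiling(self) -> float:
        return 255.0 / self.gain_divisor


@dataclass
class WeightTrajectory:
    """Time-ordered weight snapshots across training iterations."""

    snapshots: np.ndarray  # (n_iterations + 1, n_weights)
    iteration_index: np.ndarray

    def __post_init__(self) -> None:
        self.snapshots = np.asarray(self.snapshots, dtype=float)
        self.iteration_index = np.asarray(self.iteration_index, dtype=int)
        if self.snapshots.ndim != 2:
            raise ValueError("snapshots must be 2-D (n_snapshots, n_weights)")

    @property
    def increments(self) -> np.ndarray:
        return np.diff(self.snapshots, axis=0)

    def save(self, path) -> None:
        """Write snapshots as an .npz container plus a CSV manifest.

        The container holds named entries ``snapshots`` and
        ``iteration_index``; the sidecar ``<path>.manifest.csv`` lists one
        row per snapshot (iteration index, weight count, L2 norm) for
        quick inspection without loading the arrays.
        """
        import pathlib

        path = pathlib.Path(path)
        np.savez_compressed(
            path, snapshots=self.snapshots, iteration_index=self.iteration_index
        )
        manifest = path.with_suffix(path.suffix + ".manifest.csv")
        with open(manifest, "w") as fh:
            fh.write("iteration,n_weights,l2_norm\n")
            for k, snap in zip(self.iteration_index, self.snapshots):
                fh.write(f"{k},{snap.size},{np.linalg.norm(snap):.8g}\n")

    @classmethod
    def load(cls, path) -> "WeightTrajectory":
        with np.load(path) as data:
            return cls(
                snapshots=data["snapshots"],
                iteration_index=data["iteration_index"],
            )


@dataclass
class TrainRun:
    """Everything produced by one training run."""

    topology: NetworkTopology
    trajectory: WeightTrajectory
    exc_params: NeuronParams
    inh_params: NeuronParams
    schedule: TrainSchedule
    stdp: STDPConfig
    theta: np.ndarray
    class_map: np.ndarray | None = None
    train_accuracy: float | None = None
    test_accuracy: float | None = None
    per_iteration_loss: list = field(default_factory=list)

    @property
    def generalization_error(self) -> float | None:
        if self.train_accuracy is None or self.test_accuracy is None:
            return None
        return generalization_error(self.train_accuracy, self.test_accuracy)


def train(
    dataset: LabeledImageSet,
    topology: NetworkTopology,
    exc_params: NeuronParams,
    inh_params: NeuronParams,
    stdp_cfg: STDPConfig,
    schedule: TrainSchedule | None = None,
    seed: int | None = None,
) -> TrainRun:
    """Train the network on the dataset's presentation stream.

    Weights are snapshotted before training and after every iteration
    boundary.  All stochastic elements (input encoding, update noise)
    derive from ``seed``.  Raises on divergent (non-finite) weights,
    naming the iteration.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    sched = schedule or TrainSchedule()
    rng = np.random.default_rng(seed)
    topo = topology.copy()
    slices = partition_iterations(dataset, sched.images_per_iteration)
    if sched.max_iterations is not None:
        slices = slices[: sched.max_iterations]
    snapshots = [topo.input_to_exc.ravel().copy()]
    carry = (None, None, None)
    for it, (subset, _short) in enumerate(slices):
        for img in subset.images:
            rates = image_rates(img, sched.gain_divisor)
            try:
                _, topo, carry = run_presentation(
                    topo, exc_params, inh_params, stdp_cfg, rates,
                    duration=sched.duration, dt=sched.dt, rng=rng,
                    exc_state=carry[0], inh_state=carry[1], traces=carry[2],
                    min_spikes=sched.min_spikes, boost_hz=sched.boost_hz,
                    rate_ceiling=sched.rate_ceiling, boost_cap=sched.boost_cap,
                    rest_interval=sched.rest_interval,
                )
            except BoostDivergence as err:
                raise BoostDivergence(f"iteration {it}: {err}") from err
        if not np.isfinite(topo.input_to_exc).all():
            raise FloatingPointError(f"non-finite weights at iteration {it}")
        snapshots.append(topo.input_to_exc.ravel().copy())
    trajectory = WeightTrajectory(
        snapshots=np.asarray(snapshots),
        iteration_index=np.arange(len(snapshots)),
    )
    theta = carry[0].theta.copy() if carry[0] is not None else np.zeros(topo.n_exc)
    return TrainRun(
        topology=topo, trajectory=trajectory,
        exc_params=exc_params, inh_params=inh_params,
        schedule=sched, stdp=stdp_cfg, theta=theta,
    )


def _frozen_params(run: TrainRun) -> NeuronParams:
    """Evaluation-time excitatory parameters: thresholds fixed.

    theta stays at its trained value but no longer grows or decays
    (theta_inc = 0, tau_theta effectively infinite).
    """
    from dataclasses import replace

    return replace(run.exc_params, theta_inc=0.0, tau_theta=1e12)


def _eval_counts(
    run: TrainRun,
    images: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-image spike counts of every excitatory neuron, learning frozen."""
    from .lif import NeuronState

    sched = run.schedule
    exc_params = _frozen_params(run)
    counts = np.empty((len(images), run.topology.n_exc), dtype=np.int64)
    exc0 = NeuronState.resting(run.topology.n_exc, exc_params)
    exc0.theta[:] = run.theta  # thresholds fixed at their trained values
    carry = (exc0, None, None)
    for k, img in enumerate(images):
        rates = image_rates(img, sched.gain_divisor)
        c, _, carry = run_presentation(
            run.topology, exc_params, run.inh_params, None, rates,
            duration=sched.duration, dt=sched.dt, rng=rng,
            exc_state=carry[0], inh_state=carry[1], traces=carry[2],
            min_spikes=sched.min_spikes, boost_hz=sched.boost_hz,
            rate_ceiling=sched.rate_ceiling, boost_cap=sched.boost_cap,
            rest_interval=sched.rest_interval,
        )
        counts[k] = c
    return counts


def class_responses(
    run: TrainRun,
    dataset: LabeledImageSet,
    seed: int | None = None,
) -> np.ndarray:
    """Mean spike count of each neuron per class: (n_classes, n_exc)."""
    rng = np.random.default_rng(seed)
    counts = _eval_counts(run, dataset.images, rng)
    n_classes = dataset.n_classes
    out = np.zeros((n_classes, run.topology.n_exc))
    for c in range(n_classes):
        mask = dataset.labels == c
        if mask.any():
            out[c] = counts[mask].mean(axis=0)
    return out


def assign_classes(
    run: TrainRun,
    dataset: LabeledImageSet,
    seed: int | None = None,
) -> np.ndarray:
    """Assign each excitatory neuron the class of its highest mean response.

    Ties break toward the lowest class index; neurons silent on every
    class get the ``UNRESPONSIVE`` sentinel and are excluded from
    prediction.
    """
    responses = class_responses(run, dataset, seed=seed)
    class_map = responses.argmax(axis=0).astype(int)
    silent = responses.sum(axis=0) == 0
    class_map[silent] = UNRESPONSIVE
    return class_map


def predict_from_counts(counts: np.ndarray, class_map: np.ndarray, n_classes: int) -> int:
    """Argmax over classes of the mean spike count of assigned neurons."""
    means = np.full(n_classes, -np.inf)
    for c in range(n_classes):
        mask = class_map == c
        if mask.any():
            means[c] = counts[mask].mean()
    if not np.isfinite(means).any() or counts[class_map != UNRESPONSIVE].sum() == 0:
        raise ValueError("no responsive assigned neuron spiked; cannot predict")
    return int(means.argmax())


def predict(
    run: TrainRun,
    class_map: np.ndarray,
    image: np.ndarray,
    n_classes: int,
    seed: int | None = None,
) -> int:
    """Predict the class of a single image with the frozen network."""
    if (class_map == UNRESPONSIVE).all():
        raise ValueError("class map has no responsive neurons")
    rng = np.random.default_rng(seed)
    counts = _eval_counts(run, image[None], rng)[0]
    return predict_from_counts(counts, class_map, n_classes)


def accuracy(
    run: TrainRun,
    class_map: np.ndarray,
    dataset: LabeledImageSet,
    seed: int | None = None,
) -> float:
    """Classification accuracy (%) over a labeled set, frozen network."""
    rng = np.random.default_rng(seed)
    counts = _eval_counts(run, dataset.images, rng)
    n_classes = max(dataset.n_classes, int(class_map.max()) + 1)
    correct = 0
    for k in range(len(dataset)):
        try:
            pred = predict_from_counts(counts[k], class_map, n_classes)
        except ValueError:
            continue
        correct += pred == dataset.labels[k]
    return 100.0 * correct / len(dataset)


def class_probabilities_from_counts(
    counts: np.ndarray, class_map: np.ndarray, n_classes: int, eps: float = 1e-9
) -> np.ndarray:
    """Per-class response distribution for one image.

    The mean spike count of each class's assigned neurons is divided by
    the maximum (max-normalization), then smoothed by ``eps`` and
    renormalized to sum to one so it forms a probability vector.  An
    all-silent response falls back to the uniform distribution.
    """
    per_class = np.zeros(n_classes)
    for c in range(n_classes):
        mask = class_map == c
        if mask.any():
            per_class[c] = counts[mask].mean()
    m = per_class.max()
    if m <= 0:
        return np.full(n_classes, 1.0 / n_classes)
    p = per_class / m + eps
    return p / p.sum()


def cross_entropy_loss(counts: np.ndarray, class_map: np.ndarray, label: int,
                       n_classes: int, eps: float = 1e-9) -> float:
    """Cross-entropy of the max-normalized response against the true label."""
    p = class_probabilities_from_counts(counts, class_map, n_classes, eps)
    return float(-np.log(p[label]))


def training_loss(
    run: TrainRun,
    class_map: np.ndarray,
    subset: LabeledImageSet,
    n_repeats: int = 5,
    seed: int | None = None,
    eps: float = 1e-9,
):
    """Cross-entropy loss of max-normalized class responses, with spread.

    Per image the per-class mean spike counts (over that class's assigned
    neurons) are divided by their maximum, renormalized to sum to one
    (with additive smoothing ``eps``), and scored by cross-entropy against
    the true label.  The subset is evaluated ``n_repeats`` times with
    shuffled presentation order; returns ``(mean_loss, std_over_repeats)``.
    Images on which no assigned neuron spikes fall back to a uniform
    distribution.
    """
    if len(subset) == 0:
        raise ValueError("subset is empty")
    rng = np.random.default_rng(seed)
    n_classes = max(subset.n_classes, int(class_map.max()) + 1)
    losses = []
    for _ in range(n_repeats):
        order = rng.permutation(len(subset))
        counts = _eval_counts(run, subset.images[order], rng)
        total = 0.0
        for k, idx in enumerate(order):
            total += cross_entropy_loss(counts[k], class_map, subset.labels[idx],
                                        n_classes, eps)
        losses.append(total / len(subset))
    losses = np.asarray(losses)
    return float(losses.mean()), float(losses.std())


def generalization_error(train_acc: float, test_acc: float) -> float:
    """|train - test| accuracy, percentage points."""
    for v in (train_acc, test_acc):
        if not 0.0 <= v <= 100.0:
            raise ValueError("accuracies must lie in [0, 100]")
    return abs(train_acc - test_acc)
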