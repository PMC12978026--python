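"""The four-cluster Gaussian classification task and input perturbations.

The circuit's "environment" is a deliberately easy problem: four Gaussian
clusters in the plane, one per class, centred at (-3,-3), (3,3), (-3,3) and
(3,-3) with within-cluster spread 0.8.  A healthy dense network solves it
essentially perfectly, so every later deficit is attributable to pruning,
noise, or their combination rather than task difficulty.

Three splits are generated: a training set, a "clean" test set (held-out
draws from the intrinsic cluster distribution, no added perturbation) and a
"standard" test set (clean-process draws plus additive Gaussian input jitter,
the everyday noisy condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._streams import substream

CANONICAL_CENTERS = ((-3.0, -3.0), (3.0, 3.0), (-3.0, 3.0), (3.0, -3.0))


@dataclass(frozen=True)
class ClusterSpec:
    """Geometry of the class-conditional Gaussians."""

    centers: tuple[tuple[float, float], ...] = CANONICAL_CENTERS
    cluster_sigma: float = 0.8

    def __post_init__(self) -> None:
        if self.cluster_sigma < 0:
            raise ValueError(f"cluster_sigma must be >= 0, got {self.cluster_sigma}")
        if len(self.centers) < 2:
            raise ValueError("need at least 2 cluster centers")

    @property
    def n_classes(self) -> int:
        return len(self.centers)


@dataclass
class DatasetBundle:
    """Train / standard-test / clean-test splits with labels."""

    train: tuple[np.ndarray, np.ndarray]
    test_standard: tuple[np.ndarray, np.ndarray]
    test_clean: tuple[np.ndarray, np.ndarray]
    spec: ClusterSpec = field(default_factory=ClusterSpec)
    seed: int = 42

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return {"train": self.train, "standard": self.test_standard,
                    "clean": self.test_clean}[name]
        except KeyError:
            raise ValueError(f"unknown split {name!r}") from None


def _draw_cluster_points(
    spec: ClusterSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced round-robin labels, Gaussian points, then an in-stream shuffle."""
    k = spec.n_classes
    labels = np.arange(n) % k  # round-robin => balanced to +-1
    centers = np.asarray(spec.centers, dtype=np.float64)
    points = centers[labels] + rng.normal(0.0, spec.cluster_sigma, size=(n, 2))
    order = rng.permutation(n)
    return points[order].astype(np.float32), labels[order].astype(np.int64)


def add_input_noise(
    points: np.ndarray, sigma: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Return ``points`` plus i.i.d. N(0, sigma^2) per coordinate (copy; input untouched)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    points = np.asarray(points)
    if sigma == 0:
        return points.copy()
    if rng is None:
        raise ValueError("an rng (Generator or seed) is required when sigma > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return (points + rng.normal(0.0, sigma, size=points.shape)).astype(points.dtype)


def generate_dataset(
    spec: ClusterSpec | None = None,
    n_train: int = 12_000,
    n_test_standard: int = 4_000,
    n_test_clean: int = 2_000,
    input_noise_sigma_standard: float = 0.8,
    seed: int = 42,
) -> DatasetBundle:
    """Generate the canonical 12,000 / 4,000 / 2,000 dataset bundle.

    The standard test split is drawn by the clean process and then perturbed
    with additive input noise of ``input_noise_sigma_standard``.  The same
    seed always regenerates a bit-identical bundle.
    """
    spec = spec or ClusterSpec()
    for name, n in (("n_train", n_train), ("n_test_standard", n_test_standard),
                    ("n_test_clean", n_test_clean)):
        if n <= 0:
            raise ValueError(f"{name} must be positive, got {n}")
    if input_noise_sigma_standard < 0:
        raise ValueError("input_noise_sigma_standard must be >= 0")

    rng = substream(seed, "data")
    train = _draw_cluster_points(spec, n_train, rng)
    clean = _draw_cluster_points(spec, n_test_clean, rng)
    std_pts, std_labels = _draw_cluster_points(spec, n_test_standard, rng)
    std_pts = add_input_noise(std_pts, input_noise_sigma_standard, rng)
    return DatasetBundle(
        train=train,
        test_standard=(std_pts, std_labels),
        test_clean=clean,
        spec=spec,
        seed=seed,
    )


def bundle_to_frame(bundle: DatasetBundle) -> pd.DataFrame:
    """Flatten a bundle to a tidy frame (columns x1, x2, label, split)."""
    frames = []
    for split in ("train", "standard", "clean"):
        pts, labels = bundle.split(split)
        frames.append(pd.DataFrame(
            {"x1": pts[:, 0], "x2": pts[:, 1], "label": labels, "split": split}))
    return pd.concat(frames, ignore_index=True)


def write_bundle_csv(bundle: DatasetBundle, path) -> None:
    bundle_to_frame(bundle).to_csv(path, index=False)


def read_bundle_csv(path, spec: ClusterSpec | None = None, seed: int = 42) -> DatasetBundle:
    df = pd.read_csv(path)
    parts = {}
    for split in ("train", "standard", "clean"):
        sub = df[df["split"] == split]
        parts[split] = (
            sub[["x1", "x2"]].to_numpy(dtype=np.float32),
            sub["label"].to_numpy(dtype=np.int64),
        )
    return DatasetBundle(train=parts["train"], test_standard=parts["standard"],
                         test_clean=parts["clean"], spec=spec or ClusterSpec(), seed=seed)


def quadrant_accuracy(points: np.ndarray, labels: np.ndarray,
                      spec: ClusterSpec | None = None) -> float:
    """Accuracy (%) of the Bayes-optimal nearest-center classifier.

    With equal priors and isotropic equal-variance clusters this is the
    Bayes rule; for the canonical (+-3, +-3) layout it reduces to reading
    the signs of the two coordinates.
    """
    spec = spec or ClusterSpec()
    centers = np.asarray(spec.centers, dtype=np.float64)
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float((d2.argmin(axis=1) == labels).mean() * 100.0)
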