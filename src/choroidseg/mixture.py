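"""Gaussian mixture modeling of wavelet texture descriptors.

Three full-covariance Gaussians over the 5-D descriptors represent the
area above Bruch's membrane, the choroid, and the area beneath the
choroid-sclera interface.  The primary fitting path is supervised
moment estimation from labeled training masks -- the class means,
covariances and pixel-fraction weights are computed directly, pooled
over all training images -- so no per-image EM is needed at test time.
A standard EM refinement is available as an alternative.  Per-pixel
posterior class probabilities (responsibilities) feed the graph-cut
stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .wavelet import FeatureStack

__all__ = [
    "LabelMask",
    "GaussianComponent",
    "MixtureModel",
    "ResponsibilityMaps",
    "gaussian_density",
    "fit_from_masks",
    "em_refine",
    "responsibilities",
]

log = logging.getLogger(__name__)

#: label values used in training masks and output label maps
LABEL_ABOVE_BM = 1
LABEL_CHOROID = 2
LABEL_BELOW_CSI = 3


@dataclass
class LabelMask:
    """Per-pixel class labels: 0 unlabeled, 1 above-BM, 2 choroid, 3 below-CSI."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.isin(np.unique(self.labels), [0, 1, 2, 3]).all():
            raise ValueError("mask values must be in {0, 1, 2, 3}")


@dataclass
class GaussianComponent:
    """One weighted multivariate normal component."""

    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        n = self.mean.size
        if self.covariance.shape != (n, n):
            raise ValueError("covariance shape must match the mean's dimension")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError("component weight must be in (0, 1]")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")

    def require_spd(self, name: str = "component") -> None:
        try:
            np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"covariance of {name} is not positive-definite"
            ) from exc


@dataclass
class MixtureModel:
    """Weighted sum of Gaussian components, ordered by class label."""

    components: list[GaussianComponent]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in self.components)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"component weights sum to {total}, expected 1")
        dims = {c.mean.size for c in self.components}
        if len(dims) != 1:
            raise ValueError("all components must share one dimensionality")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def n_dims(self) -> int:
        return self.components[0].mean.size

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "n_dims": self.n_dims,
            "K": self.K,
            "components": [
                {
                    "weight": float(c.weight),
                    "mean": c.mean.tolist(),
                    "covariance": c.covariance.tolist(),
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        comps = [
            GaussianComponent(
                weight=c["weight"],
                mean=np.asarray(c["mean"]),
                covariance=np.asarray(c["covariance"]),
            )
            for c in d["components"]
        ]
        return cls(components=comps)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        return cls.from_dict(json.loads(text))


@dataclass
class ResponsibilityMaps:
    """Per-pixel posterior class probabilities, shape ``(K, rows, cols)``."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise ValueError("responsibilities must be (K, rows, cols)")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pixel responsibilities must sum to 1")

    @property
    def K(self) -> int:
        return self.probs.shape[0]


def _component_logpdf(X: np.ndarray, comp: GaussianComponent, name: str) -> np.ndarray:
    comp.require_spd(name)
    # scipy squeezes single-point output to a scalar; keep it 1-D
    return np.atleast_1d(
        multivariate_normal(mean=comp.mean, cov=comp.covariance).logpdf(X)
    )


def gaussian_density(x: np.ndarray, component: GaussianComponent) -> float:
    """Multivariate normal density of one descriptor under one component.

    Evaluated through a stable factorization rather than an explicit
    matrix inverse.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != component.mean.size:
        raise ValueError("descriptor dimension does not match the component")
    return float(np.exp(_component_logpdf(x[None, :], component, "component")[0]))


def fit_from_masks(
    features: list[FeatureStack] | FeatureStack,
    masks: list[LabelMask] | LabelMask,
    ridge: float = 1e-6,
    n_classes: int = 3,
) -> MixtureModel:
    """Supervised moment fit of the mixture from labeled training images.

    For every class the mean and (biased, denominator N_k) covariance of
    its descriptors, pooled over all training images, become the
    component parameters; the weight is the class's fraction of labeled
    pixels.  A small ridge, scaled by the covariance's mean eigenvalue,
    keeps the covariance positive-definite on small training sets.
    Unlabeled (0) pixels are ignored.
    """
    if isinstance(features, FeatureStack):
        features = [features]
    if isinstance(masks, LabelMask):
        masks = [masks]
    if len(features) != len(masks) or not features:
        raise ValueError("need matching, non-empty feature and mask lists")

    n_dims = features[0].n_features
    per_class: dict[int, list[np.ndarray]] = {k: [] for k in range(1, n_classes + 1)}
    for fs, mask in zip(features, masks):
        if mask.labels.shape != fs.image_shape:
            raise ValueError("mask shape does not match its feature stack")
        desc = fs.descriptors()
        flat = mask.labels.ravel()
        for k in per_class:
            sel = desc[flat == k]
            if sel.size:
                per_class[k].append(sel)

    components = []
    counts = {}
    for k in range(1, n_classes + 1):
        if not per_class[k]:
            raise ValueError(f"training data contains no pixels of class {k}")
        X = np.concatenate(per_class[k], axis=0)
        if X.shape[0] < n_dims + 1:
            raise ValueError(
                f"class {k} has {X.shape[0]} labeled pixels; at least "
                f"{n_dims + 1} are needed for a full-rank covariance"
            )
        counts[k] = X.shape[0]
        mean = X.mean(axis=0)
        centered = X - mean
        cov = centered.T @ centered / X.shape[0]
        if np.linalg.matrix_rank(cov) == 0:
            raise ValueError(
                f"class {k} descriptors are all identical; covariance has zero rank"
            )
        cov = cov + ridge * (np.trace(cov) / n_dims) * np.eye(n_dims)
        comp = GaussianComponent(weight=1.0, mean=mean, covariance=cov)
        comp.require_spd(f"class {k}")
        components.append(comp)

    total = sum(counts.values())
    for k, comp in zip(sorted(counts), components):
        comp.weight = counts[k] / total
    return MixtureModel(components=components)


def _log_joint(X: np.ndarray, model: MixtureModel) -> np.ndarray:
    """log(pi_k) + log p(x | component k), shape (N, K)."""
    cols = []
    for k, comp in enumerate(model.components, start=1):
        cols.append(np.log(comp.weight) + _component_logpdf(X, comp, f"class {k}"))
    return np.stack(cols, axis=1)


def em_refine(
    features: FeatureStack,
    model: MixtureModel,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MixtureModel:
    """Standard EM refinement of a mixture on one image's descriptors.

    E-step: posterior responsibilities; M-step: weight = mean
    responsibility, mean and covariance = responsibility-weighted
    moments.  Stops when the relative log-likelihood change drops below
    ``tol`` or after ``max_iter`` iterations.  The data log-likelihood
    is checked to be non-decreasing at every step.
    """
    X = features.descriptors()
    n = X.shape[0]
    current = model
    prev_ll = -np.inf
    for it in range(max_iter):
        lj = _log_joint(X, current)
        lse = logsumexp(lj, axis=1)
        ll = float(lse.sum())
        if ll < prev_ll - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
        resp = np.exp(lj - lse[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk / n < 1e-8):
            bad = int(np.argmin(nk))
            raise ValueError(
                f"component {bad + 1} collapsed (weight < 1e-8) at iteration {it}"
            )
        new_components = []
        for k in range(current.K):
            mean = resp[:, k] @ X / nk[k]
            centered = X - mean
            cov = (resp[:, k][:, None] * centered).T @ centered / nk[k]
            cov = (cov + cov.T) / 2
            comp = GaussianComponent(weight=nk[k] / n, mean=mean, covariance=cov)
            try:
                comp.require_spd(f"component {k + 1}")
            except ValueError as exc:
                raise ValueError(
                    f"component {k + 1} covariance lost positive-definiteness "
                    f"at iteration {it}"
                ) from exc
            new_components.append(comp)
        current = MixtureModel(components=new_components)
    return current


def responsibilities(model: MixtureModel, features: FeatureStack) -> ResponsibilityMaps:
    """Posterior class probability of every pixel under the mixture.

    Computed in log space so well-separated classes do not underflow.
    Pixels where every component's density underflows to exact zero get
    a uniform posterior; their count is logged.
    """
    if features.n_features != model.n_dims:
        raise ValueError(
            f"descriptors have {features.n_features} dimensions but the "
            f"model expects {model.n_dims}"
        )
    X = features.descriptors()
    lj = _log_joint(X, model)
    lse = logsumexp(lj, axis=1)
    degenerate = ~np.isfinite(lse)
    if degenerate.any():
        log.warning(
            "%d pixel(s) had zero density under every component; "
            "uniform posterior assigned",
            int(degenerate.sum()),
        )
        lj[degenerate] = 0.0
        lse[degenerate] = np.log(model.K)
    probs = np.exp(lj - lse[:, None])
    shape = features.image_shape
    return ResponsibilityMaps(probs=probs.T.reshape(model.K, *shape))
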