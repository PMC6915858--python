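"""Gaussian mixture decomposition of paralog similarity distributions.

The distribution of percent similarities between syntenic paralogs is a
mixture of normal components, one per polyploidy event (older event = lower
mean).  This module fits such mixtures by EM — with optional fixed component
means, as used when an event's peak is identified a priori — and computes the
maximum-likelihood *transition points* H between adjacent components: the
cutoff maximizing the product of the lower component's density over
similarities at or below H and the upper component's density over those
above it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixtureComponent:
    """One normal component of the similarity mixture (percent scale)."""

    mean: float
    sd: float
    proportion: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 100.0:
            raise ValueError(f"component mean {self.mean} outside (0, 100)")
        if self.sd <= 0:
            raise ValueError("component sd must be positive")
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError("component proportion must be in (0, 1]")


@dataclass(frozen=True)
class MixtureModel:
    """Components ascending by mean; component k corresponds to event k."""

    components: Tuple[MixtureComponent, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        means = [c.mean for c in comps]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("component means must be strictly increasing")
        if abs(sum(c.proportion for c in comps) - 1.0) > 1e-9:
            raise ValueError("component proportions must sum to 1")
        object.__setattr__(self, "components", comps)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component(self, event: int) -> MixtureComponent:
        """Component for 1-based event index (oldest event = lowest mean)."""
        return self.components[event - 1]

    @property
    def means(self) -> Tuple[float, ...]:
        return tuple(c.mean for c in self.components)

    def to_dict(self) -> dict:
        return {
            "components": [
                {"mean": c.mean, "sd": c.sd, "proportion": c.proportion}
                for c in self.components
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MixtureModel":
        return cls(
            tuple(
                MixtureComponent(d["mean"], d["sd"], d["proportion"])
                for d in data["components"]
            )
        )


@dataclass(frozen=True)
class TransitionPoints:
    """ML cutoffs H_1 < ... < H_{k-1} plus optional pre-filter exclusions."""

    cutoffs: Tuple[float, ...]
    low_exclusion: Optional[float] = None
    high_exclusion: Optional[float] = None

    def __post_init__(self) -> None:
        cuts = tuple(float(h) for h in self.cutoffs)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        if any(not 0.0 < h < 100.0 for h in cuts):
            raise ValueError("cutoffs must lie in (0, 100)")
        if cuts:
            if self.low_exclusion is not None and self.low_exclusion >= cuts[0]:
                raise ValueError("low exclusion must fall below the first cutoff")
            if self.high_exclusion is not None and self.high_exclusion <= cuts[-1]:
                raise ValueError("high exclusion must exceed the last cutoff")
        object.__setattr__(self, "cutoffs", cuts)

    @property
    def n_events(self) -> int:
        return len(self.cutoffs) + 1

    def classify(self, x: float) -> int:
        return classify_similarity(x, self)

    def to_dict(self) -> dict:
        return {
            "cutoffs": list(self.cutoffs),
            "exclusions": {"low": self.low_exclusion, "high": self.high_exclusion},
        }


def serialize_fit(mixture: MixtureModel, cutoffs: TransitionPoints) -> str:
    """JSON block with components, cutoffs and exclusions."""
    return json.dumps({**mixture.to_dict(), **cutoffs.to_dict()}, indent=2)


def deserialize_fit(text: str) -> Tuple[MixtureModel, TransitionPoints]:
    data = json.loads(text)
    excl = data.get("exclusions", {})
    return (
        MixtureModel.from_dict(data),
        TransitionPoints(
            tuple(data["cutoffs"]),
            low_exclusion=excl.get("low"),
            high_exclusion=excl.get("high"),
        ),
    )


class GaussianMixture1D(BaseEstimator):
    """Univariate Gaussian mixture fitted by EM, with optional fixed means.

    Parameters
    ----------
    n_components:
        Number of components k (one per hypothesized polyploidy event).
    fixed_means:
        Optional sequence of means to hold exactly during EM.  Give either
        one value per component (``None`` entries stay free) or fewer values
        than components, which pins the lowest components and leaves the
        rest free.  Must be strictly increasing.
    max_iter, tol:
        EM stopping rule: stop when the mean log-likelihood improves by less
        than ``tol`` or after ``max_iter`` iterations.
    sd_floor:
        Lower bound (percent) applied to component standard deviations to
        prevent degenerate collapse.

    Attributes
    ----------
    means_, sds_, weights_ : fitted parameters, components sorted ascending
        by initial mean (free means may reorder; ``to_model`` re-sorts).
    log_likelihood_ : total data log-likelihood of the final fit.
    log_likelihood_path_ : per-iteration log-likelihoods (non-decreasing).
    n_iter_, converged_
    """

    def __init__(
        self,
        n_components: int = 2,
        fixed_means: Optional[Sequence[Optional[float]]] = None,
        max_iter: int = 500,
        tol: float = 1e-8,
        sd_floor: float = 1e-2,
        random_state: Optional[int] = None,
    ):
        self.n_components = n_components
        self.fixed_means = fixed_means
        self.max_iter = max_iter
        self.tol = tol
        self.sd_floor = sd_floor
        self.random_state = random_state

    def _validate_fixed(self) -> List[Optional[float]]:
        k = self.n_components
        if self.fixed_means is None:
            return [None] * k
        fixed = list(self.fixed_means)
        if len(fixed) > k:
            raise ValueError("more fixed means than components")
        fixed = fixed + [None] * (k - len(fixed))
        given = [m for m in fixed if m is not None]
        if any(b <= a for a, b in zip(given, given[1:])):
            raise ValueError("fixed means must be strictly increasing")
        return fixed

    def fit(self, X, y=None) -> "GaussianMixture1D":
        x = np.asarray(X, dtype=float).ravel()
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if x.size < 10 * k:
            raise ValueError(
                f"need at least {10 * k} observations to fit {k} components"
            )
        if np.ptp(x) == 0.0:
            raise ValueError("all observations identical: degenerate sd")
        fixed = self._validate_fixed()

        # deterministic initialization: quantile means, pooled sd, equal weights
        means = np.quantile(x, (np.arange(k) + 0.5) / k)
        for j, fm in enumerate(fixed):
            if fm is not None:
                means[j] = fm
        pooled = max(float(np.std(x)), self.sd_floor)
        sds = np.full(k, pooled / max(k, 1))
        sds = np.maximum(sds, self.sd_floor)
        weights = np.full(k, 1.0 / k)

        loglik_path: List[float] = []
        prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # E step
            logpdf = norm.logpdf(x[:, None], means[None, :], sds[None, :])
            logpdf = logpdf + np.log(weights[None, :])
            top = logpdf.max(axis=1, keepdims=True)
            dens = np.exp(logpdf - top)
            total = dens.sum(axis=1, keepdims=True)
            resp = dens / total
            loglik = float(np.sum(np.log(total) + top))
            loglik_path.append(loglik)
            if loglik - prev < self.tol * x.size and n_iter > 1:
                converged = True
                break
            prev = loglik
            # M step
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            weights = nk / x.size
            new_means = resp.T @ x / nk
            for j, fm in enumerate(fixed):
                means[j] = fm if fm is not None else new_means[j]
            var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.maximum(np.sqrt(var), self.sd_floor)

        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_iter} iterations", stacklevel=2
            )
        order = np.argsort(means)
        self.means_ = means[order]
        self.sds_ = sds[order]
        self.weights_ = weights[order]
        self.log_likelihood_ = loglik_path[-1]
        self.log_likelihood_path_ = loglik_path
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def predict_proba(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        logpdf = norm.logpdf(x[:, None], self.means_[None, :], self.sds_[None, :])
        logpdf = logpdf + np.log(self.weights_[None, :])
        top = logpdf.max(axis=1, keepdims=True)
        dens = np.exp(logpdf - top)
        return dens / dens.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1) + 1

    def score(self, X, y=None) -> float:
        x = np.asarray(X, dtype=float).ravel()
        logpdf = norm.logpdf(x[:, None], self.means_[None, :], self.sds_[None, :])
        logpdf = logpdf + np.log(self.weights_[None, :])
        top = logpdf.max(axis=1)
        return float(
            np.mean(np.log(np.exp(logpdf - top[:, None]).sum(axis=1)) + top)
        )

    def to_model(self) -> MixtureModel:
        weights = self.weights_ / self.weights_.sum()
        return MixtureModel(
            tuple(
                MixtureComponent(float(m), float(s), float(w))
                for m, s, w in zip(self.means_, self.sds_, weights)
            )
        )


def fit_mixture(
    similarities,
    k: int,
    fixed_means: Optional[Sequence[Optional[float]]] = None,
    **kwargs,
) -> MixtureModel:
    """EM fit of a k-component similarity mixture; returns the sorted model."""
    est = GaussianMixture1D(n_components=k, fixed_means=fixed_means, **kwargs)
    est.fit(similarities)
    return est.to_model()


def _logdensity_gap(x: np.ndarray, lower: MixtureComponent,
                    upper: MixtureComponent) -> np.ndarray:
    """log f_lower(x) - log f_upper(x) with full normal densities."""
    lo = -np.log(lower.sd) - (x - lower.mean) ** 2 / (2.0 * lower.sd**2)
    hi = -np.log(upper.sd) - (x - upper.mean) ** 2 / (2.0 * upper.sd**2)
    return lo - hi


def ml_transition_point(
    similarities,
    lower: MixtureComponent,
    upper: MixtureComponent,
    grid_step: Optional[float] = None,
) -> float:
    """ML cutoff H between two adjacent components.

    Maximizes over h in (lower.mean, upper.mean) the product of the lower
    component's density at every similarity <= h and the upper component's
    density at every similarity > h.  The objective is piecewise constant
    between order statistics, so by default the argmax is located exactly on
    the sorted data and the midpoint of the maximizing plateau is returned;
    passing ``grid_step`` forces a numeric grid search instead.
    """
    x = np.sort(np.asarray(similarities, dtype=float).ravel())
    if lower.mean >= upper.mean:
        raise ValueError("lower component mean must be below upper component mean")
    inner = x[(x > lower.mean) & (x < upper.mean)]
    if inner.size == 0:
        raise ValueError(
            "no similarities strictly between the component means: "
            "cannot place a transition point"
        )

    if grid_step is not None:
        grid = np.arange(lower.mean + grid_step, upper.mean, grid_step)
        gaps = _logdensity_gap(inner, lower, upper)
        objective = np.array([gaps[inner <= h].sum() for h in grid])
        best = objective.max()
        mask = objective >= best - 1e-12
        idx = np.flatnonzero(mask)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        run = max(runs, key=len)
        return float((grid[run[0]] + grid[run[-1]]) / 2.0)

    # exact: objective(h) = const + sum of gaps over inner points <= h
    gaps = _logdensity_gap(inner, lower, upper)
    cum = np.concatenate(([0.0], np.cumsum(gaps)))
    best = cum.max()
    ties = np.flatnonzero(cum >= best - 1e-12)
    # contiguous run of tying prefix lengths = one plateau of h values
    runs = np.split(ties, np.flatnonzero(np.diff(ties) > 1) + 1)
    run = max(runs, key=len)
    bounds = np.concatenate(([lower.mean], inner, [upper.mean]))
    left = bounds[run[0]]
    right = bounds[run[-1] + 1]
    return float((left + right) / 2.0)


def ml_transition_points(
    similarities,
    mixture: MixtureModel,
    grid_step: Optional[float] = None,
    low_exclusion: Optional[float] = None,
    high_exclusion: Optional[float] = None,
) -> TransitionPoints:
    """ML cutoffs between every adjacent component pair of the mixture."""
    x = np.asarray(similarities, dtype=float).ravel()
    comps = mixture.components
    cutoffs: List[float] = []
    for j in range(mixture.n_components - 1):
        lo = cutoffs[-1] if cutoffs else 0.0
        hi = comps[j + 2].mean if j + 2 < mixture.n_components else 100.0
        window = x[(x > lo) & (x <= hi)]
        h = ml_transition_point(window, comps[j], comps[j + 1], grid_step=grid_step)
        if cutoffs and h <= cutoffs[-1]:
            raise RuntimeError("transition points not monotone")  # pragma: no cover
        cutoffs.append(h)
    return TransitionPoints(
        tuple(cutoffs), low_exclusion=low_exclusion, high_exclusion=high_exclusion
    )


def classify_similarity(x: float, cutoffs: TransitionPoints) -> int:
    """Event of origin for a similarity: 1 + number of cutoffs strictly below x.

    A similarity equal to a cutoff is assigned to the older event (x <= H
    belongs to I).
    """
    if not 0.0 < x <= 100.0:
        raise ValueError(f"similarity {x} outside (0, 100]")
    return int(np.searchsorted(np.asarray(cutoffs.cutoffs), x, side="left")) + 1


def classify_similarities(values, cutoffs: TransitionPoints) -> np.ndarray:
    """Vectorized :func:`classify_similarity`."""
    x = np.asarray(values, dtype=float)
    if np.any((x <= 0.0) | (x > 100.0)):
        raise ValueError("similarities outside (0, 100]")
    return np.searchsorted(np.asarray(cutoffs.cutoffs), x, side="left") + 1
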