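"""Predicted triplet profiles: trivariate-normal octant integration and ranking.

An underlying triplet of type Δ draws its three similarities from the normal
components of its events of origin.  Because components overlap, the
observed classification of those similarities (relative to the transition
points H) can land in any category.  For each Δ the trivariate normal — mean
vector from the component means, covariance from the within-triplet
estimates, cross-event covariance 0 — is integrated over every ordered sign
pattern of the cutoff partition ("octants" for two events); ordered patterns
collapse into category multisets.  The predicted profile weights these
category masses by the branching-process expectations W_M(Δ) and is
normalized to the observed total, after which candidate models are ranked
against the observed profile.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

from .branching import (
    EventSchedule,
    Profile,
    SurvivalParams,
    TripletType,
    _as_schedule,
    expected_triplet_profile_bruteforce,
    expected_triplet_profile_closed,
    triplet_types,
)
from .mixture import MixtureModel, TransitionPoints
from .triplets import TripletCovariance

logger = logging.getLogger(__name__)

#: fixed seed for the quasi-random trivariate-normal integrator (determinism)
_MVN_SEED = 20191217


def octant_patterns(n_events: int) -> Tuple[Tuple[int, ...], ...]:
    """All ordered classification outcomes of three similarities (m^3 of them)."""
    return tuple(itertools.product(range(1, n_events + 1), repeat=3))


def category_probability(
    delta: TripletType,
    mixture: MixtureModel,
    cov: TripletCovariance,
    cutoffs: TransitionPoints,
) -> Dict[TripletType, float]:
    """Mass each observed category receives from an underlying type Δ.

    Integrates the trivariate normal N(μ_Δ, Σ_Δ) over every box of the
    cutoff partition in each coordinate and sums ordered outcomes into
    multisets.  Masses sum to 1 up to integration tolerance.
    """
    delta = tuple(sorted(delta))
    m = mixture.n_components
    if max(delta) > m:
        raise ValueError(f"type {delta} needs more components than {m}")
    if len(cutoffs.cutoffs) != m - 1:
        raise ValueError("cutoff count must be one less than component count")
    mean = np.array([mixture.component(e).mean for e in delta])
    sigma = cov.matrix(delta)
    bounds = np.concatenate(([-np.inf], cutoffs.cutoffs, [np.inf]))

    out: Dict[TripletType, float] = {t: 0.0 for t in triplet_types(m)}
    diagonal = not np.any(sigma[~np.eye(3, dtype=bool)])
    if diagonal:
        # exact univariate factorization
        sds = np.sqrt(np.diag(sigma))
        cdf = norm.cdf(bounds[None, :], mean[:, None], sds[:, None])
        bin_probs = np.diff(cdf, axis=1)  # (coordinate, bin)
        for pattern in octant_patterns(m):
            mass = float(np.prod([bin_probs[i, b - 1] for i, b in enumerate(pattern)]))
            out[tuple(sorted(pattern))] += mass
        return out

    for pattern in octant_patterns(m):
        lower = np.array([bounds[b - 1] for b in pattern])
        upper = np.array([bounds[b] for b in pattern])
        mass = float(
            multivariate_normal.cdf(
                upper, mean, sigma, lower_limit=lower,
                abseps=1e-10, releps=0.0, maxpts=2_000_000,
                rng=np.random.default_rng(_MVN_SEED),
            )
        )
        out[tuple(sorted(pattern))] += max(mass, 0.0)

    total = sum(out.values())
    if not np.isfinite(total) or abs(total - 1.0) > 1e-4:
        raise RuntimeError(
            f"octant masses for {delta} sum to {total}: integration failure"
        )
    return out


def underlying_profile(schedule, params: SurvivalParams,
                       observed_total: float) -> Profile:
    """Branching-process expectations W_M(Δ), normalized to the observed total."""
    schedule = _as_schedule(schedule)
    w = _expected_profile(schedule, params)
    return w.normalized(observed_total, label="underlying")


def _expected_profile(schedule: EventSchedule, params: SurvivalParams) -> Profile:
    if schedule.n_events in (2, 3):
        return expected_triplet_profile_closed(schedule, params)
    return expected_triplet_profile_bruteforce(schedule, params)


def predicted_profile(
    schedule,
    params: SurvivalParams,
    mixture: MixtureModel,
    cov: TripletCovariance,
    cutoffs: TransitionPoints,
    observed_total: float,
) -> Profile:
    """Predicted profile: sum over Δ of W_M(Δ) times Δ's category masses."""
    schedule = _as_schedule(schedule)
    if observed_total <= 0:
        raise ValueError("observed_total must be positive")
    w = _expected_profile(schedule, params)
    if w.total <= 0:
        raise ValueError(
            f"model {schedule.label()}: all-zero underlying profile "
            "(degenerate survival parameters)"
        )
    m = mixture.n_components
    values: Dict[TripletType, float] = {t: 0.0 for t in triplet_types(m)}
    for delta, weight in w.values.items():
        if weight <= 0.0:
            continue
        masses = category_probability(delta, mixture, cov, cutoffs)
        for cat, mass in masses.items():
            values[cat] += weight * mass
    return Profile(values, label="predicted", n_events=m).normalized(
        observed_total, label="predicted"
    )


def compare_profiles(
    observed: Profile,
    candidates: Mapping[str, Profile],
    epsilon: float = 0.5,
) -> pd.DataFrame:
    """Rank candidate profiles against the observed profile.

    Reports, per candidate, a chi-square-style statistic
    ``sum (O - E)^2 / max(E, epsilon)`` and the L1 distance; ranks by the
    statistic with L1 breaking ties.  The full table is returned, sorted.
    """
    types = triplet_types(observed.n_events)
    obs = observed.as_vector()
    rows = []
    for name, profile in candidates.items():
        if triplet_types(profile.n_events) != types:
            raise ValueError(
                f"candidate {name!r} covers different triplet types"
            )
        exp = profile.as_vector()
        chi2 = float(np.sum((obs - exp) ** 2 / np.maximum(exp, epsilon)))
        l1 = float(np.abs(obs - exp).sum())
        rows.append({"model": name, "chi2": chi2, "l1": l1})
    report = pd.DataFrame(rows).sort_values(
        ["chi2", "l1", "model"], kind="mergesort"
    )
    report["rank"] = np.arange(1, len(report) + 1)
    return report.reset_index(drop=True)


def profile_table(
    observed: Profile,
    underlying: Mapping[str, Profile],
    predicted: Mapping[str, Profile],
) -> pd.DataFrame:
    """Long-form table (model, type, underlying, predicted, observed)."""
    types = triplet_types(observed.n_events)
    rows = []
    for name in underlying:
        for t in types:
            rows.append(
                {
                    "model": name,
                    "type": ",".join(f"t{e}" for e in t),
                    "underlying": underlying[name].values[t],
                    "predicted": predicted[name].values[t],
                    "observed": observed.values[t],
                }
            )
    return pd.DataFrame(rows)
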