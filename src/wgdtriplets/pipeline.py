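"""End-to-end ploidy-history selection: pairs in, ranked models out.

`PloidyHistorySelector` is the estimator-shaped surface over the whole
method: fit a similarity mixture, place ML transition points, extract gene
triangles, build the observed profile, estimate per-model survival
parameters from classified pair counts, integrate predicted profiles, and
rank candidate ploidy sequences against the observed profile.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .branching import (
    EventSchedule,
    Profile,
    SurvivalFit,
    estimate_survival_params,
)
from .mixture import (
    MixtureModel,
    TransitionPoints,
    classify_similarities,
    fit_mixture,
    ml_transition_points,
    serialize_fit,
)
from .prediction import (
    compare_profiles,
    predicted_profile,
    profile_table,
    underlying_profile,
)
from .triplets import (
    SimilarityPair,
    estimate_triplet_covariance,
    extract_triples,
    filter_pairs,
    observed_profile,
    read_pairs,
)

logger = logging.getLogger(__name__)


def _coerce_pairs(pairs) -> List[SimilarityPair]:
    if isinstance(pairs, pd.DataFrame):
        cols = list(pairs.columns[:3])
        return [
            SimilarityPair(*( (a, b) if a < b else (b, a) ), float(s))
            for a, b, s in pairs[cols].itertuples(index=False)
        ]
    out = []
    for p in pairs:
        if isinstance(p, SimilarityPair):
            out.append(p)
        else:
            a, b, s = p
            a, b = (a, b) if a < b else (b, a)
            out.append(SimilarityPair(str(a), str(b), float(s)))
    return out


class PloidyHistorySelector(BaseEstimator):
    """Infer the ploidy sequence of successive polyploidy events from pairs.

    Parameters
    ----------
    n_events:
        Number of polyploidy events (mixture components) to model.
    schedules:
        Candidate ploidy sequences; default is every sequence of doublings
        and triplings of length ``n_events`` (``2**n_events`` models).
    fixed_means:
        Optional component means to hold fixed during the mixture EM.
    low_exclusion, high_exclusion:
        Similarity filters applied before any fitting: pairs at or below the
        low cutoff (older, non-modeled events) and above the high cutoff
        (recent non-polyploidy duplicates) are dropped.
    squared_constraint:
        Use p3 = p2**2 for tripling events during survival estimation.
    grid_step:
        Optional numeric grid for the transition-point search (default:
        exact order-statistic search).
    estimation_method:
        "moments" (bounded least squares on pair/gene counts) or
        "multinomial" (likelihood over pair-event categories).

    Attributes (after fit)
    ----------------------
    mixture_, cutoffs_, triples_, observed_profile_, covariance_,
    survival_fits_, underlying_profiles_, predicted_profiles_,
    ranking_ (DataFrame), best_schedule_, filter_counts_
    """

    def __init__(
        self,
        n_events: int = 2,
        schedules: Optional[Sequence] = None,
        fixed_means: Optional[Sequence[Optional[float]]] = None,
        low_exclusion: Optional[float] = None,
        high_exclusion: Optional[float] = None,
        squared_constraint: bool = True,
        grid_step: Optional[float] = None,
        estimation_method: str = "moments",
        sd_floor: float = 1e-2,
        random_state: int = 0,
    ):
        self.n_events = n_events
        self.schedules = schedules
        self.fixed_means = fixed_means
        self.low_exclusion = low_exclusion
        self.high_exclusion = high_exclusion
        self.squared_constraint = squared_constraint
        self.grid_step = grid_step
        self.estimation_method = estimation_method
        self.sd_floor = sd_floor
        self.random_state = random_state

    def _candidate_schedules(self) -> List[EventSchedule]:
        if self.schedules is None:
            return EventSchedule.all_models(self.n_events)
        out = []
        for s in self.schedules:
            out.append(s if isinstance(s, EventSchedule) else EventSchedule(tuple(s)))
        if not out:
            raise ValueError("candidate schedule list is empty")
        return out

    def fit(self, pairs, y=None) -> "PloidyHistorySelector":
        pairs = _coerce_pairs(pairs)
        kept, removed = filter_pairs(
            pairs, self.low_exclusion, self.high_exclusion
        )
        self.filter_counts_ = removed
        if not kept:
            raise ValueError("no pairs left after exclusion filters")
        sims = np.array([p.similarity for p in kept])

        self.mixture_ = fit_mixture(
            sims, self.n_events, fixed_means=self.fixed_means,
            sd_floor=self.sd_floor,
        )
        self.cutoffs_ = ml_transition_points(
            sims, self.mixture_, grid_step=self.grid_step,
            low_exclusion=self.low_exclusion, high_exclusion=self.high_exclusion,
        )

        self.triples_ = extract_triples(kept)
        self.observed_profile_ = observed_profile(
            self.triples_, self.cutoffs_, n_events=self.n_events
        )
        self.covariance_ = estimate_triplet_covariance(
            self.triples_, self.cutoffs_, mixture=self.mixture_,
            n_events=self.n_events,
        )

        events = classify_similarities(sims, self.cutoffs_)
        pair_counts = {
            e: int(np.sum(events == e)) for e in range(1, self.n_events + 1)
        }
        genes = {g for p in kept for g in (p.gene_a, p.gene_b)}
        self.pair_counts_ = pair_counts
        self.n_genes_ = len(genes)

        total = self.observed_profile_.total
        if total == 0:
            raise ValueError("no gene triangles found: cannot build profiles")

        self.survival_fits_: Dict[str, SurvivalFit] = {}
        self.underlying_profiles_: Dict[str, Profile] = {}
        self.predicted_profiles_: Dict[str, Profile] = {}
        for schedule in self._candidate_schedules():
            name = schedule.label()
            fit = estimate_survival_params(
                schedule, pair_counts, self.n_genes_,
                squared=self.squared_constraint, observable_only=True,
                method=self.estimation_method,
            )
            self.survival_fits_[name] = fit
            self.underlying_profiles_[name] = underlying_profile(
                schedule, fit.params, total
            )
            self.predicted_profiles_[name] = predicted_profile(
                schedule, fit.params, self.mixture_, self.covariance_,
                self.cutoffs_, total,
            )

        self.ranking_ = compare_profiles(
            self.observed_profile_, self.predicted_profiles_
        )
        self.best_schedule_ = EventSchedule(
            tuple(int(r) for r in self.ranking_.iloc[0]["model"].strip("()").split(","))
        )
        return self

    def predict(self, similarities) -> np.ndarray:
        """Event of origin (1 = oldest) for each similarity, via the cutoffs."""
        return classify_similarities(similarities, self.cutoffs_)

    def report(self) -> pd.DataFrame:
        return profile_table(
            self.observed_profile_, self.underlying_profiles_,
            self.predicted_profiles_,
        )

    def summary(self) -> dict:
        return {
            "ranking": self.ranking_.to_dict(orient="records"),
            "best_model": self.best_schedule_.label(),
            "mixture": self.mixture_.to_dict(),
            "cutoffs": self.cutoffs_.to_dict(),
            "pair_counts": self.pair_counts_,
            "n_genes": self.n_genes_,
            "n_triples": len(self.triples_),
            "filter_counts": self.filter_counts_,
            "survival": {
                name: {
                    "rates": list(fit.rates),
                    "root_count": fit.root_count,
                    "residual": fit.residual,
                }
                for name, fit in self.survival_fits_.items()
            },
        }


def run_pipeline(
    input_path,
    out_dir,
    n_events: int = 2,
    fixed_means: Optional[Sequence[float]] = None,
    low_exclusion: Optional[float] = None,
    high_exclusion: Optional[float] = None,
    schedules: Optional[Sequence] = None,
    squared_constraint: bool = True,
    estimation_method: str = "moments",
    seed: int = 0,
) -> PloidyHistorySelector:
    """Read a pair list, run the full analysis, write reports under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("wgdtriplets")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        pairs = read_pairs(input_path)
        selector = PloidyHistorySelector(
            n_events=n_events,
            schedules=schedules,
            fixed_means=fixed_means,
            low_exclusion=low_exclusion,
            high_exclusion=high_exclusion,
            squared_constraint=squared_constraint,
            estimation_method=estimation_method,
            random_state=seed,
        ).fit(pairs)

        selector.report().to_csv(out / "profiles.tsv", sep="\t", index=False)
        selector.ranking_.to_csv(out / "ranking.tsv", sep="\t", index=False)
        (out / "mixture.json").write_text(
            serialize_fit(selector.mixture_, selector.cutoffs_) + "\n"
        )
        (out / "summary.json").write_text(
            json.dumps(selector.summary(), indent=2, default=float) + "\n"
        )
        (out / "observed_profile.tsv").write_text(
            selector.observed_profile_.to_tsv()
        )
        for name in selector.predicted_profiles_:
            safe = name.strip("()").replace(",", "-")
            (out / f"predicted_{safe}.tsv").write_text(
                selector.predicted_profiles_[name].to_tsv()
            )
            (out / f"underlying_{safe}.tsv").write_text(
                selector.underlying_profiles_[name].to_tsv()
            )
        logger.info("best model: %s", selector.best_schedule_.label())
        return selector
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
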