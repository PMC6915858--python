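"""Syntenic pair lists, similarity filters, gene triangles and their covariance.

Input is the shape of a SynMap-style genome self-comparison export: one
tab-separated row per syntenic paralog pair with a percent similarity.
Triples of mutually similar genes are the triangles of the graph whose edges
are the (filtered) pairs.  Classifying each triangle's three similarities by
the mixture transition points yields the *observed* triplet profile, and the
per-event variance / within-triplet covariance of classified similarities
supplies the covariance structure of the trivariate normal used for
predicted profiles.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .branching import Profile, TripletType, triplet_types
from .mixture import MixtureModel, TransitionPoints, classify_similarities

logger = logging.getLogger(__name__)


class SimilarityPair(NamedTuple):
    """A canonicalized (gene_a < gene_b) syntenic paralog pair."""

    gene_a: str
    gene_b: str
    similarity: float


@dataclass(frozen=True)
class Triple:
    """Three mutually paralogous genes with their pairwise similarities.

    ``similarities`` are ordered (ab, ac, bc) for sorted genes (a, b, c).
    """

    genes: Tuple[str, str, str]
    similarities: Tuple[float, float, float]


def read_pairs(source) -> List[SimilarityPair]:
    """Read a tab-separated pair list (gene_a, gene_b, similarity percent).

    Lines starting with ``#`` are comments; extra columns are ignored so
    trimmed SynMap exports load as-is.  Self-pairs are dropped (counted in
    the log); duplicate unordered pairs keep the maximum similarity with a
    warning.  Unparseable or out-of-range similarities raise.
    """
    if isinstance(source, (str, Path)) and "\t" not in str(source) and "\n" not in str(source):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    elif isinstance(source, io.IOBase):
        lines = source.read().splitlines()
    else:
        lines = [str(line) for line in source]

    best: Dict[Tuple[str, str], float] = {}
    self_pairs = 0
    conflicts = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected >= 3 columns")
        a, b = fields[0], fields[1]
        try:
            sim = float(fields[2])
        except ValueError as err:
            raise ValueError(
                f"line {lineno}: unparseable similarity {fields[2]!r}"
            ) from err
        if not 0.0 < sim <= 100.0:
            raise ValueError(f"line {lineno}: similarity {sim} outside (0, 100]")
        if a == b:
            self_pairs += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in best and best[key] != sim:
            conflicts += 1
            best[key] = max(best[key], sim)
        else:
            best[key] = sim
    if self_pairs:
        logger.warning("dropped %d self-pair rows", self_pairs)
    if conflicts:
        logger.warning(
            "%d duplicate pairs with differing similarity: kept the maximum",
            conflicts,
        )
    return [
        SimilarityPair(a, b, s) for (a, b), s in sorted(best.items())
    ]


def filter_pairs(
    pairs: Sequence[SimilarityPair],
    low_exclusion: Optional[float] = None,
    high_exclusion: Optional[float] = None,
) -> Tuple[List[SimilarityPair], Dict[str, int]]:
    """Keep pairs with low_exclusion < similarity <= high_exclusion.

    The low cutoff removes pairs older than the modeled events; the high
    cutoff removes recent non-polyploidy duplicates (e.g. tandem arrays).
    Returns the kept pairs and removal counts by reason.
    """
    lo = 0.0 if low_exclusion is None else float(low_exclusion)
    hi = 100.0 if high_exclusion is None else float(high_exclusion)
    if not 0.0 <= lo < hi <= 100.0:
        raise ValueError(f"inverted or out-of-range exclusions ({lo}, {hi})")
    kept: List[SimilarityPair] = []
    removed = {"low": 0, "high": 0}
    for p in pairs:
        if p.similarity <= lo:
            removed["low"] += 1
        elif p.similarity > hi:
            removed["high"] += 1
        else:
            kept.append(p)
    if removed["low"] or removed["high"]:
        logger.info(
            "filtered pairs: %d below %g, %d above %g, %d kept",
            removed["low"], lo, removed["high"], hi, len(kept),
        )
    return kept, removed


def extract_triples(pairs: Sequence[SimilarityPair]) -> List[Triple]:
    """Enumerate every triangle in the pair graph, once, in sorted gene order."""
    sim: Dict[Tuple[str, str], float] = {}
    adjacency: Dict[str, set] = {}
    for p in pairs:
        sim[(p.gene_a, p.gene_b)] = p.similarity
        adjacency.setdefault(p.gene_a, set()).add(p.gene_b)
        adjacency.setdefault(p.gene_b, set()).add(p.gene_a)

    triples: List[Triple] = []
    for a in sorted(adjacency):
        higher = sorted(x for x in adjacency[a] if x > a)
        for i, b in enumerate(higher):
            common = adjacency[a] & adjacency[b]
            for c in higher[i + 1:]:
                if c in common:
                    triples.append(
                        Triple(
                            (a, b, c),
                            (sim[(a, b)], sim[(a, c)], sim[(b, c)]),
                        )
                    )
    return triples


def observed_profile(
    triples: Sequence[Triple],
    cutoffs: TransitionPoints,
    n_events: Optional[int] = None,
) -> Profile:
    """Observed triplet profile: classify each similarity and count multisets."""
    m = n_events if n_events is not None else cutoffs.n_events
    counts: Dict[TripletType, float] = {t: 0 for t in triplet_types(m)}
    if triples:
        sims = np.array([t.similarities for t in triples], dtype=float)
        events = classify_similarities(sims, cutoffs)
        events.sort(axis=1)
        for row in events:
            counts[tuple(int(e) for e in row)] += 1
    return Profile(counts, label="observed", n_events=m)


@dataclass
class TripletCovariance:
    """Per-event variance and within-triplet same-event covariance.

    Cross-event covariance is fixed at 0 (the branching process is Markov:
    divergences at different events are conditionally independent).
    """

    variances: Dict[int, float]
    covariances: Dict[int, float]
    fallback_events: Tuple[int, ...] = ()

    def matrix(self, delta: TripletType, repair: bool = True) -> np.ndarray:
        """Assemble the 3x3 covariance for a triplet type, repairing to PSD.

        Off-diagonals between coordinates of the same event take that
        event's within-triplet covariance; cross-event entries are 0.  If
        the assembled matrix is not positive semi-definite, within-event
        covariances are shrunk toward 0 (x0.9 per step) until it is.
        """
        d = tuple(sorted(delta))
        cov = np.zeros((3, 3))
        for i in range(3):
            cov[i, i] = self.variances[d[i]]
        shrink = 1.0
        for _ in range(200):
            for i in range(3):
                for j in range(i + 1, 3):
                    if d[i] == d[j]:
                        cov[i, j] = cov[j, i] = shrink * self.covariances[d[i]]
            if np.linalg.eigvalsh(cov).min() >= -1e-12:
                if shrink < 1.0:
                    logger.warning(
                        "covariance for %s repaired: within-event covariance "
                        "shrunk by %.3g", d, shrink,
                    )
                return cov
            if not repair:
                raise ValueError(f"covariance for {d} not positive semi-definite")
            shrink *= 0.9
        raise ValueError(f"covariance for {d} could not be repaired")


def estimate_triplet_covariance(
    triples: Sequence[Triple],
    cutoffs: TransitionPoints,
    mixture: Optional[MixtureModel] = None,
    n_events: Optional[int] = None,
    all_pairs: bool = True,
) -> TripletCovariance:
    """Estimate the covariance structure of triplet similarities per event.

    For each event e, the variance is taken over every e-classified
    similarity occurrence within triples, and the within-triplet covariance
    over the unordered pairs of e-classified similarities inside each triple
    (all three pairs when a triple has three, or only the first pair with
    ``all_pairs=False``).  Events with insufficient data fall back to the
    mixture component's variance with zero covariance.
    """
    m = n_events if n_events is not None else cutoffs.n_events
    occurrences: Dict[int, List[float]] = {e: [] for e in range(1, m + 1)}
    within: Dict[int, List[Tuple[float, float]]] = {e: [] for e in range(1, m + 1)}
    for t in triples:
        events = [cutoffs.classify(s) for s in t.similarities]
        by_event: Dict[int, List[float]] = {}
        for s, e in zip(t.similarities, events):
            occurrences[e].append(s)
            by_event.setdefault(e, []).append(s)
        for e, vals in by_event.items():
            if len(vals) >= 2:
                pair_list = [
                    (vals[i], vals[j])
                    for i in range(len(vals))
                    for j in range(i + 1, len(vals))
                ]
                within[e].extend(pair_list if all_pairs else pair_list[:1])

    variances: Dict[int, float] = {}
    covariances: Dict[int, float] = {}
    fallbacks: List[int] = []
    for e in range(1, m + 1):
        occ = np.asarray(occurrences[e], dtype=float)
        if occ.size >= 2:
            mu = occ.mean()
            variances[e] = float(occ.var(ddof=1))
            pairs_e = np.asarray(within[e], dtype=float)
            if pairs_e.size:
                covariances[e] = float(
                    np.mean((pairs_e[:, 0] - mu) * (pairs_e[:, 1] - mu))
                )
            else:
                covariances[e] = 0.0
        else:
            if mixture is None:
                raise ValueError(
                    f"event {e}: not enough triplet similarities and no "
                    "mixture to fall back on"
                )
            comp = mixture.component(e)
            variances[e] = comp.sd**2
            covariances[e] = 0.0
            fallbacks.append(e)
            logger.warning(
                "event %d: insufficient triplet data; falling back to the "
                "mixture sd with zero within-event covariance", e,
            )
    return TripletCovariance(variances, covariances, tuple(fallbacks))
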