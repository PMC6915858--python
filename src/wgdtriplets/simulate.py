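"""Synthetic genome self-comparison data from the branching process.

``G`` independent root genes each undergo the scheduled polyploidy events
with the given survival probabilities; every extant paralog pair is labelled
by its event of origin (the pair's last common ancestor) and receives a
percent similarity drawn from that event's normal component, truncated to
(0, 100].  The emitted pair list has exactly the shape the triplets module
reads, and ground-truth tables (pair events, triplet profile) let every
downstream stage be checked without real genome downloads.

Defaults emulate a two-event history with well-studied component placement
(older event near 71% similarity, recent event near 90%); contaminant pairs
model recent non-polyploidy duplicates above the usual >98% exclusion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .branching import (
    EventSchedule,
    Profile,
    SurvivalParams,
    TripletType,
    _as_schedule,
    triplet_types,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """World description for one synthetic dataset."""

    schedule: EventSchedule
    params: SurvivalParams
    root_count: int
    means: Tuple[float, ...]
    sds: Tuple[float, ...]
    seed: int
    contaminant_rate: float = 0.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        schedule = _as_schedule(self.schedule)
        object.__setattr__(self, "schedule", schedule)
        self.params.validate_for(schedule)
        means = tuple(float(x) for x in self.means)
        sds = tuple(float(x) for x in self.sds)
        if len(means) != schedule.n_events or len(sds) != schedule.n_events:
            raise ValueError("one similarity component per event required")
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError(
                "component means must ascend with event index "
                "(older event = lower similarity)"
            )
        if any(s <= 0 for s in sds):
            raise ValueError("component sds must be positive")
        if self.root_count < 1:
            raise ValueError("root_count must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    def to_dict(self) -> dict:
        return {
            "schedule": list(self.schedule.ploidies),
            "survival": [list(row) for row in self.params.survival],
            "root_count": self.root_count,
            "means": list(self.means),
            "sds": list(self.sds),
            "seed": self.seed,
            "contaminant_rate": self.contaminant_rate,
            "background_rate": self.background_rate,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return cls(
            schedule=EventSchedule(tuple(data["schedule"])),
            params=SurvivalParams(tuple(tuple(r) for r in data["survival"])),
            root_count=int(data["root_count"]),
            means=tuple(data["means"]),
            sds=tuple(data["sds"]),
            seed=int(data["seed"]),
            contaminant_rate=float(data.get("contaminant_rate", 0.0)),
            background_rate=float(data.get("background_rate", 0.0)),
        )


def default_config(
    schedule=(3, 2),
    rates: Sequence[float] = (0.3, 0.4),
    root_count: int = 20000,
    means: Sequence[float] = (71.0, 90.0),
    sds: Sequence[float] = (4.0, 3.0),
    seed: int = 1,
    **kwargs,
) -> SimulationConfig:
    """A realistic two-event world: WGT then WGD, components at 71% and 90%."""
    schedule = _as_schedule(schedule)
    return SimulationConfig(
        schedule=schedule,
        params=SurvivalParams.from_rates(schedule, rates),
        root_count=root_count,
        means=tuple(means),
        sds=tuple(sds),
        seed=seed,
        **kwargs,
    )


@dataclass
class History:
    """Realized genealogies: per-root leaf paths and event-labelled pairs."""

    config: SimulationConfig
    leaf_paths: List[List[Tuple[int, ...]]]  # per root
    pair_index: np.ndarray  # (n_pairs, 3): root, leaf i, leaf j
    pair_events: np.ndarray  # (n_pairs,)

    @property
    def n_genes(self) -> int:
        return sum(len(paths) for paths in self.leaf_paths)

    def gene_name(self, root: int, leaf: int) -> str:
        return f"g{root:06d}_{leaf:02d}"

    def truth_pairs(self) -> List[Tuple[str, str, int]]:
        return [
            (self.gene_name(r, i), self.gene_name(r, j), int(e))
            for (r, i, j), e in zip(self.pair_index, self.pair_events)
        ]

    def truth_profile(self) -> Profile:
        """Exact triplet-type counts of the realized genealogies."""
        m = self.config.schedule.n_events
        counts: Dict[TripletType, float] = {t: 0 for t in triplet_types(m)}
        for paths in self.leaf_paths:
            n = len(paths)
            for a in range(n):
                for b in range(a + 1, n):
                    e_ab = _lca_event(paths[a], paths[b])
                    for c in range(b + 1, n):
                        key = tuple(
                            sorted(
                                (
                                    e_ab,
                                    _lca_event(paths[a], paths[c]),
                                    _lca_event(paths[b], paths[c]),
                                )
                            )
                        )
                        counts[key] += 1
        return Profile(counts, label="truth", n_events=m)

    def pair_event_counts(self) -> Dict[int, int]:
        m = self.config.schedule.n_events
        return {
            e: int(np.sum(self.pair_events == e)) for e in range(1, m + 1)
        }


def _lca_event(a: Tuple[int, ...], b: Tuple[int, ...]) -> int:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i + 1
    raise ValueError("identical leaves")


def simulate_history(config: SimulationConfig) -> History:
    """Draw G independent branching-process realizations (reproducible by seed)."""
    rng = np.random.default_rng(config.seed)
    schedule = config.schedule
    m = schedule.n_events
    # per-event cumulative survivor-count thresholds
    cums = [np.cumsum(row) for row in config.params.survival]

    leaf_paths: List[List[Tuple[int, ...]]] = []
    pair_rows: List[Tuple[int, int, int]] = []
    pair_events: List[int] = []
    for root in range(config.root_count):
        paths = [()]
        for i in range(m):
            draws = rng.random(len(paths))
            nxt = []
            for path, d in zip(paths, draws):
                c = int(np.searchsorted(cums[i], d, side="right")) + 1
                c = min(c, len(cums[i]))
                nxt.extend(path + (k,) for k in range(c))
            paths = nxt
        leaf_paths.append(paths)
        for a in range(len(paths)):
            for b in range(a + 1, len(paths)):
                pair_rows.append((root, a, b))
                pair_events.append(_lca_event(paths[a], paths[b]))
    return History(
        config=config,
        leaf_paths=leaf_paths,
        pair_index=np.array(pair_rows, dtype=np.int64).reshape(-1, 3),
        pair_events=np.array(pair_events, dtype=np.int64),
    )


def _truncated_normal(rng, mean, sd, size) -> np.ndarray:
    """Draw from N(mean, sd) truncated to (0, 100] by redraw (cap 100, then clamp)."""
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out <= 0.0) | (out > 100.0)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    n_clamped = int(((out <= 0.0) | (out > 100.0)).sum())
    if n_clamped:
        logger.warning("clamping %d similarities into (0, 100]", n_clamped)
    return np.clip(out, np.nextafter(0.0, 1.0), 100.0)


def emit_similarities(history: History, config: Optional[SimulationConfig] = None
                      ) -> Tuple[List[Tuple[str, str, float]], List[Tuple[str, str, int]]]:
    """Attach similarities to labelled pairs; returns (pair list, truth labels).

    Each pair's similarity is drawn from the normal component of its event of
    origin; optional contaminant pairs (similarity in (98, 100]) and uniform
    background pairs are appended, labelled event 0 in the truth table.
    """
    config = config or history.config
    rng = np.random.default_rng(config.seed + 1)
    events = history.pair_events
    sims = np.empty(events.shape[0], dtype=float)
    for e in range(1, config.schedule.n_events + 1):
        mask = events == e
        if mask.any():
            sims[mask] = _truncated_normal(
                rng, config.means[e - 1], config.sds[e - 1], int(mask.sum())
            )

    names = [
        (history.gene_name(r, i), history.gene_name(r, j))
        for r, i, j in history.pair_index
    ]
    pair_list = [(a, b, float(s)) for (a, b), s in zip(names, sims)]
    truth = [
        (a, b, int(e)) for (a, b), e in zip(names, events)
    ]

    extra = []
    if config.contaminant_rate > 0:
        extra.append((config.contaminant_rate, lambda n: rng.uniform(98.0, 100.0, n)))
    if config.background_rate > 0:
        extra.append((config.background_rate, lambda n: rng.uniform(50.0, 100.0, n)))
    for rate, draw in extra:
        n_extra = int(rng.poisson(rate * max(len(pair_list), 1)))
        for s in draw(n_extra):
            a = history.gene_name(int(rng.integers(config.root_count)), 90 + int(rng.integers(10)))
            b = history.gene_name(int(rng.integers(config.root_count)), 90 + int(rng.integers(10)))
            if a == b:
                continue
            if a > b:
                a, b = b, a
            pair_list.append((a, b, float(s)))
            truth.append((a, b, 0))
    return pair_list, truth


def make_fixture(config: SimulationConfig, out_dir) -> Dict[str, Path]:
    """Write pairs.tsv, truth_pairs.tsv, truth_profile.tsv and config.json.

    Byte-identical for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    history = simulate_history(config)
    pair_list, truth = emit_similarities(history, config)

    paths = {
        "pairs": out / "pairs.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
        "truth_profile": out / "truth_profile.tsv",
        "config": out / "config.json",
    }
    with paths["pairs"].open("w") as fh:
        fh.write("#gene_a\tgene_b\tsimilarity_percent\n")
        for a, b, s in pair_list:
            fh.write(f"{a}\t{b}\t{s:.4f}\n")
    with paths["truth_pairs"].open("w") as fh:
        fh.write("#gene_a\tgene_b\tevent\n")
        for a, b, e in truth:
            fh.write(f"{a}\t{b}\t{e}\n")
    paths["truth_profile"].write_text(history.truth_profile().to_tsv())
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    logger.info("fixture with %d pairs written to %s", len(pair_list), out)
    return paths
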