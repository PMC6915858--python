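"""Discrete-time branching process of successive polyploidizations with fractionation.

A genome lineage starts from a single gene and undergoes ``m`` polyploidy
events.  Event ``i`` multiplies every extant gene into ``r_i`` progeny
(``r_i = 2`` for whole-genome doubling, ``r_i = 3`` for tripling), of which
``j >= 1`` survive fractionation until the next event (or the present) with
probability ``p_j^(i)``; death is conditioned on at least one survivor.  The
leaves of the resulting genealogy are the extant members of a gene family,
and the event of origin of a paralog pair is the last common ancestor of the
two leaves.

This module enumerates genealogies, evaluates trajectory probabilities and
expected gene counts, and computes expected *triplet profiles*: the expected
number of gene triples whose three pairwise divergences originate in each
multiset of events (e.g. ``{t1, t1, t2}``).  Profiles are available by
exhaustive genealogy enumeration (any schedule up to a cap) and in closed
form for two and three events.  Survival probabilities can be estimated from
observed per-event pair counts by bounded least squares or a multinomial
likelihood.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

TripletType = Tuple[int, int, int]

#: default cap on schedule length for exhaustive enumeration
MAX_ENUMERATION_EVENTS = 4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventSchedule:
    """Ordered ploidies ``(r_1, ..., r_m)`` of successive events, oldest first."""

    ploidies: Tuple[int, ...]

    def __post_init__(self) -> None:
        ploidies = tuple(int(r) for r in self.ploidies)
        if len(ploidies) < 1:
            raise ValueError("schedule needs at least one event")
        for r in ploidies:
            if r not in (2, 3):
                raise ValueError(
                    f"ploidy {r} unsupported: only doubling (2) and tripling (3)"
                )
        object.__setattr__(self, "ploidies", ploidies)

    @property
    def n_events(self) -> int:
        return len(self.ploidies)

    def __iter__(self):
        return iter(self.ploidies)

    def __len__(self) -> int:
        return len(self.ploidies)

    def label(self) -> str:
        return "(" + ",".join(str(r) for r in self.ploidies) + ")"

    @classmethod
    def all_models(cls, n_events: int) -> List["EventSchedule"]:
        """The model set: all ``2**m`` ploidy sequences of length ``m``."""
        return [
            cls(p) for p in itertools.product((2, 3), repeat=n_events)
        ]


def _as_schedule(schedule) -> EventSchedule:
    if isinstance(schedule, EventSchedule):
        return schedule
    return EventSchedule(tuple(schedule))


@dataclass(frozen=True)
class SurvivalParams:
    """Per-event survival probabilities ``p_j^(i)`` (j survivors, conditioned >=1).

    ``survival[i][j-1]`` is the probability that exactly ``j`` of the ``r_i``
    progeny survive.  Each event's probabilities must sum to 1.
    """

    survival: Tuple[Tuple[float, ...], ...]

    def __post_init__(self) -> None:
        surv = tuple(tuple(float(p) for p in row) for row in self.survival)
        for i, row in enumerate(surv):
            if len(row) not in (2, 3):
                raise ValueError(f"event {i + 1}: need 2 or 3 survival entries")
            if any(p < -1e-12 for p in row):
                raise ValueError(f"event {i + 1}: negative survival probability")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(
                    f"event {i + 1}: survival probabilities sum to {sum(row)}, not 1"
                )
        object.__setattr__(self, "survival", surv)

    @property
    def n_events(self) -> int:
        return len(self.survival)

    def p(self, event: int, j: int) -> float:
        """Probability of exactly ``j`` survivors at 1-based ``event``."""
        row = self.survival[event - 1]
        if not 1 <= j <= len(row):
            raise ValueError(f"event {event} has no j={j} entry")
        return row[j - 1]

    def validate_for(self, schedule: EventSchedule) -> None:
        schedule = _as_schedule(schedule)
        if self.n_events != schedule.n_events:
            raise ValueError(
                f"{self.n_events} parameter rows for {schedule.n_events} events"
            )
        for i, r in enumerate(schedule):
            if len(self.survival[i]) != r:
                raise ValueError(
                    f"event {i + 1}: ploidy {r} but "
                    f"{len(self.survival[i])} survival entries"
                )

    @classmethod
    def from_rates(
        cls,
        schedule,
        two_survivor: Sequence[float],
        three_survivor: Optional[Sequence[Optional[float]]] = None,
        squared: bool = True,
    ) -> "SurvivalParams":
        """Build from the named rates u, v, w (= ``p_2`` per event).

        For tripling events ``p_3`` defaults to the squared constraint
        ``p_3 = p_2**2`` (u' = u^2); pass ``three_survivor`` with
        ``squared=False`` to set it freely.
        """
        schedule = _as_schedule(schedule)
        two_survivor = list(two_survivor)
        if len(two_survivor) != schedule.n_events:
            raise ValueError("one two-survivor rate per event required")
        rows = []
        for i, r in enumerate(schedule):
            p2 = float(two_survivor[i])
            if r == 2:
                rows.append((1.0 - p2, p2))
            else:
                if squared:
                    p3 = p2 * p2
                else:
                    if three_survivor is None or three_survivor[i] is None:
                        raise ValueError(
                            f"event {i + 1} is a tripling: p_3 required "
                            "when squared=False"
                        )
                    p3 = float(three_survivor[i])
                p1 = 1.0 - p2 - p3
                if p1 < -1e-12:
                    raise ValueError(
                        f"event {i + 1}: p2={p2}, p3={p3} leave no mass for p1"
                    )
                rows.append((max(p1, 0.0), p2, p3))
        return cls(tuple(rows))

    # expected per-gene factors used throughout the closed forms
    def pair_factor(self, event: int) -> float:
        """E[C(c, 2)]: expected same-event pairs created per gene."""
        row = self.survival[event - 1]
        return row[1] + (3.0 * row[2] if len(row) == 3 else 0.0)

    def growth_factor(self, event: int) -> float:
        """E[c]: expected survivors per gene."""
        row = self.survival[event - 1]
        return 1.0 + row[1] + (2.0 * row[2] if len(row) == 3 else 0.0)

    def triple_factor(self, event: int) -> float:
        """E[C(c, 3)]: probability all three progeny survive (0 for doubling)."""
        row = self.survival[event - 1]
        return row[2] if len(row) == 3 else 0.0


@dataclass(frozen=True)
class TrajectoryCounts:
    """Survivor-count configuration ``a_j^(i)`` of a trajectory (Eq.-1 bookkeeping).

    ``a[i][j-1]`` counts genes at time ``t_i`` with exactly ``j`` surviving
    progeny.  Implied totals: ``m_1 = 1``, ``m_{i+1} = sum_j j a_j^(i)``.
    """

    a: Tuple[Tuple[int, ...], ...]

    def __post_init__(self) -> None:
        rows = tuple(tuple(int(x) for x in row) for row in self.a)
        if any(x < 0 for row in rows for x in row):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "a", rows)

    def gene_counts(self) -> List[int]:
        """Totals ``m_1, ..., m_{n}`` implied by the counts; validates identities."""
        m = [1]
        for i, row in enumerate(self.a):
            if sum(row) != m[-1]:
                raise ValueError(
                    f"event {i + 1}: counts sum to {sum(row)}, expected m={m[-1]}"
                )
            m.append(sum(j * x for j, x in enumerate(row, start=1)))
        return m


@dataclass(frozen=True)
class Genealogy:
    """One realization of the branching process from a single root gene.

    ``tree`` is a nested tuple: an internal node at level ``i`` is the tuple
    of its surviving children; a leaf (extant gene) is ``()`` at level
    ``m + 1``.  Leaves are addressed by their path of child indices.
    """

    schedule: EventSchedule
    tree: tuple
    weight: float

    def leaves(self) -> List[Tuple[int, ...]]:
        out: List[Tuple[int, ...]] = []

        def walk(node, path):
            if not node:
                out.append(path)
                return
            for idx, child in enumerate(node):
                walk(child, path + (idx,))

        walk(self.tree, ())
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def trajectory_counts(self) -> TrajectoryCounts:
        """Aggregate the tree into per-event survivor-count tallies."""
        m = self.schedule.n_events
        a = [[0] * r for r in self.schedule]
        level = [self.tree]
        for i in range(m):
            nxt = []
            for node in level:
                a[i][len(node) - 1] += 1
                nxt.extend(node)
            level = nxt
        return TrajectoryCounts(tuple(tuple(row) for row in a))


@dataclass
class Profile:
    """Triplet-type counts or expectations, covering all types for ``m`` events."""

    values: Dict[TripletType, float]
    label: str = "underlying"
    n_events: int = 0

    def __post_init__(self) -> None:
        if self.n_events == 0:
            self.n_events = max(max(t) for t in self.values) if self.values else 1
        full = {t: 0.0 for t in triplet_types(self.n_events)}
        for t, v in self.values.items():
            key = tuple(sorted(t))
            if key not in full:
                raise ValueError(f"triplet type {t} invalid for {self.n_events} events")
            if v < -1e-12:
                raise ValueError(f"negative profile value for {t}")
            full[key] += float(v)
        self.values = full

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))

    def normalized(self, total: float, label: Optional[str] = None) -> "Profile":
        own = self.total
        if own <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        scale = float(total) / own
        return Profile(
            {t: v * scale for t, v in self.values.items()},
            label=label or self.label,
            n_events=self.n_events,
        )

    def as_vector(self) -> np.ndarray:
        return np.array([self.values[t] for t in triplet_types(self.n_events)])

    def to_tsv(self) -> str:
        lines = ["#type\tvalue\tlabel"]
        for t in triplet_types(self.n_events):
            name = ",".join(f"t{e}" for e in t)
            lines.append(f"{name}\t{self.values[t]:.10g}\t{self.label}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "Profile":
        values: Dict[TripletType, float] = {}
        label = "profile"
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, value, label = line.split("\t")[:3]
            key = tuple(sorted(int(part.lstrip("t")) for part in name.split(",")))
            values[key] = float(value)
        return cls(values, label=label)


# ---------------------------------------------------------------------------
# triplet-type combinatorics
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def triplet_types(n_events: int) -> Tuple[TripletType, ...]:
    """All size-3 multisets over events 1..m — the tetrahedral number of them."""
    return tuple(
        itertools.combinations_with_replacement(range(1, n_events + 1), 3)
    )


def is_realizable(triplet: TripletType) -> bool:
    """A type is realizable iff its oldest event appears at least twice.

    The genealogy is ultrametric: the pair diverging at the oldest event
    separates one leaf from the other two, so those two leaves' own divergence
    and their divergences from the first leaf cannot both postdate it.
    """
    t = tuple(sorted(triplet))
    return t.count(t[0]) >= 2


# ---------------------------------------------------------------------------
# genealogy enumeration and trajectory probabilities
# ---------------------------------------------------------------------------


def enumerate_genealogies(
    schedule, params: SurvivalParams, max_events: int = MAX_ENUMERATION_EVENTS
) -> List[Genealogy]:
    """Exhaustively enumerate survivor-count genealogies with probabilities.

    Children are ordered, so each distinct survivor-count configuration
    appears exactly once and weights sum to 1.
    """
    schedule = _as_schedule(schedule)
    params.validate_for(schedule)
    if schedule.n_events > max_events:
        raise ValueError(
            f"{schedule.n_events} events exceed the enumeration cap {max_events}"
        )

    def gen(level: int):
        if level == schedule.n_events:
            yield (), 1.0
            return
        r = schedule.ploidies[level]
        subtrees = list(gen(level + 1))
        for c in range(1, r + 1):
            p = params.p(level + 1, c)
            if p == 0.0:
                continue
            for combo in itertools.product(subtrees, repeat=c):
                w = p
                for _, cw in combo:
                    w *= cw
                yield tuple(t for t, _ in combo), w

    return [Genealogy(schedule, tree, w) for tree, w in gen(0)]


def trajectory_probability(
    schedule, params: SurvivalParams, counts: TrajectoryCounts
) -> float:
    """Probability of a survivor-count trajectory (product of multinomials, Eq.-2 form)."""
    schedule = _as_schedule(schedule)
    params.validate_for(schedule)
    if len(counts.a) != schedule.n_events:
        raise ValueError("counts must cover every event")
    for i, r in enumerate(schedule):
        if len(counts.a[i]) != r:
            raise ValueError(f"event {i + 1}: expected {r} count entries")
    m = counts.gene_counts()  # validates the identities
    prob = 1.0
    for i, row in enumerate(counts.a):
        coeff = math.factorial(m[i])
        for x in row:
            coeff //= math.factorial(x)
        prob *= coeff
        for j, x in enumerate(row, start=1):
            prob *= params.p(i + 1, j) ** x
    return prob


def classify_triplet(
    genealogy: Genealogy, leaves: Sequence[Tuple[int, ...]]
) -> TripletType:
    """Type of a leaf triple: multiset of the three pairwise LCA event indices."""
    if len(leaves) != 3 or len(set(leaves)) != 3:
        raise ValueError("three distinct leaves required")
    known = set(genealogy.leaves())
    for leaf in leaves:
        if tuple(leaf) not in known:
            raise ValueError(f"unknown leaf {leaf}")

    def lca_event(a, b) -> int:
        for i, (x, y) in enumerate(zip(a, b)):
            if x != y:
                return i + 1
        raise ValueError("identical leaves")

    a, b, c = (tuple(leaf) for leaf in leaves)
    return tuple(sorted((lca_event(a, b), lca_event(a, c), lca_event(b, c))))


# ---------------------------------------------------------------------------
# exhaustive expectation engine (shape table)
# ---------------------------------------------------------------------------
#
# Genealogy shapes are enumerated once per schedule.  Each shape carries exact
# leaf/pair/triple counts and the exponent of every survival probability, so
# expectations for any parameter values are a single weighted sum.  Shapes
# with identical counts and exponents are aggregated with multiplicities.


class _ShapeTable:
    __slots__ = ("schedule", "slots", "exponents", "mult", "leaves", "pairs",
                 "triples", "types")

    def __init__(self, schedule, slots, exponents, mult, leaves, pairs,
                 triples, types):
        self.schedule = schedule
        self.slots = slots          # [(event, j)] order of exponent columns
        self.exponents = exponents  # (n_entries, n_slots) int array
        self.mult = mult            # (n_entries,) multiplicities
        self.leaves = leaves        # (n_entries,)
        self.pairs = pairs          # (n_entries, m) pair counts by event
        self.triples = triples      # (n_entries, n_types)
        self.types = types

    def weights(self, params: SurvivalParams) -> np.ndarray:
        p = np.array(
            [params.p(event, j) for event, j in self.slots], dtype=float
        )
        return self.mult * np.prod(
            np.power(p[None, :], self.exponents), axis=1
        )


@lru_cache(maxsize=64)
def _shape_table(ploidies: Tuple[int, ...]) -> _ShapeTable:
    schedule = EventSchedule(ploidies)
    m = schedule.n_events
    types = triplet_types(m)
    type_index = {t: k for k, t in enumerate(types)}
    slots = [(i + 1, j) for i, r in enumerate(ploidies) for j in range(1, r + 1)]
    slot_index = {s: k for k, s in enumerate(slots)}

    # Entry: (exp tuple, leaves, pairs tuple, triples tuple) -> multiplicity
    def level(i: int) -> List[tuple]:
        if i == m:
            exp = (0,) * len(slots)
            return [(exp, 1, (0,) * m, (0,) * len(types), 1)]
        sub = level(i + 1)
        event = i + 1
        out: Dict[tuple, int] = {}
        r = ploidies[i]
        for c in range(1, r + 1):
            for combo in itertools.combinations_with_replacement(
                range(len(sub)), c
            ):
                # ordered arrangements of this multiset of child entries
                mult = math.factorial(c)
                for k in set(combo):
                    mult //= math.factorial(combo.count(k))
                children = [sub[k] for k in combo]
                for child in children:
                    mult *= child[4]

                exp = [0] * len(slots)
                exp[slot_index[(event, c)]] = 1
                leaves = 0
                pairs = [0] * m
                trip = [0] * len(types)
                ls = []
                for child in children:
                    for s in range(len(slots)):
                        exp[s] += child[0][s]
                    leaves += child[1]
                    for e in range(m):
                        pairs[e] += child[2][e]
                    for k in range(len(types)):
                        trip[k] += child[3][k]
                    ls.append(child[1])
                # pairs split across children diverge at this event
                cross2 = 0
                for a in range(len(ls)):
                    for b in range(a + 1, len(ls)):
                        cross2 += ls[a] * ls[b]
                pairs[event - 1] += cross2
                # triples: one leaf per three children
                cross3 = 0
                for a in range(len(ls)):
                    for b in range(a + 1, len(ls)):
                        for d in range(b + 1, len(ls)):
                            cross3 += ls[a] * ls[b] * ls[d]
                if cross3:
                    trip[type_index[(event, event, event)]] += cross3
                # triples: a deeper pair in one child, a singleton in another
                for a, child_a in enumerate(children):
                    for e in range(event, m + 1):
                        pe = child_a[2][e - 1]
                        if not pe:
                            continue
                        others = leaves - ls[a]
                        key = tuple(sorted((event, event, e)))
                        trip[type_index[key]] += pe * others

                key = (tuple(exp), leaves, tuple(pairs), tuple(trip))
                out[key] = out.get(key, 0) + mult
        return [(e, l, p, t, mu) for (e, l, p, t), mu in out.items()]

    entries = level(0)
    return _ShapeTable(
        schedule,
        slots,
        np.array([e[0] for e in entries], dtype=np.int64),
        np.array([e[4] for e in entries], dtype=float),
        np.array([e[1] for e in entries], dtype=float),
        np.array([e[2] for e in entries], dtype=float),
        np.array([e[3] for e in entries], dtype=float),
        types,
    )


def _table_for(schedule, max_events: int) -> _ShapeTable:
    schedule = _as_schedule(schedule)
    if schedule.n_events > max_events:
        raise ValueError(
            f"{schedule.n_events} events exceed the enumeration cap {max_events}"
        )
    return _shape_table(schedule.ploidies)


def expected_gene_count(schedule, params: SurvivalParams,
                        max_events: int = MAX_ENUMERATION_EVENTS) -> float:
    """Expected extant genes per root, by exhaustive enumeration (Eq.-3 sum)."""
    schedule = _as_schedule(schedule)
    params.validate_for(schedule)
    table = _table_for(schedule, max_events)
    return float(table.weights(params) @ table.leaves)


def expected_pair_counts(schedule, params: SurvivalParams,
                         max_events: int = MAX_ENUMERATION_EVENTS
                         ) -> Dict[int, float]:
    """Expected paralog pairs per root, keyed by event of origin (enumeration)."""
    schedule = _as_schedule(schedule)
    params.validate_for(schedule)
    table = _table_for(schedule, max_events)
    vals = table.weights(params) @ table.pairs
    return {e + 1: float(vals[e]) for e in range(schedule.n_events)}


def expected_triplet_profile_bruteforce(
    schedule, params: SurvivalParams, max_events: int = MAX_ENUMERATION_EVENTS
) -> Profile:
    """Expected triplet profile per root by exhaustive genealogy enumeration."""
    schedule = _as_schedule(schedule)
    params.validate_for(schedule)
    table = _table_for(schedule, max_events)
    vals = table.weights(params) @ table.triples
    return Profile(
        {t: float(v) for t, v in zip(table.types, vals)},
        label="underlying",
        n_events=schedule.n_events,
    )


# ---------------------------------------------------------------------------
# closed forms (two and three events)
# ---------------------------------------------------------------------------


def _closed_values(schedule: EventSchedule, params: SurvivalParams
                   ) -> Dict[TripletType, float]:
    m = schedule.n_events
    A = [params.pair_factor(e) for e in range(1, m + 1)]
    B = [params.growth_factor(e) for e in range(1, m + 1)]
    C = [params.triple_factor(e) for e in range(1, m + 1)]
    if m == 2:
        return {
            (1, 1, 1): C[0] * B[1] ** 3,
            (1, 1, 2): 2.0 * A[0] * A[1] * B[1],
            (1, 2, 2): 0.0,
            (2, 2, 2): B[0] * C[1],
        }
    # three events
    return {
        (1, 1, 1): C[0] * (B[1] * B[2]) ** 3,
        (1, 1, 2): 2.0 * A[0] * A[1] * B[1] * B[2] ** 3,
        (1, 1, 3): 2.0 * A[0] * A[2] * B[1] ** 2 * B[2],
        (1, 2, 2): 0.0,
        (1, 2, 3): 0.0,
        (1, 3, 3): 0.0,
        (2, 2, 2): B[0] * C[1] * B[2] ** 3,
        (2, 2, 3): 2.0 * B[0] * A[1] * A[2] * B[2],
        (2, 3, 3): 0.0,
        (3, 3, 3): B[0] * B[1] * C[2],
    }


def expected_triplet_profile_closed(schedule, params: SurvivalParams) -> Profile:
    """Closed-form expected triplet profile for two- or three-event models.

    Evaluates the published per-model polynomials in u, u', v, v', w, w'
    (written here through the per-event factors E[C(c,2)], E[c], E[C(c,3)],
    which reproduce each printed term exactly).
    """
    schedule = _as_schedule(schedule)
    params.validate_for(schedule)
    if schedule.n_events not in (2, 3):
        raise ValueError(
            "closed forms cover 2 or 3 events; use the brute-force enumerator"
        )
    return Profile(
        _closed_values(schedule, params),
        label="underlying",
        n_events=schedule.n_events,
    )


def _closed_pair_counts(schedule: EventSchedule, params: SurvivalParams
                        ) -> np.ndarray:
    """Expected pairs per root by event, in closed form (any m)."""
    m = schedule.n_events
    B = [params.growth_factor(e) for e in range(1, m + 1)]
    out = np.empty(m)
    for e in range(1, m + 1):
        before = math.prod(B[: e - 1])
        after = math.prod(B[e:])
        out[e - 1] = before * params.pair_factor(e) * after ** 2
    return out


def _closed_gene_count(schedule: EventSchedule, params: SurvivalParams,
                       observable_only: bool = False) -> float:
    m = schedule.n_events
    total = math.prod(params.growth_factor(e) for e in range(1, m + 1))
    if observable_only:
        # singleton families (every draw leaves one survivor) yield no pairs
        singleton = math.prod(params.p(e, 1) for e in range(1, m + 1))
        total -= singleton
    return total


# ---------------------------------------------------------------------------
# survival-parameter estimation
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    """Estimated survival parameters with the implied root count."""

    schedule: EventSchedule
    params: SurvivalParams
    root_count: float
    residual: float
    rates: Tuple[float, ...] = ()
    method: str = "moments"

    def expected_pair_counts(self) -> Dict[int, float]:
        vals = self.root_count * _closed_pair_counts(self.schedule, self.params)
        return {e + 1: float(v) for e, v in enumerate(vals)}


def _rate_bounds(schedule: EventSchedule) -> Tuple[np.ndarray, np.ndarray]:
    # for triplings under p3 = p2^2, p1 >= 0 forces p2 <= (sqrt(5)-1)/2
    upper = np.array(
        [1.0 if r == 2 else (math.sqrt(5.0) - 1.0) / 2.0 for r in schedule]
    )
    return np.zeros(len(upper)), upper


def estimate_survival_params(
    schedule,
    observed_pair_counts: Mapping[int, float],
    total_genes: float,
    squared: bool = True,
    observable_only: bool = False,
    method: str = "moments",
) -> SurvivalFit:
    """Estimate survival rates (u, v, ...) and the root count G from pair data.

    Matches ``G x`` expected per-root pair counts per event and ``G x`` the
    expected gene count against the observations by bounded least squares on
    relative error (``method="moments"``), or maximizes a multinomial
    likelihood over the pair-event categories augmented with the gene count
    (``method="multinomial"``; the augmentation makes the rates identifiable
    and equals a joint Poisson likelihood with G profiled out).  Tripling events use the squared constraint
    ``p_3 = p_2**2`` (required for identifiability from pair counts).
    """
    schedule = _as_schedule(schedule)
    if not squared and any(r == 3 for r in schedule):
        raise ValueError(
            "estimation with free p_3 is unidentifiable from pair counts; "
            "the squared constraint is required for tripling events"
        )
    m = schedule.n_events
    obs = np.array(
        [float(observed_pair_counts.get(e, 0.0)) for e in range(1, m + 1)]
    )
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if np.all(obs == 0):
        raise ValueError("all pair counts are zero: nothing to estimate")
    total_genes = float(total_genes)

    lo, hi = _rate_bounds(schedule)

    def params_of(theta: np.ndarray) -> SurvivalParams:
        return SurvivalParams.from_rates(schedule, theta, squared=True)

    def model_counts(theta: np.ndarray) -> Tuple[np.ndarray, float]:
        p = params_of(np.clip(theta, lo, hi))
        return (
            _closed_pair_counts(schedule, p),
            _closed_gene_count(schedule, p, observable_only=observable_only),
        )

    targets = np.append(obs, total_genes)
    denom = np.maximum(targets, 1.0)

    if method == "moments":

        def residuals(theta: np.ndarray) -> np.ndarray:
            pairs, genes = model_counts(theta)
            per_root = np.append(pairs, genes)
            ratio = per_root / denom
            ssq = float(ratio @ ratio)
            g = float(ratio @ (targets / denom)) / ssq if ssq > 0 else 0.0
            return (g * per_root - targets) / denom

        best = None
        for start in ([0.5] * m, [0.2] * m, [0.6] * m if np.all(hi >= 0.6) else [0.55] * m):
            sol = optimize.least_squares(
                residuals, np.clip(np.array(start, dtype=float), lo + 1e-6, hi - 1e-6),
                bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        theta = np.clip(best.x, lo, hi)
        pairs, genes = model_counts(theta)
        per_root = np.append(pairs, genes)
        ratio = per_root / denom
        g = float(ratio @ (targets / denom)) / float(ratio @ ratio)
        residual = float(np.sqrt(2.0 * best.cost))
    elif method == "multinomial":
        # pair-event categories alone leave a flat ridge (m proportions with
        # m - 1 degrees of freedom for m rates), so the gene count joins the
        # category vector; with G profiled out this is a joint Poisson ML.

        def negloglik(theta: np.ndarray) -> float:
            pairs, genes = model_counts(theta)
            cats = np.append(pairs, genes)
            total = cats.sum()
            if total <= 0 or np.any(cats[targets > 0] <= 0):
                return np.inf
            probs = np.clip(cats / total, 1e-300, 1.0)
            return -float(targets @ np.log(probs))

        best = None
        for start in ([0.5] * m, [0.2] * m):
            sol = optimize.minimize(
                negloglik, np.clip(np.array(start, dtype=float), lo + 1e-6, hi - 1e-6),
                bounds=list(zip(lo + 1e-9, hi - 1e-9)), method="L-BFGS-B",
                options={"ftol": 1e-15, "gtol": 1e-12},
            )
            if best is None or sol.fun < best.fun:
                best = sol
        theta = np.clip(best.x, lo, hi)
        pairs, genes = model_counts(theta)
        per_root = np.append(pairs, genes)
        g = float(targets.sum() / per_root.sum())
        residual = float(np.linalg.norm((g * per_root - targets) / denom))
    else:
        raise ValueError(f"unknown method {method!r}")

    at_zero = [e + 1 for e in range(m) if theta[e] < 1e-8 and obs[e] == 0]
    if at_zero:
        warnings.warn(
            f"no observed pairs for event(s) {at_zero}: survival rate "
            "estimated at the boundary 0",
            stacklevel=2,
        )
    if residual > 0.05:
        logger.warning(
            "survival fit for %s leaves relative residual %.3g",
            schedule.label(), residual,
        )
    return SurvivalFit(
        schedule=schedule,
        params=params_of(theta),
        root_count=float(g),
        residual=residual,
        rates=tuple(float(t) for t in theta),
        method=method,
    )
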