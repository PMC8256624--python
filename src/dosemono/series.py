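"""Decomposition of partially ordered dose sets into fully orderable
analysis series.

Doses in combination trials are multi-agent amounts compared component-wise
(product order): dose a is below dose b when every agent's amount in a is at
most that in b, strictly for at least one agent.  Two doses that each exceed
the other in one agent — e.g. (A=10, B=20) versus (A=20, B=10) — are
incomparable, and a dose-event curve cannot be fit across them.  Such dose
sets are decomposed into fully ordered chains ("analysis series"): the
longest series is made as long as possible, every dose is kept, and a dose
is shared between series only when the alternative is an orphan (a series
of size one).  Ties between equally good decompositions are broken by
preferring fewer total repetitions, then lexicographic order of dose labels,
so the output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DoseCombination",
    "SeriesPoint",
    "AnalysisSeries",
    "Ordering",
    "compare_doses",
    "build_series",
    "make_analysis_series",
]


class Ordering(str, Enum):
    LESS = "less"
    GREATER = "greater"
    EQUAL = "equal"
    INCOMPARABLE = "incomparable"


@dataclass(frozen=True)
class DoseCombination:
    """One administered dose: a map of agent name to nonnegative amount.

    Units are free text and assumed consistent within a study; amounts are
    never converted.  An agent absent from the map is an amount of zero.
    """

    components: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a dose needs at least one component")
        for agent, amount in self.components.items():
            if not (amount >= 0 and amount == amount and amount != float("inf")):
                raise ValueError(f"amount for {agent!r} must be finite and >= 0")
        object.__setattr__(self, "components", dict(self.components))
        if not self.label:
            object.__setattr__(
                self,
                "label",
                ";".join(f"{a}={g}" for a, g in sorted(self.components.items())),
            )

    def __hash__(self) -> int:
        return hash(frozenset(self.components.items()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, DoseCombination):
            return NotImplemented
        return dict(self.components) == dict(other.components)


def compare_doses(a: DoseCombination, b: DoseCombination) -> Ordering:
    """Component-wise (product-order) comparison of two doses.

    ``a`` is below ``b`` iff every agent's amount in ``a`` is <= that in
    ``b`` (missing agents count as zero), with strict inequality for at
    least one agent; symmetric for above; equal iff identical maps;
    otherwise incomparable.
    """
    agents = set(a.components) | set(b.components)
    any_lt = any_gt = False
    for agent in agents:
        av = a.components.get(agent, 0.0)
        bv = b.components.get(agent, 0.0)
        if av < bv:
            any_lt = True
        elif av > bv:
            any_gt = True
    if any_lt and any_gt:
        return Ordering.INCOMPARABLE
    if any_lt:
        return Ordering.LESS
    if any_gt:
        return Ordering.GREATER
    return Ordering.EQUAL


@dataclass(frozen=True)
class SeriesPoint:
    """One dose-level of an analysis series with its outcome counts."""

    dose: DoseCombination
    level: int
    n: int
    events: int

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("levels start at 1")
        if self.n < 1:
            raise ValueError("n must be a positive patient count")
        if not (0 <= self.events <= self.n):
            raise ValueError("events must satisfy 0 <= events <= n")


@dataclass(frozen=True)
class AnalysisSeries:
    """A fully ordered sequence of dose-levels with per-level counts for
    one outcome (DLT or OR) in one study.

    Levels run 1..K with no gaps and doses are strictly ascending under
    the component-wise partial order.  Series with a single level carry no
    gradient information and are flagged non-fittable.
    """

    study_id: str
    outcome: str  # "DLT" or "OR"
    points: tuple[SeriesPoint, ...]
    series_id: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in ("DLT", "OR"):
            raise ValueError("outcome must be 'DLT' or 'OR'")
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        for k, pt in enumerate(pts, start=1):
            if pt.level != k:
                raise ValueError("levels must be 1..K with no gaps")
        for lo, hi in zip(pts, pts[1:]):
            if compare_doses(lo.dose, hi.dose) is not Ordering.LESS:
                raise ValueError(
                    f"doses must be strictly ascending: {lo.dose.label!r} vs "
                    f"{hi.dose.label!r}"
                )
        if not self.series_id:
            object.__setattr__(self, "series_id", f"{self.study_id}-{self.outcome}-1")

    @property
    def n_levels(self) -> int:
        return len(self.points)

    @property
    def fittable(self) -> bool:
        return len(self.points) >= 2

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(p.level for p in self.points)


# ---------------------------------------------------------------------------
# chain decomposition


def _chain_key(chain: Sequence[DoseCombination]) -> tuple[str, ...]:
    return tuple(d.label for d in chain)


def _maximal_chains(doses: Sequence[DoseCombination]) -> list[tuple[int, ...]]:
    """All inclusion-maximal chains of the partial order, as index tuples."""
    n = len(doses)
    below = [[j for j in range(n)
              if compare_doses(doses[i], doses[j]) is Ordering.LESS]
             for i in range(n)]
    minimal = [i for i in range(n)
               if not any(i in below[j] for j in range(n))]
    # covers: j covers i if i < j with nothing strictly between
    covers = [[j for j in below[i]
               if not any(k in below[i] and j in below[k] for k in below[i])]
              for i in range(n)]
    chains: list[tuple[int, ...]] = []

    def extend(path: list[int]) -> None:
        succ = covers[path[-1]]
        if not succ:
            chains.append(tuple(path))
            return
        for j in succ:
            extend(path + [j])

    for i in minimal:
        extend([i])
    return chains


def build_series(doses: Sequence[DoseCombination]) -> list[list[DoseCombination]]:
    """Decompose a set of distinct doses into fully ordered chains.

    The returned chains cover every dose; the longest chain is a
    maximum-length chain of the partial order; a dose is repeated across
    chains only when the alternative would leave an orphan (a chain of
    size 1).  Every emitted chain is inclusion-maximal — a series always
    absorbs each dose comparable with all of its members, since dropping
    observed doses from a series would discard data.  Among such covers
    the one with fewest orphans, then fewest total repetitions, then
    lexicographically smallest label sequence is returned, so the result
    is deterministic.
    """
    doses = list(doses)
    if not doses:
        return []
    if len(set(doses)) != len(doses):
        raise ValueError("doses must be pairwise distinct")

    chains = _maximal_chains(doses)
    max_len = max(len(c) for c in chains)
    # candidate chains, sorted for deterministic search order
    chains.sort(key=lambda c: tuple(doses[i].label for i in c))

    n = len(doses)
    member: list[list[int]] = [[] for _ in range(n)]
    for ci, chain in enumerate(chains):
        for i in chain:
            member[i].append(ci)

    best: tuple | None = None  # (n_orphans, n_repetitions, labels_key, cover)

    def score(cover: list[int]) -> tuple:
        orphans = sum(1 for ci in cover if len(chains[ci]) == 1)
        total = sum(len(chains[ci]) for ci in cover)
        reps = total - n
        labels = tuple(sorted(_chain_key([doses[i] for i in chains[ci]])
                              for ci in cover))
        return (orphans, reps, labels)

    def search(cover: list[int], covered: set[int]) -> None:
        nonlocal best
        if best is not None:
            # prune on (orphans-so-far, reps-so-far)
            orphans = sum(1 for ci in cover if len(chains[ci]) == 1)
            reps = sum(len(chains[ci]) for ci in cover) - len(covered)
            if (orphans, reps) > best[:2]:
                return
        if len(covered) == n:
            s = score(cover)
            if best is None or s < best[:3]:
                best = (*s, sorted(cover))
            return
        target = min(i for i in range(n) if i not in covered)
        for ci in member[target]:
            if ci in cover:
                continue
            search(cover + [ci], covered | set(chains[ci]))

    # seed with each maximum-length chain so the longest returned chain is
    # always a maximum chain of the partial order
    for ci, chain in enumerate(chains):
        if len(chain) == max_len:
            search([ci], set(chain))
    assert best is not None
    result = [[doses[i] for i in chains[ci]] for ci in best[3]]
    result.sort(key=_chain_key)
    return result


def make_analysis_series(
    study_id: str,
    records: Iterable,
    outcome: str,
) -> list[AnalysisSeries]:
    """Build the analysis series for one outcome from a study's dose rows.

    Only doses with a non-missing count pair for the requested outcome
    enter the decomposition; counts are attached and ordinal levels 1..K
    assigned within each chain.  Returns an empty list when no dose
    reports the outcome.  Size-1 chains are emitted (flagged non-fittable
    via :attr:`AnalysisSeries.fittable`).
    """
    if outcome not in ("DLT", "OR"):
        raise ValueError("outcome must be 'DLT' or 'OR'")
    recs = list(records)
    if any(r.study_id != study_id for r in recs):
        raise ValueError("records must all belong to the given study")

    usable = []
    for r in recs:
        if outcome == "DLT":
            n, events = r.n_evaluable_dlt, r.n_dlt
        else:
            n, events = r.n_evaluable_or, r.n_or
        if n is None or events is None or n == 0:
            continue
        usable.append((DoseCombination(r.dose_components, label=r.dose_label), n, events))

    if not usable:
        return []
    counts = {dose: (n, events) for dose, n, events in usable}
    chains = build_series([dose for dose, _, _ in usable])

    out: list[AnalysisSeries] = []
    for idx, chain in enumerate(chains, start=1):
        points = tuple(
            SeriesPoint(dose=d, level=k, n=counts[d][0], events=counts[d][1])
            for k, d in enumerate(chain, start=1)
        )
        out.append(
            AnalysisSeries(
                study_id=study_id,
                outcome=outcome,
                points=points,
                series_id=f"{study_id}-{outcome}-{idx}",
            )
        )
    return out
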