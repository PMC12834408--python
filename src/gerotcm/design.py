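"""Composition of novel formulas by greedy maximum coverage over herbs.

Given a target compound set, herbs are selected one at a time to maximize
the number of newly covered target compounds, subject to constraints
(herb-count cap, exclusion of animal-derived herbs, explicit include/exclude
lists).  Greedy selection carries the classic (1 - 1/e) approximation
guarantee for maximum coverage.  Ties break toward the herb with fewer
total compounds (parsimony), then lexicographic id, so selections are fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .datamodel import ConfigError, TCMDatabase


class ConstraintError(ValueError):
    """Raised when constraints leave no eligible herbs."""


@dataclass(frozen=True)
class DesignConstraints:
    max_herbs: Optional[int] = None
    exclude_animal_derived: bool = False
    excluded_herb_ids: frozenset[str] = frozenset()
    required_herb_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "excluded_herb_ids", frozenset(self.excluded_herb_ids))
        object.__setattr__(self, "required_herb_ids", frozenset(self.required_herb_ids))
        if self.required_herb_ids & self.excluded_herb_ids:
            raise ConfigError("required and excluded herb sets overlap")
        if self.max_herbs is not None and self.max_herbs < 1:
            raise ConfigError("max_herbs must be positive")


@dataclass
class DesignStep:
    herb_id: str
    newly_covered: frozenset[str]
    cumulative_coverage: int
    forced: bool = False  # seeded via required_herb_ids


@dataclass
class DesignResult:
    """An ordered herb selection with its per-step coverage audit."""

    target_compounds: frozenset[str]
    steps: list[DesignStep] = field(default_factory=list)
    covered: frozenset[str] = frozenset()
    #: audit notes: constraint relaxations, unknown-annotation herbs, etc.
    audit: list[str] = field(default_factory=list)

    @property
    def herbs(self) -> list[str]:
        return [s.herb_id for s in self.steps]

    @property
    def uncovered(self) -> frozenset[str]:
        return self.target_compounds - self.covered

    @property
    def coverage(self) -> int:
        return len(self.covered)


def _eligible_herbs(db: TCMDatabase, constraints: DesignConstraints, audit: list[str]) -> list[str]:
    pool = []
    unknown_animal = 0
    for hid in sorted(db.herbs):
        if hid in constraints.excluded_herb_ids:
            continue
        herb = db.herbs[hid]
        if constraints.exclude_animal_derived:
            if herb.animal_derived is True:
                continue
            if herb.animal_derived is None:
                # annotation absent in many dumps: eligible but flagged
                unknown_animal += 1
        pool.append(hid)
    if unknown_animal:
        audit.append(
            f"{unknown_animal} eligible herbs lack an animal-derived annotation"
        )
    return pool


def _greedy(
    db: TCMDatabase,
    target: frozenset[str],
    constraints: DesignConstraints,
    max_steps: Optional[int],
) -> DesignResult:
    audit: list[str] = []
    result = DesignResult(target_compounds=target, audit=audit)
    pool = _eligible_herbs(db, constraints, audit)
    if not pool:
        raise ConstraintError("no eligible herbs after applying constraints")
    missing_req = constraints.required_herb_ids - set(pool)
    if missing_req:
        raise ConstraintError(f"required herbs not eligible: {sorted(missing_req)}")

    covered: set[str] = set()
    chosen: list[str] = []

    def add(hid: str, forced: bool) -> None:
        gain = (db.herbs[hid].compounds & target) - covered
        covered.update(gain)
        chosen.append(hid)
        result.steps.append(
            DesignStep(hid, frozenset(gain), len(covered), forced=forced)
        )

    for hid in sorted(constraints.required_herb_ids):
        add(hid, forced=True)

    candidates = [h for h in pool if h not in chosen]
    while True:
        if max_steps is not None and len(chosen) >= max_steps:
            break
        if covered >= target:
            break
        best_hid, best_gain = None, -1
        for hid in candidates:
            gain = len((db.herbs[hid].compounds & target) - covered)
            if gain > best_gain or (
                gain == best_gain
                and best_hid is not None
                and (
                    len(db.herbs[hid].compounds),
                    hid,
                ) < (len(db.herbs[best_hid].compounds), best_hid)
            ):
                best_hid, best_gain = hid, gain
        if best_hid is None:
            break
        if best_gain == 0:
            # never pad with zero-gain herbs, even in fixed-size designs
            break
        add(best_hid, forced=False)
        candidates.remove(best_hid)

    result.covered = frozenset(covered)
    if constraints.max_herbs is not None and len(chosen) > constraints.max_herbs:
        raise ConstraintError(
            f"required herbs ({len(chosen)}) exceed max_herbs={constraints.max_herbs}"
        )
    return result


def greedy_design(
    db: TCMDatabase,
    compound_set: Iterable[str],
    constraints: Optional[DesignConstraints] = None,
) -> DesignResult:
    """Greedy maximum-coverage herb selection for a target compound set.

    Selection stops when marginal gain reaches zero, the target set is fully
    covered, or ``constraints.max_herbs`` is reached.  Required herbs are
    seeded first (in id order) and count toward the cap.
    """
    target = frozenset(compound_set)
    if not target:
        raise ConfigError("compound_set is empty")
    constraints = constraints or DesignConstraints()
    return _greedy(db, target, constraints, constraints.max_herbs)


def design_k_herbs(
    db: TCMDatabase,
    compound_set: Iterable[str],
    k: int,
    constraints: Optional[DesignConstraints] = None,
) -> DesignResult:
    """Greedy design truncated at exactly ``k`` herb selections.

    If marginal gain runs out before ``k`` herbs, the result is shorter and
    the audit says so — zero-gain herbs are never added to pad the formula.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    target = frozenset(compound_set)
    if not target:
        raise ConfigError("compound_set is empty")
    constraints = constraints or DesignConstraints()
    if constraints.max_herbs is not None and constraints.max_herbs < k:
        raise ConfigError(f"max_herbs={constraints.max_herbs} < k={k}")
    result = _greedy(db, target, constraints, k)
    if len(result.herbs) < k:
        result.audit.append(
            f"marginal gain exhausted after {len(result.herbs)} herb(s); "
            f"requested size k={k} not reached"
        )
    return result


def exhaustive_best_coverage(
    db: TCMDatabase,
    compound_set: Iterable[str],
    k: int,
    herb_pool: Optional[Iterable[str]] = None,
) -> tuple[frozenset[str], int]:
    """Best k-herb coverage by exhaustive subset search (small pools only).

    Returns (best herb subset, its coverage).  Intended as an optimality
    reference at test scale; cost grows as C(n, k).
    """
    from itertools import combinations

    target = frozenset(compound_set)
    pool = sorted(herb_pool) if herb_pool is not None else sorted(db.herbs)
    if len(pool) > 25:
        raise ConfigError("exhaustive search limited to pools of <= 25 herbs")
    best_set: frozenset[str] = frozenset()
    best_cov = -1
    k = min(k, len(pool))
    for combo in combinations(pool, k):
        cov: set[str] = set()
        for hid in combo:
            cov |= db.herbs[hid].compounds & target
        if len(cov) > best_cov:
            best_set, best_cov = frozenset(combo), len(cov)
    return best_set, best_cov
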