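"""Minimum AND-combination marker sets for target-cultivar identification.

A sample is called the target only when every marker in the set
amplifies; the set is *unique* when no other cultivar carries all of its
members.  Equivalently this is a set-cover problem: each chosen marker
excludes the non-target cultivars lacking it, and the set must exclude
them all.  Only presences in the target are usable (dominant markers:
an absent fragment on a gel proves nothing about a failed PCR), so
candidates are the target-present, non-control markers.

``minimal_and_set`` enumerates subsets by increasing size — exact, fine
for panels of tens of markers; ``greedy_and_set`` is the scalable
fallback for large panels and upper-bounds the exact answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .genotype import GenotypeMatrix

DEFAULT_MAX_K = 4


@dataclass(frozen=True)
class MarkerSet:
    target: str
    members: tuple[str, ...]
    unique: bool

    @property
    def size(self) -> int:
        return len(self.members)


def _candidate_markers(matrix: GenotypeMatrix, target: str,
                       restrict=None) -> list[str]:
    if target not in matrix.data.index:
        raise KeyError(f"unknown cultivar {target!r}")
    pool = matrix.informative_markers()
    if restrict is not None:
        restrict = list(restrict)
        unknown = [m for m in restrict if m not in matrix.data.columns]
        if unknown:
            raise KeyError(f"unknown markers {unknown}")
        pool = [m for m in pool if m in set(restrict)]
    return sorted(m for m in pool if matrix.presence(target, m) == 1)


def _carrier_masks(matrix: GenotypeMatrix, markers: list[str]) -> dict[str, int]:
    """Bitmask per marker over the cultivar index order."""
    masks = {}
    for m in markers:
        col = matrix.data[m].to_numpy()
        mask = 0
        for i, bit in enumerate(col):
            if bit:
                mask |= 1 << i
        masks[m] = mask
    return masks


def verify_uniqueness(matrix: GenotypeMatrix, target: str,
                      members) -> tuple[bool, list[str]]:
    """Check the AND-rule: which non-target cultivars defeat the set?

    Returns ``(unique, offending)`` where offending lists every
    non-target cultivar carrying all members.  An empty member set is
    defeated by everyone (the empty conjunction holds vacuously).
    """
    if target not in matrix.data.index:
        raise KeyError(f"unknown cultivar {target!r}")
    members = list(members)
    unknown = [m for m in members if m not in matrix.data.columns]
    if unknown:
        raise KeyError(f"unknown markers {unknown}")
    offending = []
    for cultivar in matrix.cultivar_ids:
        if cultivar == target:
            continue
        if all(matrix.presence(cultivar, m) == 1 for m in members):
            offending.append(cultivar)
    return (not offending, offending)


def minimal_and_set(matrix: GenotypeMatrix, target: str,
                    max_k: int = DEFAULT_MAX_K,
                    candidates=None) -> MarkerSet:
    """Exhaustive minimum-size unique AND-set for ``target``.

    Subsets of the target-present markers are enumerated by increasing
    size, in lexicographic member order, and the first unique set is
    returned — so ties resolve to the lexicographically smallest member
    list.  ``candidates`` optionally restricts the marker pool (e.g. to
    the fragments actually primed into a kit).  When no subset of size
    <= max_k is unique, the best-covering
    set found (fewest surviving non-targets, then lexicographic) is
    returned with ``unique=False``.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    candidates = _candidate_markers(matrix, target, candidates)
    masks = _carrier_masks(matrix, candidates)
    target_bit = 1 << matrix.cultivar_ids.index(target)
    all_mask = (1 << matrix.n_cultivars) - 1
    nontarget_mask = all_mask & ~target_bit

    best: tuple[int, tuple[str, ...]] | None = None  # (n_offending, members)
    for k in range(1, max_k + 1):
        for combo in combinations(candidates, k):
            joint = nontarget_mask
            for m in combo:
                joint &= masks[m]
            if joint == 0:
                return MarkerSet(target=target, members=combo, unique=True)
            n_off = joint.bit_count()
            if best is None or n_off < best[0]:
                best = (n_off, combo)
    members = best[1] if best is not None else ()
    return MarkerSet(target=target, members=members, unique=False)


def greedy_and_set(matrix: GenotypeMatrix, target: str,
                   candidates=None) -> MarkerSet:
    """Greedy cover: repeatedly add the marker excluding most survivors.

    Ties break lexicographically.  Stops when every non-target is
    excluded (unique=True) or no candidate removes another survivor.
    The result is never smaller than the exhaustive minimum.
    """
    candidates = _candidate_markers(matrix, target, candidates)
    masks = _carrier_masks(matrix, candidates)
    target_bit = 1 << matrix.cultivar_ids.index(target)
    survivors = ((1 << matrix.n_cultivars) - 1) & ~target_bit

    chosen: list[str] = []
    remaining = list(candidates)
    while survivors and remaining:
        scored = sorted(remaining,
                        key=lambda m: ((survivors & masks[m]).bit_count(), m))
        pick = scored[0]
        new_survivors = survivors & masks[pick]
        if new_survivors == survivors:
            break  # nothing helps
        chosen.append(pick)
        remaining.remove(pick)
        survivors = new_survivors
    return MarkerSet(target=target, members=tuple(chosen), unique=survivors == 0)
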