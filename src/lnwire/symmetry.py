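"""Bilateral symmetry of innervation patterns and the random-pairing null.

The symmetry index of two neurons is the Jaccard similarity of their
innervated glomerulus sets: x/y with x the intersection size and y the
union size. Intraindividual pairs (left/right neurons of the same brain)
are compared against interindividual null cohorts built by randomly
re-matching hemispheres across brains, with same-brain pairs excluded by
construction.

Hemisphere labels follow the observer-view convention used throughout the
package: neurons labeled "R" sit in the fly's anatomical left hemisphere.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError
from .profiles import InnervationProfile, ProfileCollection

PAIRING_MODES = ("intra", "r_based", "l_based")

_MAX_RETRIES = 100


def symmetry_index(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Jaccard similarity |a n b| / |a u b| of two innervated-glomerulus sets.

    Symmetric in its arguments; 1 iff the sets are equal; 0 iff disjoint.
    Two empty sets are rejected (a labeled neuron always innervates
    something; a 0/0 here indicates a data bug upstream).
    """
    a, b = frozenset(set_a), frozenset(set_b)
    union = a | b
    if not union:
        raise ValueError("symmetry index undefined for two empty sets")
    return len(a & b) / len(union)


def profile_symmetry_index(left: InnervationProfile,
                           right: InnervationProfile) -> float:
    return symmetry_index(left.innervated_set(), right.innervated_set())


@dataclass
class HemispherePair:
    """Two profiles plus their symmetry index and pairing provenance."""

    left: InnervationProfile
    right: InnervationProfile
    group: str  # intra | r_based | l_based
    index: float = field(init=False)

    def __post_init__(self) -> None:
        if self.group not in PAIRING_MODES:
            raise ValueError(f"group must be one of {PAIRING_MODES}")
        same = self.left.brain_id == self.right.brain_id
        if self.group == "intra" and not same:
            raise IntegrityError("intra pair must share brain_id")
        if self.group != "intra" and same:
            raise IntegrityError("random pair must not share brain_id")
        self.index = profile_symmetry_index(self.left, self.right)


@dataclass
class PairingCohort:
    """A set of hemisphere pairs from one pairing procedure."""

    pairs: list[HemispherePair]
    group: str
    n_left: int
    n_right: int
    seed: int | None = None

    @property
    def indices(self) -> np.ndarray:
        return np.array([p.index for p in self.pairs])


def _split_hemispheres(collection: ProfileCollection
                       ) -> tuple[list[InnervationProfile],
                                  list[InnervationProfile]]:
    lefts = [p for p in collection if p.hemisphere == "L"]
    rights = [p for p in collection if p.hemisphere == "R"]
    return lefts, rights


def enumerate_intra_pairs(collection: ProfileCollection
                          ) -> list[HemispherePair]:
    """All same-brain left/right pairs (brains with exactly one profile per
    hemisphere). A brain with more than one profile in a hemisphere is a
    data-integrity violation."""
    by_brain: dict[str, dict[str, InnervationProfile]] = {}
    for p in collection:
        slot = by_brain.setdefault(p.brain_id, {})
        if p.hemisphere in slot:
            raise IntegrityError(
                f"brain {p.brain_id} has >1 profile in hemisphere "
                f"{p.hemisphere}")
        slot[p.hemisphere] = p
    pairs = []
    for brain in sorted(by_brain):
        slot = by_brain[brain]
        if "L" in slot and "R" in slot:
            pairs.append(HemispherePair(slot["L"], slot["R"], "intra"))
    return pairs


def _fix_same_brain(lefts: list[InnervationProfile],
                    rights: list[InnervationProfile],
                    rng: np.random.Generator) -> bool:
    """Swap-repair a matching in place so no slot pairs same-brain profiles.

    Returns True on success. ``rights[i]`` is the partner of ``lefts[i]``.
    """
    n = len(lefts)
    for _ in range(_MAX_RETRIES * n):
        bad = [i for i in range(n)
               if lefts[i].brain_id == rights[i].brain_id]
        if not bad:
            return True
        i = bad[0]
        candidates = [j for j in range(n) if j != i
                      and lefts[i].brain_id != rights[j].brain_id
                      and lefts[j].brain_id != rights[i].brain_id]
        if not candidates:
            return False
        j = int(rng.choice(candidates))
        rights[i], rights[j] = rights[j], rights[i]
    return False


def random_pairing(collection: ProfileCollection, mode: str,
                   seed: int) -> PairingCohort:
    """Interindividual null pairings of left and right hemispheres.

    With n left and m right profiles (requires m < n < 2m, the regime of
    the source cohorts):

    - ``r_based``: m of the n left profiles are sampled without
      replacement and matched one-to-one with the m right profiles
      -> m pairs (R-based / L-random).
    - ``l_based``: n - m right profiles are resampled uniformly without
      replacement from the m rights and appended, then the n rights are
      randomly matched one-to-one with the n lefts -> n pairs
      (L-based / R-random).

    Same-brain pairs never occur: the matching is re-drawn (bounded
    retries), then repaired by targeted swaps, so the stated pair counts
    are always achieved. Deterministic under a fixed seed.
    """
    if mode not in ("r_based", "l_based"):
        raise ValueError("mode must be 'r_based' or 'l_based'")
    lefts, rights = _split_hemispheres(collection)
    n, m = len(lefts), len(rights)
    if not (m < n < 2 * m):
        raise ValueError(
            f"random pairing requires m < n < 2m (got n={n} lefts, "
            f"m={m} rights)")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_RETRIES):
        if mode == "r_based":
            chosen = [lefts[i] for i in
                      rng.choice(n, size=m, replace=False)]
            partners = [rights[i] for i in rng.permutation(m)]
        else:
            extra_idx = rng.choice(m, size=n - m, replace=False)
            pool = rights + [rights[i] for i in extra_idx]
            chosen = list(lefts)
            partners = [pool[i] for i in rng.permutation(n)]
        if _fix_same_brain(chosen, partners, rng):
            pairs = [HemispherePair(l, r, mode)
                     for l, r in zip(chosen, partners)]
            return PairingCohort(pairs, mode, n_left=n, n_right=m,
                                 seed=seed)
    raise IntegrityError(
        "could not construct a same-brain-free matching (too many profiles "
        "share a brain_id)")


@dataclass
class SymmetryTestReport:
    """Kruskal-Wallis across groups plus pairwise rank-sum comparisons."""

    kruskal_h: float
    kruskal_p: float
    medians: dict[str, float]
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p

    def intra_exceeds(self, random_group: str, alpha: float = 0.05) -> bool:
        """Whether intra-pair indices are significantly larger than the
        given random group's (direction from medians, two-sided p)."""
        row = self.pairwise[
            ((self.pairwise.group_a == "intra")
             & (self.pairwise.group_b == random_group))
            | ((self.pairwise.group_a == random_group)
               & (self.pairwise.group_b == "intra"))]
        if row.empty:
            raise KeyError(f"no comparison intra vs {random_group}")
        return (self.medians["intra"] > self.medians[random_group]
                and float(row.iloc[0]["p"]) < alpha)


def compare_symmetry_groups(groups: Mapping[str, Sequence[float]]
                            ) -> SymmetryTestReport:
    """Kruskal-Wallis over >=2 groups of symmetry indices, then pairwise
    Wilcoxon rank-sum (Mann-Whitney, exact when sample sizes permit)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has <2 values")
    names = list(groups)
    h, p = stats.kruskal(*[np.asarray(groups[g], float) for g in names])
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.mannwhitneyu(groups[a], groups[b],
                                     alternative="two-sided", method="auto")
            rows.append({"group_a": a, "group_b": b,
                         "statistic": float(res.statistic),
                         "p": float(res.pvalue)})
    medians = {g: float(np.median(groups[g])) for g in names}
    return SymmetryTestReport(kruskal_h=float(h), kruskal_p=float(p),
                              medians=medians,
                              pairwise=pd.DataFrame(rows))
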