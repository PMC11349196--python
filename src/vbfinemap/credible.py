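"""LD-aware credible sets from posterior causal probabilities.

A level-q_thr credible set with purity eta is an index set U with
cumulative posterior probability P_k = sum_{i in U} q_i > q_thr whose
members are mutually correlated: min_{i,j in U} |r_ij| > eta.

Construction (greedy, in descending-q order):

1. sort the q_i descending (ties broken by original index);
2. seed up to L sets with the highest-q variants whose pairwise absolute
   correlation with every previously accepted seed is below eta;
3. walk the remaining sorted variants and assign each to the first set
   (in seed order) that still needs mass and whose current members are all
   correlated with it above eta in absolute value; assigned variants leave
   the pool;
4. a set stops growing once P_k > q_thr;
5. sets that never reach P_k > q_thr are dropped.

Anchoring step 3 on all current members (not only the seed) guarantees the
purity constraint by construction; under decaying LD two variants can each
tag the seed above eta yet fall below it with each other.  L defaults to
ceil(M * pi1) from the fitted prior causal fraction; for q_thr below 0.95
it is raised to ceil(M * pi1 * 0.95 / q_thr) since looser sets can be more
numerous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import LDMatrix


@dataclass
class CredibleSet:
    """Members (0-based indices, in join order), P_k, and purity."""

    members: list[int]
    pk: float
    purity: float


def default_num_sets(m: int, pi1: float, q_thr: float = 0.95) -> int:
    l = math.ceil(m * pi1)
    if q_thr < 0.95:
        l = math.ceil(m * pi1 * 0.95 / q_thr)
    return max(l, 1)


def build_credible_sets(
    q: np.ndarray,
    ld: LDMatrix,
    eta: float = 0.5,
    q_thr: float = 0.95,
    l: int | None = None,
    pi1: float | None = None,
) -> list[CredibleSet]:
    """Construct credible sets; ``l=None`` derives L from ``pi1`` (required then).

    Returns pairwise-disjoint sets, each satisfying P_k > q_thr and
    min pairwise |r| > eta, ordered by seed rank.
    """
    q = np.asarray(q, dtype=float)
    m = q.shape[0]
    if ld.m != m:
        raise ValueError(f"LD matrix is {ld.m}x{ld.m} but q has length {m}")
    if not 0.0 <= eta < 1.0:
        raise ValueError(f"eta={eta} must lie in [0, 1)")
    if not 0.0 < q_thr < 1.0:
        raise ValueError(f"q_thr={q_thr} must lie in (0, 1)")
    if l is None:
        if pi1 is None:
            raise ValueError("either l or pi1 must be given")
        l = default_num_sets(m, pi1, q_thr)
    if l < 1:
        raise ValueError("number of candidate sets must be >= 1")

    absr = np.abs(ld.r)
    order = np.argsort(-q, kind="stable")

    # Step 2: greedy seeding in descending-q order
    seeds: list[int] = []
    for i in order:
        if len(seeds) >= l:
            break
        if all(absr[i, s] < eta for s in seeds):
            seeds.append(int(i))

    members = [[s] for s in seeds]
    pk = [float(q[s]) for s in seeds]
    taken = set(seeds)

    # Steps 3-4: assign remaining variants until each set clears q_thr
    for i in order:
        i = int(i)
        if i in taken:
            continue
        for k in range(len(members)):
            if pk[k] > q_thr:
                continue
            if all(absr[i, j] > eta for j in members[k]):
                members[k].append(i)
                pk[k] += float(q[i])
                taken.add(i)
                break

    # Step 5: keep sets that reached the cumulative threshold
    out = []
    for k in range(len(members)):
        if pk[k] > q_thr:
            sub = absr[np.ix_(members[k], members[k])]
            purity = 1.0 if len(members[k]) == 1 else float(np.min(sub[np.triu_indices(len(members[k]), 1)]))
            out.append(CredibleSet(members=members[k], pk=float(np.sum(q[members[k]])), purity=purity))
    return out


def verify_credible_sets(
    sets: list[CredibleSet],
    q: np.ndarray,
    ld: LDMatrix,
    eta: float = 0.5,
    q_thr: float = 0.95,
) -> bool:
    """Independent post-hoc check of the two defining constraints plus
    disjointness; recomputes P_k and purity from scratch."""
    q = np.asarray(q, dtype=float)
    seen: set[int] = set()
    for cs in sets:
        if not cs.members:
            return False
        if seen.intersection(cs.members):
            return False
        seen.update(cs.members)
        pk = float(sum(q[i] for i in cs.members))
        if not (pk > q_thr and math.isclose(pk, cs.pk, rel_tol=1e-9, abs_tol=1e-12)):
            return False
        purity = min(
            (abs(ld.r[i, j]) for i in cs.members for j in cs.members if i < j),
            default=1.0,
        )
        if not (purity > eta and math.isclose(purity, cs.purity, rel_tol=1e-9, abs_tol=1e-12)):
            return False
    return True
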