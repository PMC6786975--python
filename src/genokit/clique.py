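"""Pedigree-feasibility analysis of mutually second-degree cliques.

A family network in which every pair is second-degree leaves three
possible relationship types per pair: half-siblings, grandparent–
grandchild, or avuncular (a full sibling of a parent).  Each type pins the
generation gap of the pair (0, 2 and 1 respectively), so a mutual clique
admits a consistent integer generation for every member spanning at most
three levels.  Within a level every pair must be half-siblings — sharing
exactly one parent (sharing both would make them full siblings, a
first-degree pair).  Across levels, avuncular and grandparent edges force
latent relatives: an uncle's nephew must have a parent who is a full
sibling of the uncle, and a grandchild must have a parent whose own parent
is the grandparent.

:func:`analyze_clique` searches all realizable configurations — level
assignments, within-level parent-sharing structures, and role assignments
of the latent parents — subject to the structural constraints (acyclic
generations, at most two parents per individual, implied parent links,
no parent–offspring or full-sibling pair inside the clique) and returns
the minimum achievable number of half-sibling pairs sharing one single
common parent, with a witnessing configuration.

Exploiting the complete symmetry of the clique (every member relates
identically to every other), the search enumerates level-size
compositions rather than labelled assignments, which keeps it exact and
fast for any clique size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb


@dataclass
class CliqueAnalysis:
    n_members: int
    n_pairs: int
    min_shared_parent_halfsib_pairs: int
    exact: bool
    certificate: dict


def _enumerate_families(n: int) -> list[list[frozenset]]:
    """All parent-pair assignments for ``n`` mutual half-siblings.

    Each member gets an unordered pair of parent ids; every two members
    must share exactly one parent.  Ids are allocated canonically
    (first-use order), so the enumeration is small: a star (one common
    parent) for any n, plus the parent-triangle for n <= 3.
    """
    results: list[list[frozenset]] = []

    def rec(assigned: list[frozenset], next_id: int) -> None:
        if len(assigned) == n:
            results.append(list(assigned))
            return
        candidates = []
        for a, b in itertools.combinations(range(next_id), 2):
            candidates.append((frozenset((a, b)), next_id))
        for a in range(next_id):
            candidates.append((frozenset((a, next_id)), next_id + 1))
        candidates.append((frozenset((next_id, next_id + 1)), next_id + 2))
        for pair, nid in candidates:
            if all(len(pair & prev) == 1 for prev in assigned):
                assigned.append(pair)
                rec(assigned, nid)
                assigned.pop()

    rec([], 0)
    # dedupe isomorphic labelings by the sorted per-parent child-count profile
    seen, unique = set(), []
    for fam in results:
        counts: dict[int, int] = {}
        for pair in fam:
            for p in pair:
                counts[p] = counts.get(p, 0) + 1
        sig = tuple(sorted(counts.values()))
        if sig not in seen:
            seen.add(sig)
            unique.append(fam)
    return unique


def _family_shape(family: list[frozenset]) -> tuple[dict, dict]:
    """children_of parent id, and private parents per member index."""
    children: dict[int, list[int]] = {}
    for v, pair in enumerate(family):
        for p in pair:
            children.setdefault(p, []).append(v)
    private = {v: [p for p in pair if len(children[p]) == 1]
               for v, pair in enumerate(family)}
    return children, private


def _cross_feasible(sizes: list[int], families: list) -> bool:
    """Check latent-parent role assignments for every lower level.

    For generation g, each member must host: one full-sibling-of-u parent
    for every clique member u at generation g-1 (distinct uncles need
    distinct parents, as non-full-sib uncles cannot share a full sibling),
    and, for every clique member at g-2, a parent whose own parent-pair
    contains that grandparent.  A latent that is a full sibling of an
    uncle has the uncle's (all-latent) parents, so it cannot also carry a
    clique grandparent: the roles are exclusive.  Shared parents
    (within-level) carry one role for all their children; private parents
    are free per member.
    """
    for g, size in enumerate(sizes):
        if size == 0 or families[g] is None:
            continue
        n_uncles = sizes[g - 1] if g >= 1 else 0
        n_gps = sizes[g - 2] if g >= 2 else 0
        if n_uncles == 0 and n_gps == 0:
            continue
        family = families[g]
        children, private = _family_shape(family)
        shared = [p for p, ch in children.items() if len(ch) > 1]
        uncles = list(range(n_uncles))
        gps = list(range(n_gps))

        role_options: list[list] = []
        for _ in shared:
            opts: list = [("none",)]
            opts += [("fs", u) for u in uncles]
            for r in (1, 2):
                opts += [("gp", frozenset(s)) for s in itertools.combinations(gps, r)]
            role_options.append(opts)

        feasible_assignment = False
        for roles in itertools.product(*role_options):
            role_of = dict(zip(shared, roles))
            ok = True
            for v, pair in enumerate(family):
                covered_fs = {role_of[p][1] for p in pair
                              if p in role_of and role_of[p][0] == "fs"}
                covered_gp = set()
                for p in pair:
                    if p in role_of and role_of[p][0] == "gp":
                        covered_gp |= role_of[p][1]
                rem_fs = len(set(uncles) - covered_fs)
                rem_gp = len(set(gps) - covered_gp)
                free = len(private[v])
                if rem_fs + (rem_gp + 1) // 2 > free:
                    ok = False
                    break
            if ok:
                feasible_assignment = True
                break
        if not feasible_assignment:
            return False
    return True


def _objective(families: list) -> int:
    """Largest number of clique half-sib pairs sharing one single parent."""
    best = 0
    for fam in families:
        if fam is None:
            continue
        children, _ = _family_shape(fam)
        for ch in children.values():
            best = max(best, comb(len(ch), 2))
    return best


def analyze_clique(n_members: int, max_exact: int = 12) -> CliqueAnalysis:
    """Minimum same-parent half-sibling pairs in a mutual second-degree clique.

    Searches every generation composition and realizable pedigree
    structure; ``max_exact`` is kept for interface stability but the
    symmetric search is exact at any size.
    """
    if n_members < 2:
        raise ValueError("a clique needs at least 2 members")
    n_pairs = comb(n_members, 2)

    patterns = set()
    for n0 in range(n_members + 1):
        for n1 in range(n_members + 1 - n0):
            n2 = n_members - n0 - n1
            sizes = [n0, n1, n2]
            while sizes and sizes[0] == 0:
                sizes.pop(0)
            while sizes and sizes[-1] == 0:
                sizes.pop()
            if sizes:
                patterns.add(tuple(sizes))

    best_obj = None
    best_cert = None
    for sizes in sorted(patterns):
        sizes = list(sizes)
        options = [_enumerate_families(s) if s > 0 else [None] for s in sizes]
        for families in itertools.product(*options):
            if not _cross_feasible(sizes, list(families)):
                continue
            obj = _objective(list(families))
            if best_obj is None or obj < best_obj:
                best_obj = obj
                best_cert = {
                    "generation_sizes": list(sizes),
                    "parent_families": [
                        None if f is None else [sorted(p) for p in f]
                        for f in families
                    ],
                }
    if best_obj is None:
        raise RuntimeError("no realizable pedigree found (should not happen)")
    return CliqueAnalysis(
        n_members=n_members, n_pairs=n_pairs,
        min_shared_parent_halfsib_pairs=int(best_obj),
        exact=True, certificate=best_cert,
    )
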