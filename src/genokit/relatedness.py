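"""Structure-robust kinship, relationship classes and family networks.

The kinship estimator is the within-family robust estimator of the KING
method: with counts taken over markers non-missing in both samples,

    phi = (N_AaAa - 2 N_AAaa) / (2 m) + 1/2 - (N_het_i + N_het_j) / (4 m),
    m = min(N_het_i, N_het_j),

where ``N_AaAa`` counts markers at which both are heterozygous, ``N_AAaa``
counts opposite homozygotes, and ``N_het_i`` is sample i's heterozygote
count.  The estimator uses no population allele frequencies, which is what
makes it robust to structure.  IBS0 — the opposite-homozygote fraction —
separates parent–offspring pairs (IBS0 = 0 barring genotype error) from
full siblings at the same kinship level.

Relationship degrees follow the standard powers-of-two partition: degree d
when phi falls in (2^-(d+3/2), 2^-(d+1/2)], duplicates/MZ above 2^-3/2.
Only pairs at or above the third-degree floor (2^-4.5) are reported by
default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CohortGenotypes

#: Reporting floor: lower edge of the third-degree kinship band.
THIRD_DEGREE_FLOOR = 2.0 ** -4.5
#: IBS0 cut separating parent-offspring from full siblings at first degree.
DEFAULT_PO_IBS0_CUT = 0.0012

CLASS_ORDER = ["duplicate/MZ", "parent-offspring", "full-sib",
               "second-degree", "third-degree", "unrelated"]


@dataclass(frozen=True)
class KinshipRecord:
    i: str
    j: str
    kinship: float
    ibs0: float
    n_compared: int
    klass: str


def classify_pair(kinship: float, ibs0: float,
                  po_ibs0_cut: float = DEFAULT_PO_IBS0_CUT) -> str:
    """Relationship class from (kinship, IBS0)."""
    if not (np.isfinite(kinship) and np.isfinite(ibs0)):
        return "unrelated"
    if kinship > 2.0 ** -1.5:
        return "duplicate/MZ"
    if kinship > 2.0 ** -2.5:
        return "parent-offspring" if ibs0 < po_ibs0_cut else "full-sib"
    if kinship > 2.0 ** -3.5:
        return "second-degree"
    if kinship > 2.0 ** -4.5:
        return "third-degree"
    return "unrelated"


def king_kinship(cohort: CohortGenotypes, marker_index: np.ndarray | None = None,
                 pairs: list | None = None, floor: float = THIRD_DEGREE_FLOOR,
                 max_missing: float = 0.05, block_size: int = 8192,
                 report_all: bool = False) -> list[KinshipRecord]:
    """KING-robust kinship for all pairs (or the listed pairs).

    Markers are restricted to ``marker_index`` (callers should pass a
    subset only weakly informative of ancestry; see
    :func:`select_kinship_markers`).  Samples with missing rate above
    ``max_missing`` on the subset are excluded from estimation.  Pairs
    whose smaller heterozygote count is zero are skipped (the estimator is
    undefined there).  Counts are accumulated blockwise over markers;
    results do not depend on the block size.
    """
    idx = np.arange(cohort.n_markers) if marker_index is None else np.asarray(marker_index)
    calls = cohort.calls[:, idx]
    ids = cohort.samples["sample_id"].to_numpy()

    miss = (calls < 0).mean(axis=1)
    usable = np.flatnonzero(miss <= max_missing)
    calls = calls[usable]
    ids = ids[usable]
    n = len(usable)
    if n < 2:
        return []

    records = []

    def emit(ia, ib, n_aa, n_opp, het_a, het_b, n_cmp):
        m = min(het_a, het_b)
        if m == 0 or n_cmp == 0:
            return
        phi = ((n_aa - 2.0 * n_opp) / (2.0 * m)
               + 0.5 - (het_a + het_b) / (4.0 * m))
        ibs0 = n_opp / n_cmp
        if report_all or phi >= floor:
            records.append(KinshipRecord(
                i=str(ids[ia]), j=str(ids[ib]), kinship=float(phi),
                ibs0=float(ibs0), n_compared=int(n_cmp),
                klass=classify_pair(phi, ibs0),
            ))

    if pairs is not None:
        # listed pairs: direct per-pair counting, linear in markers
        id_pos = {s: k for k, s in enumerate(ids)}
        for a, b in pairs:
            if a not in id_pos or b not in id_pos:
                continue
            ia, ib = id_pos[a], id_pos[b]
            ca, cb = calls[ia], calls[ib]
            both = (ca >= 0) & (cb >= 0)
            het_a = int(((ca == 1) & both).sum())
            het_b = int(((cb == 1) & both).sum())
            n_aa = int(((ca == 1) & (cb == 1)).sum())
            n_opp = int((both & (ca != 1) & (cb != 1) & (ca != cb)).sum())
            emit(ia, ib, n_aa, n_opp, het_a, het_b, int(both.sum()))
        return records

    # all pairs: blockwise indicator matmuls over packed genotype classes
    n_aa = np.zeros((n, n))
    n_opp = np.zeros((n, n))
    het_i = np.zeros((n, n))   # het count of row sample over cols' non-missing sites
    n_cmp = np.zeros((n, n))
    for start in range(0, calls.shape[1], block_size):
        blk = calls[:, start:start + block_size]
        het = (blk == 1).astype(np.float64)
        ref = (blk == 0).astype(np.float64)
        alt = (blk == 2).astype(np.float64)
        obs = (blk >= 0).astype(np.float64)
        n_aa += het @ het.T
        n_opp += ref @ alt.T + alt @ ref.T
        het_i += het @ obs.T
        n_cmp += obs @ obs.T

    for ia, ib in itertools.combinations(range(n), 2):
        emit(ia, ib, n_aa[ia, ib], n_opp[ia, ib], het_i[ia, ib], het_i[ib, ia],
             n_cmp[ia, ib])
    return records


def select_kinship_markers(loadings: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Indices of markers only weakly informative of ancestry.

    Drops markers in the top ``fraction`` of maximum absolute loading on
    the leading PCs (default PCs supplied by the caller, typically 1-6).
    """
    score = np.abs(np.asarray(loadings)).max(axis=1)
    cut = np.quantile(score, 1.0 - fraction)
    return np.flatnonzero(score <= cut)


def records_to_table(records: list[KinshipRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.i, r.j, r.kinship, r.ibs0, r.n_compared, r.klass) for r in records],
        columns=["id1", "id2", "kinship", "ibs0", "n", "class"],
    )


# ---------------------------------------------------------------------------
# family networks
# ---------------------------------------------------------------------------

@dataclass
class FamilyNetwork:
    members: tuple
    edges: list            # (i, j, class)
    signature: tuple       # sorted multiset of edge classes (relabel-invariant)

    @property
    def size(self) -> int:
        return len(self.members)


def build_networks(records: list[KinshipRecord],
                   min_class: str = "third-degree"
                   ) -> tuple[list[FamilyNetwork], pd.DataFrame]:
    """Connected components over edges of the requested class or closer.

    Returns the networks plus per-sample relative counts by class.
    """
    keep = set(CLASS_ORDER[:CLASS_ORDER.index(min_class) + 1])
    g = nx.Graph()
    for r in records:
        if r.klass in keep:
            g.add_edge(r.i, r.j, klass=r.klass)
    networks = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        edges = [(a, b, g.edges[a, b]["klass"]) for a, b in g.subgraph(comp).edges]
        signature = tuple(sorted(e[2] for e in edges))
        networks.append(FamilyNetwork(members=members, edges=edges, signature=signature))
    counts = {}
    for r in records:
        if r.klass not in keep:
            continue
        for s in (r.i, r.j):
            counts.setdefault(s, dict.fromkeys(CLASS_ORDER[:-1], 0))
            counts[s][r.klass] += 1
    count_table = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    return networks, count_table


def network_census(networks: list[FamilyNetwork]) -> pd.Series:
    """Multiplicity of each network configuration signature."""
    sigs = pd.Series([n.signature for n in networks])
    return sigs.value_counts()


def find_trios_quartets(records: list[KinshipRecord], ages: dict, sexes: dict,
                        age_margin: float = 12.0) -> dict:
    """Detect (father, mother, child) trios and two-child quartets.

    A trio requires two parent-offspring edges to an opposite-sex parent
    pair, parents older than the child by ``age_margin`` years, and
    parents not themselves first-degree relatives or closer.  Quartets are
    unique parent pairs with two children who are full siblings of each
    other.  Candidates with missing age or sex are skipped.
    """
    po = {}
    close = set()
    klass_of = {}
    for r in records:
        key = frozenset((r.i, r.j))
        klass_of[key] = r.klass
        if r.klass == "parent-offspring":
            po.setdefault(r.i, set()).add(r.j)
            po.setdefault(r.j, set()).add(r.i)
        if r.klass in ("duplicate/MZ", "parent-offspring", "full-sib"):
            close.add(key)

    trios = []
    for child, partners in po.items():
        if child not in ages:
            continue
        for pa, pb in itertools.combinations(sorted(partners), 2):
            if pa not in ages or pb not in ages or pa not in sexes or pb not in sexes:
                continue
            if sexes[pa] == sexes[pb] or "" in (sexes[pa], sexes[pb]):
                continue
            if ages[pa] < ages[child] + age_margin or ages[pb] < ages[child] + age_margin:
                continue
            if frozenset((pa, pb)) in close:
                continue
            father, mother = (pa, pb) if sexes[pa] == "M" else (pb, pa)
            trios.append((father, mother, child))

    parent_pairs = {}
    for father, mother, child in trios:
        parent_pairs.setdefault((father, mother), []).append(child)
    quartets = []
    for (father, mother), children in parent_pairs.items():
        for c1, c2 in itertools.combinations(sorted(children), 2):
            if klass_of.get(frozenset((c1, c2))) == "full-sib":
                quartets.append((father, mother, c1, c2))
    return {
        "trios": trios,
        "unique_parent_pairs": sorted(parent_pairs),
        "quartets": quartets,
    }


def unrelated_subset(records: list[KinshipRecord], sample_ids) -> np.ndarray:
    """Greedy maximum-independent-set heuristic over relatedness edges.

    Repeatedly removes the sample with the most remaining related pairs
    until no related pair is left; returns the kept sample ids.
    """
    g = nx.Graph()
    g.add_nodes_from(sample_ids)
    for r in records:
        if r.klass != "unrelated":
            g.add_edge(r.i, r.j)
    g = g.copy()
    while g.number_of_edges():
        worst = max(g.degree, key=lambda kv: kv[1])[0]
        g.remove_node(worst)
    kept = set(g.nodes)
    return np.array([s for s in sample_ids if s in kept])


def expected_sibling_pairs(n: int, population_size: int,
                           sibship_distribution: dict) -> float:
    """Expected sibling pairs in a random sample of ``n`` from ``N`` people.

    ``sibship_distribution`` maps sibship size s to q_s, the probability
    that a random *individual* belongs to a sibship of size s.  The
    population contains S_pop = N * sum_s q_s (s-1) / 2 sibling pairs
    (each individual in a size-s sibship contributes (s-1)/2 pairs), and a
    uniform random sample keeps each pair with probability
    n(n-1) / (N(N-1)), so E[pairs] = S_pop * n(n-1) / (N(N-1)).
    """
    sizes = np.array(list(sibship_distribution), dtype=float)
    q = np.array(list(sibship_distribution.values()), dtype=float)
    if (q < 0).any() or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("sibship distribution must be a probability distribution")
    if n > population_size:
        raise ValueError("sample size exceeds population size")
    s_pop = population_size * float((q * (sizes - 1) / 2.0).sum())
    if population_size < 2:
        return 0.0
    return s_pop * n * (n - 1) / (population_size * (population_size - 1))
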