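"""PC-stable causal discovery with Gaussian (Fisher-z) conditional-independence tests.

The search is the order-independent "stable" variant: at each conditioning-set
size the neighbor sets are frozen before any edge is removed, so the output
does not depend on the ordering of the gene columns. Unshielded colliders are
then oriented from the recorded separation sets and Meek rules R1-R4 propagate
the remaining forced orientations, yielding a CPDAG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .graph import CPDAG, ExpressionMatrix

logger = logging.getLogger(__name__)

_R_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one Fisher-z conditional-independence test."""

    partial_corr: float
    statistic: float
    p_value: float
    independent: bool


def _partial_correlation(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Partial correlation of (i, j) given S from a full correlation matrix.

    Uses the inverse of the (i, j, S) submatrix; for empty S this is just
    corr[i, j].
    """
    if not S:
        return float(corr[i, j])
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom == 0 or not np.isfinite(denom):
        return 1.0
    return float(-prec[0, 1] / denom)


def fisher_z_test(
    x: ExpressionMatrix,
    i: int,
    j: int,
    S: set[int] | tuple[int, ...] = (),
    alpha: float = 0.05,
    _corr: np.ndarray | None = None,
) -> CITestResult:
    """Test X_i independent of X_j given X_S via the Fisher z-transform.

    The statistic is sqrt(n - |S| - 3) * |atanh(r)| with r the partial
    correlation; the p-value is the two-sided Gaussian tail. Numerically
    degenerate |r| >= 1 is clamped and flagged as dependence. A sample size
    too small for the conditioning set (n <= |S| + 3) keeps the edge
    (dependence) with a warning.
    """
    S = tuple(sorted(S))
    if i == j or i in S or j in S:
        raise ValueError("i, j must be distinct and not in the conditioning set")
    n = x.n_samples
    if n <= len(S) + 3:
        warnings.warn(
            f"skipping CI test of ({i},{j}) given |S|={len(S)}: n={n} too small; "
            "treating as dependent",
            stacklevel=2,
        )
        return CITestResult(np.nan, np.inf, 0.0, False)
    corr = _corr if _corr is not None else np.corrcoef(x.values, rowvar=False)
    r = _partial_correlation(corr, i, j, S)
    if not np.isfinite(r) or abs(r) >= 1.0:
        r = np.sign(r) * _R_CLAMP if np.isfinite(r) else _R_CLAMP
    z = np.arctanh(r)
    statistic = float(np.sqrt(n - len(S) - 3) * abs(z))
    p_value = float(2.0 * stats.norm.sf(statistic))
    return CITestResult(float(r), statistic, p_value, p_value > alpha)


SeparationSets = dict[frozenset[int], tuple[int, ...]]


def learn_skeleton(
    x: ExpressionMatrix,
    alpha: float = 0.05,
    max_cond_size: int = 3,
) -> tuple[np.ndarray, SeparationSets]:
    """PC-stable adjacency search.

    Starts from the complete undirected graph; for conditioning-set size
    l = 0, 1, ..., max_cond_size removes the edge i-j on the first subset
    S of the (level-frozen) neighbors of i excluding j that renders them
    independent, recording S as the separation set of {i, j}.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    d = x.n_genes
    corr = np.corrcoef(x.values, rowvar=False)
    adj = np.ones((d, d), dtype=bool)
    np.fill_diagonal(adj, False)
    sepsets: SeparationSets = {}

    for level in range(max_cond_size + 1):
        # freeze neighbor sets for order independence
        neighbors = [set(np.nonzero(adj[i])[0]) for i in range(d)]
        if all(len(nb) - 1 < level for nb in neighbors):
            break
        for i in range(d):
            for j in sorted(neighbors[i]):
                if not adj[i, j]:
                    continue  # removed earlier this level
                cands = sorted(neighbors[i] - {j})
                if len(cands) < level:
                    continue
                for S in combinations(cands, level):
                    res = fisher_z_test(x, i, j, S, alpha, _corr=corr)
                    if res.independent:
                        adj[i, j] = adj[j, i] = False
                        sepsets[frozenset((i, j))] = S
                        break
    return adj, sepsets


def _maxp_separating_set(
    x: ExpressionMatrix,
    skeleton: np.ndarray,
    i: int,
    j: int,
    max_cond_size: int,
    corr: np.ndarray,
) -> tuple[tuple[int, ...], float]:
    """Conditioning set with the largest Fisher-z p-value for (i, j).

    Candidate sets are subsets (up to ``max_cond_size``) of the skeleton
    neighbors of either endpoint; enumeration order breaks p-value ties
    deterministically.
    """
    best_p, best_S = -1.0, ()
    seen: set[tuple[int, ...]] = set()
    for anchor in (i, j):
        other = j if anchor == i else i
        cands = sorted(int(v) for v in np.nonzero(skeleton[anchor])[0] if v != other)
        for size in range(min(max_cond_size, len(cands)) + 1):
            for S in combinations(cands, size):
                if S in seen:
                    continue
                seen.add(S)
                res = fisher_z_test(x, i, j, S, alpha=0.5, _corr=corr)
                if res.p_value > best_p:
                    best_p, best_S = res.p_value, S
    return best_S, best_p


def orient_v_structures(
    skeleton: np.ndarray,
    sepsets: SeparationSets,
    gene_ids: list[str] | None = None,
    rule: str = "sepset",
    x: ExpressionMatrix | None = None,
    max_cond_size: int = 3,
) -> CPDAG:
    """Orient unshielded colliders i -> k <- j when k is outside the separating set.

    Two rules decide membership of k. ``"sepset"`` uses the set recorded
    during skeleton search (the textbook rule). ``"maxp"`` re-selects, per
    non-adjacent pair, the conditioning set with the maximum test p-value
    over both endpoints' neighbor subsets and requires ``x`` (the data);
    this is far more robust when several near-cancelling paths connect the
    pair, a common situation under star-like regulator graphs where a first
    spurious separating set would otherwise orient false colliders into the
    regulators. In either rule, conflicting double-orientation of one edge
    is resolved by leaving that edge undirected (the conservative choice).
    """
    if rule not in ("sepset", "maxp"):
        raise ValueError(f"unknown v-structure rule {rule!r}")
    if rule == "maxp" and x is None:
        raise ValueError("rule='maxp' requires the data matrix x")
    d = skeleton.shape[0]
    amat = skeleton.astype(int).copy()
    corr = np.corrcoef(x.values, rowvar=False) if rule == "maxp" else None
    maxp_cache: dict[frozenset[int], tuple[int, ...]] = {}

    def separating_set(i: int, j: int) -> tuple[int, ...]:
        key = frozenset((i, j))
        if key not in sepsets:
            raise RuntimeError(
                f"non-adjacent pair {set(key)} has no recorded separation set"
            )
        if rule == "sepset":
            return sepsets[key]
        if key not in maxp_cache:
            maxp_cache[key] = _maxp_separating_set(
                x, skeleton, i, j, max_cond_size, corr
            )[0]
        return maxp_cache[key]

    collider_votes: set[tuple[int, int]] = set()
    for k in range(d):
        nb = np.nonzero(skeleton[k])[0]
        for i, j in combinations(nb, 2):
            if skeleton[i, j]:
                continue  # shielded
            if k not in separating_set(int(i), int(j)):
                collider_votes.add((int(i), int(k)))
                collider_votes.add((int(j), int(k)))
    for (a, b) in collider_votes:
        if (b, a) in collider_votes:
            continue  # conflicting orientations: leave undirected
        amat[b, a] = 0
    return CPDAG(amat, list(gene_ids) if gene_ids else [])


def _meek_pass(amat: np.ndarray) -> bool:
    """One sweep of Meek rules R1-R4; returns True if any edge was oriented.

    Conditions are evaluated against the live matrix so an orientation made
    earlier in the sweep immediately informs later rule checks.
    """
    d = amat.shape[0]

    def is_directed(a: int, b: int) -> bool:
        return amat[a, b] == 1 and amat[b, a] == 0

    def is_undirected(a: int, b: int) -> bool:
        return amat[a, b] == 1 and amat[b, a] == 1

    def adjacent(a: int, b: int) -> bool:
        return amat[a, b] == 1 or amat[b, a] == 1

    def fires(a: int, b: int) -> bool:
        """Should the undirected edge a - b be oriented a -> b?"""
        # R1: c -> a, a - b, c and b non-adjacent
        for c in range(d):
            if c not in (a, b) and is_directed(c, a) and not adjacent(c, b):
                return True
        # R2: a -> c -> b with a - b (acyclicity forces a -> b)
        for c in range(d):
            if c not in (a, b) and is_directed(a, c) and is_directed(c, b):
                return True
        # R3: a - c -> b and a - e -> b with c, e non-adjacent
        mids = [
            c
            for c in range(d)
            if c not in (a, b) and is_undirected(a, c) and is_directed(c, b)
        ]
        for c, e in combinations(mids, 2):
            if not adjacent(c, e):
                return True
        # R4: a - c, c -> e, e -> b, c and b non-adjacent, a and e adjacent
        for c in range(d):
            if c in (a, b) or not is_undirected(a, c) or adjacent(c, b):
                continue
            for e in range(d):
                if (
                    e not in (a, b, c)
                    and is_directed(c, e)
                    and is_directed(e, b)
                    and adjacent(a, e)
                ):
                    return True
        return False

    changed = False
    for a in range(d):
        for b in range(d):
            if a != b and is_undirected(a, b) and fires(a, b):
                amat[b, a] = 0
                changed = True
    return changed


def apply_meek_rules(pdag: CPDAG) -> CPDAG:
    """Close a partially directed graph under Meek rules R1-R4."""
    amat = pdag.amat.copy()
    while _meek_pass(amat):
        pass
    return CPDAG(amat, list(pdag.gene_ids))


def dag_to_cpdag(support: np.ndarray, gene_ids: list[str] | None = None) -> CPDAG:
    """CPDAG of the Markov equivalence class of a DAG given as a boolean support.

    Orients the DAG's own v-structures on its skeleton and closes under Meek
    rules; edges left undirected are exactly those reversible within the
    equivalence class.
    """
    support = np.asarray(support).astype(bool)
    d = support.shape[0]
    skel = support | support.T
    amat = skel.astype(int)
    for k in range(d):
        parents = np.nonzero(support[:, k])[0]
        for i, j in combinations(parents, 2):
            if not skel[i, j]:
                amat[k, i] = 0
                amat[k, j] = 0
    return apply_meek_rules(CPDAG(amat, list(gene_ids) if gene_ids else []))


def compelled_edge_fraction(support: np.ndarray) -> float:
    """Fraction of DAG edges whose direction is identifiable from its CPDAG.

    An edge is compelled when reversing it would exit the Markov equivalence
    class (create or destroy a v-structure, or create a cycle); these are the
    edges that remain directed in the CPDAG.
    """
    support = np.asarray(support).astype(bool)
    edges = list(zip(*np.nonzero(support)))
    if not edges:
        return float("nan")
    A = dag_to_cpdag(support).amat
    return sum(1 for i, j in edges if A[i, j] == 1 and A[j, i] == 0) / len(edges)


def run_pc(
    x: ExpressionMatrix,
    alpha: float = 0.05,
    max_cond_size: int = 3,
    v_structure_rule: str = "maxp",
) -> CPDAG:
    """Full PC-stable pipeline: skeleton, collider orientation, Meek closure.

    Deterministic given the data and parameters. Data are standardized per
    gene first; Fisher-z is scale invariant so this only affects numerics.
    Collider orientation defaults to the max-p separating-set rule (see
    :func:`orient_v_structures`).
    """
    xs = x.standardized()
    skeleton, sepsets = learn_skeleton(xs, alpha=alpha, max_cond_size=max_cond_size)
    pdag = orient_v_structures(
        skeleton,
        sepsets,
        gene_ids=x.gene_ids,
        rule=v_structure_rule,
        x=xs,
        max_cond_size=max_cond_size,
    )
    return apply_meek_rules(pdag)
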