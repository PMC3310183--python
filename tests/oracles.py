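"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: betweenness is
computed by explicitly enumerating every shortest path, and
hypergeometric tails by exact integer binomial-coefficient sums.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def all_shortest_paths(adj, s, t):
    """Every shortest s-t path, by breadth-first frontier of simple paths."""
    if s == t:
        return [[s]]
    frontier = [[s]]
    found = []
    while frontier and not found:
        nxt = []
        for path in frontier:
            for nb in sorted(adj[path[-1]]):
                if nb in path:
                    continue
                if nb == t:
                    found.append(path + [nb])
                else:
                    nxt.append(path + [nb])
        frontier = nxt
    return found


def brute_betweenness(graph):
    """Exact normalized betweenness of every node, as Fractions.

    Sum over unordered pairs {s, t} of the fraction of enumerated
    shortest s-t paths whose interior contains the node, divided by
    (N-1)(N-2)/2; disconnected pairs contribute nothing.
    """
    nodes = sorted(graph.nodes)
    adj = {u: set(graph.neighbors(u)) for u in nodes}
    n = len(nodes)
    totals = {u: Fraction(0) for u in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        denom = len(paths)
        interior_counts = {}
        for p in paths:
            for u in p[1:-1]:
                interior_counts[u] = interior_counts.get(u, 0) + 1
        for u, c in interior_counts.items():
            totals[u] += Fraction(c, denom)
    norm = Fraction((n - 1) * (n - 2), 2)
    return {u: totals[u] / norm for u in nodes}


def exact_hypergeom_tails(N, K, n):
    """Exact upper and lower tails P(X>=k), P(X<=k) for k = 0..min(K, n).

    Pure integer arithmetic; floats come from Python's correctly rounded
    big-int division.
    """
    total = comb(N, n)
    kmax = min(K, n)
    terms = [comb(K, k) * comb(N - K, n - k) for k in range(kmax + 1)]
    prefix = []
    acc = 0
    for t in terms:
        acc += t
        prefix.append(acc)
    # note: acc == total only when the support starts at 0
    upper = [(total - (prefix[k - 1] if k else 0)) / total for k in range(kmax + 1)]
    lower = [prefix[k] / total for k in range(kmax + 1)]
    return upper, lower
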