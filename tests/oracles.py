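"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's own code paths: plain breadth-first
searches, exhaustive pair/triple scans, and draw enumeration.
"""

from collections import deque
from itertools import combinations
from math import comb


def bf_shortest_path_counts(net, s):
    """BFS from s: (dist, number-of-geodesics) per reachable node."""
    dist = {s: 0}
    sigma = {s: 1}
    q = deque([s])
    order = []
    while q:
        u = q.popleft()
        order.append(u)
        for w in sorted(net.successors(u)):
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def bf_betweenness(net, v):
    """Sum over ordered pairs (s, t), s != t != v, of sigma_st(v)/sigma_st,
    computed by enumerating every geodesic via DFS."""
    total = 0.0
    nodes = sorted(net.nodes)
    for s in nodes:
        if s == v:
            continue
        dist, sigma = bf_shortest_path_counts(net, s)
        for t in nodes:
            if t in (s, v) or t not in dist:
                continue
            # count geodesics s->t through v: sigma_s(v) * sigma_v(t) if on a geodesic
            if v in dist and dist[v] + _bf_dist(net, v).get(t, 10**9) == dist[t]:
                sigma_v_t = _bf_sigma(net, v).get(t, 0)
                total += sigma[v] * sigma_v_t / sigma[t]
    return total


def _bf_dist(net, s):
    return bf_shortest_path_counts(net, s)[0]


def _bf_sigma(net, s):
    return bf_shortest_path_counts(net, s)[1]


def bf_clustering(net, v):
    nbrs = sorted(net.neighbors(v))
    k = len(nbrs)
    if k < 2:
        return 0.0
    arcs = sum(1 for i in nbrs for j in nbrs if i != j and net.has_arc(i, j))
    return arcs / (k * (k - 1))


def bf_reachability(net, v):
    dist = _bf_dist(net, v)
    return (len(dist) - 1) / (net.n_nodes - 1)


def bf_apl(net):
    total = 0
    pairs = 0
    for s in sorted(net.nodes):
        dist = _bf_dist(net, s)
        for t, d in dist.items():
            if t != s:
                total += d
                pairs += 1
    return (total / pairs if pairs else float("nan")), pairs


def bf_connected_triples(net):
    """Exhaustive scan over all node triples; connected in the underlying
    undirected sense."""
    nodes = sorted(net.nodes)
    out = []
    for a, b, c in combinations(nodes, 3):
        und = set()
        for x, y in [(a, b), (a, c), (b, c)]:
            if net.has_arc(x, y) or net.has_arc(y, x):
                und.add(frozenset((x, y)))
        # connected iff >= 2 of the 3 possible undirected pairs present
        if len(und) >= 2:
            out.append(frozenset((a, b, c)))
    return out


def bf_singletons_after_removals(net, k_max):
    """Step-by-step re-count oracle for hub removal."""
    alive = set(net.nodes)
    originally_connected = {v for v in net.nodes if net.degree(v) > 0}

    def deg(v):
        # total degree: in + out (a mutual pair contributes two arcs)
        return sum(1 for u in alive if u != v and net.has_arc(v, u)) + sum(
            1 for u in alive if u != v and net.has_arc(u, v)
        )

    curve = []
    for _ in range(k_max):
        hub = min(alive, key=lambda v: (-deg(v), v))
        alive.discard(hub)
        singles = sum(1 for v in alive if deg(v) == 0 and v in originally_connected)
        curve.append((hub, singles))
    return curve


def enumerate_hypergeom_tail(c, k, G, n):
    """P(X >= k) by exact counting over draws of size c from G with n marked."""
    total = comb(G, c)
    hits = sum(comb(n, i) * comb(G - n, c - i) for i in range(k, min(c, n) + 1))
    return hits / total
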