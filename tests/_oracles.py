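"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the DCJ oracle
does breadth-first search over all double-cut-and-join operations on
adjacency-set states, and the core-region oracle enumerates every
candidate interval.
"""

from collections import deque
from itertools import combinations, permutations, product

# --- DCJ oracle -----------------------------------------------------------
# Extremity encoding: marker m (1-based) has tail 2m-2 and head 2m-1.
# An adjacency is an int a*64+b with a <= b; a telomere has a == b.


def _adj(a: int, b: int) -> int:
    if a > b:
        a, b = b, a
    return a * 64 + b


def _ends(code: int) -> tuple[int, int]:
    return divmod(code, 64)


def order_to_state(order) -> frozenset:
    """Adjacency-set state of a signed linear order [(marker, sign), ...]."""
    ends = []
    for m, s in order:
        tail, head = 2 * m - 2, 2 * m - 1
        ends.append((tail, head) if s > 0 else (head, tail))
    adjs = [_adj(ends[0][0], ends[0][0]), _adj(ends[-1][1], ends[-1][1])]
    for (_, r), (l2, _) in zip(ends, ends[1:]):
        adjs.append(_adj(r, l2))
    return frozenset(adjs)


def _neighbors(state: frozenset):
    adjs = list(state)
    for p, q in combinations(adjs, 2):
        a, b = _ends(p)
        c, d = _ends(q)
        rest = state - {p, q}
        if a == b and c == d:  # two telomeres -> join
            yield rest | {_adj(a, c)}
        elif a == b:  # telomere + adjacency
            yield rest | {_adj(a, c), _adj(d, d)}
            yield rest | {_adj(a, d), _adj(c, c)}
        elif c == d:
            yield rest | {_adj(c, a), _adj(b, b)}
            yield rest | {_adj(c, b), _adj(a, a)}
        else:
            yield rest | {_adj(a, c), _adj(b, d)}
            yield rest | {_adj(a, d), _adj(b, c)}
    for p in adjs:  # cut one adjacency into two telomeres
        a, b = _ends(p)
        if a != b:
            yield (state - {p}) | {_adj(a, a), _adj(b, b)}


def bfs_all_distances(source: frozenset) -> dict:
    """Minimal DCJ operation count from source to every reachable state."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        s = queue.popleft()
        d = dist[s] + 1
        for t in _neighbors(s):
            if t not in dist:
                dist[t] = d
                queue.append(t)
    return dist


def identity_order(n: int):
    return [(m, 1) for m in range(1, n + 1)]


def relabel_to_identity(order_a, order_b):
    """Rename markers/signs so order_a becomes the identity; return new order_b.

    Renaming a marker and flipping its reading direction consistently in
    both genomes is a bijection on extremities, so DCJ distances are
    preserved.
    """
    rename = {m: (i + 1, s) for i, (m, s) in enumerate(order_a)}
    return [(rename[m][0], s * rename[m][1]) for m, s in order_b]


def all_signed_orders(n: int):
    for perm in permutations(range(1, n + 1)):
        for signs in product((1, -1), repeat=n):
            yield list(zip(perm, signs))


# --- core-region oracle ---------------------------------------------------


def minimal_core_interval(core_ranks, n_genes: int, fraction: float = 0.95):
    """Exhaustive search for the shortest rank interval holding >= ceil(f*C)
    core genes; ties broken toward the chromosome centre, then smaller start."""
    import math

    pos = sorted(core_ranks)
    need = math.ceil(fraction * len(pos))
    centre = (n_genes - 1) / 2.0
    best = None
    for lo in range(n_genes):
        for hi in range(lo, n_genes):
            count = sum(1 for p in pos if lo <= p <= hi)
            if count >= need:
                key = (hi - lo + 1, abs((lo + hi) / 2.0 - centre), lo)
                if best is None or key < best[0]:
                    best = (key, lo, hi)
                break  # larger hi only lengthens the interval
    return best[1], best[2]
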