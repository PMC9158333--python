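"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written against raw edge tuples with a plain recursive DFS —
no networkx, no package internals — so they stay independent of the code
paths they verify.
"""

from __future__ import annotations


def brute_force_paths(edges, source, targets, cutoff):
    """All simple directed paths of <= cutoff edges ending at a target.

    ``edges`` is an iterable of (source, target, sign, score) tuples with
    sign in {-1, +1}.  A target terminates a path: targets never occur as
    intermediate nodes.  Returns a set of (node_tuple, sign_tuple,
    score_tuple).
    """
    adjacency: dict[str, list[tuple[str, int, float]]] = {}
    for u, v, sign, score in edges:
        adjacency.setdefault(u, []).append((v, sign, score))
    targets = set(targets)
    found = set()

    def recurse(node, visited, signs, scores):
        if len(signs) >= cutoff:
            return
        for nxt, sign, score in adjacency.get(node, ()):
            if nxt in visited:
                continue
            chain = visited + (nxt,)
            if nxt in targets:
                found.add((chain, signs + (sign,), scores + (score,)))
                continue  # a target ends the path
            recurse(nxt, chain, signs + (sign,), scores + (score,))

    recurse(source, (source,), (), ())
    return found


def brute_force_sign(signs):
    """Parity rule by explicit product of edge signs."""
    product = 1
    for s in signs:
        product *= s
    return "inhibiting" if product < 0 else "activating"


def brute_force_distance(scores):
    return sum(1.0 - s for s in scores)
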