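"""Independent brute-force oracles shared by the test modules.

Deliberately naive implementations (exhaustive path enumeration) kept
separate from the package so they cannot share code with what they check.
"""


def brute_force_distances(graph, seeds, radius):
    """All-simple-paths enumeration of intervening-sequence distances."""
    adj = graph.adjacency()
    best = {s: 0 for s in seeds}
    for seed in seeds:
        stack = [(seed, [seed], 0)]
        while stack:
            node, path, cost = stack.pop()
            for nxt, ov in adj[node].items():
                if nxt in path:
                    continue
                step = 0 if node in seeds else max(0, graph.length_of(node) - ov)
                nc = cost + step
                if nc <= radius and nc < best.get(nxt, nc + 1):
                    best[nxt] = nc
                if nc <= radius:
                    stack.append((nxt, path + [nxt], nc))
    return best


def brute_force_members(graph, seeds, radius):
    return set(brute_force_distances(graph, seeds, radius))
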