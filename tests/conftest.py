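import numpy as np
import pytest

import mihc


@pytest.fixture
def tiny_expr():
    """4 genes x 5 time points with simple linear/anti-linear profiles."""
    t = np.arange(5, dtype=float)
    values = np.array([
        t,                  # g1: increasing
        2 * t + 1,          # g2: perfectly correlated with g1
        -t,                 # g3: anti-correlated
        np.array([0.0, 3.0, -2.0, 5.0, -1.0]),  # g4: wiggly
    ])
    return mihc.TimeCourseMatrix(
        gene_ids=["g1", "g2", "g3", "g4"],
        time_points=t * 10,
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
    )


@pytest.fixture
def chain_dag():
    """root <- mid <- leaf is_a chain."""
    return mihc.GoDag.from_edges([("leaf", "mid"), ("mid", "root")])


@pytest.fixture
def default_synthetic():
    return mihc.generate(mihc.SyntheticSpec(seed=7))


def naive_bag_distance(a, b, mode="avg_hausdorff"):
    """Independent double-loop bag distance used as an oracle."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))

    def d(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 2.0
        return 1.0 - np.corrcoef(x, y)[0, 1]

    row_mins = [min(d(x, y) for y in b) for x in a]
    col_mins = [min(d(x, y) for x in a) for y in b]
    if mode == "avg_hausdorff":
        return (sum(row_mins) + sum(col_mins)) / (len(a) + len(b))
    if mode == "max_hausdorff":
        return max(max(row_mins), max(col_mins))
    return min(col_mins)


def exact_max_clique_size(graph):
    """Exhaustive maximum-clique size for graphs of <= ~12 vertices."""
    import itertools
    nodes = sorted(graph.nodes)
    for size in range(len(nodes), 0, -1):
        for combo in itertools.combinations(nodes, size):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(combo, 2)):
                return size
    return 0
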