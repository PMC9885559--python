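"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths they check: full-matrix dynamic
programming for edit distance, pairwise/triple enumeration for Gini and
graph statistics, and exhaustive evaluation of the greedy mRMR objective.
"""

import itertools

import numpy as np


def levenshtein_dp(u: str, v: str) -> int:
    """Full O(len(u)*len(v)) dynamic-programming edit distance."""
    prev = list(range(len(v) + 1))
    for i, cu in enumerate(u, start=1):
        cur = [i]
        for j, cv in enumerate(v, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (cu != cv)))
        prev = cur
    return prev[-1]


def gini_pairwise(p) -> float:
    """Gini via the literal double sum over all pairs of proportions."""
    p = np.asarray(p, dtype=float)
    s = p.size
    if s == 1:
        return 0.0
    total = sum(abs(pi - pj) for pi in p for pj in p)
    return total / (2.0 * s * s * (1.0 / s))


def graph_stats_bruteforce(nodes, edges):
    """The six graph features by direct enumeration of pairs and triples."""
    nodes = list(nodes)
    eset = {frozenset(e) for e in edges}
    n = len(nodes)
    m = len(eset)
    adj = {u: set() for u in nodes}
    for e in eset:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)

    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0

    local = []
    for u in nodes:
        k = len(adj[u])
        if k < 2:
            local.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(adj[u], 2)
                    if frozenset((a, b)) in eset)
        local.append(2.0 * links / (k * (k - 1)))
    avg_clustering = sum(local) / n if n else 0.0

    triangles = 0
    triples = 0
    for a, b, c in itertools.combinations(nodes, 3):
        e_ab = frozenset((a, b)) in eset
        e_bc = frozenset((b, c)) in eset
        e_ac = frozenset((a, c)) in eset
        k = e_ab + e_bc + e_ac
        if k == 3:
            triangles += 1
            triples += 3
        elif k == 2:
            triples += 1
    transitivity = 3.0 * triangles / triples if triples else 0.0

    # connected components by flood fill
    seen, comps = set(), 0
    for u in nodes:
        if u in seen:
            continue
        comps += 1
        stack = [u]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj[x])
    return {"n_nodes": n, "n_edges": m, "density": density,
            "avg_clustering": avg_clustering, "transitivity": transitivity,
            "n_components": comps}


def mrmr_greedy_bruteforce(X, y, k, floor=1e-6):
    """Greedy FCQ mRMR by exhaustively scoring every candidate at each step.

    Relevance is the one-way ANOVA F statistic computed from first
    principles; redundancy the mean |Pearson r| with the selected set.
    Ties break lexicographically by feature name.
    """
    X = {name: np.asarray(col, dtype=float) for name, col in X.items()}
    y = np.asarray(y)

    def f_stat(col):
        groups = [col[y == g] for g in np.unique(y)]
        grand = col.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        dfb = len(groups) - 1
        dfw = len(col) - len(groups)
        if ssw == 0 or dfw == 0:
            return 0.0 if ssb == 0 else np.inf
        return (ssb / dfb) / (ssw / dfw)

    def abs_corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return abs(np.corrcoef(a, b)[0, 1])

    relevance = {name: f_stat(col) for name, col in X.items()}
    selected = []
    remaining = sorted(X)
    while remaining and len(selected) < k:
        scores = {}
        for f in remaining:
            if not selected:
                scores[f] = relevance[f]
            else:
                red = np.mean([abs_corr(X[f], X[s]) for s in selected])
                scores[f] = relevance[f] / max(red, floor)
        best = min(remaining, key=lambda f: (-scores[f], f))
        selected.append(best)
        remaining.remove(best)
    return selected


def metrics_counting(y_true, y_pred, positive):
    """Accuracy/precision/recall/F1 by naive counting."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    n = len(y_true)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"accuracy": (tp + tn) / n, "precision": prec, "recall": rec,
            "f1": f1, "tp": tp, "tn": tn, "fp": fp, "fn": fn}


def auc_rank(y01, scores):
    """AUC as the normalized Mann-Whitney U with mid-rank ties."""
    y01 = np.asarray(y01)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y01 == 1]
    neg = scores[y01 == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
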