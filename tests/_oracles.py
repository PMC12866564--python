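"""Independent brute-force oracles shared by unit and acceptance tests.

Each oracle re-derives a result by direct enumeration, independently of
the library code path it checks.
"""

import itertools
import math
from fractions import Fraction

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(c + d, c1 - k)
               for k in range(lo, hi + 1)}
    w_obs = weights[a]
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs),
                          sum(weights.values())))


def mwu_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p over all group labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2

    def u_of(xs, ys):
        return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                   for xi in xs for yj in ys)

    dev_obs = abs(u_of(x, y) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(u_of(xs, ys) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def partition_oracle(presence, labels, tau: float, strict: float):
    """Brute-force orthogroup partition over all non-empty group subsets.

    presence: DataFrame isolates x orthogroups (0/1); labels: isolate ->
    group. Returns (core, {frozenset: set}, unclassified) by testing all
    2^g - 1 subsets per orthogroup.
    """
    groups = sorted(set(labels.values()))
    core, combos, unclassified = set(), {}, set()
    n = presence.shape[0]
    for og in presence.columns:
        col = presence[og]
        if col.sum() / n >= tau:
            core.add(og)
            continue
        match = None
        for r in range(1, len(groups) + 1):
            for subset in itertools.combinations(groups, r):
                ok = True
                for g in groups:
                    members = [i for i in presence.index if labels[i] == g]
                    frac = np.mean([col[i] for i in members])
                    if g in subset:
                        if frac == 0 or frac < strict:
                            ok = False
                            break
                    elif frac > 0:
                        ok = False
                        break
                if ok:
                    match = frozenset(subset)
                    break
            if match:
                break
        if match:
            combos.setdefault(match, set()).add(og)
        else:
            unclassified.add(og)
    return core, combos, unclassified


def pathway_completeness_oracle(node, kos) -> float:
    """Completeness by exhaustive enumeration of OR-branch assignments.

    Every OR node independently commits to one child; for each full
    assignment the tree is a pure AND tree scored by nested means; the
    oracle returns the maximum over all assignments. Optional nodes must
    already be pruned.
    """
    or_nodes = []

    def collect(nd):
        if nd.kind == "or":
            or_nodes.append(nd)
        for child in nd.children:
            collect(child)

    collect(node)

    def score_fixed(nd, choice):
        if nd.kind == "leaf":
            return 1.0 if nd.ko in kos else 0.0
        if nd.kind == "or":
            return score_fixed(nd.children[choice[id(nd)]], choice)
        return sum(score_fixed(c, choice) for c in nd.children) / len(nd.children)

    best = 0.0
    for picks in itertools.product(*[range(len(n.children)) for n in or_nodes]):
        choice = {id(n): p for n, p in zip(or_nodes, picks)}
        best = max(best, score_fixed(node, choice))
    return 100.0 * best


def auc_pairwise(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
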