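"""Independent brute-force references for diversity metrics.

Deliberately naive (pure-Python loops, explicit subtree traversals) so they
share no code path with the package implementations they check.
"""

import math


def naive_chao1(counts):
    nz = [c for c in counts if c > 0]
    s_obs = len(nz)
    f1 = sum(1 for c in nz if c == 1)
    f2 = sum(1 for c in nz if c == 2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def naive_ace(counts, cutoff=10):
    rare = [c for c in counts if 0 < c <= cutoff]
    abund = [c for c in counts if c > cutoff]
    if not rare:
        return float(len(abund))
    n_rare = sum(rare)
    f1 = sum(1 for c in rare if c == 1)
    c_ace = 1 - f1 / n_rare
    if c_ace == 0:
        return naive_chao1(counts)
    s_rare = len(rare)
    num = sum(i * (i - 1) * sum(1 for c in rare if c == i) for i in range(1, cutoff + 1))
    gamma2 = 0.0
    if n_rare > 1:
        gamma2 = max(s_rare / c_ace * num / (n_rare * (n_rare - 1)) - 1, 0.0)
    return len(abund) + s_rare / c_ace + f1 / c_ace * gamma2


def naive_shannon(counts, base=2):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p, base)
    return h


def naive_simpson(counts):
    total = sum(counts)
    return sum((c / total) ** 2 for c in counts)


def _edges_with_tipsets(tree):
    """(length, frozenset of tip names below) for every non-root node."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        out.append((node.length or 0.0, tips))
    return out


def naive_faith_pd(present_tips, tree):
    present = set(present_tips)
    return sum(l for l, tips in _edges_with_tipsets(tree) if tips & present)


def naive_unweighted_unifrac(tips_a, tips_b, tree):
    a, b = set(tips_a), set(tips_b)
    unique = union = 0.0
    for l, tips in _edges_with_tipsets(tree):
        in_a, in_b = bool(tips & a), bool(tips & b)
        if in_a or in_b:
            union += l
            if in_a != in_b:
                unique += l
    return unique / union if union else 0.0


def naive_bray_curtis(x, y, sqrt_transform=True):
    tx, ty = sum(x), sum(y)
    u = [c / tx for c in x]
    v = [c / ty for c in y]
    if sqrt_transform:
        u = [math.sqrt(c) for c in u]
        v = [math.sqrt(c) for c in v]
    num = sum(abs(a - b) for a, b in zip(u, v))
    den = sum(a + b for a, b in zip(u, v))
    return num / den
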