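"""Independent brute-force oracles used only by the test suite.

These re-derive each metric from first principles (explicit path unions,
per-branch classification, double loops) without touching the package's
implementation paths.
"""

import numpy as np


def _root_path_edges(tree, tip_name):
    """Edges (as node objects) on the path from a tip to the root."""
    node = next(t for t in tree.tips() if t.name == tip_name)
    edges = []
    while node.parent is not None:
        edges.append(node)
        node = node.parent
    return edges


def faith_pd_bruteforce(tree, present_tips) -> float:
    """Total branch length of the union of root-to-tip paths."""
    edges = set()
    for name in present_tips:
        edges.update(id(e) for e in _root_path_edges(tree, name))
    lengths = {id(n): n.length for n in tree.traverse(include_self=False)}
    return sum(lengths[e] for e in edges)


def _branch_tipsets(tree):
    """(length, set of tip names below) for every branch in the tree."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() \
            else {node.name}
        out.append((node.length, tips))
    return out


def unweighted_unifrac_bruteforce(tree, tips_i, tips_j) -> float:
    """Classify every branch as shared / unique / outside the union."""
    unique = 0.0
    union_len = 0.0
    for length, below in _branch_tipsets(tree):
        in_i = bool(below & set(tips_i))
        in_j = bool(below & set(tips_j))
        if in_i or in_j:
            union_len += length
            if in_i != in_j:
                unique += length
    return unique / union_len if union_len > 0 else 0.0


def weighted_unifrac_bruteforce(tree, abund_i, abund_j,
                                normalized=False) -> float:
    """Per-branch |P_i - P_j| weighted by branch length.

    ``abund_*`` map tip name -> relative abundance (summing to 1).
    """
    total = 0.0
    norm = 0.0
    for length, below in _branch_tipsets(tree):
        p_i = sum(abund_i.get(t, 0.0) for t in below)
        p_j = sum(abund_j.get(t, 0.0) for t in below)
        total += length * abs(p_i - p_j)
        norm += length * (p_i + p_j)
    return total / norm if normalized else total


def bray_curtis_bruteforce(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    denom = x.sum() + y.sum()
    return 1.0 - 2.0 * np.minimum(x, y).sum() / denom


def patristic_bruteforce(tree, a, b) -> float:
    """Tip-to-tip distance via root paths (shared prefix cancels)."""
    pa = _root_path_edges(tree, a)
    pb = _root_path_edges(tree, b)
    ids_a = {id(e) for e in pa}
    ids_b = {id(e) for e in pb}
    return (sum(e.length for e in pa if id(e) not in ids_b)
            + sum(e.length for e in pb if id(e) not in ids_a))


def beta_mntd_bruteforce(tree, table, i, j, weighted) -> float:
    """Double loop over all tip pairs using root-path patristic distances."""
    taxa = table.taxon_ids
    ci = table.counts[:, i].astype(float)
    cj = table.counts[:, j].astype(float)
    pres_i = [taxa[k] for k in range(len(taxa)) if ci[k] > 0]
    pres_j = [taxa[k] for k in range(len(taxa)) if cj[k] > 0]
    if weighted:
        wi = {taxa[k]: ci[k] / ci.sum() for k in range(len(taxa)) if ci[k] > 0}
        wj = {taxa[k]: cj[k] / cj.sum() for k in range(len(taxa)) if cj[k] > 0}
    else:
        wi = {t: 1.0 / len(pres_i) for t in pres_i}
        wj = {t: 1.0 / len(pres_j) for t in pres_j}
    term_i = sum(w * min(patristic_bruteforce(tree, t, u) for u in pres_j)
                 for t, w in wi.items())
    term_j = sum(w * min(patristic_bruteforce(tree, t, u) for u in pres_i)
                 for t, w in wj.items())
    return 0.5 * (term_i + term_j)
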