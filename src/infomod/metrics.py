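"""Partition-comparison utilities."""

from __future__ import annotations

import math
from collections import Counter

__all__ = ["partition_nmi", "recovery_nmi"]


def partition_nmi(labels_a: dict, labels_b: dict) -> float:
    """Normalized mutual information between two partitions of one item set.

    Arithmetic-mean normalization: I(A;B) / ((H(A) + H(B)) / 2).  Items must
    coincide.  Two all-in-one partitions are identical, hence NMI 1.
    """
    if set(labels_a) != set(labels_b):
        raise ValueError("partitions cover different item sets")
    items = list(labels_a)
    n = len(items)
    if n == 0:
        raise ValueError("empty partitions")
    ca = Counter(labels_a[i] for i in items)
    cb = Counter(labels_b[i] for i in items)
    joint = Counter((labels_a[i], labels_b[i]) for i in items)
    h_a = -sum((c / n) * math.log(c / n) for c in ca.values())
    h_b = -sum((c / n) * math.log(c / n) for c in cb.values())
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    mi = sum(
        (c / n) * math.log((c / n) / ((ca[a] / n) * (cb[b] / n)))
        for (a, b), c in joint.items()
    )
    return mi / ((h_a + h_b) / 2.0)


def recovery_nmi(
    components: list,
    trees: list,
    coarse_truth: dict,
    fine_truth: dict,
) -> tuple[float, float]:
    """NMI of a network decomposition against planted two-level truth.

    ``trees`` holds the module tree of each analyzed component, aligned
    with ``components`` (untreed components may pass None).  The coarse
    level of a gene is its component, refined by the tree's top internal
    level when the tree is deeper than one (a depth-1 tree has no level
    between root and leaf partition); the fine level is the leaf module.
    Genes absent from the truth maps are ignored.
    """
    coarse: dict = {}
    fine: dict = {}
    for idx, comp in enumerate(components):
        tree = trees[idx] if idx < len(trees) else None
        if tree is not None and tree.max_depth() >= 2:
            top_of = {g: m.path for m in tree.modules_at_depth(1) for g in m.genes}
        else:
            top_of = {}
        leaf_of = tree.leaf_assignment() if tree is not None else {}
        for g in comp:
            coarse[g] = f"{idx}:{top_of[g]}" if g in top_of else str(idx)
            fine[g] = f"{idx}:{leaf_of[g]}" if g in leaf_of else str(idx)
    coarse = {g: v for g, v in coarse.items() if g in coarse_truth}
    fine = {g: v for g, v in fine.items() if g in fine_truth}
    nmi_coarse = partition_nmi(coarse, {g: coarse_truth[g] for g in coarse})
    nmi_fine = partition_nmi(fine, {g: fine_truth[g] for g in fine})
    return nmi_coarse, nmi_fine
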