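"""Hypergeometric over-representation of gene sets in module trees.

The tail probability P(X >= k) for X ~ Hypergeometric(N, K, n) is summed
term by term in log space (log-gamma binomials) so tiny p-values stay
accurate.  BH correction is applied separately within each hierarchy depth,
since module-level and submodule-level scans are reported as separate
analyses.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from infomod.mapeq import ModuleTree
from infomod.de import bh_adjust

__all__ = ["hypergeom_tail", "enrich_modules", "read_gmt", "write_gmt", "write_enrichment"]

DEFAULT_MIN_MODULE_SIZE = 5
DEFAULT_SET_FDR = 0.05


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) drawing n from a universe of N with K marked, log-gamma based.

    k = observed marked genes in the draw; returns 1.0 exactly at k == 0.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("need 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, np.array(n))
    return float(min(np.exp(logsumexp(log_terms)), 1.0))


def enrich_modules(
    tree: ModuleTree,
    sets: dict[str, list[str]],
    universe_policy: str = "annotation",
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    fdr_threshold: float = DEFAULT_SET_FDR,
) -> pd.DataFrame:
    """Test every tree module against every gene set.

    Universe: policy "annotation" (default) = all annotated genes; policy
    "network" = genes of this component carrying at least one annotation.
    The annotation universe matches the null of sets assembled without
    regard to the network; the network universe conditions on component
    membership and will flag sets that merely concentrate inside the
    component.  Modules are reduced to their annotated members; BH runs
    separately per hierarchy depth.  Rows sorted by (module path, q).
    """
    if not sets:
        raise ValueError("empty gene-set collection")
    if universe_policy not in ("network", "annotation"):
        raise ValueError(f"unknown universe policy: {universe_policy!r}")
    annotated = set().union(*(set(s) for s in sets.values()))
    if universe_policy == "network":
        universe = set(tree.genes) & annotated
    else:
        universe = annotated
    if not universe:
        raise ValueError("empty universe: no annotated genes")
    N = len(universe)
    trimmed = {name: set(s) & universe for name, s in sets.items()}
    trimmed = {name: s for name, s in trimmed.items() if s}  # K = 0 sets are untestable

    rows = []
    for depth in range(1, tree.max_depth() + 1):
        for m in tree.modules_at_depth(depth):
            members = set(m.genes) & universe
            n = len(members)
            if n < min_module_size:
                continue
            for name, s in trimmed.items():
                K = len(s)
                k = len(members & s)
                p = hypergeom_tail(k, K, n, N)
                rows.append((depth, m.path, m.label, name, k, K, n, N, p))
    table = pd.DataFrame(
        rows, columns=["depth", "module_path", "module_label", "set", "k", "K", "n", "N", "p"]
    )
    if len(table):
        table["q"] = np.nan
        for depth, idx in table.groupby("depth").groups.items():
            table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"].to_numpy())
        table["significant"] = table["q"] < fdr_threshold
        table = table.sort_values(["module_path", "q", "set"], ignore_index=True)
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


# -- GMT interchange ----------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate set name: {name}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["module_path", "module_label", "set", "k", "K", "n", "N", "p", "q"]
    table[cols].to_csv(path, sep="\t", index=False)
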