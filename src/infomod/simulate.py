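"""Synthetic expression data with planted hierarchical block structure.

The generator uses a Gaussian latent-factor model so planted correlations
have closed forms: genes in a sub-block share a sub-block factor, sub-block
factors within a super-block share a super-block factor, and the amplicon
clique has its own factor coupled to nothing else.  For a gene with loading
``lam`` on sub-block factor ``u``:

    x = lam * u + sqrt(1 - lam^2) * noise_sd * eps

With ``u = alpha * z + sqrt(1 - alpha^2) * w`` the expected correlations are
``lam^2`` within a sub-block, ``lam^2 * alpha^2`` across sub-blocks of one
super-block, and 0 across super-blocks — the nesting the module detector
must recover.  Differential expression is overlaid as a signed log2 shift on
tumor samples only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from infomod.dataset import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "generate_gene_sets",
    "suggested_top_edges",
]


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    ``super_blocks`` lists, per super-block, the sizes of its sub-blocks,
    e.g. ``[[20, 15], [25]]`` = two super-blocks, the first with sub-blocks
    of 20 and 15 genes.  ``de_by_block`` optionally maps sub-block names
    (``"B1.2"``) to signed log2 shifts; when given it replaces the random
    ``de_fraction`` draw so whole sub-blocks move coherently.
    """

    n_background_genes: int = 200
    super_blocks: list[list[int]] = field(default_factory=lambda: [[40, 30, 30], [35, 35, 30]])
    within_sub_loading: float = 0.9
    super_coupling: float = 0.6
    amplicon_size: int = 4
    amplicon_loading: float = 0.95
    n_tumor: int = 493
    n_normal: int = 61
    de_fraction: float = 0.1
    de_shift: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    de_by_block: dict[str, float] | None = None

    def validate(self) -> None:
        lam, alpha = self.within_sub_loading, self.super_coupling
        if not (0.0 < lam < 1.0):
            raise ValueError("within_sub_loading must lie in (0, 1)")
        if not (0.0 <= alpha < 1.0):
            raise ValueError("super_coupling must lie in [0, 1)")
        if self.amplicon_size and not (0.0 < self.amplicon_loading < 1.0):
            raise ValueError("amplicon_loading must lie in (0, 1)")
        if self.amplicon_size and self.amplicon_loading < lam:
            raise ValueError("amplicon must be the tightest block (amplicon_loading >= loading)")
        if self.n_tumor <= 0 or self.n_normal <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_background_genes < 0 or self.amplicon_size < 0:
            raise ValueError("gene counts must be non-negative")
        if any(size <= 0 for sizes in self.super_blocks for size in sizes):
            raise ValueError("sub-block sizes must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted assignments recorded by the generator.

    ``block_tree`` maps super-block name -> sub-block name -> gene list;
    ``de_genes`` maps gene -> signed log2 shift applied to tumor samples.
    """

    block_tree: dict[str, dict[str, list[str]]]
    amplicon_genes: list[str]
    de_genes: dict[str, float]
    planted_sets: dict[str, list[str]] = field(default_factory=dict)
    all_genes: list[str] = field(default_factory=list)

    def sub_block_genes(self) -> dict[str, list[str]]:
        """Flat map sub-block name -> genes."""
        return {sub: genes for subs in self.block_tree.values() for sub, genes in subs.items()}

    def super_assignment(self) -> dict[str, str]:
        """gene -> super-block name, block genes only."""
        return {
            g: sup
            for sup, subs in self.block_tree.items()
            for genes in subs.values()
            for g in genes
        }

    def sub_assignment(self) -> dict[str, str]:
        """gene -> sub-block name, block genes only."""
        return {g: sub for sub, genes in self.sub_block_genes().items() for g in genes}

    def write_json(self, path: str | Path) -> None:
        payload = {
            "block_tree": self.block_tree,
            "amplicon_genes": self.amplicon_genes,
            "de_genes": self.de_genes,
            "planted_sets": self.planted_sets,
            "all_genes": self.all_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def suggested_top_edges(config: SimulationConfig, cross_fraction: float = 0.06) -> int:
    """Edge budget matching the generator's design density.

    All within-sub-block and amplicon pairs, plus the strongest
    ``cross_fraction`` of cross-sub-block pairs inside each super-block —
    enough cross edges to hold a super-block together in one component
    while the resulting MI cutoff stays above the noise floor (so the
    amplicon clique remains isolated).
    """
    within = sum(s * (s - 1) // 2 for sizes in config.super_blocks for s in sizes)
    within += config.amplicon_size * (config.amplicon_size - 1) // 2
    cross = sum(
        a * b
        for sizes in config.super_blocks
        for i, a in enumerate(sizes)
        for b in sizes[i + 1 :]
    )
    return within + int(round(cross_fraction * cross))


def _gene_names(config: SimulationConfig) -> tuple[dict[str, dict[str, list[str]]], list[str], list[str]]:
    block_tree: dict[str, dict[str, list[str]]] = {}
    for b, sizes in enumerate(config.super_blocks, start=1):
        block_tree[f"B{b}"] = {
            f"B{b}.{s}": [f"B{b}.{s}.G{j:03d}" for j in range(1, size + 1)]
            for s, size in enumerate(sizes, start=1)
        }
    amplicon = [f"AMP.G{j:03d}" for j in range(1, config.amplicon_size + 1)]
    background = [f"BG.G{j:04d}" for j in range(1, config.n_background_genes + 1)]
    return block_tree, amplicon, background


def simulate_expression(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one expression matrix plus its ground truth.

    Deterministic given the seed (``config.seed`` unless overridden).  All
    randomness flows through per-stage child streams of one seeded
    generator, so e.g. changing the DE overlay leaves the factors intact.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    rng_factors, rng_noise, rng_de = (np.random.default_rng(s) for s in root.spawn(3))

    block_tree, amplicon_genes, background_genes = _gene_names(config)
    gene_ids = (
        [g for subs in block_tree.values() for genes in subs.values() for g in genes]
        + amplicon_genes
        + background_genes
    )
    n_genes = len(gene_ids)
    n_samples = config.n_tumor + config.n_normal
    sample_ids = [f"T{j:03d}" for j in range(1, config.n_tumor + 1)] + [
        f"N{j:03d}" for j in range(1, config.n_normal + 1)
    ]
    condition = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal

    lam, alpha = config.within_sub_loading, config.super_coupling
    matrix = np.empty((n_genes, n_samples))
    matrix[:] = np.sqrt(1.0 - lam**2) * config.noise_sd * rng_noise.standard_normal(
        (n_genes, n_samples)
    )

    row = 0
    for subs in block_tree.values():
        z = rng_factors.standard_normal(n_samples)
        for genes in subs.values():
            w = rng_factors.standard_normal(n_samples)
            u = alpha * z + np.sqrt(1.0 - alpha**2) * w
            matrix[row : row + len(genes)] += lam * u
            row += len(genes)
    if amplicon_genes:
        a = rng_factors.standard_normal(n_samples)
        al = config.amplicon_loading
        # amplicon rows were pre-filled with the block noise scale; rescale
        block = matrix[row : row + len(amplicon_genes)]
        block *= np.sqrt(1.0 - al**2) / np.sqrt(1.0 - lam**2)
        block += al * a
        row += len(amplicon_genes)
    if background_genes:
        block = matrix[row:]
        block *= 1.0 / np.sqrt(1.0 - lam**2)  # pure noise at noise_sd scale

    # differential-expression overlay on tumor columns
    de_genes: dict[str, float] = {}
    tumor = np.array([c == "tumor" for c in condition])
    if config.de_by_block is not None:
        sub_map = {sub: genes for subs in block_tree.values() for sub, genes in subs.items()}
        for sub, shift in config.de_by_block.items():
            if sub not in sub_map:
                raise ValueError(f"unknown sub-block in de_by_block: {sub}")
            for g in sub_map[sub]:
                de_genes[g] = float(shift)
    elif config.de_fraction > 0:
        # DE pool: block and background genes alike; the amplicon stays
        # clean so its isolation is a pure co-expression property
        pool = [i for i, g in enumerate(gene_ids) if g not in set(amplicon_genes)]
        n_de = int(round(config.de_fraction * len(pool)))
        chosen = rng_de.choice(len(pool), size=n_de, replace=False)
        signs = rng_de.choice([-1.0, 1.0], size=n_de)
        for idx, sign in zip(chosen, signs):
            de_genes[gene_ids[pool[idx]]] = float(sign * config.de_shift)

    index = {g: i for i, g in enumerate(gene_ids)}
    for g, shift in de_genes.items():
        matrix[index[g], tumor] += shift

    data = ExpressionDataset(matrix, gene_ids, sample_ids, condition)
    truth = GroundTruth(
        block_tree=block_tree,
        amplicon_genes=amplicon_genes,
        de_genes=de_genes,
        all_genes=gene_ids,
    )
    return data, truth


def generate_gene_sets(
    truth: GroundTruth,
    n_decoy_sets: int = 0,
    decoy_size: int = 20,
    seed: int = 0,
    contamination: float = 0.0,
) -> dict[str, list[str]]:
    """Gene sets aligned to planted sub-blocks, plus uniform decoy sets.

    One set per sub-block named ``SET_<sub-block>``, holding its genes plus
    ``round(contamination * size)`` random outside genes; decoys are drawn
    uniformly without replacement from the gene universe.  The planted
    (non-decoy) sets are also recorded in ``truth.planted_sets``.
    """
    if not truth.all_genes:
        raise ValueError("ground truth has no genes")
    if n_decoy_sets and decoy_size > len(truth.all_genes):
        raise ValueError("decoy_size exceeds gene universe")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = np.array(truth.all_genes)

    sets: dict[str, list[str]] = {}
    for sub, genes in truth.sub_block_genes().items():
        members = list(genes)
        n_extra = int(round(contamination * len(genes)))
        if n_extra:
            outside = np.array(sorted(set(truth.all_genes) - set(genes)))
            members += list(rng.choice(outside, size=n_extra, replace=False))
        sets[f"SET_{sub}"] = members
    truth.planted_sets = dict(sets)

    for d in range(1, n_decoy_sets + 1):
        sets[f"DECOY_{d:03d}"] = list(rng.choice(universe, size=decoy_size, replace=False))
    return sets
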