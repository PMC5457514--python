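"""Simulate two-group bulk expression matrices with known differential genes.

Emulates a developmental comparison with four biological replicates per
group: log-normal expression spanning several orders of magnitude, a
mean-variance relationship that makes rank-windowed background variance
meaningful, and a designated target set shifted down in the second group by
a fixed log2 fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_expression"]


def simulate_expression(
    n_genes: int,
    n_reps_per_group: int = 4,
    target_set_size: int = 0,
    effect_log2fc: float = 0.0,
    dispersion: float = 0.25,
    seed: int | None = None,
    *,
    group_names: tuple = ("groupA", "groupB"),
    base_log2_mean: float = 5.0,
    base_log2_sd: float = 2.5,
):
    """Generate a genes × samples expression matrix for two groups.

    Parameters
    ----------
    n_genes
        Number of genes.
    n_reps_per_group
        Biological replicates per group (4 matches a typical design).
    target_set_size
        Number of genes designated as true targets; they are shifted by
        −``effect_log2fc`` log2 units in the second group.
    effect_log2fc
        True effect size (log2 fold change) applied to target genes.
    dispersion
        Baseline SD of within-group log2 expression; low-expressed genes
        get inflated noise so variance decreases with mean expression.
    seed
        Generator seed; identical seeds give identical matrices.

    Returns
    -------
    matrix : pandas.DataFrame
        Genes (index) × samples, non-negative linear-scale expression.
    groups : dict
        sample name → group name.
    truth : dict
        ``target_genes`` (the designated set) and ``de_genes`` (targets with
        a nonzero true effect).
    """
    if target_set_size >= n_genes:
        raise ValueError("target_set_size must be < n_genes")
    if n_reps_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)

    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)])
    base = rng.normal(base_log2_mean, base_log2_sd, n_genes)
    # monotone mean-variance: noise shrinks with expression level
    level = (base - base.min()) / max(np.ptp(base), 1e-12)
    gene_sd = dispersion * (1.0 + 1.5 * (1.0 - level))

    targets = gene_ids[rng.choice(n_genes, size=target_set_size, replace=False)]
    is_target = np.isin(gene_ids, targets)

    cols, data = [], []
    for gi, gname in enumerate(group_names):
        shift = np.where(is_target, -effect_log2fc if gi == 1 else 0.0, 0.0)
        for r in range(n_reps_per_group):
            cols.append(f"{gname}_rep{r + 1}")
            data.append(2.0 ** (base + shift + rng.normal(0.0, gene_sd, n_genes)))
    matrix = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    matrix.index.name = "gene_id"
    groups = {
        c: group_names[0] if c.startswith(group_names[0]) else group_names[1]
        for c in cols
    }
    truth = {
        "target_genes": set(targets),
        "de_genes": set(targets) if effect_log2fc != 0 else set(),
    }
    return matrix, groups, truth
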