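"""Scaffold-to-chromosome assignment from micro-dissected chromosome reads.

For each (chromosome sample, scaffold) pair the position representation
ratio PRR = (positions on scaffold / positions in genome) divided by
(scaffold length / genome length) measures enrichment; PRR is lognormal, so
the threshold is applied to logPRR (> 0), together with a one-sided
binomial test (p <= 0.01) of the position count against the scaffold's
length share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest


def prr(n_pos_scaffold: int, n_pos_genome: int, scaffold_len: int, genome_len: int) -> tuple[float, float]:
    """Position representation ratio and its natural log."""
    if min(n_pos_scaffold, 1) <= 0 or n_pos_genome <= 0 or scaffold_len <= 0 or genome_len <= 0:
        raise ValueError("counts and lengths must be positive")
    ratio = (n_pos_scaffold / n_pos_genome) / (scaffold_len / genome_len)
    return float(ratio), float(np.log(ratio))


def prr_pvalue(n_pos_scaffold: int, n_pos_genome: int, scaffold_len: int, genome_len: int) -> float:
    """One-sided (enrichment) binomial test of the scaffold position count."""
    p0 = scaffold_len / genome_len
    if not 0 < p0 < 1:
        raise ValueError("scaffold length share must lie in (0, 1)")
    return float(binomtest(n_pos_scaffold, n_pos_genome, p0, alternative="greater").pvalue)


def mean_pairwise_distance(positions: np.ndarray) -> float:
    """Mean |x_i - x_j| over all position pairs (NaN for a single position).

    Uses the sorted-prefix identity, O(n log n).
    """
    x = np.sort(np.asarray(positions, dtype=float))
    n = x.size
    if n < 2:
        return float("nan")
    weights = 2 * np.arange(n) - (n - 1)
    return float(np.sum(weights * x) / (n * (n - 1) / 2))


def scaffold_stats(table: pd.DataFrame, chromosome: str, scaffold: str) -> dict:
    """Per-(chromosome, scaffold) position count, spacing and read depth."""
    sel = table[(table["chromosome"] == chromosome) & (table["scaffold"] == scaffold)]
    if len(sel) == 0:
        raise ValueError("no positions for this chromosome/scaffold")
    pos = sel["position"].to_numpy()
    return {
        "n_positions": int(len(sel)),
        "mean_pairwise_distance": mean_pairwise_distance(pos),
        "mean_reads_per_position": float(sel["n_reads"].mean()) if "n_reads" in sel else float("nan"),
    }


@dataclass
class ScaffoldAssignment:
    chromosome: str
    scaffold: str
    n_positions: int
    mean_pairwise_distance: float
    mean_reads_per_position: float
    prr: float
    log_prr: float
    p_binomial: float
    enriched: bool


def assign(
    table: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    min_positions: int = 2,
    p_max: float = 0.01,
    min_mean_distance: float | None = None,
) -> pd.DataFrame:
    """Per-chromosome scaffold enrichment calls.

    A scaffold is enriched for a chromosome sample when logPRR > 0, the
    binomial p-value is at most ``p_max`` and at least ``min_positions``
    positions support it; ``min_mean_distance`` optionally also requires the
    positions to be spread out (off by default).
    """
    genome_len = int(sum(scaffold_lengths.values()))
    rows = []
    for chrom, sub in table.groupby("chromosome", sort=False):
        n_genome = len(sub)
        for scaf, ssub in sub.groupby("scaffold", sort=False):
            st = scaffold_stats(table, chrom, scaf)
            ratio, log_ratio = prr(len(ssub), n_genome, scaffold_lengths[scaf], genome_len)
            p = prr_pvalue(len(ssub), n_genome, scaffold_lengths[scaf], genome_len)
            enriched = (log_ratio > 0) and (p <= p_max) and (st["n_positions"] >= min_positions)
            if enriched and min_mean_distance is not None:
                enriched = st["mean_pairwise_distance"] >= min_mean_distance
            rows.append(
                ScaffoldAssignment(
                    chromosome=chrom,
                    scaffold=scaf,
                    n_positions=st["n_positions"],
                    mean_pairwise_distance=st["mean_pairwise_distance"],
                    mean_reads_per_position=st["mean_reads_per_position"],
                    prr=ratio,
                    log_prr=log_ratio,
                    p_binomial=p,
                    enriched=enriched,
                ).__dict__
            )
    return pd.DataFrame(rows)


def assignment_map(assignments: pd.DataFrame) -> dict[str, list[str]]:
    """chromosome -> enriched scaffolds (many-to-one maps allowed)."""
    out: dict[str, list[str]] = {}
    for chrom, sub in assignments[assignments["enriched"]].groupby("chromosome", sort=False):
        out[chrom] = sorted(sub["scaffold"].tolist())
    return out
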