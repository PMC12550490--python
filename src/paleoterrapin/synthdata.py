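"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the field data the pipeline consumes: a sequential
coalescent simulator for single-diploid heterozygosity tracks (known
piecewise-constant Ne and hidden TMRCA series), gridded climate layers with
occurrences drawn from a known logistic suitability surface, an ultrametric
pure-birth tree with Brownian traits, and mapped-read position tables with
controlled scaffold enrichment.  All generators are deterministic given
their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .hetstats import BIN_HET, BIN_HOM, GenotypeTrack, HET, HetBinTrack
from .rasters import RasterStack


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

@dataclass
class DemographyScenario:
    """Piecewise-constant diploid Ne history plus sequence parameters.

    ``epochs`` is a list of (start_time_generations, Ne) with start times
    strictly increasing from 0; the last epoch extends to infinity.
    """

    epochs: list[tuple[float, float]]
    mutation_rate_per_site_per_gen: float = 1e-8
    recombination_rate_per_site_per_gen: float = 1e-8
    sequence_length_bp: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        starts = [t for t, _ in self.epochs]
        if not starts or starts[0] != 0 or any(np.diff(starts) <= 0):
            raise ValueError("epoch start times must increase strictly from 0")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("all Ne must be positive")
        for r in (self.mutation_rate_per_site_per_gen, self.recombination_rate_per_site_per_gen):
            if not (0 <= r < 1):
                raise ValueError("rates must lie in [0, 1)")
        if self.sequence_length_bp <= 0:
            raise ValueError("sequence length must be positive")


@dataclass
class SimulatedGenome:
    """Het-bin track plus the hidden truth behind it."""

    het_track: HetBinTrack
    tmrca_segments: pd.DataFrame  # columns start, end (bp, half-open), tmrca_gen
    het_positions: np.ndarray  # 0-based site positions
    scenario: DemographyScenario


def _sample_coalescent_time(start: float, epochs: list[tuple[float, float]], n_pairs_rate: float, rng) -> float:
    """First event time after ``start`` under piecewise rate n_pairs_rate/(2*Ne(t))."""
    e = rng.exponential()
    t = start
    for i, (t0, ne) in enumerate(epochs):
        t1 = epochs[i + 1][0] if i + 1 < len(epochs) else np.inf
        if t1 <= t:
            continue
        seg_start = max(t, t0)
        rate = n_pairs_rate / (2.0 * ne)
        need = e / rate
        if seg_start + need < t1:
            return seg_start + need
        e -= rate * (t1 - seg_start)
    raise RuntimeError("unreachable: last epoch is unbounded")


def _smc_prime_update(t_cur: float, epochs, rng) -> float:
    """Resample TMRCA after a recombination event, SMC' style.

    The recombination point is uniform on (0, t); below the old TMRCA the
    floating lineage meets two branches (total rate 2 * pair rate) and
    re-coalescing onto its own branch restores the old height.
    """
    u = rng.uniform(0.0, t_cur)
    v = _sample_coalescent_time(u, epochs, 2.0, rng)
    if v < t_cur:
        return v if rng.random() < 0.5 else t_cur
    return _sample_coalescent_time(t_cur, epochs, 1.0, rng)


def _smc_update(t_cur: float, epochs, rng) -> float:
    """Plain-SMC resampling: erase above the recombination point, recoalesce."""
    u = rng.uniform(0.0, t_cur)
    return _sample_coalescent_time(u, epochs, 1.0, rng)


def sample_pairwise_tmrca(scenario: DemographyScenario, n: int, seed: int | None = None) -> np.ndarray:
    """Marginal TMRCA draws (generations) under the scenario's Ne history."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    return np.array([_sample_coalescent_time(0.0, scenario.epochs, 1.0, rng) for _ in range(n)])


def simulate_het_track(
    scenario: DemographyScenario,
    bin_size: int = 100,
    scaffold_name: str = "chr1",
    smc_prime: bool = True,
) -> SimulatedGenome:
    """Simulate the het/hom bin sequence of one diploid genome.

    TMRCA is piecewise constant along the sequence; recombination events
    (rate 2*r*TMRCA per bp) trigger an SMC' (default) or plain-SMC
    resampling.  Heterozygous sites are Poisson-placed at 2*mu*TMRCA per
    site within each constant-TMRCA segment.
    """
    L = scenario.sequence_length_bp
    if L < bin_size:
        raise ValueError("sequence shorter than one bin")
    rng = np.random.default_rng(scenario.seed)
    mu = scenario.mutation_rate_per_site_per_gen
    rr = scenario.recombination_rate_per_site_per_gen
    update = _smc_prime_update if smc_prime else _smc_update

    t = _sample_coalescent_time(0.0, scenario.epochs, 1.0, rng)
    pos = 0.0
    seg_start: list[float] = []
    seg_end: list[float] = []
    seg_t: list[float] = []
    het_positions: list[np.ndarray] = []
    while pos < L:
        dist = rng.exponential(1.0 / (2.0 * rr * t)) if rr > 0 and t > 0 else np.inf
        end = min(pos + dist, float(L))
        seg_start.append(pos)
        seg_end.append(end)
        seg_t.append(t)
        if mu > 0 and end > pos:
            n_het = rng.poisson(2.0 * mu * t * (end - pos))
            if n_het:
                het_positions.append(rng.uniform(pos, end, size=n_het).astype(np.int64))
        if end >= L:
            break
        pos = end
        t = update(t, scenario.epochs, rng)

    hets = np.unique(np.concatenate(het_positions)) if het_positions else np.empty(0, dtype=np.int64)
    n_bins = int(np.ceil(L / bin_size))
    arr = np.full(n_bins, BIN_HOM, dtype=np.int8)
    if hets.size:
        arr[np.unique(hets // bin_size)] = BIN_HET
    track = HetBinTrack(bins={scaffold_name: arr}, bin_size=bin_size, genome_size_bp=L)
    segments = pd.DataFrame({"start": seg_start, "end": seg_end, "tmrca_gen": seg_t})
    return SimulatedGenome(track, segments, hets, scenario)


def genome_to_genotype_track(
    sim: SimulatedGenome, depth_mean: float = 30.0, scaffold_name: str = "chr1", seed: int = 0
) -> GenotypeTrack:
    """Emit the simulated het sites as a per-site genotype table.

    Only heterozygous sites are materialised (hom-ref sites are implicit),
    which is enough for genome-size-denominator heterozygosity.
    """
    rng = np.random.default_rng(seed)
    pos = sim.het_positions + 1  # 1-based
    df = pd.DataFrame(
        {
            "scaffold": scaffold_name,
            "pos": pos,
            "genotype": HET,
            "depth": rng.poisson(depth_mean, size=pos.size),
            "baseq": 60,
            "mapq": 60,
        }
    )
    return GenotypeTrack(df, {scaffold_name: sim.scenario.sequence_length_bp})


# ---------------------------------------------------------------------------
# niche / climate
# ---------------------------------------------------------------------------

@dataclass
class NicheScenario:
    """Synthetic climate grids and a known logistic suitability surface.

    ``true_coefficients`` maps feature names over the synthetic layers
    ("L1", "L2^2", "L1*L3", or "const") to real coefficients; suitability is
    the logistic transform of the resulting linear predictor on standardized
    layers.  ``per_period_climate_shift`` maps period labels to additive
    per-layer offsets, so the true suitable area changes in a known way.
    """

    grid_shape: tuple[int, int] = (60, 60)
    cell_size_km: float = 4.5
    true_coefficients: dict[str, float] = field(default_factory=lambda: {"L1": 2.0, "L2": -1.0, "const": -0.5})
    n_occurrences: int = 200
    n_climate_layers: int = 4
    per_period_climate_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0
    cell_size_deg: float = 0.05
    noise_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.n_climate_layers < 2:
            raise ValueError("need at least two climate layers")
        if self.grid_shape[0] < 2 or self.grid_shape[1] < 2:
            raise ValueError("grid too small")


@dataclass
class NicheTruth:
    suitability: dict[str, np.ndarray]
    suitable_area_km2: dict[str, float]
    coefficients: dict[str, float]


def _feature_value(name: str, layers: dict[str, np.ndarray]) -> np.ndarray:
    if name == "const":
        return np.ones_like(next(iter(layers.values())))
    if "*" in name:
        a, b = name.split("*")
        return layers[a] * layers[b]
    if name.endswith("^2"):
        return layers[name[:-2]] ** 2
    return layers[name]


def _standardize(arr: np.ndarray) -> np.ndarray:
    sd = arr.std()
    return (arr - arr.mean()) / (sd if sd > 0 else 1.0)


def simulate_rasters_and_occurrences(
    scenario: NicheScenario, allow_few: bool = False, area_threshold: float = 0.36
) -> tuple[dict[str, RasterStack], "OccurrenceSet", NicheTruth]:
    """Per-period climate stacks plus occurrences drawn from known suitability."""
    from .niche import OccurrenceSet  # local import to keep module layering acyclic

    if scenario.n_occurrences < 15 and not allow_few:
        raise ValueError("fewer than 15 occurrences; pass allow_few=True to override")
    rng = np.random.default_rng(scenario.seed)
    nrow, ncol = scenario.grid_shape
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")

    layers: dict[str, np.ndarray] = {}
    for i in range(scenario.n_climate_layers):
        theta = rng.uniform(0, 2 * np.pi)
        grad = np.cos(theta) * rows / nrow + np.sin(theta) * cols / ncol
        noise = gaussian_filter(rng.normal(size=(nrow, ncol)), sigma=3.0)
        layers[f"L{i + 1}"] = _standardize(grad + scenario.noise_sigma * noise)

    base_mean = {k: v.mean() for k, v in layers.items()}
    base_sd = {k: v.std() if v.std() > 0 else 1.0 for k, v in layers.items()}

    def suitability_of(lyr: dict[str, np.ndarray]) -> np.ndarray:
        # standardized against the present-day baseline so period shifts
        # move the linear predictor instead of being normalized away
        std = {k: (v - base_mean[k]) / base_sd[k] for k, v in lyr.items()}
        eta = np.zeros((nrow, ncol))
        for name, coef in scenario.true_coefficients.items():
            eta += coef * _feature_value(name, std)
        return expit(eta)

    periods = ["present"] + list(scenario.per_period_climate_shift)
    stacks: dict[str, RasterStack] = {}
    suit: dict[str, np.ndarray] = {}
    areas: dict[str, float] = {}
    cell_area = scenario.cell_size_km**2
    for period in periods:
        shift = scenario.per_period_climate_shift.get(period, {})
        lyr = {k: v + shift.get(k, 0.0) for k, v in layers.items()}
        stacks[period] = RasterStack(
            layers=lyr,
            cell_size_deg=scenario.cell_size_deg,
            cell_size_km=scenario.cell_size_km,
            period=period,
        )
        s = suitability_of(lyr)
        suit[period] = s
        areas[period] = float(np.sum(s >= area_threshold) * cell_area)

    p = suit["present"].ravel()
    cells = rng.choice(p.size, size=scenario.n_occurrences, replace=True, p=p / p.sum())
    r, c = np.unravel_index(cells, (nrow, ncol))
    lon, lat = stacks["present"].lonlat_of(r, c)
    jitter = scenario.cell_size_deg / 2
    lon = lon + rng.uniform(-jitter, jitter, size=lon.size)
    lat = lat + rng.uniform(-jitter, jitter, size=lat.size)
    occ = OccurrenceSet(species="synthetic", lon=np.asarray(lon), lat=np.asarray(lat))
    return stacks, occ, NicheTruth(suit, areas, dict(scenario.true_coefficients))


# ---------------------------------------------------------------------------
# comparative (tree + traits)
# ---------------------------------------------------------------------------

@dataclass
class ComparativeScenario:
    n_species: int = 16
    tree_depth: float = 1.0
    brownian_sigma2: float = 1.0
    status_assignment_rule: str = "random"  # or "by_area"
    status_effect: float = 0.0  # additive shift on traits for at-risk species
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        if self.tree_depth <= 0 or self.brownian_sigma2 < 0:
            raise ValueError("tree depth must be positive and sigma2 non-negative")


def simulate_yule_tree(n_species: int, tree_depth: float, seed: int = 0, star: bool = False):
    """Ultrametric pure-birth tree as a dendropy Tree, total depth fixed."""
    import dendropy

    rng = np.random.default_rng(seed)
    labels = [f"sp{i + 1}" for i in range(n_species)]
    if star:
        newick = "(" + ",".join(f"{x}:{tree_depth}" for x in labels) + ");"
        return dendropy.Tree.get(data=newick, schema="newick")

    # forward Yule: root splits at time 0, then exponential waits with rate =
    # #lineages between successive splits, rescaled so tips sit at tree_depth
    waits = [rng.exponential(1.0 / k) for k in range(2, n_species)]
    waits.append(rng.exponential(1.0 / n_species))  # tip extension after last split
    scale = tree_depth / sum(waits)
    split_times = np.concatenate([[0.0], np.cumsum(waits[:-1]) * scale])

    class _N:  # lightweight node for assembly
        def __init__(self, birth):
            self.birth = birth
            self.children = []
            self.label = None

    root = _N(0.0)
    active = [root]
    for t in split_times:
        parent = active.pop(int(rng.integers(len(active))))
        parent.split = t
        for _ in range(2):
            child = _N(t)
            parent.children.append(child)
            active.append(child)
    rng.shuffle(active)
    for node, lab in zip(active, labels):
        node.label = lab

    def to_newick(node) -> str:
        if not node.children:
            return f"{node.label}:{tree_depth - node.birth:.10f}"
        inner = ",".join(to_newick(c) for c in node.children)
        return f"({inner}):{node.split - node.birth:.10f}"

    inner = ",".join(to_newick(c) for c in root.children)
    return dendropy.Tree.get(data=f"({inner});", schema="newick")


def simulate_comparative(scenario: ComparativeScenario, star: bool = False):
    """Tree plus Brownian species traits, optional additive status effect.

    Returns (dendropy Tree, species table) with traits H, mean_Ne,
    current_area_km2 and mean_past_area_km2 evolving under Brownian motion
    with variance scenario.brownian_sigma2 on the tree, and categorical
    status / habitat / climate labels.
    """
    from .pgls import brownian_covariance

    rng = np.random.default_rng(scenario.seed)
    tree = simulate_yule_tree(scenario.n_species, scenario.tree_depth, seed=scenario.seed, star=star)
    C, taxa = brownian_covariance(tree)
    n = len(taxa)
    if scenario.brownian_sigma2 > 0:
        L = np.linalg.cholesky(scenario.brownian_sigma2 * C + 1e-12 * np.eye(n))
    else:
        L = np.zeros((n, n))
    traits = {name: L @ rng.standard_normal(n) for name in ("H", "mean_Ne", "current_area_km2", "mean_past_area_km2")}

    if scenario.status_assignment_rule == "by_area":
        order = np.argsort(traits["current_area_km2"])
        at_risk = np.zeros(n, dtype=bool)
        at_risk[order[: n // 2]] = True
    else:
        at_risk = np.zeros(n, dtype=bool)
        at_risk[rng.permutation(n)[: n // 2]] = True
    for name in traits:
        traits[name] = traits[name] + scenario.status_effect * at_risk

    table = pd.DataFrame(
        {
            "species": taxa,
            **traits,
            "status": np.where(at_risk, "At risk", "Not at risk"),
            "habitat": rng.choice(["aquatic", "terrestrial"], size=n),
            "climate": rng.choice(["tropical", "temperate"], size=n),
        }
    )
    return tree, table


# ---------------------------------------------------------------------------
# chromosome reads
# ---------------------------------------------------------------------------

def simulate_chromosome_reads(
    n_chromosomes: int,
    scaffold_lengths: dict[str, int],
    enrichment_map: dict[str, str],
    seed: int = 0,
    enrichment_factor: float = 10.0,
    positions_per_chromosome: int = 500,
    mean_reads_per_position: float = 2.0,
) -> pd.DataFrame:
    """Mapped-position table for micro-dissected chromosome samples.

    Each chromosome's positions fall on its true scaffold with sampling
    weight ``enrichment_factor`` times the per-bp background; an infinite
    factor puts every position on the true scaffold.
    """
    rng = np.random.default_rng(seed)
    scaffolds = list(scaffold_lengths)
    lengths = np.array([scaffold_lengths[s] for s in scaffolds], dtype=float)
    recs = []
    for i in range(n_chromosomes):
        chrom = f"chr{i + 1}"
        true_scaf = enrichment_map.get(chrom)
        w = lengths.copy()
        if true_scaf is not None:
            j = scaffolds.index(true_scaf)
            if np.isinf(enrichment_factor):
                w = np.zeros_like(w)
                w[j] = 1.0
            else:
                w[j] *= enrichment_factor
        w = w / w.sum()
        choice = rng.choice(len(scaffolds), size=positions_per_chromosome, p=w)
        for k in np.bincount(choice, minlength=len(scaffolds)).nonzero()[0]:
            npos = int(np.sum(choice == k))
            pos = np.sort(rng.integers(1, scaffold_lengths[scaffolds[k]] + 1, size=npos))
            reads = 1 + rng.poisson(mean_reads_per_position - 1.0, size=npos)
            for p, nr in zip(pos, reads):
                recs.append((chrom, scaffolds[k], int(p), int(nr)))
    return pd.DataFrame(recs, columns=["chromosome", "scaffold", "position", "n_reads"])
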