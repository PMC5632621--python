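"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shape of the real inputs — spatially
autocorrelated climate layers, lineages with Gaussian niches in
environment space, discrete characters evolved under Mk1 on a fixed
tree, and small alignments with shared indels and few-step haplotype
structure — while exposing the generating parameters as sidecar ground
truth so downstream tests can assert recovery.

Suitability is Gaussian in *environment* space, not geographic space:
a lineage's probability of occupying a cell depends on the cell's
climate, matching the niche concept the ordination analysis assumes.
The default scenario mirrors the study system qualitatively: three
lineages, two with strongly overlapping niches and one distinct, with
sample sizes 100/100/300.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .char_evolution import mk1_transition, _TreeArrays
from .io_env import EnvRasterStack

DEFAULT_N_VARS = 10  # matches a 10-layer bioclim stack


@dataclass
class VirtualLineageSpec:
    """Gaussian niche of one virtual lineage in environment space."""

    label: str
    centroid: np.ndarray  # per environmental variable
    covariance: np.ndarray  # symmetric positive-definite
    n: int

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.n < 1:
            raise ValueError("sample size n must be >= 1")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance must be positive-definite")


def make_env_rasters(
    n_vars: int = DEFAULT_N_VARS,
    grid_dims: tuple[int, int] = (80, 80),
    smoothness: float = 6.0,
    seed: int | np.random.Generator = 0,
    correlations: list[tuple[int, int, float]] | None = None,
    xmin: float = 0.0,
    ymin: float = 0.0,
    cellsize: float = 0.1,
) -> EnvRasterStack:
    """Spatially autocorrelated, standardized environmental layers.

    Each layer is white noise smoothed with a Gaussian filter of radius
    ``smoothness`` cells then standardized to zero mean / unit variance.
    ``correlations`` entries (i, j, rho) overwrite layer j with a mixture
    rho * layer_i + sqrt(1 - rho^2) * layer_j to inject a known pairwise
    correlation.
    """
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layers = rng.standard_normal((n_vars,) + tuple(grid_dims))
    if smoothness > 0:
        layers = np.stack([
            ndimage.gaussian_filter(l, sigma=smoothness, mode="reflect") for l in layers
        ])
    layers = (layers - layers.mean(axis=(1, 2), keepdims=True)) / layers.std(
        axis=(1, 2), keepdims=True
    )
    for i, j, rho in correlations or []:
        mixed = rho * layers[i] + np.sqrt(1.0 - rho ** 2) * layers[j]
        layers[j] = (mixed - mixed.mean()) / mixed.std()
    names = [f"bio{i + 1}" for i in range(n_vars)]
    return EnvRasterStack(names, layers, xmin=xmin, ymin=ymin, cellsize=cellsize)


def sample_occurrences(
    spec: VirtualLineageSpec,
    rasters: EnvRasterStack,
    seed: int | np.random.Generator = 0,
    year_range: tuple[int, int] = (1990, 2015),
    missing_year_fraction: float = 0.1,
) -> pd.DataFrame:
    """Sample occurrence records from a lineage's Gaussian suitability.

    Cells are drawn (with replacement) with probability proportional to
    exp(-0.5 * (env - mu)' Sigma^-1 (env - mu)); coordinates are
    jittered uniformly within the chosen cell.  The true suitability of
    each record's cell is attached for audit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    valid = ~rasters.nodata_mask
    env = rasters.background_env()  # (n_cells, n_vars)
    diff = env - spec.centroid
    prec = np.linalg.inv(spec.covariance)
    maha = np.einsum("ij,jk,ik->i", diff, prec, diff)
    suit = np.exp(-0.5 * (maha - maha.min()))
    total = suit.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("zero total suitability over the raster")
    rows, cols = np.nonzero(valid)
    idx = rng.choice(len(rows), size=spec.n, p=suit / total)
    r, c = rows[idx], cols[idx]
    nrows = rasters.shape[0]
    lon = rasters.xmin + (c + rng.uniform(0, 1, spec.n)) * rasters.cellsize
    lat = rasters.ymin + (nrows - 1 - r + rng.uniform(0, 1, spec.n)) * rasters.cellsize
    years = rng.integers(year_range[0], year_range[1] + 1, spec.n).astype(object)
    n_missing = int(round(missing_year_fraction * spec.n))
    if n_missing:
        years[rng.choice(spec.n, n_missing, replace=False)] = pd.NA
    return pd.DataFrame({
        "lineage": spec.label,
        "lon": lon,
        "lat": lat,
        "year": pd.array(years, dtype="Int64"),
        "true_suitability": suit[idx] / suit.max(),
    })


@dataclass
class NicheScenario:
    rasters: EnvRasterStack
    occurrences: pd.DataFrame
    specs: list[VirtualLineageSpec]
    ground_truth: dict = field(default_factory=dict)


def default_scenario(seed: int = 0, n_vars: int = DEFAULT_N_VARS,
                     grid_dims: tuple[int, int] = (80, 80)) -> NicheScenario:
    """Three virtual lineages: two with overlapping niches, one distinct.

    Lineages A and B share most of their niche (centroids 0.4 standard
    environmental units apart along the first two gradients); lineage C
    sits on the opposite side of the climate space.  Sample sizes are
    100, 300 and 100: the second overlapping lineage is the widespread,
    densely collected one.
    """
    rng = np.random.default_rng(seed)
    rasters = make_env_rasters(n_vars=n_vars, grid_dims=grid_dims, seed=rng)
    base = np.zeros(n_vars)
    c_a = base.copy(); c_a[:2] = (0.9, 0.7)
    c_b = base.copy(); c_b[:2] = (0.7, 0.4)
    c_c = base.copy(); c_c[:2] = (-1.1, -0.9)
    cov = np.eye(n_vars) * 0.35 ** 2
    specs = [
        VirtualLineageSpec("lineageA", c_a, cov, 100),
        VirtualLineageSpec("lineageB", c_b, cov, 300),
        VirtualLineageSpec("lineageC", c_c, cov, 100),
    ]
    occ = pd.concat(
        [sample_occurrences(s, rasters, seed=rng) for s in specs], ignore_index=True
    )
    truth = {
        "overlapping_pair": ["lineageA", "lineageB"],
        "distinct_lineage": "lineageC",
        "centroids": {s.label: s.centroid.tolist() for s in specs},
        "sample_sizes": {s.label: s.n for s in specs},
    }
    return NicheScenario(rasters=rasters, occurrences=occ, specs=specs,
                         ground_truth=truth)


def simulate_mk_characters(
    tree: dendropy.Tree,
    alpha: float,
    k: int,
    n_chars: int,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve discrete characters down a fixed tree under Mk1.

    Root states are uniform; each branch applies the Mk1 transition for
    its length.  Returns (tip matrix, internal-node truth matrix), both
    taxa/nodes x characters with integer state indices.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = _TreeArrays(tree)
    n = len(arrays.nodes)
    states = np.empty((n, n_chars), dtype=int)
    # preorder: root first
    for i in range(n - 1, -1, -1):
        if i == arrays.root:
            states[i] = rng.integers(0, k, n_chars)
            continue
        P = mk1_transition(alpha, arrays.blen[i], k)
        parent_states = states[arrays.parent[i]]
        u = rng.uniform(size=n_chars)
        cum = np.cumsum(P[parent_states], axis=1)
        states[i] = (u[:, None] > cum).sum(axis=1)
    cols = [f"char{j}" for j in range(n_chars)]
    tips = pd.DataFrame(
        states[[i for i in range(n) if arrays.is_tip[i]]],
        index=[arrays.labels[i] for i in range(n) if arrays.is_tip[i]],
        columns=cols,
    )
    internal = pd.DataFrame(
        states[[i for i in range(n) if not arrays.is_tip[i]]],
        index=[arrays.labels[i] for i in range(n) if not arrays.is_tip[i]],
        columns=cols,
    )
    return tips, internal


BASES = "ACGT"


def make_toy_alignment(
    n_haplotypes: int = 3,
    steps_between: int | list[int] = 1,
    indel_spec: list[tuple[int, int, list[int]]] | None = None,
    n_copies: int | list[int] = 1,
    seed: int | np.random.Generator = 0,
    length: int = 60,
) -> tuple[list[tuple[str, str]], dict]:
    """Aligned toy sequences with known haplotype and indel structure.

    A haplotype backbone is built by sequential point mutations
    (``steps_between[i]`` fresh positions between haplotype i and i+1).
    ``indel_spec`` entries (start, end, haplotype_indices) gap the
    1-based inclusive span in those haplotypes' copies.  ``n_copies``
    replicates each haplotype.  Returns (records, ground truth) where
    the truth maps sequence ids to haplotype indices and lists the
    expected SIC spans.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = ([steps_between] * (n_haplotypes - 1)
             if isinstance(steps_between, int) else list(steps_between))
    copies = [n_copies] * n_haplotypes if isinstance(n_copies, int) else list(n_copies)
    if len(steps) != n_haplotypes - 1 or len(copies) != n_haplotypes:
        raise ValueError("steps_between / n_copies lengths do not match n_haplotypes")
    indel_spec = indel_spec or []
    blocked = {p for s, e, _ in indel_spec for p in range(s - 1, e)}
    # keep flanks gap-free so indels are internal
    blocked |= {0, length - 1}
    free = [p for p in range(length) if p not in blocked]
    if sum(steps) > len(free):
        raise ValueError("alignment too short for the requested mutations")
    base = "".join(rng.choice(list(BASES), length))
    mut_positions = list(rng.choice(free, size=sum(steps), replace=False))
    haplotypes = [base]
    pos_iter = iter(mut_positions)
    for s in steps:
        seq = list(haplotypes[-1])
        for _ in range(s):
            p = next(pos_iter)
            seq[p] = rng.choice([b for b in BASES if b != seq[p]])
        haplotypes.append("".join(seq))
    records = []
    hap_of = {}
    for h, (seq, m) in enumerate(zip(haplotypes, copies)):
        for c in range(m):
            sid = f"hap{h}_{c}"
            s = list(seq)
            for start, end, members in indel_spec:
                if h in members:
                    s[start - 1:end] = "-" * (end - start + 1)
            records.append((sid, "".join(s)))
            hap_of[sid] = h
    truth = {
        "haplotype_of": hap_of,
        "n_haplotypes": n_haplotypes,
        "multiplicities": copies,
        "sic_spans": sorted({(s, e) for s, e, _ in indel_spec}),
        "backbone": haplotypes,
    }
    return records, truth


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def random_tree(n_tips: int, seed: int | np.random.Generator = 0,
                mean_blen: float = 0.3) -> dendropy.Tree:
    """Random rooted birth-order topology with exponential branch lengths."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=_RngShim(rng),
    )
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = float(rng.exponential(mean_blen))
    return tree


class _RngShim:
    """Adapter giving dendropy the stdlib-random surface of a numpy
    Generator so tree simulation shares the package seed stream."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def random(self):
        return float(self._rng.uniform())

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(0, len(seq)))]

    def expovariate(self, lambd):
        return float(self._rng.exponential(1.0 / lambd))

    def gauss(self, mu, sigma):
        return float(self._rng.normal(mu, sigma)) if sigma else float(mu)

    def shuffle(self, x):
        self._rng.shuffle(x)
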