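"""Individual-based, non-Wright–Fisher forward simulator of evolutionary
potential under declining carrying capacity.

The model: a hermaphroditic, randomly mating diploid population with
overlapping generations.  Each yearly tick, individuals over one year of
age pair at random (no selfing) and produce Poisson litters; gametes
recombine between genes and assort freely between chromosomes and acquire
new mutations; everyone then survives viability selection with probability
``min(1, w * K / N)`` — absolute fitness times density regulation — and,
in projected future populations, an additional catastrophic mortality
drawn once per tick from a Beta distribution.  Deleterious mutation
effects come from a gamma distribution of selection coefficients with a
mixed dominance rule (fully recessive when s < -0.01, h = 0.25 otherwise);
fitness is multiplicative across loci.

Population rescaling by a factor ``lambda`` (N -> N/lambda, u -> u*lambda,
r -> min(0.5, r*lambda), s -> s*lambda) keeps the products N*u, N*r and
N*s invariant so desk-scale runs preserve the population-genetic regime of
full-scale ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .demography import DemographicTrajectory, KScenario

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GenomeArchitecture:
    """Coding-genome layout: genes in contiguous blocks per chromosome.

    Recombination happens at gene boundaries with probability
    ``intergene_recomb`` per boundary per meiosis (each boundary standing
    in for the intergenic DNA between genes); chromosomes assort freely.
    ``within_gene_recomb`` is a per-site rate folded into the boundary
    probability at gene resolution.
    """

    n_chromosomes: int = 56
    n_genes: int = 20_000
    gene_length: int = 1_500
    intergene_recomb: float = 1e-3
    within_gene_recomb: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")
        # contiguous blocks of genes per chromosome, sizes as even as the
        # division allows; precompute crossover-candidate positions
        base, extra = divmod(self.n_genes, self.n_chromosomes)
        counts = np.full(self.n_chromosomes, base, dtype=np.int64)
        counts[:extra] += 1
        all_junctions = np.arange(1, self.n_genes, dtype=np.int64) * self.gene_length
        chrom_junctions = np.cumsum(counts)[:-1] * self.gene_length
        self._junction_pos = chrom_junctions
        self._boundary_pos = np.setdiff1d(all_junctions, chrom_junctions)

    @property
    def genome_length(self) -> int:
        return self.n_genes * self.gene_length

    @property
    def n_internal_boundaries(self) -> int:
        return len(self._boundary_pos)

    def effective_recomb_report(self) -> str:
        """Human-readable summary of the implied effective recombination."""
        per_gene = self.intergene_recomb + self.gene_length * self.within_gene_recomb
        implied = per_gene / self.gene_length
        return (
            f"per-boundary crossover prob {per_gene:.2e} "
            f"(~{implied:.2e} per coding bp; one boundary stands in for the "
            f"intergenic DNA between adjacent genes)"
        )


@dataclass
class DFEConfig:
    """Mutation rates and the distribution of fitness effects.

    New mutations are deleterious with probability ratio/(ratio+1); a
    deleterious selection coefficient is minus a gamma draw (``gamma_shape``,
    mean ``gamma_mean``), truncated at -1 (lethal), with the mixed dominance
    rule h = 0 if s < -0.01 else 0.25.  Neutral mutations have s = 0,
    h = 0.5.
    """

    mutation_rate: float = 1.47e-8
    deleterious_to_neutral_ratio: float = 2.31
    gamma_shape: float = 0.186
    gamma_mean: float = 0.0131
    dominance_threshold: float = -0.01
    h_mild: float = 0.25
    neutral_only: bool = False

    def __post_init__(self) -> None:
        if self.deleterious_to_neutral_ratio <= 0 or self.gamma_shape <= 0:
            raise ValueError("ratio and gamma shape must be positive")

    @property
    def deleterious_fraction(self) -> float:
        r = self.deleterious_to_neutral_ratio
        return r / (r + 1.0)


@dataclass
class CatastropheModel:
    """Random natural disasters: one Beta(alpha, beta) mortality draw per
    tick, applied as an independent death probability per individual."""

    alpha: float = 0.5
    beta: float = 8.0
    enabled: bool = True


@dataclass
class SimConfig:
    architecture: GenomeArchitecture = field(default_factory=GenomeArchitecture)
    dfe: DFEConfig = field(default_factory=DFEConfig)
    catastrophe: CatastropheModel = field(default_factory=CatastropheModel)
    trajectory: DemographicTrajectory | None = None
    k_scenario: KScenario | None = None
    burn_in_generations: int | None = None  # default: 8 x (ancestral N / lambda)
    n_replicates: int = 25
    report_interval: int = 100
    horizon: int = 1_000
    rescale_factor: float = 1.0
    mean_litter: float = 2.0         # Poisson mean offspring per mated pair
    fitness_floor: float = 1e-6
    n_marker_loci: int = 0           # standing neutral markers seeded at 0.5
    wright_fisher_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rescale_factor < 1:
            raise ValueError("rescale_factor must be >= 1")

    def scaled(self, n: float) -> int:
        """A population size under the rescaling factor."""
        return max(2, int(round(n / self.rescale_factor)))

    @property
    def scaled_mutation_rate(self) -> float:
        return self.dfe.mutation_rate * self.rescale_factor

    @property
    def scaled_boundary_recomb(self) -> float:
        arch = self.architecture
        per_boundary = (
            arch.intergene_recomb + arch.gene_length * arch.within_gene_recomb
        )
        return min(0.5, per_boundary * self.rescale_factor)


# ---------------------------------------------------------------------------
# Mutation effects
# ---------------------------------------------------------------------------


def sample_mutation_effect(
    dfe: DFEConfig, rng: np.random.Generator, size: int = 1, rescale: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (s, h) for ``size`` new mutations.

    Deleterious with probability ratio/(ratio+1): s is minus a gamma draw
    (applied on the natural scale, then multiplied by the rescale factor and
    truncated at -1); the dominance rule uses the unscaled s.  Otherwise
    neutral: s = 0, h = 0.5.
    """
    s = np.zeros(size)
    h = np.full(size, 0.5)
    if not dfe.neutral_only:
        deleterious = rng.random(size) < dfe.deleterious_fraction
        n_del = int(deleterious.sum())
        if n_del:
            raw = -rng.gamma(dfe.gamma_shape, dfe.gamma_mean / dfe.gamma_shape, n_del)
            h_del = np.where(raw < dfe.dominance_threshold, 0.0, dfe.h_mild)
            s_del = np.maximum(raw * rescale, -1.0)
            s[deleterious] = s_del
            h[deleterious] = h_del
    return s, h


def draw_catastrophe(model: CatastropheModel, rng: np.random.Generator) -> float:
    """One per-generation mortality fraction from Beta(alpha, beta)."""
    return float(rng.beta(model.alpha, model.beta))


# ---------------------------------------------------------------------------
# Mutation registry and individuals
# ---------------------------------------------------------------------------


class MutationRegistry:
    """Growable arrays of mutation position, s and h, addressed by id.

    Amortized-O(1) appends via capacity doubling; ``positions``/``s``/``h``
    are views over the live prefix and are refreshed after every add.
    """

    def __init__(self, capacity: int = 1024) -> None:
        self._pos = np.empty(capacity, dtype=np.int64)
        self._s = np.empty(capacity)
        self._h = np.empty(capacity)
        self._n = 0
        self.any_selected = False
        self._refresh()

    def _refresh(self) -> None:
        self.positions = self._pos[: self._n]
        self.s = self._s[: self._n]
        self.h = self._h[: self._n]

    def __len__(self) -> int:
        return self._n

    def _reserve(self, extra: int) -> None:
        need = self._n + extra
        if need <= len(self._pos):
            return
        cap = max(need, 2 * len(self._pos))
        for name in ("_pos", "_s", "_h"):
            old = getattr(self, name)
            new = np.empty(cap, dtype=old.dtype)
            new[: self._n] = old[: self._n]
            setattr(self, name, new)

    def add(self, positions: np.ndarray, s: np.ndarray, h: np.ndarray) -> np.ndarray:
        k = len(positions)
        self._reserve(k)
        start = self._n
        self._pos[start: start + k] = positions
        self._s[start: start + k] = s
        self._h[start: start + k] = h
        self._n += k
        if not self.any_selected and np.any(np.asarray(s) != 0):
            self.any_selected = True
        self._refresh()
        return np.arange(start, start + k, dtype=np.int64)


@dataclass
class Individual:
    """Two haplotypes (arrays of mutation ids, sorted by genomic position)
    and a cached absolute fitness.  ``pos1``/``pos2`` cache the positions of
    the haplotype mutations (same order) to avoid registry lookups in
    meiosis."""

    hap1: np.ndarray
    hap2: np.ndarray
    age: int = 0
    fitness: float = 1.0
    pos1: np.ndarray | None = None
    pos2: np.ndarray | None = None

    def cache_positions(self, registry: "MutationRegistry") -> None:
        self.pos1 = registry.positions[self.hap1]
        self.pos2 = registry.positions[self.hap2]


def individual_fitness(
    ind: Individual, registry: MutationRegistry, floor: float = 1e-6,
    fixed_log_fitness: float = 0.0,
) -> float:
    """Multiplicative absolute fitness: (1+s) per homozygous mutation,
    (1+h s) per heterozygous one, times the fixed-substitution baseline,
    floored at a small positive value."""
    if len(registry) == 0 or not registry.any_selected:
        return max(float(np.exp(fixed_log_fitness)), floor)
    hom = np.intersect1d(ind.hap1, ind.hap2, assume_unique=True)
    het = np.setxor1d(ind.hap1, ind.hap2, assume_unique=True)
    logw = fixed_log_fitness
    if hom.size:
        s = registry.s[hom]
        s = s[s != 0]
        if s.size:
            if np.any(s <= -1.0):
                return floor  # homozygous lethal
            logw += np.log1p(s).sum()
    if het.size:
        s = registry.s[het]
        h = registry.h[het]
        nz = s != 0
        if nz.any():
            logw += np.log1p(h[nz] * s[nz]).sum()
    return max(float(np.exp(logw)), floor)


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    population: list[Individual]
    registry: MutationRegistry
    generation: int = 0
    fixed_log_fitness: float = 0.0
    extinct: bool = False
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def census(self) -> int:
        return len(self.population)

    def mean_fitness(self) -> float:
        if not self.population:
            return 0.0
        return float(np.mean([i.fitness for i in self.population]))

    def mean_heterozygosity(self, genome_length: int) -> float:
        """Mean per-individual heterozygosity: heterozygous mutation sites
        over the simulated genome length."""
        if not self.population:
            return 0.0
        n_het = [np.setxor1d(i.hap1, i.hap2).size for i in self.population]
        return float(np.mean(n_het)) / genome_length


def init_population(
    cfg: SimConfig, n: int, rng: np.random.Generator
) -> SimState:
    """Founders: mutation-free diploids (plus optional standing neutral
    markers at frequency 0.5 for drift calibration runs)."""
    registry = MutationRegistry()
    pop = [
        Individual(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), age=1)
        for _ in range(n)
    ]
    if cfg.n_marker_loci > 0:
        L = cfg.architecture.genome_length
        pos = np.sort(rng.choice(L, size=cfg.n_marker_loci, replace=False))
        ids = registry.add(pos, np.zeros(cfg.n_marker_loci), np.full(cfg.n_marker_loci, 0.5))
        for ind in pop:
            for hap_name, pos_name in (("hap1", "pos1"), ("hap2", "pos2")):
                carry = rng.random(cfg.n_marker_loci) < 0.5
                setattr(ind, hap_name, ids[carry].copy())
                setattr(ind, pos_name, pos[carry].copy())
    state = SimState(pop, registry, rng=rng)
    for ind in pop:
        ind.fitness = individual_fitness(ind, registry, cfg.fitness_floor)
    return state


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def _gamete(
    parent: Individual,
    cfg: SimConfig,
    registry: MutationRegistry,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete: crossover at gene boundaries, free assortment
    between chromosomes, sorted by genomic position."""
    h1, h2 = parent.hap1, parent.hap2
    if h1.size == 0 and h2.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    if parent.pos1 is None:
        parent.cache_positions(registry)
    arch = cfg.architecture
    # crossover events: gene boundaries (prob p each) + chromosome junctions
    # (prob 1/2 each, which is free assortment)
    p = cfg.scaled_boundary_recomb
    n_boundaries = arch.n_internal_boundaries
    events: list[np.ndarray] = []
    if n_boundaries > 0 and p > 0:
        n_cross = rng.binomial(n_boundaries, p)
        if n_cross:
            b = rng.choice(n_boundaries, size=n_cross, replace=False)
            events.append(arch._boundary_pos[b])
    if arch.n_chromosomes > 1:
        flip = rng.random(arch.n_chromosomes - 1) < 0.5
        if flip.any():
            events.append(arch._junction_pos[flip])
    if events:
        cuts = np.sort(np.concatenate(events))
    else:
        cuts = np.empty(0, dtype=np.int64)
    start = int(rng.integers(0, 2))
    if cuts.size == 0:
        if start == 0:
            return h1.copy(), parent.pos1.copy()
        return h2.copy(), parent.pos2.copy()
    take1 = (np.searchsorted(cuts, parent.pos1, side="right") + start) % 2 == 0
    take2 = (np.searchsorted(cuts, parent.pos2, side="right") + start) % 2 == 1
    gam = np.concatenate([h1[take1], h2[take2]])
    pos = np.concatenate([parent.pos1[take1], parent.pos2[take2]])
    if gam.size > 1:
        order = np.argsort(pos, kind="stable")
        gam = gam[order]
        pos = pos[order]
    return gam, pos


def _add_new_mutations(
    gam: np.ndarray, gam_pos: np.ndarray, cfg: SimConfig,
    registry: MutationRegistry, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    u_genome = cfg.scaled_mutation_rate * cfg.architecture.genome_length
    k = rng.poisson(u_genome) if u_genome > 0 else 0
    if k == 0:
        return gam, gam_pos
    pos = rng.integers(0, cfg.architecture.genome_length, k)
    s, h = sample_mutation_effect(cfg.dfe, rng, size=k, rescale=cfg.rescale_factor)
    ids = registry.add(pos, s, h)
    out = np.concatenate([gam, ids])
    out_pos = np.concatenate([gam_pos, pos])
    order = np.argsort(out_pos, kind="stable")
    return out[order], out_pos[order]



def _breed(
    pairs: list[tuple[Individual, Individual]],
    cfg: SimConfig,
    registry: MutationRegistry,
    rng: np.random.Generator,
) -> list[Individual]:
    """Produce one offspring per parent pair, batching all random draws
    (crossovers, assortment, new mutations) across the brood."""
    n_off = len(pairs)
    if n_off == 0:
        return []
    G = 2 * n_off
    arch = cfg.architecture
    n_boundaries = arch.n_internal_boundaries
    p = cfg.scaled_boundary_recomb

    if n_boundaries > 0 and p > 0:
        bmask = rng.random((G, n_boundaries)) < p
        boundary_pos = arch._boundary_pos
    else:
        bmask = None
        boundary_pos = None
    if arch.n_chromosomes > 1:
        jmask = rng.random((G, arch.n_chromosomes - 1)) < 0.5
        junction_pos = arch._junction_pos
    else:
        jmask = None
        junction_pos = None
    starts = rng.integers(0, 2, G)

    u_genome = cfg.scaled_mutation_rate * arch.genome_length
    if u_genome > 0:
        ks = rng.poisson(u_genome, G)
        total = int(ks.sum())
        new_pos = rng.integers(0, arch.genome_length, total)
        s, h = sample_mutation_effect(cfg.dfe, rng, size=total,
                                      rescale=cfg.rescale_factor)
        new_ids = registry.add(new_pos, s, h)
        offsets = np.concatenate([[0], np.cumsum(ks)])
    else:
        ks = None

    gametes: list[tuple[np.ndarray, np.ndarray]] = []
    for g in range(G):
        parent = pairs[g // 2][g % 2]
        if parent.pos1 is None:
            parent.cache_positions(registry)
        cut_parts = []
        if bmask is not None and bmask[g].any():
            cut_parts.append(boundary_pos[bmask[g]])
        if jmask is not None and jmask[g].any():
            cut_parts.append(junction_pos[jmask[g]])
        start = int(starts[g])
        if not cut_parts:
            if start == 0:
                ids, pos = parent.hap1, parent.pos1
            else:
                ids, pos = parent.hap2, parent.pos2
            ids = ids.copy()
            pos = pos.copy()
        else:
            cuts = np.sort(np.concatenate(cut_parts)) if len(cut_parts) > 1 else np.sort(cut_parts[0])
            take1 = (np.searchsorted(cuts, parent.pos1, side="right") + start) % 2 == 0
            take2 = (np.searchsorted(cuts, parent.pos2, side="right") + start) % 2 == 1
            ids = np.concatenate([parent.hap1[take1], parent.hap2[take2]])
            pos = np.concatenate([parent.pos1[take1], parent.pos2[take2]])
            if ids.size > 1:
                order = np.argsort(pos, kind="stable")
                ids = ids[order]
                pos = pos[order]
        if ks is not None and ks[g]:
            lo, hi = offsets[g], offsets[g + 1]
            ids = np.concatenate([ids, new_ids[lo:hi]])
            pos = np.concatenate([pos, new_pos[lo:hi]])
            order = np.argsort(pos, kind="stable")
            ids = ids[order]
            pos = pos[order]
        gametes.append((ids, pos))

    offspring = []
    for i in range(n_off):
        (h1, p1), (h2, p2) = gametes[2 * i], gametes[2 * i + 1]
        offspring.append(Individual(h1, h2, age=0, pos1=p1, pos2=p2))
    return offspring


def _make_offspring(
    mother: Individual, father: Individual, cfg: SimConfig,
    registry: MutationRegistry, rng: np.random.Generator,
) -> Individual:
    hap1, pos1 = _add_new_mutations(
        *_gamete(mother, cfg, registry, rng), cfg, registry, rng
    )
    hap2, pos2 = _add_new_mutations(
        *_gamete(father, cfg, registry, rng), cfg, registry, rng
    )
    return Individual(hap1, hap2, age=0, pos1=pos1, pos2=pos2)


# ---------------------------------------------------------------------------
# One generation
# ---------------------------------------------------------------------------


def run_generation(
    state: SimState,
    cfg: SimConfig,
    k: int,
    catastrophes: bool = False,
) -> SimState:
    """Advance the population by one tick under carrying capacity ``k``.

    Order of events: reproduction by adults (age >= 1) in random pairs with
    Poisson litters; viability selection with survival min(1, w K / N);
    optional catastrophic mortality; ageing.  In Wright–Fisher mode the
    tick instead replaces the whole population with exactly ``k`` offspring
    of randomly drawn distinct parents (non-overlapping generations).
    """
    rng = state.rng
    registry = state.registry
    if state.extinct or not state.population:
        state.extinct = True
        return state

    if cfg.wright_fisher_mode:
        # non-overlapping generations, exactly k offspring; selection (when
        # present) acts through fitness-proportional parent sampling, the
        # classical fecundity-selection WF limit
        parents = state.population
        n = len(parents)
        if registry.any_selected:
            w = np.array([p.fitness for p in parents])
            probs = w / w.sum()
            ii = rng.choice(n, size=k, p=probs)
            jj = rng.choice(n, size=k, p=probs)
            clash = jj == ii
            while clash.any():
                jj[clash] = rng.choice(n, size=int(clash.sum()), p=probs)
                clash = jj == ii
        else:
            ii = rng.integers(0, n, k)
            jj = rng.integers(0, n - 1, k)
            jj = np.where(jj >= ii, jj + 1, jj)
        pairs = [(parents[int(a)], parents[int(b)]) for a, b in zip(ii, jj)]
        offspring = _breed(pairs, cfg, registry, rng)
        compute_w = registry.any_selected
        for ind in offspring:
            ind.age = 1
            if compute_w:
                ind.fitness = individual_fitness(
                    ind, registry, cfg.fitness_floor, state.fixed_log_fitness
                )
        state.population = offspring
        state.generation += 1
        return state

    # 1. reproduction
    adults = [i for i in state.population if i.age >= 1]
    offspring: list[Individual] = []
    if len(adults) >= 2:
        order = rng.permutation(len(adults))
        n_pairs = len(adults) // 2
        litters = rng.poisson(cfg.mean_litter, n_pairs)
        pairs = []
        for pi, (a, b) in enumerate(zip(order[0::2], order[1::2])):
            pairs.extend([(adults[a], adults[b])] * int(litters[pi]))
        offspring = _breed(pairs, cfg, registry, rng)
    for ind in offspring:
        ind.fitness = individual_fitness(
            ind, registry, cfg.fitness_floor, state.fixed_log_fitness
        )
    pool = state.population + offspring

    # 2. viability selection with density regulation
    n_total = len(pool)
    if n_total == 0:
        state.extinct = True
        return state
    w = np.array([i.fitness for i in pool])
    base = np.exp(state.fixed_log_fitness)
    # density regulation acts on fitness relative to the fixed baseline so a
    # drifting substitution load shifts mean fitness without collapsing N
    p_surv = np.minimum(1.0, (w / base) * (k / n_total))
    alive = rng.random(n_total) < p_surv

    # 3. catastrophe: one mortality draw applied i.i.d. per individual
    if catastrophes and cfg.catastrophe.enabled:
        m = draw_catastrophe(cfg.catastrophe, rng)
        alive &= rng.random(n_total) >= m

    survivors = [ind for ind, a in zip(pool, alive) if a]
    # 4. ageing
    for ind in survivors:
        ind.age += 1
    state.population = survivors
    state.generation += 1
    if len(survivors) == 0:
        state.extinct = True
    return state


def _prune_fixed(state: SimState, cfg: SimConfig) -> None:
    """Fold mutations fixed in every haplotype into the substitution
    baseline and drop them from all haplotypes (bookkeeping only)."""
    pop = state.population
    if not pop:
        return
    registry = state.registry
    counts = np.zeros(len(registry), dtype=np.int32)
    for ind in pop:
        np.add.at(counts, ind.hap1, 1)
        np.add.at(counts, ind.hap2, 1)
    fixed = np.flatnonzero(counts == 2 * len(pop))
    if fixed.size == 0:
        return
    fixed_set = np.zeros(len(registry), dtype=bool)
    fixed_set[fixed] = True
    s = registry.s[fixed]
    state.fixed_log_fitness += float(np.log1p(s[s != 0]).sum())
    for ind in pop:
        keep1 = ~fixed_set[ind.hap1]
        keep2 = ~fixed_set[ind.hap2]
        ind.hap1 = ind.hap1[keep1]
        ind.hap2 = ind.hap2[keep2]
        if ind.pos1 is not None:
            ind.pos1 = ind.pos1[keep1]
            ind.pos2 = ind.pos2[keep2]
        ind.fitness = individual_fitness(
            ind, registry, cfg.fitness_floor, state.fixed_log_fitness
        )




def state_to_genotype_table(state: SimState, chrom: str = "1"):
    """Export the population's segregating sites as a GenotypeTable.

    Positions are 1-based simulator coordinates; alt dosage counts copies
    of the mutation.  Sites where several distinct mutations share a
    position are skipped.  Useful for running the panel statistics (LD,
    Fst, ...) on simulated populations with real linkage.
    """
    import pandas as pd

    from .io import GenotypeTable

    pop = state.population
    registry = state.registry
    if not pop:
        raise ValueError("empty population")
    counts = np.zeros(len(registry), dtype=np.int32)
    for ind in pop:
        np.add.at(counts, ind.hap1, 1)
        np.add.at(counts, ind.hap2, 1)
    seg = np.flatnonzero((counts > 0) & (counts < 2 * len(pop)))
    pos = registry.positions[seg]
    # drop position collisions between distinct mutations
    uniq, first_idx, n_at = np.unique(pos, return_index=True, return_counts=True)
    keep = seg[first_idx[n_at == 1]]
    keep = keep[np.argsort(registry.positions[keep], kind="stable")]
    id_to_col = {int(m): j for j, m in enumerate(keep)}
    g = np.zeros((len(keep), len(pop)), dtype=np.int8)
    for j, ind in enumerate(pop):
        for hap in (ind.hap1, ind.hap2):
            for m in hap:
                col = id_to_col.get(int(m))
                if col is not None:
                    g[col, j] += 1
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": registry.positions[keep] + 1,
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeTable(sites, [f"ind{j}" for j in range(len(pop))], g)


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------


@dataclass
class SimOutput:
    """Per-tick records of one replicate's future projection.

    ``mean_fitness`` is absolute (including the fixed-substitution
    baseline); ``mean_fitness_seg`` divides that baseline out and tracks
    the segregating load only — the quantity genetic purging acts on and
    the one used for fitness-recovery detection.
    """

    generations: np.ndarray
    census: np.ndarray
    mean_fitness: np.ndarray
    mean_fitness_seg: np.ndarray
    mean_heterozygosity: np.ndarray
    inbreeding_index: np.ndarray       # F_t = 1 - H_t / H_0, F_0 = 0
    extinct: bool = False
    extinction_generation: int | None = None


def _record(state: SimState, cfg: SimConfig) -> tuple[int, float, float, float]:
    w = state.mean_fitness()
    base = float(np.exp(state.fixed_log_fitness))
    return (
        state.census,
        w,
        w / base if base > 0 else 0.0,
        state.mean_heterozygosity(cfg.architecture.genome_length),
    )


def run_projection(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    shared_start: SimState | None = None,
) -> SimOutput:
    """Burn-in at ancestral Ne, run the 100-generation historical
    trajectory, then project ``horizon`` generations at the scenario's
    carrying capacity, recording every ``report_interval`` ticks.

    ``shared_start`` lets several K scenarios branch from one burnt-in
    historical state (the replicate-pairing construction).
    """
    if cfg.trajectory is None or cfg.k_scenario is None:
        raise ValueError("projection needs a trajectory and a K scenario")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if shared_start is None:
        state = run_history(cfg, rng)
    else:
        state = shared_start
        state.rng = rng

    k_future = cfg.scaled(cfg.k_scenario.k)
    ticks = [0]
    records = [_record(state, cfg)]
    h0 = max(records[0][3], 1e-300)
    for t in range(1, cfg.horizon + 1):
        state = run_generation(state, cfg, k_future, catastrophes=True)
        if state.extinct:
            return _finalize(ticks, records, h0, extinct=True, ext_gen=t)
        if t % 10 == 0:
            _prune_fixed(state, cfg)
        if t % cfg.report_interval == 0:
            ticks.append(t)
            records.append(_record(state, cfg))
    return _finalize(ticks, records, h0)


def run_history(cfg: SimConfig, rng: np.random.Generator) -> SimState:
    """Burn-in at the trajectory's earliest Ne, then walk the historical
    per-generation Ne series up to the present."""
    state = _run_burn_in(cfg, rng)
    return _run_historical(state, cfg, rng)


def _run_burn_in(cfg: SimConfig, rng: np.random.Generator) -> SimState:
    traj = cfg.trajectory
    n_anc = cfg.scaled(traj.ne[0])
    burn = (
        cfg.burn_in_generations
        if cfg.burn_in_generations is not None
        else 8 * n_anc
    )
    state = init_population(cfg, n_anc, rng)
    for t in range(burn):
        state = run_generation(state, cfg, n_anc)
        if state.extinct:
            raise RuntimeError("population went extinct during burn-in")
        if t % 10 == 0:
            _prune_fixed(state, cfg)
    return state


def _run_historical(state: SimState, cfg: SimConfig, rng: np.random.Generator) -> SimState:
    state.rng = rng
    for ne in cfg.trajectory.ne[1:]:
        state = run_generation(state, cfg, cfg.scaled(ne))
        if state.extinct:
            raise RuntimeError("population went extinct during the historical trajectory")
    _prune_fixed(state, cfg)
    return state


def _finalize(ticks, records, h0, extinct=False, ext_gen=None) -> SimOutput:
    arr = np.array(records)
    het = arr[:, 3]
    return SimOutput(
        generations=np.array(ticks),
        census=arr[:, 0].astype(int),
        mean_fitness=arr[:, 1],
        mean_fitness_seg=arr[:, 2],
        mean_heterozygosity=het,
        inbreeding_index=1.0 - het / h0 if h0 > 0 else np.zeros_like(het),
        extinct=extinct,
        extinction_generation=ext_gen,
    )


def clone_state(state: SimState) -> SimState:
    """Deep-enough copy for branching scenarios from a shared history."""
    pop = [
        Individual(i.hap1.copy(), i.hap2.copy(), i.age, i.fitness)
        for i in state.population
    ]
    src = state.registry
    reg = MutationRegistry(capacity=max(1024, len(src)))
    reg.add(src.positions.copy(), src.s.copy(), src.h.copy())
    return SimState(pop, reg, state.generation, state.fixed_log_fitness,
                    state.extinct, state.rng)


# ---------------------------------------------------------------------------
# Replicates and reporting
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSummary:
    generations: np.ndarray
    mean: dict[str, np.ndarray]          # metric -> per-tick mean
    ci_low: dict[str, np.ndarray]
    ci_high: dict[str, np.ndarray]
    outputs: list[SimOutput]

    @property
    def n_replicates(self) -> int:
        return len(self.outputs)

    def extinction_probability(self) -> float:
        return float(np.mean([o.extinct for o in self.outputs]))


_METRICS = ("census", "mean_fitness", "mean_fitness_seg", "mean_heterozygosity", "inbreeding_index")


def summarize_replicates(outputs: Sequence[SimOutput]) -> ReplicateSummary:
    """Per-tick mean and normal-approximation 95% CI across replicates.

    Replicates that went extinct before the horizon are excluded from
    per-tick means (they have no trailing ticks) but count toward the
    extinction probability.
    """
    complete = [o for o in outputs if not o.extinct]
    if not complete:
        raise RuntimeError("all replicates went extinct; no trajectory to summarize")
    gens = complete[0].generations
    mean, lo, hi = {}, {}, {}
    for m in _METRICS:
        stack = np.vstack([getattr(o, m) for o in complete]).astype(float)
        mu = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(len(complete)) if len(complete) > 1 else np.zeros_like(mu)
        mean[m], lo[m], hi[m] = mu, mu - 1.96 * se, mu + 1.96 * se
    return ReplicateSummary(gens, mean, lo, hi, list(outputs))


def replicate_seeds(master_seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


def run_replicates(cfg: SimConfig) -> ReplicateSummary:
    """Run ``cfg.n_replicates`` independent projections with seeds derived
    from the master seed, and summarize."""
    if cfg.n_replicates < 1:
        raise ValueError("need at least one replicate")
    outputs = []
    for rng in replicate_seeds(cfg.seed, cfg.n_replicates):
        outputs.append(run_projection(cfg, rng=rng))
    return summarize_replicates(outputs)


def run_scenarios_paired(
    cfg: SimConfig,
    scenarios: Sequence[KScenario],
    share_burn_in: bool = False,
) -> dict[float, ReplicateSummary]:
    """Run several K scenarios branching from shared per-replicate
    histories (common burn-in and historical trajectory), so replicate i is
    directly comparable across scenarios.

    With ``share_burn_in`` a single long burn-in at the ancestral size is
    run once and every replicate branches from it through its own
    historical decline and future projections — replicates then share
    ancestral standing variation but diverge through the contraction, which
    is the relevant randomness for paired scenario contrasts.
    """
    results: dict[float, list[SimOutput]] = {s.fraction: [] for s in scenarios}
    burn_state = None
    if share_burn_in:
        burn_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
        burn_state = _run_burn_in(cfg, burn_rng)
    for rng in replicate_seeds(cfg.seed + 1, cfg.n_replicates):
        if burn_state is None:
            start = run_history(cfg, rng)
        else:
            start = _run_historical(clone_state(burn_state), cfg, rng)
        branch_seeds = rng.integers(0, 2**31 - 1, size=len(scenarios))
        for scen, bs in zip(scenarios, branch_seeds):
            sub = dataclasses.replace(cfg, k_scenario=scen)
            out = run_projection(
                sub,
                rng=np.random.default_rng(int(bs)),
                shared_start=clone_state(start),
            )
            results[scen.fraction].append(out)
    return {f: summarize_replicates(outs) for f, outs in results.items()}


# ---------------------------------------------------------------------------
# Comparison report
# ---------------------------------------------------------------------------


def fitness_recovery_generation(
    generations: np.ndarray, fitness: np.ndarray, dip_threshold: float = 0.01
) -> int:
    """Generation at which fitness recovers from its post-contraction dip.

    A trajectory "dips" at the first report tick where fitness falls more
    than ``dip_threshold`` below its projection-start value; it has
    "recovered" at the first tick at or after the dip from which the mean
    fitness over the remaining horizon is back at or above the start — a
    tail-mean criterion, so one noisy tick cannot declare recovery.
    Trajectories that never dip, or dip and never recover, are
    right-censored at one report interval past the horizon ("no recovery
    observed" sorts after every observed recovery).
    """
    fitness = np.asarray(fitness, dtype=float)
    w0 = fitness[0]
    step = int(generations[-1] - generations[-2]) if len(generations) > 1 else 1
    censored = int(generations[-1]) + step
    below = np.flatnonzero(fitness < w0 * (1 - dip_threshold))
    if below.size == 0:
        return censored
    for t in range(max(int(below[0]), 1), len(fitness)):
        if fitness[t:].mean() >= w0:
            return int(generations[t])
    return censored


def projection_report(
    summaries: dict[str, ReplicateSummary],
) -> "pd.DataFrame":
    """Per-scenario comparison: extinction probability, mean-fitness
    recovery tick, heterozygosity decline % and inbreeding increase over the
    projection (percent-change arithmetic on the replicate means)."""
    import pandas as pd

    from .demography import percent_change

    rows = []
    for label, s in summaries.items():
        w = s.mean["mean_fitness_seg"]
        het = s.mean["mean_heterozygosity"]
        f = s.mean["inbreeding_index"]
        rec = fitness_recovery_generation(s.generations, w)
        het_decline = percent_change(het[0], het[-1], "decline") if het[0] > 0 else np.nan
        rows.append(
            {
                "scenario": label,
                "extinction_probability": s.extinction_probability(),
                "fitness_recovery_generation": rec,
                "het_decline_pct": het_decline,
                "final_inbreeding_index": f[-1],
                "final_mean_fitness": w[-1],
            }
        )
    return pd.DataFrame(rows)
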