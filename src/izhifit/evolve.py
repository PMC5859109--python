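"""Generational evolutionary algorithm over bounded model genomes.

A genome is a flat float vector: the compartment parameters (9 for a
single compartment; 8 per compartment plus one shared resting potential
for chains), the coupling genes (G, P) per link, and one stimulation
current per target trace.  The current genes search a narrow window
around the experimentally injected current when it is known, which keeps
phenotypes comparable across trials, and an open 50-800 pA window
otherwise.

The algorithm is non-overlapping and elitist: each generation the
lowest-error tenth survives unchanged and the remainder is refilled by
binary-tournament selection, two-point crossover and a mixed mutation
operator (integer random walk for the integer-natured genes d, C, G and
I; uniform reset within bounds for the rest).  Everything is driven by a
single seeded NumPy generator, so (seed, config, target) fully
determines a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import CompartmentParams, CouplingLink, MCModel, SimConfig
from .objective import MAX_ERROR, ErrorBreakdown, TargetSpec, evaluate_model

__all__ = [
    "Gene",
    "GenomeLayout",
    "EAConfig",
    "RunRecord",
    "DEFAULT_BOUNDS",
    "single_compartment_layout",
    "symmetric_pair_layout",
    "chain_layout",
    "init_population",
    "select_parent",
    "crossover_two_point",
    "mutate",
    "step_generation",
    "run_trial",
    "run_trials",
]

# generous per-parameter search ranges bracketing all packaged reference
# optima; class-specific presets may narrow them
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "k": (0.2, 6.5),
    "a": (0.0005, 0.15),
    "b": (-35.0, 95.0),
    "d": (-20.0, 120.0),
    "C": (20.0, 2000.0),
    "Vr": (-80.0, -50.0),
    "Vt": (-65.0, -5.0),
    "Vpeak": (0.0, 90.0),
    "Vmin": (-70.0, -35.0),
    "G": (0.0, 200.0),
    "P": (0.01, 0.99),
}

INTEGER_WALK_PARAMS = ("d", "C", "G", "I")  # mutated by +-1 random walk

I_UNKNOWN_BOUNDS = (50.0, 800.0)
I_WINDOW = 10.0  # pA around a known experimental current


class DecodeError(ValueError):
    """The genome does not decode to a valid model."""


@dataclass(frozen=True)
class Gene:
    name: str
    lo: float
    hi: float
    integer_walk: bool = False

    def __post_init__(self):
        if not self.lo <= self.hi:
            raise ValueError(f"empty bounds for gene {self.name!r}")


@dataclass(frozen=True)
class GenomeLayout:
    """Gene order, bounds and the decode map to (MCModel, currents)."""

    genes: Tuple[Gene, ...]
    compartment_names: Tuple[str, ...]
    soma: str
    n_traces: int
    kind: str  # "single" | "symmetric_pair" | "chain"

    @property
    def length(self) -> int:
        return len(self.genes)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[g.lo, g.hi] for g in self.genes])

    def index(self, name: str) -> int:
        for i, g in enumerate(self.genes):
            if g.name == name:
                return i
        raise KeyError(name)

    def current_genes(self) -> List[int]:
        return [i for i, g in enumerate(self.genes) if g.name.startswith("I_")]

    def decode(self, genome: np.ndarray) -> Tuple[MCModel, np.ndarray]:
        genome = np.asarray(genome, dtype=np.float64)
        if genome.shape != (self.length,):
            raise DecodeError(f"genome length {genome.size} != {self.length}")
        g = {gene.name: float(v) for gene, v in zip(self.genes, genome)}
        currents = np.array([g[f"I_{i}"] for i in range(self.n_traces)])
        try:
            if self.kind == "single":
                p = CompartmentParams(**{n: g[n] for n in
                                         ("k", "a", "b", "d", "C", "Vr", "Vt",
                                          "Vpeak", "Vmin")})
                return MCModel.single(p, name=self.soma), currents
            if self.kind == "symmetric_pair":
                p = CompartmentParams(**{n: g[n] for n in
                                         ("k", "a", "b", "d", "C", "Vr", "Vt",
                                          "Vpeak", "Vmin")})
                model = MCModel(
                    compartments=((self.compartment_names[0], p),
                                  (self.compartment_names[1], p)),
                    links=(CouplingLink(self.compartment_names[0],
                                        self.compartment_names[1], g["G"], 0.5),),
                    soma=self.soma)
                return model, currents
            # chain
            comps = []
            for name in self.compartment_names:
                comps.append((name, CompartmentParams(
                    Vr=g["Vr"], **{f: g[f"{f}_{name}"] for f in
                                   ("k", "a", "b", "d", "C", "Vt", "Vpeak", "Vmin")})))
            links = []
            for prox, dist in zip(self.compartment_names[:-1],
                                  self.compartment_names[1:]):
                links.append(CouplingLink(prox, dist, g[f"G_{dist}"], g[f"P_{dist}"]))
            return MCModel(compartments=tuple(comps), links=tuple(links),
                           soma=self.soma), currents
        except ValueError as e:
            raise DecodeError(str(e)) from e


def _current_genes(I_exp: Sequence[Optional[float]]) -> List[Gene]:
    genes = []
    for i, I in enumerate(I_exp):
        if I is None:
            lo, hi = I_UNKNOWN_BOUNDS
        else:
            lo, hi = I - I_WINDOW, I + I_WINDOW
        genes.append(Gene(f"I_{i}", lo, hi, integer_walk=True))
    return genes


def _param_genes(bounds: Dict[str, Tuple[float, float]], suffix: str = "",
                 names=("k", "a", "b", "d", "C", "Vr", "Vt", "Vpeak", "Vmin")):
    return [Gene(n + suffix, *bounds[n], integer_walk=n in INTEGER_WALK_PARAMS)
            for n in names]


def single_compartment_layout(I_exp: Sequence[Optional[float]],
                              bounds: Optional[dict] = None,
                              soma: str = "soma") -> GenomeLayout:
    """9 + n_I genes: the nine model parameters plus one current per trace."""
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    genes = _param_genes(b) + _current_genes(I_exp)
    return GenomeLayout(tuple(genes), (soma,), soma, len(I_exp), "single")


def symmetric_pair_layout(I_exp: Sequence[Optional[float]],
                          bounds: Optional[dict] = None) -> GenomeLayout:
    """Two identical compartments with symmetric coupling (P = 0.5): the
    nine shared parameters, the coupling conductance G, and the currents."""
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    genes = _param_genes(b) + [Gene("G", *b["G"], integer_walk=True)]
    genes += _current_genes(I_exp)
    return GenomeLayout(tuple(genes), ("c1", "c2"), "c1", len(I_exp),
                        "symmetric_pair")


def chain_layout(compartment_names: Sequence[str], soma: str,
                 I_exp: Sequence[Optional[float]],
                 bounds: Optional[dict] = None) -> GenomeLayout:
    """8c + 1 + 2(c-1) + n_I genes for a compartment chain with shared Vr."""
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    names = tuple(compartment_names)
    if soma not in names:
        raise ValueError(f"soma {soma!r} not in chain {names}")
    genes = [Gene("Vr", *b["Vr"])]
    for name in names:
        genes += _param_genes(b, suffix=f"_{name}",
                              names=("k", "a", "b", "d", "C", "Vt", "Vpeak", "Vmin"))
    for dist in names[1:]:
        genes.append(Gene(f"G_{dist}", *b["G"], integer_walk=True))
        genes.append(Gene(f"P_{dist}", *b["P"]))
    genes += _current_genes(I_exp)
    return GenomeLayout(tuple(genes), names, soma, len(I_exp), "chain")


@dataclass(frozen=True)
class EAConfig:
    """Evolutionary settings (population presets: 120 single-compartment,
    400 multi-compartment, 800 for hard fast-spiking searches)."""

    population: int = 120
    generations: int = 500
    elite_fraction: float = 0.10
    tournament: int = 2
    p_mutation: float = 0.2
    seed: int = 0
    sim: SimConfig = field(default_factory=lambda: SimConfig(dt=0.1, duration=1100.0,
                                                             method="euler"))
    final_sim: Optional[SimConfig] = field(
        default_factory=lambda: SimConfig(dt=0.05, duration=1100.0, method="rk4"))
    record_every: int = 1

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must hold at least 2 individuals")
        if not 0 < self.elite_fraction < 1:
            raise ValueError("elite fraction must lie in (0, 1)")
        if not 0 <= self.p_mutation <= 1:
            raise ValueError("mutation probability must lie in [0, 1]")


@dataclass
class RunRecord:
    """One EA trial: per-generation error statistics and the final best."""

    seed: int
    best_error: List[float] = field(default_factory=list)
    mean_error: List[float] = field(default_factory=list)
    median_error: List[float] = field(default_factory=list)
    best_genome: Optional[np.ndarray] = None
    best_breakdown: Optional[ErrorBreakdown] = None
    accepted: bool = False

    @property
    def final_error(self) -> float:
        return self.best_error[-1] if self.best_error else math.inf

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "generations": len(self.best_error),
            "final_error": self.final_error,
            "accepted": self.accepted,
            "best_genome": None if self.best_genome is None
            else [float(v) for v in self.best_genome],
        }


def init_population(layout: GenomeLayout, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform sampling within each gene's bounds; integer-walk genes are
    rounded to integers (and stay within bounds)."""
    b = layout.bounds
    pop = rng.uniform(b[:, 0], b[:, 1], size=(size, layout.length))
    for i, gene in enumerate(layout.genes):
        if gene.integer_walk:
            pop[:, i] = np.clip(np.round(pop[:, i]), gene.lo, gene.hi)
    return pop


def select_parent(population: np.ndarray, errors: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Binary tournament without replacement; ties broken uniformly."""
    n = population.shape[0]
    if n == 1:
        return population[0]
    i, j = rng.choice(n, size=2, replace=False)
    if errors[i] < errors[j]:
        return population[i]
    if errors[j] < errors[i]:
        return population[j]
    return population[i if rng.random() < 0.5 else j]


def crossover_two_point(parent_a: np.ndarray, parent_b: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Child = parent_a with the segment [p1, p2) replaced from parent_b,
    cut points drawn on gene boundaries with 0 <= p1 <= p2 <= length."""
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must share one genome layout")
    L = parent_a.size
    p1, p2 = sorted(rng.integers(0, L + 1, size=2))
    child = parent_a.copy()
    child[p1:p2] = parent_b[p1:p2]
    return child


def mutate(genome: np.ndarray, layout: GenomeLayout, p_mut: float,
           rng: np.random.Generator) -> np.ndarray:
    """Independent per-gene mutation: +-1 integer random walk for the
    integer-natured genes, uniform reset within bounds for the rest."""
    out = genome.copy()
    hits = rng.random(layout.length) < p_mut
    for i in np.nonzero(hits)[0]:
        gene = layout.genes[i]
        if gene.integer_walk:
            step = 1.0 if rng.random() < 0.5 else -1.0
            out[i] = min(max(out[i] + step, gene.lo), gene.hi)
        else:
            out[i] = rng.uniform(gene.lo, gene.hi)
    return out


def step_generation(population: np.ndarray, errors: np.ndarray,
                    layout: GenomeLayout, config: EAConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Elitist generational replacement: the lowest-error ceil(10%)
    survive unchanged, the rest are tournament/crossover/mutation
    offspring.  Population size is preserved."""
    n = population.shape[0]
    n_elite = math.ceil(config.elite_fraction * n)
    order = np.argsort(errors, kind="stable")
    nxt = np.empty_like(population)
    nxt[:n_elite] = population[order[:n_elite]]
    for i in range(n_elite, n):
        pa = select_parent(population, errors, rng)
        pb = select_parent(population, errors, rng)
        nxt[i] = mutate(crossover_two_point(pa, pb, rng), layout,
                        config.p_mutation, rng)
    return nxt


def _evaluate(genome: np.ndarray, layout: GenomeLayout, spec: TargetSpec,
              config: EAConfig) -> ErrorBreakdown:
    try:
        model, currents = layout.decode(genome)
    except DecodeError as e:
        bd = ErrorBreakdown(accepted=False, diagnostic=str(e))
        bd.trace_terms.append({"decode": MAX_ERROR})
        return bd
    return evaluate_model(model, currents, spec, sim_config=config.sim)


def run_trial(spec: TargetSpec, layout: GenomeLayout, config: EAConfig,
              seed: int,
              evaluate: Optional[Callable[[np.ndarray], ErrorBreakdown]] = None
              ) -> RunRecord:
    """One seeded EA run; returns the per-generation record and final best."""
    rng = np.random.default_rng(seed)
    custom_eval = evaluate is not None
    evaluate = evaluate or (lambda g: _evaluate(g, layout, spec, config))
    pop = init_population(layout, config.population, rng)
    rec = RunRecord(seed=seed)
    best_err = math.inf
    best_genome = None
    best_bd = None
    for gen in range(config.generations):
        breakdowns = [evaluate(g) for g in pop]
        errors = np.array([bd.total for bd in breakdowns])
        i_best = int(np.argmin(errors))
        if errors[i_best] < best_err:
            best_err = float(errors[i_best])
            best_genome = pop[i_best].copy()
            best_bd = breakdowns[i_best]
        rec.best_error.append(best_err)
        rec.mean_error.append(float(np.mean(errors)))
        rec.median_error.append(float(np.median(errors)))
        if gen < config.generations - 1:
            pop = step_generation(pop, errors, layout, config, rng)
    if config.final_sim is not None and best_genome is not None and not custom_eval:
        # the search integrates fast; the reported best is re-selected
        # from the final population under the accurate integrator
        candidates = [best_genome] + [g for g in pop]
        rescored = [(g, _evaluate(g, layout, spec,
                                  replace(config, sim=config.final_sim)))
                    for g in candidates]
        best_genome, best_bd = min(rescored, key=lambda t: t[1].total)
        best_err = best_bd.total
        rec.best_error[-1] = best_err
    rec.best_genome = best_genome
    rec.best_breakdown = best_bd
    rec.accepted = bool(best_bd is not None and best_bd.accepted)
    return rec


def run_trials(spec: TargetSpec, layout: GenomeLayout, config: EAConfig,
               n_trials: int, seed: Optional[int] = None) -> List[RunRecord]:
    """Independent seeded trials (a reduced-scale counterpart of running
    many EA instances per neuron type); rejected trials are kept in the
    output with accepted=False."""
    base = config.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(base).generate_state(n_trials) % (2 ** 31)
    return [run_trial(spec, layout, config, int(s)) for s in child_seeds]
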