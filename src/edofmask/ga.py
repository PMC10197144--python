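"""Elitist ("queen bee") genetic algorithm for binary pupil-mask design.

Each candidate is a three-trait vector (axicon strength, defocus
displacement in um, spherical aberration in waves).  A candidate is scored
by composing and binarizing its phase, simulating the slice-wise 3D
intensity of an on-axis neuron-sized source through the masked, aberrated
pupil with scattering decay, and counting the depths whose signal stays
above half the stack maximum:

    cost = -(# on-depths inside z_target) + alpha * (# on-depths outside)

Lower is better; a perfect design keeps the signal above half maximum over
every target depth and nowhere else.  Generations evolve through three
subpopulations: elite children (exact copies of the best candidates),
crossover children (per-trait mixes of two tournament winners) and mutation
children (tournament children whose traits are re-drawn uniformly from the
bounds with a fixed per-trait probability).  Elitism makes the best cost
monotone non-increasing across generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as scipy_fft

from .doe import BasisCoefficients, binarize_phase, compose_continuous_phase, mask_transmission
from .optics import AberrationModel, OpticalConfig, grin_aberration, make_pupil_grid
from .psf import (
    IntensityStack,
    SourceObject,
    centered_fft2,
    centered_ifft2,
    on_axis_profile,
)
from .optics import defocus_phase

__all__ = [
    "FitnessSpec",
    "GAConfig",
    "OptimizationResult",
    "fitness",
    "evaluate_candidate",
    "next_generation",
    "run_ga",
    "DesignProblem",
]

DEFAULT_BOUNDS = {
    "axicon": (0.0, 5.0),
    "defocus_um": (-300.0, 300.0),
    "spherical_waves": (-60.0, 60.0),
}


@dataclass(frozen=True)
class FitnessSpec:
    """Target depth interval and penalty weights of the cost function.

    ``z_target`` is a closed interval (um, in the simulated z coordinate)
    that the design should keep above ``threshold * Imax``; depths outside
    it that stay above threshold are penalized with weight ``alpha``.
    ``mode`` selects whether the half-max test is applied to the per-depth
    signal profile (default) or to every voxel of each slice.
    """

    z_target: tuple[float, float] = (-180.0, -100.0)
    threshold: float = 0.5
    alpha: float = 4.0
    mode: str = "profile"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.z_target[1] <= self.z_target[0]:
            raise ValueError("z_target must be a non-degenerate interval")
        if self.mode not in ("profile", "voxel"):
            raise ValueError("mode must be 'profile' or 'voxel'")


@dataclass(frozen=True)
class GAConfig:
    """Population-evolution hyperparameters."""

    generations: int = 10
    population: int = 60
    elite_fraction: float = 0.20
    tournament_size: int = 4
    mutation_rate: float = 0.10
    crossover_fraction: float = 0.4
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.elite_fraction < 1.0):
            raise ValueError("elite_fraction must lie in (0, 1)")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        for name in ("mutation_rate", "crossover_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.population < 2 or self.generations < 1:
            raise ValueError("need population >= 2 and generations >= 1")
        for key, (lo, hi) in self.bounds.items():
            if hi <= lo:
                raise ValueError(f"degenerate bounds for {key}")
        n_elite = self.n_elite
        if n_elite >= self.population:
            raise ValueError("elite subpopulation swallows the whole population")

    @property
    def n_elite(self) -> int:
        return int(round(self.elite_fraction * self.population))

    @property
    def n_crossover(self) -> int:
        return int(math.floor(self.crossover_fraction * (self.population - self.n_elite)))

    @property
    def n_mutation(self) -> int:
        return self.population - self.n_elite - self.n_crossover

    def bounds_array(self) -> np.ndarray:
        return np.array(
            [
                self.bounds["axicon"],
                self.bounds["defocus_um"],
                self.bounds["spherical_waves"],
            ]
        )


@dataclass
class OptimizationResult:
    best_coefficients: BasisCoefficients
    best_fitness: float
    fitness_history: list[dict]
    seed: int
    evaluations: int

    def to_dict(self) -> dict:
        return {
            "best_coefficients": {
                "axicon": self.best_coefficients.axicon,
                "defocus_um": self.best_coefficients.defocus_um,
                "spherical_waves": self.best_coefficients.spherical_waves,
            },
            "best_fitness": self.best_fitness,
            "fitness_history": self.fitness_history,
            "seed": self.seed,
            "evaluations": self.evaluations,
        }


def _profile_cost(profile: np.ndarray, z: np.ndarray, spec: FitnessSpec) -> float:
    imax = float(profile.max())
    if imax <= 0:
        raise ValueError("all-zero stack: fitness undefined")
    on = profile >= spec.threshold * imax
    inside = (z >= spec.z_target[0]) & (z <= spec.z_target[1])
    return float(-np.sum(on & inside) + spec.alpha * np.sum(on & ~inside))


def fitness(stack: IntensityStack, spec: FitnessSpec) -> float:
    """Eq.-style coverage cost of a simulated stack (lower is better)."""
    z = np.asarray(stack.z_coords)
    if spec.mode == "voxel":
        imax = float(stack.data.max())
        if imax <= 0:
            raise ValueError("all-zero stack: fitness undefined")
        on = stack.data >= spec.threshold * imax
        inside = (z >= spec.z_target[0]) & (z <= spec.z_target[1])
        n_in = float(on[inside].sum())
        n_out = float(on[~inside].sum())
        return -n_in + spec.alpha * n_out
    return _profile_cost(on_axis_profile(stack), z, spec)


class DesignProblem:
    """Precomputed forward-model context shared by every GA evaluation.

    The source spectrum, native aberration, NA aperture and the per-depth
    defocus kernels do not depend on the candidate, so they are computed
    once; evaluating a candidate then costs one pupil multiply and one
    batched inverse FFT per depth.  Everything is kept in the *unshifted*
    FFT layout: the per-slice maximum is invariant to the lattice origin,
    so the fitness loop never pays for fftshifts.  Costs are memoized per
    coefficient vector (evaluation is a pure function), which spares the
    elite candidates from being re-simulated every generation.
    """

    def __init__(
        self,
        config: OpticalConfig,
        aberration: AberrationModel | np.ndarray,
        source: SourceObject,
        ls: float,
        spec: FitnessSpec,
        dtype=np.complex64,
    ) -> None:
        self.config = config
        self.spec = spec
        self.ls = float(ls)
        self.grid = make_pupil_grid(config)
        if isinstance(aberration, AberrationModel):
            ab_phase = grin_aberration(aberration, self.grid)
        else:
            ab_phase = np.asarray(aberration)
        self.depths = config.depths()
        spectrum = centered_fft2(source.amplitude.astype(dtype))
        base = spectrum * np.exp(1j * ab_phase) * self.grid.aperture
        self.base_pupil = np.fft.ifftshift(base).astype(dtype)
        self.defocus_kernels = np.stack(
            [
                np.fft.ifftshift(
                    np.exp(1j * defocus_phase(self.grid, z, config))
                ).astype(dtype)
                for z in self.depths
            ]
        )
        if np.isinf(self.ls):
            self.decay = np.ones_like(self.depths)
        else:
            self.decay = np.exp(-(self.depths - self.depths.min()) / self.ls)
        self.evaluations = 0
        self._cache: dict[tuple[float, float, float], float] = {}

    def signal_profile(self, pupil_field: np.ndarray) -> np.ndarray:
        """Per-depth maximum intensity for an arbitrary candidate pupil.

        ``pupil_field`` is given in the centered layout (like the masks).
        """
        pupil = self.base_pupil * np.fft.ifftshift(np.asarray(pupil_field))
        n = pupil.shape[0]
        nz = len(self.depths)
        profile = np.empty(nz)
        batch = max(1, int(2**25 // (n * n)))
        for start in range(0, nz, batch):
            fields = scipy_fft.ifft2(
                pupil[None, :, :] * self.defocus_kernels[start : start + batch],
                norm="ortho",
                axes=(-2, -1),
            )
            intens = fields.real**2 + fields.imag**2
            profile[start : start + len(intens)] = intens.reshape(
                len(intens), -1
            ).max(axis=1)
        return profile * self.decay

    def cost(self, coeffs: BasisCoefficients) -> float:
        key = (coeffs.axicon, coeffs.defocus_um, coeffs.spherical_waves)
        if key in self._cache:
            return self._cache[key]
        phase = compose_continuous_phase(coeffs, self.grid, self.config)
        mask = binarize_phase(phase, provenance=coeffs)
        profile = self.signal_profile(mask_transmission(mask))
        self.evaluations += 1
        value = _profile_cost(profile, self.depths, self.spec)
        self._cache[key] = value
        return value


def evaluate_candidate(
    coeffs: BasisCoefficients,
    spec: FitnessSpec,
    config: OpticalConfig,
    aberration: AberrationModel | np.ndarray,
    source: SourceObject,
    ls: float,
    problem: DesignProblem | None = None,
) -> float:
    """Compose -> binarize -> simulate -> score one candidate (pure function)."""
    if problem is None:
        problem = DesignProblem(config, aberration, source, ls, spec)
    return problem.cost(coeffs)


def _tournament_parents(
    costs: np.ndarray, ga: GAConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Pick ``tournament_size`` distinct candidates; return the two best."""
    contenders = rng.choice(len(costs), size=ga.tournament_size, replace=False)
    order = contenders[np.argsort(costs[contenders], kind="stable")]
    return int(order[0]), int(order[1])


def _crossover_child(
    population: np.ndarray, costs: np.ndarray, ga: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    i, j = _tournament_parents(costs, ga, rng)
    pick = rng.integers(0, 2, size=population.shape[1])
    return np.where(pick == 0, population[i], population[j])


def next_generation(
    population: np.ndarray,
    costs: np.ndarray,
    ga: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one generation: elite copies, crossover and mutation children."""
    population = np.asarray(population, dtype=float)
    costs = np.asarray(costs, dtype=float)
    if len(population) != ga.population or len(costs) != ga.population:
        raise ValueError("population/costs size must match GAConfig.population")

    order = np.argsort(costs, kind="stable")  # ties: earlier index wins
    children = [population[order[: ga.n_elite]].copy()]
    bounds = ga.bounds_array()
    for _ in range(ga.n_crossover):
        children.append(_crossover_child(population, costs, ga, rng)[None, :])
    for _ in range(ga.n_mutation):
        child = _crossover_child(population, costs, ga, rng)
        mutate = rng.random(population.shape[1]) < ga.mutation_rate
        fresh = rng.uniform(bounds[:, 0], bounds[:, 1])
        children.append(np.where(mutate, fresh, child)[None, :])
    return np.vstack(children)


def run_ga(
    ga: GAConfig,
    spec: FitnessSpec,
    config: OpticalConfig,
    aberration: AberrationModel | np.ndarray,
    source: SourceObject,
    ls: float,
    progress: bool = False,
) -> OptimizationResult:
    """Full optimization loop; fully reproducible from ``ga.seed``."""
    rng = np.random.default_rng(ga.seed)
    problem = DesignProblem(config, aberration, source, ls, spec)
    bounds = ga.bounds_array()
    population = rng.uniform(
        bounds[:, 0], bounds[:, 1], size=(ga.population, len(bounds))
    )

    history: list[dict] = []
    best_cost = np.inf
    best = population[0]
    for gen in range(ga.generations):
        if gen > 0:
            population = next_generation(population, costs, ga, rng)
        costs = np.array(
            [problem.cost(BasisCoefficients.from_array(c)) for c in population]
        )
        idx = int(np.argmin(costs))
        if costs[idx] < best_cost:
            best_cost = float(costs[idx])
            best = population[idx].copy()
        history.append(
            {
                "generation": gen,
                "best_cost": float(costs.min()),
                "mean_cost": float(costs.mean()),
            }
        )
        if progress:
            print(
                f"[seed {ga.seed}] generation {gen}: best {costs.min():.1f} "
                f"mean {costs.mean():.1f}"
            )
    return OptimizationResult(
        best_coefficients=BasisCoefficients.from_array(best),
        best_fitness=best_cost,
        fitness_history=history,
        seed=ga.seed,
        evaluations=problem.evaluations,
    )
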