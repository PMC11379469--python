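"""Synthetic data generation for benchmarking the deconvolution model.

All test inputs are generated here: synthetic reference atlases with
entity-specific marker blocks, cfDNA mixtures with Dirichlet-sampled
proportions and binomial count noise, mixtures spiked with an unknown
contributor of random methylation pattern, and tumor-fraction dilution
series at shallow (6X-like) depth.

The generative model per mixture cell: the expected methylation ratio
is ``r_ik = (A @ true_ratios)_ik``; the total CpG count ``D_ik`` is
Poisson around a per-region mean depth (optionally heteroscedastic via
log-normal per-region depth multipliers, to emulate mappability and
capture-efficiency differences across the genome); the methylated
count is ``M_ik ~ Binomial(D_ik, r_ik)``. Everything is deterministic
given a seed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .io_formats import CountAtlas, MixtureCounts, Region, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageModel",
    "SimulationSpec",
    "DilutionSpec",
    "DEFAULT_FRACTION_GRID",
    "make_synthetic_atlas",
    "perturb_ratios",
    "sample_proportions",
    "synthesize_mixture_counts",
    "inject_unknown",
    "simulate_mixtures",
    "make_dilution_series",
]

#: Tumor-fraction grid (percent) for dilution series: 12 values from
#: 50% down to 0.1%.
DEFAULT_FRACTION_GRID: tuple[float, ...] = (
    50.0, 25.0, 12.5, 10.0, 7.5, 5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.1,
)


@dataclasses.dataclass
class CoverageModel:
    """Per-region sequencing depth model.

    mean_depth
        Expected CpG count per region (Poisson mean).
    het_sigma
        Standard deviation of log-normal per-region depth multipliers;
        0 gives homoscedastic coverage. A sigma of ~1.2 yields well
        over 10x spread between low- and high-coverage regions.
    """

    mean_depth: float = 100.0
    het_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        if self.het_sigma < 0:
            raise ValidationError("het_sigma must be >= 0")

    def region_depths(self, n_regions: int, rng: np.random.Generator) -> np.ndarray:
        """Expected depth per region (drawn once, shared by all samples)."""
        base = np.full(n_regions, float(self.mean_depth))
        if self.het_sigma > 0:
            mult = rng.lognormal(mean=-0.5 * self.het_sigma**2, sigma=self.het_sigma, size=n_regions)
            base = base * mult
        return base


@dataclasses.dataclass
class SimulationSpec:
    """Parameters of a Dirichlet/binomial mixture simulation."""

    n_samples: int = 100
    n_entities: int = 13
    n_regions: int = 500
    dirichlet_alpha: float | Sequence[float] = 1.0
    coverage: CoverageModel = dataclasses.field(default_factory=CoverageModel)
    unknown_range: tuple[float, float] | None = None  # proportion range of an injected unknown
    bias_sigma: float = 0.0  # additive Gaussian bias on mixing profiles
    seed: int = 0

    def __post_init__(self) -> None:
        alphas = np.atleast_1d(np.asarray(self.dirichlet_alpha, dtype=float))
        if (alphas <= 0).any():
            raise ValidationError("dirichlet_alpha must be > 0")
        if self.unknown_range is not None:
            lo, hi = self.unknown_range
            if not (0 < lo <= hi < 1):
                raise ValidationError("unknown proportion range must lie in (0, 1)")


@dataclasses.dataclass
class DilutionSpec:
    """Parameters of a tumor-fraction dilution series."""

    tumor_entity: str
    fractions: tuple[float, ...] = DEFAULT_FRACTION_GRID
    replicates: int = 10
    mean_depth: float = 6.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for f in self.fractions:
            if not 0 < f <= 100:
                raise ValidationError(f"fraction {f} outside (0, 100]")


def make_synthetic_atlas(
    n_entities: int,
    n_regions: int,
    seed: int = 0,
    mean_depth: float = 100.0,
    hi: float = 0.9,
    lo: float = 0.1,
    noiseless: bool = False,
    entity_names: Sequence[str] | None = None,
) -> tuple[CountAtlas, np.ndarray]:
    """Generate a block-structured atlas and its noise-free ratios.

    The first ``n_entities * b`` regions are entity-specific
    (round-robin ownership; ratio ``hi`` for the owner, ``lo`` for
    everyone else), the remainder are shared background regions with a
    common random ratio. With ``noiseless=True`` counts are taken at a
    fixed depth with methylated counts rounded from the exact ratios;
    otherwise depths are Poisson and methylated counts binomial.
    Returns the atlas and the true entity x region ratio matrix.
    """
    if n_regions < n_entities:
        raise ValidationError("need at least one region per entity")
    rng = np.random.default_rng(seed)
    if entity_names is None:
        entity_names = [f"entity_{j:02d}" for j in range(n_entities)]

    n_specific = max(n_entities, int(round(n_regions * 0.6)) // n_entities * n_entities)
    n_specific = min(n_specific, n_regions)
    ratios = np.empty((n_entities, n_regions))
    for k in range(n_specific):
        owner = k % n_entities
        ratios[:, k] = lo
        ratios[owner, k] = hi
    background = rng.uniform(0.2, 0.8, size=n_regions - n_specific)
    ratios[:, n_specific:] = background[None, :]

    if noiseless:
        D = np.full((n_entities, n_regions), int(round(mean_depth)), dtype=np.int64)
        M = np.rint(ratios * D).astype(np.int64)
    else:
        D = rng.poisson(mean_depth, size=(n_entities, n_regions)).astype(np.int64)
        M = rng.binomial(D, ratios).astype(np.int64)

    regions = [Region("chr1", 1000 * k, 1000 * k + 500) for k in range(n_regions)]
    atlas = CountAtlas(entities=list(entity_names), regions=regions, D=D, M=M)
    return atlas, ratios


def perturb_ratios(
    true_ratios: np.ndarray,
    bias_sigma: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Additive-Gaussian bias on entity ratio profiles, clipped to [0,1].

    Emulates systematic deviation between the atlas profiles and the
    profiles actually shed into the mixtures (purity, chemistry or
    cohort differences). A stand-in for whatever bias structure real
    references carry; the perturbation is i.i.d. per cell.
    """
    if bias_sigma < 0:
        raise ValidationError("bias_sigma must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if bias_sigma == 0:
        return np.asarray(true_ratios, dtype=float).copy()
    noisy = np.asarray(true_ratios, dtype=float) + rng.normal(0.0, bias_sigma, size=np.shape(true_ratios))
    return np.clip(noisy, 0.0, 1.0)


def sample_proportions(
    n_samples: int,
    n_entities: int,
    alpha: float | Sequence[float] = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw mixture proportions from a Dirichlet distribution."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    alphas = np.broadcast_to(np.atleast_1d(np.asarray(alpha, dtype=float)), (n_entities,))
    if (alphas <= 0).any():
        raise ValidationError("dirichlet alpha must be > 0")
    return rng.dirichlet(alphas, size=n_samples)


def synthesize_mixture_counts(
    A: np.ndarray,
    true_ratios: np.ndarray,
    coverage: CoverageModel | np.ndarray,
    rng: np.random.Generator | int | None = None,
    regions: Sequence[Region] | None = None,
    sample_names: Sequence[str] | None = None,
) -> MixtureCounts:
    """Draw noisy mixture counts for given proportions and profiles.

    ``coverage`` is either a :class:`CoverageModel` or a precomputed
    per-region expected-depth vector.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    A = np.asarray(A, dtype=float)
    true_ratios = np.asarray(true_ratios, dtype=float)
    n_samples, n_regions = A.shape[0], true_ratios.shape[1]
    r = A @ true_ratios
    if (r < -1e-9).any() or (r > 1 + 1e-9).any():
        logger.warning("expected ratios outside [0,1] by numeric error; clipping")
    r = np.clip(r, 0.0, 1.0)
    if isinstance(coverage, CoverageModel):
        depths = coverage.region_depths(n_regions, rng)
    else:
        depths = np.asarray(coverage, dtype=float)
    D = rng.poisson(np.broadcast_to(depths, (n_samples, n_regions))).astype(np.int64)
    M = rng.binomial(D, r).astype(np.int64)
    if regions is None:
        regions = [Region("chr1", 1000 * k, 1000 * k + 500) for k in range(n_regions)]
    if sample_names is None:
        sample_names = [f"sample_{i:04d}" for i in range(n_samples)]
    return MixtureCounts(samples=list(sample_names), regions=list(regions), D=D, M=M)


def inject_unknown(
    A_known: np.ndarray,
    true_ratios: np.ndarray,
    proportion_range: tuple[float, float],
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add an unknown contributor with a random methylation pattern.

    Per sample, an unknown proportion is drawn uniformly from
    ``proportion_range``; the known proportions are scaled down so the
    extended rows still sum to 1. The unknown's per-region ratios are
    Uniform(0, 1). Returns ``(A_extended, ratios_extended, profile)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = proportion_range
    if not (0 <= lo <= hi < 1):
        raise ValidationError("unknown proportion range must lie in [0, 1)")
    A_known = np.asarray(A_known, dtype=float)
    true_ratios = np.asarray(true_ratios, dtype=float)
    p = rng.uniform(lo, hi, size=A_known.shape[0])
    A_ext = np.hstack([A_known * (1.0 - p)[:, None], p[:, None]])
    profile = rng.uniform(0.0, 1.0, size=true_ratios.shape[1])
    ratios_ext = np.vstack([true_ratios, profile[None, :]])
    return A_ext, ratios_ext, profile


def simulate_mixtures(
    spec: SimulationSpec,
    true_ratios: np.ndarray | None = None,
) -> tuple[MixtureCounts, np.ndarray, CountAtlas | None, np.ndarray | None]:
    """One-call simulation: atlas (optional), truth and noisy mixtures.

    If ``true_ratios`` is None a synthetic atlas is generated from the
    spec's seed. Returns ``(mixture, true_A, atlas_or_None,
    unknown_profile_or_None)``; ``true_A`` includes the unknown column
    when one is injected.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = None
    if true_ratios is None:
        atlas, true_ratios = make_synthetic_atlas(
            spec.n_entities, spec.n_regions,
            seed=int(rng.integers(2**31)),
            mean_depth=spec.coverage.mean_depth,
        )
    if spec.bias_sigma > 0:
        true_ratios = perturb_ratios(true_ratios, spec.bias_sigma, rng)
    A = sample_proportions(spec.n_samples, true_ratios.shape[0], spec.dirichlet_alpha, rng)
    profile = None
    if spec.unknown_range is not None:
        A, true_ratios, profile = inject_unknown(A, true_ratios, spec.unknown_range, rng)
    mixture = synthesize_mixture_counts(A, true_ratios, spec.coverage, rng)
    return mixture, A, atlas, profile


def make_dilution_series(
    spec: DilutionSpec,
    true_ratios: np.ndarray,
    entity_names: Sequence[str],
    background: np.ndarray,
    rng: np.random.Generator | int | None = None,
    regions: Sequence[Region] | None = None,
) -> tuple[MixtureCounts, "np.ndarray", "np.ndarray"]:
    """Spike a tumor profile into a healthy background at known fractions.

    For each fraction f (percent) and replicate, the mixture ratio is
    ``(f/100) * tumor + (1 - f/100) * background`` and counts are
    drawn at ``mean_depth`` (default 6, emulating shallow
    whole-genome methylation sequencing). Returns the mixtures plus
    parallel arrays of the spiked fraction and replicate index per
    sample.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if spec.tumor_entity not in entity_names:
        raise ValidationError(f"tumor entity {spec.tumor_entity!r} not in atlas")
    ti = list(entity_names).index(spec.tumor_entity)
    tumor = np.asarray(true_ratios, dtype=float)[ti]
    background = np.asarray(background, dtype=float)
    n_regions = tumor.shape[0]

    rows_r = []
    fracs = []
    reps = []
    names = []
    for f in spec.fractions:
        for rep in range(spec.replicates):
            rows_r.append((f / 100.0) * tumor + (1.0 - f / 100.0) * background)
            fracs.append(f)
            reps.append(rep)
            names.append(f"{spec.tumor_entity}_f{f:g}_r{rep}")
    r = np.clip(np.vstack(rows_r), 0.0, 1.0)
    D = rng.poisson(spec.mean_depth, size=r.shape).astype(np.int64)
    M = rng.binomial(D, r).astype(np.int64)
    if regions is None:
        regions = [Region("chr1", 1000 * k, 1000 * k + 500) for k in range(n_regions)]
    mix = MixtureCounts(samples=names, regions=list(regions), D=D, M=M)
    return mix, np.asarray(fracs), np.asarray(reps)
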