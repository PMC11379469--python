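"""Coverage-weighted deconvolution of cfDNA methylation profiles.

The mixture model: each cfDNA sample i is a convex combination of
reference entities, so its per-region methylation ratio vector is
approximately ``(A G)_i``, where the rows of A live on the probability
simplex (one proportion per entity, plus ``h`` optional unknown
contributors) and G holds per-entity, per-region methylation ratios.
A and G are estimated jointly by minimizing a coverage-weighted mean
absolute error

    L(A, G) = sum_ik  w_ik |R_ik - (A G)_ik|
            + lambda * sum_jk  v_jk |G_jk - Ratlas_jk|

where w_ik is the sample's CpG count at region k normalized per
sample (regions with no coverage get weight 0 and drop out of the
fit), and the second term tethers the learned atlas G to the observed
atlas ratios with per-row-normalized atlas-coverage weights v; rows of
G that model unknown contributors carry no tether. A is initialized
from a non-negative least squares (NNLS) fit and G from the atlas
ratios; unknown rows are seeded from coverage-weighted NNLS residuals.

Optimization uses Adam on unconstrained parameters: A is a row-wise
softmax and G an elementwise logistic of free variables, so every
iterate satisfies the simplex and [0,1] box constraints exactly. The
weighted-MAE objective is piecewise linear; its subgradient (sign of
the residual) is used wherever the absolute value is not
differentiable. The best-loss iterate is returned, so the final
objective never exceeds the objective at initialization.

After fitting, entity identities are re-established by maximum-weight
bipartite matching between rows of G and rows of the atlas ratio
matrix under Pearson similarity; G rows left unmatched are labeled
``unknown_1 ... unknown_h``.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import optimize

from .io_formats import CountAtlas, MixtureCounts, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionConfig",
    "RatioMatrix",
    "DeconvolutionResult",
    "compute_ratios",
    "compute_weights",
    "nnls_deconvolve",
    "estimate_unknowns",
    "fit",
    "reidentify_entities",
    "deconvolve",
]


@dataclasses.dataclass
class DeconvolutionConfig:
    """Hyperparameters of the joint A/G fit.

    n_unknowns
        Number of contributors absent from the atlas to model
        (default 0).
    max_iters, learning_rate, tolerance, patience
        Adam budget and early-stopping rule: stop once the objective
        has improved by less than ``tolerance`` over the last
        ``patience`` iterations.
    atlas_tether
        Weight (lambda) of the L1 penalty pulling known rows of G
        toward the observed atlas ratios; 0 lets G float freely.
    weighting
        "coverage" uses per-sample coverage-proportional weights;
        "uniform" weights every covered region equally (ablation).
    """

    n_unknowns: int = 0
    max_iters: int = 5000
    learning_rate: float = 0.01
    tolerance: float = 1e-6
    patience: int = 100
    atlas_tether: float = 1.0
    seed: int = 0
    similarity: str = "pearson"
    weighting: str = "coverage"

    def __post_init__(self) -> None:
        if self.n_unknowns < 0:
            raise ValidationError("n_unknowns must be >= 0")
        if self.max_iters < 1 or self.learning_rate <= 0 or self.tolerance <= 0:
            raise ValidationError("invalid optimizer settings")
        if self.atlas_tether < 0:
            raise ValidationError("atlas_tether must be >= 0")
        if self.similarity != "pearson":
            raise ValidationError(f"unsupported similarity {self.similarity!r}")
        if self.weighting not in ("coverage", "uniform"):
            raise ValidationError(f"unsupported weighting {self.weighting!r}")


@dataclasses.dataclass
class RatioMatrix:
    """Methylation ratios with a mask for zero-coverage cells."""

    values: np.ndarray
    mask: np.ndarray  # True where total count was 0 (ratio undefined)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError("values/mask shape mismatch")


@dataclasses.dataclass
class DeconvolutionResult:
    """Estimated proportions, refined atlas and bookkeeping."""

    samples: list[str]
    column_labels: list[str]  # per G-row label: atlas entity or unknown_i
    proportions: np.ndarray  # samples x (entities + h)
    G: np.ndarray  # (entities + h) x regions, refined ratios
    identity_map: dict[int, str]  # G-row index -> label
    loss_trace: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            lab: self.proportions[:, j] for j, lab in enumerate(self.column_labels)
        }


def compute_ratios(D: np.ndarray, M: np.ndarray) -> RatioMatrix:
    """Elementwise M/D with zero-coverage cells masked."""
    D = np.asarray(D)
    M = np.asarray(M)
    if (M > D).any():
        i, k = np.argwhere(M > D)[0]
        raise ValidationError(f"meth > total at cell ({i}, {k})")
    mask = D == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(mask, 0.0, M / np.where(mask, 1, D))
    return RatioMatrix(values=R, mask=mask)


def compute_weights(
    D_cfdna: np.ndarray, sample_names: Sequence[str] | None = None
) -> np.ndarray:
    """Per-sample coverage weights, proportional to CpG counts.

    Each row is normalized to sum to 1; zero-coverage regions get
    weight 0 so masked markers contribute nothing to the objective.
    """
    D = np.asarray(D_cfdna, dtype=float)
    row_sums = D.sum(axis=1)
    if (row_sums == 0).any():
        i = int(np.nonzero(row_sums == 0)[0][0])
        name = sample_names[i] if sample_names is not None else f"#{i}"
        raise ValidationError(f"sample {name} has zero coverage in every region")
    return D / row_sums[:, None]


def uniform_weights(D_cfdna: np.ndarray) -> np.ndarray:
    """Equal weight on every covered region (coverage-weighting ablation)."""
    D = np.asarray(D_cfdna, dtype=float)
    covered = (D > 0).astype(float)
    n = covered.sum(axis=1)
    if (n == 0).any():
        i = int(np.nonzero(n == 0)[0][0])
        raise ValidationError(f"sample #{i} has zero coverage in every region")
    return covered / n[:, None]


def nnls_deconvolve(R_cfdna: RatioMatrix, R_atlas: np.ndarray) -> np.ndarray:
    """Per-sample NNLS estimate of proportions, renormalized to the simplex.

    Masked cfDNA cells are excluded from each sample's fit. An
    all-zero NNLS solution is replaced by uniform proportions.
    """
    R_atlas = np.asarray(R_atlas, dtype=float)
    n_samples = R_cfdna.values.shape[0]
    n_entities = R_atlas.shape[0]
    if R_atlas.shape[1] < n_entities:
        logger.warning(
            "under-determined NNLS: %d regions < %d entities",
            R_atlas.shape[1], n_entities,
        )
    A0 = np.empty((n_samples, n_entities))
    for i in range(n_samples):
        use = ~R_cfdna.mask[i]
        if not use.any():
            raise ValidationError(f"sample #{i} has no covered region")
        a, _ = optimize.nnls(R_atlas[:, use].T, R_cfdna.values[i, use])
        s = a.sum()
        A0[i] = a / s if s > 0 else np.full(n_entities, 1.0 / n_entities)
    return A0


def _impute_atlas_ratios(R_atlas: RatioMatrix) -> np.ndarray:
    """Fill zero-coverage atlas cells with the region's cross-entity mean.

    Used for initialization only; tether weights are 0 at imputed
    cells so the fill never constrains the fit.
    """
    R = R_atlas.values.copy()
    if R_atlas.mask.any():
        covered = ~R_atlas.mask
        with np.errstate(invalid="ignore"):
            col_mean = np.where(
                covered.sum(axis=0) > 0,
                (R * covered).sum(axis=0) / np.maximum(covered.sum(axis=0), 1),
                0.5,
            )
        R[R_atlas.mask] = np.broadcast_to(col_mean, R.shape)[R_atlas.mask]
    return R


def estimate_unknowns(
    R_cfdna: RatioMatrix,
    W: np.ndarray,
    D_atlas: np.ndarray,
    M_atlas: np.ndarray,
    R_atlas: np.ndarray,
    h: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed ``h`` unknown-contributor rows from NNLS residuals.

    Each round deconvolves the samples against the current atlas by
    NNLS, then forms the unknown's ratio profile per region as the
    coverage-weighted mean (over samples) of the reconstruction plus
    the coverage-weighted mean residual, clipped to [0, 1]. The
    appended row gets pseudo-counts at the per-region median atlas
    depth so downstream ratio computations stay well-defined; the
    refined-atlas tether never applies to unknown rows. Returns the
    extended (D_atlas, M_atlas, R_atlas).
    """
    if h == 0:
        return D_atlas, M_atlas, R_atlas
    D_ext = np.asarray(D_atlas, dtype=np.int64).copy()
    M_ext = np.asarray(M_atlas, dtype=np.int64).copy()
    R_ext = np.asarray(R_atlas, dtype=float).copy()
    omega = np.where(R_cfdna.mask, 0.0, W)
    for _ in range(h):
        A0 = nnls_deconvolve(R_cfdna, R_ext)
        recon = A0 @ R_ext
        resid = np.where(R_cfdna.mask, 0.0, R_cfdna.values - recon)
        wsum = omega.sum(axis=0)
        safe = np.maximum(wsum, 1e-300)
        u = (omega * recon).sum(axis=0) / safe + (omega * resid).sum(axis=0) / safe
        # regions no sample covers: fall back to the atlas column mean
        u = np.where(wsum > 0, u, R_ext.mean(axis=0))
        u = np.clip(u, 0.0, 1.0)
        d_new = np.median(D_ext, axis=0).astype(np.int64)
        m_new = np.rint(u * d_new).astype(np.int64)
        D_ext = np.vstack([D_ext, d_new[None, :]])
        M_ext = np.vstack([M_ext, m_new[None, :]])
        R_ext = np.vstack([R_ext, u[None, :]])
    return D_ext, M_ext, R_ext


def _softmax_rows(P: np.ndarray) -> np.ndarray:
    Z = P - P.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _sigmoid(Q: np.ndarray) -> np.ndarray:
    out = np.empty_like(Q)
    pos = Q >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-Q[pos]))
    e = np.exp(Q[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def fit(
    R_cfdna: RatioMatrix,
    W: np.ndarray,
    R_atlas: np.ndarray,
    D_atlas: np.ndarray,
    config: DeconvolutionConfig,
    n_known: int | None = None,
    tether_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jointly optimize proportions A and refined atlas G by Adam.

    ``R_atlas`` (rows = known entities followed by any unknown seed
    rows) provides both the initialization of G and the tether target.
    ``n_known`` marks how many leading rows are true atlas entities;
    rows past it (the unknowns) carry no tether. ``tether_mask``
    optionally zeroes the tether at specific (row, region) cells, used
    for zero-coverage atlas cells whose ratios were imputed.

    Returns ``(A, G, loss_trace)`` for the best-loss iterate.
    """
    R = np.where(R_cfdna.mask, 0.0, R_cfdna.values)
    W = np.asarray(W, dtype=float)
    w = np.where(R_cfdna.mask, 0.0, W)
    R_target = np.asarray(R_atlas, dtype=float)
    n_rows, n_regions = R_target.shape
    if n_known is None:
        n_known = n_rows

    # atlas-coverage tether weights, normalized per known row
    v = np.zeros((n_rows, n_regions))
    Dat = np.asarray(D_atlas, dtype=float)
    for j in range(n_known):
        row = Dat[j].copy()
        if tether_mask is not None:
            row = np.where(tether_mask[j], 0.0, row)
        s = row.sum()
        if s > 0:
            v[j] = row / s
    lam = config.atlas_tether

    # unconstrained parameterization: A = softmax(P) rows, G = sigmoid(Q)
    A0 = nnls_deconvolve(R_cfdna, R_target)
    P = np.log(np.clip(A0, 1e-8, None))
    G0 = np.clip(R_target, 1e-6, 1.0 - 1e-6)
    Q = np.log(G0) - np.log1p(-G0)

    lr = config.learning_rate
    b1, b2, eps = 0.9, 0.999, 1e-8
    mP = np.zeros_like(P); vP = np.zeros_like(P)
    mQ = np.zeros_like(Q); vQ = np.zeros_like(Q)

    best_loss = np.inf
    best_P, best_Q = P.copy(), Q.copy()
    trace: list[float] = []

    for it in range(config.max_iters):
        A = _softmax_rows(P)
        G = _sigmoid(Q)
        E = A @ G - R
        S = w * np.sign(E)
        loss = float((w * np.abs(E)).sum() + lam * (v * np.abs(G - R_target)).sum())
        if not np.isfinite(loss):
            raise ValidationError(f"non-finite loss at iteration {it}")
        trace.append(loss)
        if loss < best_loss:
            best_loss = loss
            best_P, best_Q = P.copy(), Q.copy()
        if it >= config.patience and trace[it - config.patience] - trace[it] < config.tolerance:
            break

        gA = S @ G.T
        gG = A.T @ S + lam * v * np.sign(G - R_target)
        # chain rule through row-softmax and elementwise sigmoid
        gP = A * (gA - (gA * A).sum(axis=1, keepdims=True))
        gQ = gG * G * (1.0 - G)

        t = it + 1
        mP = b1 * mP + (1 - b1) * gP; vP = b2 * vP + (1 - b2) * gP**2
        mQ = b1 * mQ + (1 - b1) * gQ; vQ = b2 * vQ + (1 - b2) * gQ**2
        P = P - lr * (mP / (1 - b1**t)) / (np.sqrt(vP / (1 - b2**t)) + eps)
        Q = Q - lr * (mQ / (1 - b1**t)) / (np.sqrt(vQ / (1 - b2**t)) + eps)

    A = _softmax_rows(best_P)
    G = _sigmoid(best_Q)
    return A, G, np.asarray(trace)


def reidentify_entities(
    G: np.ndarray, R_atlas_known: np.ndarray, entity_names: Sequence[str]
) -> dict[int, str]:
    """Match G rows back to atlas entities by Pearson similarity.

    Solves a maximum-similarity one-to-one assignment (Hungarian
    algorithm) between rows of G and the known atlas rows; constant
    rows get similarity 0. Unmatched G rows are labeled
    ``unknown_1 ... unknown_h`` in row order.
    """
    G = np.asarray(G, dtype=float)
    Rk = np.asarray(R_atlas_known, dtype=float)
    if G.shape[0] < Rk.shape[0]:
        raise ValidationError("G must have at least as many rows as the known atlas")
    sim = np.zeros((G.shape[0], Rk.shape[0]))
    for a in range(G.shape[0]):
        ga = G[a] - G[a].mean()
        na = np.sqrt((ga**2).sum())
        for b in range(Rk.shape[0]):
            rb = Rk[b] - Rk[b].mean()
            nb = np.sqrt((rb**2).sum())
            if na == 0 or nb == 0:
                sim[a, b] = 0.0
            else:
                sim[a, b] = float((ga * rb).sum() / (na * nb))
    rows, cols = optimize.linear_sum_assignment(-sim)
    identity: dict[int, str] = {int(r): entity_names[int(c)] for r, c in zip(rows, cols)}
    u = 0
    for a in range(G.shape[0]):
        if a not in identity:
            u += 1
            identity[a] = f"unknown_{u}"
    return identity


def deconvolve(
    mixture: MixtureCounts,
    atlas: CountAtlas,
    config: DeconvolutionConfig | None = None,
) -> DeconvolutionResult:
    """Full pipeline: ratios -> weights -> unknowns -> fit -> re-identify.

    The mixture and atlas must list the same regions in the same
    order. Deterministic given the inputs and config.
    """
    if config is None:
        config = DeconvolutionConfig()
    if len(mixture.regions) != len(atlas.regions):
        raise ValidationError(
            f"region count mismatch: mixture has {len(mixture.regions)}, "
            f"atlas has {len(atlas.regions)}"
        )
    for k, (rm, ra) in enumerate(zip(mixture.regions, atlas.regions)):
        if tuple(rm) != tuple(ra):
            raise ValidationError(
                f"region mismatch at index {k}: mixture {tuple(rm)} vs atlas {tuple(ra)}"
            )

    R_cf = compute_ratios(mixture.D, mixture.M)
    R_at_raw = compute_ratios(atlas.D, atlas.M)
    R_at = _impute_atlas_ratios(R_at_raw)
    if config.weighting == "coverage":
        W = compute_weights(mixture.D, mixture.samples)
    else:
        W = uniform_weights(mixture.D)

    n_known = atlas.n_entities
    D_ext, M_ext, R_ext = estimate_unknowns(
        R_cf, W, atlas.D, atlas.M, R_at, config.n_unknowns
    )
    tether_mask = np.zeros_like(R_ext, dtype=bool)
    tether_mask[:n_known] = R_at_raw.mask

    A, G, trace = fit(
        R_cf, W, R_ext, D_ext, config, n_known=n_known, tether_mask=tether_mask
    )
    identity = reidentify_entities(G, R_at, atlas.entities)
    labels = [identity[j] for j in range(G.shape[0])]
    return DeconvolutionResult(
        samples=list(mixture.samples),
        column_labels=labels,
        proportions=A,
        G=G,
        identity_map=identity,
        loss_trace=trace,
    )
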