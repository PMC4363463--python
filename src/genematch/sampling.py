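"""Kernel-density-ratio sampling weights and matched replicate gene sets.

Weights are the ratio of a kernel density estimate fit on the target set's
covariates to one fit on the whole universe, evaluated at every universe
gene, floored and normalized. Replicate sets are drawn without replacement
with the exponential-keys scheme, which reproduces sequential weighted
draws exactly and splits cleanly across seeds.

The kernels are Gaussian; the default bandwidth in every dimension is the
normal-reference rule ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``. Evaluation is
an exact kernel sum at the query points (no grid interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .universe import GeneSet, GeneUniverse

_SQRT_2PI = np.sqrt(2.0 * np.pi)

#: Raw density ratios below this are floored so every pool gene stays drawable.
RATIO_FLOOR = 1e-12

#: Sampling modes and the universe covariates they match on.
MODE_COVARIATES = {
    "expression": ("log_expr",),
    "cds_length": ("cds_len_log2",),
    "both_2d": ("cds_len_log2", "log_expr"),
}


def nrd_bandwidth(values: np.ndarray) -> float:
    """Normal-reference bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("bandwidth selection needs >= 2 values")
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * n ** (-1.0 / 5.0)
    if bw <= 0:
        raise ValueError("bandwidth is zero: all values identical")
    return bw


@dataclass(frozen=True)
class DensityEstimate:
    """Gaussian-kernel density estimate with exact evaluation.

    ``data`` has shape (n, d); ``bandwidths`` has length d. ``evaluate``
    accepts an (m, d) array (or a length-m vector when d == 1) and returns m
    non-negative density values.
    """

    data: np.ndarray
    bandwidths: tuple[float, ...]

    @property
    def dimensionality(self) -> int:
        return self.data.shape[1]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if self.dimensionality == 1 and pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim == 1:
            pts = pts[None, :]
        if pts.shape[1] != self.dimensionality:
            raise ValueError(f"expected {self.dimensionality}-d points, got shape {pts.shape}")
        h = np.asarray(self.bandwidths)
        out = np.empty(pts.shape[0])
        # chunked so the (m, n) kernel matrix stays small
        step = max(1, int(2**22 // max(1, self.data.shape[0])))
        for start in range(0, pts.shape[0], step):
            block = pts[start : start + step]  # (b, d)
            z = (block[:, None, :] - self.data[None, :, :]) / h  # (b, n, d)
            kern = np.exp(-0.5 * np.sum(z * z, axis=2)) / np.prod(h * _SQRT_2PI)
            out[start : start + step] = kern.mean(axis=1)
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points)


def kde_1d(values: Sequence[float], bandwidth: float | None = None) -> DensityEstimate:
    """Univariate Gaussian KDE with exact kernel-sum evaluation."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("kde_1d needs a flat array of >= 2 values")
    if np.unique(arr).size < 2:
        raise ValueError("kde_1d needs >= 2 distinct values (bandwidth would be 0)")
    bw = float(bandwidth) if bandwidth is not None else nrd_bandwidth(arr)
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    return DensityEstimate(data=arr[:, None], bandwidths=(bw,))


def kde_2d(
    x: Sequence[float],
    y: Sequence[float],
    bandwidths: tuple[float, float] | None = None,
) -> DensityEstimate:
    """Bivariate product-Gaussian KDE with exact evaluation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise ValueError("kde_2d needs two equal-length flat arrays of >= 2 points")
    if bandwidths is None:
        bandwidths = (nrd_bandwidth(xa), nrd_bandwidth(ya))
    hx, hy = (float(b) for b in bandwidths)
    if hx <= 0 or hy <= 0:
        raise ValueError("degenerate (zero-variance) dimension: bandwidth must be > 0")
    return DensityEstimate(data=np.column_stack([xa, ya]), bandwidths=(hx, hy))


@dataclass(frozen=True)
class WeightVector:
    """Per-gene sampling probabilities aligned to a universe.

    ``raw_ratio`` is the floored target/universe density ratio before
    normalization; ``probability`` sums to 1. ``bandwidths`` records the KDE
    smoothing actually used so runs are reproducible and overridable.
    """

    symbols: tuple[str, ...]
    raw_ratio: np.ndarray
    probability: np.ndarray
    mode: str
    bandwidths: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.probability
        if len(self.symbols) != p.shape[0] or self.raw_ratio.shape[0] != p.shape[0]:
            raise ValueError("weight vector arrays must align with symbols")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite and >= 0")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")

    def __len__(self) -> int:
        return len(self.symbols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"symbol": self.symbols, "raw_ratio": self.raw_ratio, "probability": self.probability}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class SamplingPlan:
    """Replicate-sampling request: mode, sizes, optional exclusion, seed."""

    mode: str
    n_per_set: int
    n_replicates: int
    exclude: GeneSet | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODE_COVARIATES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {sorted(MODE_COVARIATES)}")
        if self.n_per_set < 1 or self.n_replicates < 1:
            raise ValueError("n_per_set and n_replicates must be >= 1")


def _mode_matrix(universe: GeneUniverse, mode: str) -> np.ndarray:
    cols = [universe.covariate(c) for c in MODE_COVARIATES[mode]]
    return np.column_stack(cols)


def density_ratio_weights(
    universe: GeneUniverse,
    target: GeneSet,
    mode: str = "expression",
    bandwidths: tuple[float, ...] | None = None,
) -> WeightVector:
    """Density-ratio sampling weights matching the target's covariate density.

    For each universe gene g, the raw weight is f_target(x_g) / f_universe(x_g)
    with both densities estimated by Gaussian KDE on the mode's covariate(s);
    ratios are floored at :data:`RATIO_FLOOR` and normalized to sum 1.
    """
    if mode not in MODE_COVARIATES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(MODE_COVARIATES)}")
    X = _mode_matrix(universe, mode)
    member_idx = [i for i, r in enumerate(universe) if r.symbol in target.symbols]
    if len(member_idx) < 2:
        raise ValueError(
            f"target {target.name!r} has {len(member_idx)} members in the universe; need >= 2"
        )
    Xt = X[member_idx]

    if X.shape[1] == 1:
        f_t = kde_1d(Xt[:, 0], None if bandwidths is None else bandwidths[0])
        f_u = kde_1d(X[:, 0], None if bandwidths is None else bandwidths[0])
    else:
        f_t = kde_2d(Xt[:, 0], Xt[:, 1], bandwidths)
        f_u = kde_2d(X[:, 0], X[:, 1], bandwidths)

    dens_t = f_t.evaluate(X)
    dens_u = f_u.evaluate(X)
    raw = np.maximum(dens_t / dens_u, RATIO_FLOOR)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite density ratio encountered")
    prob = raw / raw.sum()
    return WeightVector(
        symbols=universe.symbols,
        raw_ratio=raw,
        probability=prob,
        mode=mode,
        bandwidths={"target": f_t.bandwidths, "universe": f_u.bandwidths},
    )


def _as_seed_sequence(seed: int | np.random.SeedSequence) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def replicate_seed(seed: int, replicate: int) -> np.random.SeedSequence:
    """Splittable per-replicate seed: replicates reproduce in any order."""
    return np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))


def _pool_mask(weights: WeightVector, exclude: GeneSet | None) -> np.ndarray:
    mask = weights.probability > 0
    if exclude is not None:
        excluded = np.fromiter(
            (s in exclude.symbols for s in weights.symbols), dtype=bool, count=len(weights)
        )
        mask &= ~excluded
    return mask


def sample_matched_set(
    universe: GeneUniverse,
    weights: WeightVector,
    n: int,
    exclude: GeneSet | None = None,
    seed: int | np.random.SeedSequence = 0,
    name: str = "sampled",
) -> GeneSet:
    """Draw ``n`` distinct genes, weighted, without replacement.

    Uses exponential keys: gene i gets key e_i / w_i with e_i ~ Exp(1); the n
    smallest keys win. Equivalent to sequential draws proportional to the
    remaining weights. Excluded genes keep their weight but leave the pool
    ("same probabilities" exclusion semantics).
    """
    if tuple(universe.symbols) != weights.symbols:
        raise ValueError("weight vector is not aligned to this universe")
    mask = _pool_mask(weights, exclude)
    pool_size = int(mask.sum())
    if n > pool_size:
        raise ValueError(
            f"requested {n} genes but the pool holds only {pool_size} "
            f"(universe {len(universe)}, excluded/zero-weight {len(universe) - pool_size})"
        )
    rng = np.random.default_rng(_as_seed_sequence(seed))
    keys = np.full(len(weights), np.inf)
    keys[mask] = rng.exponential(size=pool_size) / weights.probability[mask]
    chosen = np.argpartition(keys, n - 1)[:n]
    return GeneSet.from_symbols(name, (universe[i].symbol for i in sorted(chosen)))


def sample_replicates(
    universe: GeneUniverse,
    weights: WeightVector,
    plan: SamplingPlan,
) -> list[GeneSet]:
    """Draw ``plan.n_replicates`` independent matched sets from fixed weights.

    Replicate r uses the splittable seed :func:`replicate_seed`\\ (plan.seed, r);
    weights are not recomputed between replicates.
    """
    return [
        sample_matched_set(
            universe,
            weights,
            plan.n_per_set,
            exclude=plan.exclude,
            seed=replicate_seed(plan.seed, r),
            name=f"{plan.mode}_rep{r:04d}",
        )
        for r in range(plan.n_replicates)
    ]


def top_weighted_set(
    universe: GeneUniverse,
    weights: WeightVector,
    n: int,
    exclude: GeneSet | None = None,
    name: str = "top_weighted",
) -> GeneSet:
    """Deterministic set: the n pool genes with the highest sampling weight."""
    mask = _pool_mask(weights, exclude)
    if n > int(mask.sum()):
        raise ValueError(f"requested {n} genes but the pool holds only {int(mask.sum())}")
    score = np.where(mask, weights.probability, -np.inf)
    order = np.argsort(-score, kind="stable")[:n]
    return GeneSet.from_symbols(name, (universe[i].symbol for i in sorted(order)))


def write_replicates_tsv(replicates: Sequence[GeneSet], path: str | Path) -> None:
    """Long-format TSV (replicate_id, symbol), one row per sampled gene."""
    rows = [
        {"replicate_id": i, "symbol": s}
        for i, rep in enumerate(replicates)
        for s in sorted(rep.symbols)
    ]
    pd.DataFrame(rows, columns=["replicate_id", "symbol"]).to_csv(path, sep="\t", index=False)
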