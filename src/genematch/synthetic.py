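"""Synthetic gene universes with known covariance structure and planted sets.

The generator mirrors the structure the analysis assumes: right-skewed
expression (Gaussian on the log2 scale), log2 transcript length correlated
with expression through a Gaussian copula, coding-sequence length as a
logit-normal fraction of transcript length (so cds <= tx always), CLIP tag
counts from a log-linear model of the three covariates, and target/candidate
membership drawn with logistic covariate bias. Every quantity needed to
check the downstream fits in closed form is recoverable from the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .universe import GeneRecord, GeneSet, GeneUniverse


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the synthetic universe generator.

    ``beta`` is (intercept, b_expr, b_cds, b_tx) for the log2 CLIP-count
    model. ``target_bias`` / ``candidate_bias`` are logistic coefficients
    (intercept, on standardized log-expression, standardized cds length,
    standardized tx length) for membership probability.
    """

    n_genes: int = 5000
    expr_mean: float = 5.0
    expr_sd: float = 2.0
    len_mean: float = 11.0
    len_sd: float = 1.2
    rho_expr_len: float = 0.3
    cds_frac_logit_mean: float = -0.5
    cds_frac_logit_sd: float = 0.5
    beta: tuple[float, float, float, float] = (-9.0, 1.0, 0.5, 0.3)
    noise_sd: float = 1.5
    target_size: int = 500
    target_bias: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    candidate_size: int = 300
    candidate_bias: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        for name in ("expr_sd", "len_sd", "cds_frac_logit_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (-1.0 < self.rho_expr_len < 1.0):
            raise ValueError("rho_expr_len must be strictly inside (-1, 1)")
        for name in ("target_size", "candidate_size"):
            size = getattr(self, name)
            if not (1 <= size <= self.n_genes):
                raise ValueError(f"{name} must be in [1, n_genes]")

    # -- closed-form moments -------------------------------------------------
    def _log2_frac_moments(self) -> tuple[float, float]:
        """Mean and variance of log2(sigmoid(w)), w ~ N(mu, sd^2), by quadrature."""
        nodes, weights = np.polynomial.hermite.hermgauss(201)
        w = self.cds_frac_logit_mean + np.sqrt(2.0) * self.cds_frac_logit_sd * nodes
        g = -np.log1p(np.exp(-w)) / np.log(2.0)  # log2(sigmoid(w)), stable
        mean = float(np.sum(weights * g) / np.sqrt(np.pi))
        var = float(np.sum(weights * (g - mean) ** 2) / np.sqrt(np.pi))
        return mean, var

    def covariance(self) -> np.ndarray:
        """Population covariance of (log_expr, cds_len_log2, tx_len_log2)."""
        _, var_l = self._log2_frac_moments()
        v_e = self.expr_sd**2
        v_t = self.len_sd**2
        c_et = self.rho_expr_len * self.expr_sd * self.len_sd
        return np.array(
            [
                [v_e, c_et, c_et],
                [c_et, v_t + var_l, v_t],
                [c_et, v_t, v_t],
            ]
        )

    def expected_r2(self) -> float:
        """Closed-form r² of the full log2-count model: var(βx)/(var(βx)+σ²).

        Exact for the continuous response; count rounding is ignored, which
        is negligible when typical counts are large.
        """
        b = np.asarray(self.beta[1:])
        var_signal = float(b @ self.covariance() @ b)
        return var_signal / (var_signal + self.noise_sd**2)


def _weighted_indices_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, n: int
) -> np.ndarray:
    """Exponential-keys weighted draw of n distinct indices."""
    keys = rng.exponential(size=weights.size) / weights
    return np.sort(np.argpartition(keys, n - 1)[:n])


def generate_universe(params: SyntheticParams) -> GeneUniverse:
    """Draw a synthetic gene universe; deterministic under ``params.seed``."""
    p = params
    rng = np.random.default_rng(np.random.SeedSequence(entropy=p.seed, spawn_key=(0,)))
    z = rng.multivariate_normal(
        mean=[0.0, 0.0],
        cov=[[1.0, p.rho_expr_len], [p.rho_expr_len, 1.0]],
        size=p.n_genes,
    )
    log_expr = p.expr_mean + p.expr_sd * z[:, 0]
    tx_len_log2 = p.len_mean + p.len_sd * z[:, 1]
    w = rng.normal(p.cds_frac_logit_mean, p.cds_frac_logit_sd, size=p.n_genes)
    cds_len_log2 = tx_len_log2 - np.log1p(np.exp(-w)) / np.log(2.0)
    # keep the length invariants: at least 2 nt, cds never above tx
    tx_len_log2 = np.maximum(tx_len_log2, 1.0 + 1e-9)
    cds_len_log2 = np.clip(cds_len_log2, 1.0, tx_len_log2)

    b0, b_e, b_c, b_t = p.beta
    mu = b0 + b_e * log_expr + b_c * cds_len_log2 + b_t * tx_len_log2
    mu += rng.normal(0.0, p.noise_sd, size=p.n_genes) if p.noise_sd > 0 else 0.0
    clip_count = np.maximum(np.rint(np.exp2(mu)), 0.0).astype(int)

    width = len(str(p.n_genes))
    records = [
        GeneRecord(
            symbol=f"G{i:0{width}d}",
            log_expr=float(log_expr[i]),
            cds_len_log2=float(cds_len_log2[i]),
            tx_len_log2=float(tx_len_log2[i]),
            clip_count=int(clip_count[i]),
        )
        for i in range(p.n_genes)
    ]
    return GeneUniverse(records, provenance=(f"synthetic(seed={p.seed}, n={p.n_genes})",))


def _membership_weights(universe: GeneUniverse, bias: tuple[float, ...]) -> np.ndarray:
    cols = [universe.covariate(c) for c in ("log_expr", "cds_len_log2", "tx_len_log2")]
    zs = [(c - c.mean()) / c.std() for c in cols]
    score = bias[0] + sum(b * z for b, z in zip(bias[1:], zs))
    return 1.0 / (1.0 + np.exp(-score))


def generate_labeled_sets(
    universe: GeneUniverse, params: SyntheticParams
) -> tuple[GeneSet, GeneSet]:
    """Draw the target and candidate sets with logistic covariate bias.

    Both draws are weighted without replacement; given the covariates they
    use independent randomness, so candidate membership is conditionally
    independent of target membership.
    """
    p = params
    target_w = _membership_weights(universe, p.target_bias)
    candidate_w = _membership_weights(universe, p.candidate_bias)
    rng_t = np.random.default_rng(np.random.SeedSequence(entropy=p.seed, spawn_key=(1,)))
    rng_c = np.random.default_rng(np.random.SeedSequence(entropy=p.seed, spawn_key=(2,)))
    idx_t = _weighted_indices_without_replacement(rng_t, target_w, p.target_size)
    idx_c = _weighted_indices_without_replacement(rng_c, candidate_w, p.candidate_size)
    target = GeneSet.from_symbols("target", (universe[i].symbol for i in idx_t))
    candidate = GeneSet.from_symbols("candidate", (universe[i].symbol for i in idx_c))
    return target, candidate
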