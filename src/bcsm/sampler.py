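"""Gibbs sampler for the response-time BCSM.

Every (co)variance parameter has a truncated shifted inverse-gamma (TSIG)
full conditional driven by a single sum of squares; the fixed effects have a
multivariate-normal conditional under a locally uniform prior.  One sweep
updates, in order: fixed effects → measurement-error variances σ²_gk → the
auxiliary mean variance σ̄²_g → the speed covariance δ_g → each additional
layer's Δ_gd in declared order → missing-data imputation.  Because each
(co)variance draw respects its positive-definiteness bound conditional on the
parameters updated before it in the sweep, the covariance matrix after every
sweep is positive definite by construction.

Shift parameters are computed recursively: the shift of each parameter's TSIG
conditional equals the total contribution of all *other* (co)variance
parameters to the variance of that parameter's sufficient statistic.  For the
base compound-symmetry model this reduces to the familiar pairs
(δ ← σ̄²/p, σ²_k ← δ); with testlet layers present the overlap terms
Δ_d·(vᵀ_d v)²/|v|⁴ enter as well.  The conditional prior uses the same shift
and truncation with the hyperparameters (α0, β0), which is exactly what makes
the family conjugate (prior kernel × sufficient-statistic likelihood kernel
equals the claimed posterior kernel identically).

Identification (equal mean time intensity across groups, zero speed mean in
the first group) is imposed by rescaling the stored samples, leaving every
fitted mean vector μ_Tg = λ_g − μ_ζg invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .covstruct import (
    CovarianceStructure,
    LayerSpec,
    PositiveDefiniteError,
    build_matrix,
)
from .suffstats import RTDataset
from .tsig import TSIGParams, tsig_sample

__all__ = [
    "PriorHyper",
    "vague_prior",
    "LayerDesign",
    "ModelSpec",
    "ChainState",
    "PosteriorChains",
    "run_chain",
    "rescale_identify",
    "sample_delta",
    "sample_sigma2",
    "sample_mean_sigma2",
    "sample_Delta",
    "sample_fixed_effects",
    "impute_missing",
    "conditional_delta",
    "conditional_sigma2",
    "conditional_mean_sigma2",
    "conditional_Delta",
    "suffstat_loglik_kernel",
    "group_structure",
]


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class PriorHyper:
    """TSIG hyperparameters shared by all (co)variance priors."""

    alpha0: float = 1e-8
    beta0: float = 1e-8

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("prior hyperparameters must be positive")


def vague_prior(shape: float, scale: float) -> PriorHyper:
    """Vague prior in the (shape, scale) parameterization of the precision.

    ``scale`` is the scale of the gamma law on the precision 1/x, i.e. the
    TSIG scale is β0 = 1/scale.  ``vague_prior(1e-8, 1e8)`` is the near
    scale-invariant IG(1e-8, 1e-8).
    """
    return PriorHyper(alpha0=shape, beta0=1.0 / scale)


@dataclass(frozen=True)
class LayerDesign:
    """One additional covariance layer: a name plus per-group design vectors.

    ``vectors`` has shape (G, p); rows are 0/1 membership vectors (group
    layouts may differ, e.g. in a Latin-square design).
    """

    name: str
    vectors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vectors", np.atleast_2d(np.asarray(self.vectors, float)))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model: groups, items, covariance layers, ties, prior.

    The base all-ones speed layer (parameter δ_g) is always present and is
    not listed in ``layers``.  ``tied_sigma2_items`` (0-based item indices)
    constrains those items' error variances to be equal across groups;
    ``tie_layers_across_groups`` constrains each layer's Δ to a single value
    shared by all groups.  Identification is either ``"first_group_zero"``
    (μ_ζ1 = 0 and equal mean intensities λ̄_g across groups) or
    ``"all_groups_zero"`` (μ_ζg = 0 for every group).
    """

    n_items: int
    n_groups: int = 1
    layers: tuple = ()
    prior: PriorHyper = field(default_factory=PriorHyper)
    tie_layers_across_groups: bool = False
    tied_sigma2_items: tuple = ()
    identification: str = "first_group_zero"

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "tied_sigma2_items", tuple(self.tied_sigma2_items))
        if self.identification not in ("first_group_zero", "all_groups_zero"):
            raise ValueError(f"unknown identification rule {self.identification!r}")
        problems = self.validate_design()
        if problems:
            raise ValueError("invalid model design: " + "; ".join(problems))
        mats = []
        for g in range(self.n_groups):
            if self.layers:
                mat = np.stack(
                    [_group_vector(layer, g, self.n_groups) for layer in self.layers]
                )
            else:
                mat = np.zeros((0, self.n_items))
            mat.setflags(write=False)
            mats.append(mat)
        object.__setattr__(self, "_layer_mats", tuple(mats))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_matrix(self, g: int) -> np.ndarray:
        """(D, p) design-vector matrix of the additional layers for group g."""
        mats = getattr(self, "_layer_mats", None)
        if mats is not None:
            return mats[g]
        if not self.layers:
            return np.zeros((0, self.n_items))
        return np.stack([_group_vector(layer, g, self.n_groups) for layer in self.layers])

    def validate_design(self) -> list[str]:
        out: list[str] = []
        for layer in self.layers:
            if layer.vectors.shape[1] != self.n_items:
                out.append(
                    f"layer {layer.name!r} has vectors of length "
                    f"{layer.vectors.shape[1]}, expected {self.n_items}"
                )
            if layer.vectors.shape[0] not in (1, self.n_groups):
                out.append(
                    f"layer {layer.name!r} must have 1 or {self.n_groups} design vectors"
                )
        if out:
            return out
        for g in range(self.n_groups):
            mat = self.layer_matrix(g)
            vecs = [np.ones(self.n_items)] + [mat[d] for d in range(mat.shape[0])]
            names = ["speed"] + [layer.name for layer in self.layers]
            for a in range(len(vecs)):
                if not np.any(vecs[a] != 0):
                    out.append(f"layer {names[a]!r} has an all-zero design vector")
                for b in range(a + 1, len(vecs)):
                    if np.array_equal(vecs[a], vecs[b]):
                        out.append(
                            f"group {g + 1}: design vectors of layers {names[a]!r} "
                            f"and {names[b]!r} are not distinct"
                        )
        bad = [k for k in self.tied_sigma2_items if not 0 <= k < self.n_items]
        if bad:
            out.append(f"tied_sigma2_items out of range: {bad}")
        return out


def _group_vector(layer: LayerDesign, g: int, n_groups: int) -> np.ndarray:
    return layer.vectors[0] if layer.vectors.shape[0] == 1 else layer.vectors[g]


# --------------------------------------------------------------------------
# chain state and sufficient statistics
# --------------------------------------------------------------------------
@dataclass
class ChainState:
    """One Gibbs state.  Person speeds are deliberately absent (marginalized)."""

    mu_T: np.ndarray  # (G, p) fitted group mean vectors λ_g − μ_ζg
    sigma2: np.ndarray  # (G, p)
    mean_sigma2: np.ndarray  # (G,) auxiliary σ̄²_g
    delta: np.ndarray  # (G,)
    Delta: np.ndarray  # (G, D)
    completed: np.ndarray | None = None  # (N, p) values with current imputations


@dataclass
class _GroupStats:
    n: int
    item_means: np.ndarray  # (p,)
    ssb: float
    ssw_k: np.ndarray  # (p,)
    ssw: float
    ssb_d: np.ndarray  # (D,)


def _compute_stats(values: np.ndarray, layer_mat: np.ndarray) -> _GroupStats:
    n, p = values.shape
    item_means = values.mean(axis=0)
    person_means = values.mean(axis=1)
    ssb = float(np.sum((person_means - person_means.mean()) ** 2))
    dev = values - item_means
    ssw_k = np.einsum("ij,ij->j", dev, dev)
    D = layer_mat.shape[0]
    ssb_d = np.zeros(D)
    for d in range(D):
        members = layer_mat[d] != 0
        lm = values[:, members].mean(axis=1)
        ssb_d[d] = np.sum((lm - lm.mean()) ** 2)
    return _GroupStats(n, item_means, ssb, ssw_k, float(ssw_k.sum()), ssb_d)


def _build_sigma(spec: ModelSpec, state: ChainState, g: int) -> np.ndarray:
    """Dense Σ_g without intermediate structure objects (hot path)."""
    sigma = np.diag(state.sigma2[g]) + float(state.delta[g])
    mat = spec.layer_matrix(g)
    for d in range(mat.shape[0]):
        v = mat[d]
        sigma += float(state.Delta[g, d]) * np.outer(v, v)
    return sigma


def group_structure(spec: ModelSpec, state: ChainState, g: int) -> CovarianceStructure:
    """The group's covariance structure at the current state."""
    layers = [LayerSpec(np.ones(spec.n_items), "delta", float(state.delta[g]))]
    mat = spec.layer_matrix(g)
    for d, layer in enumerate(spec.layers):
        layers.append(LayerSpec(mat[d], layer.name, float(state.Delta[g, d])))
    return CovarianceStructure(state.sigma2[g].copy(), layers)


# --------------------------------------------------------------------------
# conditional TSIG parameters (posterior and prior share shift/truncation)
# --------------------------------------------------------------------------
def _layer_sizes(layer_mat: np.ndarray) -> np.ndarray:
    return layer_mat.sum(axis=1)


def _delta_shift(spec: ModelSpec, state: ChainState, g: int) -> float:
    p = spec.n_items
    mat = spec.layer_matrix(g)
    sizes = _layer_sizes(mat)
    overlap = 0.0
    if mat.shape[0]:
        overlap = float(np.sum(state.Delta[g] * (sizes / p) ** 2))
    return float(state.mean_sigma2[g]) / p + overlap


def _delta_trunc(state: ChainState, g: int) -> float:
    return -1.0 / float(np.sum(1.0 / state.sigma2[g]))


def conditional_delta(
    spec: ModelSpec, state: ChainState, g: int, stats: _GroupStats
) -> TSIGParams:
    """TSIG parameters of the full conditional of δ_g."""
    pr = spec.prior
    return TSIGParams(
        alpha=pr.alpha0 + stats.n / 2.0,
        beta=pr.beta0 + stats.ssb / 2.0,
        shift=_delta_shift(spec, state, g),
        trunc=_delta_trunc(state, g),
    )


def _sigma2_shift(spec: ModelSpec, state: ChainState, g: int) -> np.ndarray:
    mat = spec.layer_matrix(g)
    shift = np.full(spec.n_items, float(state.delta[g]))
    if mat.shape[0]:
        shift = shift + state.Delta[g] @ mat
    return shift


def conditional_sigma2(
    spec: ModelSpec, state: ChainState, g: int, stats: _GroupStats
) -> TSIGParams:
    """Vector TSIG conditional of σ²_g (one set of parameters per item)."""
    pr = spec.prior
    return TSIGParams(
        alpha=pr.alpha0 + stats.n / 2.0,
        beta=pr.beta0 + stats.ssw_k / 2.0,
        shift=_sigma2_shift(spec, state, g),
        trunc=0.0,
    )


def conditional_mean_sigma2(
    spec: ModelSpec, state: ChainState, g: int, stats: _GroupStats
) -> TSIGParams:
    pr = spec.prior
    p = spec.n_items
    mat = spec.layer_matrix(g)
    sizes = _layer_sizes(mat)
    shift = float(state.delta[g])
    if mat.shape[0]:
        shift += float(np.sum(state.Delta[g] * sizes / p))
    return TSIGParams(
        alpha=pr.alpha0 + stats.n / 2.0,
        beta=pr.beta0 + stats.ssw / (2.0 * p),
        shift=shift,
        trunc=0.0,
    )


def _Delta_shift(spec: ModelSpec, state: ChainState, g: int, d: int) -> float:
    mat = spec.layer_matrix(g)
    v = mat[d]
    members = v != 0
    p_d = float(members.sum())
    shift = float(state.sigma2[g][members].mean()) / p_d + float(state.delta[g])
    for other in range(mat.shape[0]):
        if other == d:
            continue
        ov = float(mat[other] @ v)
        if ov:
            shift += float(state.Delta[g, other]) * (ov / p_d) ** 2
    return shift


def _Delta_trunc(spec: ModelSpec, state: ChainState, g: int, d: int) -> float:
    """PD lower bound of layer d given the layers below it (declared order)."""
    mat = spec.layer_matrix(g)
    inv = np.diag(1.0 / state.sigma2[g])
    logdenoms = []
    vs = [np.ones(spec.n_items)] + [mat[dd] for dd in range(d)]
    psis = [float(state.delta[g])] + [float(state.Delta[g, dd]) for dd in range(d)]
    for v, psi, name in zip(
        vs, psis, ["delta"] + [spec.layers[dd].name for dd in range(d)]
    ):
        w = inv @ v
        denom = 1.0 + psi * float(v @ w)
        if denom <= 0:
            raise PositiveDefiniteError(
                f"layer {name!r} below layer {spec.layers[d].name!r} violates PD"
            )
        inv -= (psi / denom) * np.outer(w, w)
    v = mat[d]
    return -1.0 / float(v @ inv @ v)


def conditional_Delta(
    spec: ModelSpec, state: ChainState, g: int, d: int, stats: _GroupStats
) -> TSIGParams:
    pr = spec.prior
    return TSIGParams(
        alpha=pr.alpha0 + stats.n / 2.0,
        beta=pr.beta0 + stats.ssb_d[d] / 2.0,
        shift=_Delta_shift(spec, state, g, d),
        trunc=_Delta_trunc(spec, state, g, d),
    )


def prior_params(posterior: TSIGParams, prior: PriorHyper) -> TSIGParams:
    """Conditional prior matching a conditional posterior's shift/truncation."""
    return replace(posterior, alpha=prior.alpha0, beta=prior.beta0)


def suffstat_loglik_kernel(x, shift: float, n: int, ss: float):
    """Log of the sufficient-statistic likelihood kernel
    (x + shift)^(−n/2) · exp(−(ss/2)/(x + shift)); −inf where x + shift <= 0."""
    x = np.asarray(x, dtype=float)
    y = x + shift
    ok = y > 0
    y = np.where(ok, y, 1.0)
    out = -0.5 * n * np.log(y) - 0.5 * ss / y
    return np.where(ok, out, -np.inf)


def _pool(params: list[TSIGParams], weights: np.ndarray, prior: PriorHyper) -> TSIGParams:
    """Pool per-group conditionals of a tied parameter into one TSIG law.

    Shapes and scales add (minus the repeated prior contribution); the shift
    is the sample-size weighted mean and the truncation the tightest bound.
    Exact when per-group shifts coincide.
    """
    alphas = np.array([float(np.asarray(p.alpha)) for p in params])
    betas = np.array([float(np.asarray(p.beta)) for p in params])
    shifts = np.array([float(np.asarray(p.shift)) for p in params])
    truncs = np.array([float(np.asarray(p.trunc)) for p in params])
    return TSIGParams(
        alpha=prior.alpha0 + float(np.sum(alphas - prior.alpha0)),
        beta=prior.beta0 + float(np.sum(betas - prior.beta0)),
        shift=float(np.sum(weights * shifts) / np.sum(weights)),
        trunc=float(np.max(truncs)),
    )


# --------------------------------------------------------------------------
# single-site sampling operations (public, data-facing)
# --------------------------------------------------------------------------
def _stats_for(data: RTDataset, spec: ModelSpec, g: int) -> _GroupStats:
    vals = data.group_values(g)
    if vals.size == 0:
        raise ValueError(f"group {g} is empty")
    if np.isnan(vals).any():
        raise ValueError("missing values present; impute before sampling")
    return _compute_stats(vals, spec.layer_matrix(g))


def sample_delta(state: ChainState, data: RTDataset, spec: ModelSpec, group: int, rng):
    params = conditional_delta(spec, state, group, _stats_for(data, spec, group))
    state.delta[group] = tsig_sample(params, rng=rng)
    return state.delta[group]


def sample_sigma2(
    state: ChainState, data: RTDataset, spec: ModelSpec, group: int, rng, item=None
):
    params = conditional_sigma2(spec, state, group, _stats_for(data, spec, group))
    draw = tsig_sample(params, rng=rng)
    if item is None:
        state.sigma2[group] = draw
        return draw
    state.sigma2[group, item] = draw[item]
    return draw[item]


def sample_mean_sigma2(state: ChainState, data: RTDataset, spec: ModelSpec, group: int, rng):
    params = conditional_mean_sigma2(spec, state, group, _stats_for(data, spec, group))
    state.mean_sigma2[group] = tsig_sample(params, rng=rng)
    return state.mean_sigma2[group]


def sample_Delta(
    state: ChainState, data: RTDataset, spec: ModelSpec, group: int, layer_d: int, rng
):
    params = conditional_Delta(spec, state, group, layer_d, _stats_for(data, spec, group))
    state.Delta[group, layer_d] = tsig_sample(params, rng=rng)
    return state.Delta[group, layer_d]


def sample_fixed_effects(state: ChainState, data: RTDataset, spec: ModelSpec, rng):
    """Draw μ_Tg ~ N(item means, Σ_g/n_g) per group under the flat prior."""
    for g in range(spec.n_groups):
        stats = _stats_for(data, spec, g)
        sigma = build_matrix(group_structure(spec, state, g))
        chol = _safe_cholesky(sigma)
        z = rng.standard_normal(spec.n_items)
        state.mu_T[g] = stats.item_means + (chol @ z) / np.sqrt(stats.n)
    return state.mu_T


def _safe_cholesky(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # numerically semidefinite (e.g. degenerate data); nudge the diagonal
        jitter = 1e-10 * max(float(np.mean(np.diag(sigma))), 1e-12)
        return np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))


def impute_missing(state: ChainState, data: RTDataset, spec: ModelSpec, rng):
    """Redraw missing cells from the conditional normal given observed cells.

    Fully missing persons are drawn from their unconditional group law.
    Returns the updated completed-value matrix (also stored on the state).
    """
    if state.completed is None:
        state.completed = data.values.copy()
    if not data.has_missing:
        return state.completed
    for g in range(spec.n_groups):
        rows = data.group_rows(g)
        miss = data.missing[rows]
        if not miss.any():
            continue
        sigma = build_matrix(group_structure(spec, state, g))
        mu = state.mu_T[g]
        patterns: dict[bytes, list[int]] = {}
        for local_i in np.flatnonzero(miss.any(axis=1)):
            patterns.setdefault(miss[local_i].tobytes(), []).append(local_i)
        for key, members in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            obs = np.flatnonzero(~m)
            mis = np.flatnonzero(m)
            idx = rows[members]
            if obs.size == 0:
                chol = _safe_cholesky(sigma)
                z = rng.standard_normal((len(members), sigma.shape[0]))
                state.completed[idx] = mu + z @ chol.T
                continue
            s_oo = sigma[np.ix_(obs, obs)]
            s_mo = sigma[np.ix_(mis, obs)]
            s_mm = sigma[np.ix_(mis, mis)]
            solve = np.linalg.solve(s_oo, s_mo.T)  # (obs, mis)
            cond_cov = s_mm - s_mo @ solve
            chol = _safe_cholesky(cond_cov)
            resid = state.completed[np.ix_(idx, obs)] - mu[obs]
            cond_mean = mu[mis] + resid @ solve
            z = rng.standard_normal((len(members), mis.size))
            vals = cond_mean + z @ chol.T
            state.completed[np.ix_(idx, mis)] = vals
    return state.completed


# --------------------------------------------------------------------------
# identification
# --------------------------------------------------------------------------
def rescale_identify(mu_T: np.ndarray, identification: str = "first_group_zero"):
    """Split fitted means μ_Tg = λ_g − μ_ζg into identified (λ, μ_ζ).

    Works on a single state (G, p) or a whole chain (M, G, p).  Under
    ``first_group_zero``: μ_ζ1 = 0 and λ̄_g equal across groups; under
    ``all_groups_zero``: μ_ζg = 0 everywhere.  The transformation leaves
    λ_g − μ_ζg equal to the input exactly.
    """
    arr = np.asarray(mu_T, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    M, G, p = arr.shape
    if identification == "all_groups_zero":
        lam = arr.copy()
        mu_zeta = np.zeros((M, G))
    else:
        mu_zeta = np.zeros((M, G))
        lbar1 = arr[:, 0, :].mean(axis=1)  # (M,)
        group_means = arr.mean(axis=2)  # (M, G)
        mu_zeta[:, 1:] = lbar1[:, None] - group_means[:, 1:]
        lam = arr + mu_zeta[:, :, None]
    if single:
        return lam[0], mu_zeta[0]
    return lam, mu_zeta


# --------------------------------------------------------------------------
# posterior chains
# --------------------------------------------------------------------------
@dataclass
class PosteriorChains:
    """Stored MCMC samples plus the per-iteration sufficient statistics.

    ``samples`` holds raw draws (mu_T, sigma2, mean_sigma2, delta, Delta) and
    the identified (lam, mu_zeta); ``stats`` holds the per-iteration
    sufficient statistics (constant when there is no missing data), which the
    evidence module needs to rebuild full-conditional densities.
    """

    spec: ModelSpec
    samples: dict
    stats: dict
    n_iterations: int
    burn_in: int
    seed: int
    n_g: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.burn_in

    def retained(self, name: str) -> np.ndarray:
        return self.samples[name][self.burn_in :]

    def retained_stats(self, name: str) -> np.ndarray:
        arr = self.stats[name]
        if arr.shape[0] == 1:  # constant statistics (complete data)
            reps = (self.n_retained,) + (1,) * (arr.ndim - 1)
            return np.tile(arr, reps)
        return arr[self.burn_in :]

    def posterior_means(self) -> dict:
        return {k: self.retained(k).mean(axis=0) for k in self.samples}

    def credible_interval(self, name: str, level: float = 0.95) -> np.ndarray:
        """Equal-tailed interval; stacked (2, ...) array of lower/upper."""
        a = 100.0 * (1.0 - level) / 2.0
        return np.percentile(self.retained(name), [a, 100.0 - a], axis=0)

    def summary(self, level: float = 0.95):
        import pandas as pd

        rows = []
        for name in ("lam", "mu_zeta", "sigma2", "mean_sigma2", "delta", "Delta"):
            draws = self.retained(name)
            flat = draws.reshape(draws.shape[0], -1)
            lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
            shape = draws.shape[1:]
            for j in range(flat.shape[1]):
                idx = np.unravel_index(j, shape) if shape else ()
                label = name + "".join(f"[{i + 1}]" for i in idx)
                rows.append(
                    {
                        "parameter": label,
                        "mean": flat[:, j].mean(),
                        "sd": flat[:, j].std(ddof=1),
                        f"{100 * (1 - level) / 2:g}%": lo[j],
                        f"{100 * (1 + level) / 2:g}%": hi[j],
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# the full sampler
# --------------------------------------------------------------------------
def _initial_state(data: RTDataset, spec: ModelSpec) -> ChainState:
    """Method-of-moments start inside the PD region by construction."""
    G, p, D = spec.n_groups, spec.n_items, spec.n_layers
    completed = data.values.copy()
    if data.has_missing:
        # start missing cells at their item means within the group
        for g in range(G):
            rows = data.group_rows(g)
            block = completed[rows]
            col_means = np.nanmean(np.where(data.missing[rows], np.nan, block), axis=0)
            col_means = np.where(np.isfinite(col_means), col_means, np.nanmean(block))
            fill = np.broadcast_to(col_means, block.shape)
            block[data.missing[rows]] = fill[data.missing[rows]]
            completed[rows] = block
    mu_T = np.zeros((G, p))
    sigma2 = np.ones((G, p))
    delta = np.zeros(G)
    for g in range(G):
        vals = completed[data.group_rows(g)]
        mu_T[g] = vals.mean(axis=0)
        var_k = vals.var(axis=0, ddof=1) if vals.shape[0] > 1 else np.ones(p)
        sigma2[g] = np.maximum(var_k, 1e-8)
        if vals.shape[0] > 1:
            cov = np.cov(vals, rowvar=False)
            off = cov[~np.eye(p, dtype=bool)]
            delta_mom = float(off.mean()) if off.size else 0.0
        else:
            delta_mom = 0.0
        bound = -1.0 / float(np.sum(1.0 / sigma2[g]))
        delta[g] = max(delta_mom, 0.5 * bound)
    return ChainState(
        mu_T=mu_T,
        sigma2=sigma2,
        mean_sigma2=sigma2.mean(axis=1),
        delta=delta,
        Delta=np.zeros((G, D)),
        completed=completed,
    )


def run_chain(
    data: RTDataset,
    spec: ModelSpec,
    iterations: int = 2000,
    burn_in: float = 0.1,
    seed: int = 0,
) -> PosteriorChains:
    """Run the Gibbs sampler and return stored chains.

    ``burn_in`` is a fraction of ``iterations`` (the retained draws are the
    remainder).  Two runs with the same seed are bit-identical.
    """
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be a fraction in [0, 1)")
    rng = np.random.default_rng(seed)
    G, p, D = spec.n_groups, spec.n_items, spec.n_layers
    if data.G != G:
        raise ValueError(f"data has {data.G} groups but the model declares {G}")
    if data.p != p:
        raise ValueError(f"data has {data.p} items but the model declares {p}")
    state = _initial_state(data, spec)
    n_g = data.n_g
    group_rows = [data.group_rows(g) for g in range(G)]
    layer_mats = [spec.layer_matrix(g) for g in range(G)]
    stats = [
        _compute_stats(state.completed[group_rows[g]], layer_mats[g]) for g in range(G)
    ]
    tied_items = np.array(spec.tied_sigma2_items, dtype=int)
    free_mask = np.ones(p, dtype=bool)
    free_mask[tied_items] = False
    pr = spec.prior

    samples = {
        "mu_T": np.empty((iterations, G, p)),
        "sigma2": np.empty((iterations, G, p)),
        "mean_sigma2": np.empty((iterations, G)),
        "delta": np.empty((iterations, G)),
        "Delta": np.empty((iterations, G, D)),
    }
    track_stats = data.has_missing
    n_stats = iterations if track_stats else 1
    stats_store = {
        "ssb": np.empty((n_stats, G)),
        "ssw_k": np.empty((n_stats, G, p)),
        "ssw": np.empty((n_stats, G)),
        "ssb_d": np.empty((n_stats, G, D)),
        "item_means": np.empty((n_stats, G, p)),
    }

    for it in range(iterations):
        # fixed effects
        for g in range(G):
            sigma = _build_sigma(spec, state, g)
            chol = _safe_cholesky(sigma)
            z = rng.standard_normal(p)
            state.mu_T[g] = stats[g].item_means + (chol @ z) / np.sqrt(stats[g].n)
        # measurement-error variances
        cond_s2 = [conditional_sigma2(spec, state, g, stats[g]) for g in range(G)]
        for g in range(G):
            draw = tsig_sample(cond_s2[g], rng=rng)
            state.sigma2[g, free_mask] = np.atleast_1d(draw)[free_mask]
        for k in tied_items:
            per_group = [
                TSIGParams(
                    alpha=np.asarray(cond_s2[g].alpha).item(),
                    beta=np.asarray(cond_s2[g].beta)[k],
                    shift=np.asarray(cond_s2[g].shift)[k],
                    trunc=0.0,
                )
                for g in range(G)
            ]
            pooled = _pool(per_group, n_g.astype(float), pr)
            state.sigma2[:, k] = tsig_sample(pooled, rng=rng)
        # auxiliary mean variance and speed covariance
        for g in range(G):
            state.mean_sigma2[g] = tsig_sample(
                conditional_mean_sigma2(spec, state, g, stats[g]), rng=rng
            )
            state.delta[g] = tsig_sample(
                conditional_delta(spec, state, g, stats[g]), rng=rng
            )
        # additional layers, declared order, PD bounds from updated lower
        # layers via an incrementally downdated Sherman-Morrison inverse
        if D:
            invs = []
            for g in range(G):
                inv = np.diag(1.0 / state.sigma2[g])
                w = inv.sum(axis=0)
                denom = 1.0 + float(state.delta[g]) * float(w.sum())
                inv -= (float(state.delta[g]) / denom) * np.outer(w, w)
                invs.append(inv)
            for d in range(D):
                conds = []
                for g in range(G):
                    v = layer_mats[g][d]
                    w = invs[g] @ v
                    trunc = -1.0 / float(v @ w)
                    conds.append(
                        TSIGParams(
                            alpha=pr.alpha0 + stats[g].n / 2.0,
                            beta=pr.beta0 + float(stats[g].ssb_d[d]) / 2.0,
                            shift=_Delta_shift(spec, state, g, d),
                            trunc=trunc,
                        )
                    )
                if spec.tie_layers_across_groups:
                    pooled = _pool(conds, n_g.astype(float), pr)
                    state.Delta[:, d] = tsig_sample(pooled, rng=rng)
                else:
                    for g in range(G):
                        state.Delta[g, d] = tsig_sample(conds[g], rng=rng)
                for g in range(G):
                    v = layer_mats[g][d]
                    w = invs[g] @ v
                    denom = 1.0 + float(state.Delta[g, d]) * float(v @ w)
                    invs[g] -= (float(state.Delta[g, d]) / denom) * np.outer(w, w)
        # missing-data imputation and statistics refresh
        if track_stats:
            impute_missing(state, data, spec, rng)
            stats = [
                _compute_stats(state.completed[group_rows[g]], layer_mats[g])
                for g in range(G)
            ]
        for name, arr in samples.items():
            arr[it] = getattr(state, name)
        if track_stats or it == 0:
            j = it if track_stats else 0
            for g in range(G):
                stats_store["ssb"][j, g] = stats[g].ssb
                stats_store["ssw_k"][j, g] = stats[g].ssw_k
                stats_store["ssw"][j, g] = stats[g].ssw
                stats_store["ssb_d"][j, g] = stats[g].ssb_d
                stats_store["item_means"][j, g] = stats[g].item_means

    lam, mu_zeta = rescale_identify(samples["mu_T"], spec.identification)
    samples["lam"] = lam
    samples["mu_zeta"] = mu_zeta
    return PosteriorChains(
        spec=spec,
        samples=samples,
        stats=stats_store,
        n_iterations=iterations,
        burn_in=int(round(burn_in * iterations)),
        seed=seed,
        n_g=n_g,
    )
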