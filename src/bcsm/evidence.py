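"""Model evidence: importance-sampled marginal likelihoods, Bayes factors, BIC.

The marginal likelihood m(T|M) is estimated with the permuted-chain
importance sampler: the importance density is the product of the marginal
posterior distributions of the parameter blocks, realized by independently
re-ordering each block's retained MCMC draws, and both the marginal posterior
densities (denominator) and the marginal prior densities of the covariance
parameters (numerator) are estimated by Rao-Blackwellization — averaging the
closed-form full-conditional TSIG/normal densities over retained draws.
Unknown normalizing constants of the priors appear identically in the
estimated marginal posteriors and cancel.

Blocks: one fixed-effects block ξ_g per group (flat prior, contributing a
constant that cancels in any Bayes factor between models sharing the mean
structure), one block per group's σ² vector, and one block per covariance
parameter (δ_g, each Δ).  A null model that restricts covariance parameters
to zero simply omits the corresponding layers; its evidence is computed from
its own (refit) chains, with the restricted parameters excluded from both the
numerator density and the importance density.

The BIC uses the likelihood at the posterior means, the number of fixed
effects plus free covariance-matrix parameters, and effective sample size
N* = p·N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .covstruct import build_matrix
from .sampler import (
    ChainState,
    ModelSpec,
    PosteriorChains,
    _GroupStats,
    _pool,
    conditional_delta,
    conditional_Delta,
    conditional_sigma2,
    group_structure,
    prior_params,
    run_chain,
)
from .suffstats import RTDataset
from .tsig import TSIGParams, tsig_logpdf

__all__ = [
    "EvidenceResult",
    "BICResult",
    "permute_chains",
    "rb_marginal_logdensity",
    "log_marginal_likelihood",
    "log_marginal_from_weights",
    "bf_delta_restriction",
    "restrict_layers",
    "model_blocks",
    "bic",
    "bf_from_bic",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class EvidenceResult:
    """Evidence comparison across a set of competing model restrictions."""

    log_marginal: dict = field(default_factory=dict)
    log_bf: dict = field(default_factory=dict)
    bic: dict = field(default_factory=dict)
    n_importance: int = 0
    parameter_blocks: dict = field(default_factory=dict)


@dataclass
class BICResult:
    bic: float
    loglik_hat: float
    d: int
    n_star: int

    def __float__(self) -> float:
        return self.bic


# --------------------------------------------------------------------------
# permutation of chains
# --------------------------------------------------------------------------
def permute_chains(arrays: dict, rng, blocks: list | None = None, J: int | None = None):
    """Independently re-order each parameter column (or block of columns).

    ``arrays`` maps names to (M, ...) sample arrays.  Names grouped together
    in one entry of ``blocks`` are re-ordered with a common permutation;
    by default every name is its own block.  Each column's marginal sample is
    preserved exactly (same multiset); cross-column association is destroyed,
    so rows become draws from the product of marginal posteriors.
    """
    names = list(arrays)
    M = next(iter(arrays.values())).shape[0]
    if blocks is None:
        blocks = [[name] for name in names]
    J = M if J is None else min(J, M)
    out = {}
    for block in blocks:
        idx = rng.permutation(M)[:J]
        for name in block:
            out[name] = arrays[name][idx]
    return out


# --------------------------------------------------------------------------
# per-draw conditional parameters, rebuilt from stored chains
# --------------------------------------------------------------------------
def _state_at(ret: dict, m: int) -> ChainState:
    return ChainState(
        mu_T=ret["mu_T"][m],
        sigma2=ret["sigma2"][m],
        mean_sigma2=ret["mean_sigma2"][m],
        delta=ret["delta"][m],
        Delta=ret["Delta"][m],
    )


def _stats_at(st: dict, m: int, g: int, n_g) -> _GroupStats:
    return _GroupStats(
        n=int(n_g[g]),
        item_means=st["item_means"][m, g],
        ssb=float(st["ssb"][m, g]),
        ssw_k=st["ssw_k"][m, g],
        ssw=float(st["ssw"][m, g]),
        ssb_d=st["ssb_d"][m, g],
    )


def model_blocks(spec: ModelSpec) -> list[tuple]:
    """Parameter blocking: ξ per group, σ² per group, each covariance alone."""
    blocks: list[tuple] = []
    for g in range(spec.n_groups):
        blocks.append(("xi", g))
    for g in range(spec.n_groups):
        blocks.append(("sigma2", g))
    for g in range(spec.n_groups):
        blocks.append(("delta", g))
    if spec.tie_layers_across_groups:
        blocks += [("Delta", d) for d in range(spec.n_layers)]
    else:
        blocks += [
            ("Delta", (g, d))
            for g in range(spec.n_groups)
            for d in range(spec.n_layers)
        ]
    return blocks


def _cov_block_params(
    spec: ModelSpec, block: tuple, ret: dict, st: dict, n_g, rb_idx
) -> tuple[TSIGParams, TSIGParams]:
    """(posterior, prior) TSIG parameter arrays over the conditioning draws."""
    kind, which = block
    alphas, betas, shifts, truncs = [], [], [], []
    p_alphas, p_betas = [], []
    for m in rb_idx:
        state = _state_at(ret, m)
        if kind == "delta":
            g = which
            params = conditional_delta(spec, state, g, _stats_at(st, m, g, n_g))
        elif kind == "sigma2":
            g = which
            params = conditional_sigma2(spec, state, g, _stats_at(st, m, g, n_g))
        elif kind == "Delta" and spec.tie_layers_across_groups:
            d = which
            per_group = [
                conditional_Delta(spec, state, g, d, _stats_at(st, m, g, n_g))
                for g in range(spec.n_groups)
            ]
            params = _pool(per_group, np.asarray(n_g, float), spec.prior)
        elif kind == "Delta":
            g, d = which
            params = conditional_Delta(spec, state, g, d, _stats_at(st, m, g, n_g))
        else:  # pragma: no cover
            raise ValueError(f"no closed-form conditional for block {block}")
        prior = prior_params(params, spec.prior)
        shape = np.shape(np.asarray(params.beta, float))
        expand = lambda v: np.broadcast_to(np.asarray(v, float), shape).copy()  # noqa: E731
        alphas.append(expand(params.alpha))
        betas.append(expand(params.beta))
        shifts.append(expand(params.shift))
        truncs.append(expand(params.trunc))
        p_alphas.append(expand(prior.alpha))
        p_betas.append(expand(prior.beta))
    post = TSIGParams(np.stack(alphas), np.stack(betas), np.stack(shifts), np.stack(truncs))
    pri = TSIGParams(np.stack(p_alphas), np.stack(p_betas), np.stack(shifts), np.stack(truncs))
    return post, pri


def _rb_tsig_logpdf(values: np.ndarray, params: TSIGParams, chunk: int = 256) -> np.ndarray:
    """log[(1/R) Σ_m f(x_j | params_m)] for scalar-per-item TSIG conditionals.

    ``values`` is (J,) or (J, p); parameter arrays are (R,) or (R, p); the
    density of a p-vector block is the product over items.  Evaluated in
    chunks over J to bound memory.
    """
    values = np.asarray(values, float)
    vector_block = values.ndim == 2
    R = np.asarray(params.alpha).shape[0]
    out = np.empty(values.shape[0])
    for start in range(0, values.shape[0], chunk):
        chunk_vals = values[start : start + chunk]
        if vector_block:
            x = chunk_vals[:, None, :]  # (j, 1, p)
            lp = tsig_logpdf(
                x,
                TSIGParams(
                    params.alpha[None, :],
                    params.beta[None, :],
                    params.shift[None, :],
                    params.trunc[None, :] if np.ndim(params.trunc) else params.trunc,
                ),
            ).sum(axis=-1)
        else:
            x = chunk_vals[:, None]
            lp = tsig_logpdf(
                x, TSIGParams(params.alpha[None, :], params.beta[None, :], params.shift[None, :], params.trunc[None, :])
            )
        out[start : start + chunk] = logsumexp(lp, axis=1) - np.log(R)
    return out


def _rb_xi_logpdf(
    values: np.ndarray, spec: ModelSpec, g: int, ret: dict, st: dict, n_g, rb_idx
) -> np.ndarray:
    """RB marginal posterior of a fixed-effects block: average of
    N(item means, Σ_g/n_g) densities over conditioning draws."""
    J, p = values.shape
    R = len(rb_idx)
    lp = np.empty((J, R))
    n = float(n_g[g])
    from scipy.linalg import solve_triangular

    for col, m in enumerate(rb_idx):
        state = _state_at(ret, m)
        sigma = build_matrix(group_structure(spec, state, g)) / n
        chol = np.linalg.cholesky(sigma)
        diff = values - st["item_means"][m, g]
        sol = solve_triangular(chol, diff.T, lower=True)
        quad = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        lp[:, col] = -0.5 * (p * _LOG2PI + logdet + quad)
    return logsumexp(lp, axis=1) - np.log(R)


def rb_marginal_logdensity(
    chains: PosteriorChains,
    parameter: tuple,
    at_values,
    kind: str = "posterior",
    n_rb: int | None = None,
) -> np.ndarray:
    """Rao-Blackwellized log marginal density of one parameter block.

    ``parameter`` is a block label as produced by :func:`model_blocks`
    (e.g. ``("delta", 0)``); ``kind`` selects the marginal posterior or the
    marginal prior (conditional priors averaged over draws).  Fixed-effect
    blocks support only the posterior (their prior is locally uniform).
    """
    spec = chains.spec
    ret = {k: chains.retained(k) for k in ("mu_T", "sigma2", "mean_sigma2", "delta", "Delta")}
    st = {k: chains.retained_stats(k) for k in ("ssb", "ssw_k", "ssw", "ssb_d", "item_means")}
    M = ret["delta"].shape[0]
    R = M if n_rb is None else min(n_rb, M)
    rb_idx = np.unique(np.linspace(0, M - 1, R).astype(int))
    at_values = np.asarray(at_values, float)
    if parameter[0] == "xi":
        if kind != "posterior":
            raise ValueError("fixed-effect blocks have a locally uniform prior; "
                             "no closed-form marginal prior density")
        return _rb_xi_logpdf(np.atleast_2d(at_values), spec, parameter[1], ret, st, chains.n_g, rb_idx)
    post, pri = _cov_block_params(spec, parameter, ret, st, chains.n_g, rb_idx)
    params = post if kind == "posterior" else pri
    vals = at_values if parameter[0] == "sigma2" else np.atleast_1d(at_values)
    return _rb_tsig_logpdf(vals, params)


# --------------------------------------------------------------------------
# observed-data log-likelihood, fast path via per-pattern scatter matrices
# --------------------------------------------------------------------------
def _observed_patterns(data: RTDataset):
    """Per group: list of (obs indices, count, mean vector, scatter matrix)."""
    out = []
    for g in range(data.G):
        rows = data.group_rows(g)
        vals = data.values[rows]
        miss = data.missing[rows]
        patterns: dict[bytes, list[int]] = {}
        for i in range(len(rows)):
            patterns.setdefault(miss[i].tobytes(), []).append(i)
        entries = []
        for key, members in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            obs = np.flatnonzero(~m)
            if obs.size == 0:
                continue
            block = vals[np.ix_(members, obs)]
            mean = block.mean(axis=0)
            dev = block - mean
            entries.append((obs, len(members), mean, dev.T @ dev))
        out.append(entries)
    return out


def _loglik_at(spec: ModelSpec, patterns, state: ChainState) -> float:
    total = 0.0
    for g in range(spec.n_groups):
        sigma = None
        for obs, n_pat, mean, scatter in patterns[g]:
            if sigma is None:
                sigma = build_matrix(group_structure(spec, state, g))
            sub = sigma if obs.size == sigma.shape[0] else sigma[np.ix_(obs, obs)]
            chol = np.linalg.cholesky(sub)
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
            inv = np.linalg.inv(sub)
            diff = mean - state.mu_T[g][obs]
            quad = float(np.sum(inv * scatter)) + n_pat * float(diff @ inv @ diff)
            total += -0.5 * (n_pat * (obs.size * _LOG2PI + logdet) + quad)
    return total


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------
def log_marginal_from_weights(loglik, logprior, log_importance) -> float:
    """Generic importance-sampling average: log[(1/J) Σ exp(w_j)] with
    w = loglik + logprior − log importance density.  Raises on non-finite
    weights (a −inf likelihood is allowed and simply contributes nothing)."""
    w = np.asarray(loglik, float) + np.asarray(logprior, float) - np.asarray(log_importance, float)
    bad = np.flatnonzero(np.isnan(w) | np.isposinf(w))
    if bad.size:
        raise ValueError(f"non-finite importance weight at draw index {bad[0]}")
    return float(logsumexp(w) - np.log(w.size))


def log_marginal_likelihood(
    data: RTDataset,
    spec: ModelSpec,
    chains: PosteriorChains,
    J: int | None = None,
    n_rb: int | None = None,
    seed: int = 0,
):
    """Importance-sampling estimate of the log marginal likelihood.

    Permutes the retained chains block-wise, evaluates the observed-data
    likelihood and the RB marginal prior at each permuted row, divides by the
    RB marginal posterior (the importance density), and averages.  ``J``
    defaults to the number of retained draws; ``n_rb`` bounds the number of
    conditioning draws in the RB averages (default 500).
    """
    rng = np.random.default_rng(seed)
    ret = {k: chains.retained(k) for k in ("mu_T", "sigma2", "mean_sigma2", "delta", "Delta")}
    st = {k: chains.retained_stats(k) for k in ("ssb", "ssw_k", "ssw", "ssb_d", "item_means")}
    M = ret["delta"].shape[0]
    J = M if J is None else min(J, M)
    R = min(500 if n_rb is None else n_rb, M)
    rb_idx = np.unique(np.linspace(0, M - 1, R).astype(int))
    blocks = model_blocks(spec)
    n_g = chains.n_g

    # permuted draw values per block
    block_vals: dict[tuple, np.ndarray] = {}
    for block in blocks:
        idx = rng.permutation(M)[:J]
        kind, which = block
        if kind == "xi":
            block_vals[block] = ret["mu_T"][idx, which]
        elif kind == "sigma2":
            block_vals[block] = ret["sigma2"][idx, which]
        elif kind == "delta":
            block_vals[block] = ret["delta"][idx, which]
        elif kind == "Delta" and spec.tie_layers_across_groups:
            block_vals[block] = ret["Delta"][idx, 0, which]
        else:
            g, d = which
            block_vals[block] = ret["Delta"][idx, g, d]

    # log importance density and log prior, block by block
    log_den = np.zeros(J)
    log_prior = np.zeros(J)
    for block in blocks:
        vals = block_vals[block]
        if block[0] == "xi":
            log_den += _rb_xi_logpdf(vals, spec, block[1], ret, st, n_g, rb_idx)
            continue  # flat prior: constant 1 (cancels in BFs)
        post, pri = _cov_block_params(spec, block, ret, st, n_g, rb_idx)
        log_den += _rb_tsig_logpdf(vals, post)
        log_prior += _rb_tsig_logpdf(vals, pri)

    # observed-data log-likelihood at the permuted joint draws
    patterns = _observed_patterns(data)
    loglik = np.empty(J)
    D = spec.n_layers
    for j in range(J):
        Delta = np.zeros((spec.n_groups, D))
        for block in blocks:
            if block[0] != "Delta":
                continue
            if spec.tie_layers_across_groups:
                Delta[:, block[1]] = block_vals[block][j]
            else:
                g, d = block[1]
                Delta[g, d] = block_vals[block][j]
        state = ChainState(
            mu_T=np.stack([block_vals[("xi", g)][j] for g in range(spec.n_groups)]),
            sigma2=np.stack([block_vals[("sigma2", g)][j] for g in range(spec.n_groups)]),
            mean_sigma2=ret["mean_sigma2"][0],
            delta=np.array([block_vals[("delta", g)][j] for g in range(spec.n_groups)]),
            Delta=Delta,
        )
        try:
            loglik[j] = _loglik_at(spec, patterns, state)
        except np.linalg.LinAlgError:
            loglik[j] = -np.inf  # permuted combination outside the PD region
    if not np.any(np.isfinite(log_den)):
        raise ValueError("importance density vanished at every permuted draw")
    # A permuted covariance value can fall below the truncation point of every
    # conditioning draw; prior and posterior conditionals share that
    # truncation, so both RB densities underflow together.  Such a row lies
    # outside the estimated importance-density support and carries no weight.
    outside = np.isneginf(log_den) & np.isneginf(log_prior)
    if outside.mean() > 0.05:
        raise ValueError(
            f"{int(outside.sum())} of {J} permuted draws fell outside the "
            "estimated importance-density support; increase n_rb or J"
        )
    if outside.any():
        keep = ~outside
        inner = log_marginal_from_weights(loglik[keep], log_prior[keep], log_den[keep])
        return float(inner + np.log(keep.mean()))
    return log_marginal_from_weights(loglik, log_prior, log_den)


def restrict_layers(spec: ModelSpec, names) -> ModelSpec:
    """Null-model spec with the named covariance layers fixed to zero
    (removed from the estimand set and from the covariance structure)."""
    names = {names} if isinstance(names, str) else set(names)
    unknown = names - {layer.name for layer in spec.layers}
    if unknown:
        raise ValueError(f"unknown layer(s): {sorted(unknown)}")
    from dataclasses import replace

    return replace(spec, layers=tuple(l for l in spec.layers if l.name not in names))


def bf_delta_restriction(
    data: RTDataset,
    spec_alt: ModelSpec,
    spec_null: ModelSpec,
    chains_alt: PosteriorChains | None = None,
    chains_null: PosteriorChains | None = None,
    iterations: int = 3000,
    burn_in: float = 0.1,
    J: int | None = None,
    n_rb: int | None = None,
    seed: int = 0,
) -> EvidenceResult:
    """log Bayes factor of the unrestricted model against a point-null
    restriction (prior odds excluded).  Null chains are refit if not given."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    if chains_alt is None:
        chains_alt = run_chain(data, spec_alt, iterations, burn_in, seed=int(sub[0]))
    if chains_null is None:
        chains_null = run_chain(data, spec_null, iterations, burn_in, seed=int(sub[1]))
    lm_alt = log_marginal_likelihood(data, spec_alt, chains_alt, J=J, n_rb=n_rb, seed=int(sub[2]))
    lm_null = log_marginal_likelihood(data, spec_null, chains_null, J=J, n_rb=n_rb, seed=int(sub[3]))
    result = EvidenceResult(
        log_marginal={"alt": lm_alt, "null": lm_null},
        log_bf={("alt", "null"): lm_alt - lm_null},
        n_importance=J or chains_alt.n_retained,
        parameter_blocks={
            "alt": model_blocks(spec_alt),
            "null": model_blocks(spec_null),
        },
    )
    return result


# --------------------------------------------------------------------------
# BIC
# --------------------------------------------------------------------------
def count_free_parameters(spec: ModelSpec) -> int:
    """Fixed effects plus free covariance-matrix parameters."""
    G, p, D = spec.n_groups, spec.n_items, spec.n_layers
    fixed = G * p
    sig = G * p - len(spec.tied_sigma2_items) * (G - 1)
    deltas = G
    layers = D if spec.tie_layers_across_groups else D * G
    return fixed + sig + deltas + layers


def bic(data: RTDataset, spec: ModelSpec, chains: PosteriorChains) -> BICResult:
    """BIC = −2·log L̂ + d·log(N*) at the posterior means, N* = p·N."""
    from .suffstats import marginal_loglik

    means = chains.posterior_means()
    structures = {}
    state = ChainState(
        mu_T=means["mu_T"],
        sigma2=means["sigma2"],
        mean_sigma2=means["mean_sigma2"],
        delta=means["delta"],
        Delta=means["Delta"],
    )
    for g in range(spec.n_groups):
        structures[g] = group_structure(spec, state, g)
    ll = marginal_loglik(data, means["mu_T"], structures)
    d = count_free_parameters(spec)
    n_star = data.p * data.N
    return BICResult(
        bic=float(-2.0 * ll + d * np.log(n_star)), loglik_hat=float(ll), d=d, n_star=n_star
    )


def bf_from_bic(bic0, bic1) -> float:
    """BF_01 ≈ exp(−(BIC_0 − BIC_1)/2)."""
    return float(np.exp(-(float(bic0) - float(bic1)) / 2.0))
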