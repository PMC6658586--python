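"""Additive covariance structures: Σ = diag(σ²) + Σ_d ψ_d v_d v_dᵀ.

A BCSM covariance matrix is a stack of rank-one layers on top of a diagonal
of measurement-error variances.  The first layer is the all-ones "speed"
layer with parameter δ (heterogeneous compound symmetry); further layers
carry testlet or cross-testlet covariance parameters Δ_d with 0/1 membership
design vectors, or real-valued loading vectors.

Layers are applied in declared order.  Each layer's positive-definiteness
(PD) bound is conditional on the layers below it: if A_d is PD, then
A_{d+1} = A_d + ψ v vᵀ is PD iff 1 + ψ vᵀ A_d⁻¹ v > 0, i.e.
ψ > −1/(vᵀ A_d⁻¹ v).  This Sherman–Morrison denominator is the operative PD
test throughout (eigenvalue checks live only in the test suite), and the same
recursion yields the inverse and log-determinant in O(p²) per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerSpec",
    "CovarianceStructure",
    "PositiveDefiniteError",
    "build_matrix",
    "pd_lower_bound",
    "inverse_and_logdet",
    "validate",
    "compound_symmetry",
]


class PositiveDefiniteError(ValueError):
    """A layer parameter sits at or below its PD lower bound."""


@dataclass
class LayerSpec:
    """One additive covariance layer ψ · v vᵀ.

    vector     : length-p design vector (0/1 for membership, real for loadings)
    param_name : label of the covariance parameter
    value      : current value of ψ (squared log-seconds)
    """

    vector: np.ndarray
    param_name: str = "psi"
    value: float = 0.0

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.ndim != 1:
            raise ValueError("design vector must be one-dimensional")
        if not np.any(self.vector != 0):
            raise ValueError(f"design vector of layer {self.param_name!r} is all-zero")


@dataclass
class CovarianceStructure:
    """Item variances plus an ordered list of additive layers.

    By convention the first layer is the all-ones speed layer (value δ);
    that convention is checked by :func:`validate` but not forced here, so
    partial structures (layers below a given layer) can be represented too.
    """

    sigma2: np.ndarray
    layers: list[LayerSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.sigma2.ndim != 1:
            raise ValueError("sigma2 must be a vector")

    @property
    def p(self) -> int:
        return self.sigma2.shape[0]


def build_matrix(cs: CovarianceStructure) -> np.ndarray:
    """Dense p×p matrix diag(σ²) + Σ_d ψ_d v_d v_dᵀ."""
    out = np.diag(cs.sigma2).astype(float)
    for layer in cs.layers:
        if layer.vector.shape[0] != cs.p:
            raise ValueError(
                f"layer {layer.param_name!r} has length {layer.vector.shape[0]}, "
                f"expected {cs.p}"
            )
        out += layer.value * np.outer(layer.vector, layer.vector)
    return out


def _sm_inverse(cs: CovarianceStructure) -> tuple[np.ndarray, float]:
    """Sherman–Morrison recursion over layers: (inverse, logdet).

    Raises :class:`PositiveDefiniteError` naming the first offending layer.
    """
    if np.any(cs.sigma2 <= 0):
        raise PositiveDefiniteError(f"non-positive sigma2 entries: {cs.sigma2}")
    inv = np.diag(1.0 / cs.sigma2)
    logdet = float(np.sum(np.log(cs.sigma2)))
    for layer in cs.layers:
        v = layer.vector
        if v.shape[0] != cs.p:
            raise ValueError(
                f"layer {layer.param_name!r} has length {v.shape[0]}, expected {cs.p}"
            )
        w = inv @ v
        denom = 1.0 + layer.value * float(v @ w)
        if denom <= 0.0:
            raise PositiveDefiniteError(
                f"layer {layer.param_name!r} violates positive definiteness: "
                f"1 + psi*v'A^-1 v = {denom:.3e} <= 0 "
                f"(psi = {layer.value}, bound = {-1.0 / float(v @ w):.6g})"
            )
        inv = inv - (layer.value / denom) * np.outer(w, w)
        logdet += np.log(denom)
    return inv, logdet


def inverse_and_logdet(cs: CovarianceStructure) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant via recursive rank-one updates.

    The determinant recursion is the matrix-determinant lemma:
    logdet(A_{d+1}) = logdet(A_d) + log(1 + ψ vᵀ A_d⁻¹ v).
    """
    return _sm_inverse(cs)


def pd_lower_bound(cs_below: CovarianceStructure, v: np.ndarray) -> float:
    """PD lower bound −1/(vᵀ A⁻¹ v) for a new layer on top of ``cs_below``.

    Any ψ strictly above the returned bound keeps the extended matrix
    positive definite.  For the base speed layer (``cs_below`` diagonal,
    v = 1) this is −1/Σ(1/σ²_k).
    """
    v = np.asarray(v, dtype=float)
    inv, _ = _sm_inverse(cs_below)
    quad = float(v @ inv @ v)
    if quad <= 0:
        raise PositiveDefiniteError("v' A^-1 v <= 0: structure below is not PD")
    return -1.0 / quad


def validate(cs: CovarianceStructure) -> list[str]:
    """Diagnostic check; returns a list of violations (empty iff usable).

    Checks: positive σ², non-duplicate design vectors, a base all-ones first
    layer, and the layer-by-layer PD bounds in declared order.
    """
    violations: list[str] = []
    if np.any(cs.sigma2 <= 0):
        bad = np.flatnonzero(cs.sigma2 <= 0) + 1
        violations.append(f"sigma2 must be positive; offending items {bad.tolist()}")
    for d, layer in enumerate(cs.layers):
        if layer.vector.shape[0] != cs.p:
            violations.append(
                f"layer {layer.param_name!r} has length {layer.vector.shape[0]}, "
                f"expected {cs.p}"
            )
            return violations
    for a in range(len(cs.layers)):
        for b in range(a + 1, len(cs.layers)):
            if np.array_equal(cs.layers[a].vector, cs.layers[b].vector):
                violations.append(
                    "design vectors must be mutually distinct: layers "
                    f"{cs.layers[a].param_name!r} and {cs.layers[b].param_name!r} coincide"
                )
    if cs.layers and not np.all(cs.layers[0].vector == 1.0):
        violations.append("first layer must be the all-ones speed layer")
    if violations:
        return violations
    # PD bounds, each conditional on the layers below it.
    below = CovarianceStructure(cs.sigma2, [])
    for layer in cs.layers:
        try:
            bound = pd_lower_bound(below, layer.vector)
        except PositiveDefiniteError as exc:  # pragma: no cover - defensive
            violations.append(str(exc))
            return violations
        if layer.value <= bound:
            violations.append(
                f"layer {layer.param_name!r}: value {layer.value} is at or below "
                f"its PD lower bound {bound:.6g}"
            )
            return violations
        below = CovarianceStructure(cs.sigma2, below.layers + [layer])
    return violations


def compound_symmetry(sigma2: np.ndarray, delta: float) -> CovarianceStructure:
    """Convenience: diag(σ²) + δ·J, the base of every response-time BCSM."""
    sigma2 = np.asarray(sigma2, dtype=float)
    base = LayerSpec(np.ones_like(sigma2), "delta", delta)
    return CovarianceStructure(sigma2, [base])
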