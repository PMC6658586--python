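"""Readers, writers and run configuration.

Data travel as delimited text in long format (columns person, group, item,
rt or log_rt, optional missing flag; 1-based ids), model/run configuration
as YAML or JSON, chains as CSV with a JSON sidecar carrying full provenance
(seed, burn-in, config digest), and evidence reports as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covstruct import CovarianceStructure, LayerSpec, validate
from .sampler import LayerDesign, ModelSpec, PosteriorChains, PriorHyper, vague_prior
from .suffstats import RTDataset, log_transform

__all__ = [
    "RunConfig",
    "read_dataset",
    "read_wide_dataset",
    "read_model_config",
    "write_dataset",
    "write_chains",
    "write_summary",
    "write_evidence",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    data_path: str | None = None
    time_scale: str = "log"
    iterations: int = 2000
    burn_in: float = 0.1
    seed: int = 0
    J: int | None = None
    n_rb: int | None = 500
    out_dir: str | None = None
    extra: dict = field(default_factory=dict)

    def digest(self, spec: ModelSpec | None = None) -> str:
        payload = asdict(self)
        if spec is not None:
            payload["model"] = _spec_to_dict(spec)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_dataset(path, time_scale: str = "log") -> RTDataset:
    """Read a long-format response-time table (CSV).

    Requires columns person, group, item and either ``log_rt`` or ``rt``;
    raw times in seconds (``time_scale="seconds"`` or an ``rt`` column) are
    log-transformed on ingest and must be positive.
    """
    df = pd.read_csv(path)
    if time_scale not in ("log", "seconds"):
        raise ValueError(f"unknown time_scale {time_scale!r}")
    if time_scale == "seconds" or ("rt" in df.columns and "log_rt" not in df.columns):
        if "rt" not in df.columns:
            raise ValueError("time_scale='seconds' requires an 'rt' column")
        df = df.copy()
        observed = (
            ~df["missing"].astype(bool)
            if "missing" in df.columns
            else np.ones(len(df), dtype=bool)
        )
        bad = observed & ~(df["rt"] > 0)
        if bad.any():
            keys = df.loc[bad, ["person", "item"]].to_records(index=False).tolist()
            raise ValueError(f"non-positive response times for (person, item): {keys}")
        df["log_rt"] = np.where(observed, log_transform(df["rt"].where(observed, 1.0)), np.nan)
    return RTDataset.from_long(df, value_col="log_rt")


def read_wide_dataset(path, group_col: str = "group") -> RTDataset:
    """Convenience reader for a wide person×item matrix (one row per person,
    a group column, item columns named by item id); blanks are missing."""
    df = pd.read_csv(path)
    if group_col not in df.columns:
        raise ValueError(f"wide table needs a {group_col!r} column")
    item_cols = [c for c in df.columns if c != group_col]
    values = df[item_cols].to_numpy(dtype=float)
    groups = sorted(df[group_col].unique().tolist())
    g_idx = {g: i for i, g in enumerate(groups)}
    return RTDataset(
        values=values,
        group_index=df[group_col].map(g_idx).to_numpy(),
        group_ids=groups,
        item_ids=item_cols,
    )


def write_dataset(data: RTDataset, path) -> None:
    data.to_long().to_csv(path, index=False)


# --------------------------------------------------------------------------
# model configuration
# --------------------------------------------------------------------------
def _spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "items": spec.n_items,
        "groups": spec.n_groups,
        "layers": [
            {"name": l.name, "vectors": l.vectors.astype(int).tolist()}
            for l in spec.layers
        ],
        "prior": {"alpha0": spec.prior.alpha0, "beta0": spec.prior.beta0},
        "tie_layers_across_groups": spec.tie_layers_across_groups,
        "tie_sigma2_items": [k + 1 for k in spec.tied_sigma2_items],
        "identification": spec.identification,
    }


def _spec_from_dict(cfg: dict) -> ModelSpec:
    def fail(path, msg):
        raise ValueError(f"model config error at {path}: {msg}")

    if "items" not in cfg:
        fail("model.items", "missing")
    p = int(cfg["items"])
    n_groups = int(cfg.get("groups", 1))
    layers = []
    for i, entry in enumerate(cfg.get("layers", [])):
        if "name" not in entry or "vectors" not in entry:
            fail(f"model.layers[{i}]", "each layer needs 'name' and 'vectors'")
        vectors = np.atleast_2d(np.asarray(entry["vectors"], dtype=float))
        if vectors.shape[1] != p:
            fail(f"model.layers[{i}].vectors", f"vector length {vectors.shape[1]} != items {p}")
        layers.append(LayerDesign(entry["name"], vectors))
    prior_cfg = cfg.get("prior", {})
    if "alpha0" in prior_cfg or "beta0" in prior_cfg:
        prior = PriorHyper(float(prior_cfg.get("alpha0", 1e-8)), float(prior_cfg.get("beta0", 1e-8)))
    else:
        prior = vague_prior(float(prior_cfg.get("shape", 1e-8)), float(prior_cfg.get("scale", 1e8)))
    tied = tuple(int(k) - 1 for k in cfg.get("tie_sigma2_items", []))
    identification = cfg.get("identification", "first_group_zero")
    try:
        return ModelSpec(
            n_items=p,
            n_groups=n_groups,
            layers=tuple(layers),
            prior=prior,
            tie_layers_across_groups=bool(cfg.get("tie_layers_across_groups", False)),
            tied_sigma2_items=tied,
            identification=identification,
        )
    except ValueError as exc:
        raise ValueError(f"model config error: {exc}") from exc


def read_model_config(path) -> tuple[ModelSpec, RunConfig]:
    """Parse a YAML/JSON run configuration into (ModelSpec, RunConfig).

    The model's design-vector distinctness is validated on parse; schema
    violations raise with a path-to-field message.  A missing identification
    block falls back to the default (equal mean intensities, μ_ζ1 = 0).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "model" not in cfg:
        raise ValueError("config must be a mapping with a 'model' section")
    spec = _spec_from_dict(cfg["model"])
    mcmc = cfg.get("mcmc", {})
    ev = cfg.get("evidence", {})
    run = RunConfig(
        data_path=cfg.get("data"),
        time_scale=cfg.get("time_scale", "log"),
        iterations=int(mcmc.get("iterations", 2000)),
        burn_in=float(mcmc.get("burn_in", 0.1)),
        seed=int(mcmc.get("seed", 0)),
        J=ev.get("J"),
        n_rb=ev.get("n_rb", 500),
        out_dir=cfg.get("out"),
    )
    return spec, run


def validate_config_structure(spec: ModelSpec, sigma2=None) -> list[str]:
    """Run the covariance-structure diagnostics on the declared design with
    neutral values (σ² = 1, small positive layer values)."""
    out = []
    for g in range(spec.n_groups):
        mat = spec.layer_matrix(g)
        layers = [LayerSpec(np.ones(spec.n_items), "delta", 0.1)]
        layers += [LayerSpec(mat[d], spec.layers[d].name, 0.01) for d in range(mat.shape[0])]
        s2 = np.ones(spec.n_items) if sigma2 is None else np.asarray(sigma2, float)
        out += [f"group {g + 1}: {v}" for v in validate(CovarianceStructure(s2, layers))]
    return out


# --------------------------------------------------------------------------
# outputs
# --------------------------------------------------------------------------
def _sidecar(path: Path, payload: dict) -> None:
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(payload, indent=2, default=str)
    )


def chains_frame(chains: PosteriorChains) -> pd.DataFrame:
    """One column per identified parameter, one row per retained iteration."""
    cols = {}
    for name in ("lam", "mu_zeta", "sigma2", "mean_sigma2", "delta", "Delta"):
        draws = chains.retained(name)
        flat = draws.reshape(draws.shape[0], -1)
        shape = draws.shape[1:]
        for j in range(flat.shape[1]):
            idx = np.unravel_index(j, shape) if shape else ()
            label = name + "".join(f"[{i + 1}]" for i in idx)
            cols[label] = flat[:, j]
    return pd.DataFrame(cols)


def write_chains(chains: PosteriorChains, path, run: RunConfig | None = None) -> None:
    path = Path(path)
    chains_frame(chains).to_csv(path, index=False)
    run = run or RunConfig(seed=chains.seed, iterations=chains.n_iterations)
    _sidecar(
        path,
        {
            "seed": chains.seed,
            "iterations": chains.n_iterations,
            "burn_in": chains.burn_in,
            "config_digest": run.digest(chains.spec),
            "model": _spec_to_dict(chains.spec),
        },
    )


def write_summary(chains: PosteriorChains, path, level: float = 0.95) -> None:
    path = Path(path)
    chains.summary(level).to_csv(path, index=False)
    _sidecar(path, {"seed": chains.seed, "level": level})


def write_evidence(result, path, run: RunConfig | None = None) -> None:
    path = Path(path)
    payload = {
        "log_marginal": result.log_marginal,
        "log_bf": {f"{a}_vs_{b}": v for (a, b), v in result.log_bf.items()},
        "bic": {k: float(v) for k, v in result.bic.items()},
        "J": result.n_importance,
        "parameter_blocks": {
            k: [str(b) for b in v] for k, v in result.parameter_blocks.items()
        },
    }
    if run is not None:
        payload["seed"] = run.seed
        payload["config_digest"] = run.digest()
    path.write_text(json.dumps(payload, indent=2))
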