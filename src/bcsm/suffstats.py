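"""Response-time data container and sufficient statistics.

The Gibbs sampler never touches individual observations when updating
(co)variance parameters: everything flows through between- and within-person
sums of squares.  For a group g with n_g persons and p items,

    SSB        = Σ_i (T̄_ig· − T̄_·g·)²          — drives δ_g
    SSW_k      = Σ_i (T_igk − T̄_·gk)²           — drives σ²_gk
    SSW        = Σ_i Σ_k (T_igk − T̄_·gk)²       — drives the mean variance σ̄²_g
    SSB_layer  = Σ_i (layer mean_i − layer grand mean)²  — drives a layer's Δ

where means are over complete (post-imputation) data.  The log-likelihood of
the person means is a univariate normal in SSB with variance σ̄²/p + δ, which
is what makes the truncated shifted inverse-gamma conjugate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covstruct import CovarianceStructure, inverse_and_logdet

__all__ = [
    "RTDataset",
    "log_transform",
    "ssb",
    "ssw",
    "ssb_layer",
    "person_mean_loglik",
    "marginal_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class RTDataset:
    """Long-format log response times in a wide internal layout.

    values      : (N, p) array of log response times (log-seconds), NaN where missing
    missing     : (N, p) boolean mask of missing-at-random entries
    group_index : (N,) integer group codes, 0..G−1
    group_ids   : original group labels, length G
    person_ids  : original person labels, length N
    item_ids    : original item labels, length p (1..p by default)
    """

    values: np.ndarray
    group_index: np.ndarray
    group_ids: list = field(default_factory=list)
    person_ids: list = field(default_factory=list)
    item_ids: list = field(default_factory=list)
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be an (N, p) matrix")
        self.group_index = np.asarray(self.group_index, dtype=int)
        if self.group_index.shape != (self.values.shape[0],):
            raise ValueError("group_index must have one entry per person")
        if self.missing is None:
            self.missing = np.isnan(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask must match values in shape")
        bad = ~np.isfinite(self.values) & ~self.missing
        if np.any(bad):
            i, k = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value at person index {i}, item index {k} "
                "outside the missing mask"
            )
        if not self.group_ids:
            self.group_ids = sorted(set(self.group_index.tolist()))
        if not self.person_ids:
            self.person_ids = list(range(1, self.values.shape[0] + 1))
        if not self.item_ids:
            self.item_ids = list(range(1, self.values.shape[1] + 1))

    # -- shape accessors -------------------------------------------------
    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def G(self) -> int:
        return len(self.group_ids)

    @property
    def n_g(self) -> np.ndarray:
        return np.bincount(self.group_index, minlength=self.G)

    def group_rows(self, g: int) -> np.ndarray:
        """Row indices of group code g (0-based)."""
        return np.flatnonzero(self.group_index == g)

    def group_values(self, g: int) -> np.ndarray:
        return self.values[self.group_rows(g)]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing.any())

    # -- construction ----------------------------------------------------
    @classmethod
    def from_long(cls, df: pd.DataFrame, value_col: str = "log_rt") -> "RTDataset":
        """Build from a long table with columns person, group, item, <value_col>
        and an optional 0/1 ``missing`` column."""
        required = {"person", "group", "item", value_col}
        if not required.issubset(df.columns):
            raise ValueError(f"long table must have columns {sorted(required)}")
        dup = df.duplicated(subset=["person", "item"])
        if dup.any():
            key = df.loc[dup, ["person", "item"]].iloc[0].tolist()
            raise ValueError(f"duplicate (person, item) record: {key}")
        pg = df.groupby("person")["group"].nunique()
        if (pg > 1).any():
            raise ValueError(
                f"persons in more than one group: {pg.index[pg > 1].tolist()}"
            )
        persons = sorted(df["person"].unique().tolist())
        items = sorted(df["item"].unique().tolist())
        groups = sorted(df["group"].unique().tolist())
        p_idx = {v: i for i, v in enumerate(persons)}
        i_idx = {v: i for i, v in enumerate(items)}
        g_idx = {v: i for i, v in enumerate(groups)}
        values = np.full((len(persons), len(items)), np.nan)
        missing = np.ones_like(values, dtype=bool)
        rows = df["person"].map(p_idx).to_numpy()
        cols = df["item"].map(i_idx).to_numpy()
        vals = df[value_col].to_numpy(dtype=float)
        miss = (
            df["missing"].to_numpy(dtype=bool)
            if "missing" in df.columns
            else np.zeros(len(df), dtype=bool)
        )
        values[rows, cols] = np.where(miss, np.nan, vals)
        missing[rows, cols] = miss
        group_index = (
            df.drop_duplicates("person").set_index("person")["group"].loc[persons]
        )
        return cls(
            values=values,
            group_index=np.array([g_idx[g] for g in group_index]),
            group_ids=groups,
            person_ids=persons,
            item_ids=items,
            missing=missing,
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, pid in enumerate(self.person_ids):
            g = self.group_ids[self.group_index[i]]
            for k, iid in enumerate(self.item_ids):
                rows.append(
                    {
                        "person": pid,
                        "group": g,
                        "item": iid,
                        "log_rt": self.values[i, k],
                        "missing": int(self.missing[i, k]),
                    }
                )
        return pd.DataFrame(rows)


def log_transform(raw_times) -> np.ndarray:
    """Natural log of raw response times in seconds; rejects t <= 0."""
    raw = np.asarray(raw_times, dtype=float)
    bad = ~(raw > 0) & ~np.isnan(raw)
    if np.any(bad):
        raise ValueError(
            f"response times must be positive; offending entries at {np.argwhere(bad).tolist()}"
        )
    return np.log(raw)


def _complete_group(data: RTDataset, group: int) -> np.ndarray:
    rows = data.group_rows(group)
    if rows.size == 0:
        raise ValueError(f"group {group} is empty")
    vals = data.values[rows]
    if np.isnan(vals).any():
        raise ValueError(
            f"group {group} contains missing values; impute before computing statistics"
        )
    return vals


def ssb(data: RTDataset, group: int) -> float:
    """Between sum of squares of person means within the group."""
    vals = _complete_group(data, group)
    pm = vals.mean(axis=1)
    return float(np.sum((pm - pm.mean()) ** 2))


def ssw(data: RTDataset, group: int, item="all"):
    """Within sum of squares: per item, or the total over items ("all")."""
    vals = _complete_group(data, group)
    dev2 = (vals - vals.mean(axis=0)) ** 2
    if isinstance(item, str) and item == "all":
        return float(dev2.sum())
    return float(dev2[:, int(item)].sum())


def ssb_layer(data: RTDataset, group: int, layer) -> float:
    """Between sum of squares of per-person means over a layer's items.

    ``layer`` is a LayerSpec or a 0/1 membership vector.  Centering is at the
    grand mean over the layer's items within the group (not the overall grand
    mean).  Reduces to :func:`ssb` when the layer covers all items.
    """
    vector = np.asarray(getattr(layer, "vector", layer), dtype=float)
    members = np.flatnonzero(vector != 0)
    if members.size == 0:
        raise ValueError("layer has no member items")
    vals = _complete_group(data, group)[:, members]
    pm = vals.mean(axis=1)
    return float(np.sum((pm - pm.mean()) ** 2))


def person_mean_loglik(
    data: RTDataset, group: int, mean_sigma2: float, delta: float
) -> float:
    """Log-likelihood of the group's person means given (σ̄², δ).

    The person means are iid normal with variance σ̄²/p + δ, so the
    log-likelihood is −(n/2)·log(2pπ) − (n/2)·log(σ̄²/p + δ) − (SSB/2)/(σ̄²/p + δ).
    """
    vals = _complete_group(data, group)
    n, p = vals.shape
    var = mean_sigma2 / p + delta
    if var <= 0:
        raise ValueError(f"variance of person means must be positive, got {var}")
    ssb_val = float(np.sum((vals.mean(axis=1) - vals.mean()) ** 2))
    return -0.5 * n * np.log(2.0 * p * np.pi) - 0.5 * n * np.log(var) - 0.5 * ssb_val / var


def _group_loglik_complete(
    vals: np.ndarray, mu: np.ndarray, cs: CovarianceStructure
) -> float:
    inv, logdet = inverse_and_logdet(cs)
    n, p = vals.shape
    centered = vals - mu
    quad = float(np.einsum("ij,jk,ik->", centered, inv, centered))
    return -0.5 * (n * (p * _LOG2PI + logdet) + quad)


def marginal_loglik(
    data: RTDataset,
    means: dict | list,
    structures: dict | list,
) -> float:
    """Full multivariate-normal log-likelihood of the observed log times.

    ``means`` and ``structures`` map group codes 0..G−1 to the p-vector
    μ_Tg and the group's :class:`CovarianceStructure`.  Missing entries are
    handled by marginalizing each person's normal law to the observed
    coordinates (dense sub-matrix algebra per missing pattern); complete
    groups go through the Sherman–Morrison inverse.
    """
    total = 0.0
    for g in range(data.G):
        rows = data.group_rows(g)
        if rows.size == 0:
            continue
        mu = np.asarray(means[g], dtype=float)
        cs = structures[g]
        vals = data.values[rows]
        miss = data.missing[rows]
        if not miss.any():
            total += _group_loglik_complete(vals, mu, cs)
            continue
        sigma = None
        # group persons by missing pattern; complete persons use the recursion
        complete = ~miss.any(axis=1)
        if complete.any():
            total += _group_loglik_complete(vals[complete], mu, cs)
        patt = {}
        for idx in np.flatnonzero(~complete):
            patt.setdefault(miss[idx].tobytes(), []).append(idx)
        for key, members in patt.items():
            obs = ~np.frombuffer(key, dtype=bool)
            if not obs.any():
                continue  # fully missing person: no observed-data contribution
            if sigma is None:
                from .covstruct import build_matrix

                sigma = build_matrix(cs)
            sub = sigma[np.ix_(obs, obs)]
            sign, logdet = np.linalg.slogdet(sub)
            if sign <= 0:
                raise ValueError("observed-coordinate covariance is not PD")
            inv = np.linalg.inv(sub)
            centered = vals[np.ix_(members, np.flatnonzero(obs))] - mu[obs]
            quad = float(np.einsum("ij,jk,ik->", centered, inv, centered))
            q = int(obs.sum())
            total += -0.5 * (len(members) * (q * _LOG2PI + logdet) + quad)
    return float(total)
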