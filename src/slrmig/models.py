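"""Migration-probability models, production functions, flow matrices, evaluation.

Three interchangeable models map an origin and its allowed destination set to
a probability row ``P_ij`` (the chance a migrant leaving origin ``i`` settles
in destination ``j``):

* :class:`RadiationModel` — the parameter-free radiation model, whose
  unnormalised weight is ``m_i m_j / ((m_i + s_ij)(m_i + m_j + s_ij))``;
* :class:`ExtendedRadiationModel` — its one-parameter (``alpha``)
  generalisation, better behaved across spatial scales;
* :class:`NeuralMigrationModel` — a trainable fully-connected scorer over the
  same four features, fit to observed per-origin flow shares.

Rows are normalised over the destination set actually offered (a closed
system: every migrant who leaves settles somewhere in the allowed universe),
replacing the open-system radiation normalisation.  Flows are then
``T_ij = g(m_i) P_ij`` where ``g(m) = alpha * m`` is the production function —
identity (``alpha = 1``) for forced climate migration, 3% per year for
business-as-usual migration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ProductionFunction",
    "CLIMATE_PRODUCTION",
    "BAU_PRODUCTION",
    "radiation_weights",
    "extended_radiation_weights",
    "MigrationModel",
    "RadiationModel",
    "ExtendedRadiationModel",
    "DistanceTiltedModel",
    "NeuralMigrationModel",
    "MigrationMatrix",
    "cpc",
    "validate_flow_table",
]


# ---------------------------------------------------------------------------
# production functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProductionFunction:
    """Linear production ``g(m) = rate * m``: migrants produced by a zone of population m."""

    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"production rate must be in [0, 1], got {self.rate}")

    def __call__(self, m) -> np.ndarray | float:
        m = np.asarray(m, dtype=float)
        if np.any(m < 0):
            raise ValueError("population must be nonnegative")
        out = self.rate * m
        return float(out) if out.ndim == 0 else out


#: Forced climate migration: the whole affected population moves.
CLIMATE_PRODUCTION = ProductionFunction(1.0)
#: Business as usual: 3% of a county's population migrates per year.
BAU_PRODUCTION = ProductionFunction(0.03)


# ---------------------------------------------------------------------------
# closed-form mobility weights
# ---------------------------------------------------------------------------


def radiation_weights(m_i, m_j, s) -> np.ndarray:
    """Unnormalised radiation-model weight ``m_i m_j / ((m_i+s)(m_i+m_j+s))``.

    Zero whenever the destination (or origin) population vanishes; the 0/0
    cases resolve to 0.
    """
    m_i, m_j, s = (np.asarray(x, dtype=float) for x in (m_i, m_j, s))
    denom = (m_i + s) * (m_i + m_j + s)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, (m_i * m_j) / np.where(denom > 0, denom, 1.0), 0.0)
    return w


def extended_radiation_weights(m_i, m_j, s, alpha: float) -> np.ndarray:
    """Unnormalised extended-radiation weight with scale exponent ``alpha > 0``.

    ``[( (m_i+m_j+s)^a - (m_i+s)^a ) (m_i^a + 1)] / [((m_i+s)^a + 1)((m_i+m_j+s)^a + 1)]``.
    As populations grow large at ``alpha = 1`` this approaches the plain
    radiation weight.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    m_i, m_j, s = (np.asarray(x, dtype=float) for x in (m_i, m_j, s))
    n = m_i + s
    m = m_i + m_j + s
    num = (np.power(m, alpha) - np.power(n, alpha)) * (np.power(m_i, alpha) + 1.0)
    den = (np.power(n, alpha) + 1.0) * (np.power(m, alpha) + 1.0)
    return np.maximum(num, 0.0) / den


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------


class MigrationModel:
    """Base class: maps a feature table to per-origin probability rows."""

    kind: str = "abstract"

    def predict_weights(self, feats: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, feats: pd.DataFrame) -> pd.Series:
        """Probability ``P_ij`` per feature row, normalised within each origin.

        Origins whose destinations all carry zero weight fall back to a
        uniform row (with a warning): a migrant who must leave goes somewhere.
        """
        w = np.asarray(self.predict_weights(feats), dtype=float)
        if (w < 0).any():
            raise ValueError("model produced negative weights")
        origin = feats["origin"].to_numpy()
        totals = pd.Series(w).groupby(origin).transform("sum").to_numpy()
        dead = totals <= 0
        if dead.any():
            warnings.warn("origin(s) with all-zero weights; falling back to uniform rows", stacklevel=2)
            counts = pd.Series(np.ones_like(w)).groupby(origin).transform("sum").to_numpy()
            w = np.where(dead, 1.0, w)
            totals = np.where(dead, counts, totals)
        return pd.Series(w / totals, index=feats.index, name="p")


@dataclass
class RadiationModel(MigrationModel):
    kind: str = field(default="radiation", init=False)

    def predict_weights(self, feats: pd.DataFrame) -> np.ndarray:
        return radiation_weights(feats["m_i"], feats["m_j"], feats["s"])


@dataclass
class ExtendedRadiationModel(MigrationModel):
    alpha: float = 0.5
    kind: str = field(default="extended_radiation", init=False)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    def predict_weights(self, feats: pd.DataFrame) -> np.ndarray:
        return extended_radiation_weights(feats["m_i"], feats["m_j"], feats["s"], self.alpha)


@dataclass
class DistanceTiltedModel(MigrationModel):
    """Wraps a base model with an exponential distance decay ``exp(-d/scale)``.

    Mimics forced displacement after an acute event, where destinations close
    to the origin are strongly preferred relative to ordinary migration.
    """

    base: MigrationModel
    scale_km: float = 200.0
    kind: str = field(default="distance_tilted", init=False)

    def __post_init__(self) -> None:
        if self.scale_km <= 0:
            raise ValueError("scale_km must be positive")

    def predict_weights(self, feats: pd.DataFrame) -> np.ndarray:
        w = np.asarray(self.base.predict_weights(feats), dtype=float)
        return w * np.exp(-feats["d_km"].to_numpy(float) / self.scale_km)


# ---------------------------------------------------------------------------
# neural scorer
# ---------------------------------------------------------------------------


def _featurize(feats: pd.DataFrame) -> np.ndarray:
    # log1p keeps zero populations / distances finite; the scorer is free-form
    return np.column_stack(
        [
            np.log1p(feats["m_i"].to_numpy(float)),
            np.log1p(feats["m_j"].to_numpy(float)),
            np.log1p(feats["d_km"].to_numpy(float)),
            np.log1p(feats["s"].to_numpy(float)),
        ]
    )


class NeuralMigrationModel(MigrationModel):
    """Fully-connected migration scorer trained on observed flow shares.

    Scores each (origin, destination) pair from (log m_i, log m_j, log d,
    log(1+s)), standardised; the probability row is the per-origin softmax of
    the scores.  Training minimises the multinomial cross-entropy between the
    softmax rows and observed per-origin flow shares (each origin weighted by
    its outflow), with full-batch Adam and early stopping on a held-out origin
    split.  All randomness (weight init, origin split) flows from ``seed``, so
    refitting with the same data and seed is bit-for-bit reproducible.
    """

    kind = "neural"

    def __init__(
        self,
        hidden: tuple[int, ...] = (64, 64),
        *,
        lr: float = 0.01,
        epochs: int = 800,
        seed: int = 0,
        val_fraction: float = 0.15,
        patience: int = 40,
        eval_every: int = 10,
    ) -> None:
        self.hidden = tuple(int(h) for h in hidden)
        self.lr = float(lr)
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.val_fraction = float(val_fraction)
        self.patience = int(patience)
        self.eval_every = int(eval_every)
        self._params: list[np.ndarray] | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    # -- forward / backward ------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> list[np.ndarray]:
        sizes = (4, *self.hidden, 1)
        params: list[np.ndarray] = []
        for n_in, n_out in zip(sizes, sizes[1:]):
            params.append(rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out)))
            params.append(np.zeros(n_out))
        return params

    @staticmethod
    def _forward(params: list[np.ndarray], X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        h = X
        n_layers = len(params) // 2
        for layer in range(n_layers):
            W, b = params[2 * layer], params[2 * layer + 1]
            z = h @ W + b
            h = np.tanh(z) if layer < n_layers - 1 else z
            acts.append(h)
        return h[:, 0], acts

    @staticmethod
    def _backward(params: list[np.ndarray], acts: list[np.ndarray], dscore: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = [np.empty(0)] * len(params)
        delta = dscore[:, None]
        n_layers = len(params) // 2
        for layer in reversed(range(n_layers)):
            W = params[2 * layer]
            h_in, h_out = acts[layer], acts[layer + 1]
            if layer < n_layers - 1:
                delta = delta * (1.0 - h_out**2)
            grads[2 * layer] = h_in.T @ delta
            grads[2 * layer + 1] = delta.sum(axis=0)
            delta = delta @ W.T
        return grads

    @staticmethod
    def _segment_softmax(scores: np.ndarray, seg_starts: np.ndarray) -> np.ndarray:
        # per-origin softmax over contiguous segments
        p = np.empty_like(scores)
        bounds = np.append(seg_starts, len(scores))
        for a, b in zip(bounds[:-1], bounds[1:]):
            s = scores[a:b]
            e = np.exp(s - s.max())
            p[a:b] = e / e.sum()
        return p

    # -- training ----------------------------------------------------------

    def fit(self, feats: pd.DataFrame, flows: pd.DataFrame) -> "NeuralMigrationModel":
        """Fit the scorer to a flow table joined against a feature table.

        ``flows`` needs columns origin, dest, migrants; pairs absent from the
        flow table are treated as observed zeros (the model must learn *not*
        to send migrants there).
        """
        flows = validate_flow_table(flows)
        if float(flows["migrants"].sum()) <= 0:
            raise ValueError("degenerate training set: all flows zero")
        df = feats.sort_values(["origin", "dest"], kind="stable").reset_index(drop=True)
        key = pd.MultiIndex.from_frame(df[["origin", "dest"]].astype(str))
        obs = flows.set_index(
            pd.MultiIndex.from_frame(flows[["origin", "dest"]].astype(str))
        )["migrants"]
        y = obs.reindex(key).fillna(0.0).to_numpy(float)

        origins = df["origin"].to_numpy()
        seg_starts = np.flatnonzero(np.r_[True, origins[1:] != origins[:-1]])
        origin_ids = origins[seg_starts]
        n_origins = len(origin_ids)
        # keep only origins with observed outflow and >= 2 destinations
        seg_bounds = np.append(seg_starts, len(df))
        seg_tot = np.add.reduceat(y, seg_starts)
        seg_len = np.diff(seg_bounds)
        usable = (seg_tot > 0) & (seg_len >= 2)
        if not usable.any():
            raise ValueError("no origin with positive outflow and >= 2 destinations")

        rng = np.random.default_rng(self.seed)
        order = rng.permutation(np.flatnonzero(usable))
        n_val = max(1, int(round(self.val_fraction * len(order)))) if len(order) > 3 else 0
        val_origins = set(origin_ids[order[:n_val]].tolist())
        train_mask_seg = np.zeros(n_origins, dtype=bool)
        train_mask_seg[order[n_val:]] = True
        val_mask_seg = np.zeros(n_origins, dtype=bool)
        val_mask_seg[order[:n_val]] = True

        X = _featurize(df)
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self._mu) / self._sd

        def subset(mask_seg: np.ndarray):
            rows = np.concatenate(
                [np.arange(seg_bounds[k], seg_bounds[k + 1]) for k in np.flatnonzero(mask_seg)]
            ) if mask_seg.any() else np.empty(0, dtype=int)
            Xm, ym = Xs[rows], y[rows]
            lens = seg_len[mask_seg]
            starts = np.r_[0, np.cumsum(lens)[:-1]]
            return Xm, ym, starts

        Xtr, ytr, str_tr = subset(train_mask_seg)
        Xva, yva, str_va = subset(val_mask_seg)
        wtot_tr = ytr.sum()

        params = self._init_params(rng)
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        best = [p.copy() for p in params]
        best_val = np.inf
        stale = 0

        def loss_on(Xm, ym, starts, ps) -> float:
            sc, _ = self._forward(ps, Xm)
            p = self._segment_softmax(sc, starts)
            tot = ym.sum()
            return float(-(ym * np.log(np.maximum(p, 1e-300))).sum() / max(tot, 1.0))

        for epoch in range(1, self.epochs + 1):
            scores, acts = self._forward(params, Xtr)
            p = self._segment_softmax(scores, str_tr)
            seg_totals = np.add.reduceat(ytr, str_tr)
            rep = np.repeat(seg_totals, np.diff(np.append(str_tr, len(ytr))))
            dscore = (p * rep - ytr) / wtot_tr
            grads = self._backward(params, acts, dscore)
            for k, g in enumerate(grads):
                m_t[k] = b1 * m_t[k] + (1 - b1) * g
                v_t[k] = b2 * v_t[k] + (1 - b2) * g * g
                mhat = m_t[k] / (1 - b1**epoch)
                vhat = v_t[k] / (1 - b2**epoch)
                params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            if len(Xva) and epoch % self.eval_every == 0:
                val = loss_on(Xva, yva, str_va, params)
                if val < best_val - 1e-6:
                    best_val = val
                    best = [p.copy() for p in params]
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        self._params = best if len(Xva) and best_val < np.inf else params
        self.val_origins_ = frozenset(val_origins)
        return self

    # -- prediction --------------------------------------------------------

    def predict_weights(self, feats: pd.DataFrame) -> np.ndarray:
        scores = self._scores(feats)
        # stable per-origin exponentiation; predict_proba renormalises anyway
        origin = feats["origin"].to_numpy()
        mx = pd.Series(scores).groupby(origin).transform("max").to_numpy()
        return np.exp(scores - mx)

    def _scores(self, feats: pd.DataFrame) -> np.ndarray:
        if self._params is None:
            raise ValueError("neural model is not fitted")
        X = (_featurize(feats) - self._mu) / self._sd
        scores, _ = self._forward(self._params, X)
        return scores

    # -- persistence (plain JSON; float repr round-trips exactly) ----------

    def to_json(self) -> str:
        if self._params is None:
            raise ValueError("neural model is not fitted")
        payload = {
            "kind": self.kind,
            "hidden": list(self.hidden),
            "seed": self.seed,
            "mu": self._mu.tolist(),
            "sd": self._sd.tolist(),
            "params": [p.tolist() for p in self._params],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "NeuralMigrationModel":
        payload = json.loads(text)
        model = cls(hidden=tuple(payload["hidden"]), seed=payload["seed"])
        model._mu = np.asarray(payload["mu"], dtype=float)
        model._sd = np.asarray(payload["sd"], dtype=float)
        model._params = [np.asarray(p, dtype=float) for p in payload["params"]]
        return model


# ---------------------------------------------------------------------------
# flow tables and migration matrices
# ---------------------------------------------------------------------------


def validate_flow_table(flows: pd.DataFrame) -> pd.DataFrame:
    """Validate an IRS-style flow table (origin_id, dest_id, migrants[, year])."""
    rename = {"origin_id": "origin", "dest_id": "dest"}
    flows = flows.rename(columns=rename)
    for col in ("origin", "dest", "migrants"):
        if col not in flows.columns:
            raise ValueError(f"flow table missing column {col!r}")
    df = flows.copy()
    df["origin"] = df["origin"].astype(str)
    df["dest"] = df["dest"].astype(str)
    neg = df.index[df["migrants"] < 0]
    if len(neg):
        raise ValueError(f"negative migrant counts at rows {neg.tolist()}")
    keys = ["origin", "dest"] + (["year"] if "year" in df.columns else [])
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = tuple(
            v.item() if isinstance(v, np.generic) else v for v in df.loc[dup, keys].iloc[0]
        )
        raise ValueError(f"duplicate flow key {first}")
    return df


@dataclass
class MigrationMatrix:
    """Sparse nonnegative origin->destination flow matrix for one year/component.

    ``data`` is a Series over a (origin, dest) MultiIndex.  Supports entrywise
    addition (climate + business-as-usual aggregation) and county roll-ups.
    """

    data: pd.Series
    label: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.nlevels != 2:
            raise ValueError("MigrationMatrix needs a (origin, dest) MultiIndex")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.set_names(["origin", "dest"])
        if (self.data < 0).any():
            raise ValueError("negative flows")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "", year: int | None = None) -> "MigrationMatrix":
        df = validate_flow_table(df)
        data = df.set_index(["origin", "dest"])["migrants"]
        return cls(data, label=label, year=year)

    @classmethod
    def empty(cls, label: str = "", year: int | None = None) -> "MigrationMatrix":
        idx = pd.MultiIndex.from_arrays([[], []], names=["origin", "dest"])
        return cls(pd.Series([], index=idx, dtype=float), label=label, year=year)

    def total(self) -> float:
        return float(self.data.sum())

    def row_sums(self) -> pd.Series:
        return self.data.groupby(level="origin").sum()

    def col_sums(self) -> pd.Series:
        return self.data.groupby(level="dest").sum()

    def add(self, other: "MigrationMatrix", label: str = "") -> "MigrationMatrix":
        combined = self.data.add(other.data, fill_value=0.0)
        if self.year is not None and other.year is not None and self.year != other.year:
            raise ValueError(f"cannot aggregate matrices for different years ({self.year} vs {other.year})")
        return MigrationMatrix(combined, label=label or f"{self.label}+{other.label}", year=self.year or other.year)

    def to_frame(self) -> pd.DataFrame:
        df = self.data.rename("migrants").reset_index()
        if self.year is not None:
            df["year"] = self.year
        if self.label:
            df["component"] = self.label
        return df

    def county_rollup(self, county_map: pd.Series, *, exclude_intra: bool = False) -> pd.Series:
        """Sum flows to the county level; optionally drop intra-county flows."""
        o = self.data.index.get_level_values("origin").map(county_map)
        d = self.data.index.get_level_values("dest").map(county_map)
        if o.isna().any() or d.isna().any():
            raise ValueError("county map does not cover all zones in the matrix")
        mask = np.ones(len(self.data), dtype=bool)
        if exclude_intra:
            mask = np.asarray(o != d)
        return self.data[mask].groupby([o[mask], d[mask]]).sum().rename_axis(["origin_county", "dest_county"])


def cpc(a: "MigrationMatrix | pd.Series", b: "MigrationMatrix | pd.Series") -> float:
    """Common part of commuters: ``2 sum(min(Ta, Tb)) / (sum Ta + sum Tb)``.

    1 for identical matrices, 0 for disjoint support.  Undefined (raises) when
    both matrices are empty or all-zero.
    """
    sa = a.data if isinstance(a, MigrationMatrix) else a
    sb = b.data if isinstance(b, MigrationMatrix) else b
    tot = float(sa.sum() + sb.sum())
    if tot <= 0:
        raise ValueError("CPC undefined for two all-zero matrices")
    aligned_a, aligned_b = sa.align(sb, fill_value=0.0)
    overlap = np.minimum(aligned_a.to_numpy(float), aligned_b.to_numpy(float)).sum()
    return float(2.0 * overlap / tot)
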