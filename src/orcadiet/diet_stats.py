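"""Diet-variance tests and seasonal trend estimation.

Variance in diet composition across strata (population, month, year, pod)
is tested with PERMANOVA: the Bray–Curtis distance matrix is partitioned
into sequential sums of squares for an ordered list of factors via the
Gower-centred inner-product formulation, and each factor's pseudo-F is
referred to its permutation distribution under random relabelling of
samples.

Seasonal profiles pool samples by calendar month across years, average the
per-sample proportions per month, and smooth the monthly means with a
local quadratic regression (tricube weights, span = fraction of points in
each local fit; default 0.85 to damp within-month variability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from orcadiet.errors import InsufficientDataError, InvalidCompositionError

__all__ = [
    "PermanovaResult",
    "SeasonalTrend",
    "bray_curtis",
    "permanova",
    "loess",
    "seasonal_profile",
    "dominant_species",
    "presence_summary",
]


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity between composition rows.

    For rows summing to 1 this is ``1 − Σ_i min(a_i, b_i)``: 0 for identical
    compositions, 1 for disjoint support.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise InvalidCompositionError("compositions must be non-negative")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        m = np.minimum(X[i], X[i + 1 :]).sum(axis=1)
        s = X[i].sum() + X[i + 1 :].sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = 1.0 - 2.0 * m / s
        D[i, i + 1 :] = D[i + 1 :, i] = d
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(n)
    return pd.DataFrame(D, index=idx, columns=idx)


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA partition of a distance matrix.

    ``table`` has one row per factor plus Residual and Total rows with
    sums of squares, degrees of freedom, pseudo-F, R² and permutation
    p-values; factor R²s and the residual R² sum to 1.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        r2 = self.table["R2"].drop("Total")
        if not np.isclose(r2.sum(), 1.0, atol=1e-9):
            raise ValueError("factor + residual R2 must sum to 1")

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])

    def r2(self, factor: str) -> float:
        return float(self.table.loc[factor, "R2"])


def _dummy(levels: pd.Series) -> np.ndarray:
    """Full-rank dummy coding (drop-first) for one categorical factor."""
    cats = pd.Categorical(levels.astype(str))
    codes = np.asarray(cats.codes)
    k = len(cats.categories)
    X = np.zeros((len(codes), max(k - 1, 0)))
    for j in range(1, k):
        X[codes == j, j - 1] = 1.0
    return X


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal-projection (hat) matrix onto col(X) and its rank."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    rank = int((diag > 1e-10 * max(diag.max(), 1.0)).sum())
    Q = Q[:, :rank]
    return Q @ Q.T, rank


def permanova(
    dist: pd.DataFrame,
    factors: pd.DataFrame,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Sequential (ordered) PERMANOVA on a distance matrix.

    Parameters
    ----------
    dist
        Square symmetric distance matrix (samples × samples).
    factors
        One column per factor, fitted sequentially in column order;
        must share the distance matrix's index.
    n_perm
        Number of random label permutations, or ``"exact"`` to enumerate
        all permutations (small n only).
    seed
        Seed for the permutation stream.

    Notes
    -----
    Uses the inner-product (Gower-centred) formulation: with
    ``G = −½ J D² J``, the total sum of squares is ``tr(G)`` and the
    sum of squares explained by a design is ``tr(H G)`` for its hat
    matrix ``H``.  Sequential factor SS are successive differences of
    explained SS for the growing design.  p-values count permuted
    pseudo-F ≥ observed, with the +1 correction for random permutations
    and the plain fraction under exact enumeration.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    factors = factors.loc[dist.index] if isinstance(dist, pd.DataFrame) else factors
    names = list(factors.columns)
    if not names:
        raise ValueError("need at least one factor")
    for name in names:
        counts = factors[name].value_counts()
        if len(counts) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
        if (counts < 2).any():
            import warnings

            warnings.warn(
                f"factor {name!r} has singleton level(s)", UserWarning, stacklevel=2
            )

    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = float(np.trace(G))
    if ss_total <= 0:
        raise ValueError("singular partition: zero total sum of squares")

    # cumulative hat matrices for the growing (intercept + factors) design
    hats: list[np.ndarray] = []
    ranks: list[int] = []
    X = np.ones((n, 1))
    for name in names:
        X = np.hstack([X, _dummy(factors[name])])
        H, r = _hat(X)
        hats.append(H)
        ranks.append(r)
    df = [ranks[0] - 1] + [ranks[i] - ranks[i - 1] for i in range(1, len(names))]
    if any(d == 0 for d in df):
        raise ValueError("singular partition: a factor adds no rank")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def partition(Gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        explained = np.array([float(np.sum(H * Gm)) for H in hats])
        ss = np.diff(np.concatenate([[0.0], explained]))
        ss_res = float(np.trace(Gm)) - explained[-1]
        F = (ss / np.array(df)) / (ss_res / df_res)
        return ss, F

    ss_obs, F_obs = partition(G)
    ss_res = ss_total - ss_obs.sum()

    if n_perm == "exact":
        from itertools import permutations as iter_perms

        F_perm = np.array([partition(G[np.ix_(p, p)])[1] for p in iter_perms(range(n))])
        p_vals = (F_perm >= F_obs[None, :] - 1e-12).mean(axis=0)
        n_used = F_perm.shape[0]
    else:
        n_perm = int(n_perm)
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(names))
        for _ in range(n_perm):
            p = rng.permutation(n)
            _, F_p = partition(G[np.ix_(p, p)])
            exceed += F_p >= F_obs - 1e-12
        p_vals = (exceed + 1.0) / (n_perm + 1.0)
        n_used = n_perm

    table = pd.DataFrame(
        {
            "df": df + [df_res, n - 1],
            "SS": list(ss_obs) + [ss_res, ss_total],
            "F": list(F_obs) + [np.nan, np.nan],
            "R2": list(ss_obs / ss_total) + [ss_res / ss_total, 1.0],
            "p": list(p_vals) + [np.nan, np.nan],
        },
        index=pd.Index(names + ["Residual", "Total"], name="factor"),
    )
    return PermanovaResult(table=table, n_permutations=n_used, seed=seed)


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.85,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each evaluation point, fits a weighted polynomial of the given
    degree to the ``ceil(span · n)`` nearest observations, weighting by
    tricube of distance scaled to the neighbourhood radius.  Reproduces
    polynomials up to ``degree`` exactly when the window spans all points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(x)
    if n == 0:
        raise ValueError("no data")
    k = max(min(int(math.ceil(span * n)), n), degree + 1)
    if k > n:
        raise InsufficientDataError(
            f"need >= {degree + 1} points for degree-{degree} loess, have {n}"
        )
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = (1.0 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
            w[w <= 0] = 1e-9  # boundary point stays in its own fit
        deg = min(degree, len(idx) - 1)
        V = np.vander(x[idx] - x0, deg + 1, increasing=True)
        W = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(V * W[:, None], y[idx] * W, rcond=None)
        out[i] = beta[0]
    return out


@dataclass
class SeasonalTrend:
    """Smoothed monthly diet profiles per group and species.

    ``table`` is tidy: group, species, month, monthly mean proportion and
    the loess-smoothed proportion (clipped to [0, 1]).
    """

    table: pd.DataFrame
    span: float
    group_by: str

    def curve(self, group: str, species: str) -> pd.Series:
        sub = self.table[(self.table["group"] == group) & (self.table["species"] == species)]
        return sub.set_index("month")["smoothed"]


def seasonal_profile(
    proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    group_by: str = "population",
    span: float = 0.85,
    degree: int = 2,
) -> SeasonalTrend:
    """Seasonal diet profiles: monthly means smoothed with loess.

    Samples are pooled by calendar month across all years within each group
    (a population or pod); per-species monthly mean proportions are
    smoothed over the group's observed month range with a degree-2 tricube
    local regression at the given span and clipped to [0, 1].

    Raises :class:`InsufficientDataError` for groups observed in fewer than
    three distinct months.
    """
    meta = metadata.reindex(proportions.index)
    if group_by not in meta.columns:
        raise KeyError(f"metadata lacks column {group_by!r}")
    rows = []
    for group, sub_meta in meta.groupby(group_by, sort=True):
        sub = proportions.loc[sub_meta.index]
        monthly = sub.groupby(sub_meta["month"].astype(int)).mean().sort_index()
        months = monthly.index.to_numpy(dtype=float)
        if len(months) < 3:
            raise InsufficientDataError(
                f"group {group!r} observed in only {len(months)} month(s)"
            )
        for species in proportions.columns:
            smoothed = loess(months, monthly[species].to_numpy(), months, span, degree)
            smoothed = np.clip(smoothed, 0.0, 1.0)
            for m, raw, sm in zip(months, monthly[species], smoothed):
                rows.append(
                    {
                        "group": group,
                        "species": species,
                        "month": int(m),
                        "monthly_mean": float(raw),
                        "smoothed": float(sm),
                    }
                )
    return SeasonalTrend(table=pd.DataFrame(rows), span=span, group_by=group_by)


def dominant_species(sample: pd.Series, threshold: float = 0.5) -> str | None:
    """The unique species strictly exceeding half the sample, else None."""
    s = pd.Series(sample, dtype=float)
    top = s.idxmax()
    return str(top) if s[top] > threshold else None


def presence_summary(
    proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    presence_threshold: float = 0.01,
    group_by: str = "population",
) -> pd.DataFrame:
    """Occurrence and conditional abundance per group × species.

    For each group and species: the number and fraction of samples where
    the species exceeds the presence threshold (strictly), and the mean /
    min / max proportion among those present samples (empty when never
    present).
    """
    meta = metadata.reindex(proportions.index)
    rows = []
    for group, sub_meta in meta.groupby(group_by, sort=True):
        sub = proportions.loc[sub_meta.index]
        n = len(sub)
        for species in proportions.columns:
            vals = sub[species]
            present = vals[vals > presence_threshold]
            rows.append(
                {
                    group_by: group,
                    "species": species,
                    "n_samples": n,
                    "n_present": int(len(present)),
                    "frac_present": len(present) / n if n else np.nan,
                    "mean_when_present": float(present.mean()) if len(present) else np.nan,
                    "min_when_present": float(present.min()) if len(present) else np.nan,
                    "max_when_present": float(present.max()) if len(present) else np.nan,
                }
            )
    return pd.DataFrame(rows)
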