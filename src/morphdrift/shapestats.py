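"""Permutation-based linear models on shape and related summaries.

Implements sequential (type I) sums-of-squares linear models on
multivariate shape variables with significance from the randomized residual
permutation procedure (RRPP): each term's null distribution comes from
permuting the residuals of the model reduced by that term.  Goodall-style
F ratios are formed from summed squared Procrustes distances pooled across
all response columns.

Conventions (documented because they affect term-wise results):

* the observed arrangement counts as one permutation, so p >= 1/n_perm;
* effect sizes Z are computed on the F distribution, not log F;
* factors are treatment-coded with alphabetical level order;
* a single seed drives one permutation stream shared by all terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "AnovaResult",
    "SlopeComparison",
    "PCAResult",
    "rrpp_lm",
    "model_compare",
    "slope_homogeneity",
    "measurement_error_pct",
    "shape_pca",
]


@dataclass
class ModelSpec:
    """An ordered sequential-SS model formula.

    ``terms`` are column names of the covariate/factor table; interactions
    use ``:`` (e.g. ``"log_size:period"``) and must follow their main
    effects.  Order matters: sums of squares are sequential.
    """

    terms: list[str]
    ss_type: str = "sequential"
    n_perm: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ss_type != "sequential":
            raise ValueError("only sequential (type I) SS is supported")
        seen: set[frozenset[str]] = set()
        for term in self.terms:
            parts = term.split(":")
            for k in range(1, len(parts)):
                for sub in combinations(parts, k):
                    if frozenset(sub) not in seen:
                        raise ValueError(
                            f"interaction {term!r} listed before its component {':'.join(sub)!r}"
                        )
            seen.add(frozenset(parts))


@dataclass
class AnovaResult:
    """Sequential ANOVA/ANCOVA table with RRPP inference."""

    terms: list[str]
    df: np.ndarray
    ss: np.ndarray
    ms: np.ndarray
    r2: np.ndarray
    f: np.ndarray
    z: np.ndarray
    p: np.ndarray
    df_residual: int
    ss_residual: float
    df_total: int
    ss_total: float
    n_perm: int
    seed: int | None

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.df_residual

    @property
    def r2_residual(self) -> float:
        return self.ss_residual / self.ss_total

    def to_frame(self) -> pd.DataFrame:
        """Term rows plus Residuals/Total, mirroring a standard table layout."""
        rows = pd.DataFrame(
            {
                "df": self.df,
                "SS": self.ss,
                "MS": self.ms,
                "R2": self.r2,
                "F": self.f,
                "Z": self.z,
                "p": self.p,
            },
            index=self.terms,
        )
        rows.loc["Residuals"] = [
            self.df_residual, self.ss_residual, self.ms_residual,
            self.r2_residual, np.nan, np.nan, np.nan,
        ]
        rows.loc["Total"] = [self.df_total, self.ss_total] + [np.nan] * 5
        rows.index.name = "term"
        return rows

    def to_dict(self) -> dict:
        frame = self.to_frame().reset_index()
        return {
            "table": frame.where(frame.notna(), None).to_dict(orient="records"),
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


@dataclass
class SlopeComparison:
    """Pairwise allometric-slope comparisons between groups."""

    pairs: list[tuple[str, str]]
    length_diff: np.ndarray
    angle_deg: np.ndarray
    p_length: np.ndarray
    p_angle: np.ndarray
    n_perm: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_1": [a for a, _ in self.pairs],
                "group_2": [b for _, b in self.pairs],
                "length_diff": self.length_diff,
                "angle_deg": self.angle_deg,
                "p_length": self.p_length,
                "p_angle": self.p_angle,
            }
        )


@dataclass
class PCAResult:
    """Principal components of mean-centred shape variables."""

    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: np.ndarray  # n x k
    vectors: np.ndarray  # k x q, rows are axes
    mean: np.ndarray  # q
    extremes: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def scores_frame(self, ids: Sequence[str] | None = None) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, columns=cols, index=ids)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _main_effect_columns(data: pd.DataFrame, name: str) -> np.ndarray:
    if name not in data.columns:
        raise KeyError(f"model term {name!r} not in covariate/factor table")
    col = data[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None]
    levels = sorted(pd.unique(col.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has fewer than 2 levels in the data")
    # treatment contrasts, alphabetical reference level
    return np.column_stack([(col.astype(str) == lv).to_numpy(float) for lv in levels[1:]])


def _term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    blocks = [_main_effect_columns(data, part) for part in term.split(":")]
    out = blocks[0]
    for blk in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, blk).reshape(len(data), -1)
    return out


def _sequential_bases(
    data: pd.DataFrame, terms: Sequence[str]
) -> tuple[list[np.ndarray], list[int]]:
    """Orthonormal bases Q_0 .. Q_K for the nested sequence of designs.

    Q_0 spans the intercept; Q_k adds term k.  Returns the bases and the df
    (rank increment) per term; raises on aliased terms.
    """
    n = len(data)
    X = np.ones((n, 1))
    bases = [_orthobasis(X)]
    dfs = []
    rank = 1
    for term in terms:
        X = np.hstack([X, _term_columns(data, term)])
        Q = _orthobasis(X)
        new_rank = Q.shape[1]
        if new_rank <= rank:
            raise ValueError(f"design is rank-deficient: term {term!r} is aliased")
        bases.append(Q)
        dfs.append(new_rank - rank)
        rank = new_rank
    return bases, dfs


def _orthobasis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis for the column space of X (rank-safe, via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    return U[:, s > tol]


def _proj_ss(Q: np.ndarray, Y: np.ndarray) -> float:
    """Squared norm of the projection of Y onto span(Q)."""
    return float(((Q.T @ Y) ** 2).sum()) if Q.size else 0.0


# ---------------------------------------------------------------------------
# RRPP linear model
# ---------------------------------------------------------------------------

def rrpp_lm(
    Y: np.ndarray,
    model: ModelSpec,
    data: pd.DataFrame,
) -> AnovaResult:
    """Sequential-SS linear model on a multivariate response with RRPP.

    ``Y`` is the n x q response (flattened shape variables or a univariate
    column); ``data`` carries the covariates and factors named by
    ``model.terms``.  For each term, F is the Goodall ratio of the term's
    mean squared Procrustes distance to the full-model residual mean square;
    the null distribution permutes the reduced-model residuals.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and len(data) != 1:
        Y = Y.T
    n, q = Y.shape
    if n != len(data):
        raise ValueError("response and covariate table differ in length")
    bases, dfs = _sequential_bases(data, model.terms)
    rank_full = bases[-1].shape[1]
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("model uses all degrees of freedom (n <= total model df)")

    total_yy = float((Y**2).sum())
    ss_total = total_yy - _proj_ss(bases[0], Y)
    df_total = n - 1

    n_terms = len(model.terms)
    n_perm = max(int(model.n_perm), 1)
    rng = np.random.default_rng(model.seed)
    # shared permutation schedule: observed first, then n_perm-1 random
    perms = np.empty((n_perm, n), dtype=int)
    perms[0] = np.arange(n)
    for b in range(1, n_perm):
        perms[b] = rng.permutation(n)

    f_stats = np.zeros((n_terms, n_perm))
    Q_full = bases[-1]
    for k in range(n_terms):
        Q_red, Q_aug = bases[k], bases[k + 1]
        fit_red = Q_red @ (Q_red.T @ Y)
        resid_red = Y - fit_red
        for b in range(n_perm):
            Yb = fit_red + resid_red[perms[b]]
            ss_term = _proj_ss(Q_aug, Yb) - _proj_ss(Q_red, Yb)
            rss_full = float((Yb**2).sum()) - _proj_ss(Q_full, Yb)
            f_stats[k, b] = (ss_term / dfs[k]) / (rss_full / df_resid)

    ss = np.array(
        [_proj_ss(bases[k + 1], Y) - _proj_ss(bases[k], Y) for k in range(n_terms)]
    )
    rss = total_yy - _proj_ss(Q_full, Y)
    f_obs = f_stats[:, 0]
    p = (f_stats >= f_obs[:, None] - 1e-12).mean(axis=1)
    mean_f = f_stats.mean(axis=1)
    sd_f = f_stats.std(axis=1, ddof=1) if n_perm > 1 else np.ones(n_terms)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_f > 0, (f_obs - mean_f) / sd_f, 0.0)

    dfs_arr = np.array(dfs, dtype=int)
    return AnovaResult(
        terms=list(model.terms),
        df=dfs_arr,
        ss=ss,
        ms=ss / dfs_arr,
        r2=ss / ss_total,
        f=f_obs,
        z=z,
        p=p,
        df_residual=df_resid,
        ss_residual=rss,
        df_total=df_total,
        ss_total=ss_total,
        n_perm=n_perm,
        seed=model.seed,
    )


@dataclass
class ModelComparison:
    ss_diff: float
    df_diff: int
    f: float
    z: float
    p: float
    n_perm: int


def model_compare(
    Y: np.ndarray,
    full: ModelSpec,
    reduced: ModelSpec,
    data: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ModelComparison:
    """RRPP comparison of nested models (full vs reduced).

    F is built from the residual-SS difference over the df difference,
    against the full model's residual mean square; the null permutes the
    reduced model's residuals.
    """
    red_set = [frozenset(t.split(":")) for t in reduced.terms]
    full_set = [frozenset(t.split(":")) for t in full.terms]
    if any(t not in full_set for t in red_set):
        raise ValueError("models are not nested (reduced has terms absent from full)")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and len(data) != 1:
        Y = Y.T
    n = Y.shape[0]
    Q_red = _orthobasis(
        np.hstack([np.ones((n, 1))] + [_term_columns(data, t) for t in reduced.terms])
        if reduced.terms
        else np.ones((n, 1))
    )
    Q_full = _orthobasis(
        np.hstack([np.ones((n, 1))] + [_term_columns(data, t) for t in full.terms])
        if full.terms
        else np.ones((n, 1))
    )
    df_diff = Q_full.shape[1] - Q_red.shape[1]
    df_resid = n - Q_full.shape[1]
    if df_diff < 0:
        raise ValueError("full model has lower rank than reduced model")
    total_yy = float((Y**2).sum())
    rng = np.random.default_rng(seed)
    fit_red = Q_red @ (Q_red.T @ Y)
    resid_red = Y - fit_red
    f_vals = np.zeros(n_perm)
    for b in range(n_perm):
        Yb = Y if b == 0 else fit_red + resid_red[rng.permutation(n)]
        ss_diff = _proj_ss(Q_full, Yb) - _proj_ss(Q_red, Yb)
        rss_full = float((Yb**2).sum()) - _proj_ss(Q_full, Yb)
        if df_diff == 0:
            f_vals[b] = 0.0
        else:
            f_vals[b] = (ss_diff / df_diff) / (rss_full / df_resid)
    f_obs = f_vals[0]
    p = float((f_vals >= f_obs - 1e-12).mean())
    sd = f_vals.std(ddof=1)
    z = float((f_obs - f_vals.mean()) / sd) if sd > 0 else 0.0
    ss_diff_obs = _proj_ss(Q_full, Y) - _proj_ss(Q_red, Y)
    return ModelComparison(
        ss_diff=float(ss_diff_obs), df_diff=df_diff, f=float(f_obs), z=z, p=p, n_perm=n_perm
    )


# ---------------------------------------------------------------------------
# homogeneity of slopes
# ---------------------------------------------------------------------------

def _group_slopes(Y: np.ndarray, x: np.ndarray, groups: np.ndarray) -> dict[str, np.ndarray]:
    slopes = {}
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 members")
        xg = x[sel] - x[sel].mean()
        sxx = float((xg**2).sum())
        if sxx <= 0:
            raise ValueError(f"group {g!r} has zero size variance")
        Yg = Y[sel] - Y[sel].mean(axis=0)
        slopes[str(g)] = (xg @ Yg) / sxx
    return slopes


def _pair_stats(b1: np.ndarray, b2: np.ndarray) -> tuple[float, float]:
    n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
    length_diff = abs(n1 - n2)
    if n1 == 0 or n2 == 0:
        return length_diff, 0.0
    cosang = np.clip(b1 @ b2 / (n1 * n2), -1.0, 1.0)
    return length_diff, float(np.degrees(np.arccos(cosang)))


def slope_homogeneity(
    Y: np.ndarray,
    log_size: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SlopeComparison:
    """Pairwise comparison of per-group allometric slope vectors.

    Observed statistics are the absolute difference of slope-vector lengths
    and the angle between slope vectors; null distributions come from RRPP
    under the common-slope model (group + size, one shared slope).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    log_size = np.asarray(log_size, dtype=float)
    groups = np.asarray(groups).astype(str)
    if Y.shape[0] == 1 and log_size.shape[0] != 1:
        Y = Y.T
    n = Y.shape[0]
    obs = _group_slopes(Y, log_size, groups)
    names = sorted(obs)
    pairs = list(combinations(names, 2))
    obs_stats = np.array([_pair_stats(obs[a], obs[b]) for a, b in pairs])

    # common-slope null model: intercept + group dummies + shared size slope
    data = pd.DataFrame({"group": groups, "size": log_size})
    X = np.hstack(
        [np.ones((n, 1)), _main_effect_columns(data, "group"), log_size[:, None]]
    )
    Q = _orthobasis(X)
    fit = Q @ (Q.T @ Y)
    resid = Y - fit
    rng = np.random.default_rng(seed)
    count_len = np.ones(len(pairs))
    count_ang = np.ones(len(pairs))
    for _ in range(n_perm - 1):
        Yb = fit + resid[rng.permutation(n)]
        sl = _group_slopes(Yb, log_size, groups)
        for i, (a, b) in enumerate(pairs):
            ld, ang = _pair_stats(sl[a], sl[b])
            if ld >= obs_stats[i, 0] - 1e-12:
                count_len[i] += 1
            if ang >= obs_stats[i, 1] - 1e-12:
                count_ang[i] += 1
    return SlopeComparison(
        pairs=pairs,
        length_diff=obs_stats[:, 0],
        angle_deg=obs_stats[:, 1],
        p_length=count_len / n_perm,
        p_angle=count_ang / n_perm,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# measurement error and PCA
# ---------------------------------------------------------------------------

def measurement_error_pct(aligned) -> float:
    """Digitizing-error percentage from a replicated, aligned dataset.

    Procrustes ANOVA with specimen identity as the sole factor;
    returns 100 * residual SS / total SS (the share of shape variance that
    lies within specimens, i.e. between replicates).
    """
    Y = aligned.flattened()
    ids = np.asarray(aligned.specimen_ids)
    if len(np.unique(ids)) < 2:
        raise ValueError("need >= 2 distinct specimens")
    counts = pd.Series(ids).value_counts()
    if (counts < 2).all():
        raise ValueError("need >= 2 replicates for at least one specimen")
    data = pd.DataFrame({"specimen": ids})
    model = ModelSpec(terms=["specimen"], n_perm=1, seed=0)
    result = rrpp_lm(Y, model, data)
    return 100.0 * result.ss_residual / result.ss_total


def shape_pca(aligned, n_components: int | None = None) -> PCAResult:
    """PCA of mean-centred flattened shape variables (SVD-based).

    Eigenvalues are of the (n-1)-denominator covariance; their sum equals
    the total shape variance.  Per-axis extreme shapes are the consensus
    displaced to the observed score minimum and maximum.
    """
    Y = aligned.flattened() if hasattr(aligned, "flattened") else np.asarray(aligned, float)
    n, q = Y.shape
    if n < 3:
        raise ValueError("PCA needs >= 3 specimens")
    mean = Y.mean(axis=0)
    C = Y - mean
    if not np.any(C):
        raise ValueError("degenerate input: zero shape variance")
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    tol = s.max() * max(n, q) * np.finfo(float).eps
    k = int((s > tol).sum())
    if n_components is not None:
        k = min(k, n_components)
    eigenvalues = s[:k] ** 2 / (n - 1)
    scores = U[:, :k] * s[:k]
    vectors = Vt[:k]
    total_var = float((C**2).sum()) / (n - 1)
    extremes = []
    p3 = mean.reshape(-1, 3) if q % 3 == 0 else None
    for i in range(k):
        lo = mean + scores[:, i].min() * vectors[i]
        hi = mean + scores[:, i].max() * vectors[i]
        if p3 is not None:
            lo, hi = lo.reshape(-1, 3), hi.reshape(-1, 3)
        extremes.append((lo, hi))
    return PCAResult(
        eigenvalues=eigenvalues,
        pct_variance=eigenvalues / total_var,
        scores=scores,
        vectors=vectors,
        mean=mean,
        extremes=extremes,
    )
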