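"""Interlandmark-distance traits, P-matrices, and random-skewers comparison.

Distances are computed from raw digitized coordinates (mm) — they are rigid-
motion invariant, so superimposition is bypassed entirely and original units
are preserved.  Bilateral mirror-pair distances are averaged into single
traits.  Traits are not log-transformed by default; pass ``log=True`` where
offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphio import DistanceDefinition, ShapeDataset

__all__ = [
    "TraitMatrix",
    "PMatrix",
    "SkewersResult",
    "interlandmark_distances",
    "p_matrix",
    "random_skewers",
    "skewers_null_pvalue",
]


@dataclass
class TraitMatrix:
    """n x m matrix of interlandmark-distance traits (mm)."""

    specimens: list[str]
    traits: list[str]
    values: np.ndarray
    populations: list[str]  # time-period label per specimen row

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.specimens), len(self.traits)):
            raise ValueError("values shape does not match specimens x traits")

    def rows_for(self, population: str) -> np.ndarray:
        sel = np.array([p == population for p in self.populations])
        return self.values[sel]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.traits)
        frame.insert(0, "specimen_id", self.specimens)
        frame.insert(1, "population", self.populations)
        return frame


@dataclass
class PMatrix:
    """Sample phenotypic variance-covariance matrix of one population."""

    labels: list[str]
    cov: np.ndarray
    n: int
    population: str = ""

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        m = len(self.labels)
        if self.cov.shape != (m, m):
            raise ValueError("covariance shape does not match labels")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance matrix not symmetric")
        eig = np.linalg.eigvalsh(self.cov)
        if eig.min() < -1e-8 * max(np.trace(self.cov), 1.0):
            raise ValueError("covariance matrix not positive semidefinite")

    @property
    def m(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov, index=self.labels, columns=self.labels)


@dataclass
class SkewersResult:
    """Random-skewers comparison of two covariance matrices."""

    correlation: float
    p: float
    n_vectors: int
    seed: int | None
    response_correlations: np.ndarray

    def to_dict(self) -> dict:
        return {
            "correlation": self.correlation,
            "p": self.p,
            "n_vectors": self.n_vectors,
            "seed": self.seed,
        }


def interlandmark_distances(
    dataset: ShapeDataset,
    defs: list[DistanceDefinition] | None = None,
    log: bool = False,
) -> TraitMatrix:
    """Per-specimen Euclidean distances for each definition, in mm.

    Mirror pairs (``mirror_of``) collapse to one trait named after whichever
    definition appears first; its value is the mean of the two sides.
    """
    template = dataset.template
    if defs is None:
        defs = template.distance_defs
    if not defs:
        raise ValueError("no distance definitions supplied")
    by_name = {d.name: d for d in defs}
    ordered: list[tuple[str, list[DistanceDefinition]]] = []
    folded: set[str] = set()
    for d in defs:
        if d.name in folded:
            continue
        members = [d]
        if d.mirror_of is not None:
            partner = by_name.get(d.mirror_of)
            if partner is None:
                raise ValueError(f"distance {d.name!r}: mirror {d.mirror_of!r} not in defs")
            members.append(partner)
            folded.add(partner.name)
        ordered.append((d.name, members))

    specimens = [s for s in dataset.specimens if s.replicate == 0] or dataset.specimens
    values = np.zeros((len(specimens), len(ordered)))
    for i, s in enumerate(specimens):
        for j, (_, members) in enumerate(ordered):
            dists = []
            for d in members:
                a, b = (template.index(e) for e in d.endpoints)
                if s.missing_mask[a] or s.missing_mask[b]:
                    raise ValueError(
                        f"specimen {s.specimen_id!r}: distance {d.name!r} references a "
                        "missing, unimputed landmark"
                    )
                dists.append(float(np.linalg.norm(s.coords[a] - s.coords[b])))
            values[i, j] = np.mean(dists)
    if log:
        values = np.log(values)
    return TraitMatrix(
        specimens=[s.specimen_id for s in specimens],
        traits=[name for name, _ in ordered],
        values=values,
        populations=[s.period if s.period is not None else "" for s in specimens],
    )


def p_matrix(traits: TraitMatrix, population: str) -> PMatrix:
    """Unbiased (n-1) sample covariance of one population's trait rows."""
    rows = traits.rows_for(population)
    n = rows.shape[0]
    if n < 3:
        raise ValueError(f"population {population!r}: need n >= 3, have {n}")
    if n < len(traits.traits):
        import warnings

        warnings.warn(
            f"population {population!r}: n={n} < m={len(traits.traits)} traits; "
            "covariance is singular",
            stacklevel=2,
        )
    cov = np.cov(rows, rowvar=False, ddof=1)
    return PMatrix(labels=list(traits.traits), cov=np.atleast_2d(cov), n=n, population=population)


def skewers_null_pvalue(r: float, m: int) -> float:
    """P(cosine of two independent uniform random unit vectors in R^m > r).

    Closed form via cos^2 ~ Beta(1/2, (m-1)/2).
    """
    if m < 2:
        raise ValueError("need dimension >= 2")
    tail = 0.5 * stats.beta.sf(r * r, 0.5, (m - 1) / 2.0)
    p = tail if r >= 0 else 1.0 - tail
    return float(max(p, np.finfo(float).tiny))


def random_skewers(
    P1: PMatrix,
    P2: PMatrix,
    n_vectors: int = 1000,
    seed: int | None = None,
    uniform_cube: bool = False,
) -> SkewersResult:
    """Random-skewers similarity of two covariance matrices.

    Each skewer is a random selection vector (iid Gaussian, normalized to
    unit length — i.e. uniform on the sphere; ``uniform_cube`` draws from
    U(-1,1)^m instead for historical fidelity); the statistic is the mean
    cosine between the response vectors P1 @ beta and P2 @ beta.  The
    p-value is the closed-form probability that the cosine of two
    independent random unit vectors exceeds the observed mean.
    """
    if P1.labels != P2.labels:
        raise ValueError("P-matrices have different trait labels")
    m = P1.m
    rng = np.random.default_rng(seed)
    if uniform_cube:
        betas = rng.uniform(-1.0, 1.0, size=(n_vectors, m))
    else:
        betas = rng.standard_normal((n_vectors, m))
    betas /= np.linalg.norm(betas, axis=1, keepdims=True)
    r1 = betas @ P1.cov
    r2 = betas @ P2.cov
    if np.array_equal(P1.cov, P2.cov):
        corr = np.ones(n_vectors)  # parallel responses; avoid 1-ulp rounding
    else:
        num = (r1 * r2).sum(axis=1)
        den = np.linalg.norm(r1, axis=1) * np.linalg.norm(r2, axis=1)
        ok = den > 0
        corr = np.clip(np.where(ok, num / np.where(ok, den, 1.0), 0.0), -1.0, 1.0)
    mean_corr = float(corr.mean())
    return SkewersResult(
        correlation=mean_corr,
        p=skewers_null_pvalue(mean_corr, m),
        n_vectors=n_vectors,
        seed=seed,
        response_correlations=corr,
    )
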