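"""Synthetic landmark datasets and trait populations with known truth.

Everything downstream — superimposition, RRPP models, P-matrices, the drift
test — is testable offline against these generators.  Specimens are built
additively in shape space: base shape, allometric displacement per unit log
centroid size, period and sex mean shifts, individual deviations from a
known covariance, then iid digitizing noise per replicate.  Trait
populations diverge under pure drift (shift ~ MVN(0, P t/Ne)) or drift plus
a directional selection vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .driftmode import _mvn_draws
from .morphio import DistanceDefinition, LandmarkTemplate, ShapeDataset, SpecimenRecord, PERIOD_YEARS

__all__ = [
    "SyntheticShapeConfig",
    "DivergenceSimConfig",
    "make_template",
    "simulate_shapes",
    "simulate_trait_divergence",
]


@dataclass
class SyntheticShapeConfig:
    template: LandmarkTemplate
    base_shape: np.ndarray  # p x 3
    n_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("1890s", "F"): 6, ("1890s", "M"): 6, ("2010s", "F"): 6, ("2010s", "M"): 6,
        }
    )
    allometry_vector: np.ndarray | None = None  # p x 3 per unit log size
    period_effect: np.ndarray | None = None  # p x 3, added for 2010s
    sex_effect: np.ndarray | None = None  # p x 3, added for males
    individual_sd: float = 0.0  # isotropic shorthand for individual_cov
    individual_cov: np.ndarray | None = None  # 3p x 3p, overrides individual_sd
    digitizing_sd: float = 0.0  # mm, per coordinate per replicate
    size_range: tuple[float, float] = (80.0, 120.0)
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.base_shape = np.asarray(self.base_shape, dtype=float)
        p = self.template.n_landmarks
        if self.base_shape.shape != (p, 3):
            raise ValueError("base_shape must be p x 3")
        for name in ("allometry_vector", "period_effect", "sex_effect"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (p, 3):
                    raise ValueError(f"{name} must be p x 3")
                setattr(self, name, v)
        if any(c < 0 for c in self.n_per_group.values()):
            raise ValueError("group counts must be >= 0")
        if self.digitizing_sd < 0 or self.individual_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.individual_cov is not None:
            self.individual_cov = np.asarray(self.individual_cov, dtype=float)
            if self.individual_cov.shape != (3 * p, 3 * p):
                raise ValueError("individual_cov must be 3p x 3p")
            if np.linalg.eigvalsh(self.individual_cov).min() < -1e-8:
                raise ValueError("individual_cov must be positive semidefinite")


@dataclass
class DivergenceSimConfig:
    m: int
    P_true: np.ndarray
    t: float
    ne: float
    mode: str = "drift"  # drift | selection
    selection_vector: np.ndarray | None = None
    n1: int = 25
    n2: int = 25
    baseline: float = 20.0  # positive trait-mean baseline (mm scale)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.P_true = np.asarray(self.P_true, dtype=float)
        if self.P_true.shape != (self.m, self.m):
            raise ValueError("P_true must be m x m")
        if np.linalg.eigvalsh(self.P_true).min() < -1e-8 * max(np.trace(self.P_true), 1.0):
            raise ValueError("P_true must be positive semidefinite")
        if self.mode not in ("drift", "selection"):
            raise ValueError("mode must be 'drift' or 'selection'")
        if (self.selection_vector is not None) != (self.mode == "selection"):
            raise ValueError("selection_vector required iff mode == 'selection'")
        if self.selection_vector is not None:
            self.selection_vector = np.asarray(self.selection_vector, dtype=float)
            if self.selection_vector.shape != (self.m,):
                raise ValueError("selection_vector must be length m")
        if self.t < 0 or self.ne <= 0:
            raise ValueError("t must be >= 0 and Ne > 0")


def make_template(
    n_pairs: int, n_midline: int, seed: int | None = None, name_prefix: str = "lm"
) -> tuple[LandmarkTemplate, np.ndarray]:
    """Random bilaterally symmetric template plus its base shape.

    Midline landmarks sit on the sagittal (x = 0) plane; each bilateral pair
    is mirrored in x.  Distance definitions cover every midline-midline pair
    plus, per bilateral pair, the mirrored left/right distances to the first
    midline landmark (``mirror_of`` set reciprocally).
    """
    if n_pairs < 0 or n_midline < 3:
        raise ValueError("need n_pairs >= 0 and n_midline >= 3")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        mid = np.column_stack(
            [np.zeros(n_midline), rng.uniform(-30, 30, n_midline), rng.uniform(-30, 30, n_midline)]
        )
        left = np.column_stack(
            [
                rng.uniform(5, 30, n_pairs),
                rng.uniform(-30, 30, n_pairs),
                rng.uniform(-30, 30, n_pairs),
            ]
        )
        right = left * np.array([-1.0, 1.0, 1.0])
        base = np.vstack([mid, left, right]) if n_pairs else mid
        centred = base - base.mean(axis=0)
        # midline-only templates are planar by construction; require non-collinear
        if np.linalg.matrix_rank(centred, tol=1e-6) >= 2:
            break
    else:  # pragma: no cover - re-draw loop virtually always succeeds
        raise RuntimeError("could not draw a non-degenerate base shape")

    mid_names = [f"{name_prefix}_mid{i + 1:02d}" for i in range(n_midline)]
    left_names = [f"{name_prefix}_L{i + 1:02d}" for i in range(n_pairs)]
    right_names = [f"{name_prefix}_R{i + 1:02d}" for i in range(n_pairs)]
    names = mid_names + left_names + right_names

    defs: list[DistanceDefinition] = []
    for i in range(n_midline):
        for j in range(i + 1, n_midline):
            defs.append(
                DistanceDefinition(
                    name=f"d_{mid_names[i]}_{mid_names[j]}",
                    endpoints=(mid_names[i], mid_names[j]),
                )
            )
    anchor = mid_names[0]
    for ln, rn in zip(left_names, right_names):
        defs.append(DistanceDefinition(f"d_{anchor}_{ln}", (anchor, ln), mirror_of=f"d_{anchor}_{rn}"))
        defs.append(DistanceDefinition(f"d_{anchor}_{rn}", (anchor, rn), mirror_of=f"d_{anchor}_{ln}"))

    template = LandmarkTemplate(
        landmark_names=names,
        dim=3,
        paired=list(zip(left_names, right_names)),
        midline=mid_names,
        views={n: "common" for n in names},
        distance_defs=defs,
    )
    return template, base


def simulate_shapes(config: SyntheticShapeConfig) -> ShapeDataset:
    """Generate a ShapeDataset under the additive shape model.

    specimen = base + log(size) * allometry + period_effect * 1(2010s)
    + sex_effect * 1(M) + individual MVN deviation, then per-replicate iid
    digitizing noise.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    p = config.template.n_landmarks
    specimens: list[SpecimenRecord] = []
    counter = 0
    for (period, sex), count in sorted(config.n_per_group.items()):
        years = PERIOD_YEARS.get(period)
        for _ in range(count):
            counter += 1
            sid = f"S{counter:03d}"
            size = rng.uniform(*config.size_range)
            shape = config.base_shape.copy()
            if config.allometry_vector is not None:
                shape = shape + np.log(size) * config.allometry_vector
            if config.period_effect is not None and period == "2010s":
                shape = shape + config.period_effect
            if config.sex_effect is not None and sex == "M":
                shape = shape + config.sex_effect
            if config.individual_cov is not None:
                shape = shape + _mvn_draws(rng, config.individual_cov, 1).reshape(p, 3)
            elif config.individual_sd > 0:
                shape = shape + rng.normal(0.0, config.individual_sd, size=(p, 3))
            year = int(rng.integers(years[0], years[1] + 1)) if years else None
            for rep in range(config.n_replicates):
                coords = shape.copy()
                if config.digitizing_sd > 0:
                    coords = coords + rng.normal(0.0, config.digitizing_sd, size=(p, 3))
                specimens.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        coords=coords,
                        year=year,
                        period=period if period in PERIOD_YEARS else None,
                        sex=sex,
                        replicate=rep,
                    )
                )
    return ShapeDataset(config.template, specimens)


def simulate_trait_divergence(
    config: DivergenceSimConfig, return_truth: bool = False
):
    """Two trait populations diverged under drift (plus optional selection).

    pop1 rows ~ MVN(mu, P); the drift shift delta ~ MVN(0, P t/Ne) is drawn
    once; pop2 rows ~ MVN(mu + delta + s, P) with s the selection vector
    (zero in drift mode).  With ``return_truth`` the drawn drift shift and
    selection vector come back too, for ground-truth recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    mu = np.full(config.m, float(config.baseline))
    pop1 = mu + _mvn_draws(rng, config.P_true, config.n1)
    delta = (
        _mvn_draws(rng, config.P_true * (config.t / config.ne), 1)[0]
        if config.t > 0
        else np.zeros(config.m)
    )
    s = config.selection_vector if config.mode == "selection" else np.zeros(config.m)
    pop2 = mu + delta + s + _mvn_draws(rng, config.P_true, config.n2)
    if return_truth:
        return pop1, pop2, delta, np.asarray(s, dtype=float)
    return pop1, pop2
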