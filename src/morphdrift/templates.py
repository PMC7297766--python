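"""Shipped stand-in landmark templates.

These templates reproduce the structural counts of the study system — a
43-landmark cranium digitized in dorsal (18 landmarks) and ventral (30)
orientations sharing 5 common landmarks, and a 15-landmark left-side
mandible — but the landmark positions and the interlandmark-distance trait
list are STAND-INS: the true anatomical definitions live in supplementary
material not shipped here.  Counts, bilateral structure, and view membership
are correct; geometry is synthetic.
"""

from __future__ import annotations

import numpy as np

from .morphio import DistanceDefinition, LandmarkTemplate

__all__ = ["cranium_template", "mandible_template"]

# cranium structure: 15 midline + 14 bilateral pairs = 43 landmarks
#   views: 5 midline common, 5 midline + 4 pairs dorsal-only,
#          5 midline + 10 pairs ventral-only
#   -> dorsal orientation sees 13 + 5 common = 18, ventral 25 + 5 = 30
_N_MID = 15
_N_PAIRS = 14
_MID_COMMON = 5
_MID_DORSAL = 5
_PAIRS_DORSAL = 4


def cranium_template(seed: int = 20200415) -> tuple[LandmarkTemplate, np.ndarray]:
    """Stand-in cranium template and a bilaterally symmetric base shape.

    Returns the template plus a p x 3 base configuration (mm scale) whose
    midline lies in the x = 0 plane.
    """
    rng = np.random.default_rng(seed)
    mid_names = [f"mid{i + 1:02d}" for i in range(_N_MID)]
    left_names = [f"L{i + 1:02d}" for i in range(_N_PAIRS)]
    right_names = [f"R{i + 1:02d}" for i in range(_N_PAIRS)]
    names = mid_names + left_names + right_names

    views: dict[str, str] = {}
    for i, n in enumerate(mid_names):
        if i < _MID_COMMON:
            views[n] = "common"
        elif i < _MID_COMMON + _MID_DORSAL:
            views[n] = "dorsal"
        else:
            views[n] = "ventral"
    for i, (ln, rn) in enumerate(zip(left_names, right_names)):
        v = "dorsal" if i < _PAIRS_DORSAL else "ventral"
        views[ln] = views[rn] = v

    # elongated skull-ish cloud, ~40 mm long, midline on x = 0
    mid = np.column_stack(
        [np.zeros(_N_MID), np.linspace(-20, 20, _N_MID), rng.uniform(-8, 8, _N_MID)]
    )
    left = np.column_stack(
        [
            rng.uniform(4, 14, _N_PAIRS),
            rng.uniform(-20, 20, _N_PAIRS),
            rng.uniform(-8, 8, _N_PAIRS),
        ]
    )
    right = left * np.array([-1.0, 1.0, 1.0])
    base = np.vstack([mid, left, right])

    defs: list[DistanceDefinition] = []
    # midline chain spans
    for a, b in zip(mid_names[:-1], mid_names[1:]):
        defs.append(DistanceDefinition(f"d_{a}_{b}", (a, b)))
    # mirrored midline-to-side distances
    anchor = mid_names[0]
    for ln, rn in zip(left_names, right_names):
        defs.append(DistanceDefinition(f"d_{anchor}_{ln}", (anchor, ln), mirror_of=f"d_{anchor}_{rn}"))
        defs.append(DistanceDefinition(f"d_{anchor}_{rn}", (anchor, rn), mirror_of=f"d_{anchor}_{ln}"))
    # stand-in upper molar tooth row: span between two ventral side landmarks
    defs.append(
        DistanceDefinition("upper_toothrow_L", (left_names[-2], left_names[-1]),
                           mirror_of="upper_toothrow_R")
    )
    defs.append(
        DistanceDefinition("upper_toothrow_R", (right_names[-2], right_names[-1]),
                           mirror_of="upper_toothrow_L")
    )

    template = LandmarkTemplate(
        landmark_names=names,
        dim=3,
        paired=list(zip(left_names, right_names)),
        midline=mid_names,
        views=views,
        distance_defs=defs,
    )
    return template, base


def mandible_template(seed: int = 20200416) -> tuple[LandmarkTemplate, np.ndarray]:
    """Stand-in 15-landmark left-side mandible template and base shape.

    No bilateral structure (only the left side is digitized), so downstream
    alignment uses plain GPA without a symmetry step.
    """
    rng = np.random.default_rng(seed)
    names = [f"md{i + 1:02d}" for i in range(15)]
    base = np.column_stack(
        [rng.uniform(-3, 3, 15), np.linspace(-15, 15, 15), rng.uniform(-6, 6, 15)]
    )
    defs = [
        DistanceDefinition(f"d_{a}_{b}", (a, b)) for a, b in zip(names[:-1], names[1:])
    ]
    template = LandmarkTemplate(
        landmark_names=names,
        dim=3,
        paired=[],
        midline=[],
        views={n: "mandible" for n in names},
        distance_defs=defs,
    )
    return template, base
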