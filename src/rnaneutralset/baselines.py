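"""Competing sample-free neutral-set-size predictors.

Three baselines are provided for head-to-head comparison with the
free-energy-based estimator:

* the **number of stacks** (maximal runs of adjacent base pairs), a simple
  structural indicator that anti-correlates with mfe set size;
* the **two-versatility model**, which is exactly linear in the number of base
  pairs on the log10 scale: log10 N ~ a * n_bp + b (parameters fitted by OLS on
  a reference table, or supplied);
* a **contiguity statistic** over stem-loop arms (see below).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structures import (
    SecondaryStructure,
    compute_features,
    loop_decomposition,
    parse_structure,
)

__all__ = [
    "TwoVersatilityParams",
    "stack_count_indicator",
    "two_versatility_estimate",
    "fit_two_versatility",
    "contiguity_statistic",
]


@dataclass(frozen=True)
class TwoVersatilityParams:
    """Slope/intercept of log10 N ~ slope_a * n_bp + intercept_b.

    Any affine reparameterisation leaves rank-based and r^2 comparisons
    unchanged, so the absolute values of (a, b) are immaterial for the
    correlation analyses in this package.  ``component_correction`` multiplies
    the predicted set size by 2^n_bp (adds n_bp*log10(2) on the log scale) to
    convert neutral-component to neutral-set predictions; off by default.
    """

    slope_a: float
    intercept_b: float
    component_correction: bool = False


def stack_count_indicator(structure: SecondaryStructure | str) -> int:
    """Number of stacks: maximal runs of adjacent base pairs.

    A length-one bulge separates two stack regions (even though it carries a
    bridging stacking term in the energy model).
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    return compute_features(structure).n_stack_regions


def two_versatility_estimate(
    structure: SecondaryStructure | str, params: TwoVersatilityParams
) -> float:
    """log10 mfe set size predicted from the number of base pairs alone."""
    if isinstance(structure, str):
        structure = parse_structure(structure)
    n_bp = structure.n_bp
    pred = params.slope_a * n_bp + params.intercept_b
    if params.component_correction:
        pred += n_bp * np.log10(2.0)
    return pred


def fit_two_versatility(
    n_bp: Sequence[int], log10_ref: Sequence[float]
) -> TwoVersatilityParams:
    """Ordinary least squares of reference log10 set sizes on n_bp."""
    n_bp = np.asarray(n_bp, dtype=float)
    y = np.asarray(log10_ref, dtype=float)
    if n_bp.size < 2 or np.ptp(n_bp) == 0:
        raise ValueError("need at least two distinct n_bp values to fit")
    a, b = np.polyfit(n_bp, y, 1)
    return TwoVersatilityParams(slope_a=float(a), intercept_b=float(b))


def contiguity_statistic(structure: SecondaryStructure | str) -> float:
    """Contiguity of base pairing over stem-loop arms.

    The structure is split into *stem-loop arms*: the substructures hanging off
    the exterior loop and off multi-loops (multi-loops are treated like
    exterior loops when delimiting arms).  Each arm therefore contains only
    helices, bulges, internal loops and one terminal hairpin.  The statistic is

        C = mean over arms of (paired bases in arm / arm span),

    i.e. the average paired-site density within arms.  Long uninterrupted
    helices give dense arms (C -> 1); splitting a helix with a large internal
    loop dilutes its arm and lowers C.  The open structure has no arms and is
    assigned C = 0 by convention.
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    inventory = loop_decomposition(structure)
    partner = structure.partner
    # arm roots: branches of the exterior loop and of every multi-loop
    roots: list[tuple[int, int]] = []
    for lp in inventory.loops:
        if lp.kind == "exterior":
            roots.extend(lp.closing_pairs)
        elif lp.kind == "multi":
            roots.extend(lp.closing_pairs[1:])  # children, not the closing pair
    if not roots:
        return 0.0
    densities = []
    for i, j in roots:
        # arm spans (i, j) but stops where a multi-loop starts
        span, paired = _arm_extent(structure, i, j)
        densities.append(paired / span)
    return float(np.mean(densities))


def _arm_extent(structure: SecondaryStructure, i: int, j: int) -> tuple[int, int]:
    """(span, paired count) of the arm rooted at pair (i, j), cut at multi-loops."""
    partner = structure.partner
    span = 0
    paired = 0
    k, l = i, j
    while True:
        span += 2
        paired += 2
        # find children of (k, l)
        kids = []
        m = k + 1
        while m < l:
            if partner[m] > m:
                kids.append((m, partner[m]))
                m = partner[m] + 1
            else:
                m += 1
        if len(kids) == 0:  # hairpin terminates the arm
            span += l - k - 1
            return span, paired
        if len(kids) > 1:  # multi-loop: arm ends here (children are new arms)
            return span, paired
        (p, q) = kids[0]
        span += (p - k - 1) + (l - q - 1)  # bulge/internal loop sites
        k, l = p, q
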