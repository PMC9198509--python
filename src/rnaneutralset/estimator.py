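"""Sample-free estimation of low-energy and mfe neutral set sizes.

The low-energy set size N(G <= x) of a structure A is the number of sequences
that fold into A with free energy at most x (not necessarily as their mfe
structure).  The estimate starts from the exact compatible-sequence count

    N_c = 4^(L - 2 n_bp) * 6^n_bp

and asks which fraction of compatible sequences can supply enough
sequence-dependent stabilisation (stacking + end-of-stack terms) to offset the
sequence-independent loop free energy G_loop.  Sequence constraints at paired
sites and end-of-stack sites are expressed as per-site *versatilities*
v in (0, 1] (1 = unconstrained, minimum = a single allowed pair/letter), and

    N(G <= x) ~= N_c * v_eos^n_eos * v_bp^n_bp.

Versatilities are derived from the required per-stacking-term free energy
G_stacking = G_max / n_stack by linear interpolation between the unconstrained
(-0.5 kcal/mol, v_bp = 1) and GC-only (-3.0 kcal/mol, v_bp = 2/6) endpoints,
with a cascade of fallbacks when stacking alone cannot stabilise the structure.

The mfe set size is approximated by the low-energy set size at the heuristic
cut-off x = (1.5 - n_bp) kcal/mol, optionally shifted by the length-dependent
log10 offset b = 0.05 L - 0.6.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .energies import EnergyParams, load_params, loop_free_energy
from .structures import (
    SecondaryStructure,
    StructuralFeatures,
    compute_features,
    compatible_sequence_count,
    log10_compatible_sequence_count,
    parse_structure,
)

__all__ = [
    "Branch",
    "CutoffPolicy",
    "SetSizeEstimate",
    "heuristic_cutoff",
    "mfe_offset",
    "constrained_sequence_count",
    "estimate_low_energy_set_size",
    "estimate_mfe_set_size",
    "estimate_batch",
]


class Branch(str, enum.Enum):
    UNCONSTRAINED = "unconstrained"
    INTERPOLATED = "interpolated"
    GC_ONLY = "gc_only"
    EOS_CONSTRAINED = "eos_constrained"
    INFEASIBLE_FALLBACK = "infeasible_fallback"


@dataclass(frozen=True)
class CutoffPolicy:
    """How the low-energy cut-off x is chosen per structure.

    ``fixed_x`` uses the given x for every structure; ``heuristic`` derives
    x = (1.5 - n_bp) kcal/mol per structure.  ``offset_b`` (mfe estimates only)
    adds b to the predicted log10 size; ``b = 0.05 L - 0.6`` when requested.
    """

    mode: str = "heuristic"  # "fixed_x" | "heuristic"
    x: Optional[float] = None
    apply_offset: bool = False

    def __post_init__(self):
        if self.mode not in ("fixed_x", "heuristic"):
            raise ValueError(f"unknown cutoff mode {self.mode!r}")
        if self.mode == "fixed_x" and self.x is None:
            raise ValueError("fixed_x mode requires x")


@dataclass(frozen=True)
class SetSizeEstimate:
    """Estimated set size with full diagnostics.

    ``log10_size`` is the primary output; ``n_c`` is the exact compatible
    count and ``f_A = size / N_c`` the estimated fraction of compatible
    sequences meeting the energy criterion.
    """

    log10_size: float
    n_c: int
    branch: Branch
    v_bp: float
    v_eos: float
    G_loop: float
    G_max: float
    G_stacking: float
    x: float
    n_bp: int
    n_stack: int
    n_eos: int
    length: int

    @property
    def size(self) -> float:
        return 10.0 ** self.log10_size

    @property
    def feasible(self) -> bool:
        return self.branch is not Branch.INFEASIBLE_FALLBACK

    @property
    def f_A(self) -> float:
        return 10.0 ** (self.log10_size - log10_compatible_sequence_count(
            self.length, self.n_bp))


def heuristic_cutoff(n_bp: int) -> float:
    """Per-structure cut-off x = (1.5 - n_bp) kcal/mol linking N(G<=x) to N_mfe."""
    if n_bp < 1:
        raise ValueError("heuristic cut-off needs at least one base pair")
    return 1.5 - n_bp


def mfe_offset(L: int) -> float:
    """Length-dependent additive log10 correction b = 0.05 L - 0.6."""
    return 0.05 * L - 0.6


def constrained_sequence_count(
    allowed_per_site: Sequence[int], alphabet_size: int = 4
) -> int:
    """Number of sequences satisfying independent per-site letter constraints.

    The per-site constraint product: with ``k_i`` allowed letters at site i out
    of an alphabet of size ``a``, the count is ``prod(k_i/a) * a^L``.  E.g. one
    fixed letter, one two-letter site and one free site of an L = 3 RNA give
    (1/4)(2/4)(4/4) * 4^3 = 8 sequences.
    """
    count = 1
    for k in allowed_per_site:
        if not 0 <= k <= alphabet_size:
            raise ValueError(f"allowed letter count {k} outside [0, {alphabet_size}]")
        count *= k
    return count


def _interp(x: float, x0: float, y0: float, x1: float, y1: float) -> float:
    return y0 + (y1 - y0) * (x - x0) / (x1 - x0)


def estimate_low_energy_set_size(
    structure: SecondaryStructure | str,
    x: float,
    params: Optional[EnergyParams] = None,
    features: Optional[StructuralFeatures] = None,
) -> SetSizeEstimate:
    """Estimate N(G <= x) for one structure (all energies signed, kcal/mol).

    The cascade (stabilising = negative):

    1. ``G_max = x - (G_loop - a_eos * n_eos)`` is the sequence-dependent
       stabilisation required; ``G_stacking = G_max / n_stack`` per term.
    2. ``G_stacking >= -0.5``: no constraints (v_bp = v_eos = 1).
    3. ``-3.0 <= G_stacking < -0.5``: v_bp interpolated linearly, v_eos = 1.
    4. Stacking insufficient even when GC-only: v_bp = 2/6 and each
       end-of-stack term contributes an extra -0.2; if that covers G_max,
       v_eos = 1.  Otherwise the residual per-eos requirement e sets v_eos by
       interpolation between (0, 1) and (-0.9, 1/4); if |e| > 0.9 (or there are
       no eos terms to constrain) the structure cannot be stabilised within the
       model and the estimate is 0.1 * N_c * (2/6)^n_bp * (1/4)^n_eos.
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    if params is None:
        params = load_params()
    if features is None:
        features = compute_features(structure)
    if features.n_stack < 1:
        raise ValueError(
            "structure has no stacking terms; set size estimate undefined"
        )
    g_loop = loop_free_energy(features.loop_inventory, params)
    g_max = x - (g_loop - params.a_eos * features.n_eos)
    g_stacking = g_max / features.n_stack

    v_bp = params.v_bp_max
    v_eos = params.v_eos_max
    factor_log10 = 0.0
    if g_stacking >= params.G_stack_max:
        branch = Branch.UNCONSTRAINED
    elif g_stacking >= params.G_stack_min:
        branch = Branch.INTERPOLATED
        v_bp = _interp(
            g_stacking,
            params.G_stack_min, params.v_bp_min,
            params.G_stack_max, params.v_bp_max,
        )
    else:
        v_bp = params.v_bp_min
        available = (
            params.G_stack_min * features.n_stack
            - params.eos_gc_bonus * features.n_eos
        )
        if available <= g_max:
            branch = Branch.GC_ONLY
        else:
            if features.n_eos > 0:
                e = (g_max - available) / features.n_eos  # residual, negative
            else:
                e = -math.inf  # nothing left to constrain
            if e >= -params.eos_max_extra:
                branch = Branch.EOS_CONSTRAINED
                v_eos = _interp(
                    e, -params.eos_max_extra, params.v_eos_min, 0.0,
                    params.v_eos_max,
                )
            else:
                branch = Branch.INFEASIBLE_FALLBACK
                v_eos = params.v_eos_min
                factor_log10 = math.log10(params.infeasible_factor)

    log10_size = (
        log10_compatible_sequence_count(features.length, features.n_bp)
        + features.n_eos * math.log10(v_eos)
        + features.n_bp * math.log10(v_bp)
        + factor_log10
    )
    return SetSizeEstimate(
        log10_size=log10_size,
        n_c=compatible_sequence_count(features.length, features.n_bp),
        branch=branch,
        v_bp=v_bp,
        v_eos=v_eos,
        G_loop=g_loop,
        G_max=g_max,
        G_stacking=g_stacking,
        x=x,
        n_bp=features.n_bp,
        n_stack=features.n_stack,
        n_eos=features.n_eos,
        length=features.length,
    )


def estimate_mfe_set_size(
    structure: SecondaryStructure | str,
    params: Optional[EnergyParams] = None,
    apply_offset: bool = False,
    features: Optional[StructuralFeatures] = None,
) -> SetSizeEstimate:
    """Estimate the mfe set size as N(G <= x_heuristic), x = (1.5 - n_bp) kcal/mol.

    ``apply_offset`` adds the empirical log10 correction b = 0.05 L - 0.6
    (off by default).
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    if features is None:
        features = compute_features(structure)
    est = estimate_low_energy_set_size(
        structure, heuristic_cutoff(features.n_bp), params=params,
        features=features,
    )
    if apply_offset:
        est = SetSizeEstimate(
            **{
                **est.__dict__,
                "log10_size": est.log10_size + mfe_offset(features.length),
            }
        )
    return est


def estimate_batch(
    structures: Iterable[SecondaryStructure | str],
    policy: CutoffPolicy = CutoffPolicy(),
    params: Optional[EnergyParams] = None,
) -> pd.DataFrame:
    """Estimate set sizes for many structures; one row per structure.

    Columns: structure, L, n_bp, n_stack, n_eos, G_loop, x, branch, v_bp,
    v_eos, log10_size.
    """
    if params is None:
        params = load_params()
    rows = []
    for s in structures:
        structure = parse_structure(s) if isinstance(s, str) else s
        feats = compute_features(structure)
        x = (
            policy.x if policy.mode == "fixed_x"
            else heuristic_cutoff(feats.n_bp)
        )
        est = estimate_low_energy_set_size(
            structure, x, params=params, features=feats
        )
        log10_size = est.log10_size
        if policy.apply_offset:
            log10_size += mfe_offset(feats.length)
        rows.append(
            {
                "structure": structure.dotbracket,
                "L": feats.length,
                "n_bp": feats.n_bp,
                "n_stack": feats.n_stack,
                "n_eos": feats.n_eos,
                "G_loop": est.G_loop,
                "x": x,
                "branch": est.branch.value,
                "v_bp": est.v_bp,
                "v_eos": est.v_eos,
                "log10_size": log10_size,
            }
        )
    return pd.DataFrame(rows)
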