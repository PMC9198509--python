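"""Sequence-independent loop free energies and the method's fixed constants.

The loop free energy ``G_loop`` of a structure is the sum of the Turner
nearest-neighbour loop initiation terms (hairpin, bulge, internal including the
capped asymmetry penalty, multiloop linear model) over all loops; exterior
loops contribute nothing.  Sequence-dependent contributions (stacking,
dangling ends, terminal mismatches) are handled separately by the estimator,
so G_loop depends on the structure alone.  Every contribution is rounded to
0.1 kcal/mol.

Parameters default to the Turner 2004 set (vendored plain-text table); any
file in the ViennaRNA ``.par`` dialect with the hairpin/bulge/internal/NINIO/
ML_params sections can be loaded instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .structures import Loop, LoopInventory

__all__ = ["EnergyParams", "load_params", "loop_free_energy", "ParameterFileError"]

_TABLE_MAX = 30  # largest tabulated loop size; larger loops are extrapolated


class ParameterFileError(ValueError):
    """Parameter file is malformed or missing a required section."""


@dataclass(frozen=True)
class EnergyParams:
    """Loop-initiation tables plus the estimator's fixed energetic constants.

    Table energies and all constants are in kcal/mol.  ``lxc`` is the
    coefficient of the standard logarithmic long-loop extrapolation
    ``G(s) = G(30) + lxc * ln(s/30)`` for s > 30.
    """

    hairpin_init: tuple[float, ...]  # index = loop size, NaN where undefined
    bulge_init: tuple[float, ...]
    internal_init: tuple[float, ...]
    asymmetry_per_unit: float = 0.6
    asymmetry_max: float = 3.0
    multiloop_offset: float = 9.3
    multiloop_per_branch: float = -0.9
    multiloop_per_unpaired: float = 0.0
    lxc: float = 1.07856
    rounding_quantum: float = 0.1
    # estimator constants
    a_eos: float = 0.5           # minimum stabilisation per end-of-stack term
    eos_gc_bonus: float = 0.2    # extra per eos term when stacks are GC-only
    eos_max_extra: float = 0.9   # max additional eos stabilisation when constrained
    eos_total_max: float = 1.6   # = a_eos + eos_gc_bonus + eos_max_extra
    G_stack_min: float = -3.0    # GC/CG-only stacking term
    G_stack_max: float = -0.5    # unconstrained stacking term
    v_bp_min: float = 2.0 / 6.0
    v_bp_max: float = 1.0
    v_eos_min: float = 0.25
    v_eos_max: float = 1.0
    infeasible_factor: float = 0.1

    def __post_init__(self):
        if not (self.G_stack_min < self.G_stack_max < 0):
            raise ValueError("require G_stack_min < G_stack_max < 0")
        for v in (self.v_bp_min, self.v_bp_max, self.v_eos_min, self.v_eos_max):
            if not 0 < v <= 1:
                raise ValueError("versatility bounds must lie in (0, 1]")
        if abs(self.a_eos + self.eos_gc_bonus + self.eos_max_extra
               - self.eos_total_max) > 1e-9:
            raise ValueError(
                "a_eos + eos_gc_bonus + eos_max_extra must equal eos_total_max"
            )

    def _round(self, x: float) -> float:
        q = self.rounding_quantum
        return round(x / q) * q

    def _lookup(self, table: tuple[float, ...], size: int, what: str) -> float:
        if size >= len(table):
            base = table[_TABLE_MAX]
            if math.isnan(base):
                raise ValueError(f"no {what} initiation for size {size}")
            return self._round(base + self.lxc * math.log(size / _TABLE_MAX))
        val = table[size]
        if math.isnan(val):
            raise ValueError(f"no {what} initiation for loop size {size}")
        return self._round(val)

    def hairpin(self, size: int) -> float:
        return self._lookup(self.hairpin_init, size, "hairpin")

    def bulge(self, size: int) -> float:
        return self._lookup(self.bulge_init, size, "bulge")

    def internal(self, total_size: int) -> float:
        return self._lookup(self.internal_init, total_size, "internal loop")

    def asymmetry(self, s1: int, s2: int) -> float:
        return self._round(
            min(self.asymmetry_per_unit * abs(s1 - s2), self.asymmetry_max)
        )

    def multiloop(self, branch_count: int, unpaired: int) -> float:
        return self._round(
            self.multiloop_offset
            + self.multiloop_per_branch * branch_count
            + self.multiloop_per_unpaired * unpaired
        )


def _parse_par_values(lines: list[str], start: int) -> tuple[list[float], int]:
    vals: list[float] = []
    i = start
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("#") or not line:
            break
        for tok in line.split():
            if tok.upper() == "INF":
                vals.append(math.nan)
            else:
                vals.append(int(tok) / 100.0)  # dcal/mol -> kcal/mol
        i += 1
    return vals, i


def load_params(source=None) -> EnergyParams:
    """Load loop parameters from a ``.par``-dialect file (default: built-in table)."""
    if source is None:
        text = (
            resources.files("rnaneutralset")
            .joinpath("data/turner2004_loops.par")
            .read_text()
        )
    else:
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    sections: dict[str, list[float]] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("# "):
            name = line[2:].strip()
            vals, j = _parse_par_values(lines, i + 1)
            if vals:
                sections[name] = vals
                i = j
                continue
        i += 1
    missing = {"hairpin", "bulge", "internal", "NINIO", "ML_params"} - set(sections)
    if missing:
        raise ParameterFileError(f"missing parameter sections: {sorted(missing)}")
    for name in ("hairpin", "bulge", "internal"):
        if len(sections[name]) < _TABLE_MAX + 1:
            raise ParameterFileError(
                f"section {name} has {len(sections[name])} entries, "
                f"expected {_TABLE_MAX + 1}"
            )
    ninio = sections["NINIO"]       # m, m_dH, max
    ml = sections["ML_params"]      # cu, cu_dH, cc, cc_dH, ci, ci_dH
    if len(ninio) < 3 or len(ml) < 6:
        raise ParameterFileError("NINIO or ML_params section truncated")
    return EnergyParams(
        hairpin_init=tuple(sections["hairpin"][: _TABLE_MAX + 1]),
        bulge_init=tuple(sections["bulge"][: _TABLE_MAX + 1]),
        internal_init=tuple(sections["internal"][: _TABLE_MAX + 1]),
        asymmetry_per_unit=ninio[0],
        asymmetry_max=ninio[2],
        multiloop_per_unpaired=ml[0],
        multiloop_offset=ml[2],
        multiloop_per_branch=ml[4],
    )


def loop_free_energy(loops: LoopInventory, params: Optional[EnergyParams] = None) -> float:
    """Sequence-independent loop free energy G_loop in kcal/mol.

    Sums loop initiation terms (plus capped internal-loop asymmetry and the
    linear multiloop model) over all loops; no stacking, dangling-end or
    terminal-mismatch terms.  Contributions and the total are rounded to the
    0.1 kcal/mol quantum.
    """
    if params is None:
        params = load_params()
    total = 0.0
    for lp in loops.loops:
        total += _loop_term(lp, params)
    return params._round(total)


def _loop_term(lp: Loop, params: EnergyParams) -> float:
    if lp.kind == "exterior":
        return 0.0
    if lp.kind == "hairpin":
        return params.hairpin(lp.unpaired_sizes[0])
    if lp.kind == "bulge":
        return params.bulge(lp.unpaired_sizes[0])
    if lp.kind == "internal":
        s1, s2 = lp.unpaired_sizes
        return params._round(
            params.internal(s1 + s2) + params.asymmetry(s1, s2)
        )
    if lp.kind == "multi":
        return params.multiloop(lp.branch_count, lp.size)
    raise ValueError(f"unknown loop kind {lp.kind!r}")
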