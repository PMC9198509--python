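"""Sample-based reference estimates: a nested-set Monte Carlo set-size estimator.

This module provides the validation reference for the sample-free estimator:
a nested-set neutral-set-size estimator (NNSE) behind a pluggable
thermodynamic folding backend.  Two criteria are supported:

* ``mfe``: a sequence belongs to the innermost set when its predicted mfe
  structure equals the target structure; nested sets are defined by the
  base-pair distance between the two structures.
* ``low_energy``: a sequence belongs when its free energy on the target
  structure satisfies G_A <= x; nested sets are defined by the energy distance
  d = max(G_A - x, 0) binned at d = 0, d <= 1, ..., d <= 9 kcal/mol plus one
  unbounded set.

For each pair of adjacent nested sets, a seeded random walk restricted to the
outer set (point mutations at unpaired sites and legal base-pair swaps at
paired sites; moves leaving the set are rejected and the current state is
re-counted) estimates the fraction of its members lying in the inner set.  The
product of fractions times the compatible-sequence count N_c (the walks
preserve compatibility by construction) estimates the innermost-set size.
Independent measurements are averaged in log space; a walk that never visits
the inner set is retried with ten-fold more measurement steps and flagged if
it still fails.

Also included: seed-sequence search for strict energy criteria, and exhaustive
small-L oracles that enumerate every compatible sequence.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass
from typing import Iterator, Optional, Protocol

from .structures import (
    SecondaryStructure,
    compatible_sequence_count,
    parse_structure,
)

__all__ = [
    "FoldingBackend",
    "ViennaBackend",
    "NNSEConfig",
    "NNSEResult",
    "SeedSearchError",
    "seed_low_energy_sequence",
    "low_energy_distance",
    "nnse_estimate",
    "exhaustive_low_energy_count",
    "exhaustive_mfe_count",
    "compatible_sequences",
]

PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")
BASES = "ACGU"


class FoldingBackend(Protocol):
    """Thermodynamic folding engine interface."""

    def mfe_fold(self, sequence: str) -> tuple[str, float]: ...

    def energy_of(self, sequence: str, dotbracket: str) -> float: ...

    def inverse_fold(self, dotbracket: str, seed: Optional[int] = None) -> Optional[str]: ...


class ViennaBackend:
    """ViennaRNA-backed folding engine (no isolated base pairs by default)."""

    def __init__(self, no_lonely_pairs: bool = True):
        import RNA  # lazy: only reference workflows need the engine

        self._RNA = RNA
        self._md = RNA.md()
        self._md.noLP = 1 if no_lonely_pairs else 0
        RNA.cvar.noLonelyPairs = 1 if no_lonely_pairs else 0

    def mfe_fold(self, sequence: str) -> tuple[str, float]:
        fc = self._RNA.fold_compound(sequence, self._md)
        structure, energy = fc.mfe()
        return structure, float(energy)

    def energy_of(self, sequence: str, dotbracket: str) -> float:
        return float(self._RNA.energy_of_struct(sequence, dotbracket))

    def inverse_fold(self, dotbracket: str, seed: Optional[int] = None) -> Optional[str]:
        rng = random.Random(seed)
        start = random_compatible_sequence(parse_structure(dotbracket), rng)
        result, distance = self._RNA.inverse_fold(start, dotbracket)
        return result if distance == 0 else None


@dataclass(frozen=True)
class NNSEConfig:
    """Run parameters of the nested-set estimator.

    Defaults follow the reference configuration: three measurements, 2000
    initialisation and 2000 measurement steps per nested-set pair, seed walks
    of up to 5000 mutations, 11 nested distance bins (d = 0, d <= 1, ...,
    d <= 9 and one unbounded set) and a ten-fold step increase on retry.
    Proposals mix point mutations and base-pair swaps 50/50 where both exist.
    """

    n_measurements: int = 3
    init_steps: int = 2000
    measure_steps: int = 2000
    max_seed_walk_mutations: int = 5000
    bin_bounds: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)
    retry_factor: int = 10
    pair_swap_prob: float = 0.5


@dataclass(frozen=True)
class NNSEResult:
    log10_size: float
    converged: bool
    criterion: str
    x: Optional[float]
    n_measurements: int
    fractions: tuple[tuple[float, ...], ...]  # per measurement

    @property
    def size(self) -> float:
        return 10.0 ** self.log10_size


class SeedSearchError(RuntimeError):
    """No start sequence satisfying the criterion was found."""


def random_compatible_sequence(structure: SecondaryStructure, rng: random.Random) -> str:
    seq = [rng.choice(BASES) for _ in range(structure.length)]
    for i, j in structure.pairs:
        seq[i], seq[j] = rng.choice(PAIRS)
    return "".join(seq)


def _gc_a_sequence(structure: SecondaryStructure) -> str:
    seq = ["A"] * structure.length
    for i, j in structure.pairs:
        seq[i], seq[j] = "G", "C"
    return "".join(seq)


def _greedy_sequence(structure: SecondaryStructure, backend: FoldingBackend) -> str:
    """Constructive low-energy assignment: greedy pair choice from the GC/A start."""
    db = structure.dotbracket
    seq = list(_gc_a_sequence(structure))
    for i, j in structure.pairs:
        best = None
        best_g = math.inf
        for a, b in PAIRS:
            seq[i], seq[j] = a, b
            g = backend.energy_of("".join(seq), db)
            if g < best_g:
                best_g, best = g, (a, b)
        seq[i], seq[j] = best
    return "".join(seq)


def _propose(seq: list[str], structure: SecondaryStructure, rng: random.Random,
             pair_swap_prob: float) -> tuple[int, ...]:
    """Mutate seq in place; return undo information (positions, old letters)."""
    pairs = structure.pairs
    unpaired = structure.length - 2 * len(pairs)
    if pairs and (unpaired == 0 or rng.random() < pair_swap_prob):
        i, j = pairs[rng.randrange(len(pairs))]
        old = (i, seq[i], j, seq[j])
        choices = [p for p in PAIRS if p != seq[i] + seq[j]]
        seq[i], seq[j] = rng.choice(choices)
        return old
    # point mutation at an unpaired site
    partner = structure.partner
    while True:
        k = rng.randrange(structure.length)
        if partner[k] == -1:
            break
    old = (k, seq[k])
    seq[k] = rng.choice([b for b in BASES if b != seq[k]])
    return old


def _undo(seq: list[str], old: tuple) -> None:
    if len(old) == 4:
        i, a, j, b = old
        seq[i], seq[j] = a, b
    else:
        k, a = old
        seq[k] = a


def seed_low_energy_sequence(
    structure: SecondaryStructure | str,
    x: float,
    backend: FoldingBackend,
    config: NNSEConfig = NNSEConfig(),
    seed: int = 0,
) -> str:
    """Find a sequence with G_A(sequence) <= x on the given structure.

    Tries three educated guesses (GC pairs + A loops; the backend's inverse
    folding; a constructive greedy assignment), then a downhill random walk of
    point mutations and base-pair swaps from the best of the three.
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    db = structure.dotbracket
    rng = random.Random(seed)
    candidates = [_gc_a_sequence(structure)]
    inv = backend.inverse_fold(db, seed=rng.randrange(2**31))
    if inv is not None:
        candidates.append(inv)
    candidates.append(_greedy_sequence(structure, backend))
    energies = [backend.energy_of(s, db) for s in candidates]
    best_idx = min(range(len(candidates)), key=lambda i: energies[i])
    if energies[best_idx] <= x:
        return candidates[best_idx]
    # downhill walk from the best guess
    seq = list(candidates[best_idx])
    g = energies[best_idx]
    for _ in range(config.max_seed_walk_mutations):
        old = _propose(seq, structure, rng, config.pair_swap_prob)
        g_new = backend.energy_of("".join(seq), db)
        if g_new <= g:
            g = g_new
            if g <= x:
                return "".join(seq)
        else:
            _undo(seq, old)
    raise SeedSearchError(
        f"no sequence with G <= {x} kcal/mol found for {db} "
        f"(best reached: {g:.2f})"
    )


def low_energy_distance(
    sequence: str,
    structure: SecondaryStructure | str,
    x: float,
    backend: FoldingBackend,
) -> tuple[float, int]:
    """Energy distance d = max(G_A - x, 0) and the innermost nested bin holding it."""
    if isinstance(structure, str):
        structure = parse_structure(structure)
    _check_compatible(sequence, structure)
    g = backend.energy_of(sequence, structure.dotbracket)
    d = max(g - x, 0.0)
    return d, _bin_index(d, NNSEConfig().bin_bounds)


def _bin_index(d: float, bounds: tuple[float, ...]) -> int:
    for idx, bound in enumerate(bounds):
        if d <= bound + 1e-9:
            return idx
    return len(bounds)  # unbounded outermost set


def _check_compatible(sequence: str, structure: SecondaryStructure) -> None:
    if len(sequence) != structure.length:
        raise ValueError("sequence/structure length mismatch")
    for i, j in structure.pairs:
        if sequence[i] + sequence[j] not in PAIRS:
            raise ValueError(
                f"sequence not compatible: illegal pair "
                f"{sequence[i]}{sequence[j]} at ({i + 1},{j + 1})"
            )


def _bp_distance(db_a: str, db_b: str) -> int:
    pa = parse_structure(db_a).pairs if "(" in db_a else ()
    pb = parse_structure(db_b).pairs if "(" in db_b else ()
    return len(set(pa) ^ set(pb))


def nnse_estimate(
    structure: SecondaryStructure | str,
    criterion: str,
    backend: FoldingBackend,
    config: NNSEConfig = NNSEConfig(),
    seed: int = 0,
    x: Optional[float] = None,
    seed_sequence: Optional[str] = None,
) -> NNSEResult:
    """Nested-set Monte Carlo estimate of a set size (log10).

    ``criterion`` is ``"mfe"`` (innermost set: mfe structure equals the
    target) or ``"low_energy"`` (innermost set: G_A <= x).  Measurements are
    averaged in log space; fixed seeds reproduce the estimate exactly.
    A known innermost-set member (e.g. the witness from designability
    filtering) may be passed as ``seed_sequence`` to skip the seed search.
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    if criterion not in ("mfe", "low_energy"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "low_energy" and x is None:
        raise ValueError("low_energy criterion requires x")
    db = structure.dotbracket
    rng = random.Random(seed)

    if criterion == "low_energy":
        def distance(seq: str) -> float:
            return max(backend.energy_of(seq, db) - x, 0.0)
    else:
        def distance(seq: str) -> float:
            mfe_db, _ = backend.mfe_fold(seq)
            return float(_bp_distance(mfe_db, db))

    # seed sequence in the innermost set
    if seed_sequence is not None and distance(seed_sequence) == 0:
        _check_compatible(seed_sequence, structure)
        seed_seq = seed_sequence
    elif criterion == "low_energy":
        seed_seq = seed_low_energy_sequence(
            structure, x, backend, config, seed=rng.randrange(2**31)
        )
    else:
        seed_seq = _seed_mfe_sequence(structure, backend, config, rng, distance)

    bounds = config.bin_bounds
    n_c = compatible_sequence_count(structure.length, structure.n_bp)
    log10_nc = (
        (structure.length - 2 * structure.n_bp) * math.log10(4.0)
        + structure.n_bp * math.log10(6.0)
    )
    all_fractions = []
    converged = True
    for _ in range(config.n_measurements):
        fractions = []
        for k in range(1, len(bounds) + 1):
            outer = math.inf if k == len(bounds) else bounds[k]
            inner = bounds[k - 1]
            frac = _walk_fraction(
                seed_seq, structure, distance, outer, inner, rng,
                config.init_steps, config.measure_steps, config.pair_swap_prob,
            )
            if frac == 0.0:  # retry with more measurement steps
                frac = _walk_fraction(
                    seed_seq, structure, distance, outer, inner, rng,
                    config.init_steps * config.retry_factor,
                    config.measure_steps * config.retry_factor,
                    config.pair_swap_prob,
                )
            if frac == 0.0:
                converged = False
                frac = 1.0 / (config.measure_steps * config.retry_factor)
            fractions.append(frac)
        all_fractions.append(tuple(fractions))
    log10_sizes = [
        log10_nc + sum(math.log10(f) for f in fr) for fr in all_fractions
    ]
    return NNSEResult(
        log10_size=sum(log10_sizes) / len(log10_sizes),
        converged=converged,
        criterion=criterion,
        x=x,
        n_measurements=config.n_measurements,
        fractions=tuple(all_fractions),
    )


def _seed_mfe_sequence(
    structure: SecondaryStructure,
    backend: FoldingBackend,
    config: NNSEConfig,
    rng: random.Random,
    distance,
) -> str:
    """Sequence whose mfe structure is the target: inverse folding, then a
    downhill walk on the base-pair distance from the GC/A guess."""
    db = structure.dotbracket
    for _ in range(10):
        cand = backend.inverse_fold(db, seed=rng.randrange(2**31))
        if cand is not None:
            return cand
    best_d = math.inf
    for restart in range(3):
        seq = list(
            _gc_a_sequence(structure) if restart == 0
            else random_compatible_sequence(structure, rng)
        )
        d = distance("".join(seq))
        if d == 0:
            return "".join(seq)
        for _ in range(config.max_seed_walk_mutations):
            old = _propose(seq, structure, rng, config.pair_swap_prob)
            d_new = distance("".join(seq))
            if d_new <= d:
                d = d_new
                if d == 0:
                    return "".join(seq)
            else:
                _undo(seq, old)
        best_d = min(best_d, d)
    raise SeedSearchError(
        f"no sequence with mfe structure {db} found (closest distance {best_d})"
    )


def _walk_fraction(
    seed_seq: str,
    structure: SecondaryStructure,
    distance,
    outer_bound: float,
    inner_bound: float,
    rng: random.Random,
    init_steps: int,
    measure_steps: int,
    pair_swap_prob: float,
) -> float:
    """Fraction of the outer nested set lying in the inner set, by random walk."""
    seq = list(seed_seq)
    d = distance(seed_seq)
    hits = 0
    for step in range(init_steps + measure_steps):
        old = _propose(seq, structure, rng, pair_swap_prob)
        d_new = distance("".join(seq))
        if d_new <= outer_bound + 1e-9:
            d = d_new
        else:
            _undo(seq, old)
        if step >= init_steps and d <= inner_bound + 1e-9:
            hits += 1
    return hits / measure_steps


# ---------------------------------------------------------------------------
# Exhaustive oracles (small L): every compatible sequence is evaluated
# ---------------------------------------------------------------------------


def compatible_sequences(structure: SecondaryStructure | str) -> Iterator[str]:
    """All sequences compatible with the structure (N_c of them)."""
    if isinstance(structure, str):
        structure = parse_structure(structure)
    pairs = structure.pairs
    unpaired = [k for k in range(structure.length) if structure.partner[k] == -1]
    template = ["A"] * structure.length
    for pair_choice in itertools.product(PAIRS, repeat=len(pairs)):
        for (i, j), (a, b) in zip(pairs, pair_choice):
            template[i], template[j] = a, b
        for letters in itertools.product(BASES, repeat=len(unpaired)):
            for k, c in zip(unpaired, letters):
                template[k] = c
            yield "".join(template)


def exhaustive_low_energy_count(
    structure: SecondaryStructure | str, x: float, backend: FoldingBackend
) -> int:
    """Exact N(G <= x): count compatible sequences with G_A <= x."""
    if isinstance(structure, str):
        structure = parse_structure(structure)
    db = structure.dotbracket
    return sum(
        1 for seq in compatible_sequences(structure)
        if backend.energy_of(seq, db) <= x
    )


def exhaustive_mfe_count(
    structure: SecondaryStructure | str, backend: FoldingBackend
) -> int:
    """Exact N_mfe: count compatible sequences whose mfe structure is the target.

    Only compatible sequences can fold into the structure at all, so the scan
    over N_c sequences is exact even though 4^L sequences exist.
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    db = structure.dotbracket
    return sum(
        1 for seq in compatible_sequences(structure)
        if backend.mfe_fold(seq)[0] == db
    )
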