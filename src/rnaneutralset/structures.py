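"""Dot-bracket secondary structures, loop decomposition and structural features.

An RNA secondary structure is represented in dot-bracket notation: '(' and ')'
mark the two halves of a base pair, '.' marks an unpaired base.  Structures are
nested (no pseudoknots), hairpin loops contain at least three unpaired bases and,
optionally, every base pair must sit in a helix of at least two adjacent pairs
("no lonely pairs", the default folding convention used throughout this package).

Positions are 0-based internally; user-facing reports convert to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log10
from typing import Iterable, Iterator, Sequence

__all__ = [
    "StructureError",
    "InvalidCharacterError",
    "UnbalancedBracketsError",
    "HairpinTooShortError",
    "LonelyPairError",
    "SecondaryStructure",
    "Loop",
    "LoopInventory",
    "StructuralFeatures",
    "parse_structure",
    "loop_decomposition",
    "compute_features",
    "compatible_sequence_count",
    "log10_compatible_sequence_count",
    "read_dotbracket_file",
    "write_dotbracket_file",
]

MIN_HAIRPIN = 3


class StructureError(ValueError):
    """Base class for structure validation errors."""


class InvalidCharacterError(StructureError):
    """Input contains characters other than '(', ')' and '.'."""


class UnbalancedBracketsError(StructureError):
    """Opening and closing brackets do not match up."""


class HairpinTooShortError(StructureError):
    """A hairpin loop encloses fewer unpaired bases than the minimum."""


class LonelyPairError(StructureError):
    """A base pair is not adjacent to another pair (isolated pair)."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A validated dot-bracket secondary structure.

    Attributes
    ----------
    dotbracket:
        The dot-bracket string, reproduced exactly on serialisation.
    pairs:
        Sorted tuple of 0-based index pairs ``(i, j)`` with ``i < j``.
    """

    dotbracket: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def n_bp(self) -> int:
        return len(self.pairs)

    @property
    def partner(self) -> list[int]:
        """Partner index per position (-1 for unpaired)."""
        table = [-1] * self.length
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table

    def __str__(self) -> str:  # round-trips the input exactly
        return self.dotbracket


def parse_structure(
    dotbracket: str,
    no_lonely_pairs: bool = False,
    min_hairpin: int = MIN_HAIRPIN,
) -> SecondaryStructure:
    """Parse and validate a dot-bracket string.

    Raises
    ------
    InvalidCharacterError, UnbalancedBracketsError, HairpinTooShortError,
    LonelyPairError
        Each violated invariant raises its own error type.
    """
    if not dotbracket:
        raise StructureError("empty structure string")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, char in enumerate(dotbracket):
        if char == "(":
            stack.append(pos)
        elif char == ")":
            if not stack:
                raise UnbalancedBracketsError(
                    f"unmatched ')' at position {pos + 1}"
                )
            i = stack.pop()
            pairs.append((i, pos))
        elif char != ".":
            raise InvalidCharacterError(
                f"invalid character {char!r} at position {pos + 1}"
            )
    if stack:
        raise UnbalancedBracketsError(
            f"unmatched '(' at position {stack[-1] + 1}"
        )
    pairs.sort()
    pair_set = set(pairs)
    for i, j in pairs:
        # hairpin check: innermost pairs enclose only unpaired positions
        if all(dotbracket[k] == "." for k in range(i + 1, j)):
            if j - i - 1 < min_hairpin:
                raise HairpinTooShortError(
                    f"hairpin closed by pair ({i + 1},{j + 1}) has length "
                    f"{j - i - 1} < {min_hairpin}"
                )
    if no_lonely_pairs:
        for i, j in pairs:
            if (i + 1, j - 1) not in pair_set and (i - 1, j + 1) not in pair_set:
                raise LonelyPairError(
                    f"isolated base pair ({i + 1},{j + 1})"
                )
    return SecondaryStructure(dotbracket=dotbracket, pairs=tuple(pairs))


@dataclass(frozen=True)
class Loop:
    """One loop region.

    ``unpaired_sizes`` holds one entry per strand segment of the loop (hairpins
    have one, internal loops two, bulges one non-empty segment, multi/exterior
    loops one per gap between branches, zeros included).  ``branch_count``
    counts helices bordering the loop, including the closing pair for
    hairpin/bulge/internal/multi loops.
    """

    kind: str  # hairpin | bulge | internal | multi | exterior
    unpaired_sizes: tuple[int, ...]
    branch_count: int
    closing_pairs: tuple[tuple[int, int], ...]

    @property
    def size(self) -> int:
        return sum(self.unpaired_sizes)


@dataclass(frozen=True)
class LoopInventory:
    loops: tuple[Loop, ...]

    def by_kind(self, kind: str) -> tuple[Loop, ...]:
        return tuple(lp for lp in self.loops if lp.kind == kind)

    @property
    def total_unpaired(self) -> int:
        return sum(lp.size for lp in self.loops)


def _children(
    structure: SecondaryStructure, i: int, j: int
) -> list[tuple[int, int]]:
    """Pairs directly enclosed by (i, j) (exclusive); use i=-1, j=L for top level."""
    partner = structure.partner
    out = []
    k = i + 1
    while k < j:
        if partner[k] > k:
            out.append((k, partner[k]))
            k = partner[k] + 1
        else:
            k += 1
    return out


def loop_decomposition(structure: SecondaryStructure) -> LoopInventory:
    """Assign every unpaired position to exactly one loop.

    The exterior loop is always present (possibly with zero unpaired sites and
    zero branches).  Two pairs stacked directly on top of each other enclose no
    loop between them.
    """
    partner = structure.partner
    L = structure.length
    loops: list[Loop] = []

    # exterior loop
    top = _children(structure, -1, L)
    gaps = _gap_sizes(-1, L, top)
    loops.append(
        Loop(
            kind="exterior",
            unpaired_sizes=tuple(gaps),
            branch_count=len(top),
            closing_pairs=tuple(top),
        )
    )

    stack: list[tuple[int, int]] = list(top)
    while stack:
        i, j = stack.pop()
        kids = _children(structure, i, j)
        stack.extend(kids)
        if not kids:
            loops.append(
                Loop(
                    kind="hairpin",
                    unpaired_sizes=(j - i - 1,),
                    branch_count=0,
                    closing_pairs=((i, j),),
                )
            )
        elif len(kids) == 1:
            (k, l) = kids[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                continue  # stacked pairs, no loop
            if s1 == 0 or s2 == 0:
                loops.append(
                    Loop(
                        kind="bulge",
                        unpaired_sizes=(max(s1, s2),),
                        branch_count=2,
                        closing_pairs=((i, j), (k, l)),
                    )
                )
            else:
                loops.append(
                    Loop(
                        kind="internal",
                        unpaired_sizes=(s1, s2),
                        branch_count=2,
                        closing_pairs=((i, j), (k, l)),
                    )
                )
        else:
            loops.append(
                Loop(
                    kind="multi",
                    unpaired_sizes=tuple(_gap_sizes(i, j, kids)),
                    branch_count=len(kids) + 1,
                    closing_pairs=tuple([(i, j)] + kids),
                )
            )
    return LoopInventory(loops=tuple(loops))


def _gap_sizes(i: int, j: int, kids: Sequence[tuple[int, int]]) -> list[int]:
    """Unpaired segment lengths between position i, the child helices, and j."""
    bounds = [i]
    for k, l in kids:
        bounds.extend([k, l])
    bounds.append(j)
    return [bounds[m + 1] - bounds[m] - 1 for m in range(0, len(bounds), 2)]


@dataclass(frozen=True)
class StructuralFeatures:
    """Counts consumed by the set-size estimator and the baselines.

    ``n_stack_regions`` counts maximal runs of adjacent base pairs (a
    length-one bulge separates two regions).  ``n_stack`` counts stacking
    free-energy terms: one per adjacent pair of base pairs plus one per
    length-one bulge bridging two helices.  ``n_eos`` counts end-of-stack
    (merged dangling-end / terminal-mismatch) terms.
    """

    n_bp: int
    n_stack_regions: int
    n_stack: int
    n_eos: int
    loop_inventory: LoopInventory
    length: int


def _eos_qualifies(loop: Loop) -> int:
    """End-of-stack terms contributed by one loop, over all adjacent stack ends."""
    if loop.kind == "hairpin":
        return 1 if loop.unpaired_sizes[0] >= 4 else 0
    if loop.kind == "internal":
        s1, s2 = loop.unpaired_sizes
        if min(s1, s2) >= 2 and max(s1, s2) >= 3:
            return 2  # one per adjacent stack end
        return 0
    if loop.kind == "multi":
        return loop.branch_count
    if loop.kind == "exterior":
        return loop.branch_count  # no length condition, even if zero unpaired
    return 0  # bulges carry no end-of-stack term


def compute_features(structure: SecondaryStructure) -> StructuralFeatures:
    pair_set = set(structure.pairs)
    n_bp = len(pair_set)
    # stack regions: maximal runs of directly adjacent pairs
    n_regions = sum(1 for (i, j) in pair_set if (i - 1, j + 1) not in pair_set)
    n_adjacent = sum(1 for (i, j) in pair_set if (i + 1, j - 1) in pair_set)
    inventory = loop_decomposition(structure)
    n_bridges = sum(
        1 for lp in inventory.loops if lp.kind == "bulge" and lp.size == 1
    )
    n_eos = sum(_eos_qualifies(lp) for lp in inventory.loops)
    return StructuralFeatures(
        n_bp=n_bp,
        n_stack_regions=n_regions,
        n_stack=n_adjacent + n_bridges,
        n_eos=n_eos,
        loop_inventory=inventory,
        length=structure.length,
    )


def compatible_sequence_count(L: int, n_bp: int) -> int:
    """Exact number of sequences compatible with a structure: 4^(L-2n_bp) * 6^n_bp.

    A compatible sequence carries one of the six legal pairs (AU, UA, GC, CG,
    GU, UG) at every paired position and any base elsewhere.
    """
    if n_bp < 0:
        raise ValueError("n_bp must be non-negative")
    if 2 * n_bp > L:
        raise ValueError(f"structure cannot hold {n_bp} pairs in {L} bases")
    return 4 ** (L - 2 * n_bp) * 6 ** n_bp


def log10_compatible_sequence_count(L: int, n_bp: int) -> float:
    if n_bp < 0 or 2 * n_bp > L:
        compatible_sequence_count(L, n_bp)  # raise the same errors
    return (L - 2 * n_bp) * log10(4.0) + n_bp * log10(6.0)


def read_dotbracket_file(path) -> list[str]:
    """Read dot-bracket strings, one per line; '#' comments and blanks ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split()[0])
    return out


def write_dotbracket_file(path, structures: Iterable[str | SecondaryStructure]) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s}\n")


def read_fasta_structures(path) -> list[tuple[str, str, str]]:
    """Read FASTA-style paired records: header, sequence line, structure line.

    Returns (name, sequence, dotbracket) triples; used by reference-sampler
    workflows where a sequence accompanies each structure.
    """
    records = []
    name, lines = None, []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(_fasta_record(name, lines))
                name, lines = line[1:].strip(), []
            else:
                lines.append(line)
    if name is not None:
        records.append(_fasta_record(name, lines))
    return records


def _fasta_record(name: str, lines: list[str]) -> tuple[str, str, str]:
    if len(lines) != 2:
        raise ValueError(
            f"record {name!r}: expected one sequence line and one structure "
            f"line, got {len(lines)} lines"
        )
    sequence, dotbracket = lines
    if len(sequence) != len(dotbracket):
        raise ValueError(f"record {name!r}: sequence/structure length mismatch")
    return name, sequence, dotbracket.split()[0]
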