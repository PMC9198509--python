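"""Counting, enumeration and uniform sampling of valid secondary structures.

A valid structure of length L has matched brackets, no pseudoknots, hairpin
loops of at least ``min_hairpin`` unpaired bases and, when ``no_lonely_pairs``
is set (the default, matching the folding convention used throughout), every
base pair sits in a helix of two or more adjacent pairs.

Counting uses a dynamic-programming recursion over region lengths; enumeration
grows dot-bracket strings symbol by symbol with feasibility pruning, an
independent algorithm that must agree with the DP count.  Uniform sampling
unranks structures from the DP tables, so no full structure list is ever
materialised (at L = 35 the no-lonely-pair space alone exceeds 10^7 strings).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterator, Optional, Sequence

from .structures import (
    SecondaryStructure,
    StructuralFeatures,
    compute_features,
    parse_structure,
)

__all__ = [
    "StructureConstraints",
    "count_structures",
    "enumerate_structures",
    "sample_structures",
    "unrank_structure",
    "EnumerationLimitError",
    "single_stack_hairpin_family",
    "extended_core_family",
    "two_stack_internal_loop_family",
    "sample_fixed_bp_stacks",
]

ENUMERATION_LIMIT = 35


class EnumerationLimitError(RuntimeError):
    """Enumeration requested above the practical length limit without override."""


@dataclass(frozen=True)
class StructureConstraints:
    """Structure-space constraints plus an optional feature predicate.

    The predicate is a pure function of :class:`StructuralFeatures`; it is
    applied by enumeration and sampling but not by the DP count.
    """

    L: int
    min_hairpin: int = 3
    no_lonely_pairs: bool = True
    predicate: Optional[Callable[[StructuralFeatures], bool]] = None

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.min_hairpin < 1:
            raise ValueError("min_hairpin must be >= 1")


# ---------------------------------------------------------------------------
# Dynamic-programming counts
#
# Grammar (region of n bases):
#   A(n): any structure      = '.' A(n-1) | Cc(k) A(n-k)
#   Cc(k): closed component spanning k bases, outermost pair at (1, k)
# With lonely pairs allowed: Cc(k) = A(k-2) minus the all-unpaired interior
# when it is shorter than the hairpin minimum.
# Without lonely pairs, the outer pair must be stacked from inside:
#   Cc(k) = D(k-2) where D(m) is a region with pair (1, m) whose outer pair is
#   already supported from outside:
#   D(m) = D(m-2)            (helix continues)
#        + B(m-2)            (loop interior: first/last not paired together)
#   B(u) = A(u) - Cc(u) - [u < min_hairpin]   (all-unpaired interior of size
#                                              < min_hairpin is an invalid hairpin)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _dp_tables(L: int, min_hairpin: int, no_lonely_pairs: bool):
    mh = min_hairpin
    A = [0] * (L + 1)
    Cc = [0] * (L + 1)
    A[0] = 1
    if no_lonely_pairs:
        D = [0] * (L + 1)
        B = [0] * (L + 1)
        for n in range(1, L + 1):
            # closed tables for span n need smaller A/B values, filled in order
            m = n - 2
            if m >= 0:
                B[m] = A[m] - Cc[m] - (1 if m < mh else 0)
                if m - 2 >= 0:
                    D[m] = (D[m - 2] if m - 4 >= 0 else 0) + B[m - 2]
                Cc[n] = D[m]
            A[n] = A[n - 1] + sum(
                Cc[k] * A[n - k] for k in range(2 * 2 + mh, n + 1)
            )
        return tuple(A), tuple(Cc), tuple(D), tuple(B)
    else:
        for n in range(1, L + 1):
            if n - 2 >= 0:
                Cc[n] = A[n - 2] - (1 if n - 2 < mh else 0)
            A[n] = A[n - 1] + sum(
                Cc[k] * A[n - k] for k in range(mh + 2, n + 1)
            )
        return tuple(A), tuple(Cc), None, None


def count_structures(constraints: StructureConstraints) -> int:
    """Exact number of valid structures (includes the fully unpaired one).

    Feature predicates are not supported here: the count is a DP over region
    lengths, not an enumeration.
    """
    if constraints.predicate is not None:
        raise ValueError("count_structures does not support feature predicates")
    A, _, _, _ = _dp_tables(
        constraints.L, constraints.min_hairpin, constraints.no_lonely_pairs
    )
    return A[constraints.L]


# ---------------------------------------------------------------------------
# Enumeration by recursive symbol extension with pruning (independent of the DP)
# ---------------------------------------------------------------------------


def _extend(
    chars: list[str],
    stack: list[list],  # entries [open_idx, has_child]
    pos: int,
    L: int,
    mh: int,
    nlp: bool,
    must_close: bool,  # previous ')' closed an unsupported pair; forced ')' next
    last_closed_at: int,  # position just after the most recently closed pair, or -1
) -> Iterator[str]:
    if pos == L:
        if not stack and not must_close:
            yield "".join(chars)
        return
    remaining = L - pos
    if must_close:
        # the pair just closed needs support from its enclosing pair: force ')'
        if stack and remaining >= len(stack):
            yield from _do_close(chars, stack, pos, L, mh, nlp)
        return
    # '.'
    if remaining - 1 >= len(stack):
        chars.append(".")
        yield from _extend(chars, stack, pos + 1, L, mh, nlp, False, -1)
        chars.pop()
    # '('
    min_cost = mh + 1  # hairpin + its own ')'
    if nlp and not (stack and stack[-1][0] == pos - 1):
        min_cost = mh + 2 + 2 - 1  # fresh helix needs a second pair
    if remaining - 1 >= len(stack) + min_cost:
        chars.append("(")
        stack.append([pos, False])
        yield from _extend(chars, stack, pos + 1, L, mh, nlp, False, -1)
        stack.pop()
        chars.pop()
    # ')'
    if stack and remaining - 1 >= len(stack) - 1:
        yield from _do_close(chars, stack, pos, L, mh, nlp)


def _do_close(chars, stack, pos, L, mh, nlp):
    open_idx, has_child = stack[-1]
    if not has_child and pos - open_idx - 1 < mh:
        return
    supported = has_child and chars[open_idx + 1] == "(" and _partner_is(
        chars, open_idx + 1, pos - 1
    )
    entry = stack.pop()
    if stack:
        parent_had = stack[-1][1]
        stack[-1][1] = True
    chars.append(")")
    if nlp and not supported:
        # must be rescued by the enclosing pair, closed immediately after;
        # that pair has to sit directly outside: open index open_idx - 1
        if stack and stack[-1][0] == open_idx - 1:
            yield from _extend(chars, stack, pos + 1, L, mh, nlp, True, pos + 1)
    else:
        yield from _extend(chars, stack, pos + 1, L, mh, nlp, False, -1)
    chars.pop()
    if stack:
        stack[-1][1] = parent_had
    stack.append(entry)


def _partner_is(chars: list[str], i: int, j: int) -> bool:
    """True if '(' at i pairs with position j in the string built so far."""
    depth = 0
    for k in range(i, j + 1):
        if chars[k] == "(":
            depth += 1
        elif chars[k] == ")":
            depth -= 1
            if depth == 0:
                return k == j
    return False


def enumerate_structures(
    constraints: StructureConstraints, allow_large: bool = False
) -> Iterator[SecondaryStructure]:
    """Yield every valid structure exactly once (lexicographic in '.', '(', ')').

    Applies the feature predicate, if any, as a filter on the stream.
    """
    if constraints.L > ENUMERATION_LIMIT and not allow_large:
        raise EnumerationLimitError(
            f"enumeration above L={ENUMERATION_LIMIT} requires allow_large=True"
        )
    for s in _extend(
        [], [], 0, constraints.L, constraints.min_hairpin,
        constraints.no_lonely_pairs, False, -1,
    ):
        structure = parse_structure(
            s, no_lonely_pairs=constraints.no_lonely_pairs,
            min_hairpin=constraints.min_hairpin,
        )
        if constraints.predicate is not None:
            if not constraints.predicate(compute_features(structure)):
                continue
        yield structure


# ---------------------------------------------------------------------------
# Unranking and uniform sampling
# ---------------------------------------------------------------------------


def unrank_structure(rank: int, constraints: StructureConstraints) -> str:
    """Dot-bracket string of the structure with the given DP rank.

    The bijection follows the counting grammar: rank 0 is the fully unpaired
    structure; ranks are dense in ``[0, count_structures(constraints))``.
    """
    A, Cc, D, B = _dp_tables(
        constraints.L, constraints.min_hairpin, constraints.no_lonely_pairs
    )
    total = A[constraints.L]
    if not 0 <= rank < total:
        raise ValueError(f"rank {rank} outside [0, {total})")
    mh = constraints.min_hairpin
    nlp = constraints.no_lonely_pairs

    def gen_A(n: int, u: int) -> str:
        if n == 0:
            return ""
        if u < A[n - 1]:
            return "." + gen_A(n - 1, u)
        u -= A[n - 1]
        kmin = (4 + mh) if nlp else (mh + 2)
        for k in range(kmin, n + 1):
            block = Cc[k] * A[n - k]
            if u < block:
                uc, ua = divmod(u, A[n - k])
                return gen_C(k, uc) + gen_A(n - k, ua)
            u -= block
        raise AssertionError("rank decoding fell through")

    def gen_C(k: int, u: int) -> str:
        if nlp:
            return "(" + gen_D(k - 2, u) + ")"
        return "(" + gen_interior(k - 2, u) + ")"

    def gen_interior(m: int, u: int) -> str:
        # lonely pairs allowed: interior is any A(m) except too-short hairpin
        if m < mh:
            u += 1  # skip the all-unpaired string (rank 0 of A(m))
        return gen_A(m, u)

    def gen_D(m: int, u: int) -> str:
        helix = D[m - 2] if m - 2 >= 2 else 0
        if u < helix:
            return "(" + gen_D(m - 2, u) + ")"
        u -= helix
        return "(" + gen_B(m - 2, u) + ")"

    def gen_B(m: int, u: int) -> str:
        # A(m) minus closed-component strings, minus too-short all-unpaired
        if m < mh:
            raise AssertionError("empty B block decoded")
        if u < A[m - 1]:
            return "." + gen_A(m - 1, u)
        u -= A[m - 1]
        kmin = 4 + mh
        for k in range(kmin, m):  # k == m (first/last paired) excluded
            block = Cc[k] * A[m - k]
            if u < block:
                uc, ua = divmod(u, A[m - k])
                return gen_C(k, uc) + gen_A(m - k, ua)
            u -= block
        raise AssertionError("rank decoding fell through in B")

    return gen_A(constraints.L, rank)


def sample_structures(
    constraints: StructureConstraints,
    n: int,
    seed: int,
    designability_filter=None,
    max_inverse_attempts: int = 10,
    include_open: bool = False,
    max_draws: Optional[int] = None,
    with_witnesses: bool = False,
) -> list[SecondaryStructure] | list[tuple[SecondaryStructure, Optional[str]]]:
    """Uniform sample of valid structures, without replacement, seeded.

    Equivalent to shuffling the full structure list and taking the first n, but
    implemented by unranking random ranks from the DP tables.  The fully
    unpaired structure is excluded by default (it has no folded set).  If a
    ``designability_filter`` (an object with an ``inverse_fold(dotbracket)``
    method returning a sequence or None) is given, structures for which no
    sequence is found within ``max_inverse_attempts`` tries are discarded and
    sampling continues until n survivors are collected.  With
    ``with_witnesses`` the result pairs each structure with the sequence the
    filter found for it (None when no filter is active).
    """
    total = count_structures(
        StructureConstraints(
            constraints.L, constraints.min_hairpin, constraints.no_lonely_pairs
        )
    )
    pool = total if include_open else total - 1
    if constraints.predicate is None and n > pool:
        raise ValueError(f"requested {n} structures but only {pool} exist")
    rng = random.Random(seed)
    seen: set[int] = set()
    out: list[SecondaryStructure] = []
    draws = 0
    limit = max_draws if max_draws is not None else max(100 * n, 10000)
    while len(out) < n:
        if len(seen) >= total:
            raise RuntimeError("candidate structures exhausted")
        draws += 1
        if draws > limit:
            raise RuntimeError(
                f"gave up after {draws - 1} draws with {len(out)}/{n} accepted"
            )
        r = rng.randrange(total)
        if r in seen:
            continue
        seen.add(r)
        s = unrank_structure(r, constraints)
        if not include_open and "(" not in s:
            continue
        structure = parse_structure(
            s, no_lonely_pairs=constraints.no_lonely_pairs,
            min_hairpin=constraints.min_hairpin,
        )
        if constraints.predicate is not None:
            if not constraints.predicate(compute_features(structure)):
                continue
        witness = None
        if designability_filter is not None:
            witness = _design_witness(
                structure, designability_filter, max_inverse_attempts, rng
            )
            if witness is None:
                continue
        out.append((structure, witness) if with_witnesses else structure)
    return out


def _design_witness(
    structure, backend, attempts: int, rng: random.Random
) -> Optional[str]:
    for _ in range(attempts):
        seq = backend.inverse_fold(structure.dotbracket, seed=rng.randrange(2**31))
        if seq is not None:
            return seq
    return None


def write_sample(path, structures: Sequence[SecondaryStructure], meta: dict) -> None:
    """Write sampled structures plus a JSON sidecar with seed/constraints."""
    from .structures import write_dotbracket_file

    write_dotbracket_file(path, structures)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# Constrained structure families (single-stack, extended-core, two-stack shapes)
# ---------------------------------------------------------------------------


def single_stack_hairpin_family(
    L: int = 35, hairpin: int = 11, min_stack: int = 2
) -> list[SecondaryStructure]:
    """All structures with one helix closing a fixed-size hairpin, plus exterior dots.

    The family varies the helix depth and the split of the remaining unpaired
    bases between the two exterior segments.
    """
    out = []
    for b in range(min_stack, (L - hairpin) // 2 + 1):
        ext = L - 2 * b - hairpin
        for e1 in range(ext + 1):
            s = "." * e1 + "(" * b + "." * hairpin + ")" * b + "." * (ext - e1)
            out.append(parse_structure(s, no_lonely_pairs=True))
    return out


def extended_core_family(
    core: str = "((...((...))..))", L: int = 35
) -> list[SecondaryStructure]:
    """Structures that extend the outermost helix of a fixed core motif.

    Base pairs are appended directly onto the helix that terminates the core,
    and the leftover bases become exterior loops; the total length stays fixed.
    """
    out = []
    for k in range((L - len(core)) // 2 + 1):
        ext = L - len(core) - 2 * k
        for e1 in range(ext + 1):
            s = "." * e1 + "(" * k + core + ")" * k + "." * (ext - e1)
            out.append(parse_structure(s, no_lonely_pairs=True))
    return out


def two_stack_internal_loop_family(
    L: int = 35, n_bp: int = 6, min_stack: int = 2
) -> Iterator[SecondaryStructure]:
    """All structures of shape [_[]_]: two helices, one internal loop, one hairpin.

    Both internal-loop strands are non-empty; exterior segments may be empty.
    """
    for s1 in range(min_stack, n_bp - min_stack + 1):
        s2 = n_bp - s1
        rest = L - 2 * n_bp
        for a in range(1, rest - 1 - 3 + 1):
            for b in range(1, rest - a - 3 + 1):
                for h in range(3, rest - a - b + 1):
                    ext = rest - a - b - h
                    for e1 in range(ext + 1):
                        s = (
                            "." * e1 + "(" * s1 + "." * a + "(" * s2
                            + "." * h + ")" * s2 + "." * b + ")" * s1
                            + "." * (ext - e1)
                        )
                        yield parse_structure(s, no_lonely_pairs=True)


def sample_fixed_bp_stacks(
    L: int,
    n_bp: int,
    n_stacks: int,
    n: int,
    seed: int,
    min_stack: int = 2,
    max_attempts: int = 200000,
) -> list[SecondaryStructure]:
    """Seeded sample of distinct structures with a fixed base-pair and stack count.

    Structures are built constructively: helix sizes are a random composition of
    ``n_bp`` into ``n_stacks`` parts of at least ``min_stack`` pairs, helices are
    nested or concatenated at random, and the unpaired bases are distributed at
    random over the loop segments (respecting the minimum hairpin length and
    keeping nested helices separated so stacks do not merge).  Candidates are
    validated through the parser; duplicates are discarded.
    """
    rng = random.Random(seed)
    out: list[SecondaryStructure] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        s = _random_fixed_bp_structure(rng, L, n_bp, n_stacks, min_stack)
        if s is None or s in seen:
            continue
        try:
            structure = parse_structure(s, no_lonely_pairs=True)
        except Exception:
            continue
        feats = compute_features(structure)
        if feats.n_bp != n_bp or feats.n_stack_regions != n_stacks:
            continue
        seen.add(s)
        out.append(structure)
    if len(out) < n:
        raise RuntimeError(
            f"only built {len(out)}/{n} structures with n_bp={n_bp}, "
            f"n_stacks={n_stacks} at L={L}"
        )
    return out


def _random_fixed_bp_structure(rng, L, n_bp, n_stacks, min_stack):
    if n_bp < n_stacks * min_stack or 2 * n_bp > L:
        return None
    # random composition of n_bp into n_stacks parts >= min_stack
    extra = n_bp - n_stacks * min_stack
    cuts = sorted(rng.randrange(extra + 1) for _ in range(n_stacks - 1))
    parts = []
    prev = 0
    for c in list(cuts) + [extra]:
        parts.append(min_stack + c - prev)
        prev = c
    rng.shuffle(parts)
    # random forest over the helices: parent[i] < i or root (-1)
    parents = [-1]
    for i in range(1, n_stacks):
        parents.append(rng.randrange(-1, i))
    # build nested token tree; each helix node: (size, children)
    children: list[list[int]] = [[] for _ in range(n_stacks)]
    roots: list[int] = []
    for i, p in enumerate(parents):
        (roots if p < 0 else children[p]).append(i)

    unpaired = L - 2 * n_bp
    segments: list[list[str]] = []  # (kind,) per insertable gap

    def render(i: int) -> tuple[str, list[int]]:
        """Return template with placeholders; collect mandatory minimums."""
        kids = children[i]
        if not kids:
            return "(" * parts[i] + "\0h" + ")" * parts[i], []
        inner = ""
        for k_idx, k in enumerate(kids):
            sub, _ = render(k)
            inner += "\0g" + sub
        inner += "\0g"
        return "(" * parts[i] + inner + ")" * parts[i], []

    template = ""
    for r_idx, r in enumerate(roots):
        sub, _ = render(r)
        template += "\0g" + sub
    template += "\0g"

    # identify gaps: hairpin gaps need >= 3; single-child loops need >= 1 total
    # distribute unpaired bases randomly over gaps, then enforce minima by retry
    gap_positions = [i for i, ch in enumerate(template) if ch == "\0"]
    kinds = [template[i + 1] for i in gap_positions]
    n_gaps = len(kinds)
    mins = [3 if k == "h" else 0 for k in kinds]
    if sum(mins) > unpaired:
        return None
    free = unpaired - sum(mins)
    alloc = [0] * n_gaps
    for _ in range(free):
        alloc[rng.randrange(n_gaps)] += 1
    alloc = [a + m for a, m in zip(alloc, mins)]
    # substitute
    out = []
    gi = 0
    i = 0
    while i < len(template):
        if template[i] == "\0":
            out.append("." * alloc[gi])
            gi += 1
            i += 2
        else:
            out.append(template[i])
            i += 1
    return "".join(out)
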