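"""GF(2) linear-system solvers: Gaussian elimination, belief propagation,
and the structure-only pseudo-decoder.

Every fountain decoding reduces to a binary system A x = b: row i of A is
the indicator of the chunks XORed into packet i and b[i] is its payload.
Rows are stored as Python integers used as bit sets (bit j = unknown j) and
right-hand sides as integers holding the payload bytes, so a row operation
is two machine-word-striped XORs — the A-and-b consistency contract is kept
by construction.

"Partial pivoting" degenerates in GF(2) to choosing any row with a 1 in the
pivot column; rows are consumed in input order with the earliest eligible
row winning, which makes elimination deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CorruptionError, ParameterError

__all__ = [
    "GF2System",
    "GaussResult",
    "gauss_solve",
    "IncrementalGauss",
    "belief_propagate",
    "pseudo_decode",
]


def mask_from_indices(indices) -> int:
    mask = 0
    for i in indices:
        mask |= 1 << i
    return mask


def indices_from_mask(mask: int) -> list[int]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return out


@dataclass
class GF2System:
    """Binary constraint matrix with byte-vector right-hand sides.

    ``rows[i]`` is an int bit mask over the ``n_unknowns`` columns,
    ``rhs[i]`` the payload as a big-endian integer of ``payload_size``
    bytes.  Appending a row keeps both lists aligned.
    """

    n_unknowns: int
    payload_size: int
    rows: list[int] = field(default_factory=list)
    rhs: list[int] = field(default_factory=list)

    def add_row(self, indices, payload: bytes | int = 0) -> None:
        mask = mask_from_indices(indices)
        if mask >> self.n_unknowns:
            raise ParameterError("row index beyond unknown count")
        value = payload if isinstance(payload, int) \
            else int.from_bytes(payload, "big")
        self.rows.append(mask)
        self.rhs.append(value)

    def __len__(self) -> int:
        return len(self.rows)

    def index_sets(self) -> list[list[int]]:
        return [indices_from_mask(m) for m in self.rows]


@dataclass
class GaussResult:
    """Outcome of a solve: either every unknown resolved (``solved`` holds
    one byte vector per unknown) or a report of rank and the unresolved
    pivot columns."""

    solved: list[bytes] | None
    rank: int
    missing: frozenset[int]

    @property
    def ok(self) -> bool:
        return self.solved is not None


class IncrementalGauss:
    """Online Gaussian elimination over GF(2).

    Rows may arrive one at a time (decode-after-each-packet) or in bulk
    (decode-at-end); the final reduced system is identical either way
    because insertion keeps one pivot row per leading column.  Also runs
    payload-free for the pseudo-decoder.
    """

    def __init__(self, n_unknowns: int, payload_size: int = 0) -> None:
        self.n = n_unknowns
        self.payload_size = payload_size
        self.pivots: dict[int, tuple[int, int]] = {}
        self.inconsistent = False

    @property
    def rank(self) -> int:
        return len(self.pivots)

    @property
    def solvable(self) -> bool:
        return self.rank == self.n

    def add(self, mask: int, rhs: int = 0) -> bool:
        """Reduce one row against the current basis; returns True when the
        row increased the rank."""
        while mask:
            top = mask.bit_length() - 1
            if top not in self.pivots:
                self.pivots[top] = (mask, rhs)
                return True
            pm, pr = self.pivots[top]
            mask ^= pm
            rhs ^= pr
        if rhs != 0:
            self.inconsistent = True
        return False

    def missing_columns(self) -> frozenset[int]:
        return frozenset(range(self.n)) - self.pivots.keys()

    def determined(self, count: int) -> bool:
        """True when unknowns 0..count-1 are each uniquely determined.

        Weaker than full rank: free columns are allowed as long as no
        null-space vector touches the first ``count`` coordinates.  Checked
        by back-solving one null-space basis vector per free column, with a
        fast rejection when a free column itself lies below ``count``.
        """
        if self.solvable:
            return True
        free = [j for j in range(self.n) if j not in self.pivots]
        if any(f < count for f in free):
            return False
        tops = sorted(self.pivots)
        low_mask = (1 << count) - 1
        for f in free:
            x = 1 << f
            for top in tops:
                mask, _ = self.pivots[top]
                if (mask & x).bit_count() & 1:
                    x |= 1 << top
            if x & low_mask:
                return False
        return True

    def _jordan(self) -> None:
        """Eliminate pivot columns from all pivot rows (ascending top
        order); afterwards each pivot row holds its own bit plus free-column
        bits only."""
        for top in sorted(self.pivots):
            mask, rhs = self.pivots[top]
            rest = mask & ~(1 << top)
            dropped = 0
            while rest:
                b = rest.bit_length() - 1
                if b in self.pivots:
                    pm, pr = self.pivots[b]  # lower tops already reduced
                    mask ^= pm
                    rhs ^= pr
                else:
                    # free column: move aside (XOR toggle — a later pivot
                    # row may reintroduce it, cancelling out)
                    dropped ^= 1 << b
                    mask &= ~(1 << b)
                rest = mask & ~(1 << top)
            self.pivots[top] = (mask | dropped, rhs)

    def back_substitute(self) -> list[bytes | None]:
        """Jordan-reduce and read off the solution.

        Returns one byte vector per unknown; entries whose value is not
        uniquely determined (their pivot row still touches a free column,
        or they have no pivot) are None.
        """
        self._jordan()
        out: list[bytes | None] = []
        for j in range(self.n):
            entry = self.pivots.get(j)
            if entry is not None and entry[0] == 1 << j:
                out.append(entry[1].to_bytes(self.payload_size, "big"))
            else:
                out.append(None)
        return out


def gauss_solve(system: GF2System,
                required: range | None = None) -> GaussResult:
    """Solve A x = b by row-XOR elimination with back substitution.

    With ``required=None`` the solve succeeds iff rank equals the unknown
    count.  ``required`` relaxes this to a subset of unknowns that must be
    uniquely determined (codecs with auxiliary/parity symbols only need
    the chunk unknowns); undetermined entries of the returned solution are
    None.  The input system is not mutated.  Raises
    :class:`CorruptionError` when a row reduces to 0 = nonzero — an
    undetected packet error — whether or not the rest reaches full rank:
    a corrupt equation poisons any solution built from rows it touched.
    """
    inc = IncrementalGauss(system.n_unknowns, system.payload_size)
    for mask, rhs in zip(system.rows, system.rhs):
        inc.add(mask, rhs)
    if inc.inconsistent:
        raise CorruptionError(
            "inconsistent system: an undetected packet error is present")
    if required is None:
        if not inc.solvable:
            return GaussResult(None, inc.rank, inc.missing_columns())
        return GaussResult(inc.back_substitute(), inc.rank, frozenset())
    solution = inc.back_substitute()
    missing = frozenset(j for j in required if solution[j] is None)
    if missing:
        return GaussResult(None, inc.rank, missing)
    return GaussResult(solution, inc.rank, frozenset())


def belief_propagate(system: GF2System, incremental: bool = False) -> GaussResult:
    """Iterative peeling decoder.

    Any row of degree 1 resolves its unknown, which is then XORed out of
    every other row containing it; the cascade repeats until a fixpoint.
    Strictly weaker than Gaussian elimination (it may stall on systems of
    full rank with no degree-1 row) but never succeeds where Gauss fails.
    ``incremental`` only changes the feeding order (one row at a time with
    propagation in between versus all rows up front); the fixpoint — and
    therefore the result — is the same.
    """
    n = system.n_unknowns
    solved: dict[int, int] = {}
    rows: list[set[int]] = []
    rhs: list[int] = []
    by_unknown: dict[int, set[int]] = {}
    queue: list[int] = []

    def feed(mask: int, value: int) -> None:
        idxs = set(indices_from_mask(mask))
        for u in list(idxs):
            if u in solved:
                idxs.discard(u)
                value ^= solved[u]
        rid = len(rows)
        rows.append(idxs)
        rhs.append(value)
        for u in idxs:
            by_unknown.setdefault(u, set()).add(rid)
        if len(idxs) == 1:
            queue.append(rid)

    def propagate() -> None:
        while queue:
            rid = queue.pop()
            if len(rows[rid]) != 1:
                continue
            (u,) = rows[rid]
            value = rhs[rid]
            if u in solved:
                rows[rid].clear()
                continue
            solved[u] = value
            for other in list(by_unknown.get(u, ())):
                rows[other].discard(u)
                rhs[other] ^= value
                if len(rows[other]) == 1:
                    queue.append(other)
            by_unknown.pop(u, None)

    for mask, value in zip(system.rows, system.rhs):
        feed(mask, value)
        if incremental:
            propagate()
    propagate()

    if len(solved) == n:
        return GaussResult(
            [solved[j].to_bytes(system.payload_size, "big") for j in range(n)],
            n, frozenset())
    return GaussResult(None, len(solved),
                       frozenset(range(n)) - solved.keys())


def pseudo_decode(index_sets, n_unknowns: int) -> bool:
    """Structure-only decodability check.

    Works purely on the chunk-index sets, ignoring payloads: the verdict
    equals :func:`gauss_solve` solvability on the indicator matrix, i.e.
    whether A reduces to the identity.
    """
    inc = IncrementalGauss(n_unknowns)
    for s in index_sets:
        inc.add(mask_from_indices(s))
        if inc.solvable:
            return True
    return inc.solvable
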