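"""Multi-access identification-key engine.

A key is a matrix of taxa x descriptors.  Descriptors are either
categorical (a set of named states; taxa may be polymorphic and carry
several) or quantitative (a fixed [min, max] range per taxon, e.g. a
body ratio).  Each descriptor has an importance weight from 1 (little
important) to 5 (highly important) that orders suggestions but never
affects elimination.

Identification proceeds by free choice of characters: the user selects
a state or enters a measured value, and every taxon inconsistent with
the observation is eliminated.  Cells recorded as unknown (or
inapplicable) never eliminate, so damaged specimens can be identified
by simply avoiding the characters that cannot be observed.

The module also provides database diagnostics (duplicate descriptions,
undescribed cells, all-unknown descriptors), an exhaustive search for
the shortest sequence of observations isolating a given taxon, and
export of a conventional dichotomous (flat) key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

UNKNOWN = "unknown"
INAPPLICABLE = "inapplicable"

CellValue = object  # frozenset[str] | tuple[float, float] | UNKNOWN | INAPPLICABLE


class KeyMatrixError(ValueError):
    """A key matrix or selection violated an invariant."""


class NotIsolatableError(KeyMatrixError):
    """No sequence of observations can isolate the target taxon."""


class BoundExceededError(KeyMatrixError):
    """No isolating sequence exists within the requested depth bound."""


@dataclass(frozen=True)
class Descriptor:
    """One character of the key."""

    name: str
    kind: str  # "categorical" | "quantitative"
    states: tuple[str, ...] = ()
    unit: str = ""
    weight: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "quantitative"):
            raise KeyMatrixError(f"descriptor {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.states) < 2:
                raise KeyMatrixError(
                    f"categorical descriptor {self.name!r} needs >= 2 states"
                )
            if len(set(self.states)) != len(self.states):
                raise KeyMatrixError(f"descriptor {self.name!r} has duplicate states")
        if not 1 <= int(self.weight) <= 5:
            raise KeyMatrixError(
                f"descriptor {self.name!r}: weight {self.weight} outside 1..5"
            )


@dataclass(frozen=True)
class TaxonDescription:
    """One taxon's cells: a state subset or numeric range per descriptor."""

    name: str
    description: Mapping[str, CellValue] = field(default_factory=dict)
    tags: tuple[str, ...] = ()


@dataclass
class KeyMatrix:
    """Taxa x weighted descriptors."""

    descriptors: tuple[Descriptor, ...]
    taxa: tuple[TaxonDescription, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise KeyMatrixError(f"duplicate taxon names: {dup}")
        dnames = [d.name for d in self.descriptors]
        if len(set(dnames)) != len(dnames):
            raise KeyMatrixError("duplicate descriptor names")
        self._dmap = {d.name: d for d in self.descriptors}
        for taxon in self.taxa:
            for dname, cell in taxon.description.items():
                d = self._dmap.get(dname)
                if d is None:
                    raise KeyMatrixError(
                        f"taxon {taxon.name!r} references undeclared descriptor "
                        f"{dname!r}"
                    )
                _validate_cell(taxon.name, d, cell)

    def descriptor(self, name: str) -> Descriptor:
        try:
            return self._dmap[name]
        except KeyError:
            raise KeyMatrixError(f"unknown descriptor {name!r}") from None

    def taxon(self, name: str) -> TaxonDescription:
        for t in self.taxa:
            if t.name == name:
                return t
        raise KeyMatrixError(f"unknown taxon {name!r}")

    def cell(self, taxon: str, descriptor: str) -> CellValue:
        t = self.taxon(taxon)
        return t.description.get(descriptor, UNKNOWN)

    @property
    def taxon_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.taxa)

    def n_described_cells(self) -> int:
        return sum(
            1
            for t in self.taxa
            for d in self.descriptors
            if t.description.get(d.name, UNKNOWN) not in (UNKNOWN, INAPPLICABLE)
        )


def _validate_cell(taxon: str, d: Descriptor, cell: CellValue) -> None:
    if cell in (UNKNOWN, INAPPLICABLE):
        return
    if d.kind == "categorical":
        if not isinstance(cell, (frozenset, set)):
            raise KeyMatrixError(
                f"taxon {taxon!r}, descriptor {d.name!r}: expected a state set"
            )
        extra = set(cell) - set(d.states)
        if extra:
            raise KeyMatrixError(
                f"taxon {taxon!r}, descriptor {d.name!r}: undeclared states "
                f"{sorted(extra)}"
            )
        if len(cell) == 0:
            raise KeyMatrixError(
                f"taxon {taxon!r}, descriptor {d.name!r}: empty state set "
                f"(use 'unknown' or 'inapplicable')"
            )
    else:
        lo, hi = cell
        if not float(lo) <= float(hi):
            raise KeyMatrixError(
                f"taxon {taxon!r}, descriptor {d.name!r}: min {lo} > max {hi}"
            )


# ---------------------------------------------------------------------------
# JSON interchange


def matrix_to_dict(matrix: KeyMatrix) -> dict:
    doc: dict = {"descriptors": [], "taxa": []}
    for d in matrix.descriptors:
        entry: dict = {"name": d.name, "kind": d.kind, "weight": d.weight}
        if d.kind == "categorical":
            entry["states"] = list(d.states)
        else:
            entry["unit"] = d.unit
        doc["descriptors"].append(entry)
    for t in matrix.taxa:
        desc: dict = {}
        for dname, cell in t.description.items():
            if cell in (UNKNOWN, INAPPLICABLE):
                desc[dname] = cell
            elif isinstance(cell, (frozenset, set)):
                desc[dname] = sorted(cell)
            else:
                desc[dname] = {"min": float(cell[0]), "max": float(cell[1])}
        doc["taxa"].append(
            {"name": t.name, "tags": list(t.tags), "description": desc}
        )
    return doc


def matrix_from_dict(doc: Mapping) -> KeyMatrix:
    descriptors = []
    for entry in doc.get("descriptors", []):
        descriptors.append(
            Descriptor(
                name=entry["name"],
                kind=entry["kind"],
                states=tuple(entry.get("states", ())),
                unit=entry.get("unit", ""),
                weight=int(entry.get("weight", 3)),
            )
        )
    taxa = []
    for entry in doc.get("taxa", []):
        desc: dict[str, CellValue] = {}
        for dname, cell in entry.get("description", {}).items():
            if cell in (UNKNOWN, INAPPLICABLE):
                desc[dname] = cell
            elif isinstance(cell, list):
                desc[dname] = frozenset(cell)
            elif isinstance(cell, Mapping):
                desc[dname] = (float(cell["min"]), float(cell["max"]))
            else:
                raise KeyMatrixError(
                    f"taxon {entry.get('name')!r}: malformed cell for {dname!r}"
                )
        taxa.append(
            TaxonDescription(
                name=entry["name"],
                description=desc,
                tags=tuple(entry.get("tags", ())),
            )
        )
    return KeyMatrix(descriptors=tuple(descriptors), taxa=tuple(taxa))


def load_key_matrix(source) -> KeyMatrix:
    """Load a key matrix from a JSON path, stream, or already-parsed dict."""
    if isinstance(source, Mapping):
        return matrix_from_dict(source)
    if hasattr(source, "read"):
        return matrix_from_dict(json.load(source))
    with open(source, "r", encoding="utf-8") as fh:
        return matrix_from_dict(json.load(fh))


def save_key_matrix(matrix: KeyMatrix, target) -> None:
    doc = matrix_to_dict(matrix)
    if hasattr(target, "write"):
        json.dump(doc, target, indent=1, sort_keys=True)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def matrix_to_csv(matrix: KeyMatrix) -> str:
    """Description matrix as CSV text: one row per taxon, '?' unknown, '-' inapplicable."""
    import csv
    import io

    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["taxon"] + [d.name for d in matrix.descriptors])
    for t in matrix.taxa:
        row = [t.name]
        for d in matrix.descriptors:
            cell = t.description.get(d.name, UNKNOWN)
            if cell == UNKNOWN:
                row.append("?")
            elif cell == INAPPLICABLE:
                row.append("-")
            elif isinstance(cell, (frozenset, set)):
                row.append("|".join(sorted(cell)))
            else:
                row.append(f"{cell[0]}..{cell[1]}")
        writer.writerow(row)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Elimination


def taxon_matches(
    matrix: KeyMatrix,
    taxon: str,
    descriptor: str,
    choice,
    tolerance: float = 0.0,
) -> bool:
    """Whether a taxon survives the observation (descriptor, choice).

    Categorical: survives iff its state set contains the chosen state, or
    the cell is unknown/inapplicable.  Quantitative: survives iff the
    entered value lies in its closed [min, max] range (optionally widened
    by a relative ``tolerance``), or the cell is unknown/inapplicable.
    """
    d = matrix.descriptor(descriptor)
    cell = matrix.cell(taxon, descriptor)
    if cell in (UNKNOWN, INAPPLICABLE):
        return True
    if d.kind == "categorical":
        if choice not in d.states:
            raise KeyMatrixError(
                f"state {choice!r} not declared for descriptor {descriptor!r}"
            )
        return choice in cell
    value = float(choice)
    lo, hi = float(cell[0]), float(cell[1])
    slack = tolerance * max(abs(lo), abs(hi))
    return lo - slack <= value <= hi + slack


@dataclass(frozen=True)
class KeySession:
    """Immutable identification session: selections so far and remaining taxa.

    ``remaining`` is always exactly the set of taxa consistent with every
    selection in ``history``; replaying the history from a fresh session
    reproduces it.
    """

    matrix: KeyMatrix
    history: tuple[tuple[str, object], ...] = ()
    remaining: tuple[str, ...] = ()
    tolerance: float = 0.0

    @staticmethod
    def start(matrix: KeyMatrix, tolerance: float = 0.0) -> "KeySession":
        return KeySession(
            matrix=matrix,
            history=(),
            remaining=matrix.taxon_names,
            tolerance=tolerance,
        )

    @property
    def used_descriptors(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.history)


def apply_selection(session: KeySession, descriptor: str, choice) -> KeySession:
    """Record one observation and eliminate every inconsistent taxon."""
    d = session.matrix.descriptor(descriptor)
    if d.kind == "quantitative":
        choice = float(choice)
    remaining = tuple(
        t
        for t in session.remaining
        if taxon_matches(session.matrix, t, descriptor, choice, session.tolerance)
    )
    return replace(
        session,
        history=session.history + ((descriptor, choice),),
        remaining=remaining,
    )


def replay(session: KeySession) -> KeySession:
    """Re-run a session's history from scratch (audit helper)."""
    fresh = KeySession.start(session.matrix, session.tolerance)
    for descriptor, choice in session.history:
        fresh = apply_selection(fresh, descriptor, choice)
    return fresh


# ---------------------------------------------------------------------------
# Suggestion metric


def _quantitative_probes(
    matrix: KeyMatrix, descriptor: str, taxa: Sequence[str]
) -> list[float]:
    """Candidate entry values: the remaining taxa's range endpoints."""
    pts: set[float] = set()
    for t in taxa:
        cell = matrix.cell(t, descriptor)
        if cell in (UNKNOWN, INAPPLICABLE):
            continue
        pts.add(float(cell[0]))
        pts.add(float(cell[1]))
    return sorted(pts)


def elimination_power(
    matrix: KeyMatrix,
    descriptor: str,
    taxa: Sequence[str],
    tolerance: float = 0.0,
) -> float:
    """Expected fraction of ``taxa`` eliminated by one observation.

    Categorical descriptors average over a uniform choice of state;
    quantitative descriptors average over probe values taken at the
    remaining taxa's range endpoints.
    """
    d = matrix.descriptor(descriptor)
    if len(taxa) == 0:
        return 0.0
    if d.kind == "categorical":
        choices: Iterable = d.states
    else:
        choices = _quantitative_probes(matrix, descriptor, taxa)
    choices = list(choices)
    if not choices:
        return 0.0
    total = 0.0
    for c in choices:
        kept = sum(
            1 for t in taxa if taxon_matches(matrix, t, descriptor, c, tolerance)
        )
        total += (len(taxa) - kept) / len(taxa)
    return total / len(choices)


def suggest_descriptors(session: KeySession) -> list[str]:
    """Unused descriptors, best first.

    Ordered by weight (descending), then expected elimination power over
    the remaining taxa (descending), then name.  Weights order
    suggestions only; they never change elimination itself.
    """
    used = set(session.used_descriptors)
    ranked = []
    for d in session.matrix.descriptors:
        if d.name in used:
            continue
        power = elimination_power(
            session.matrix, d.name, session.remaining, session.tolerance
        )
        ranked.append((-d.weight, -power, d.name))
    ranked.sort()
    return [name for _, _, name in ranked]


# ---------------------------------------------------------------------------
# Checkbase diagnostics


@dataclass(frozen=True)
class CheckReport:
    """Database defects: duplicates, undescribed cells, unusable descriptors."""

    identical_pairs: tuple[tuple[str, str], ...]
    undescribed: tuple[tuple[str, str], ...]
    all_unknown_descriptors: tuple[str, ...]
    inapplicable: tuple[tuple[str, str], ...]

    @property
    def is_empty(self) -> bool:
        return not (
            self.identical_pairs
            or self.undescribed
            or self.all_unknown_descriptors
            or self.inapplicable
        )


def _normalized_description(matrix: KeyMatrix, taxon: TaxonDescription):
    cells = []
    for d in matrix.descriptors:
        cell = taxon.description.get(d.name, UNKNOWN)
        if isinstance(cell, (frozenset, set)):
            cell = tuple(sorted(cell))
        cells.append(cell)
    return tuple(cells)


def checkbase(matrix: KeyMatrix) -> CheckReport:
    """Automated scan for database errors.

    Reports taxon pairs with identical descriptions, undescribed
    (unknown or absent) cells, descriptors unknown for every taxon, and
    cells marked inapplicable.  Ordering is deterministic (matrix
    order / lexicographic pairs).
    """
    norm = {t.name: _normalized_description(matrix, t) for t in matrix.taxa}
    names = matrix.taxon_names
    pairs = tuple(
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if norm[names[i]] == norm[names[j]]
    )
    undescribed = []
    inapplicable = []
    for t in matrix.taxa:
        for d in matrix.descriptors:
            cell = t.description.get(d.name, UNKNOWN)
            if cell == UNKNOWN:
                undescribed.append((t.name, d.name))
            elif cell == INAPPLICABLE:
                inapplicable.append((t.name, d.name))
    all_unknown = tuple(
        d.name
        for d in matrix.descriptors
        if all(
            t.description.get(d.name, UNKNOWN) == UNKNOWN for t in matrix.taxa
        )
    )
    return CheckReport(
        identical_pairs=pairs,
        undescribed=tuple(undescribed),
        all_unknown_descriptors=all_unknown,
        inapplicable=tuple(inapplicable),
    )


# ---------------------------------------------------------------------------
# Shortest identification path


def _target_choices(matrix: KeyMatrix, target: str, descriptor: str) -> list:
    """Observations consistent with the target's own description."""
    d = matrix.descriptor(descriptor)
    cell = matrix.cell(target, descriptor)
    if cell in (UNKNOWN, INAPPLICABLE):
        return []
    if d.kind == "categorical":
        return sorted(cell)
    lo, hi = float(cell[0]), float(cell[1])
    pts = [
        p
        for p in _quantitative_probes(matrix, descriptor, matrix.taxon_names)
        if lo <= p <= hi
    ]
    pts = sorted(set(pts) | {lo, hi})
    probes = list(pts)
    probes += [(a + b) / 2 for a, b in zip(pts, pts[1:])]
    return sorted(set(probes))


def shortest_identification_path(
    matrix: KeyMatrix, target: str, bound: int = 8
) -> list[tuple[str, object]]:
    """Minimum-length observation sequence isolating ``target``.

    Searches, by iterative deepening with pruning, over selections drawn
    from the target's own description (so the target always survives)
    until the remaining set is exactly ``{target}``.  Raises
    :class:`NotIsolatableError` when some other taxon can never be
    eliminated (e.g. an identical description) and
    :class:`BoundExceededError` when no sequence of length <= ``bound``
    exists.
    """
    matrix.taxon(target)
    # per-descriptor candidate observations and their eliminated sets
    moves: list[tuple[str, object, frozenset[str]]] = []
    others = [t for t in matrix.taxon_names if t != target]
    for d in matrix.descriptors:
        for choice in _target_choices(matrix, target, d.name):
            eliminated = frozenset(
                t for t in others if not taxon_matches(matrix, t, d.name, choice)
            )
            if eliminated:
                moves.append((d.name, choice, eliminated))
    eliminable = frozenset().union(*(m[2] for m in moves)) if moves else frozenset()
    stubborn = sorted(set(others) - eliminable)
    if stubborn:
        raise NotIsolatableError(
            f"taxon {target!r} cannot be isolated: no observation separates "
            f"it from {stubborn}"
        )
    goal = frozenset(others)

    # Deduplicate moves with identical elimination sets, keep deterministic order
    seen: dict[frozenset, tuple[str, object]] = {}
    for name, choice, elim in moves:
        if elim not in seen:
            seen[elim] = (name, choice)
    uniq = sorted(
        ((elim, nc) for elim, nc in seen.items()),
        key=lambda t: (-len(t[0]), t[1][0], str(t[1][1])),
    )

    for depth in range(1, bound + 1):
        path = _dfs_cover(frozenset(), goal, uniq, depth, [])
        if path is not None:
            return path
    raise BoundExceededError(
        f"no isolating sequence of length <= {bound} for {target!r}"
    )


def _dfs_cover(covered, goal, moves, depth, acc):
    if covered == goal:
        return list(acc)
    if depth == 0:
        return None
    # prune: even taking the largest remaining contributions cannot finish
    best = max((len(elim - covered) for elim, _ in moves), default=0)
    if best == 0 or len(goal - covered) > best * depth:
        return None
    used = {d for d, _ in acc}
    for elim, (dname, choice) in moves:
        if dname in used or not (elim - covered):
            continue
        acc.append((dname, choice))
        found = _dfs_cover(covered | elim, goal, moves, depth - 1, acc)
        if found is not None:
            return found
        acc.pop()
    return None


# ---------------------------------------------------------------------------
# Flat (dichotomous) key export


def export_flat_key(matrix: KeyMatrix) -> str:
    """Render the matrix as a numbered, couplet-structured text key.

    At each node the descriptor with the best (weight, elimination
    power) is chosen and one lead is emitted per choice; taxa whose cell
    is unknown follow every lead.  Leaves list a single taxon, or
    several flagged ``[indistinguishable]`` when no descriptor separates
    them.
    """
    lines: list[str] = []
    counter = {"n": 0}

    def node(taxa: tuple[str, ...], used: frozenset[str]) -> str:
        if len(taxa) == 1:
            return taxa[0]
        candidates = []
        for d in matrix.descriptors:
            if d.name in used:
                continue
            power = elimination_power(matrix, d.name, taxa)
            candidates.append((-d.weight, -power, d.name, power))
        candidates.sort()
        chosen = None
        entries: list[tuple[str, tuple[str, ...]]] = []
        for _, _, name, power in candidates:
            if power <= 0:
                continue
            d = matrix.descriptor(name)
            if d.kind == "categorical":
                choices: list = list(d.states)
                labels = [f"{name} = {c}" for c in choices]
            else:
                choices = _quantitative_probes(matrix, name, taxa)
                unit = f" {d.unit}" if d.unit else ""
                labels = [f"{name} ~ {c:g}{unit}" for c in choices]
            trial = []
            for choice, label in zip(choices, labels):
                kept = tuple(
                    t for t in taxa if taxon_matches(matrix, t, name, choice)
                )
                if kept:
                    trial.append((label, kept))
            # accept only a descriptor that actually splits the current taxa
            if trial and any(len(kept) < len(taxa) for _, kept in trial):
                chosen, entries = name, trial
                break
        if chosen is None:
            return "{" + ", ".join(taxa) + "} [indistinguishable]"
        counter["n"] += 1
        number = counter["n"]
        lines.append(f"{number}.")
        slots = []
        for label, kept in entries:
            slots.append(len(lines))
            lines.append(f"    {label} -> ?")
        for slot, (label, kept) in zip(slots, entries):
            ref = node(kept, used | {chosen})
            lines[slot] = f"    {label} -> {ref}"
        return str(number)

    root = node(matrix.taxon_names, frozenset())
    if not lines:  # single taxon or indistinguishable from the start
        lines.append(f"1.\n    -> {root}")
    return "\n".join(lines) + "\n"
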