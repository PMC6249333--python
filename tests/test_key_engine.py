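import io
import re
from collections import deque

import numpy as np
import pytest

from morphokey.key_engine import (
    UNKNOWN,
    BoundExceededError,
    Descriptor,
    KeyMatrix,
    KeyMatrixError,
    KeySession,
    NotIsolatableError,
    TaxonDescription,
    apply_selection,
    checkbase,
    export_flat_key,
    load_key_matrix,
    replay,
    save_key_matrix,
    shortest_identification_path,
    suggest_descriptors,
    taxon_matches,
)
from morphokey.synth import simulate_key_matrix


def toy_matrix():
    descriptors = (
        Descriptor("inclination", "categorical", states=("sharp", "blunt"),
                   weight=2),
        Descriptor("pit", "categorical", states=("present", "absent"),
                   weight=3),
        Descriptor("eye.d/pol.l", "quantitative", unit="ratio", weight=5),
    )
    taxa = (
        TaxonDescription("capito", {
            "inclination": frozenset({"blunt"}),
            "pit": frozenset({"absent"}),
            "eye.d/pol.l": (2.73, 3.5),
        }),
        TaxonDescription("albipennis", {
            "inclination": frozenset({"sharp"}),
            "pit": frozenset({"present"}),
            "eye.d/pol.l": (2.0, 2.73),
        }),
        TaxonDescription("achillei", {
            "inclination": frozenset({"sharp", "blunt"}),
            "pit": frozenset({"present", "absent"}),
            "eye.d/pol.l": UNKNOWN,
        }),
    )
    return KeyMatrix(descriptors=descriptors, taxa=taxa)


class TestMatrixIO:
    def test_duplicate_taxon_rejected(self):
        d = Descriptor("c", "categorical", states=("a", "b"))
        with pytest.raises(KeyMatrixError, match="duplicate"):
            KeyMatrix((d,), (TaxonDescription("x"), TaxonDescription("x")))

    def test_undeclared_state_rejected(self):
        d = Descriptor("c", "categorical", states=("a", "b"))
        with pytest.raises(KeyMatrixError, match="undeclared"):
            KeyMatrix((d,), (TaxonDescription("x", {"c": frozenset({"z"})}),))

    def test_weight_bounds(self):
        with pytest.raises(KeyMatrixError, match="weight"):
            Descriptor("c", "categorical", states=("a", "b"), weight=6)

    def test_round_trip_random_matrix(self):
        matrix = simulate_key_matrix(12, 7, seed=5)
        buf = io.StringIO()
        save_key_matrix(matrix, buf)
        buf.seek(0)
        back = load_key_matrix(buf)
        assert back.taxon_names == matrix.taxon_names
        assert back.descriptors == matrix.descriptors
        for t in matrix.taxon_names:
            for d in matrix.descriptors:
                assert back.cell(t, d.name) == matrix.cell(t, d.name)


class TestElimination:
    def test_disjoint_singleton_excluded(self):
        m = toy_matrix()
        s = apply_selection(KeySession.start(m), "inclination", "blunt")
        assert "albipennis" not in s.remaining

    def test_polymorphic_taxon_retained_either_way(self):
        m = toy_matrix()
        for choice in ("sharp", "blunt"):
            s = apply_selection(KeySession.start(m), "inclination", choice)
            assert "achillei" in s.remaining

    def test_quantitative_below_lower_bound_excludes(self):
        m = toy_matrix()
        s = apply_selection(KeySession.start(m), "eye.d/pol.l", 2.5)
        assert "capito" not in s.remaining
        assert "albipennis" in s.remaining

    def test_unknown_cell_never_excludes(self):
        m = toy_matrix()
        for value in (0.1, 2.73, 99.0):
            s = apply_selection(KeySession.start(m), "eye.d/pol.l", value)
            assert "achillei" in s.remaining

    def test_undeclared_state_raises(self):
        m = toy_matrix()
        with pytest.raises(KeyMatrixError):
            apply_selection(KeySession.start(m), "inclination", "wavy")

    def test_monotonic_and_replayable_random_sessions(self):
        rng = np.random.default_rng(23)
        matrix = simulate_key_matrix(15, 8, seed=2)
        for _ in range(20):
            session = KeySession.start(matrix)
            for _ in range(5):
                d = matrix.descriptors[rng.integers(len(matrix.descriptors))]
                if d.kind == "categorical":
                    choice = d.states[rng.integers(len(d.states))]
                else:
                    choice = float(rng.integers(0, 12)) * 10.0
                before = len(session.remaining)
                session = apply_selection(session, d.name, choice)
                assert len(session.remaining) <= before
            assert replay(session).remaining == session.remaining

    def test_truthful_retention(self):
        # choosing only states/values from a taxon's own description never
        # eliminates that taxon
        rng = np.random.default_rng(31)
        matrix = simulate_key_matrix(12, 8, seed=7)
        for taxon in matrix.taxon_names:
            session = KeySession.start(matrix)
            for d in matrix.descriptors:
                cell = matrix.cell(taxon, d.name)
                if cell == UNKNOWN:
                    continue
                if d.kind == "categorical":
                    states = sorted(cell)
                    choice = states[rng.integers(len(states))]
                else:
                    choice = float(rng.uniform(cell[0], cell[1]))
                session = apply_selection(session, d.name, choice)
            assert taxon in session.remaining


class TestSuggest:
    def test_constant_descriptor_ranked_last_in_weight_class(self):
        descriptors = (
            Descriptor("useless", "categorical", states=("a", "b"), weight=3),
            Descriptor("useful", "categorical", states=("a", "b"), weight=3),
        )
        taxa = tuple(
            TaxonDescription(f"t{i}", {
                "useless": frozenset({"a"}),
                "useful": frozenset({"a" if i % 2 else "b"}),
            })
            for i in range(4)
        )
        order = suggest_descriptors(KeySession.start(KeyMatrix(descriptors, taxa)))
        assert order == ["useful", "useless"]

    def test_weight_dominates_equal_power(self):
        descriptors = (
            Descriptor("low", "categorical", states=("a", "b"), weight=1),
            Descriptor("high", "categorical", states=("a", "b"), weight=5),
        )
        taxa = tuple(
            TaxonDescription(f"t{i}", {
                "low": frozenset({"a" if i % 2 else "b"}),
                "high": frozenset({"a" if i % 2 else "b"}),
            })
            for i in range(4)
        )
        order = suggest_descriptors(KeySession.start(KeyMatrix(descriptors, taxa)))
        assert order[0] == "high"

    def test_greedy_top_matches_exhaustive_best_split(self):
        matrix = simulate_key_matrix(5, 6, seed=13, unknown_rate=0.0)
        # neutralize weights so power alone decides
        flat = KeyMatrix(
            descriptors=tuple(
                Descriptor(d.name, d.kind, d.states, d.unit, 3)
                for d in matrix.descriptors
            ),
            taxa=matrix.taxa,
        )
        session = KeySession.start(flat)
        top = suggest_descriptors(session)[0]

        def power_oracle(d):
            if d.kind == "categorical":
                choices = list(d.states)
            else:
                pts = set()
                for t in flat.taxa:
                    cell = t.description.get(d.name, UNKNOWN)
                    if cell != UNKNOWN:
                        pts.update(cell)
                choices = sorted(pts)
            if not choices:
                return 0.0
            fracs = []
            for c in choices:
                kept = sum(
                    taxon_matches(flat, t, d.name, c) for t in flat.taxon_names
                )
                fracs.append((len(flat.taxa) - kept) / len(flat.taxa))
            return sum(fracs) / len(fracs)

        best = max(flat.descriptors, key=power_oracle)
        assert power_oracle(flat.descriptor(top)) == pytest.approx(
            power_oracle(best)
        )


class TestCheckbase:
    def test_clean_matrix_empty_report(self):
        report = checkbase(toy_matrix())
        assert report.identical_pairs == ()
        assert report.all_unknown_descriptors == ()
        # achillei's ratio cell is the single undescribed cell
        assert report.undescribed == (("achillei", "eye.d/pol.l"),)

    def test_planted_duplicate_pair_found(self):
        d = Descriptor("c", "categorical", states=("a", "b"))
        taxa = (
            TaxonDescription("x", {"c": frozenset({"a"})}),
            TaxonDescription("y", {"c": frozenset({"a"})}),
            TaxonDescription("z", {"c": frozenset({"b"})}),
        )
        report = checkbase(KeyMatrix((d,), taxa))
        assert report.identical_pairs == (("x", "y"),)

    def test_fully_described_distinct_matrix_is_empty(self):
        matrix = simulate_key_matrix(6, 5, unknown_rate=0.0, distinct=True,
                                     seed=3)
        report = checkbase(matrix)
        assert report.is_empty

    def test_complete_against_brute_force_on_50x50(self):
        matrix = simulate_key_matrix(50, 50, unknown_rate=0.15,
                                     polymorphism_rate=0.3, seed=19)
        report = checkbase(matrix)

        def cell_key(t, d):
            v = matrix.cell(t, d.name)
            return tuple(sorted(v)) if isinstance(v, frozenset) else v

        names = matrix.taxon_names
        expect_pairs = set()
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if all(
                    cell_key(names[i], d) == cell_key(names[j], d)
                    for d in matrix.descriptors
                ):
                    expect_pairs.add((names[i], names[j]))
        assert set(report.identical_pairs) == expect_pairs
        expect_undescribed = {
            (t, d.name)
            for t in names
            for d in matrix.descriptors
            if matrix.cell(t, d.name) == UNKNOWN
        }
        assert set(report.undescribed) == expect_undescribed
        expect_all_unknown = {
            d.name
            for d in matrix.descriptors
            if all(matrix.cell(t, d.name) == UNKNOWN for t in names)
        }
        assert set(report.all_unknown_descriptors) == expect_all_unknown


def _bfs_shortest_length(matrix, target, bound=6):
    """Breadth-first oracle over selection sequences."""
    moves = []
    others = [t for t in matrix.taxon_names if t != target]
    for d in matrix.descriptors:
        cell = matrix.cell(target, d.name)
        if cell == UNKNOWN:
            continue
        if d.kind == "categorical":
            choices = sorted(cell)
        else:
            pts = set()
            for t in matrix.taxon_names:
                c2 = matrix.cell(t, d.name)
                if c2 != UNKNOWN:
                    pts.update(c2)
            pts = sorted(p for p in pts if cell[0] <= p <= cell[1])
            pts = sorted(set(pts) | {cell[0], cell[1]})
            choices = pts + [(a + b) / 2 for a, b in zip(pts, pts[1:])]
        for c in choices:
            elim = frozenset(
                t for t in others if not taxon_matches(matrix, t, d.name, c)
            )
            moves.append((d.name, c, elim))
    goal = frozenset(others)
    queue = deque([(frozenset(), 0, frozenset())])
    seen = {(frozenset(), frozenset())}
    while queue:
        covered, depth, used = queue.popleft()
        if covered == goal:
            return depth
        if depth >= bound:
            continue
        for dname, _, elim in moves:
            if dname in used:
                continue
            nxt = covered | elim
            nxt_used = used | {dname}
            if (nxt, nxt_used) not in seen:
                seen.add((nxt, nxt_used))
                queue.append((nxt, depth + 1, nxt_used))
    return None


class TestShortestPath:
    def test_unique_state_gives_length_one(self):
        d = Descriptor("c", "categorical", states=("a", "b"))
        taxa = (
            TaxonDescription("x", {"c": frozenset({"a"})}),
            TaxonDescription("y", {"c": frozenset({"b"})}),
            TaxonDescription("z", {"c": frozenset({"b"})}),
        )
        path = shortest_identification_path(KeyMatrix((d,), taxa), "x")
        assert path == [("c", "a")]

    def test_identical_descriptions_not_isolatable(self):
        d = Descriptor("c", "categorical", states=("a", "b"))
        taxa = (
            TaxonDescription("x", {"c": frozenset({"a"})}),
            TaxonDescription("y", {"c": frozenset({"a"})}),
        )
        with pytest.raises(NotIsolatableError):
            shortest_identification_path(KeyMatrix((d,), taxa), "x")

    def test_path_isolates_target(self):
        matrix = simulate_key_matrix(10, 6, distinct=True, unknown_rate=0.0,
                                     seed=29)
        for target in matrix.taxon_names:
            path = shortest_identification_path(matrix, target, bound=6)
            session = KeySession.start(matrix)
            for dname, choice in path:
                session = apply_selection(session, dname, choice)
            assert session.remaining == (target,)

    def test_length_matches_bfs_oracle(self):
        for seed in (1, 5, 9):
            matrix = simulate_key_matrix(6, 5, distinct=True,
                                         unknown_rate=0.0, seed=seed)
            for target in matrix.taxon_names:
                path = shortest_identification_path(matrix, target, bound=6)
                assert len(path) == _bfs_shortest_length(matrix, target)

    def test_bound_exceeded(self):
        # isolating needs one selection per descriptor here: each descriptor
        # separates the target from exactly one other taxon
        descriptors = tuple(
            Descriptor(f"c{i}", "categorical", states=("a", "b"))
            for i in range(3)
        )
        taxa = [TaxonDescription("t", {d.name: frozenset({"a"})
                                       for d in descriptors})]
        for i in range(3):
            desc = {d.name: frozenset({"a"}) for d in descriptors}
            desc[f"c{i}"] = frozenset({"b"})
            taxa.append(TaxonDescription(f"o{i}", desc))
        matrix = KeyMatrix(descriptors, tuple(taxa))
        assert len(shortest_identification_path(matrix, "t", bound=3)) == 3
        with pytest.raises(BoundExceededError):
            shortest_identification_path(matrix, "t", bound=2)


def _parse_flat_key(text):
    nodes = {}
    current = None
    for line in text.splitlines():
        m = re.match(r"^(\d+)\.$", line.strip())
        if m and not line.startswith(" "):
            current = int(m.group(1))
            nodes[current] = []
        elif line.strip() and current is not None:
            label, ref = line.strip().rsplit(" -> ", 1)
            nodes[current].append((label, ref))
    return nodes


def _lead_consistent(matrix, taxon, label):
    if " = " in label:
        dname, state = label.split(" = ")
        cell = matrix.cell(taxon, dname)
        return cell == UNKNOWN or state in cell
    dname, rest = label.split(" ~ ")
    value = float(rest.split()[0])
    cell = matrix.cell(taxon, dname)
    return cell == UNKNOWN or cell[0] <= value <= cell[1]


class TestFlatKey:
    def test_two_taxa_single_couplet(self):
        d = Descriptor("c", "categorical", states=("a", "b"))
        taxa = (
            TaxonDescription("x", {"c": frozenset({"a"})}),
            TaxonDescription("y", {"c": frozenset({"b"})}),
        )
        text = export_flat_key(KeyMatrix((d,), taxa))
        nodes = _parse_flat_key(text)
        assert len(nodes) == 1
        assert {ref for _, ref in nodes[1]} == {"x", "y"}

    def test_identical_taxa_flagged_leaf(self):
        d = Descriptor("c", "categorical", states=("a", "b"))
        taxa = (
            TaxonDescription("x", {"c": frozenset({"a"})}),
            TaxonDescription("y", {"c": frozenset({"a"})}),
        )
        text = export_flat_key(KeyMatrix((d,), taxa))
        assert "indistinguishable" in text

    def test_replay_reaches_each_taxon(self):
        matrix = simulate_key_matrix(8, 6, distinct=True, unknown_rate=0.0,
                                     seed=41)
        text = export_flat_key(matrix)
        nodes = _parse_flat_key(text)

        def reachable_leaves(taxon, node, depth=0):
            assert depth < 50
            found = set()
            for label, ref in nodes[node]:
                if not _lead_consistent(matrix, taxon, label):
                    continue
                if ref.isdigit():
                    found |= reachable_leaves(taxon, int(ref), depth + 1)
                else:
                    found.add(ref)
            return found

        for taxon in matrix.taxon_names:
            leaves = reachable_leaves(taxon, 1)
            assert any(
                taxon == leaf or taxon in leaf for leaf in leaves
            ), f"{taxon} unreachable in flat key"
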