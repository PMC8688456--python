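"""Graph construction, parsing, generators and isomer enumeration."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from molconduct.molgraph import (
    EdgeListError,
    MolecularGraph,
    SmilesError,
    broom_graph,
    canonical_form,
    e_graph,
    enumerate_alkanes,
    is_isomorphic,
    parse_edge_list,
    parse_smiles,
    path_graph,
    to_smiles,
    write_edge_list,
)

FIG1 = "CC(C)(C)C(C)(C)C"


class TestParseSmiles:
    def test_quaternary_example_degrees(self):
        g = parse_smiles(FIG1)
        assert g.n == 8
        assert Counter(g.degrees()) == {1: 6, 4: 2}

    def test_single_atom(self):
        g = parse_smiles("C")
        assert (g.n, len(g.edges)) == (1, 0)

    @pytest.mark.parametrize(
        "bad",
        ["CC(O)C", "CC(C", "CC)C", "cC", "C=C", "", "C1CC1"],
        ids=["heteroatom", "open-paren", "close-paren", "aromatic", "bond", "empty", "ring"],
    )
    def test_rejects_out_of_subset(self, bad):
        with pytest.raises(SmilesError):
            parse_smiles(bad)

    def test_error_reports_position(self):
        with pytest.raises(SmilesError) as exc:
            parse_smiles("CC(O)C")
        assert exc.value.position == 3

    def test_valence_over_four_rejected(self):
        with pytest.raises(SmilesError):
            parse_smiles("C(C)(C)(C)(C)C")

    def test_ring_closure_allowed_when_cyclic(self):
        g = parse_smiles("C1CCC1", alkane=False)
        assert g.n == 4 and len(g.edges) == 4 and not g.is_tree

    def test_vertex_order_follows_atom_order(self):
        g = parse_smiles("CC(C)C")
        assert (0, 1) in g.edges and (1, 2) in g.edges and (1, 3) in g.edges


class TestEdgeList:
    def test_path(self):
        g = parse_edge_list("0 1\n1 2")
        assert is_isomorphic(g, path_graph(3))

    def test_disconnected_rejected(self):
        with pytest.raises(EdgeListError, match="connect"):
            parse_edge_list("0 1\n2 3")

    @pytest.mark.parametrize("bad", ["0 0", "0 1\n0 1", "1 2 3", "a b"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(EdgeListError):
            parse_edge_list(bad)

    def test_labels_normalised_preserving_order(self):
        g = parse_edge_list("# comment\n10 30\n30 20")
        assert g.n == 3
        assert g.edges == frozenset({(0, 2), (1, 2)})

    def test_fig1_edge_list_isomorphic_to_smiles(self):
        text = "0 1\n1 2\n1 3\n1 4\n4 5\n4 6\n4 7"
        assert is_isomorphic(parse_edge_list(text), parse_smiles(FIG1))


class TestGenerators:
    def test_path_is_normal_alkane_skeleton(self):
        assert Counter(path_graph(6).degrees()) == {1: 2, 2: 4}
        assert path_graph(1).n == 1
        with pytest.raises(ValueError):
            path_graph(0)

    def test_broom_is_methyl_series_skeleton(self):
        # B_{6,2} is 2-methylpentane; B_{5,3} the neopentane star
        assert Counter(broom_graph(6, 2).degrees()) == {1: 3, 2: 2, 3: 1}
        assert Counter(broom_graph(5, 3).degrees()) == {1: 4, 4: 1}

    @pytest.mark.parametrize("n", range(2, 31))
    def test_broom_q1_is_path(self, n):
        assert is_isomorphic(broom_graph(n, 1), path_graph(n))

    def test_broom_alkane_degree_guard(self):
        with pytest.raises(ValueError):
            broom_graph(8, 4)  # degree 5 hub is not an alkane
        broom_graph(8, 4, alkane=False)  # allowed as a plain graph

    def test_broom_parameter_guards(self):
        with pytest.raises(ValueError):
            broom_graph(3, 3)
        with pytest.raises(ValueError):
            broom_graph(5, 0)

    def test_e_catalogue(self):
        assert is_isomorphic(e_graph(8), parse_smiles(FIG1))
        assert is_isomorphic(e_graph(5), broom_graph(5, 3))
        with pytest.raises(ValueError, match="not catalogued"):
            e_graph(11)
        with pytest.raises(ValueError, match="not catalogued"):
            e_graph(4)


# --- independent brute force: labelled trees from Prüfer sequences ---------

def _prufer_tree(seq, n):
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    for x in seq:
        for v in range(n):
            if degree[v] == 1:
                edges.append((v, x))
                degree[v] -= 1
                degree[x] -= 1
                break
    last = [v for v in range(n) if degree[v] == 1]
    edges.append((last[0], last[1]))
    return edges


def _ahu_local(n, edges):
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)

    def enc(v, parent):
        return "(" + "".join(sorted(enc(w, v) for w in adj[v] if w != parent)) + ")"

    return min(enc(v, None) for v in range(n))


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 1), (3, 1), (4, 2), (5, 3), (6, 5), (7, 9), (8, 18)])
    def test_isomer_counts(self, n, expected):
        assert len(enumerate_alkanes(n)) == expected

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_counts_match_prufer_brute_force(self, n):
        classes = set()
        for seq in itertools.product(range(n), repeat=n - 2):
            edges = _prufer_tree(seq, n)
            deg = Counter(x for e in edges for x in e)
            if max(deg.values()) <= 4:
                classes.add(_ahu_local(n, edges))
        assert len(classes) == len(enumerate_alkanes(n))

    def test_representatives_are_distinct_and_valid(self):
        graphs = enumerate_alkanes(8)
        forms = {canonical_form(g) for g in graphs}
        assert len(forms) == len(graphs)
        for g in graphs:
            assert g.is_tree and max(g.degrees()) <= 4

    def test_bounds(self):
        with pytest.raises(ValueError):
            enumerate_alkanes(13)


class TestRoundTrips:
    @pytest.mark.parametrize("n", [2, 5, 7])
    def test_smiles_round_trip_all_isomers(self, n):
        for g in enumerate_alkanes(n):
            assert is_isomorphic(parse_smiles(to_smiles(g)), g)

    def test_edge_list_round_trip(self, ):
        g = parse_smiles(FIG1)
        assert is_isomorphic(parse_edge_list(write_edge_list(g)), g)

    @given(st.integers(2, 9), st.data())
    def test_random_tree_round_trips(self, n, data):
        seq = data.draw(st.lists(st.integers(0, n - 1), min_size=max(0, n - 2), max_size=max(0, n - 2)))
        edges = _prufer_tree(seq, n) if n > 2 else [(0, 1)]
        deg = Counter(x for e in edges for x in e)
        g = MolecularGraph(n, frozenset(edges), alkane_flag=max(deg.values()) <= 4)
        assert is_isomorphic(parse_edge_list(write_edge_list(g)), g)
        if g.alkane_flag:
            assert is_isomorphic(parse_smiles(to_smiles(g)), g)


class TestInvariants:
    def test_self_loop_and_range_rejected(self):
        with pytest.raises(ValueError):
            MolecularGraph(2, frozenset({(0, 0)}))
        with pytest.raises(ValueError):
            MolecularGraph(2, frozenset({(0, 5)}))

    def test_cycle_rejected_under_alkane_flag(self):
        edges = frozenset({(0, 1), (1, 2), (0, 2)})
        with pytest.raises(ValueError):
            MolecularGraph(3, edges)
        assert MolecularGraph(3, edges, alkane_flag=False).n == 3

    def test_smiles_parser_agrees_with_rdkit(self):
        from rdkit import Chem

        for text in ("CC(C)(C)C(C)(C)C", "CC(C)CC(C)CC", "CCCC", "CCC(C)(CC)CC"):
            mol = Chem.MolFromSmiles(text)
            g = parse_smiles(text)
            assert mol.GetNumAtoms() == g.n
            bonds = {
                tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
                for b in mol.GetBonds()
            }
            assert bonds == set(g.edges)

    def test_canonical_form_detects_isomorphism(self):
        a = parse_smiles("CCC(C)CC")   # 3-methylpentane
        b = parse_smiles("CC(CC)CC")   # same molecule written differently
        c = parse_smiles("CC(C)CCC")   # 2-methylpentane
        assert canonical_form(a) == canonical_form(b)
        assert canonical_form(a) != canonical_form(c)
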