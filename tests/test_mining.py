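"""Cluster mining: planted layouts, oracle equivalence, census counting."""
import numpy as np
import pytest

from quadhop import io as qio
from quadhop import synthetic as syn
from quadhop.geometry import min_site_distance
from quadhop.mining import (
    cofactor_proximity,
    find_clusters,
    scan_structure,
    size_distribution,
    tight_quadruplex_check,
)


def union_find_components(coords_list, cutoff):
    """Independent oracle: exhaustive union-find over the full pairwise
    min-distance matrix."""
    n = len(coords_list)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(n):
        for j in range(i + 1, n):
            d = min(
                float(np.linalg.norm(a - b))
                for a in coords_list[i]
                for b in coords_list[j]
            )
            if d <= cutoff:
                union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(c) for c in comps.values()}


class TestPlantedLayouts:
    def test_single_chain_quadruplex(self):
        st = syn.gen_planted_pdb([("A", 4, 6.0)], seed=1)
        clusters = find_clusters(st)
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.size == 4
        assert cl.classification == "intramolecular"
        assert not cl.dimer_link

    def test_cross_chain_dimer(self):
        st = syn.gen_planted_pdb([("A", 2, 6.0), ("B", 2, 6.0)], seed=2)
        clusters = find_clusters(st)
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.size == 4
        assert cl.classification == "interfacial"
        assert cl.dimer_link

    def test_below_linkage_gives_singletons(self):
        st = syn.gen_planted_pdb([("A", 4, 12.0)], seed=3)
        scan = scan_structure(st)
        assert scan.clusters == []
        assert len(scan.singletons) == 4
        assert scan.n_trp == 4

    def test_decoys_do_not_join_clusters(self):
        st = syn.gen_planted_pdb([("A", 4, 6.0)], decoys=3, seed=4)
        scan = scan_structure(st)
        assert len(scan.clusters) == 1
        assert len(scan.singletons) == 3

    def test_linkage_monotone_coarsening(self):
        st = syn.gen_random_trp_structure(25, seed=5)
        sizes_small = sorted(c.size for c in find_clusters(st, link_cutoff=8.0, min_size=1))
        sizes_large = sorted(c.size for c in find_clusters(st, link_cutoff=12.0, min_size=1))
        assert max(sizes_large) >= max(sizes_small)
        assert len(sizes_large) <= len(sizes_small)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_components_match_union_find(self, seed):
        st = syn.gen_random_trp_structure(20, seed=seed, box=45.0)
        sites = qio.indole_sites(st[0], min_atoms=1)
        ordered = sorted(sites.values(), key=lambda s: (s.chain_id, s.residue_number))
        coords = [s.coords for s in ordered]
        oracle = union_find_components(coords, 10.0)
        got = scan_structure(st, link_cutoff=10.0, min_size=1)
        members = {(s.chain_id, s.residue_number): k for k, s in enumerate(ordered)}
        found = {
            frozenset(members[m] for m in cl.members) for cl in got.clusters
        }
        assert found == oracle

    def test_invariant_to_rigid_transform(self):
        st = syn.gen_random_trp_structure(15, seed=42)
        base = [tuple(c.members) for c in find_clusters(st, min_size=1)]
        st2 = st.clone()
        theta = 1.1
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        t = np.array([25.0, -13.0, 7.0])
        for chain in st2[0]:
            for res in chain:
                for atom in res:
                    p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    q = R @ p + t
                    atom.pos = type(atom.pos)(*q)
        moved = [tuple(c.members) for c in find_clusters(st2, min_size=1)]
        assert moved == base


class TestTightQuadruplex:
    def test_all_pairs_close_passes(self):
        st = syn.gen_planted_pdb([("A", 4, 4.0)], seed=6)
        cl = find_clusters(st, link_cutoff=10.0)[0]
        ok, failing = tight_quadruplex_check(cl)
        assert ok and failing == []

    def test_reference_quadruplex_fails_on_long_diagonal(self, reference_structure):
        """The crystal-interface quadruplex has a 5.4 Å long diagonal, so the
        strict all-pairs-below-5-Å test fails on exactly that pair."""
        cl = find_clusters(reference_structure, link_cutoff=10.0)[0]
        ok, failing = tight_quadruplex_check(cl)
        assert not ok
        assert len(failing) == 1
        (m1, m2, d) = failing[0]
        assert {m1, m2} == {("A", 124), ("D", 124)}
        assert d == pytest.approx(5.4, abs=0.05)

    def test_infinite_cutoff_always_true(self, reference_structure):
        cl = find_clusters(reference_structure)[0]
        ok, _ = tight_quadruplex_check(cl, cutoff=np.inf)
        assert ok

    def test_wrong_size_rejected(self):
        st = syn.gen_planted_pdb([("A", 3, 5.0)], seed=7)
        cl = find_clusters(st)[0]
        with pytest.raises(ValueError, match="size 4"):
            tight_quadruplex_check(cl)


class TestSizeDistribution:
    def test_known_composition_exact_histogram(self):
        scans = [
            scan_structure(syn.gen_planted_pdb([("A", 4, 6.0)], seed=10), "s1"),
            scan_structure(
                syn.gen_planted_pdb([("A", 2, 6.0), ("B", 2, 6.0)], seed=11), "s2"
            ),
            scan_structure(syn.gen_planted_pdb([("A", 2, 5.0)], seed=12), "s3"),
            # two disjoint clusters in one structure (different spacings)
            scan_structure(
                syn.gen_planted_pdb([("A", 4, 6.0), ("A", 4, 7.0)], seed=13), "s4"
            ),
        ]
        dist = size_distribution(scans)
        assert dist.per_size.loc[4, "n_clusters"] == 4
        assert dist.per_size.loc[4, "n_structures"] == 3  # s4 counted once
        assert dist.per_size.loc[2, "n_clusters"] == 1
        assert dist.quad_breakdown == {
            "intramolecular": 3,
            "interfacial": 1,
            "dimer": 1,
        }

    def test_empty_set(self):
        dist = size_distribution([])
        assert dist.per_size.empty
        assert dist.n_structures == 0


class TestCofactorProximity:
    def test_planted_distance_recovered(self):
        st = syn.gen_planted_pdb([("A", 4, 6.0)], seed=14, cofactors=[("FAD", 12.0)])
        cl = find_clusters(st)[0]
        prox = cofactor_proximity(st, cl)
        assert len(prox) == 1
        assert prox[0].cofactor[0] == "FAD"
        assert prox[0].d_min == pytest.approx(12.0, abs=0.05)

    def test_no_het_groups_empty(self):
        st = syn.gen_planted_pdb([("A", 4, 6.0)], seed=15)
        cl = find_clusters(st)[0]
        assert cofactor_proximity(st, cl) == []

    def test_two_cofactors_match_brute_force(self):
        st = syn.gen_planted_pdb(
            [("A", 4, 6.0)], seed=16, cofactors=[("FAD", 12.0), ("HEM", 15.0)]
        )
        cl = find_clusters(st)[0]
        prox = {p.cofactor[0]: p.d_min for p in cofactor_proximity(st, cl)}
        sites = qio.indole_sites(st[0], min_atoms=1)
        cluster_atoms = np.vstack(
            [sites[f"{n}{c}"].coords for c, n in cl.members]
        )
        for chain in st[0]:
            for res in chain:
                if res.name in ("FAD", "HEM"):
                    pts = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
                    brute = min(
                        np.linalg.norm(a - b) for a in pts for b in cluster_atoms
                    )
                    assert prox[res.name] == pytest.approx(brute, abs=1e-9)


class TestAltlocHandling:
    def test_highest_occupancy_kept(self, tmp_path):
        pdb_text = """\
ATOM      1  CG ATRP A 122      10.000  10.000  10.000  0.40 10.00           C
ATOM      2  CG BTRP A 122      20.000  10.000  10.000  0.60 10.00           C
ATOM      3  CD1ATRP A 122      11.200  10.000  10.000  0.40 10.00           C
ATOM      4  CD1BTRP A 122      21.200  10.000  10.000  0.60 10.00           C
ATOM      5  NE1ATRP A 122      12.000  11.000  10.000  0.40 10.00           N
ATOM      6  NE1BTRP A 122      22.000  11.000  10.000  0.60 10.00           N
ATOM      7  CD2ATRP A 122      10.500  11.300  10.000  0.40 10.00           C
ATOM      8  CD2BTRP A 122      20.500  11.300  10.000  0.60 10.00           C
ATOM      9  CE2ATRP A 122      11.800  12.000  10.000  0.40 10.00           C
ATOM     10  CE2BTRP A 122      21.800  12.000  10.000  0.60 10.00           C
END
"""
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb_text)
        st = qio.read_structure(path)
        sites = qio.indole_sites(st[0], min_atoms=1)
        assert len(sites) == 1
        # the B conformer (occupancy 0.60) wins
        assert sites["122A"].coords[:, 0].min() >= 20.0
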