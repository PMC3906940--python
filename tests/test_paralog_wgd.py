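import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import salmodiv as sd
from salmodiv.io_formats import Alignment
from salmodiv.paralog_wgd import ParalogPair
from conftest import gene_tree_taxon_map, make_scenario_spec


def _rotate_children(tree, rng):
    for node in tree.preorder_internal_node_iter():
        if rng.random() < 0.5:
            kids = node.child_nodes()
            node.set_child_nodes(kids[::-1])
    return tree


class TestClassifier:
    @pytest.mark.parametrize(
        "scenario,expected,keep",
        [
            ("b_ancestral_DR", "resolved_ancestral", True),
            ("c_lineage_specific_DR", "lineage_specific", False),
            ("d_unresolved_tetrasomic", "unresolved_tetrasomic", False),
            ("a_species_only", "ambiguous", False),
        ],
    )
    def test_simulated_scenarios(self, species_tree, scenario, expected, keep):
        gt = sd.simulate_wgd_gene_tree(species_tree, make_scenario_spec(scenario))
        res = sd.classify_diploidization(gt, gene_tree_taxon_map(gt))
        assert res.scenario == expected
        assert res.keep is keep

    def test_invariant_to_rotation_and_rerooting(self, species_tree):
        rng = np.random.default_rng(0)
        for scenario in ("b_ancestral_DR", "c_lineage_specific_DR",
                         "d_unresolved_tetrasomic"):
            gt = sd.simulate_wgd_gene_tree(species_tree, make_scenario_spec(scenario))
            tmap = gene_tree_taxon_map(gt)
            base = sd.classify_diploidization(gt, tmap).scenario
            rotated = _rotate_children(gt.clone(depth=1), rng)
            assert sd.classify_diploidization(rotated, tmap).scenario == base
            # reroot along the branch to the outermost outgroup
            rerooted = gt.clone(depth=1)
            og = next(
                l for l in rerooted.leaf_node_iter() if l.taxon.label == "Osmerus"
            )
            rerooted.reroot_at_edge(
                og.edge, length1=og.edge.length * 0.3, length2=og.edge.length * 0.7
            )
            assert sd.classify_diploidization(rerooted, tmap).scenario == base

    def test_support_threshold_semantics(self):
        # paralogue split annotated with support 0.99 at the ingroup crown
        newick = (
            "(((S1|P1:10,S2|P1:10)1.0:30,(S1|P2:10,S2|P2:10)1.0:30)0.99:20,OG:60);"
        )
        gt = sd.read_newick(newick)
        tmap = sd.TaxonMap.from_subfamilies(
            [l.taxon.label for l in gt.leaf_node_iter()],
            {"S1": "Salmoninae", "S2": "Coregoninae"},
            outgroups=("OG",),
        )
        assert sd.classify_diploidization(gt, tmap, min_support=0.95).keep
        res = sd.classify_diploidization(gt, tmap, min_support=0.995)
        assert res.scenario == "ambiguous"
        # unannotated split with a threshold requested -> ambiguous
        bare = sd.read_newick(
            "(((S1|P1:10,S2|P1:10):30,(S1|P2:10,S2|P2:10):30):20,OG:60);"
        )
        assert (
            sd.classify_diploidization(bare, tmap, min_support=0.95).scenario
            == "ambiguous"
        )
        assert sd.classify_diploidization(bare, tmap).keep  # no threshold

    def test_error_conditions(self, species_tree):
        gt = sd.simulate_wgd_gene_tree(species_tree, make_scenario_spec("b_ancestral_DR"))
        tmap = gene_tree_taxon_map(gt)
        with pytest.raises(ValueError, match="unmapped"):
            partial = {
                k: v
                for k, v in tmap.entries.items()
                if not k.startswith("Salmo|")
            }
            sd.classify_diploidization(gt, sd.TaxonMap(partial))

    def test_screen_keeps_18_of_26(self, species_tree):
        """A mixed batch of 26 paralogue datasets passes exactly the 18
        ancestrally-resolved ones through the keep filter."""
        trees = []
        for i in range(18):
            trees.append(
                sd.simulate_wgd_gene_tree(
                    species_tree,
                    make_scenario_spec("b_ancestral_DR", dr_depths=60.0 + 2.0 * i),
                )
            )
        for i in range(4):
            trees.append(
                sd.simulate_wgd_gene_tree(
                    species_tree,
                    make_scenario_spec(
                        "c_lineage_specific_DR",
                        dr_depths={"Oncorhynchus": 42.0 + i, "Coregonus": 44.0 + i},
                    ),
                )
            )
        for i in range(4):
            trees.append(
                sd.simulate_wgd_gene_tree(
                    species_tree,
                    make_scenario_spec(
                        "d_unresolved_tetrasomic", conversion_strength=1.0 - 0.1 * i
                    ),
                )
            )
        kept = sum(
            sd.classify_diploidization(t, gene_tree_taxon_map(t)).keep for t in trees
        )
        assert kept == 18


def _pair(name, taxa, length, seed):
    rng = np.random.default_rng(seed)
    mk = lambda: {
        t: "".join(rng.choice(list("ACGT"), size=length)) for t in taxa
    }
    return ParalogPair(name, Alignment(mk()), Alignment(mk()))


class TestConcatenation:
    def test_counts(self):
        taxa = ["sp1", "sp2"]
        pairs = [_pair(f"g{i}", taxa, 6, i) for i in range(18)]
        cset = sd.enumerate_concatenations(pairs)
        assert cset.n_assignments == 262_144
        assert cset.n_canonical == 131_072
        small = sd.enumerate_concatenations(pairs[:1])
        assert small.n_assignments == 2 and small.n_canonical == 1

    def test_exhaustive_small_k(self):
        taxa = ["sp1", "sp2"]
        pairs = [_pair(f"g{i}", taxa, 3, i) for i in range(2)]
        cset = sd.enumerate_concatenations(pairs)
        alns = sd.sample_concatenations(cset, 4, seed=0)
        assert len({tuple(sorted(a.sequences.items())) for a in alns}) == 4

    def test_sampling_distinct_and_reproducible(self):
        taxa = ["sp1", "sp2", "sp3"]
        pairs = [_pair(f"g{i}", taxa, 9, i) for i in range(18)]
        cset = sd.enumerate_concatenations(pairs)
        bits1 = sd.sample_concatenations(cset, 50, seed=42, as_alignments=False)
        bits2 = sd.sample_concatenations(cset, 50, seed=42, as_alignments=False)
        assert bits1 == bits2
        assert len(set(bits1)) == 50
        with pytest.raises(ValueError):
            sd.sample_concatenations(cset, cset.n_assignments + 1, seed=0)

    def test_sampling_uniformity(self):
        """Assignment draws are uniform over the 2^k set (chi-square GOF)."""
        from scipy.stats import chisquare

        taxa = ["sp1"]
        pairs = [_pair(f"g{i}", taxa, 3, i) for i in range(3)]
        cset = sd.enumerate_concatenations(pairs)
        rng = np.random.default_rng(123)
        counts = np.zeros(8)
        for _ in range(10_000 // 4):
            for bits in sd.sample_concatenations(
                cset, 4, seed=rng, as_alignments=False
            ):
                counts[sum(b << i for i, b in enumerate(bits))] += 1
        assert chisquare(counts).pvalue > 0.001

    def test_build_matrix_shape(self):
        taxa = ["sp1", "sp2"]
        pairs = [_pair(f"g{i}", taxa, 6, i) for i in range(3)]
        cset = sd.enumerate_concatenations(pairs)
        aln = cset.build((0, 1, 0))
        assert aln.length == 18
        assert sorted(aln.taxa) == ["sp1|A", "sp1|B", "sp2|A", "sp2|B"]


def _block_lengths_summing(total, k):
    base = total // k // 3 * 3
    lengths = [base] * k
    lengths[-1] = total - base * (k - 1)
    assert sum(lengths) == total and all(l % 3 == 0 for l in lengths)
    return lengths


def _ortholog_pairs(lengths, species, outgroups, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for i, length in enumerate(lengths):
        taxa = species + outgroups
        mk = lambda: Alignment(
            {t: "".join(rng.choice(list("ACGT"), size=length)) for t in taxa}
        )
        pairs.append(ParalogPair(f"g{i}", mk(), mk()))
    return pairs


class TestOrthologSupermatrix:
    def test_printed_dimensions(self):
        """Blocks summing to 10,833 bp per paralogue give a 21,666-column
        supermatrix, and 14,444 columns once codon position 3 is removed."""
        lengths = _block_lengths_summing(10_833, 18)
        species = ["Salmo", "Thymallus", "Coregonus"]
        tmap = sd.TaxonMap.from_subfamilies(
            species + ["Esox"],
            {"Salmo": "Salmoninae", "Thymallus": "Thymallinae",
             "Coregonus": "Coregoninae"},
            outgroups=("Esox",),
        )
        pairs = _ortholog_pairs(lengths, species, ["Esox"])
        aln = sd.concat_orthologs(pairs, tmap)
        assert aln.length == 21_666
        assert sorted(aln.taxa) == sorted(species + ["Esox"])
        reduced = sd.codon_partition(aln, {1, 2})
        assert reduced.length == 14_444

    def test_outgroup_single_policy_gap_fills(self):
        species = ["A", "B"]
        tmap = sd.TaxonMap.from_subfamilies(
            species + ["OG"],
            {"A": "Salmoninae", "B": "Coregoninae"},
            outgroups=("OG",),
        )
        pairs = _ortholog_pairs([6], species, ["OG"])
        aln = sd.concat_orthologs(pairs, tmap, outgroup_policy="single")
        assert aln.sequences["OG"][6:] == "-" * 6
        assert "-" not in aln.sequences["A"]

    def test_partition_commutes_with_concatenation(self):
        species = ["A", "B"]
        tmap = sd.TaxonMap.from_subfamilies(
            species + ["OG"],
            {"A": "Salmoninae", "B": "Coregoninae"},
            outgroups=("OG",),
        )
        pairs = _ortholog_pairs([6, 9], species, ["OG"], seed=3)
        whole = sd.codon_partition(sd.concat_orthologs(pairs, tmap), {1, 2})
        per_block = sd.concat_orthologs(
            [
                ParalogPair(
                    p.name,
                    sd.codon_partition(p.first, {1, 2}),
                    sd.codon_partition(p.second, {1, 2}),
                )
                for p in pairs
            ],
            tmap,
        )
        assert whole.sequences == per_block.sequences


class TestCodonPartition:
    def test_identity_and_single_position(self):
        aln = Alignment({"x": "ATGCCCGGG", "y": "ATGCCCGGT"})
        assert sd.codon_partition(aln, {1, 2, 3}).sequences == aln.sequences
        third = sd.codon_partition(aln, {3})
        assert third.length == 3
        assert third.sequences["x"] == "GCG"

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            sd.codon_partition(Alignment({"x": "ATGC"}), {1, 2})


class TestTajima:
    def test_closed_form_example(self):
        # 6 sites where A alone differs, 2 where B alone differs
        a = "C" * 6 + "A" * 2 + "A" * 10
        b = "A" * 6 + "C" * 2 + "A" * 10
        o = "A" * 6 + "A" * 2 + "A" * 10
        res = sd.tajima_rrt(Alignment({"A": a, "B": b, "O": o}), "A", "B", "O")
        assert res.details["m1"] == 6 and res.details["m2"] == 2
        assert res.statistic == pytest.approx(2.0)
        assert res.pvalue == pytest.approx(0.1573, abs=2e-4)

    def test_symmetric_counts_give_p_one(self):
        a = "CCAA" + "G" * 8
        b = "AACC" + "G" * 8
        o = "AAAA" + "G" * 8
        res = sd.tajima_rrt(Alignment({"A": a, "B": b, "O": o}), "A", "B", "O")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_identical_sequences(self):
        aln = Alignment({"A": "ACGT", "B": "ACGT", "O": "ACGT"})
        res = sd.tajima_rrt(aln, "A", "B", "O")
        assert res.details["m1"] == res.details["m2"] == 0
        assert res.pvalue == 1.0

    def test_gapped_sites_excluded(self):
        aln = Alignment({"A": "C-GT", "B": "A-GT", "O": "ANGT"})
        res = sd.tajima_rrt(aln, "A", "B", "O")
        assert res.details["n_sites"] == 3  # gap and N columns excluded
        assert res.details["m1"] == 1

    def test_missing_taxon_rejected(self):
        with pytest.raises(ValueError):
            sd.tajima_rrt(Alignment({"A": "ACGT", "B": "ACGT"}), "A", "B", "O")


class TestSaturationScan:
    def test_identical_pair(self):
        scan = sd.saturation_scan(Alignment({"a": "ACGT" * 5, "b": "ACGT" * 5}))
        row = scan.table.iloc[0]
        assert row["differences"] == 0 and row["k2p"] == 0.0

    def test_k2p_closed_form(self):
        # P = 0.1 transitions, Q = 0: d = -0.5 ln(0.8)
        a = "A" * 10
        b = "G" + "A" * 9
        scan = sd.saturation_scan(Alignment({"a": a, "b": b}))
        row = scan.table.iloc[0]
        assert row["P"] == pytest.approx(0.1)
        assert row["k2p"] == pytest.approx(-0.5 * math.log(0.8), abs=1e-9)

    def test_saturated_pair_flagged(self):
        # transversion proportion 0.5 -> 1 - 2Q = 0: undefined distance
        a = "A" * 10
        b = "C" * 5 + "A" * 5
        scan = sd.saturation_scan(Alignment({"a": a, "b": b}))
        assert not scan.table.iloc[0]["k2p_defined"]

    def test_slope_on_clocklike_data(self):
        tree = sd.simulate_bd_tree(0.5, 0.0, 6, seed=2)
        aln = sd.simulate_alignment(tree, sd.HkyParams(), 400, seed=2, clock_rate=0.05)
        scan = sd.saturation_scan(aln)
        assert scan.slope > 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    ts=st.integers(min_value=0, max_value=40),
    tv=st.integers(min_value=0, max_value=40),
)
def test_k2p_dominates_p_distance(ts, tv):
    """K2P >= p-distance wherever the distance is defined."""
    n = 100
    a = "A" * n
    b = "G" * ts + "C" * tv + "A" * (n - ts - tv)
    scan = sd.saturation_scan(Alignment({"a": a, "b": b}))
    row = scan.table.iloc[0]
    if row["k2p_defined"]:
        assert row["k2p"] >= row["p_distance"] - 1e-12
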