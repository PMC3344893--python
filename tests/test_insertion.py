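import numpy as np
import pytest

from phylofoot.insertion import (
    AlignParams,
    InsertionInterval,
    align_pair,
    classify_element,
    detect_polya,
    detect_tsd,
    find_insertions,
    place_gain,
    render_gain_newick,
)
from phylofoot.seqio import SeqRecord, read_newick, revcomp
from phylofoot.simulate import InsertionImplant, implant_insertion, make_ancestor

PARAMS = AlignParams()


def dp_oracle(a: str, b: str, p: AlignParams = PARAMS) -> float:
    """Independent affine-gap global alignment DP (Gotoh three-matrix)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = p.gap_open + (i - 1) * p.gap_extend
    for j in range(1, m + 1):
        Y[0][j] = p.gap_open + (j - 1) * p.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + p.gap_open, X[i - 1][j] + p.gap_extend,
                          Y[i - 1][j] + p.gap_open)
            Y[i][j] = max(M[i][j - 1] + p.gap_open, Y[i][j - 1] + p.gap_extend,
                          X[i][j - 1] + p.gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignPair:
    def test_identical(self):
        aln = align_pair("ACGT", "ACGT")
        assert aln.score == 4 and aln.gap_blocks == ()

    def test_single_long_gap(self):
        x = "GATTACAGATTACAGATTACAGATTACAGC"  # 30-mer
        aln = align_pair("ACGT" + x + "ACGT", "ACGTACGT")
        blocks = [b for b in aln.gap_blocks if b.row == 1]
        assert len(blocks) == 1 and blocks[0].length == 30

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    def test_score_matches_dp_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(500):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
            assert align_pair(a, b).score == pytest.approx(dp_oracle(a, b))

    def test_deterministic(self):
        a, b = "ACGTACGTTT", "ACGGTACGT"
        r1, r2 = align_pair(a, b), align_pair(a, b)
        assert (r1.a_aligned, r1.b_aligned) == (r2.a_aligned, r2.b_aligned)


class TestFindInsertions:
    def test_single_insertion(self):
        rng = np.random.default_rng(43)
        ref = "".join(rng.choice(list("ACGT"), size=400))
        ins = "".join(rng.choice(list("ACGT"), size=300))
        carrier = ref[:199] + ins + ref[199:]
        got = find_insertions(carrier, ref)
        assert len(got) == 1
        iv = got[0]
        assert iv.length == 300
        # canonicalisation may slide within flanking repeats; content must match
        assert abs(iv.start - 200) <= 2

    def test_identical_pair_empty(self):
        rng = np.random.default_rng(44)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert find_insertions(seq, seq) == []

    def test_two_insertions_in_order(self):
        rng = np.random.default_rng(45)
        ref = "".join(rng.choice(list("ACGT"), size=500))
        i1 = "".join(rng.choice(list("ACGT"), size=60))
        i2 = "".join(rng.choice(list("ACGT"), size=80))
        carrier = ref[:100] + i1 + ref[100:300] + i2 + ref[300:]
        got = find_insertions(carrier, ref)
        assert [iv.length for iv in got] == [60, 80]
        assert got[0].start < got[1].start


class TestDetectTsd:
    def build(self, tsd_len=18, seed=47):
        rng = np.random.default_rng(seed)
        host = "".join(rng.choice(list("ACGT"), size=400))
        element = "".join(rng.choice(list("ACGT"), size=120))
        imp = InsertionImplant(
            name="e", clade=("sp",), element=element, position=200,
            orientation="sense", tsd_len=tsd_len, tail_len=10,
        )
        seqs, truth = implant_insertion({"sp": host}, imp)
        t = truth["sp"]
        return seqs["sp"], InsertionInterval(t["start"], t["length"])

    def test_exact_18(self):
        carrier, iv = self.build()
        tsd = detect_tsd(carrier, iv)
        assert tsd is not None and tsd.length == 18 and tsd.left == tsd.right

    def test_no_flanking_repeat(self):
        rng = np.random.default_rng(48)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert detect_tsd(seq, InsertionInterval(100, 80)) is None

    def test_longest_wins(self):
        carrier, iv = self.build(tsd_len=25)
        tsd = detect_tsd(carrier, iv)
        assert tsd is not None and tsd.length == 25

    def test_interval_at_sequence_start(self):
        assert detect_tsd("ACGT" * 30, InsertionInterval(1, 40)) is None

    def test_exact_recovery_200_insertions(self):
        # the central simulator round trip: implanted TSD length, uniform in
        # 8..25, is recovered exactly on every one of 200 insertions
        rng = np.random.default_rng(49)
        exact = 0
        for _ in range(200):
            host = "".join(rng.choice(list("ACGT"), size=300))
            element = "".join(rng.choice(list("ACGT"), size=60))
            k = int(rng.integers(8, 26))
            pos = int(rng.integers(60, 240))
            imp = InsertionImplant(
                name="e", clade=("sp",), element=element, position=pos,
                orientation="antisense" if rng.random() < 0.5 else "sense",
                tsd_len=k, tail_len=int(rng.integers(8, 15)),
            )
            seqs, truth = implant_insertion({"sp": host}, imp)
            t = truth["sp"]
            tsd = detect_tsd(seqs["sp"], InsertionInterval(t["start"], t["length"]))
            exact += tsd is not None and tsd.length == k
        assert exact == 200


class TestDetectPolya:
    def test_a_tail(self):
        got = detect_polya("CGTC" * 10 + "A" * 10)
        assert got.side == "A-tail" and got.length == 10

    def test_t_head_antisense_signature(self):
        got = detect_polya("T" * 9 + "CGAC" * 10)
        assert got.side == "T-head" and got.length == 9

    def test_short_run_none(self):
        assert detect_polya("AAACGT" * 5) is None


@pytest.fixture(scope="module")
def consensus():
    return [SeqRecord("SINE_synthetic", make_ancestor(280, 0.55, 99))]


class TestClassifyElement:

    def test_verbatim_sense(self, consensus):
        call = classify_element(consensus[0].residues, consensus)
        assert call.name == "SINE_synthetic" and call.orientation == "sense"
        assert call.score == 280

    def test_mutated_revcomp_antisense(self, consensus):
        rng = np.random.default_rng(51)
        seq = list(revcomp(consensus[0].residues))
        for i in rng.choice(len(seq), size=14, replace=False):  # 5% substitutions
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        call = classify_element("".join(seq), consensus)
        assert call is not None and call.orientation == "antisense"

    def test_random_insert_unclassified(self, consensus):
        # the default threshold sits far above the background score
        # distribution of random inserts
        rng = np.random.default_rng(53)
        scores = []
        for _ in range(100):
            insert = "".join(rng.choice(list("ACGT"), size=300))
            call = classify_element(insert, consensus, min_score=0)
            scores.append(call.score)
            assert classify_element(insert, consensus, min_score=50) is None
        assert max(scores) < 50

    def test_orientation_antisymmetric(self, consensus):
        rng = np.random.default_rng(57)
        for _ in range(5):
            seq = list(consensus[0].residues)
            for i in rng.choice(len(seq), size=10, replace=False):
                seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
            fwd = classify_element("".join(seq), consensus)
            rev = classify_element(revcomp("".join(seq)), consensus)
            assert {fwd.orientation, rev.orientation} == {"sense", "antisense"}


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def exhaustive_gain_oracle(tree, present: set[str]) -> frozenset[str]:
    """Smallest clade (over every edge of the tree) containing all carriers."""
    best = None
    for node in tree.preorder_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if present <= below and (best is None or len(below) < len(best)):
            best = below
    return best


class TestPlaceGain:
    def test_clade_consistent_catarrhine_pattern(self, insertion_cohort):
        from phylofoot.presets import CATARRHINES, PRIMATE_NEWICK

        tree = read_newick(PRIMATE_NEWICK)
        presence = {
            l.taxon.label: l.taxon.label in CATARRHINES for l in tree.leaf_node_iter()
        }
        placement = place_gain(tree, presence)
        assert placement.gain_clade == frozenset(CATARRHINES)
        assert placement.loss_clades == ()
        assert placement.gain_clade == exhaustive_gain_oracle(tree, set(CATARRHINES))

    def test_all_present_gain_at_root(self):
        tree = read_newick("((A,B),(C,D));")
        placement = place_gain(tree, {sp: True for sp in "ABCD"})
        assert placement.gain_clade == frozenset("ABCD")

    def test_single_leaf(self):
        tree = read_newick("((A,B),(C,D));")
        placement = place_gain(tree, {sp: sp == "C" for sp in "ABCD"})
        assert placement.gain_clade == frozenset("C") and placement.loss_clades == ()

    def test_losses_inside_clade(self):
        tree = read_newick("(((A,B),(C,D)),E);")
        placement = place_gain(tree, {"A": True, "B": True, "C": False, "D": False, "E": False})
        assert placement.gain_clade == frozenset("AB")
        placement2 = place_gain(tree, {"A": True, "B": True, "C": False, "D": True, "E": False})
        assert placement2.gain_clade == frozenset("ABCD")
        assert placement2.loss_clades == (frozenset("C"),)

    def test_no_carriers_rejected(self):
        tree = read_newick("(A,B);")
        with pytest.raises(ValueError):
            place_gain(tree, {"A": False, "B": False})

    def test_presence_matrix_must_cover_tree(self):
        tree = read_newick("(A,B);")
        with pytest.raises(ValueError, match="mismatch"):
            place_gain(tree, {"A": True})

    def test_100_random_clade_consistent_trees(self):
        # for presence exactly matching a clade, the gain lands on that
        # clade's stem with zero losses, agreeing with the exhaustive oracle
        rng = np.random.default_rng(59)
        done = 0
        while done < 100:
            tree = read_newick(random_tree_newick(rng, int(rng.integers(4, 15))))
            internals = [
                n for n in tree.preorder_node_iter()
                if not n.is_leaf() and n is not tree.seed_node
            ]
            if not internals:
                continue
            node = internals[rng.integers(len(internals))]
            clade = {l.taxon.label for l in node.leaf_iter()}
            presence = {
                l.taxon.label: l.taxon.label in clade for l in tree.leaf_node_iter()
            }
            placement = place_gain(tree, presence)
            assert placement.gain_clade == frozenset(clade)
            assert placement.loss_clades == ()
            assert placement.gain_clade == exhaustive_gain_oracle(tree, clade)
            done += 1

    def test_rendered_newick_labels_gain(self):
        tree = read_newick("((A,B),(C,D));")
        placement = place_gain(tree, {"A": True, "B": True, "C": False, "D": False})
        assert "GAIN" in render_gain_newick(tree, placement)
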