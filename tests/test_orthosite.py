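"""Alignment, site mapping and genotyping against independent oracles."""

import numpy as np
import pytest

from sacph import orthosite as o
from sacph import synth

# ---------------------------------------------------------------------------
# Independent brute-force alignment oracle (full enumeration, own scorer)
# ---------------------------------------------------------------------------

_B62 = {}  # filled lazily from biopython, but scoring logic is independent


def _pair_score(x, y):
    if not _B62:
        from Bio.Align import substitution_matrices
        m = substitution_matrices.load("BLOSUM62")
        for a in m.alphabet:
            for b in m.alphabet:
                _B62[a, b] = float(m[a, b])
    if "X" in (x, y):
        return 0.0
    return _B62[x, y]


def _enumerate_score(a, b, open_=-11.0, ext=-1.0):
    """Max score over *all* global alignments, by explicit enumeration."""
    best = [-np.inf]

    def rec(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _pair_score(a[i], b[j]), "m")
        if i < len(a):  # gap in b
            cost = ext if prev == "gb" else open_
            rec(i + 1, j, score + cost, "gb")
        if j < len(b):  # gap in a
            cost = ext if prev == "ga" else open_
            rec(i, j + 1, score + cost, "ga")

    rec(0, 0, 0.0, "")
    return best[0]


@pytest.mark.parametrize("a,b", [
    ("KAGDR", "KGDR"),
    ("KAGDR", "KAGDN"),
    ("AAAA", "GGGG"),
    ("KR", "KAGDR"),
    ("AGDKRA", "RKDGA"),
])
def test_aligner_matches_enumeration_oracle(a, b):
    ra = o.ProteinRecord(id="a", residues=a)
    rb = o.ProteinRecord(id="b", residues=b)
    aln = o.align_global(ra, rb)
    assert aln.score == pytest.approx(_enumerate_score(a, b))
    # the returned alignment re-scores to its reported score
    assert o.score_alignment(aln.aligned_a, aln.aligned_b) == pytest.approx(
        aln.score)
    # ungapping recovers the inputs
    assert aln.ungapped_a == a and aln.ungapped_b == b


def test_aligner_matches_oracle_on_random_short_pairs():
    rng = np.random.default_rng(11)
    alphabet = np.array(list("AGKR"))
    for _ in range(15):
        a = "".join(rng.choice(alphabet, rng.integers(2, 7)))
        b = "".join(rng.choice(alphabet, rng.integers(2, 7)))
        aln = o.align_global(o.ProteinRecord(id="a", residues=a),
                             o.ProteinRecord(id="b", residues=b))
        assert aln.score == pytest.approx(_enumerate_score(a, b)), (a, b)


def test_alignment_input_errors():
    with pytest.raises(o.InputError):
        o.ProteinRecord(id="x", residues="")
    with pytest.raises(o.ConfigError):
        o.AlignmentParams(gap_open=-1, gap_extend=-2)
    with pytest.raises(o.ConfigError):
        o.align_global(o.ProteinRecord(id="a", residues="KA"),
                       o.ProteinRecord(id="b", residues="KA"),
                       o.AlignmentParams(substitution_matrix="NOSUCH"))


# ---------------------------------------------------------------------------
# percent identity and site mapping
# ---------------------------------------------------------------------------

def test_percent_identity_policies():
    ra = o.ProteinRecord(id="a", residues="KAGDR")
    self_aln = o.align_global(ra, ra)
    assert o.percent_identity(self_aln) == 100.0
    aln = o.align_global(ra, o.ProteinRecord(id="b", residues="KAGDN"))
    assert o.percent_identity(aln) == pytest.approx(80.0)  # 4 of 5
    assert o.percent_identity(aln, "alignment_length") == pytest.approx(80.0)
    with pytest.raises(o.ConfigError):
        o.percent_identity(aln, "bogus")


def test_map_site_toy_gap_case():
    # optimal alignment of KAGDR vs KGDR places the gap under A (pos 2)
    aln = o.align_global(o.ProteinRecord(id="a", residues="KAGDR"),
                         o.ProteinRecord(id="b", residues="KGDR"))
    assert o.map_site(aln, 1) == 1
    assert o.map_site(aln, 2) is None
    assert o.map_site(aln, 5) == 4
    with pytest.raises(o.InputError):
        o.map_site(aln, 6)


def test_map_site_order_preserving(reference):
    rng = np.random.default_rng(5)
    rec, _ = synth.gen_sequences("clade_survey_panel", reference, seed=2)
    for query in rec[::7]:
        aln = o.align_global(reference, query)
        mapped = [(p, q) for p in rng.choice(len(reference), 30, replace=False) + 1
                  if (q := o.map_site(aln, int(p))) is not None]
        mapped.sort()
        qs = [q for _, q in mapped]
        assert qs == sorted(qs)


# ---------------------------------------------------------------------------
# genotyping and motifs
# ---------------------------------------------------------------------------

def test_reference_self_genotype_is_k_r(reference, sites):
    aln = o.align_global(reference, reference)
    call = o.call_genotype(reference, aln, sites)
    assert call.label == "K/R"
    assert call.charge_class == "both-positive"
    motifs = o.check_motifs(reference, aln, sites)
    assert all(rep["match"] for rep in motifs.values())


def test_urchin_like_analogue_maps_to_documented_coordinates(reference, sites):
    ap = synth.gen_urchin_like(reference)
    aln = o.align_global(reference, ap)
    assert o.map_site(aln, 95) == 117
    assert o.map_site(aln, 176) == 198
    call = o.call_genotype(ap, aln, sites)
    assert call.label == "K/N"
    assert call.charge_class == "one-positive"
    motifs = o.check_motifs(ap, aln, sites)
    assert motifs["C1-b2/3"]["range"] == (119, 121)
    assert motifs["C2-b2/3"]["range"] == (418, 421)
    assert all(rep["match"] for rep in motifs.values())


def test_planted_double_positive_genotype(reference, sites):
    seq = list(reference.residues)
    seq[175] = "K"  # R176 -> K: insect-type double-positive genotype
    rec = o.ProteinRecord(id="ins", residues="".join(seq))
    aln = o.align_global(reference, rec)
    call = o.call_genotype(rec, aln, sites)
    assert call.label == "K/K"
    assert call.charge_class == "both-positive"


def test_mutated_loop_motif_reported_false(reference, sites):
    seq = list(reference.residues)
    seq[98] = "E"  # AGD -> AGE
    rec = o.ProteinRecord(id="mut", residues="".join(seq))
    aln = o.align_global(reference, rec)
    motifs = o.check_motifs(rec, aln, sites)
    assert motifs["C1-b2/3"]["match"] is False
    assert motifs["C2-b2/3"]["match"] is True


# ---------------------------------------------------------------------------
# survey
# ---------------------------------------------------------------------------

def test_survey_aggregates_recompute_from_rows(reference, sites):
    records, truth = synth.gen_sequences("clade_survey_panel", reference,
                                         seed=3)
    table = o.survey(records, reference, sites)
    assert len(table.rows) == len(records)
    for _, agg in table.aggregates.iterrows():
        sub = table.rows[table.rows["group"] == agg["group"]]
        assert agg["n"] == len(sub)
        assert agg["n_with_sac"] == int(sub["has_sac"].sum())
        assert 0.0 <= agg["fraction_with_sac"] <= 1.0
        if agg["genotype"]:
            n_label = int((sub["genotype"] == agg["genotype"]).sum())
            assert agg["n_genotype"] == n_label
            assert agg["fraction_genotype"] == pytest.approx(
                n_label / agg["n_with_sac"])


def test_survey_presence_fraction_from_curated_counts(reference, sites):
    # 11 of 13 cartilaginous-fish species possess the gene: 11 sequences
    # plus 2 curated absences
    records, _ = synth.gen_sequences(
        synth.FixturePreset("t", "sequences", {
            "groups": [{"group": "cartilaginous", "n": 11,
                        "genotype": "N/R"}],
            "sub_rate": 0.02, "indel_rate": 0.0}),
        reference, seed=4)
    absent = [("lamprey-like sp. 1", "cartilaginous"),
              ("lamprey-like sp. 2", "cartilaginous")]
    table = o.survey(records, reference, sites, absent_species=absent)
    agg = table.aggregates.iloc[0]
    assert agg["n"] == 13 and agg["n_with_sac"] == 11
    assert agg["fraction_with_sac"] == pytest.approx(11 / 13)


def test_survey_input_errors(reference, sites):
    rec = o.ProteinRecord(id="dup", residues="KAGDR")
    with pytest.raises(o.InputError):
        o.survey([rec, rec], reference, sites)
    with pytest.raises(o.InputError):
        o.survey([reference], reference, sites)
    empty = o.survey([], reference, sites)
    assert empty.rows.empty and empty.aggregates.empty


# ---------------------------------------------------------------------------
# tree annotation
# ---------------------------------------------------------------------------

def test_annotate_tree_roundtrip(reference, sites):
    records, _ = synth.gen_sequences("clade_survey_panel", reference, seed=6)
    table = o.survey(records[:3], reference, sites)
    names = list(table.rows["species"])
    newick = f"(('{names[0]}','{names[1]}'),'{names[2]}');"
    tree, unmatched = o.annotate_tree(newick, table)
    assert unmatched == []
    labels = {leaf.taxon.label: dict(
        (a.name, a.value) for a in leaf.annotations)
        for leaf in tree.leaf_node_iter()}
    assert all("genotype" in v for v in labels.values())
    # round trip preserves annotations
    out = tree.as_string(schema="newick", suppress_annotations=False)
    assert "genotype" in out

    tree2, unmatched2 = o.annotate_tree(
        f"(('{names[0]}','no such species'),'{names[2]}');", table)
    assert unmatched2 == ["no such species"]
    with pytest.raises(o.InputError):
        o.annotate_tree("(((", table)


def test_fasta_roundtrip(tmp_path, reference):
    path = tmp_path / "seqs.fasta"
    o.write_fasta([reference], path)
    back = o.read_fasta(path)
    assert back[0].residues == reference.residues
    assert back[0].group == reference.group
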