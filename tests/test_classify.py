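import numpy as np
import pytest

import termscape as ts
from termscape.classify import StructureError, _pair_table
from termscape.model import revcomp


# ---------------------------------------------------------------------------
# upstream windows


def test_upstream_rna_plus_strand(flat_genome):
    tep = ts.Tep("c1", 1000, "+")
    rna = ts.upstream_rna(flat_genome, tep, 40)
    expected = flat_genome.contigs["c1"][960:1000].replace("T", "U")
    assert rna == expected


def test_upstream_rna_minus_strand(flat_genome):
    tep = ts.Tep("c1", 1000, "-")
    rna = ts.upstream_rna(flat_genome, tep, 40)
    expected = revcomp(flat_genome.contigs["c1"][1001:1041]).replace("T", "U")
    assert rna == expected


def test_upstream_rna_clipped_returns_empty():
    genome = ts.Genome({"c": "ACGT" * 30})
    tep = ts.Tep("c", 5, "+")
    assert ts.upstream_rna(genome, tep, 40) == ""
    assert tep.flagged


# ---------------------------------------------------------------------------
# folding


def test_fold_unpaired_homopolymer():
    dg, structure = ts.fold_mfe("A" * 20, 30.0)
    assert dg == 0.0
    assert structure == "." * 20


def test_fold_simple_hairpin():
    dg, structure = ts.fold_mfe("GGGGGAAAACCCCC", 30.0)
    assert dg < 0
    assert "(" in structure and ")" in structure


def test_fold_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        ts.fold_mfe("ACGX")


# ---------------------------------------------------------------------------
# stem-loop parsing


def oracle_stem_loop(db):
    """Exhaustive helix enumeration: independent reference for the parser."""
    pairs = _pair_table(db)
    if not pairs:
        return None
    n = len(db)
    opening = sorted(i for i, j in pairs.items() if i < j)
    hairpins = [(i, pairs[i]) for i in opening
                if all(k not in pairs for k in range(i + 1, pairs[i]))]
    i, j = max(hairpins, key=lambda ij: ij[1])
    loop = j - i - 1
    chain = [(i, j)]
    while True:
        below = [k for k in opening if k < chain[-1][0]]
        if not below:
            break
        i2 = max(below)
        j2 = pairs[i2]
        ci, cj = chain[-1]
        if (j2 > cj and ci - i2 - 1 <= 1 and j2 - cj - 1 <= 1
                and all(k not in pairs for k in range(cj + 1, j2))):
            chain.append((i2, j2))
        else:
            break
    return len(chain), loop, max(j for _, j in chain) - n


def test_parse_stem_loop_examples():
    stem = ts.parse_stem_loop("((((....))))")
    assert (stem.stem_length, stem.loop_length, stem.stem_end_offset) == (4, 4, -1)
    assert ts.parse_stem_loop("............") is None
    inner = ts.parse_stem_loop("((..((....))..))")
    assert (inner.stem_length, inner.loop_length) == (2, 4)


def test_parse_stem_loop_unbalanced_raises():
    with pytest.raises(StructureError):
        ts.parse_stem_loop("(((...")
    with pytest.raises(StructureError):
        ts.parse_stem_loop("...)))")


def enumerate_structures(n, min_loop=3, _memo={}):
    """All valid dot-bracket strings of length n (hairpin loops >= min_loop)."""
    if n in _memo:
        return _memo[n]
    if n == 0:
        return [""]
    out = ["." + s for s in enumerate_structures(n - 1, min_loop)]
    for k in range(min_loop, n - 1):
        for inner in enumerate_structures(k, min_loop):
            for rest in enumerate_structures(n - 2 - k, min_loop):
                out.append("(" + inner + ")" + rest)
    _memo[n] = out
    return out


def test_parse_stem_loop_matches_enumeration_oracle():
    for n in range(1, 13):
        for db in enumerate_structures(n):
            ours = ts.parse_stem_loop(db)
            ref = oracle_stem_loop(db)
            if ref is None:
                assert ours is None, db
            else:
                got = (ours.stem_length, ours.loop_length, ours.stem_end_offset)
                assert got == ref, db


# ---------------------------------------------------------------------------
# U-tract counting and classification


def test_count_u_tract_examples():
    # layout: 20 nt padding, then an 8-nt tract, TEP right after it
    for tract, expected in [("TTTTTTTT", 8), ("GCGCGCGC", 0), ("TTGCCGCA", 2)]:
        seq = "A" * 20 + tract + "G" + "A" * 20
        genome = ts.Genome({"c": seq})
        tep = ts.Tep("c", 28, "+")  # tract occupies offsets -8..-1
        stem = ts.StemLoop(4, 4, -9, "")
        assert ts.count_u_tract(genome, tep, stem) == expected


def test_count_u_tract_minus_strand():
    # transcript U-tract on the minus strand is an A-tract on the reference
    seq = "A" * 20 + "AAAAAAAA" + "G" + "C" * 20
    genome = ts.Genome({"c": seq})
    tep = ts.Tep("c", 19, "-")  # transcript runs right-to-left
    stem = ts.StemLoop(4, 4, -9, "")
    assert ts.count_u_tract(genome, tep, stem) == 8


def test_count_u_tract_without_stem_uses_window_at_tep():
    seq = "G" * 20 + "TTTTTTTT" + "G" * 20
    genome = ts.Genome({"c": seq})
    tep = ts.Tep("c", 27, "+")  # last T of the tract
    assert ts.count_u_tract(genome, tep, None) == 8


@pytest.mark.parametrize("dg,u,expected", [
    (-32.0, 4, "HS-U-rich"),
    (-32.0, 2, "HS-U-lack"),
    (-15.0, 8, "LS"),
    (-23.0, 5, "LS"),   # boundary: structured means strictly below
    (-23.001, 3, "HS-U-rich"),
])
def test_classify_tep(dg, u, expected):
    assert ts.classify_tep(dg, u) == expected


def test_classify_partitions_pipeline_teps(pipeline_result):
    for tep in pipeline_result.teps:
        if tep.category == "Internal":
            continue
        assert tep.tep_class in ("HS-U-rich", "HS-U-lack", "LS")


# ---------------------------------------------------------------------------
# bimodal threshold


def test_bimodal_split_recovers_intersection():
    rng = np.random.default_rng(12)
    values = np.concatenate([rng.normal(-32, 3, 500), rng.normal(-15, 3, 500)])
    threshold = ts.bimodal_split(values, seed=0)
    assert abs(threshold - (-23.5)) <= 1.0


def test_bimodal_split_degenerate_cases():
    rng = np.random.default_rng(13)
    with pytest.raises(ValueError):
        ts.bimodal_split(rng.normal(-20, 2, 400), seed=0)  # unimodal
    with pytest.raises(ValueError):
        ts.bimodal_split([-20.0, -21.0], seed=0)  # too few values


def test_bimodal_split_separates_planted_classes():
    genome, genes, tss_set = ts.generate_genome(n_genes=80, gc=0.72, seed=14)
    genome, truth = ts.plant_terminators(genome, genes, tss_set,
                                         class_mix=(0.35, 0.25, 0.4), seed=14)
    records = []
    for planted in truth.teps:
        probe = ts.Tep(planted.contig, planted.position, planted.strand)
        dg, _ = ts.fold_mfe(ts.upstream_rna(genome, probe, 40), 30.0)
        records.append((dg, planted.tep_class))
    threshold = ts.bimodal_split([dg for dg, _ in records], seed=0)
    agree = np.mean([(dg < threshold) == (cls != "LS")
                     for dg, cls in records])
    assert agree >= 0.9


# ---------------------------------------------------------------------------
# enrichment statistics


def test_nucleotide_enrichment_null_case():
    rng = np.random.default_rng(21)
    genome = ts.Genome({"c": "".join(rng.choice(list("ACGT"), size=60000))})
    teps = [ts.Tep("c", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(100, 59900, size=1000)]
    profile = ts.nucleotide_enrichment(teps, genome, random_n=2000, seed=5)
    assert profile.shape == (101, 4)
    assert float(np.abs(profile.values - 1).max()) < 0.2

    again = ts.nucleotide_enrichment(teps, genome, random_n=2000, seed=5)
    np.testing.assert_array_equal(profile.values, again.values)  # seeded


def test_nucleotide_enrichment_fold_arithmetic():
    # one TEP set where an offset is always U against a known background
    genome = ts.Genome({"c": "ACGT" * 5000})
    teps = [ts.Tep("c", p, "+") for p in range(103, 19903, 400)]
    profile = ts.nucleotide_enrichment(teps, genome, random_n=500, seed=1)
    # the periodic genome has background 25% per base; offset 0 is always T
    assert profile.loc[0, "U"] == pytest.approx(1 / 0.25, rel=0.05)


def test_interaction_matrix_unstructured_and_single():
    genome = ts.Genome({"c": "A" * 400})
    teps = [ts.Tep("c", 300, "+")]
    mat = ts.interaction_matrix(teps, genome, window=100)
    assert mat.shape == (100, 100)
    assert mat.sum() == 0  # poly-A cannot pair

    stem = "GCGCGCGCGC"
    seq = "A" * 200 + stem + "AAAA" + revcomp(stem) + "A" * 200
    genome2 = ts.Genome({"c": seq})
    tep = ts.Tep("c", 250, "+")
    mat2 = ts.interaction_matrix([tep], genome2, window=100)
    np.testing.assert_array_equal(mat2, mat2.T)
    assert set(np.unique(mat2)) <= {0.0, 1.0}
    # every MFE pair of the window appears exactly once
    _, structure = ts.fold_mfe(ts.upstream_rna(genome2, tep, 100), 30.0)
    n_pairs = structure.count("(")
    assert mat2.sum() == 2 * n_pairs and n_pairs >= 8
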