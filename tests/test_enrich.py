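"""Enrichment analytics: fold enrichment, QC, concordance, families, hits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from delsub.decode import CountTable
from delsub.design import Gene, Molecule, build_design, enumerate_genes
from delsub.enrich import (
    _spearman,
    abundance_qc,
    approx_gene_abundance_from_codons,
    collapse_to_molecules,
    detect_families,
    dope_in_metrics,
    fold_enrichment,
    fold_enrichment_vectors,
    redundancy_concordance,
    select_hits,
    synthon_summary,
)


def _table(design, counts, sample="s"):
    genes = list(enumerate_genes(design))
    return CountTable.from_vector(genes[: len(counts)], counts, sample)


# -- fold enrichment ---------------------------------------------------------

def test_identical_tables_give_unit_enrichment(small_design):
    counts = list(range(1, 21))
    df = fold_enrichment(_table(small_design, counts), _table(small_design, counts),
                         small_design, alpha=1.0)
    assert np.allclose(df["E"], 1.0)


def test_fold_enrichment_matches_frequency_ratio_oracle(small_design, rng):
    """alpha=0 on strictly positive counts equals the plain frequency ratio."""
    sel = rng.integers(1, 200, size=30)
    ref = rng.integers(1, 200, size=30)
    df = fold_enrichment(_table(small_design, sel, "sel"), _table(small_design, ref, "ref"),
                         small_design, alpha=0.0)
    genes = list(enumerate_genes(small_design))[:30]
    oracle = {g: (s / sel.sum()) / (r / ref.sum()) for g, s, r in zip(genes, sel, ref)}
    for row in df.itertuples():
        g = Gene(row.lineage, (row.c1, row.c2, row.c3, row.c4))
        assert row.E == pytest.approx(oracle[g], rel=1e-12)


def test_fold_enrichment_hand_arithmetic(tiny_design):
    df = fold_enrichment(_table(tiny_design, [198, 2], "sel"),
                         _table(tiny_design, [100, 100], "ref"),
                         tiny_design, alpha=0.0)
    assert df["E"].tolist() == pytest.approx([1.98, 0.02])
    assert df["rank"].tolist() == [1, 2]


def test_fold_enrichment_empty_selected_errors(tiny_design):
    with pytest.raises(ValueError, match="empty"):
        fold_enrichment(CountTable("sel"), _table(tiny_design, [1]), tiny_design)


def test_fold_enrichment_vectors_matches_table_formula(tiny_design):
    sel, ref = np.array([50, 10, 0, 5]), np.array([10, 10, 10, 10])
    E = fold_enrichment_vectors(sel, ref, alpha=1.0, G=4)
    expected = ((sel + 1) / (65 + 4)) / ((ref + 1) / (40 + 4))
    assert np.allclose(E, expected)


# -- codon-marginal abundance approximation ----------------------------------

def test_marginal_abundance_product_formula():
    design = build_design({"n": [2, 2, 1, 1], "codon_seed": 3, "singly_encoded": True})
    genes = list(enumerate_genes(design))
    # marginals: cycle1 {0: 0.75, 1: 0.25}, cycle2 {0: 0.5, 1: 0.5}, T = 1000
    counts = {Molecule(0, 0, 0, 0): 300, Molecule(0, 1, 0, 0): 450,
              Molecule(1, 0, 0, 0): 200, Molecule(1, 1, 0, 0): 50}
    table = CountTable.from_vector(
        [Gene("A", tuple(m)) for m in counts], list(counts.values()), "ref"
    )
    ab = approx_gene_abundance_from_codons(table, design)
    assert ab[("A", 0, 0, 0, 0)] == pytest.approx(375.0)
    assert ab.sum() == pytest.approx(1000.0)
    assert len(ab) == len(genes)


def test_uniform_marginals_give_uniform_abundance(tiny_design):
    genes = list(enumerate_genes(tiny_design))
    table = CountTable.from_vector(genes, [10] * len(genes), "ref")
    ab = approx_gene_abundance_from_codons(table, tiny_design)
    assert np.allclose(ab, ab.iloc[0])


# -- abundance QC ------------------------------------------------------------

def test_abundance_qc_examples():
    qc = abundance_qc(np.ones(100))
    assert qc["within_10fold_fraction"] == 1.0 and qc["max_disparity"] == 1.0
    qc = abundance_qc([1.0, 10.0, 100.0])
    assert qc["max_disparity"] == pytest.approx(100.0)
    assert qc["within_10fold_fraction"] == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        abundance_qc([1.0, 0.0])


# -- molecule collapse -------------------------------------------------------

def _records_for(design, e_a, e_b):
    rows = []
    mols = [Molecule(*t) for t in
            itertools.islice(itertools.product(*[design.block_ids(c) for c in (1, 2, 3, 4)]),
                             len(e_a))]
    for lin, evals in (("A", e_a), ("B", e_b)):
        for m, e in zip(mols, evals):
            rows.append({"lineage": lin, "c1": m.b1, "c2": m.b2, "c3": m.b3, "c4": m.b4,
                         "count_sel": int(e * 10), "count_ref": 10, "E": e})
    return pd.DataFrame(rows)


def test_collapse_merge_rules(tiny_design):
    rec = _records_for(tiny_design, [4.0, 100.0], [4.0, 1.0])
    geo = collapse_to_molecules(rec, tiny_design, "mean_log").set_index(["c1", "c2", "c3", "c4"])
    assert geo.loc[(0, 0, 0, 0), "E_combined"] == pytest.approx(4.0)
    assert geo.loc[(0, 0, 0, 1), "E_combined"] == pytest.approx(10.0)  # geometric mean
    mx = collapse_to_molecules(rec, tiny_design, "max").set_index(["c1", "c2", "c3", "c4"])
    assert mx.loc[(0, 0, 0, 1), "E_combined"] == pytest.approx(100.0)


def test_collapse_sum_counts_pools_lineages(tiny_design):
    rec = _records_for(tiny_design, [3.0], [5.0])
    rec["count_sel"] = [3, 5]
    out = collapse_to_molecules(rec, tiny_design, "sum_counts")
    assert out["count_sel_total"].iloc[0] == 8


def test_collapse_rejects_unknown_lineage(tiny_design):
    rec = _records_for(tiny_design, [1.0], [1.0])
    rec.loc[0, "lineage"] = "C"
    with pytest.raises(ValueError):
        collapse_to_molecules(rec, tiny_design)


# -- redundancy concordance --------------------------------------------------

def test_concordance_identical_rankings():
    e = np.linspace(10, 1, 50)
    df = pd.DataFrame({"E_A": e, "E_B": e})
    out = redundancy_concordance(df, 10)
    assert out["n_in_both"] == 10
    assert out["topk_overlap_fraction"] == 1.0
    assert out["rank_correlation"] == pytest.approx(1.0)


def test_concordance_random_overlap_matches_hypergeometric(rng):
    """Independent rankings overlap at the chance level k/N on average."""
    N, k, reps = 400, 40, 300
    overlaps = []
    for _ in range(reps):
        df = pd.DataFrame({"E_A": rng.random(N), "E_B": rng.random(N)})
        overlaps.append(redundancy_concordance(df, k)["n_in_both"])
    # E[overlap] = k^2/N = 4; permutation-sampled mean should agree
    expected = k * k / N
    se = np.sqrt(np.var(overlaps) / reps)
    assert abs(np.mean(overlaps) - expected) < 4 * se + 0.2


def test_spearman_explicit_formula_matches_scipy(rng):
    for _ in range(10):
        x = rng.integers(0, 10, size=60).astype(float)  # heavy ties
        y = x * 0.5 + rng.normal(size=60)
        expected = stats.spearmanr(x, y).statistic
        assert _spearman(x, y) == pytest.approx(expected, abs=1e-12)


# -- synthon summaries and families ------------------------------------------

def test_synthon_summary_phenol_fraction(small_design):
    phenol_cap = sorted(small_design.phenol_cap_ids())[0]
    other = [b for b in small_design.block_ids(4) if b != phenol_cap][0]
    top = [Molecule(0, 0, 0, phenol_cap)] * 7 + [Molecule(0, 0, 0, other)] * 3
    syn = synthon_summary(top, small_design)
    assert syn["phenol_cap_fraction"] == pytest.approx(0.7)
    assert syn["composition"][4][phenol_cap] == pytest.approx(0.7)
    assert len(syn["cube_b1_b2_b4"]) == 10
    assert len(syn["cube_b1_b2_b3_phenol"]) == 7


def test_detect_families_line_example():
    mols = [Molecule(1, 2, 3, 0), Molecule(1, 2, 4, 0), Molecule(1, 2, 5, 0)]
    fams = detect_families(mols, min_size=3)
    assert len(fams) == 1
    assert fams[0].varying_cycle == 3 and fams[0].size == 3
    assert fams[0].fixed_blocks == ((1, 1), (2, 2), (4, 0))


def test_detect_families_none_when_unrelated():
    mols = [Molecule(1, 1, 1, 0), Molecule(2, 2, 2, 1), Molecule(3, 3, 3, 0)]
    assert detect_families(mols, min_size=2) == []


def _oracle_families(mols, min_size):
    """Quadratic brute force: group by pairwise agreement on 3 positions."""
    mols = sorted(set(mols))
    out = set()
    for varying in (1, 2, 3, 4):
        fixed_cycles = tuple(c for c in (1, 2, 3, 4) if c != varying)
        for m in mols:
            members = tuple(sorted(
                n for n in mols
                if all(n[c - 1] == m[c - 1] for c in fixed_cycles)
            ))
            if len(members) >= min_size:
                out.add((varying, members))
    return out


def test_detect_families_agrees_with_bruteforce(rng):
    mols = [Molecule(*rng.integers(0, 4, size=4)) for _ in range(500)]
    fams = {(f.varying_cycle, f.members) for f in detect_families(mols, min_size=3)}
    assert fams == _oracle_families(mols, 3)


# -- hit filter --------------------------------------------------------------

def test_select_hits_threshold_and_order_invariance(rng):
    df = pd.DataFrame({
        "c1": [0, 1, 2], "c2": [0, 0, 0], "c3": [0, 0, 0], "c4": [0, 0, 0],
        "E_combined": [5.0, 10.0, 50.0],
    })
    hits = select_hits(df, min_enrichment=10.0)
    assert hits["E_combined"].tolist() == [50.0, 10.0]  # boundary inclusive
    shuffled = df.sample(frac=1.0, random_state=2).reset_index(drop=True)
    assert select_hits(shuffled, 10.0).equals(hits)
    assert select_hits(df, min_enrichment=100.0).empty


def test_select_hits_family_intersection():
    df = pd.DataFrame({
        "c1": [1, 1, 1, 9], "c2": [2, 2, 2, 9], "c3": [3, 4, 5, 9], "c4": [0, 0, 0, 0],
        "E_combined": [20.0, 30.0, 40.0, 1000.0],
    })
    mols = [Molecule(int(r.c1), int(r.c2), int(r.c3), int(r.c4)) for r in df.itertuples()]
    fams = detect_families(mols, min_size=3)
    hits = select_hits(df, 10.0, require_family=True, families=fams)
    assert len(hits) == 3 and 9 not in hits["c1"].tolist()


# -- dope-in metrics ---------------------------------------------------------

def test_dope_in_metrics_implied_background():
    m = dope_in_metrics(enrichment=2600.0, input_copies=300_000,
                        recovered_copies=0.09 * 300_000)
    assert m.recovery == pytest.approx(0.09)
    assert m.implied_background == pytest.approx(3.46e-5, rel=0.01)
    m1 = dope_in_metrics(1.0, 1000, 42.0)
    assert m1.implied_background == pytest.approx(m1.recovery)
    with pytest.raises(ValueError):
        dope_in_metrics(2600.0, 0, 1.0)
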