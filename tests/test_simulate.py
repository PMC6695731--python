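"""Simulator calibration and mechanics: abundances, selection, reads, assays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delsub.decode import count_genes
from delsub.design import enumerate_genes
from delsub.simulate import (
    LIBRARY_DOSE,
    AbundanceCalibration,
    ActivityModel,
    QpcrCurve,
    SelectionParams,
    SelectionPool,
    assign_activities,
    capture_probability,
    emit_reads,
    generate_assay_data,
    generate_gene_abundances,
    phospho_probability,
    pool_from_design,
    simulate_qpcr_ct,
    simulate_selection,
    specificity_for_phospho_probability,
    spike_dope_in,
)
from delsub.kinetics import qpcr_quantify


# -- gene abundances ---------------------------------------------------------

@pytest.mark.parametrize("seed", [1, 2, 3])
def test_abundance_calibration_10fold_window(seed):
    """~95% of genes within a 10-fold window, disparity bounded at 100-fold."""
    ab = generate_gene_abundances(AbundanceCalibration(G=200_000, seed=seed))
    la = np.log10(ab)
    within = np.abs(la - np.median(la)) <= 0.5
    assert within.mean() == pytest.approx(0.95, abs=0.005)
    assert ab.max() / ab.min() <= 100.0


def test_abundance_degenerate_and_reproducible():
    cal = AbundanceCalibration(G=1000, sigma10=0.0, seed=4)
    assert np.allclose(generate_gene_abundances(cal), 1e-3)
    c1 = AbundanceCalibration(G=500, seed=11)
    assert np.array_equal(generate_gene_abundances(c1), generate_gene_abundances(c1))
    with pytest.raises(ValueError):
        AbundanceCalibration(G=0)


# -- activities --------------------------------------------------------------

def test_assign_activities_silent_and_saturated(small_design):
    x0 = assign_activities(small_design, ActivityModel(pi_active=0.0), seed=1)
    assert np.all(x0 == 0.0)
    model = ActivityModel(pi_active=1.0, x_mu10=0.0, x_sigma10=0.0)
    x1 = assign_activities(small_design, model, seed=1)
    mols = small_design.molecule_array()
    phenol = np.isin(mols[:, 3], sorted(small_design.phenol_cap_ids()))
    assert np.all(x1[phenol] == 1.0)
    assert np.all(x1[~phenol] == 0.0)


def test_assign_activities_binomial_rate():
    from delsub.design import build_design

    design = build_design({"n": [20, 20, 25, 4], "codon_seed": 2})  # 10,000 phenol mols
    x = assign_activities(design, ActivityModel(pi_active=0.05), seed=3)
    n_active = int((x > 0).sum())
    # Binomial(10000, 0.05): mean 500, sd ~22
    assert 400 <= n_active <= 600


# -- phosphorylation and capture ---------------------------------------------

def test_phospho_probability_closed_forms():
    assert phospho_probability(1.0, 0.0) == 0.0
    assert phospho_probability(1.0, LIBRARY_DOSE) == pytest.approx(1.0, abs=1e-12)
    # ~1% completion at library dose implies x ~ 2.18e-4 (weak substrate)
    x = specificity_for_phospho_probability(0.01, LIBRARY_DOSE)
    assert x == pytest.approx(2.18e-4, rel=0.01)
    assert phospho_probability(x, LIBRARY_DOSE) == pytest.approx(0.01, rel=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    x=st.floats(min_value=0, max_value=10),
    dose=st.floats(min_value=0, max_value=100),
    bump=st.floats(min_value=0, max_value=5),
)
def test_phospho_and_capture_monotone(x, dose, bump):
    params = SelectionParams()
    p1, p2 = phospho_probability(x, dose), phospho_probability(x + bump, dose)
    assert p2 >= p1
    assert phospho_probability(x, dose + bump) >= p1
    assert capture_probability(p2, params) >= capture_probability(p1, params)
    assert params.beta <= capture_probability(p1, params) <= params.p_ab


def test_capture_probability_dope_in_calibration():
    params = SelectionParams(p_ab=0.09, beta=0.09 / 2600)
    # fully phosphorylated dope-in is recovered at 9%
    assert capture_probability(1.0, params) == pytest.approx(0.09)
    assert capture_probability(0.0, params) == pytest.approx(params.beta)
    # enrichment of a full substrate over inert background is p_ab/beta
    assert capture_probability(1.0, params) / capture_probability(0.0, params) == (
        pytest.approx(2600.0)
    )


# -- selection sampling ------------------------------------------------------

def test_selection_conserves_depth_and_neutrality():
    pre = np.full(2000, 1000, dtype=np.int64)
    p_cap = np.full(2000, 0.05)
    reads = simulate_selection(pre, p_cap, depth=1_000_000, seed=0)
    assert reads.sum() == 1_000_000
    freq = reads / reads.sum()
    fold = freq / (pre / pre.sum())
    assert np.median(fold) == pytest.approx(1.0, abs=0.05)


def test_selection_strong_separation_read_ratio():
    pre = np.array([10**6, 10**6])
    reads = simulate_selection(pre, np.array([0.09, 9e-5]), depth=100_000, seed=1)
    ratio = reads[0] / reads[1]
    assert ratio == pytest.approx(1000.0, rel=0.25)


def test_selection_edge_cases():
    pre = np.array([100, 100])
    assert np.all(simulate_selection(pre, np.array([0.5, 0.5]), 0, seed=0) == 0)
    with pytest.raises(RuntimeError, match="extinguished"):
        simulate_selection(pre, np.array([0.0, 0.0]), 10, seed=0)


# -- dope-in spiking ---------------------------------------------------------

def test_spike_dope_in_fractions():
    pool = SelectionPool(ids=["ctrl"], pre_counts=np.array([500_000]), x=np.array([0.0]))
    pool = spike_dope_in(pool, "LYNtide", 1000, x=1.0)
    assert pool.fraction("LYNtide") == pytest.approx(1 / 501)

    big = SelectionPool(ids=["lib"], pre_counts=np.array([5_420_000_000 - 300_000]),
                        x=np.array([0.0]))
    big = spike_dope_in(big, "dope", 300_000)
    assert big.fraction("dope") == pytest.approx(5.5e-5, rel=0.01)


def test_spike_dope_in_bookkeeping(small_design):
    pool = pool_from_design(small_design, copies_per_member=100)
    total = pool.total_copies
    pool2 = spike_dope_in(pool, "empty", 0)
    assert pool2.total_copies == total and "empty" in pool2.dope_ins
    with pytest.raises(ValueError, match="duplicate"):
        spike_dope_in(pool2, "empty", 10)


# -- reads -------------------------------------------------------------------

def test_emit_reads_conservation_and_roundtrip(small_design):
    genes = list(enumerate_genes(small_design))
    rng = np.random.default_rng(7)
    post = rng.integers(0, 6, size=len(genes))
    records = list(emit_reads(post, small_design, 0.0, seed=1, genes=genes))
    assert len(records) == int(post.sum())
    table = count_genes(records, small_design, sample_id="sim")
    assert table.total_rejected == 0
    recovered = np.array([table.counts.get(g, 0) for g in genes])
    assert np.array_equal(recovered, post)


def test_emit_reads_error_rate_bounds(small_design):
    with pytest.raises(ValueError):
        list(emit_reads([1], small_design, 0.5, genes=[next(enumerate_genes(small_design))]))


# -- qPCR --------------------------------------------------------------------

def test_qpcr_ct_closed_form_and_roundtrip():
    curve = QpcrCurve(intercept=40.0)
    ct = simulate_qpcr_ct(1000, curve)
    assert ct == pytest.approx(30.034, abs=1e-3)
    assert simulate_qpcr_ct(2000, curve) - ct == pytest.approx(-1.0, abs=1e-9)
    assert qpcr_quantify(ct, curve) == pytest.approx(1000.0, rel=1e-9)
    with pytest.raises(ValueError):
        simulate_qpcr_ct(0, curve)


# -- assay data generation ---------------------------------------------------

def test_assay_curves_anchor_points():
    mm = generate_assay_data("michaelis_menten", {"kcat": 2.0, "E0": 0.5, "km": 18.0},
                             np.array([18.0]))
    assert mm["value"].iloc[0] == pytest.approx(2.0 * 0.5 / 2)

    lg = generate_assay_data("logistic4p", {"top": 100.0, "bottom": 0.0, "ic50": 8.1, "h": 1.3},
                             np.array([8.1]))
    assert lg["value"].iloc[0] == pytest.approx(50.0)

    fp = generate_assay_data("fp_binding", {"r_f": 0.1, "r_b": 0.3, "kd": 7.5},
                             np.array([7.5]))
    assert fp["value"].iloc[0] == pytest.approx(0.2)

    # Beer-Lambert: a total drop of 0.622 at eps=6220, l=1 is 100 uM ADP
    nd = generate_assay_data("nadh_progress", {"rate_uM_s": 1.0, "a0": 0.9},
                             np.array([0.0, 100.0]))
    assert nd["value"].iloc[0] - nd["value"].iloc[1] == pytest.approx(0.622)

    with pytest.raises(ValueError, match="unknown assay model"):
        generate_assay_data("sigmoid", {}, np.array([1.0]))
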