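"""Forward simulation of the substrate-mediated selection.

The generative model: every gene of the library enters the selection at
an abundance drawn from a truncated log-normal calibrated so that ~95%
of genes fall within a 10-fold window and the max/min disparity is
bounded at 100-fold.  Each molecule carries a latent relative
specificity x (kcat/Km normalised to the LYNtide reference peptide = 1);
phenol-capped members are substrates with probability pi_active.  Kinase
exposure phosphorylates a member with probability 1 - exp(-x * dose),
where dose is a dimensionless enzyme-exposure (kappa*[E]*t) scaled so
that x = 1 reaches "full" (99%) phosphorylation at one tenth of the
library dose.  An anti-phosphotyrosine antibody pull-down captures
phosphorylated members with probability p_ab and unphosphorylated ones
at a nonspecific background beta; sequencing is multinomial sampling of
the captured pool at fixed depth.

Also provided: dope-in spiking at defined copy numbers, FASTQ read
emission with substitution errors, qPCR Ct simulation, and noiseless or
noisy assay curves (Michaelis-Menten, 4-parameter logistic, FP binding,
NADH progress) for the kinetics fitters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .design import BASES, Gene, LibraryDesign, assemble_gene_sequence, enumerate_genes

#: Dimensionless exposure at which a LYNtide-like substrate (x = 1) is 99%
#: phosphorylated ("full phosphorylation").
FULL_PHOSPHO_DOSE = float(np.log(100.0))
#: Library selection used ~10x the full-phosphorylation exposure.
LIBRARY_DOSE = 10.0 * FULL_PHOSPHO_DOSE
#: Capture probability of a fully phosphorylated member (dope-in recovery).
DEFAULT_P_AB = 0.09
#: Nonspecific background capture, back-solved from recovery/enrichment.
DEFAULT_BETA = 0.09 / 2600.0


# ---------------------------------------------------------------------------
# Abundances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceCalibration:
    """Truncated log10-normal gene-abundance model.

    sigma10 defaults to 0.5/1.96 so the central 95% interval spans one
    log10 unit (a 10-fold window); trunc10 = 1.0 bounds the max/min
    disparity at 100-fold.
    """

    G: int
    sigma10: float = 0.5 / 1.959963984540054
    trunc10: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("G must be positive")
        if self.sigma10 < 0:
            raise ValueError("sigma10 must be non-negative")
        if self.sigma10 > 0 and self.trunc10 < self.sigma10:
            raise ValueError("trunc10 must be >= sigma10")


def generate_gene_abundances(cal: AbundanceCalibration) -> np.ndarray:
    """Relative gene frequencies (sum 1) under the truncated log-normal."""
    if cal.sigma10 == 0:
        return np.full(cal.G, 1.0 / cal.G)
    a = -cal.trunc10 / cal.sigma10
    b = cal.trunc10 / cal.sigma10
    rng = np.random.default_rng(cal.seed)
    log10_ab = stats.truncnorm.rvs(a, b, scale=cal.sigma10, size=cal.G, random_state=rng)
    ab = np.power(10.0, log10_ab)
    return ab / ab.sum()


# ---------------------------------------------------------------------------
# Activities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityModel:
    """Latent substrate-activity model over library members.

    pi_active: probability that a phenol-capped member is a substrate at
    all.  Active members draw a relative specificity x from a log-normal
    in log10 space (median 10**x_mu10, spread x_sigma10); everything
    else has x = 0.  The defaults place typical hits one to three orders
    of magnitude below the optimised reference peptide, which is where
    the selected library hits sit.
    """

    pi_active: float = 0.02
    x_mu10: float = -2.0
    x_sigma10: float = 0.5
    nonphenol_active_rate: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.pi_active, self.nonphenol_active_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("activity probabilities must be in [0, 1]")
        if self.x_sigma10 < 0:
            raise ValueError("x_sigma10 must be non-negative")


def assign_activities(design: LibraryDesign, model: ActivityModel, seed: int) -> np.ndarray:
    """Per-molecule relative specificity x, in molecule enumeration order."""
    rng = np.random.default_rng(seed)
    mols = design.molecule_array()
    phenol_caps = np.array(sorted(design.phenol_cap_ids()), dtype=mols.dtype)
    is_phenol = np.isin(mols[:, 3], phenol_caps)
    p_active = np.where(is_phenol, model.pi_active, model.nonphenol_active_rate)
    active = rng.random(len(mols)) < p_active
    x = np.zeros(len(mols))
    n_active = int(active.sum())
    if n_active:
        draws = rng.normal(model.x_mu10, model.x_sigma10, size=n_active)
        x[active] = np.power(10.0, draws)
    return x


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionParams:
    """Mechanistic parameters of the two-step selection."""

    dose: float = LIBRARY_DOSE
    p_ab: float = DEFAULT_P_AB
    beta: float = DEFAULT_BETA
    depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ab <= 1.0:
            raise ValueError("p_ab must be in [0, 1]")
        if not 0.0 <= self.beta <= self.p_ab:
            raise ValueError("beta must satisfy 0 <= beta <= p_ab")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


def phospho_probability(x, dose):
    """P(phosphorylated) = 1 - exp(-x * dose); monotone in both arguments."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("relative specificity x must be non-negative")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    out = -np.expm1(-x * dose)
    return float(out) if out.ndim == 0 else out


def specificity_for_phospho_probability(p: float, dose: float) -> float:
    """Invert phospho_probability: the x implied by an observed completion p."""
    if not 0.0 <= p < 1.0:
        raise ValueError("p must be in [0, 1)")
    return float(-np.log1p(-p) / dose)


def capture_probability(p_phos, params: SelectionParams):
    """p_cap = p_ab * p_phos + beta * (1 - p_phos); lies in [beta, p_ab]."""
    p_phos = np.asarray(p_phos, dtype=float)
    if np.any((p_phos < 0) | (p_phos > 1)):
        raise ValueError("p_phos must be in [0, 1]")
    out = params.p_ab * p_phos + params.beta * (1.0 - p_phos)
    return float(out) if out.ndim == 0 else out


def simulate_selection(
    pre_counts: np.ndarray, p_cap: np.ndarray, depth: int, seed: int
) -> np.ndarray:
    """Binomial capture of each member, then multinomial sequencing at depth.

    Returns a read-count vector summing exactly to depth.  Raises if the
    captured pool is empty ("selection extinguished").
    """
    pre = np.asarray(pre_counts)
    p = np.asarray(p_cap, dtype=float)
    if pre.shape != p.shape:
        raise ValueError("pre_counts and p_cap must have equal length")
    if np.any(pre < 0) or np.any((p < 0) | (p > 1)):
        raise ValueError("invalid counts or capture probabilities")
    rng = np.random.default_rng(seed)
    captured = rng.binomial(pre.astype(np.int64), p)
    total = int(captured.sum())
    if depth == 0:
        return np.zeros_like(captured)
    if total == 0:
        raise RuntimeError("selection extinguished: no members captured")
    return rng.multinomial(depth, captured / total)


@dataclass
class SelectionPool:
    """Pre-selection state: member ids, input copies, relative specificities.

    Library members are Gene ids; dope-ins are tracked by string id with
    their own activity channel.
    """

    ids: list
    pre_counts: np.ndarray
    x: np.ndarray
    dope_ins: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre_counts = np.asarray(self.pre_counts, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        if not (len(self.ids) == len(self.pre_counts) == len(self.x)):
            raise ValueError("pool arrays must have equal length")

    @property
    def total_copies(self) -> int:
        return int(self.pre_counts.sum())

    def fraction(self, construct_id: str) -> float:
        return float(self.pre_counts[self.dope_ins[construct_id]]) / self.total_copies


def pool_from_design(
    design: LibraryDesign,
    copies_per_member: float | None = None,
    abundances: np.ndarray | None = None,
    total_copies: float | None = None,
    x_by_molecule: np.ndarray | None = None,
) -> SelectionPool:
    """Assemble the pre-selection pool over all genes of a design.

    Either a flat copies_per_member or an abundance vector (relative
    gene frequencies, paired with total_copies) sets the input counts.
    Per-molecule activities are expanded to both redundant genes.
    """
    ids = list(enumerate_genes(design))
    G = len(ids)
    if abundances is not None:
        if total_copies is None:
            raise ValueError("total_copies is required with an abundance vector")
        if len(abundances) != G:
            raise ValueError(f"abundance vector length {len(abundances)} != {G} genes")
        pre = np.rint(np.asarray(abundances) / np.sum(abundances) * total_copies).astype(np.int64)
    elif copies_per_member is not None:
        pre = np.full(G, int(round(copies_per_member)), dtype=np.int64)
    else:
        raise ValueError("provide copies_per_member or abundances")
    if x_by_molecule is None:
        x = np.zeros(G)
    else:
        if len(x_by_molecule) != design.n_molecules:
            raise ValueError("x_by_molecule must have one entry per molecule")
        x = np.tile(np.asarray(x_by_molecule, dtype=float), len(design.lineages))
    return SelectionPool(ids=ids, pre_counts=pre, x=x)


def spike_dope_in(pool: SelectionPool, construct_id: str, copies: float, x: float = 1.0
                  ) -> SelectionPool:
    """Add a tracked spike-in construct (e.g. a LYNtide conjugate) to the pool."""
    if construct_id in pool.dope_ins:
        raise ValueError(f"duplicate dope-in id {construct_id!r}")
    if copies < 0:
        raise ValueError("copies must be non-negative")
    new = SelectionPool(
        ids=pool.ids + [construct_id],
        pre_counts=np.append(pool.pre_counts, np.int64(round(copies))),
        x=np.append(pool.x, float(x)),
        dope_ins=dict(pool.dope_ins),
    )
    new.dope_ins[construct_id] = len(new.ids) - 1
    return new


def select_pool(pool: SelectionPool, params: SelectionParams) -> dict:
    """Run the full two-step selection on a pool.

    Returns a dict with p_phos, p_cap, post read counts, and the
    expected captured copies per member (used for recovery metrics).
    """
    p_phos = phospho_probability(pool.x, params.dose)
    p_cap = capture_probability(p_phos, params)
    rng_seed = params.seed
    post = simulate_selection(pool.pre_counts, p_cap, params.depth, rng_seed)
    return {
        "p_phos": p_phos,
        "p_cap": p_cap,
        "post_counts": post,
        "expected_captured": pool.pre_counts * p_cap,
    }


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = base_bytes[base_bytes != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def emit_reads(
    post_counts: Iterable[int],
    design: LibraryDesign,
    per_base_error_rate: float = 0.0,
    seed: int = 0,
    genes: list[Gene] | None = None,
    quality: int = 30,
) -> Iterator[SeqRecord]:
    """Yield FASTQ records for a post-selection count vector.

    One record per read; sequences are the assembled gene 180-mers with
    i.i.d. substitution errors; qualities are a constant placeholder.
    """
    if not 0.0 <= per_base_error_rate <= 0.2:
        raise ValueError("per_base_error_rate must be in [0, 0.2]")
    if genes is None:
        genes = list(enumerate_genes(design))
    counts = list(post_counts)
    if len(counts) != len(genes):
        raise ValueError("post_counts and genes must have equal length")
    rng = np.random.default_rng(seed)
    read_i = 0
    for gene, count in zip(genes, counts):
        if count <= 0:
            continue
        base = assemble_gene_sequence(gene, design)
        for _ in range(int(count)):
            seq = _mutate(base, rng, per_base_error_rate)
            rec = SeqRecord(Seq(seq), id=f"read_{read_i}", description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            read_i += 1
            yield rec


def write_fastq(records: Iterable[SeqRecord], path) -> int:
    with open(path, "w") as fh:
        return seqio_write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrCurve:
    """Standard-curve parameters: Ct = intercept + slope * log10(copies)."""

    slope: float = -3.321928094887362  # -log2(10): 100% amplification efficiency
    intercept: float = 40.0
    ct_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("qPCR slope must be negative")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be non-negative")


def simulate_qpcr_ct(copies: float, curve: QpcrCurve, seed: int | None = None) -> float:
    if copies <= 0:
        raise ValueError("copies must be positive")
    ct = curve.intercept + curve.slope * np.log10(copies)
    if curve.ct_noise_sd > 0:
        ct += np.random.default_rng(seed).normal(0.0, curve.ct_noise_sd)
    return float(ct)


# ---------------------------------------------------------------------------
# Assay curves
# ---------------------------------------------------------------------------

ASSAY_MODELS = ("michaelis_menten", "logistic4p", "fp_binding", "nadh_progress")


def generate_assay_data(
    model: str,
    params: dict,
    design_points: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic assay tables for the kinetics fitters.

    michaelis_menten: v = kcat*E0*S/(Km+S)     (columns conc_uM, rate)
    logistic4p:       y = bottom+(top-bottom)/(1+(I/IC50)^h)
    fp_binding:       r = r_f+(r_b-r_f)*P/(P+Kd)
    nadh_progress:    A340(t) = A0 - eps*l*ADP(t), ADP made at a constant
                      rate (columns time_s, a340)
    Gaussian noise with sd noise_sd is added to the response.
    """
    pts = np.asarray(design_points, dtype=float)
    if np.any(pts < 0):
        raise ValueError("design points must be non-negative")
    rng = np.random.default_rng(seed)
    if model == "michaelis_menten":
        vmax = params.get("vmax", params.get("kcat", 1.0) * params.get("E0", 1.0))
        y = vmax * pts / (params["km"] + pts)
        df = pd.DataFrame({"conc_uM": pts, "value": y})
    elif model == "logistic4p":
        top, bottom = params["top"], params["bottom"]
        y = bottom + (top - bottom) / (1.0 + np.power(pts / params["ic50"], params.get("h", 1.0)))
        df = pd.DataFrame({"conc_uM": pts, "value": y})
    elif model == "fp_binding":
        rf, rb = params["r_f"], params["r_b"]
        y = rf + (rb - rf) * pts / (pts + params["kd"])
        df = pd.DataFrame({"conc_uM": pts, "value": y})
    elif model == "nadh_progress":
        eps = params.get("epsilon", 6220.0)  # M^-1 cm^-1 at 340 nm
        ell = params.get("pathlength", 1.0)
        rate = params["rate_uM_s"]
        a0 = params.get("a0", 1.0)
        adp_uM = rate * pts
        y = a0 - eps * ell * adp_uM * 1e-6
        df = pd.DataFrame({"time_s": pts, "value": y})
    else:
        raise ValueError(f"unknown assay model {model!r}; expected one of {ASSAY_MODELS}")
    if noise_sd > 0:
        df["value"] = df["value"] + rng.normal(0.0, noise_sd, size=len(df))
    return df
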