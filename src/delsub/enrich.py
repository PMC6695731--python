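"""Enrichment analytics for substrate-mediated DEL selections.

Fold enrichment per gene against the unselected reference, abundance
quality control, collapse of the two redundant genes per molecule,
redundancy-concordance/undersampling diagnostics, synthon-space
composition and family ("line") detection, dope-in calibration metrics,
and the >= 10-fold hit filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import CountTable
from .design import Gene, LibraryDesign, Molecule

GENE_COLS = ["lineage", "c1", "c2", "c3", "c4"]


# ---------------------------------------------------------------------------
# Fold enrichment
# ---------------------------------------------------------------------------

def _counts_series(table: CountTable) -> pd.Series:
    idx = pd.MultiIndex.from_tuples(
        [(g.lineage, *g.codons) for g in table.counts], names=GENE_COLS
    )
    return pd.Series(list(table.counts.values()), index=idx, dtype=np.int64)


def _all_gene_index(design: LibraryDesign) -> pd.MultiIndex:
    tuples = [
        (lin, *ids)
        for lin in design.lineages
        for ids in itertools.product(*(design.block_ids(c) for c in (1, 2, 3, 4)))
    ]
    return pd.MultiIndex.from_tuples(tuples, names=GENE_COLS)


def fold_enrichment(
    sel: CountTable,
    ref: CountTable,
    design: LibraryDesign,
    alpha: float = 1.0,
    mode: str = "observed_ref",
    complete: bool = False,
) -> pd.DataFrame:
    """Per-gene fold enrichment of selected vs reference frequencies.

    E_i = [(c_sel,i + alpha) / (T_sel + alpha*G)] /
          [(c_ref,i + alpha) / (T_ref + alpha*G)]

    with G the number of genes in the design (plus any extra ids present
    in the tables).  mode="marginal_ref" replaces observed reference
    counts with the codon-marginal abundance approximation, which
    assigns an expected count to genes unobserved in the reference.
    With complete=True the table covers every design gene, not just the
    observed union.  Rows are ranked descending by (E, count_sel, gene
    id) — a documented, stable tie-break.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if not sel.counts:
        raise ValueError("selected count table is empty")
    if mode not in ("observed_ref", "marginal_ref"):
        raise ValueError(f"unknown mode {mode!r}")

    s_sel = _counts_series(sel)
    s_ref = _counts_series(ref)
    if complete:
        index = _all_gene_index(design)
        index = index.union(s_sel.index.union(s_ref.index), sort=False)
    else:
        index = s_sel.index.union(s_ref.index, sort=False)
    c_sel = s_sel.reindex(index, fill_value=0)
    T_sel = int(s_sel.sum())
    T_ref = int(s_ref.sum())
    if mode == "marginal_ref":
        marg = codon_marginals(ref)
        c_ref = _marginal_expected_counts(index, marg, T_ref)
    else:
        c_ref = s_ref.reindex(index, fill_value=0).astype(float)
    extra = index.difference(_all_gene_index(design), sort=False)
    G = design.n_genes + len(extra)

    freq_sel = (c_sel + alpha) / (T_sel + alpha * G)
    freq_ref = (c_ref + alpha) / (T_ref + alpha * G)
    E = freq_sel / freq_ref

    df = pd.DataFrame(
        {
            "count_sel": c_sel.astype(np.int64),
            "count_ref": c_ref,
            "freq_sel": c_sel / T_sel if T_sel else 0.0,
            "freq_ref": c_ref / T_ref if T_ref else 0.0,
            "E": E,
        },
        index=index,
    ).reset_index()
    df = df.sort_values(
        by=["E", "count_sel", *GENE_COLS],
        ascending=[False, False, True, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs.update(
        alpha=alpha, T_sel=T_sel, T_ref=T_ref, G=G, mode=mode,
        sample_sel=sel.sample_id, sample_ref=ref.sample_id,
    )
    return df


def fold_enrichment_vectors(count_sel, count_ref, alpha: float = 1.0,
                            G: int | None = None) -> np.ndarray:
    """Vectorised pseudocounted fold enrichment over aligned count arrays.

    Same formula as fold_enrichment, for member-aligned vectors (e.g.
    molecule-level analyses at full library scale where building a
    per-gene table is unnecessary).  G defaults to the vector length.
    """
    cs = np.asarray(count_sel, dtype=float)
    cr = np.asarray(count_ref, dtype=float)
    if cs.shape != cr.shape:
        raise ValueError("count vectors must be aligned")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if G is None:
        G = cs.size
    fs = (cs + alpha) / (cs.sum() + alpha * G)
    fr = (cr + alpha) / (cr.sum() + alpha * G)
    return fs / fr


def top_k_indices(E: np.ndarray, count_sel: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest enrichments under the documented tie-break
    (E desc, selected count desc, member index asc)."""
    order = np.lexsort((np.arange(E.size), -np.asarray(count_sel), -np.asarray(E)))
    return order[:k]


def record_gene(row) -> Gene:
    return Gene(row.lineage, (int(row.c1), int(row.c2), int(row.c3), int(row.c4)))


# ---------------------------------------------------------------------------
# Codon-marginal abundance approximation
# ---------------------------------------------------------------------------

def codon_marginals(table: CountTable) -> dict[int, pd.Series]:
    """Marginal codon frequencies per cycle from an observed count table.

    Cycles 1-3 marginals are over (lineage, codon id); cycle 4 over the
    shared codon id alone.
    """
    if not table.counts:
        raise ValueError("count table is empty")
    df = _counts_series(table).reset_index(name="count")
    out: dict[int, pd.Series] = {}
    total = df["count"].sum()
    for cycle in (1, 2, 3):
        g = df.groupby(["lineage", f"c{cycle}"])["count"].sum() / total
        out[cycle] = g
    out[4] = df.groupby("c4")["count"].sum() / total
    return out


def _marginal_expected_counts(index: pd.MultiIndex, marg: dict[int, pd.Series],
                              total: float) -> pd.Series:
    frame = index.to_frame(index=False)
    f = np.ones(len(frame))
    for cycle in (1, 2, 3):
        keys = pd.MultiIndex.from_frame(frame[["lineage", f"c{cycle}"]])
        f *= marg[cycle].reindex(keys, fill_value=0.0).to_numpy()
    f *= marg[4].reindex(frame["c4"], fill_value=0.0).to_numpy()
    return pd.Series(total * f, index=index)


def approx_gene_abundance_from_codons(ref: CountTable, design: LibraryDesign) -> pd.Series:
    """Expected abundance of every design gene from per-cycle codon marginals.

    abundance(gene) = T * prod_cycles f_cycle(codon); sums to T over all
    genes that are combinations of observed codons.
    """
    marg = codon_marginals(ref)
    index = _all_gene_index(design)
    return _marginal_expected_counts(index, marg, float(_counts_series(ref).sum()))


def abundance_qc(abundances, window_log10: float = 0.5) -> dict:
    """Spread diagnostics of a positive abundance vector.

    within_10fold_fraction: share of values within +/- window_log10
    (default 0.5, i.e. a 10-fold window) of the median in log10 space.
    max_disparity: max/min ratio.  histogram: (counts, log10 bin edges).
    """
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or np.any(a <= 0):
        raise ValueError("abundances must be positive and non-empty")
    la = np.log10(a)
    center = np.median(la)
    within = np.abs(la - center) <= window_log10
    counts, edges = np.histogram(la - center, bins=40)
    return {
        "within_10fold_fraction": float(within.mean()),
        "max_disparity": float(a.max() / a.min()),
        "histogram": (counts, edges),
    }


# ---------------------------------------------------------------------------
# Molecule collapse and redundancy concordance
# ---------------------------------------------------------------------------

MERGE_RULES = ("mean_log", "max", "sum_counts")


def collapse_to_molecules(records: pd.DataFrame, design: LibraryDesign,
                          merge_rule: str = "mean_log") -> pd.DataFrame:
    """Merge the two redundant genes of each molecule into one summary row.

    merge_rule "mean_log" (default) is the geometric mean of the two
    per-lineage enrichments — symmetric, and it penalises spikes seen in
    only one lineage, which is exactly the redundancy-as-noise-filter
    use.  "max" takes the better lineage; "sum_counts" pools raw counts
    and recomputes E from the stored totals.
    A gene absent from the record table gets the pseudocount floor
    enrichment implied by the table's alpha/T/G attributes.
    """
    if merge_rule not in MERGE_RULES:
        raise ValueError(f"unknown merge rule {merge_rule!r}")
    if set(records["lineage"]) - set(design.lineages):
        raise ValueError("records contain lineages unknown to the design")
    alpha, T_sel, T_ref, G = (records.attrs.get(k) for k in ("alpha", "T_sel", "T_ref", "G"))
    floor_E = None
    if alpha is not None and alpha > 0:
        floor_E = ((0 + alpha) / (T_sel + alpha * G)) / ((0 + alpha) / (T_ref + alpha * G))

    lib = records[records["lineage"].isin(design.lineages)]
    pivot_E = lib.pivot_table(index=["c1", "c2", "c3", "c4"], columns="lineage",
                              values="E", aggfunc="first")
    pivot_cs = lib.pivot_table(index=["c1", "c2", "c3", "c4"], columns="lineage",
                               values="count_sel", aggfunc="first")
    pivot_cr = lib.pivot_table(index=["c1", "c2", "c3", "c4"], columns="lineage",
                               values="count_ref", aggfunc="first")
    for lin in design.lineages:
        if lin not in pivot_E:
            pivot_E[lin] = np.nan
    if floor_E is not None:
        pivot_E = pivot_E.fillna(floor_E)
    pivot_cs = pivot_cs.reindex(columns=list(design.lineages)).fillna(0)
    pivot_cr = pivot_cr.reindex(columns=list(design.lineages)).fillna(0)

    out = pd.DataFrame(index=pivot_E.index)
    if len(design.lineages) == 2:
        out["E_A"], out["E_B"] = pivot_E["A"], pivot_E["B"]
        out["count_sel_A"] = pivot_cs["A"].astype(np.int64)
        out["count_sel_B"] = pivot_cs["B"].astype(np.int64)
    else:
        out["E_A"] = pivot_E["A"]
        out["E_B"] = np.nan
        out["count_sel_A"] = pivot_cs["A"].astype(np.int64)
    if merge_rule == "mean_log":
        if len(design.lineages) == 2:
            out["E_combined"] = np.sqrt(out["E_A"] * out["E_B"])
        else:
            out["E_combined"] = out["E_A"]
    elif merge_rule == "max":
        out["E_combined"] = np.nanmax(pivot_E.to_numpy(), axis=1)
    else:  # sum_counts
        cs = pivot_cs.sum(axis=1)
        cr = pivot_cr.sum(axis=1)
        a = alpha if alpha is not None else 0.0
        fs = (cs + a) / ((T_sel or cs.sum()) + a * (G or len(cs)))
        fr = (cr + a) / ((T_ref or cr.sum()) + a * (G or len(cr)))
        out["E_combined"] = fs / fr
        out["count_sel_total"] = cs
        out["count_ref_total"] = cr
    out = out.reset_index()
    out.attrs.update(records.attrs)
    out.attrs["merge_rule"] = merge_rule
    return out


def redundancy_concordance(summaries: pd.DataFrame, k: int) -> dict:
    """Do the two redundant encodings agree on the top hits?

    n_in_both: molecules in both per-lineage top-k sets;
    topk_overlap_fraction = n_in_both / k; rank_correlation: Spearman
    rho over per-lineage enrichments, computed by the explicit
    average-rank Pearson formula.  Under heavy undersampling the overlap
    collapses toward the chance level k/N.

    Only molecules with selected-read evidence in a lineage are eligible
    for that lineage's top-k (columns count_sel_A/count_sel_B when
    present; otherwise members tied at the lineage-wide floor enrichment
    are excluded): a tie of no-evidence members carries no ranking
    information, and breaking it deterministically would fabricate
    concordance.  A lineage can therefore contribute fewer than k
    eligible molecules.
    """
    if k > len(summaries):
        raise ValueError("k exceeds the number of molecules")

    def topk(col: str, count_col: str) -> set[int]:
        e = summaries[col].to_numpy(dtype=float)
        order = np.argsort(-e, kind="mergesort")
        if count_col in summaries.columns:
            counts = summaries[count_col].to_numpy()
            eligible = order[counts[order] > 0]
        else:
            floor = e.min()
            eligible = order[e[order] > floor] if (e == floor).sum() > 1 else order
        return set(eligible[:k].tolist())

    ea = summaries["E_A"].to_numpy(dtype=float)
    eb = summaries["E_B"].to_numpy(dtype=float)
    n_in_both = len(topk("E_A", "count_sel_A") & topk("E_B", "count_sel_B"))
    rho = _spearman(ea, eb)
    return {
        "k": int(k),
        "n_in_both": int(n_in_both),
        "topk_overlap_fraction": n_in_both / k,
        "rank_correlation": rho,
    }


def _average_ranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average ranks (tie-safe)."""
    rx, ry = _average_ranks(x), _average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


# ---------------------------------------------------------------------------
# Synthon space, families, hits
# ---------------------------------------------------------------------------

def synthon_summary(top: list[Molecule], design: LibraryDesign) -> dict:
    """Building-block composition of a hit list plus 3-D cube coordinates.

    Returns per-cycle composition fractions, the phenol-cap fraction,
    and two coordinate tables matching the two plotting conventions:
    (b1, b2, b4) over all molecules and (b1, b2, b3) restricted to the
    phenol-capped subset.
    """
    if not top:
        raise ValueError("empty molecule list")
    arr = np.array([tuple(m) for m in top])
    composition = {}
    for cycle in (1, 2, 3, 4):
        ids, counts = np.unique(arr[:, cycle - 1], return_counts=True)
        composition[cycle] = {int(i): float(c) / len(arr) for i, c in zip(ids, counts)}
    phenol = design.phenol_cap_ids()
    phenol_frac = float(np.isin(arr[:, 3], sorted(phenol)).mean()) if phenol else 0.0
    cube_124 = pd.DataFrame(arr[:, [0, 1, 3]], columns=["b1", "b2", "b4"])
    mask = np.isin(arr[:, 3], sorted(phenol)) if phenol else np.zeros(len(arr), bool)
    cube_123 = pd.DataFrame(arr[mask][:, [0, 1, 2]], columns=["b1", "b2", "b3"])
    return {
        "composition": composition,
        "phenol_cap_fraction": phenol_frac,
        "cube_b1_b2_b4": cube_124,
        "cube_b1_b2_b3_phenol": cube_123,
    }


@dataclass(frozen=True)
class Family:
    """Molecules identical at three positions, varying at one cycle ("a line")."""

    varying_cycle: int
    fixed_blocks: tuple[tuple[int, int], ...]  # ((cycle, block_id), ...)
    members: tuple[Molecule, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def detect_families(top: list[Molecule], min_size: int = 3) -> list[Family]:
    """Maximal single-cycle-varying families within a molecule list.

    A family is the set of list members sharing the other three
    positions; a molecule can belong to up to four families (one per
    varying cycle).  Output ordering is deterministic: by varying cycle
    then fixed-position key.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    mols = sorted(set(top))
    families: list[Family] = []
    for varying in (1, 2, 3, 4):
        fixed_cycles = [c for c in (1, 2, 3, 4) if c != varying]
        groups: dict[tuple, list[Molecule]] = {}
        for m in mols:
            key = tuple(m[c - 1] for c in fixed_cycles)
            groups.setdefault(key, []).append(m)
        for key in sorted(groups):
            members = groups[key]
            if len(members) >= min_size:
                families.append(
                    Family(
                        varying_cycle=varying,
                        fixed_blocks=tuple(zip(fixed_cycles, key)),
                        members=tuple(sorted(members)),
                    )
                )
    return families


def select_hits(summaries: pd.DataFrame, min_enrichment: float = 10.0,
                require_family: bool = False,
                families: list[Family] | None = None) -> pd.DataFrame:
    """Molecules with combined enrichment >= threshold (boundary inclusive),
    optionally intersected with family membership; sorted by E descending
    with a stable synthon-id tie-break (order-invariant to input)."""
    if min_enrichment <= 0:
        raise ValueError("min_enrichment must be positive")
    df = summaries[summaries["E_combined"] >= min_enrichment].copy()
    if require_family:
        if families is None:
            raise ValueError("require_family=True needs a family list")
        in_family = {m for fam in families for m in fam.members}
        keys = [Molecule(int(r.c1), int(r.c2), int(r.c3), int(r.c4)) for r in df.itertuples()]
        df = df[[m in in_family for m in keys]]
    df = df.sort_values(
        by=["E_combined", "c1", "c2", "c3", "c4"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Dope-in metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DopeInMetrics:
    enrichment: float
    recovery: float
    implied_background: float


def dope_in_metrics(enrichment: float, input_copies: float,
                    recovered_copies: float) -> DopeInMetrics:
    """Calibration metrics for a spiked control construct.

    recovery = recovered/input copies (from qPCR or simulation truth);
    implied_background = recovery / enrichment, i.e. the nonspecific
    capture probability consistent with the observed pair.
    """
    if input_copies <= 0:
        raise ValueError("input_copies must be positive")
    if enrichment < 0 or recovered_copies < 0:
        raise ValueError("enrichment and recovered_copies must be non-negative")
    recovery = recovered_copies / input_copies
    implied = recovery / enrichment if enrichment > 0 else float("nan")
    return DopeInMetrics(enrichment=float(enrichment), recovery=float(recovery),
                         implied_background=float(implied))


def frequency_fold_enrichment(post_fraction: float, pre_fraction: float) -> float:
    """Fold enrichment from raw frequency shares (dope-in convenience)."""
    if pre_fraction <= 0:
        raise ValueError("pre_fraction must be positive")
    if post_fraction < 0:
        raise ValueError("post_fraction must be non-negative")
    return post_fraction / pre_fraction


def cube_export(summaries: pd.DataFrame, path) -> None:
    """Write (b1,b2,b3,b4,E,rank) coordinates for external 3-D plotting."""
    df = summaries.sort_values("E_combined", ascending=False, kind="mergesort").copy()
    out = pd.DataFrame(
        {
            "b1": df["c1"], "b2": df["c2"], "b3": df["c3"], "b4": df["c4"],
            "E": df["E_combined"],
            "rank": np.arange(1, len(df) + 1),
        }
    )
    out.to_csv(path, sep="\t", index=False)
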