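"""Encoded-library design: building blocks, codon tables, read layout.

A DNA-encoded library (DEL) member is assembled in four combinatorial
cycles; each building block incorporated at a cycle is recorded by a
20-base DNA "codon" in the member's barcode ("gene").  The library
modelled here is doubly redundant: every cycle-1..3 building block has
two codons, one in each of two lineages (A and B) that are kept
physically separate until after translation, while cycle-4 caps are
singly encoded by a shared codon.  A molecule therefore maps to exactly
two genes, and the redundancy can be used downstream as an internal
replicate to diagnose undersampling.

This module is the genetic contract the rest of the package references:
it builds and validates designs, enumerates molecules and genes,
assembles full-length barcode sequences, and converts molar amounts to
copy numbers.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import yaml
from scipy.constants import Avogadro

BASES = "ACGT"
CODON_LENGTH = 20
DEFAULT_D_MIN = 8

MONOMER_CLASSES = ("fmoc_amino_acid", "peptoid", "benzyl_peptoid", "cap")


class Molecule(NamedTuple):
    """A library member: one building-block id per combinatorial cycle."""

    b1: int
    b2: int
    b3: int
    b4: int


class Gene(NamedTuple):
    """A full barcode: lineage (A/B) plus one codon id per cycle.

    Codon ids coincide with building-block ids; the lineage selects
    which of the two redundant codon tables encodes cycles 1-3.  The
    cycle-4 codon is lineage-independent.
    """

    lineage: str
    codons: tuple[int, int, int, int]


@dataclass(frozen=True)
class BuildingBlock:
    id: int
    cycle: int
    monomer_class: str = "fmoc_amino_acid"
    has_phenol: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.cycle not in (1, 2, 3, 4):
            raise ValueError(f"cycle must be 1-4, got {self.cycle}")
        if self.monomer_class not in MONOMER_CLASSES:
            raise ValueError(f"unknown monomer_class {self.monomer_class!r}")
        if self.cycle == 4 and self.monomer_class != "cap":
            raise ValueError("cycle-4 building blocks must be caps")


@dataclass(frozen=True)
class CodonTable:
    """Codon assignments for one cycle and lineage (A, B, or shared)."""

    cycle: int
    lineage: str
    entries: Mapping[int, str]

    def __post_init__(self) -> None:
        if self.lineage not in ("A", "B", "shared"):
            raise ValueError(f"lineage must be A, B or shared, got {self.lineage!r}")
        if self.lineage == "shared" and self.cycle != 4:
            raise ValueError("lineage 'shared' is only allowed for cycle 4")
        for bid, seq in self.entries.items():
            if len(seq) != CODON_LENGTH:
                raise ValueError(
                    f"codon for block {bid} (cycle {self.cycle}) has length "
                    f"{len(seq)}, expected {CODON_LENGTH}"
                )
            if set(seq) - set(BASES):
                raise ValueError(f"codon for block {bid} contains non-ACGT characters")


@dataclass(frozen=True)
class Segment:
    kind: str  # "common" | "variable"
    length: int
    cycle: int | None = None


@dataclass(frozen=True)
class ReadLayout:
    """Ordered common/variable segments of the sequenced construct."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        var = [s for s in self.segments if s.kind == "variable"]
        if [s.cycle for s in var] != [1, 2, 3, 4]:
            raise ValueError(
                "layout must contain exactly 4 variable segments in cycle order 1-4"
            )
        for s in self.segments:
            if s.kind not in ("common", "variable"):
                raise ValueError(f"unknown segment kind {s.kind!r}")
            if s.length <= 0:
                raise ValueError("segment lengths must be positive")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def variable_slices(self) -> list[tuple[int, int, int]]:
        """(cycle, start, stop) for each variable segment, 0-based half-open."""
        out, pos = [], 0
        for s in self.segments:
            if s.kind == "variable":
                out.append((s.cycle, pos, pos + s.length))
            pos += s.length
        return out

    def n_common(self) -> int:
        return sum(1 for s in self.segments if s.kind == "common")


def default_layout() -> ReadLayout:
    """Five 20-base common sequences interleaved with four 20-base codons (180-mer)."""
    segs: list[Segment] = []
    for cycle in range(1, 5):
        segs.append(Segment("common", CODON_LENGTH))
        segs.append(Segment("variable", CODON_LENGTH, cycle))
    segs.append(Segment("common", CODON_LENGTH))
    return ReadLayout(tuple(segs))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def generate_codons(
    n: int,
    rng: np.random.Generator,
    length: int = CODON_LENGTH,
    d_min: int = DEFAULT_D_MIN,
    max_attempts_per_codon: int = 2000,
) -> list[str]:
    """Greedily accept random DNA words under a pairwise-Hamming floor.

    Random 20-mers are mutually distant on average (expected distance
    15), so greedy acceptance at d_min = 8 succeeds easily at the sizes
    used here; a hard attempt cap converts pathological requests into a
    clear error.
    """
    accepted: list[str] = []
    arr: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_codon * max(n, 1)
    while len(accepted) < n:
        if attempts >= budget:
            raise ValueError(
                f"could not generate {n} codons of length {length} with pairwise "
                f"Hamming >= {d_min} after {attempts} attempts"
            )
        attempts += 1
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= d_min for a in arr):
            arr.append(cand)
            accepted.append("".join(BASES[i] for i in cand))
    return accepted


@dataclass
class LibraryDesign:
    """A validated encoded-library design.

    blocks
        Per-cycle building-block lists (cycle -> list of BuildingBlock).
    codon_tables
        (cycle, lineage) -> CodonTable.  Cycles 1-3 carry "A" (and "B"
        when doubly encoded); cycle 4 carries a single "shared" table.
    layout
        Read architecture of the sequenced construct.
    common_sequences
        The common 20-mers, in layout order.
    """

    blocks: dict[int, list[BuildingBlock]]
    codon_tables: dict[tuple[int, str], CodonTable]
    layout: ReadLayout
    common_sequences: list[str]
    d_min: int = DEFAULT_D_MIN

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if sorted(self.blocks) != [1, 2, 3, 4]:
            raise ValueError("design must define building blocks for cycles 1-4")
        for cycle, blist in self.blocks.items():
            ids = [b.id for b in blist]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate building-block ids in cycle {cycle}")
            if not blist:
                raise ValueError(f"cycle {cycle} has no building blocks")
            for b in blist:
                if b.cycle != cycle:
                    raise ValueError("building block filed under the wrong cycle")
        doubly = (1, "B") in self.codon_tables
        for cycle in (1, 2, 3):
            for lin in ("A", "B") if doubly else ("A",):
                if (cycle, lin) not in self.codon_tables:
                    raise ValueError(f"missing codon table for cycle {cycle}, lineage {lin}")
            keys_a = set(self.codon_tables[(cycle, "A")].entries)
            if keys_a != {b.id for b in self.blocks[cycle]}:
                raise ValueError(f"cycle {cycle} lineage A codon ids do not match block ids")
            if doubly:
                if set(self.codon_tables[(cycle, "B")].entries) != keys_a:
                    raise ValueError(f"cycle {cycle} A/B codon tables have different key sets")
        if (4, "shared") not in self.codon_tables:
            raise ValueError("cycle 4 requires a single shared codon table")
        if set(self.codon_tables[(4, "shared")].entries) != {b.id for b in self.blocks[4]}:
            raise ValueError("cycle 4 codon ids do not match block ids")
        for key in self.codon_tables:
            if key[0] in (1, 2, 3) and key[1] == "shared":
                raise ValueError("shared tables are only allowed at cycle 4")
        # codon orthogonality within each cycle, across lineages
        for cycle in (1, 2, 3, 4):
            labelled: list[tuple[str, int, str]] = []
            for (c, lin), table in self.codon_tables.items():
                if c == cycle:
                    labelled.extend((lin, bid, seq) for bid, seq in table.entries.items())
            for (l1, i1, s1), (l2, i2, s2) in itertools.combinations(labelled, 2):
                d = hamming(s1, s2)
                if d < self.d_min:
                    raise ValueError(
                        f"codon orthogonality violated in cycle {cycle}: "
                        f"({l1}, block {i1}) vs ({l2}, block {i2}) at Hamming "
                        f"distance {d} < d_min={self.d_min}"
                    )
        if len(self.common_sequences) != self.layout.n_common():
            raise ValueError(
                f"layout expects {self.layout.n_common()} common sequences, "
                f"got {len(self.common_sequences)}"
            )
        for cycle, start, stop in self.layout.variable_slices():
            lin = "shared" if cycle == 4 else "A"
            any_seq = next(iter(self.codon_tables[(cycle, lin)].entries.values()))
            if stop - start != len(any_seq):
                raise ValueError(f"variable segment length mismatch at cycle {cycle}")
        common_lengths = [s.length for s in self.layout.segments if s.kind == "common"]
        for seq, length in zip(self.common_sequences, common_lengths):
            if len(seq) != length:
                raise ValueError("common sequence length does not match layout")

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> tuple[int, int, int, int]:
        return tuple(len(self.blocks[c]) for c in (1, 2, 3, 4))  # type: ignore[return-value]

    @property
    def n_molecules(self) -> int:
        n1, n2, n3, n4 = self.n
        return n1 * n2 * n3 * n4

    @property
    def lineages(self) -> tuple[str, ...]:
        return ("A", "B") if (1, "B") in self.codon_tables else ("A",)

    @property
    def n_genes(self) -> int:
        return self.n_molecules * len(self.lineages)

    def block_ids(self, cycle: int) -> list[int]:
        return [b.id for b in self.blocks[cycle]]

    def phenol_cap_ids(self) -> set[int]:
        return {b.id for b in self.blocks[4] if b.has_phenol}

    def block(self, cycle: int, bid: int) -> BuildingBlock:
        for b in self.blocks[cycle]:
            if b.id == bid:
                return b
        raise KeyError(f"no building block {bid} in cycle {cycle}")

    def molecule_array(self) -> np.ndarray:
        """All molecules as an (N, 4) int array in enumeration order."""
        grids = np.meshgrid(*(np.array(self.block_ids(c)) for c in (1, 2, 3, 4)), indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_molecules(design: LibraryDesign) -> Iterator[Molecule]:
    """Yield every library member exactly once (cycle-1-major order)."""
    for ids in itertools.product(*(design.block_ids(c) for c in (1, 2, 3, 4))):
        yield Molecule(*ids)


def genes_of(molecule: Molecule, design: LibraryDesign) -> list[Gene]:
    """The redundant genes of a molecule: one per lineage, shared cycle-4 codon."""
    for cycle, bid in zip((1, 2, 3, 4), molecule):
        if bid not in set(design.block_ids(cycle)):
            raise KeyError(f"unknown building-block id {bid} in cycle {cycle}")
    return [Gene(lin, tuple(molecule)) for lin in design.lineages]


def molecule_of(gene: Gene) -> Molecule:
    """Decode a gene to the molecule it encodes (total inverse of genes_of)."""
    return Molecule(*gene.codons)


def enumerate_genes(design: LibraryDesign) -> Iterator[Gene]:
    """All genes, lineage-major then molecule order."""
    for lin in design.lineages:
        for ids in itertools.product(*(design.block_ids(c) for c in (1, 2, 3, 4))):
            yield Gene(lin, ids)


def assemble_gene_sequence(gene: Gene, design: LibraryDesign) -> str:
    """Concatenate common and codon segments in layout order (default 180-mer)."""
    parts: list[str] = []
    common_iter = iter(design.common_sequences)
    for seg in design.layout.segments:
        if seg.kind == "common":
            parts.append(next(common_iter))
        else:
            cycle = seg.cycle
            lineage = "shared" if cycle == 4 else gene.lineage
            table = design.codon_tables[(cycle, lineage)]
            parts.append(table.entries[gene.codons[cycle - 1]])
    return "".join(parts)


def copies_from_amount(amount_mol: float) -> float:
    """Convert a molar amount (mol) to molecule copies via the Avogadro constant."""
    if amount_mol < 0:
        raise ValueError("amount must be non-negative")
    return amount_mol * Avogadro


def amount_from_copies(copies: float) -> float:
    """Inverse of copies_from_amount (copies -> mol)."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    return copies / Avogadro


# ---------------------------------------------------------------------------
# Construction from config
# ---------------------------------------------------------------------------

_DEFAULT_CLASS = {1: "fmoc_amino_acid", 2: "peptoid", 3: "benzyl_peptoid", 4: "cap"}


def _blocks_from_config(config: Mapping) -> dict[int, list[BuildingBlock]]:
    if "blocks" in config:
        blocks: dict[int, list[BuildingBlock]] = {}
        for cycle_key, blist in config["blocks"].items():
            cycle = int(cycle_key)
            blocks[cycle] = [
                BuildingBlock(
                    id=int(b.get("id", i)),
                    cycle=cycle,
                    monomer_class=b.get("monomer_class", _DEFAULT_CLASS[cycle]),
                    has_phenol=bool(b.get("has_phenol", False)),
                    name=b.get("name", f"c{cycle}_{b.get('id', i)}"),
                )
                for i, b in enumerate(blist)
            ]
        return blocks
    if "n" not in config:
        raise KeyError("design config requires 'n' (sizes per cycle) or explicit 'blocks'")
    n = list(config["n"])
    if len(n) != 4 or any(int(x) <= 0 for x in n):
        raise ValueError("'n' must be four positive cycle sizes")
    phenol = {int(c): set(ids) for c, ids in (config.get("phenol_blocks") or {}).items()}
    # default phospho-acceptor placement: one tyrosine-like monomer per
    # diversity cycle and one phenol cap
    if not phenol:
        phenol = {1: {0}, 2: {0}, 3: {0}, 4: {0}}
    blocks = {}
    for cycle, size in zip((1, 2, 3, 4), n):
        blocks[cycle] = [
            BuildingBlock(
                id=i,
                cycle=cycle,
                monomer_class=_DEFAULT_CLASS[cycle],
                has_phenol=i in phenol.get(cycle, set()),
                name=("phenol_cap" if cycle == 4 and i in phenol.get(4, set()) else f"c{cycle}_{i}"),
            )
            for i in range(int(size))
        ]
    return blocks


def _layout_from_config(config: Mapping) -> ReadLayout:
    layout_cfg = config.get("layout", "default")
    if layout_cfg in (None, "default"):
        return default_layout()
    segs = []
    for seg in layout_cfg:
        segs.append(Segment(seg["kind"], int(seg["length"]), seg.get("cycle")))
    return ReadLayout(tuple(segs))


def build_design(config: Mapping) -> LibraryDesign:
    """Build and validate a LibraryDesign from a structured config mapping.

    Keys: ``n`` (four cycle sizes) or ``blocks``; ``codon_seed`` or explicit
    ``codon_tables``; optional ``d_min`` (default 8), ``singly_encoded``,
    ``phenol_blocks`` ({cycle: [ids]}), ``layout`` ("default" or a segment
    list).  Codon generation is reproducible from ``codon_seed``.
    """
    blocks = _blocks_from_config(config)
    layout = _layout_from_config(config)
    d_min = int(config.get("d_min", DEFAULT_D_MIN))
    doubly = not bool(config.get("singly_encoded", False))

    tables: dict[tuple[int, str], CodonTable] = {}
    if "codon_tables" in config:
        for key, entries in config["codon_tables"].items():
            if isinstance(key, str):
                c_str, lin = key.split("/")
                cycle = int(c_str)
            else:
                cycle, lin = key
            tables[(int(cycle), lin)] = CodonTable(
                int(cycle), lin, {int(k): v for k, v in entries.items()}
            )
    else:
        if "codon_seed" not in config:
            raise KeyError("design config requires 'codon_seed' or explicit 'codon_tables'")
        rng = np.random.default_rng(int(config["codon_seed"]))
        for cycle in (1, 2, 3):
            ids = [b.id for b in blocks[cycle]]
            lineages = ("A", "B") if doubly else ("A",)
            codons = generate_codons(len(ids) * len(lineages), rng, d_min=d_min)
            for j, lin in enumerate(lineages):
                chunk = codons[j * len(ids) : (j + 1) * len(ids)]
                tables[(cycle, lin)] = CodonTable(cycle, lin, dict(zip(ids, chunk)))
        ids4 = [b.id for b in blocks[4]]
        tables[(4, "shared")] = CodonTable(
            4, "shared", dict(zip(ids4, generate_codons(len(ids4), rng, d_min=d_min)))
        )

    if "common_sequences" in config:
        common = list(config["common_sequences"])
    else:
        seed = int(config.get("codon_seed", 0)) + 1
        rng_c = np.random.default_rng(seed)
        lengths = [s.length for s in layout.segments if s.kind == "common"]
        common = [
            "".join(BASES[i] for i in rng_c.integers(0, 4, size=length)) for length in lengths
        ]

    return LibraryDesign(
        blocks=blocks,
        codon_tables=tables,
        layout=layout,
        common_sequences=common,
        d_min=d_min,
    )


def design_from_yaml(path) -> LibraryDesign:
    with open(path) as fh:
        return build_design(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Import/export
# ---------------------------------------------------------------------------

def codon_tables_to_tsv(design: LibraryDesign, path) -> None:
    """Write all codon tables as TSV (cycle, lineage, block_id, sequence)."""
    with open(path, "w") as fh:
        fh.write("cycle\tlineage\tblock_id\tsequence\n")
        for (cycle, lin) in sorted(design.codon_tables):
            for bid, seq in sorted(design.codon_tables[(cycle, lin)].entries.items()):
                fh.write(f"{cycle}\t{lin}\t{bid}\t{seq}\n")


def codon_tables_from_tsv(path) -> dict[tuple[int, str], CodonTable]:
    entries: dict[tuple[int, str], dict[int, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["cycle", "lineage", "block_id", "sequence"]:
            raise ValueError("unexpected codon-table TSV header")
        for line in fh:
            cycle, lin, bid, seq = line.rstrip("\n").split("\t")
            entries.setdefault((int(cycle), lin), {})[int(bid)] = seq
    return {key: CodonTable(key[0], key[1], ent) for key, ent in entries.items()}


def export_gene_fasta(design: LibraryDesign, path) -> int:
    """Write every assembled gene sequence as FASTA; returns records written."""
    n = 0
    with open(path, "w") as fh:
        for gene in enumerate_genes(design):
            name = f"{gene.lineage}_" + "_".join(str(c) for c in gene.codons)
            fh.write(f">{name}\n{assemble_gene_sequence(gene, design)}\n")
            n += 1
    return n
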