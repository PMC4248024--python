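"""Input/output for the selection pipeline: codon alignments, variant tables, trees.

Codon alignments are read from FASTA with an in-frame validation pass;
variant tables come either from a VCF subset or from a flat TSV carrying
per-population allele counts and an outgroup allele column. Trees are
Newick via dendropy, wrapped in a light structure the likelihood engine
consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(STANDARD_TABLE.forward_table))  # 61 codons
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
NUCLEOTIDES = "ACGT"
_VALID_CHARS = frozenset("ACGTN-")


class FrameError(ValueError):
    """Sequence length not divisible by 3."""


class AlignmentValidationError(ValueError):
    """Alignment violates a codon-alignment invariant."""


def translate_codon(codon: str) -> str:
    """Single-letter amino acid for a sense codon ('*' for stops)."""
    if codon in STOP_CODONS:
        return "*"
    return STANDARD_TABLE.forward_table[codon]


@dataclass
class CodonAlignment:
    """Aligned coding sequences held codon-wise.

    Rows are sequences, columns are codon sites. Cells are 3-character
    strings over {A,C,G,T,N,-}. Only the standard nuclear genetic code is
    supported; an ungapped row must not contain an in-frame stop codon.
    """

    sequence_ids: list[str]
    codons: np.ndarray  # dtype '<U3', shape (n_seqs, n_sites)
    genetic_code: int = 1

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype="<U3")
        if self.genetic_code != 1:
            raise AlignmentValidationError(
                "only the standard nuclear genetic code (id 1) is supported"
            )
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.sequence_ids):
            raise AlignmentValidationError("codon matrix shape does not match ids")
        for sid, row in zip(self.sequence_ids, self.codons):
            for j, codon in enumerate(row):
                if len(codon) != 3 or not set(codon) <= _VALID_CHARS:
                    raise AlignmentValidationError(
                        f"record {sid!r}, codon column {j}: invalid cell {codon!r}"
                    )
                if codon in STOP_CODONS:
                    raise AlignmentValidationError(
                        f"record {sid!r} contains in-frame stop codon {codon} "
                        f"at codon column {j}"
                    )

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def row(self, sequence_id: str) -> np.ndarray:
        try:
            i = self.sequence_ids.index(sequence_id)
        except ValueError:
            raise KeyError(f"sequence {sequence_id!r} not in alignment") from None
        return self.codons[i]

    def sequence_str(self, sequence_id: str) -> str:
        return "".join(self.row(sequence_id))


@dataclass
class VariantRecord:
    """One biallelic SNP with per-population allele counts.

    ``per_pop_alt_counts`` maps population name to (alt count, total allele
    count). ``outgroup_allele`` polarizes derived vs ancestral; ``None``
    means the outgroup state is unknown at this site.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    per_pop_alt_counts: dict[str, tuple[int, int]]
    outgroup_allele: str | None = None
    consequence: str | None = None  # synonymous | nonsynonymous | noncoding
    aa_change: tuple[str, str, int] | None = None  # (ref AA, alt AA, protein pos)
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for pop, (ac, an) in self.per_pop_alt_counts.items():
            if not 0 <= ac <= an:
                raise ValueError(
                    f"{self.chrom}:{self.pos} population {pop}: "
                    f"alt count {ac} outside [0, {an}]"
                )

    def alt_frequency(self, populations: Sequence[str] | None = None) -> float:
        pops = populations if populations is not None else self.per_pop_alt_counts
        ac = sum(self.per_pop_alt_counts[p][0] for p in pops)
        an = sum(self.per_pop_alt_counts[p][1] for p in pops)
        if an == 0:
            raise ValueError("no alleles sampled")
        return ac / an


@dataclass
class PhyloTree:
    """Phylogeny wrapper over a dendropy tree.

    Branch lengths are expected substitutions per codon. The likelihood
    engine consumes the postorder edge arrays exposed here.
    """

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def validate_against(self, aln: CodonAlignment) -> None:
        missing = set(self.leaf_labels) - set(aln.sequence_ids)
        if missing:
            raise AlignmentValidationError(
                f"tree leaves absent from alignment: {sorted(missing)}"
            )
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise AlignmentValidationError("negative branch length in tree")

    def postorder_edges(self) -> list[tuple[int, int, float | None, str | None]]:
        """(node_id, parent_id, branch_length, leaf_label) in postorder.

        The root appears last with parent_id = -1. Node ids index a dense
        array sized ``n_nodes``.
        """
        nodes = list(self.tree.postorder_node_iter())
        ids = {id(n): i for i, n in enumerate(nodes)}
        out = []
        for n in nodes:
            pid = ids[id(n.parent_node)] if n.parent_node is not None else -1
            label = n.taxon.label if n.is_leaf() else None
            out.append((ids[id(n)], pid, n.edge.length, label))
        return out

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# FASTA codon alignments


def read_codon_alignment(path: str | Path, frame_check: bool = True) -> CodonAlignment:
    """Read an aligned FASTA file into a :class:`CodonAlignment`.

    Every record must have the same length; with ``frame_check`` the length
    must be divisible by 3 and ungapped rows must be free of in-frame stops.
    Ns and gaps are preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentValidationError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentValidationError(f"unequal record lengths in {path}: {sorted(lengths)}")
    (length,) = lengths
    if frame_check and length % 3 != 0:
        raise FrameError(f"alignment length {length} not divisible by 3")
    ids = [r.id for r in records]
    mat = np.array(
        [[str(r.seq)[i : i + 3].upper() for i in range(0, length, 3)] for r in records],
        dtype="<U3",
    )
    return CodonAlignment(sequence_ids=ids, codons=mat)


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    """Write to normalized FASTA (one sequence line per record)."""
    with open(path, "w") as fh:
        for sid, row in zip(aln.sequence_ids, aln.codons):
            fh.write(f">{sid}\n{''.join(row)}\n")


def mask_gapped_codon_columns(aln: CodonAlignment) -> tuple[CodonAlignment, list[int]]:
    """Drop every codon column containing a gap or N in any row.

    Stands in for alignment-reliability column filtering: downstream
    likelihood and counting operations require fully resolved columns.
    Returns the masked alignment and the removed column indices.
    """
    bad = [
        j
        for j in range(aln.n_sites)
        if any(("-" in c) or ("N" in c) for c in aln.codons[:, j])
    ]
    keep = [j for j in range(aln.n_sites) if j not in set(bad)]
    masked = CodonAlignment(
        sequence_ids=list(aln.sequence_ids), codons=aln.codons[:, keep]
    )
    return masked, bad


# ---------------------------------------------------------------------------
# Ortholog candidate filtering


def filter_orthologs(
    sequences: dict[str, str],
    reference_id: str,
    max_length_dev: float = 0.20,
    max_missing_nt: int = 5,
) -> list[str]:
    """Retain homolog candidates comparable to the reference sequence.

    A candidate passes if its ungapped length is within ``max_length_dev``
    (default +/-20%) of the reference's ungapped length and it carries at
    most ``max_missing_nt`` (default 5) N characters. The reference itself
    is always retained. This runs on unaligned coding sequences, so the
    missing-data rule counts Ns, not alignment gaps.
    """
    if reference_id not in sequences:
        raise KeyError(f"reference {reference_id!r} not among sequences")

    def ungapped_len(s: str) -> int:
        return len(s.replace("-", ""))

    ref_len = ungapped_len(sequences[reference_id])
    retained = []
    for sid in sequences:
        if sid == reference_id:
            retained.append(sid)
            continue
        seq = sequences[sid]
        n_missing = seq.upper().count("N")
        dev = abs(ungapped_len(seq) - ref_len) / ref_len
        if dev <= max_length_dev and n_missing <= max_missing_nt:
            retained.append(sid)
    return retained


# ---------------------------------------------------------------------------
# Variant tables

_TSV_FIXED_COLS = ("chrom", "pos", "ref", "alt", "outgroup")


def read_variant_table(
    path: str | Path, populations: Sequence[str]
) -> tuple[list[VariantRecord], int]:
    """Read biallelic SNPs from a VCF (v4.x subset) or TSV file.

    TSV columns: chrom, pos, ref, alt, outgroup, then ``pop:AC`` and
    ``pop:AN`` per population; optional ``consequence``, ``gene``,
    ``aa_ref``, ``aa_alt``, ``aa_pos``. VCF population counts are read
    from ``AC_<pop>`` / ``AN_<pop>`` INFO fields, the outgroup allele from
    ``AA`` (ancestral allele). Multiallelic and indel records are skipped;
    the skip count is returned alongside the records.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("##fileformat=VCF") or path.suffix == ".vcf":
        return _read_vcf(text, populations)
    return _read_tsv(text, populations)


def _read_tsv(text: str, populations: Sequence[str]) -> tuple[list[VariantRecord], int]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    col = {name: i for i, name in enumerate(header)}
    for fixed in _TSV_FIXED_COLS[:4]:
        if fixed not in col:
            raise ValueError(f"variant TSV missing required column {fixed!r}")
    available = sorted(
        {c.split(":")[0] for c in header if c.endswith(":AC")}
    )
    unknown = [p for p in populations if p not in available]
    if unknown:
        raise KeyError(
            f"unknown population(s) {unknown}; available: {available}"
        )
    records, skipped = [], 0
    for ln in lines[1:]:
        f = ln.split("\t")
        ref, alt = f[col["ref"]], f[col["alt"]]
        if len(ref) != 1 or "," in alt or len(alt) != 1:
            skipped += 1
            continue
        out = f[col["outgroup"]] if "outgroup" in col else "."
        aa_change = None
        if "aa_ref" in col and f[col["aa_ref"]] not in (".", ""):
            aa_change = (f[col["aa_ref"]], f[col["aa_alt"]], int(f[col["aa_pos"]]))
        records.append(
            VariantRecord(
                chrom=f[col["chrom"]],
                pos=int(f[col["pos"]]),
                ref_allele=ref,
                alt_allele=alt,
                per_pop_alt_counts={
                    p: (int(f[col[f"{p}:AC"]]), int(f[col[f"{p}:AN"]]))
                    for p in populations
                },
                outgroup_allele=None if out in (".", "", "N") else out,
                consequence=f[col["consequence"]] if "consequence" in col else None,
                aa_change=aa_change,
                gene_id=f[col["gene"]] if "gene" in col else None,
            )
        )
    if skipped:
        logger.info("skipped %d multiallelic/indel records", skipped)
    return records, skipped


def _read_vcf(text: str, populations: Sequence[str]) -> tuple[list[VariantRecord], int]:
    records, skipped = [], 0
    available: set[str] = set()
    body = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    for ln in text.splitlines():
        if ln.startswith("##INFO=<ID=AC_"):
            available.add(ln.split("ID=AC_", 1)[1].split(",")[0])
    if available:
        unknown = [p for p in populations if p not in available]
        if unknown:
            raise KeyError(
                f"unknown population(s) {unknown}; available: {sorted(available)}"
            )
    for ln in body:
        f = ln.split("\t")
        chrom, pos, _, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
        if len(ref) != 1 or "," in alt or len(alt) != 1 or alt == ".":
            skipped += 1
            continue
        info = dict(
            kv.split("=", 1) if "=" in kv else (kv, "")
            for kv in f[7].split(";")
            if kv
        )
        try:
            per_pop = {
                p: (int(info[f"AC_{p}"]), int(info[f"AN_{p}"])) for p in populations
            }
        except KeyError as exc:
            raise KeyError(f"population INFO field missing at {chrom}:{pos}: {exc}")
        out = info.get("AA", ".")
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                per_pop_alt_counts=per_pop,
                outgroup_allele=None if out in (".", "", "N") else out.upper(),
                consequence=info.get("CSQ"),
                gene_id=info.get("GENE"),
            )
        )
    if skipped:
        logger.info("skipped %d multiallelic/indel records", skipped)
    return records, skipped


def write_variant_table(
    records: Iterable[VariantRecord], populations: Sequence[str], path: str | Path
) -> None:
    """Write records as the TSV dialect read_variant_table accepts."""
    cols = list(_TSV_FIXED_COLS) + ["consequence", "gene", "aa_ref", "aa_alt", "aa_pos"]
    for p in populations:
        cols += [f"{p}:AC", f"{p}:AN"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            aa = r.aa_change or (".", ".", ".")
            row = [
                r.chrom,
                str(r.pos),
                r.ref_allele,
                r.alt_allele,
                r.outgroup_allele or ".",
                r.consequence or ".",
                r.gene_id or ".",
                str(aa[0]),
                str(aa[1]),
                str(aa[2]),
            ]
            for p in populations:
                ac, an = r.per_pop_alt_counts[p]
                row += [str(ac), str(an)]
            fh.write("\t".join(row) + "\n")
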