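"""Synonymous/nonsynonymous site and difference counting (Nei–Gojobori 1986).

Produces the per-gene quantities the group contrasts and MK tests consume:
Pn/Ps from annotated polymorphism lists, Dn/Ds from pairwise ingroup–outgroup
codon comparisons with equal-weight pathway averaging, fractional site counts,
and fourfold/zerofold degeneracy classes. Per-site rates carry a Jukes–Cantor
multiple-hit correction applied separately to each class.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from .seqio import (
    NUCLEOTIDES,
    STOP_CODONS,
    VariantRecord,
    translate_codon,
)


@dataclass
class GeneCounts:
    """Per-gene polymorphism and divergence counts with a group label."""

    gene_id: str
    group: str  # "biosynthetic" | "degrading"
    Pn: int
    Ps: int
    Dn: float
    Ds: float
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    fourfold: int = 0
    zerofold: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("biosynthetic", "degrading"):
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("Pn", "Ps", "Dn", "Ds", "syn_sites", "nonsyn_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or not set(codon) <= set(NUCLEOTIDES):
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} not allowed")


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts of one codon.

    For each of the three positions, the synonymous fraction is the share
    of single-base neighbours that code for the same amino acid, taken over
    non-stop neighbours only. The two fractions always sum to exactly 3.
    """
    _check_codon(codon)
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        neighbours = [
            codon[:pos] + n + codon[pos + 1 :]
            for n in NUCLEOTIDES
            if n != codon[pos]
        ]
        non_stop = [c for c in neighbours if c not in STOP_CODONS]
        if non_stop:
            syn += sum(translate_codon(c) == aa for c in non_stop) / len(non_stop)
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts between two codons.

    All mutational pathways between the codons are enumerated (one per
    ordering of the differing positions); pathways passing through a stop
    codon are discarded; each step of each surviving pathway is classified
    by whether it changes the amino acid, and the classifications are
    averaged with equal pathway weights. Symmetric in its arguments.
    """
    _check_codon(c1)
    _check_codon(c2)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(translate_codon(cur) == translate_codon(nxt))
            cur = nxt
        if ok:
            n_paths += 1
            syn_tot += sum(steps)
            nonsyn_tot += len(steps) - sum(steps)
    if n_paths == 0:
        raise ValueError(f"all pathways between {c1} and {c2} pass through stops")
    return syn_tot / n_paths, nonsyn_tot / n_paths


def degeneracy_site_counts(seq: str | list[str]) -> tuple[int, int]:
    """Count fourfold and zerofold degenerate nucleotide positions.

    A position is fourfold if every base change there is synonymous,
    zerofold if none is (stop-codon neighbours excluded from consideration).
    """
    codons = _as_codons(seq)
    fourfold = zerofold = 0
    for codon in codons:
        _check_codon(codon)
        aa = translate_codon(codon)
        for pos in range(3):
            neighbours = [
                codon[:pos] + n + codon[pos + 1 :]
                for n in NUCLEOTIDES
                if n != codon[pos]
            ]
            non_stop = [c for c in neighbours if c not in STOP_CODONS]
            if not non_stop:
                continue
            n_syn = sum(translate_codon(c) == aa for c in non_stop)
            if n_syn == len(non_stop) and len(non_stop) == 3:
                fourfold += 1
            elif n_syn == 0:
                zerofold += 1
    return fourfold, zerofold


def _as_codons(seq: str | list[str] | np.ndarray) -> list[str]:
    if isinstance(seq, str):
        if len(seq) % 3:
            raise ValueError("sequence length not divisible by 3")
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return [str(c) for c in seq]


def count_polymorphisms(variants: list[VariantRecord]) -> tuple[int, int]:
    """Count segregating nonsynonymous (Pn) and synonymous (Ps) variants.

    Fixed or absent variants (alt count 0 or equal to the sample total) are
    not polymorphisms and are excluded. Noncoding variants are ignored; a
    coding variant without a consequence annotation is an error.
    """
    pn = ps = 0
    for v in variants:
        if v.consequence == "noncoding":
            continue
        if v.consequence not in ("synonymous", "nonsynonymous"):
            raise ValueError(
                f"unannotated coding variant at {v.chrom}:{v.pos} "
                f"(consequence={v.consequence!r})"
            )
        ac = sum(c[0] for c in v.per_pop_alt_counts.values())
        an = sum(c[1] for c in v.per_pop_alt_counts.values())
        if 0 < ac < an:
            if v.consequence == "nonsynonymous":
                pn += 1
            else:
                ps += 1
    return pn, ps


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(
            f"proportion of differences {p:.3f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * np.log(1 - 4 * p / 3)


def count_divergence(
    ingroup_seq: str | list[str], outgroup_seq: str | list[str]
) -> tuple[float, float, float, float]:
    """Pairwise divergence counts and per-site rates against an outgroup.

    Sums pathway-averaged differences over codon columns; site counts are
    averaged between the two sequences. Returns (Dn, Ds, dn, ds) where the
    rates carry a per-class Jukes-Cantor multiple-hit correction.
    """
    ing = _as_codons(ingroup_seq)
    outg = _as_codons(outgroup_seq)
    if len(ing) != len(outg):
        raise ValueError("sequences differ in codon length")
    dn = ds = syn_sites = nonsyn_sites = 0.0
    for c1, c2 in zip(ing, outg):
        s, n = codon_path_diffs(c1, c2)
        ds += s
        dn += n
        s1, n1 = codon_site_counts(c1)
        s2, n2 = codon_site_counts(c2)
        syn_sites += (s1 + s2) / 2
        nonsyn_sites += (n1 + n2) / 2
    dn_rate = _jukes_cantor(dn / nonsyn_sites) if nonsyn_sites > 0 else 0.0
    ds_rate = _jukes_cantor(ds / syn_sites) if syn_sites > 0 else 0.0
    return dn, ds, dn_rate, ds_rate


def gene_counts_from_data(
    gene_id: str,
    group: str,
    variants: list[VariantRecord],
    ingroup_seq: str | list[str],
    outgroup_seq: str | list[str],
) -> GeneCounts:
    """Assemble a GeneCounts row from annotated variants and a codon pair."""
    pn, ps = count_polymorphisms(variants)
    dn, ds, _, _ = count_divergence(ingroup_seq, outgroup_seq)
    codons = _as_codons(ingroup_seq)
    syn = nonsyn = 0.0
    for c in codons:
        s, n = codon_site_counts(c)
        syn += s
        nonsyn += n
    ff, zf = degeneracy_site_counts(codons)
    return GeneCounts(
        gene_id=gene_id,
        group=group,
        Pn=pn,
        Ps=ps,
        Dn=dn,
        Ds=ds,
        syn_sites=syn,
        nonsyn_sites=nonsyn,
        fourfold=ff,
        zerofold=zf,
    )


def write_gene_counts(genes: list[GeneCounts], path) -> None:
    cols = (
        "gene_id group Pn Ps Dn Ds syn_sites nonsyn_sites fourfold zerofold".split()
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            fh.write(
                "\t".join(
                    str(getattr(g, c)) for c in cols
                )
                + "\n"
            )


def read_gene_counts(path) -> list[GeneCounts]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        GeneCounts(
            gene_id=str(r.gene_id),
            group=str(r.group),
            Pn=int(r.Pn),
            Ps=int(r.Ps),
            Dn=float(r.Dn),
            Ds=float(r.Ds),
            syn_sites=float(getattr(r, "syn_sites", 0.0)),
            nonsyn_sites=float(getattr(r, "nonsyn_sites", 0.0)),
            fourfold=int(getattr(r, "fourfold", 0)),
            zerofold=int(getattr(r, "zerofold", 0)),
        )
        for r in df.itertuples()
    ]
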