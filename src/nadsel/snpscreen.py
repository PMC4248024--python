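"""High-frequency amino-acid variant screening with PAM250 rarity flags.

Coding SNP panels from large resequencing efforts are first binomially
down-sampled to a fixed small panel (comparability across genes and
species), then nonsynonymous variants segregating above a frequency
threshold are extracted, and each amino-acid replacement is scored with
the Dayhoff PAM250 log-odds matrix: a negative score marks a replacement
that is evolutionarily uncommon among accepted point mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import VariantRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

_PAM250 = substitution_matrices.load("PAM250")


@dataclass
class AminoAcidChange:
    gene_id: str
    ref_aa: str
    alt_aa: str
    protein_pos: int
    frequency: float
    pam250_score: int | None = None
    rare: bool | None = None


def pam250_score(a: str, b: str) -> int:
    """PAM250 log-odds score for a residue pair (symmetric lookup)."""
    a, b = a.upper(), b.upper()
    if a not in AA_ALPHABET or b not in AA_ALPHABET:
        raise KeyError(f"unknown residue in pair ({a!r}, {b!r})")
    return int(_PAM250[a][b])


def binomial_downsample(
    variants: list[VariantRecord],
    target_individuals: int = 20,
    seed: int | None = None,
) -> tuple[list[VariantRecord], int]:
    """Binomially resample each site to a panel of ``target_individuals``.

    Diploid individuals contribute two chromosomes, so the new alt count at
    a site is Binomial(2 * target_individuals, p-hat) with p-hat the
    original pooled alt frequency — a good approximation to subsampling
    when the source panel is large. Sites that become monomorphic are
    dropped (they are no longer polymorphisms); the drop count is returned.
    """
    if seed is None:
        raise ValueError("a resampling seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    m = 2 * target_individuals
    out, dropped = [], 0
    for v in variants:
        an = sum(c[1] for c in v.per_pop_alt_counts.values())
        if an < m:
            raise ValueError(
                f"{v.chrom}:{v.pos}: {an} sampled alleles < target {m}"
            )
        p_hat = v.alt_frequency()
        new_ac = int(rng.binomial(m, p_hat))
        if new_ac in (0, m):
            dropped += 1
            continue
        out.append(
            VariantRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref_allele=v.ref_allele,
                alt_allele=v.alt_allele,
                per_pop_alt_counts={"resampled": (new_ac, m)},
                outgroup_allele=v.outgroup_allele,
                consequence=v.consequence,
                aa_change=v.aa_change,
                gene_id=v.gene_id,
            )
        )
    if dropped:
        logger.info("dropped %d sites monomorphic after resampling", dropped)
    return out, dropped


def high_frequency_changes(
    variants: list[VariantRecord], threshold: float = 0.20
) -> list[AminoAcidChange]:
    """Extract amino-acid changes segregating strictly above ``threshold``.

    Only nonsynonymous variants qualify; a qualifying variant without an
    amino-acid annotation is an error. Frequency is the alternate
    (amino-acid-changing) allele frequency, not the folded minor-allele
    frequency.
    """
    out = []
    for v in variants:
        if v.consequence != "nonsynonymous":
            continue
        freq = v.alt_frequency()
        if freq > threshold:
            if v.aa_change is None:
                raise ValueError(
                    f"nonsynonymous variant at {v.chrom}:{v.pos} lacks aa annotation"
                )
            ref_aa, alt_aa, pos = v.aa_change
            out.append(
                AminoAcidChange(
                    gene_id=v.gene_id or ".",
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    protein_pos=pos,
                    frequency=freq,
                )
            )
    return out


def flag_rare_changes(
    changes: list[AminoAcidChange],
) -> tuple[list[AminoAcidChange], int]:
    """Score changes with PAM250 and flag the rare ones (score < 0).

    Returns the scored list (rare flags set in place) and the number rare.
    """
    n_rare = 0
    for c in changes:
        c.pam250_score = pam250_score(c.ref_aa, c.alt_aa)
        c.rare = c.pam250_score < 0
        n_rare += c.rare
    return changes, n_rare


def load_high_frequency_change_table() -> list[AminoAcidChange]:
    """Load the bundled panel of 21 observed high-frequency changes.

    These are the amino-acid replacements segregating above 20% frequency
    in the surveyed human NAD metabolic enzymes, shipped as package data so
    the screening stage can be exercised without the source variant panel.
    """
    text = (
        resources.files("nadsel")
        .joinpath("data/high_freq_changes.tsv")
        .read_text()
    )
    out = []
    for ln in text.splitlines()[1:]:
        if not ln.strip():
            continue
        gene, ref_aa, alt_aa, pos, freq = ln.split("\t")
        out.append(
            AminoAcidChange(
                gene_id=gene,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                protein_pos=int(pos),
                frequency=float(freq),
            )
        )
    return out


def write_change_table(changes: list[AminoAcidChange], path) -> None:
    with open(path, "w") as fh:
        fh.write("enzyme\tchange\tposition\tfrequency\tpam250\trare\n")
        for c in changes:
            fh.write(
                f"{c.gene_id}\t{c.ref_aa}<->{c.alt_aa}\t{c.protein_pos}\t"
                f"{c.frequency}\t{c.pam250_score}\t{int(bool(c.rare))}\n"
            )
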