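"""Synthetic data generators mirroring the statistical structure of the inputs.

Every downstream stage of the pipeline can be exercised and calibrated on
data produced here: codon alignments evolved under GY94 site-class
mixtures on a fixed tree (with truth labels), per-gene Poisson
polymorphism/divergence counts for two enzyme groups, neutral Kingman
coalescent samples with infinite-sites mutations and an ancestral-state
outgroup, sweep-distorted site frequency spectra, and Balding-Nichols
structured allele frequencies at a target Fst. All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codonmodels import (
    N_CODONS,
    _ClassPropagator,
    build_gy94_rate_matrix,
)
from .divcounts import GeneCounts
from .popscan import SiteFrequencySpectrum
from .seqio import SENSE_CODONS, CodonAlignment, PhyloTree, VariantRecord


# ---------------------------------------------------------------------------
# Codon alignments under GY94 site-class mixtures


def simulate_codon_alignment(
    tree: PhyloTree,
    kappa: float,
    site_classes: list[tuple[float, float]],
    n_codons: int,
    seed: int,
    codon_frequencies: np.ndarray | None = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment down a tree under an omega mixture.

    ``site_classes`` lists (omega, proportion) pairs; each site draws a
    class, a root codon from the stationary frequencies, and then evolves
    along every branch with GY94 transition probabilities. Class rate
    matrices share a single mixture-average scaling so branch lengths mean
    expected substitutions per codon. Returns the alignment and the true
    per-site class labels for recovery tests.
    """
    rng = np.random.default_rng(seed)
    omegas = np.array([w for w, _ in site_classes])
    props = np.array([p for _, p in site_classes])
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("class proportions must sum to 1")
    pi = (
        np.asarray(codon_frequencies, float)
        if codon_frequencies is not None
        else np.full(N_CODONS, 1.0 / N_CODONS)
    )
    Qs = [build_gy94_rate_matrix(kappa, w, pi, scale=False) for w in omegas]
    rates = np.array([-np.dot(pi, np.diag(Q)) for Q in Qs])
    mean_rate = float(np.dot(props, rates))
    props_cum = np.cumsum(props)
    propagators = [_ClassPropagator(Q / mean_rate, pi) for Q in Qs]

    labels = np.searchsorted(props_cum, rng.random(n_codons))
    root_states = rng.choice(N_CODONS, size=n_codons, p=pi)

    edges = tree.postorder_edges()
    # simulate preorder: parents before children
    states: dict[int, np.ndarray] = {edges[-1][0]: root_states}
    leaf_rows: dict[str, np.ndarray] = {}
    for nid, pid, length, label in reversed(edges):
        if pid == -1:
            if label is not None:
                leaf_rows[label] = states[nid]
            continue
        t = length if length is not None else 0.0
        parent_states = states[pid]
        child_states = np.empty(n_codons, dtype=int)
        if t <= 0:
            child_states[:] = parent_states
        else:
            Ps = [prop.transition_matrix(t) for prop in propagators]
            for k, P in enumerate(Ps):
                mask = labels == k
                if not np.any(mask):
                    continue
                # row-normalize to absorb numerical truncation
                rows = P[parent_states[mask]]
                rows = rows / rows.sum(axis=1, keepdims=True)
                u = rng.random(mask.sum())
                child_states[mask] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[nid] = child_states
        if label is not None:
            leaf_rows[label] = child_states

    codon_arr = np.array(SENSE_CODONS)
    ids = [lf for lf in tree.leaf_labels]
    mat = np.array([codon_arr[leaf_rows[sid]] for sid in ids], dtype="<U3")
    return CodonAlignment(sequence_ids=ids, codons=mat), labels


def symmetric_tree_newick(n_taxa: int, branch_length: float) -> str:
    """Balanced-ish Newick tree over taxa T1..Tn with equal branch lengths."""
    labels = [f"T{i + 1}" for i in range(n_taxa)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{labels[lo]}:{branch_length}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch_length}"

    inner = build(0, n_taxa)
    # strip the root's own branch length
    return inner.rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# Per-gene Poisson counts for two enzyme groups


@dataclass
class GroupRates:
    """Expected per-gene Poisson rates of the four count classes."""

    pn: float
    ps: float
    dn: float
    ds: float


def simulate_gene_counts(
    n_genes_per_group: int,
    rates: dict[str, GroupRates],
    seed: int,
) -> list[GeneCounts]:
    """Draw independent Poisson Pn/Ps/Dn/Ds per gene at group rates.

    Pooled expected ratios equal the corresponding rate ratios, so planted
    group differences are set directly through ``rates``.
    """
    rng = np.random.default_rng(seed)
    genes = []
    for group in ("biosynthetic", "degrading"):
        r = rates[group]
        for i in range(n_genes_per_group):
            genes.append(
                GeneCounts(
                    gene_id=f"{group[:3].upper()}{i + 1:03d}",
                    group=group,
                    Pn=int(rng.poisson(r.pn)),
                    Ps=int(rng.poisson(r.ps)),
                    Dn=float(rng.poisson(r.dn)),
                    Ds=float(rng.poisson(r.ds)),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Neutral coalescent with infinite-sites mutations


def simulate_neutral_coalescent(
    n_chromosomes: int,
    theta: float,
    seed: int,
    region_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kingman coalescent sample under the infinite-sites model.

    Coalescence times are exponential with rate C(k,2) (time in units of
    2N generations for a scaled mutation rate theta = 4N mu); mutations
    fall on branches as a Poisson process with rate theta/2 per unit time.
    Each mutation creates a new segregating site; the outgroup carries the
    ancestral state everywhere.

    Returns (haplotypes, outgroup, positions): a (n, S) 0/1 matrix with 1
    the derived allele, an all-zero outgroup row of length S, and sorted
    site positions uniform on [0, 1) (scaled by ``region_length`` if given).
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    n = n_chromosomes
    # trace lineage membership: each active lineage carries its descendant tips
    lineages: list[list[int]] = [[i] for i in range(n)]
    carriers: list[list[int]] = []  # per mutation, the tips carrying it
    k = n
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        # mutations on the k active branches during this interval
        for lin in lineages:
            n_mut = rng.poisson(theta / 2.0 * t)
            carriers.extend([list(lin)] * n_mut)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = sorted((i, j))
        merged = lineages[a] + lineages[b]
        lineages = [l for idx, l in enumerate(lineages) if idx not in (a, b)]
        lineages.append(merged)
        k -= 1
    S = len(carriers)
    haplotypes = np.zeros((n, S), dtype=np.int8)
    for s, tips in enumerate(carriers):
        haplotypes[tips, s] = 1
    positions = np.sort(rng.random(S))
    if region_length is not None:
        positions = np.unique((positions * region_length).astype(int))[: S]
        # re-pad if uniqueness dropped sites: positions only label sites
        if len(positions) < S:
            positions = np.arange(S)
    outgroup = np.zeros(S, dtype=np.int8)
    return haplotypes, outgroup, positions


def sfs_from_haplotypes(haplotypes: np.ndarray) -> SiteFrequencySpectrum:
    """Fold a 0/1 haplotype matrix (derived = 1) into a polarized SFS."""
    n = haplotypes.shape[0]
    derived = haplotypes.sum(axis=0)
    counts = np.zeros(n)
    for d in derived:
        if 0 < d < n:
            counts[d] += 1
    return SiteFrequencySpectrum(n=n, counts=counts)


# ---------------------------------------------------------------------------
# Sweep-distorted site frequency spectra


def simulate_sweep_sfs(
    n: int, theta: float, distortion: float, seed: int
) -> SiteFrequencySpectrum:
    """SFS from a mixture of the neutral spectrum and a high-frequency bump.

    With probability 1 - distortion a segregating site draws its derived
    count from the neutral 1/i spectrum; with probability ``distortion``
    from a mirrored 1/(n - i) component concentrated at high frequencies —
    the footprint of hitchhiking with recombination. distortion = 0
    reduces exactly to the neutral spectrum.
    """
    if distortion < 0 or distortion > 1:
        raise ValueError("distortion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n)
    neutral = (1.0 / i) / np.sum(1.0 / i)
    high = (1.0 / (n - i)) / np.sum(1.0 / (n - i))
    mix = (1 - distortion) * neutral + distortion * high
    a_n = float(np.sum(1.0 / i))
    S = rng.poisson(theta * a_n)
    counts = np.zeros(n)
    if S > 0:
        draws = rng.choice(i, size=S, p=mix)
        for d in draws:
            counts[d] += 1
    return SiteFrequencySpectrum(n=n, counts=counts)


# ---------------------------------------------------------------------------
# Balding-Nichols structured allele frequencies


def simulate_structured_freqs(
    n_pops: int,
    n_sites: int,
    target_fst: float,
    sample_size_per_pop: int,
    seed: int,
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9),
    chrom: str = "sim",
) -> list[VariantRecord]:
    """Variant table with Balding-Nichols population structure.

    Per site an ancestral frequency p is drawn uniform on
    ``ancestral_freq_range``; each population's frequency is
    Beta(p (1-F)/F, (1-p)(1-F)/F) with F the target Fst, and allele counts
    are binomial at the stated sample sizes. The outgroup carries the
    reference (ancestral) allele.
    """
    if not 0 < target_fst < 1:
        raise ValueError("target_fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pops = [f"POP{i + 1}" for i in range(n_pops)]
    lam = (1.0 - target_fst) / target_fst
    records = []
    for s in range(n_sites):
        p = rng.uniform(*ancestral_freq_range)
        pop_freqs = rng.beta(p * lam, (1 - p) * lam, size=n_pops)
        counts = rng.binomial(sample_size_per_pop, pop_freqs)
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=s + 1,
                ref_allele="A",
                alt_allele="G",
                per_pop_alt_counts={
                    pop: (int(c), sample_size_per_pop)
                    for pop, c in zip(pops, counts)
                },
                outgroup_allele="A",
                consequence="noncoding",
            )
        )
    return records
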