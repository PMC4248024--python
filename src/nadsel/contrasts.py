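"""Two-group contrasts of diversity and divergence, MK and enrichment tests.

The two enzyme groups (NAD biosynthetic vs NAD degrading) are compared on
pooled ratios: counts are summed across the genes of a group before the
ratio is formed, so genes with few synonymous events do not produce wild
per-gene ratios. Significance of the group difference comes from a label
permutation test. The McDonald-Kreitman test contrasts divergence against
polymorphism in a 2x2 Fisher exact test; domain enrichment and the
positive-selection excess use Fisher exact and binomial upper-tail tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .divcounts import GeneCounts

GROUP_A = "biosynthetic"
GROUP_B = "degrading"


@dataclass
class GroupContrast:
    group_a_ratio: float
    group_b_ratio: float
    statistic: float  # group_b_ratio - group_a_ratio
    p_value: float
    n_permutations: int
    seed: int
    kind: str


@dataclass
class MKResult:
    table: tuple[tuple[float, float], tuple[float, float]]  # [[Dn,Ds],[Pn,Ps]]
    odds_ratio: float
    p_value: float
    direction: str  # adaptive_excess | constraint_excess | none


class ZeroDenominatorError(ZeroDivisionError):
    """A pooled ratio denominator summed to zero."""


def pooled_ratio(genes: list[GeneCounts], group: str, kind: str) -> float:
    """Pooled group ratio: sum counts across the group's genes, then divide.

    ``kind`` selects diversity (sum Pn / sum Ps) or divergence
    (sum Dn / sum Ds).
    """
    members = [g for g in genes if g.group == group]
    if not members:
        raise ValueError(f"no genes with group {group!r}")
    if kind == "diversity":
        num = sum(g.Pn for g in members)
        den = sum(g.Ps for g in members)
    elif kind == "divergence":
        num = sum(g.Dn for g in members)
        den = sum(g.Ds for g in members)
    else:
        raise ValueError(f"kind must be diversity or divergence, got {kind!r}")
    if den == 0:
        raise ZeroDenominatorError(
            f"pooled {kind} denominator is zero for group {group!r}"
        )
    return num / den


def permutation_contrast(
    genes: list[GeneCounts],
    kind: str,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> GroupContrast:
    """Permutation test of the pooled-ratio difference between groups.

    Observed statistic: pooled ratio(degrading) - pooled ratio(biosynthetic).
    The null distribution shuffles group labels over genes keeping group
    sizes fixed; permutations producing a zero pooled denominator are
    redrawn. Two-sided p-value with the add-one convention
    (#{|null| >= |obs|} + 1) / (n_permutations + 1).
    """
    if seed is None:
        raise ValueError("a permutation seed is required for reproducibility")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    labels = np.array([g.group for g in genes])
    if set(labels) != {GROUP_A, GROUP_B}:
        raise ValueError("both group labels must be present")
    ra = pooled_ratio(genes, GROUP_A, kind)
    rb = pooled_ratio(genes, GROUP_B, kind)
    observed = rb - ra
    if kind == "diversity":
        num = np.array([g.Pn for g in genes], dtype=float)
        den = np.array([g.Ps for g in genes], dtype=float)
    else:
        num = np.array([g.Dn for g in genes], dtype=float)
        den = np.array([g.Ds for g in genes], dtype=float)
    is_b = labels == GROUP_B
    n_b = int(is_b.sum())
    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    exceed = 0
    n_resampled = 0
    done = 0
    while done < n_permutations:
        perm = rng.permutation(n_genes)
        b_idx = np.zeros(n_genes, dtype=bool)
        b_idx[perm[:n_b]] = True
        den_b = den[b_idx].sum()
        den_a = den[~b_idx].sum()
        if den_a == 0 or den_b == 0:
            n_resampled += 1
            if n_resampled > 100 * n_permutations:
                raise ZeroDenominatorError(
                    "could not draw permutations with nonzero pooled denominators"
                )
            continue
        null_stat = num[b_idx].sum() / den_b - num[~b_idx].sum() / den_a
        if abs(null_stat) >= abs(observed) - 1e-12:
            exceed += 1
        done += 1
    p = (exceed + 1) / (n_permutations + 1)
    return GroupContrast(
        group_a_ratio=ra,
        group_b_ratio=rb,
        statistic=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        kind=kind,
    )


def mk_test(Pn: float, Ps: float, Dn: float, Ds: float) -> MKResult:
    """McDonald-Kreitman test on the 2x2 table [[Dn, Ds], [Pn, Ps]].

    Two-sided Fisher exact probability under the hypergeometric null.
    The odds ratio is (Dn/Ds)/(Pn/Ps), with infinity allowed; direction
    reports which class of excess the table shows.
    """
    counts = [Dn, Ds, Pn, Ps]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    if all(c == 0 for c in counts):
        raise ValueError("all-zero MK table")
    table = np.array([[Dn, Ds], [Pn, Ps]])
    _, p = stats.fisher_exact(np.round(table).astype(int), alternative="two-sided")
    div = Dn / Ds if Ds > 0 else np.inf if Dn > 0 else np.nan
    poly = Pn / Ps if Ps > 0 else np.inf if Pn > 0 else np.nan
    if np.isnan(div) or np.isnan(poly) or div == poly:
        direction = "none"
    elif div > poly:
        direction = "adaptive_excess"
    else:
        direction = "constraint_excess"
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = float(np.float64(div) / np.float64(poly))
    return MKResult(
        table=((Dn, Ds), (Pn, Ps)),
        odds_ratio=float(odds),
        p_value=float(p),
        direction=direction,
    )


def fisher_domain_enrichment(
    selected_in_region: int,
    selected_total: int,
    region_sites: int,
    total_sites: int,
) -> float:
    """Fisher exact test for enrichment of selected sites inside a domain.

    Contrasts selected vs non-selected sites inside vs outside the region:
    [[sel_in, sel_out], [nonsel_in, nonsel_out]]. Two-sided.
    """
    if not 0 <= selected_in_region <= selected_total:
        raise ValueError("selected_in_region must be within [0, selected_total]")
    if not 0 <= region_sites <= total_sites:
        raise ValueError("region_sites must be within [0, total_sites]")
    sel_out = selected_total - selected_in_region
    nonsel_in = region_sites - selected_in_region
    nonsel_out = (total_sites - region_sites) - sel_out
    if nonsel_in < 0 or nonsel_out < 0:
        raise ValueError("inconsistent counts: more selected sites than sites")
    _, p = stats.fisher_exact(
        [[selected_in_region, sel_out], [nonsel_in, nonsel_out]],
        alternative="two-sided",
    )
    return float(p)


def binomial_excess_test(k: int, n: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p0).

    Used to ask whether k positively selected genes out of n exceeds a
    genome-wide background rate p0.
    """
    if not 0 <= k <= n:
        raise ValueError("k must be within [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p0))
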