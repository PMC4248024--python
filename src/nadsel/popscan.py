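"""Sliding-window population scans: Weir-Cockerham Fst and Fay & Wu's H.

The sweep scan rests on the polarized site frequency spectrum: with an
outgroup identifying the ancestral allele, an excess of high-frequency
derived variants relative to intermediate-frequency ones (negative Fay &
Wu's H) marks a recent selective sweep with recombination. Differentiation
between population samples is measured with the Weir-Cockerham (1984)
variance-components estimator, aggregated per window as a ratio of summed
components. Confidence envelopes come from repeated random subsamples of
individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seqio import VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class SiteFrequencySpectrum:
    """Polarized derived-allele count spectrum for n sampled chromosomes.

    ``counts[i]`` for i = 1..n-1 is the number of segregating sites whose
    derived allele appears i times (index 0 unused).
    """

    n: int
    counts: np.ndarray  # length n, counts[0] ignored, counts[i] = S_i
    polarized: bool = True
    sites_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if not self.polarized:
            raise ValueError("only polarized spectra are supported")
        if self.counts.shape != (self.n,):
            raise ValueError(f"counts must have length n = {self.n}")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be nonnegative")

    @property
    def segregating_sites(self) -> float:
        return float(self.counts[1:].sum())


@dataclass
class WindowStat:
    chrom: str
    start: int  # 0-based half-open
    end: int
    statistic_name: str
    value: float  # nan when undefined
    env_low: float = float("nan")
    env_high: float = float("nan")
    n_variants: int = 0
    partial: bool = False


def polarized_sfs(
    variants: list[VariantRecord],
    population: str,
    region: tuple[int, int] | None = None,
    sample_size: int | None = None,
) -> SiteFrequencySpectrum:
    """Build the derived-allele SFS for one population.

    The derived allele at a site is whichever of ref/alt differs from the
    outgroup allele; sites with a missing outgroup, an outgroup matching
    neither allele, or a sample size different from the spectrum's n are
    dropped and counted. ``region`` is 0-based half-open on ``pos - 1``.
    """
    usable = []
    dropped = 0
    for v in variants:
        if region is not None and not (region[0] <= v.pos - 1 < region[1]):
            continue
        ac, an = v.per_pop_alt_counts[population]
        if v.outgroup_allele is None or v.outgroup_allele not in (
            v.ref_allele,
            v.alt_allele,
        ):
            dropped += 1
            continue
        derived = ac if v.outgroup_allele == v.ref_allele else an - ac
        usable.append((derived, an))
    if not usable:
        raise ValueError("no usable polarized sites in region")
    n = sample_size if sample_size is not None else usable[0][1]
    counts = np.zeros(n)
    for derived, an in usable:
        if an != n:
            dropped += 1
            continue
        if 0 < derived < n:
            counts[derived] += 1
    return SiteFrequencySpectrum(n=n, counts=counts, sites_dropped=dropped)


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def theta_estimators(sfs: SiteFrequencySpectrum) -> tuple[float, float, float, float]:
    """SFS-weighted estimators of the population mutation rate theta.

    Returns (theta_pi, theta_H, theta_L, theta_W):
    pairwise diversity, the high-frequency-weighted estimator of Fay & Wu,
    the linear-weighted estimator, and Watterson's estimator.
    """
    n = sfs.n
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    i = np.arange(1, n)
    S_i = sfs.counts[1:n]
    theta_pi = float(np.sum(2.0 * i * (n - i) * S_i) / (n * (n - 1)))
    theta_H = float(np.sum(2.0 * i**2 * S_i) / (n * (n - 1)))
    theta_L = float(np.sum(i * S_i) / (n - 1))
    theta_W = float(S_i.sum() / _harmonic(n))
    return theta_pi, theta_H, theta_L, theta_W


def fay_wu_H(sfs: SiteFrequencySpectrum) -> tuple[float, float]:
    """Fay & Wu's H: raw (theta_pi - theta_H) and the normalized form.

    The normalized statistic divides theta_pi - theta_L by its standard
    deviation under neutrality, with theta and theta^2 estimated from the
    number of segregating sites (the convention of the DH framework).
    Returns (H_raw, H_normalized); the normalized value is nan when the
    variance estimate is not positive.
    """
    n = sfs.n
    theta_pi, theta_H, theta_L, _ = theta_estimators(sfs)
    H_raw = theta_pi - theta_H
    S = sfs.segregating_sites
    a_n = _harmonic(n)
    b_n = _harmonic(n, 2)
    b_n1 = b_n + 1.0 / n**2  # sum_{i=1}^{n} 1/i^2
    theta = S / a_n
    theta_sq = S * (S - 1) / (a_n**2 + b_n)
    var = (
        (n - 2) / (6.0 * (n - 1)) * theta
        + (
            18.0 * n**2 * (3.0 * n + 2.0) * b_n1
            - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
        )
        / (9.0 * n * (n - 1) ** 2)
        * theta_sq
    )
    if var <= 0:
        return H_raw, float("nan")
    return H_raw, (theta_pi - theta_L) / np.sqrt(var)


def zeng_E(sfs: SiteFrequencySpectrum) -> tuple[float, float]:
    """Zeng et al.'s E: theta_L - theta_W, raw and normalized."""
    n = sfs.n
    _, _, theta_L, theta_W = theta_estimators(sfs)
    E_raw = theta_L - theta_W
    S = sfs.segregating_sites
    a_n = _harmonic(n)
    b_n = _harmonic(n, 2)
    theta = S / a_n
    theta_sq = S * (S - 1) / (a_n**2 + b_n)
    var = (
        (n / (2.0 * (n - 1)) - 1.0 / a_n) * theta
        + (
            b_n / a_n**2
            + 2.0 * (n / (n - 1.0)) ** 2 * b_n
            - 2.0 * (n * b_n - n + 1.0) / ((n - 1.0) * a_n)
            - (3.0 * n + 1.0) / (n - 1.0)
        )
        * theta_sq
    )
    if var <= 0:
        return E_raw, float("nan")
    return E_raw, E_raw / np.sqrt(var)


def wc_fst(
    variants: list[VariantRecord],
    populations: list[str],
    region: tuple[int, int] | None = None,
) -> float:
    """Weir-Cockerham Fst over the sites of a region (ratio of sums).

    Per site, the among-population (a) and within-population (b) variance
    components are computed from the per-population allele counts; the
    multi-site estimate is sum(a) / sum(a + b). Returns nan when the region
    is monomorphic (undefined rather than zero).
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    num = den = 0.0
    informative = False
    for v in variants:
        if region is not None and not (region[0] <= v.pos - 1 < region[1]):
            continue
        acs = np.array([v.per_pop_alt_counts[p][0] for p in populations], float)
        ans = np.array([v.per_pop_alt_counts[p][1] for p in populations], float)
        if np.any(ans < 2):
            continue
        p_i = acs / ans
        if np.all(acs == 0) or np.all(acs == ans):
            continue  # monomorphic across the sample
        informative = True
        r = len(populations)
        n_bar = ans.mean()
        n_c = (r * n_bar - np.sum(ans**2) / (r * n_bar)) / (r - 1)
        p_bar = np.sum(ans * p_i) / (r * n_bar)
        s2 = np.sum(ans * (p_i - p_bar) ** 2) / ((r - 1) * n_bar)
        # allele-count (haploid-sample) form: heterozygosity term absent
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r)
        num += a
        den += a + b
    if not informative or den == 0:
        return float("nan")
    return num / den


_STATISTICS = ("fst", "fay_wu_H", "zeng_E")


def _window_statistic(
    statistic: str,
    variants: list[VariantRecord],
    populations: list[str],
    window: tuple[int, int],
) -> float:
    try:
        if statistic == "fst":
            return wc_fst(variants, populations, region=window)
        sfs = polarized_sfs(variants, populations[0], region=window)
        if statistic == "fay_wu_H":
            return fay_wu_H(sfs)[0]
        return zeng_E(sfs)[0]
    except ValueError:
        return float("nan")


def sliding_scan(
    variants: list[VariantRecord],
    populations: list[str],
    region: tuple[int, int],
    window_bp: int,
    step_bp: int,
    statistic: str,
    chrom: str = ".",
) -> list[WindowStat]:
    """Overlapping sliding-window scan of a statistic over a region.

    Windows start every ``step_bp`` from region start; a final partial
    window is kept (flagged) when the full windows do not reach the region
    end. A region shorter than the window yields one window spanning the
    region. For ``fay_wu_H``/``zeng_E`` the first population listed is
    scanned.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    if not (window_bp >= step_bp > 0):
        raise ValueError("need window >= step > 0")
    start, end = region
    if start >= end:
        raise ValueError("empty region")
    windows: list[tuple[int, int, bool]] = []
    if end - start <= window_bp:
        windows.append((start, end, end - start < window_bp))
    else:
        s = start
        while s + window_bp <= end:
            windows.append((s, s + window_bp, False))
            s += step_bp
        last_full_end = windows[-1][1]
        if last_full_end < end:
            windows.append((s, end, True))
    out = []
    for ws, we, partial in windows:
        in_win = [v for v in variants if ws <= v.pos - 1 < we]
        value = (
            _window_statistic(statistic, in_win, populations, (ws, we))
            if in_win
            else float("nan")
        )
        out.append(
            WindowStat(
                chrom=chrom,
                start=ws,
                end=we,
                statistic_name=statistic,
                value=value,
                n_variants=len(in_win),
                partial=partial,
            )
        )
    return out


def _subsample_counts(
    variants: list[VariantRecord],
    populations: list[str],
    pop_individuals: dict[str, int],
    chosen: dict[str, int],
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Resample per-site allele counts for a chosen subset of individuals.

    Individuals contribute both chromosomes; with aggregate counts as input
    the per-site alt count in population p follows a hypergeometric draw of
    2 * chosen[p] alleles from that population's sampled alleles.
    """
    out = []
    for v in variants:
        new_counts = {}
        for p in populations:
            ac, an = v.per_pop_alt_counts[p]
            m = 2 * chosen[p]
            new_counts[p] = (int(rng.hypergeometric(ac, an - ac, m)) if m else 0, m)
        out.append(
            VariantRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref_allele=v.ref_allele,
                alt_allele=v.alt_allele,
                per_pop_alt_counts=new_counts,
                outgroup_allele=v.outgroup_allele,
                consequence=v.consequence,
                aa_change=v.aa_change,
                gene_id=v.gene_id,
            )
        )
    return out


def subsample_envelope(
    variants: list[VariantRecord],
    populations: list[str],
    region: tuple[int, int],
    windows: list[WindowStat],
    pop_individuals: dict[str, int],
    n_subsamples: int = 100,
    subsample_size: int = 546,
    seed: int | None = None,
) -> list[WindowStat]:
    """Min/max envelope of a window statistic over random individual subsets.

    Each subsample draws ``subsample_size`` individuals without replacement
    from the pooled panel, individuals keeping their population labels
    (per-population subsample sizes are multivariate hypergeometric); a
    draw leaving a population empty is redrawn and logged. Returns new
    WindowStat objects with env_low/env_high filled in.
    """
    if seed is None:
        raise ValueError("a subsampling seed is required for reproducibility")
    total = sum(pop_individuals[p] for p in populations)
    if total < subsample_size:
        raise ValueError(
            f"panel has {total} individuals < subsample size {subsample_size}"
        )
    rng = np.random.default_rng(seed)
    sizes = np.array([pop_individuals[p] for p in populations])
    stat = windows[0].statistic_name
    lows = np.full(len(windows), np.inf)
    highs = np.full(len(windows), -np.inf)
    n_redrawn = 0
    for _ in range(n_subsamples):
        while True:
            chosen_arr = rng.multivariate_hypergeometric(sizes, subsample_size)
            if subsample_size < total and np.any(chosen_arr == 0):
                n_redrawn += 1
                continue
            break
        chosen = dict(zip(populations, (int(c) for c in chosen_arr)))
        if subsample_size == total:
            sub = variants
        else:
            sub = _subsample_counts(variants, populations, pop_individuals, chosen, rng)
        for w_idx, w in enumerate(windows):
            in_win = [v for v in sub if w.start <= v.pos - 1 < w.end]
            val = (
                _window_statistic(stat, in_win, populations, (w.start, w.end))
                if in_win
                else float("nan")
            )
            if np.isfinite(val):
                lows[w_idx] = min(lows[w_idx], val)
                highs[w_idx] = max(highs[w_idx], val)
    if n_redrawn:
        logger.info("redrew %d subsamples leaving a population empty", n_redrawn)
    out = []
    for w_idx, w in enumerate(windows):
        out.append(
            WindowStat(
                chrom=w.chrom,
                start=w.start,
                end=w.end,
                statistic_name=w.statistic_name,
                value=w.value,
                env_low=float(lows[w_idx]) if np.isfinite(lows[w_idx]) else float("nan"),
                env_high=float(highs[w_idx]) if np.isfinite(highs[w_idx]) else float("nan"),
                n_variants=w.n_variants,
                partial=w.partial,
            )
        )
    return out


def write_window_stats(windows: list[WindowStat], path) -> None:
    """BED-like TSV: chrom, start, end, stat, value, env_low, env_high, n."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstatistic\tvalue\tenv_low\tenv_high\tn_variants\tpartial\n")
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.statistic_name}\t"
                f"{w.value:.6g}\t{w.env_low:.6g}\t{w.env_high:.6g}\t"
                f"{w.n_variants}\t{int(w.partial)}\n"
            )
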