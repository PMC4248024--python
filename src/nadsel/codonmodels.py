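"""GY94 codon substitution models: M0 one-ratio and the M1a/M2a site models.

The model object / results object split follows the statsmodels idiom:
:class:`CodonSiteModel` binds a codon alignment to a phylogeny and a model
family; :meth:`CodonSiteModel.fit` maximizes the likelihood over kappa, the
omega site classes and their proportions, and all branch lengths, and
returns a :class:`CodonSiteModelResults` carrying the estimates, per-site
class likelihoods, and diagnostics.

Model family
------------
The Goldman-Yang codon rate matrix assigns, to a single-nucleotide codon
change i -> j, the rate pi_j multiplied by kappa for transitions and by
omega for nonsynonymous changes; multi-position changes have rate zero.
M0 fits one omega for all sites. M1a mixes a purifying class
(0 <= omega0 < 1) with a neutral class (omega1 = 1); M2a adds a positive
selection class (omega2 >= 1). M1a vs M2a is compared by a likelihood
ratio test with 2 degrees of freedom; sites driving a significant M2a fit
are identified by Naive Empirical Bayes posteriors for the omega2 class.

Likelihoods are computed by Felsenstein pruning with per-node rescaling.
Codon frequencies default to the F3x4 empirical estimate from the
alignment. Branch lengths are expected substitutions per codon, averaged
over site classes (the class matrices share one mixture-level scaling
factor).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.special import expit, logsumexp

from .seqio import (
    CODON_INDEX,
    NUCLEOTIDES,
    SENSE_CODONS,
    CodonAlignment,
    PhyloTree,
    translate_codon,
)

N_CODONS = len(SENSE_CODONS)  # 61

# Precomputed single-change structure of the sense-codon graph:
# index pairs (i, j), transition flag, synonymous flag.
_PAIR_I: list[int] = []
_PAIR_J: list[int] = []
_PAIR_TS: list[bool] = []
_PAIR_SYN: list[bool] = []
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
for _i, _c1 in enumerate(SENSE_CODONS):
    for _j, _c2 in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [(a, b) for a, b in zip(_c1, _c2) if a != b]
        if len(diffs) != 1:
            continue
        _PAIR_I.append(_i)
        _PAIR_J.append(_j)
        _PAIR_TS.append(diffs[0] in _TRANSITIONS)
        _PAIR_SYN.append(translate_codon(_c1) == translate_codon(_c2))
PAIR_I = np.array(_PAIR_I)
PAIR_J = np.array(_PAIR_J)
PAIR_TS = np.array(_PAIR_TS)
PAIR_SYN = np.array(_PAIR_SYN)


def f3x4_frequencies(aln: CodonAlignment, pseudocount: float = 1.0) -> np.ndarray:
    """F3x4 codon frequencies: position-specific nucleotide frequencies.

    Nucleotide frequencies are tallied separately for the three codon
    positions (gaps/Ns ignored), combined multiplicatively, zeroed on stop
    codons and renormalized over the 61 sense codons. A pseudocount keeps
    every sense codon at positive frequency even on small alignments.
    """
    counts = np.full((3, 4), pseudocount, dtype=float)
    nt_idx = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for row in aln.codons:
        for codon in row:
            for pos, base in enumerate(codon):
                if base in nt_idx:
                    counts[pos, nt_idx[base]] += 1
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos_freqs[0, nt_idx[c[0]]]
            * pos_freqs[1, nt_idx[c[1]]]
            * pos_freqs[2, nt_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return freqs / freqs.sum()


def build_gy94_rate_matrix(
    kappa: float, omega: float, codon_frequencies: np.ndarray, scale: bool = True
) -> np.ndarray:
    """Build the 61x61 GY94 instantaneous rate matrix.

    Entry (i, j) for a single-position change is pi_j, multiplied by kappa
    for transitions and omega for nonsynonymous changes; other off-diagonal
    entries are 0 and rows sum to 0. With ``scale`` the matrix is scaled so
    the expected substitution rate at stationarity is 1 (branch lengths are
    then expected substitutions per codon).
    """
    pi = np.asarray(codon_frequencies, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"expected {N_CODONS} codon frequencies")
    if np.any(pi <= 0):
        raise ValueError("all sense-codon frequencies must be positive "
                         "(zero frequency makes the rate matrix reducible)")
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("codon frequencies must sum to 1")
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be nonnegative")
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[PAIR_J] * np.where(PAIR_TS, kappa, 1.0) * np.where(PAIR_SYN, 1.0, omega)
    Q[PAIR_I, PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mean_rate = -np.dot(pi, np.diag(Q))
        if mean_rate > 0:
            Q /= mean_rate
    return Q


class _ClassPropagator:
    """Eigendecomposition of one scaled class matrix in pi-symmetric space.

    The GY94 matrix is reversible, so D^{1/2} Q D^{-1/2} (D = diag(pi)) is
    symmetric; one eigh per parameter set then yields P(t) for every branch
    with two small matrix products.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]
        S = (S + S.T) / 2  # symmetrize numerical noise
        self.evals, V = linalg.eigh(S)
        self.left = V / sq[:, None] * 1.0  # D^{-1/2} V
        self.right = (V * sq[:, None]).T  # V.T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.evals * t)) @ self.right
        np.maximum(P, 0.0, out=P)
        return P


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) computed through the reversible eigendecomposition."""
    return _ClassPropagator(Q, pi).transition_matrix(t)


@dataclass
class SiteSelectionCall:
    """A codon site called as evolving under positive selection."""

    site_index: int  # 0-based codon column in the fitted alignment
    posterior_w_gt_1: float
    reference_residue_position: int  # 1-based in the ungapped reference protein


MODELS = ("M0", "M1a", "M2a")


class CodonSiteModel:
    """GY94 codon model bound to an alignment and a tree.

    Parameters
    ----------
    alignment : CodonAlignment
        Masked codon alignment (no gaps or Ns in fitted columns; residual
        ambiguous cells are treated as missing data).
    tree : PhyloTree
        Phylogeny over the alignment's sequences. Branch lengths, if
        present, seed the optimizer; they are re-estimated.
    model : str
        One of "M0", "M1a", "M2a".
    codon_frequencies : array, optional
        Stationary sense-codon frequencies; defaults to F3x4 from the
        alignment.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        model: str = "M0",
        codon_frequencies: np.ndarray | None = None,
    ):
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if model != "M0" and alignment.n_sequences < 3:
            raise ValueError("site models need at least 3 sequences")
        tree.validate_against(alignment)
        self.model = model
        self.alignment = alignment
        self.tree = tree
        self.pi = (
            np.asarray(codon_frequencies, float)
            if codon_frequencies is not None
            else f3x4_frequencies(alignment)
        )
        self._edges = tree.postorder_edges()
        self._n_nodes = len(self._edges)
        # edge index for every non-root node, in postorder
        self._edge_of_node = {nid: k for k, (nid, pid, _, _) in
                              enumerate(e for e in self._edges if e[1] != -1)}
        self._n_edges = len(self._edge_of_node)
        self._leaf_states = self._encode_leaves()
        self.data_fingerprint = hashlib.sha256(
            ("|".join(alignment.sequence_ids) + "|" +
             "|".join("".join(r) for r in alignment.codons)).encode()
        ).hexdigest()[:16]

    # -- data encoding ------------------------------------------------------

    def _encode_leaves(self) -> dict[int, np.ndarray]:
        """Per-leaf integer codon states; -1 marks missing/ambiguous cells."""
        states = {}
        for nid, _, _, label in self._edges:
            if label is None:
                continue
            row = self.alignment.row(label)
            states[nid] = np.array(
                [CODON_INDEX.get(c, -1) for c in row], dtype=int
            )
        return states

    def branch_lengths_from_tree(self) -> np.ndarray:
        """Branch-length vector in the engine's edge order, from the tree."""
        b = np.empty(self._n_edges)
        for nid, pid, length, _ in self._edges:
            if pid == -1:
                continue
            b[self._edge_of_node[nid]] = length if length else 0.0
        return b

    # -- parameterization ---------------------------------------------------

    def _n_params(self) -> int:
        extra = {"M0": 2, "M1a": 3, "M2a": 6}[self.model]
        return self._n_edges + extra

    def _unpack(self, x: np.ndarray):
        """Transform the unconstrained vector into model parameters."""
        b = np.exp(x[: self._n_edges])
        kappa = float(np.exp(x[self._n_edges]))
        rest = x[self._n_edges + 1 :]
        if self.model == "M0":
            omegas = np.array([np.exp(rest[0])])
            props = np.array([1.0])
        elif self.model == "M1a":
            w0 = float(expit(rest[0]))
            p0 = float(expit(rest[1]))
            omegas = np.array([w0, 1.0])
            props = np.array([p0, 1.0 - p0])
        else:  # M2a
            w0 = float(expit(rest[0]))
            w2 = 1.0 + float(np.exp(rest[1]))
            s1 = float(expit(rest[2]))
            s2 = float(expit(rest[3]))
            omegas = np.array([w0, 1.0, w2])
            props = np.array([s1, (1 - s1) * s2, (1 - s1) * (1 - s2)])
        return b, kappa, omegas, props

    def _initial_vector(self, rng: np.random.Generator, jitter: float) -> np.ndarray:
        b0 = []
        for nid, pid, length, _ in self._edges:
            if pid == -1:
                continue
            b0.append(length if length and length > 0 else 0.1)
        x = np.concatenate(
            [
                np.log(b0),
                [np.log(2.0)],  # kappa
                {
                    "M0": [np.log(0.5)],
                    "M1a": [0.0, 0.0],  # w0 = 0.5, p0 = 0.5
                    "M2a": [0.0, np.log(1.0), 0.0, 0.0],  # w2 = 2
                }[self.model],
            ]
        )
        return x + rng.normal(0.0, jitter, size=x.size)

    # -- likelihood ---------------------------------------------------------

    def _class_site_loglik(self, b, kappa, omegas, props) -> np.ndarray:
        """Per-class per-site conditional log-likelihoods, shape (K, S)."""
        # one mixture-level scaling so branch lengths average 1 sub/codon
        Qs = [build_gy94_rate_matrix(kappa, w, self.pi, scale=False) for w in omegas]
        rates = np.array([-np.dot(self.pi, np.diag(Q)) for Q in Qs])
        mean_rate = float(np.dot(props, rates))
        if mean_rate <= 0:
            raise FloatingPointError("degenerate rate matrix")
        out = np.empty((len(omegas), self.alignment.n_sites))
        for k, Q in enumerate(Qs):
            prop = _ClassPropagator(Q / mean_rate, self.pi)
            out[k] = self._prune(prop, b)
        return out

    def _prune(self, prop: _ClassPropagator, b: np.ndarray) -> np.ndarray:
        """Felsenstein pruning for one class; per-site log-likelihoods."""
        S = self.alignment.n_sites
        partial: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        children: dict[int, list[int]] = {}
        for nid, pid, _, _ in self._edges:
            children.setdefault(pid, []).append(nid)
        root = self._edges[-1][0]
        for nid, pid, _, label in self._edges:
            if label is not None:
                L = np.zeros((S, N_CODONS))
                st = self._leaf_states[nid]
                known = st >= 0
                L[known, st[known]] = 1.0
                L[~known] = 1.0
                partial[nid] = L
                logscale[nid] = np.zeros(S)
            else:
                L = np.ones((S, N_CODONS))
                sc = np.zeros(S)
                for child in children.get(nid, []):
                    t = b[self._edge_of_node[child]]
                    P = prop.transition_matrix(t)
                    L = L * (partial[child] @ P.T)
                    sc += logscale[child]
                    del partial[child], logscale[child]
                m = L.max(axis=1)
                m[m == 0] = 1.0
                partial[nid] = L / m[:, None]
                logscale[nid] = sc + np.log(m)
        site_like = partial[root] @ self.pi
        bad = site_like <= 0
        if np.any(bad):
            raise FloatingPointError(
                f"nonfinite site likelihood at codon column {int(np.flatnonzero(bad)[0])}"
            )
        return np.log(site_like) + logscale[root]

    def loglik(self, b, kappa, omegas, props) -> tuple[float, np.ndarray]:
        """Mixture log-likelihood and the (K, S) class log-likelihood array."""
        cls = self._class_site_loglik(b, kappa, omegas, props)
        with np.errstate(divide="ignore"):  # a class proportion may be 0
            site_ll = logsumexp(cls + np.log(props)[:, None], axis=0)
        return float(site_ll.sum()), cls

    def _objective(self, x: np.ndarray) -> float:
        try:
            b, kappa, omegas, props = self._unpack(x)
            ll, _ = self.loglik(b, kappa, omegas, props)
        except (FloatingPointError, linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_restarts: int = 3,
        seed: int = 0,
        maxiter: int = 500,
    ) -> "CodonSiteModelResults":
        """Maximize the likelihood; best of ``n_restarts`` jittered starts.

        Non-convergence after all restarts is reported through the
        ``converged`` flag on the results, not raised.
        """
        rng = np.random.default_rng(seed)
        best = None
        best_conv = False
        for r in range(n_restarts):
            x0 = self._initial_vector(rng, jitter=0.0 if r == 0 else 0.5)
            res = optimize.minimize(
                self._objective,
                x0,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
            )
            if best is None or res.fun < best.fun:
                best = res
                best_conv = bool(res.success)
        b, kappa, omegas, props = self._unpack(best.x)
        ll, cls = self.loglik(b, kappa, omegas, props)
        branch_lengths = {}
        for nid, pid, _, label in self._edges:
            if pid == -1:
                continue
            key = label if label is not None else f"node{nid}"
            branch_lengths[key] = float(b[self._edge_of_node[nid]])
        return CodonSiteModelResults(
            model=self.model,
            kappa=kappa,
            site_classes=[(float(w), float(p)) for w, p in zip(omegas, props)],
            branch_lengths=branch_lengths,
            lnL=ll,
            site_class_logliks=cls,
            converged=best_conv,
            n_restarts=n_restarts,
            data_fingerprint=self.data_fingerprint,
            _model_obj=self,
        )


@dataclass
class CodonSiteModelResults:
    """Fitted GY94 codon model: estimates, likelihoods, diagnostics."""

    model: str
    kappa: float
    site_classes: list[tuple[float, float]]  # (omega, proportion)
    branch_lengths: dict[str, float]
    lnL: float
    site_class_logliks: np.ndarray  # (K, S) conditional log-likelihoods
    converged: bool
    n_restarts: int
    data_fingerprint: str
    _model_obj: CodonSiteModel | None = field(default=None, repr=False)

    @property
    def omega(self) -> float:
        """Single omega for M0; for site models, the last class omega."""
        return self.site_classes[-1][0]

    @property
    def tree_length(self) -> float:
        return float(sum(self.branch_lengths.values()))

    def site_posteriors(self) -> np.ndarray:
        """NEB posterior class memberships, shape (K, S)."""
        logp = np.log([p for _, p in self.site_classes])[:, None]
        joint = self.site_class_logliks + logp
        return np.exp(joint - logsumexp(joint, axis=0, keepdims=True))

    def positive_sites(self, reference_id: str) -> list[SiteSelectionCall]:
        return neb_positive_sites(self, reference_id)

    def summary(self) -> str:
        lines = [
            f"GY94 codon model {self.model}",
            f"  lnL         {self.lnL:.4f}",
            f"  kappa       {self.kappa:.4f}",
            f"  tree length {self.tree_length:.4f} subs/codon",
            f"  converged   {self.converged} (restarts: {self.n_restarts})",
            "  site classes (omega, proportion):",
        ]
        for k, (w, p) in enumerate(self.site_classes):
            lines.append(f"    class {k}: omega = {w:.4f}  p = {p:.4f}")
        return "\n".join(lines)


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str,
    n_restarts: int = 3,
    seed: int = 0,
    **kwargs,
) -> CodonSiteModelResults:
    """Convenience wrapper: build a CodonSiteModel and fit it."""
    return CodonSiteModel(aln, tree, model=model).fit(
        n_restarts=n_restarts, seed=seed, **kwargs
    )


def site_model_lrt(
    null_fit: CodonSiteModelResults, alt_fit: CodonSiteModelResults
) -> tuple[float, float, int]:
    """Likelihood ratio test of M2a against M1a (2 degrees of freedom).

    Returns (statistic, p_value, df). The statistic 2*(lnL_alt - lnL_null)
    is clipped at zero; the chi-square(2) upper tail gives
    p = exp(-statistic / 2).
    """
    if null_fit.data_fingerprint != alt_fit.data_fingerprint:
        raise ValueError("fits were obtained on different data")
    stat = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    p = float(np.exp(-stat / 2.0))
    return stat, p, 2


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling the family-wise rate."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def neb_positive_sites(
    fit: CodonSiteModelResults, reference_id: str, min_posterior: float = 0.5
) -> list[SiteSelectionCall]:
    """Naive Empirical Bayes identification of omega > 1 sites.

    Posterior membership in the positive-selection class is the class
    prior times the site's conditional likelihood, normalized over classes.
    Sites with posterior above ``min_posterior`` are reported, mapped to
    1-based residue positions in the ungapped reference protein.
    """
    if fit.model != "M2a":
        raise ValueError("positive-site identification needs an M2a fit")
    if fit._model_obj is None:
        raise ValueError("results object is detached from its model/data")
    aln = fit._model_obj.alignment
    if reference_id not in aln.sequence_ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref_row = aln.row(reference_id)
    post = fit.site_posteriors()[-1]  # omega2 class
    calls = []
    residue = 0
    for j in range(aln.n_sites):
        if ref_row[j] != "---":
            residue += 1
        if post[j] > min_posterior:
            calls.append(
                SiteSelectionCall(
                    site_index=j,
                    posterior_w_gt_1=float(post[j]),
                    reference_residue_position=residue,
                )
            )
    return calls
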