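"""Goldman–Yang (GY94) codon-model likelihood on a fixed unrooted 4-taxon
tree, with one dN/dS (omega) per branch, and the omega=1 likelihood-ratio
test on a named branch.

The model is a 61-state continuous-time Markov chain over sense codons.
For codons i, j differing at exactly one position,

    q_ij ∝ pi_j · kappa^[transition] · omega^[nonsynonymous],

all multi-nucleotide changes are instantaneous-rate zero, and each branch's
generator is rescaled so one unit of branch length equals one expected
substitution per codon at equilibrium.  The chain is time-reversible, so
transition matrices are computed by eigendecomposition in the
pi^(1/2)-symmetrized basis, and the likelihood is evaluated by Felsenstein
pruning rooted (arbitrarily, by reversibility) at the internal node joining
the first two species.

Topology is fixed: ((sp1, sp2), sp3, sp4) unrooted — species 1 and 2 are
constrained sisters; branch keys are the four species names plus
"internal".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.stats import chi2

from .codon_core import GeneticCode, is_transition, normalize_codon
from .divergence import CodonAlignment

log = logging.getLogger(__name__)

INTERNAL = "internal"

_LOG_T_BOUNDS = (math.log(1e-6), math.log(20.0))
_LOG_K_BOUNDS = (math.log(1e-2), math.log(100.0))
_LOG_W_BOUNDS = (math.log(1e-6), math.log(100.0))

#: optimizer starting values for transition/transversion ratio and dN/dS
INIT_KAPPA = 2.0
INIT_OMEGA = 0.4


# ---------------------------------------------------------------------------
# code structure (cached per translation table)


@lru_cache(maxsize=None)
def _code_structure(table_id: int):
    """Sense codons and the single-step change structure of the code.

    Returns (codons, index, i_idx, j_idx, transition_mask, nonsyn_mask)
    where i_idx/j_idx list all ordered sense-codon pairs one nucleotide
    apart.
    """
    from .codon_core import get_code

    code = get_code(table_id)
    codons = code.sense_codons
    index = {c: k for k, c in enumerate(codons)}
    ii, jj, trans, nonsyn = [], [], [], []
    for a, ca in enumerate(codons):
        for b, cb in enumerate(codons):
            if a == b:
                continue
            diff = [p for p in range(3) if ca[p] != cb[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            ii.append(a)
            jj.append(b)
            trans.append(is_transition(ca[p], cb[p]))
            nonsyn.append(code.translate(ca) != code.translate(cb))
    return (codons, index,
            np.array(ii), np.array(jj),
            np.array(trans, dtype=bool), np.array(nonsyn, dtype=bool))


def sense_codons(code: GeneticCode) -> tuple:
    return _code_structure(code.table_id)[0]


# ---------------------------------------------------------------------------
# parameters and data containers


@dataclass
class CodonModelParams:
    """GY94 parameters on the fixed 4-taxon topology."""

    kappa: float
    omega: dict  # branch -> dN/dS
    branch_lengths: dict  # branch -> expected substitutions per codon
    pi: np.ndarray  # (61,) sense-codon frequencies
    species: tuple  # (sp1, sp2, sp3, sp4); (sp1, sp2) are sisters

    @property
    def branches(self) -> tuple:
        return self.species + (INTERNAL,)

    def validate(self) -> None:
        if abs(float(self.pi.sum()) - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if (self.pi < 0).any():
            raise ValueError("pi entries must be >= 0")
        for b in self.branches:
            if self.omega[b] < 0 or self.branch_lengths[b] < 0:
                raise ValueError(f"negative rate parameter on branch {b}")


@dataclass
class FitResult:
    params: CodonModelParams
    log_likelihood: float
    converged: bool
    n_evaluations: int = 0
    message: str = ""


@dataclass
class LrtResult:
    """omega=1 likelihood-ratio test on one branch (chi-square, 1 df)."""

    branch: str
    logL_free: float
    logL_constrained: float
    statistic: float
    p_value: float
    p_bonferroni: float
    free_omega: float


@dataclass
class PatternAlignment:
    """Site-pattern-compressed codon alignment ready for pruning."""

    species: tuple
    states: np.ndarray  # (4, n_patterns) sense-codon indices
    counts: np.ndarray  # (n_patterns,)
    n_codons: int = 0

    @classmethod
    def from_alignment(cls, alignment: CodonAlignment, species: Sequence[str],
                       code: GeneticCode) -> "PatternAlignment":
        """Compress to site patterns; codon columns with a gap, ambiguity or
        stop codon in any species are dropped listwise."""
        _, index = _code_structure(code.table_id)[:2]
        seqs = []
        for sp in species:
            if sp not in alignment.sequences:
                raise KeyError(f"{alignment.gene_id}: species {sp!r} absent")
            seqs.append(alignment.sequences[sp])
        columns = []
        for i in range(alignment.n_codons):
            if alignment.codon_masked(i):
                continue
            col = []
            for s in seqs:
                c = normalize_codon(s[3 * i : 3 * i + 3])
                if c is None or c not in index:
                    break
                col.append(index[c])
            else:
                columns.append(tuple(col))
        if not columns:
            raise ValueError(f"{alignment.gene_id}: no usable codon columns")
        uniq: dict = {}
        for col in columns:
            uniq[col] = uniq.get(col, 0) + 1
        states = np.array(list(uniq.keys()), dtype=np.int64).T
        counts = np.array(list(uniq.values()), dtype=np.float64)
        return cls(tuple(species), states, counts, n_codons=len(columns))


# ---------------------------------------------------------------------------
# frequencies and rate matrix


def f3x4_frequencies(alignment: CodonAlignment, code: GeneticCode,
                     pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 sense-codon frequencies from position-specific nucleotide counts.

    Adds ``pseudocount`` to every nucleotide count at every codon position
    (guards structural zeros on short genes), forms codon frequencies as
    products across positions, zeroes stops, and renormalizes over the 61
    sense codons.
    """
    codons, index = _code_structure(code.table_id)[:2]
    counts = np.full((3, 4), float(pseudocount))
    base_idx = {b: k for k, b in enumerate("ACGT")}
    for seq in alignment.sequences.values():
        for i in range(0, len(seq) - len(seq) % 3, 3):
            c = normalize_codon(seq[i : i + 3])
            if c is None:
                continue
            for p in range(3):
                counts[p, base_idx[c[p]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([freqs[0, base_idx[c[0]]] * freqs[1, base_idx[c[1]]] * freqs[2, base_idx[c[2]]]
                   for c in codons])
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate F3x4 frequencies")
    return pi / total


def build_gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                           code: GeneticCode, scale: bool = True) -> np.ndarray:
    """61x61 GY94 generator; rows sum to zero; unit mean rate if ``scale``."""
    _, _, ii, jj, trans, nonsyn = _code_structure(code.table_id)
    n = len(pi)
    Q = np.zeros((n, n))
    rates = pi[jj].copy()
    rates[trans] *= kappa
    rates[nonsyn] *= omega
    Q[ii, jj] = rates
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    if scale:
        mean_rate = -float(pi @ np.diag(Q))
        if mean_rate > 0:
            Q /= mean_rate
    return Q


class _BranchPropagator:
    """Eigendecomposition of Q in the symmetrized basis, reused across t."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray, code: GeneticCode):
        Q = build_gy94_rate_matrix(kappa, omega, pi, code)
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        lam, U = eigh((B + B.T) / 2.0)
        self._lam = lam
        self._left = U / sqrt_pi[:, None]  # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.clip(P, 1e-300, None, out=P)
        return P


def transition_matrix(kappa: float, omega: float, pi: np.ndarray, t: float,
                      code: GeneticCode) -> np.ndarray:
    """P(t) = exp(Q t) for a single branch."""
    return _BranchPropagator(kappa, omega, pi, code).transition_matrix(t)


# ---------------------------------------------------------------------------
# likelihood


def _pattern_log_likelihood(data: PatternAlignment, params: CodonModelParams,
                            code: GeneticCode) -> float:
    pi = params.pi
    props: dict = {}
    P = {}
    for b in params.branches:
        key = (params.kappa, params.omega[b])
        if key not in props:
            props[key] = _BranchPropagator(params.kappa, params.omega[b], pi, code)
        P[b] = props[key].transition_matrix(params.branch_lengths[b])
    s1, s2, s3, s4 = params.species
    x1, x2, x3, x4 = data.states
    # partial at far internal node (parent of sp3, sp4)
    far = P[s3][:, x3].T * P[s4][:, x4].T  # (n_patterns, 61)
    root = P[s1][:, x1].T * P[s2][:, x2].T * (far @ P[INTERNAL].T)
    site_l = root @ pi
    if not np.all(np.isfinite(site_l)) or np.any(site_l <= 0):
        bad = int(np.argmin(site_l))
        raise FloatingPointError(f"non-finite site likelihood at pattern {bad}")
    return float(data.counts @ np.log(site_l))


def tree_log_likelihood(alignment: CodonAlignment, params: CodonModelParams,
                        code: GeneticCode) -> float:
    """Pruning log-likelihood of a 4-species codon alignment under GY94."""
    params.validate()
    data = PatternAlignment.from_alignment(alignment, params.species, code)
    return _pattern_log_likelihood(data, params, code)


# ---------------------------------------------------------------------------
# initial branch lengths from pairwise distances


def _initial_branch_lengths(data: PatternAlignment, code: GeneticCode) -> dict:
    """Closed-form additive branch lengths from the 6 pairwise distances."""
    codons = _code_structure(code.table_id)[0]
    # expand patterns back to weighted distances
    d = {}
    idx = {sp: k for k, sp in enumerate(data.species)}
    for a in range(4):
        for b in range(a + 1, 4):
            ca, cb = data.states[a], data.states[b]
            tot = 3 * float(data.counts.sum())
            diff = 0.0
            for k in range(data.states.shape[1]):
                x, y = codons[ca[k]], codons[cb[k]]
                diff += data.counts[k] * sum(u != v for u, v in zip(x, y))
            p = min(diff / tot, 0.70)
            d[(a, b)] = d[(b, a)] = max(-0.75 * math.log1p(-4 * p / 3) * 3, 1e-3)
    t1 = (d[0, 1] + (d[0, 2] + d[0, 3] - d[1, 2] - d[1, 3]) / 2) / 2
    t2 = (d[0, 1] - (d[0, 2] + d[0, 3] - d[1, 2] - d[1, 3]) / 2) / 2
    t3 = (d[2, 3] + (d[0, 2] + d[1, 2] - d[0, 3] - d[1, 3]) / 2) / 2
    t4 = (d[2, 3] - (d[0, 2] + d[1, 2] - d[0, 3] - d[1, 3]) / 2) / 2
    ti = (d[0, 2] + d[0, 3] + d[1, 2] + d[1, 3]) / 4 - (d[0, 1] + d[2, 3]) / 2
    lengths = [t1, t2, t3, t4, ti]
    s1, s2, s3, s4 = data.species
    return {b: max(t, 5e-3) for b, t in zip((s1, s2, s3, s4, INTERNAL), lengths)}


# ---------------------------------------------------------------------------
# fitting


def fit_branch_model(
    alignment: CodonAlignment,
    species: Sequence[str],
    code: GeneticCode,
    fixed_omega: Optional[Mapping[str, float]] = None,
    init: Optional[CodonModelParams] = None,
    pi: Optional[np.ndarray] = None,
    tol: float = 1e-8,
) -> FitResult:
    """Maximize the GY94 likelihood over branch lengths, kappa and
    per-branch omega (optionally holding some branches' omega fixed).

    Deterministic: starting values are kappa=2, omega=0.4 on every free
    branch, and additive branch lengths solved from pairwise distances;
    codon frequencies are the F3x4 empirical estimates (not optimized).
    """
    fixed_omega = dict(fixed_omega or {})
    data = PatternAlignment.from_alignment(alignment, species, code)
    if pi is None:
        pi = f3x4_frequencies(alignment, code)
    branches = tuple(species) + (INTERNAL,)
    free_w = [b for b in branches if b not in fixed_omega]

    if init is not None:
        t0 = dict(init.branch_lengths)
        k0 = init.kappa
        w0 = {b: init.omega[b] for b in branches}
    else:
        t0 = _initial_branch_lengths(data, code)
        k0 = INIT_KAPPA
        w0 = {b: INIT_OMEGA for b in branches}

    def pack():
        x = [math.log(max(t0[b], 1e-5)) for b in branches]
        x.append(math.log(k0))
        x += [math.log(min(max(w0[b], 1e-5), 99.0)) for b in free_w]
        return np.array(x)

    def unpack(x) -> CodonModelParams:
        t = {b: math.exp(x[i]) for i, b in enumerate(branches)}
        kappa = math.exp(x[len(branches)])
        omega = dict(fixed_omega)
        for i, b in enumerate(free_w):
            omega[b] = math.exp(x[len(branches) + 1 + i])
        return CodonModelParams(kappa=kappa, omega=omega, branch_lengths=t,
                                pi=pi, species=tuple(species))

    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        params = unpack(x)
        try:
            return -_pattern_log_likelihood(data, params, code)
        except FloatingPointError:
            return 1e12

    bounds = ([_LOG_T_BOUNDS] * len(branches) + [_LOG_K_BOUNDS]
              + [_LOG_W_BOUNDS] * len(free_w))
    res = minimize(objective, pack(), method="L-BFGS-B", bounds=bounds,
                   options={"ftol": tol, "gtol": 1e-7, "maxiter": 500})
    params = unpack(res.x)
    logL = -float(res.fun)
    converged = bool(res.success)
    if not converged:
        log.warning("branch-model fit did not fully converge: %s", res.message)
    return FitResult(params=params, log_likelihood=logL, converged=converged,
                     n_evaluations=n_eval, message=str(res.message))


def lrt_omega_equals_one(
    alignment: CodonAlignment,
    species: Sequence[str],
    branch: str,
    code: GeneticCode,
    bonferroni_factor: int = 17,
    free_fit: Optional[FitResult] = None,
) -> LrtResult:
    """Likelihood-ratio test of omega=1 on one branch (chi-square, 1 df).

    The constrained fit starts from the free optimum with the tested
    branch's omega pinned at 1; if the constrained likelihood exceeds the
    free one beyond numerical slack, the free model is refit from the
    constrained solution.
    """
    branches = tuple(species) + (INTERNAL,)
    if branch not in branches:
        raise KeyError(f"unknown branch {branch!r}; expected one of {branches}")
    if free_fit is None:
        free_fit = fit_branch_model(alignment, species, code)
    con_init = CodonModelParams(
        kappa=free_fit.params.kappa,
        omega={**free_fit.params.omega, branch: 1.0},
        branch_lengths=dict(free_fit.params.branch_lengths),
        pi=free_fit.params.pi,
        species=tuple(species),
    )
    con_fit = fit_branch_model(alignment, species, code,
                               fixed_omega={branch: 1.0}, init=con_init,
                               pi=free_fit.params.pi)
    if con_fit.log_likelihood > free_fit.log_likelihood + 1e-6:
        # free model got stuck; restart it from the constrained solution
        refit = fit_branch_model(alignment, species, code,
                                 init=con_fit.params, pi=free_fit.params.pi)
        if refit.log_likelihood > free_fit.log_likelihood:
            free_fit = refit
    stat = max(2.0 * (free_fit.log_likelihood - con_fit.log_likelihood), 0.0)
    p = float(chi2.sf(stat, df=1))
    return LrtResult(
        branch=branch,
        logL_free=free_fit.log_likelihood,
        logL_constrained=con_fit.log_likelihood,
        statistic=stat,
        p_value=p,
        p_bonferroni=min(1.0, p * bonferroni_factor),
        free_omega=free_fit.params.omega[branch],
    )
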