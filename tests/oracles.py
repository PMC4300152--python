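"""Independent reference implementations used only to cross-check the
package: deliberately different code paths and libraries (Biopython
translation, scipy expm, exact Fraction arithmetic) from the modules they
verify."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from Bio.Seq import Seq
from scipy.linalg import expm


def bio_translate(codon: str) -> str:
    """Amino acid (or '*') via Biopython's translation machinery."""
    return str(Seq(codon).translate(table=11))


def site_counts_oracle(codon: str) -> tuple:
    """(n_sites, s_sites) by direct neighbor enumeration with Biopython."""
    aa = bio_translate(codon)
    assert aa != "*"
    s_total = Fraction(0)
    for pos in range(3):
        outcomes = []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut_aa = bio_translate(codon[:pos] + base + codon[pos + 1:])
            if mut_aa != "*":
                outcomes.append(mut_aa == aa)
        if outcomes:
            s_total += Fraction(sum(outcomes), len(outcomes))
    return 3 - float(s_total), float(s_total)


def diff_counts_oracle(codon_a: str, codon_b: str) -> tuple:
    """(nd, sd) by explicit path construction over codon sequences."""
    positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not positions:
        return 0.0, 0.0
    path_counts = []
    for order in itertools.permutations(positions):
        path = [codon_a]
        for pos in order:
            nxt = path[-1][:pos] + codon_b[pos] + path[-1][pos + 1:]
            path.append(nxt)
        if any(bio_translate(c) == "*" for c in path[1:]):
            continue
        nd = sum(bio_translate(u) != bio_translate(v) for u, v in zip(path, path[1:]))
        path_counts.append((nd, len(positions) - nd))
    if not path_counts:
        return float(len(positions)), 0.0
    nd = sum(c[0] for c in path_counts) / len(path_counts)
    sd = sum(c[1] for c in path_counts) / len(path_counts)
    return nd, sd


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational two-sided Fisher p with probability-mass ordering."""
    n1, n2, c1 = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - n2), min(c1, n1)
    denom = comb(n1 + n2, c1)
    pmf = {k: Fraction(comb(n1, k) * comb(n2, c1 - k), denom) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(min(Fraction(1), sum(p for p in pmf.values() if p <= p_obs)))


def fisher_pmf_oracle(n1: int, n2: int, c1: int) -> dict:
    """Exact hypergeometric pmf for all tables with the given margins."""
    lo, hi = max(0, c1 - n2), min(c1, n1)
    denom = comb(n1 + n2, c1)
    return {k: Fraction(comb(n1, k) * comb(n2, c1 - k), denom) for k in range(lo, hi + 1)}


def pearson_oracle(x, y) -> float:
    """Pearson r from the raw covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    sxx = (x * x).sum() - x.sum() ** 2 / n
    syy = (y * y).sum() - y.sum() ** 2 / n
    return sxy / np.sqrt(sxx * syy)


def pruning_oracle_4taxon(states, counts, P1, P2, P3, P4, PI, pi) -> float:
    """Log-likelihood by exhaustive summation over both ancestral states."""
    total = 0.0
    n_states = len(pi)
    for (x1, x2, x3, x4), cnt in zip(states.T, counts):
        site = 0.0
        for i in range(n_states):
            inner = 0.0
            for j in range(n_states):
                inner += PI[i, j] * P3[j, x3] * P4[j, x4]
            site += pi[i] * P1[i, x1] * P2[i, x2] * inner
        total += cnt * np.log(site)
    return float(total)


def expm_transition(Q: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) via scipy's Pade expm (independent of eigendecomposition)."""
    return expm(Q * t)
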