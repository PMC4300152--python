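"""McDonald–Kreitman tests, Bonferroni correction, the cross-gene
log-ratio correlation, and summary-table assembly.

The MK test contrasts the nonsynonymous:synonymous ratio of fixed
interspecific differences (Dn:Ds) with that of intraspecific polymorphisms
(Pn:Ps) in a 2x2 table, tested with Fisher's exact test.  The neutrality
index NI = (Pn/Ps)/(Dn/Ds) summarizes the direction (NI < 1: excess
nonsynonymous divergence, consistent with positive selection);
alpha = 1 - NI estimates the fraction of adaptive substitutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: relative slack for the probability-mass tie rule in the two-sided test
_TIE_SLACK = 1e-12


@dataclass(frozen=True)
class MKTable:
    """A 2x2 McDonald–Kreitman table with its test results."""

    group_label: str
    outgroup: str
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    p_value: float
    p_bonferroni: float
    ni: float  # neutrality index, NaN when undefined
    alpha: float  # 1 - NI, NaN when NI undefined
    zero_margin: bool = False


@lru_cache(maxsize=100000)
def _hypergeom_pmf_vector(n1: int, n2: int, c1: int):
    """Exact hypergeometric pmf over a in [max(0, c1-n2), min(c1, n1)],
    for tables with row sums (n1, n2) and first-column sum c1."""
    lo = max(0, c1 - n2)
    hi = min(c1, n1)
    denom = comb(n1 + n2, c1)
    return lo, tuple(comb(n1, a) * comb(n2, c1 - a) / denom for a in range(lo, hi + 1))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Probability-mass ordering: p is the sum of hypergeometric probabilities
    of every table with the same margins whose probability does not exceed
    the observed table's (within a small relative slack).  A zero margin
    makes the table degenerate and returns p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    n1, n2, c1 = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, pmf = _hypergeom_pmf_vector(n1, n2, c1)
    p_obs = pmf[a - lo]
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1 + _TIE_SLACK)))


def mk_test(group_label: str, outgroup: str, Dn: int, Ds: int, Pn: int, Ps: int,
            bonferroni_factor: int = 51) -> MKTable:
    """MK 2x2 test with Bonferroni-corrected p and neutrality index."""
    zero_margin = (Dn + Ds == 0) or (Pn + Ps == 0) or (Dn + Pn == 0) or (Ds + Ps == 0)
    p = fisher_exact_2x2(Dn, Ds, Pn, Ps)
    if Ps > 0 and Dn > 0 and Ds > 0:
        ni = (Pn / Ps) / (Dn / Ds)
        alpha = 1.0 - ni
    else:
        ni = alpha = math.nan
    return MKTable(group_label, outgroup, Dn, Ds, Pn, Ps,
                   p_value=p, p_bonferroni=min(1.0, p * bonferroni_factor),
                   ni=ni, alpha=alpha, zero_margin=zero_margin)


@dataclass(frozen=True)
class SelectionSummary:
    """One summary row per gene group: divergence and polymorphism ratios."""

    group_label: str
    length: int  # nt of coding sequence analyzed
    n_poly: int
    dnds: float  # NaN when inestimable
    pnps: float  # NaN when inestimable
    dnds_fallback: bool = False


def correlate_log_ratios(summaries: Sequence[SelectionSummary],
                         min_snps: int = 3) -> dict:
    """Pearson correlation of ln(dN/dS) vs ln(pN/pS) across gene groups.

    Groups are included when they carry at least ``min_snps`` polymorphisms
    and both ratios are strictly positive and finite (log-transformable).
    Two-sided p from the t distribution with n - 2 df.
    """
    included = [
        s for s in summaries
        if s.n_poly >= min_snps
        and np.isfinite(s.dnds) and s.dnds > 0
        and np.isfinite(s.pnps) and s.pnps > 0
    ]
    n = len(included)
    if n < 3:
        raise ValueError(f"only {n} groups pass the filter; correlation undefined")
    x = np.log([s.dnds for s in included])
    y = np.log([s.pnps for s in included])
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return {
        "n_used": n,
        "r": r,
        "r_squared": r * r,
        "p_value": min(p, 1.0),
        "included_labels": [s.group_label for s in included],
    }


def summarize_table(
    summaries: Sequence[SelectionSummary],
    mean_exclusions_dnds: Sequence[str] = (),
    mean_exclusions_pnps: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-group summary rows plus an "All Genes" unweighted-mean row.

    The dN/dS mean is taken over estimable entries outside
    ``mean_exclusions_dnds`` (the hook for dropping groups whose ratio rests
    on a zero-dS fallback); the pN/pS mean drops inestimable (NaN) entries.
    """
    rows = [
        {
            "group": s.group_label,
            "dN/dS": s.dnds,
            "pN/pS": s.pnps,
            "n_polymorphisms": s.n_poly,
            "length": s.length,
            "dnds_fallback": s.dnds_fallback,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    dnds_vals = df.loc[~df["group"].isin(mean_exclusions_dnds), "dN/dS"].dropna()
    pnps_vals = df.loc[~df["group"].isin(mean_exclusions_pnps), "pN/pS"].dropna()
    mean_row = {
        "group": "All Genes",
        "dN/dS": dnds_vals.mean() if len(dnds_vals) else math.nan,
        "pN/pS": pnps_vals.mean() if len(pnps_vals) else math.nan,
        "n_polymorphisms": int(df["n_polymorphisms"].sum()),
        "length": int(df["length"].sum()),
        "dnds_fallback": False,
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
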