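"""Published per-gene divergence/polymorphism summary for the
*Campanulastrum americanum* plastid genome study.

These are the printed per-gene (or per-concatenation) dN/dS and pN/pS
values, polymorphism counts, and coding-sequence lengths from the
four-species comparison of *C. americanum* with *Trachelium caeruleum*,
*Helianthus annuus* and *Nicotiana tabacum*.  They serve as reference
inputs for the summary arithmetic (column means, SNP-filter logic,
length totals); NaN marks ratios that were inestimable because no
synonymous polymorphism was observed.  The clpP dN/dS rests on the
single-synonymous-substitution fallback (its estimated dS was zero) and is
therefore excluded from the mean dN/dS.
"""

from __future__ import annotations

import math

import pandas as pd

from .selection_stats import SelectionSummary

NA = math.nan

#: group, dN/dS, pN/pS, n_polymorphisms, coding length (nt)
_ROWS = [
    ("atp",  0.131, 0.031, 11, 4929),
    ("ndh",  0.248, 0.324, 17, 10263),
    ("pet",  0.137, 0.649, 3, 2289),
    ("psa",  0.031, 0.000, 2, 4929),
    ("psb",  0.079, 0.173, 6, 6360),
    ("rbcl", 0.102, 0.605, 3, 1425),
    ("ycf3", 0.093, NA,    1, 504),
    ("ycf4", 0.605, 0.000, 1, 552),
    ("rpl",  0.326, 0.204, 14, 2757),
    ("rpo",  0.354, 0.428, 33, 10230),
    ("rps",  0.915, 2.135, 36, 4788),
    ("ccsA", 0.509, 0.290, 2, 918),
    ("cemA", 0.578, NA,    1, 684),
    ("clpP", 5.412, 0.000, 1, 555),
    ("matK", 0.406, 0.257, 6, 1491),
    ("ycf1", 1.293, 1.144, 11, 3042),
    ("ycf2", 1.086, 1.528, 26, 7137),
]

#: groups whose dN/dS used the one-synonymous-substitution fallback
DNDS_FALLBACK_GROUPS = ("clpP",)

#: the published "All Genes" means (mean dN/dS computed without clpP)
PUBLISHED_MEAN_DNDS = 0.430
PUBLISHED_MEAN_PNPS = 0.518
PUBLISHED_TOTAL_CODING_BP = 62853
PUBLISHED_N_CORRELATED = 11


def published_table() -> pd.DataFrame:
    """The published summary rows as a DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["group", "dN/dS", "pN/pS", "n_polymorphisms", "length"]
    )


def published_summaries() -> list:
    """The published rows as SelectionSummary objects."""
    return [
        SelectionSummary(
            group_label=g, length=length, n_poly=n, dnds=dnds, pnps=pnps,
            dnds_fallback=g in DNDS_FALLBACK_GROUPS,
        )
        for g, dnds, pnps, n, length in _ROWS
    ]
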