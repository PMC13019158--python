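"""McDonald-Kreitman selection statistics per gene.

The MK test contrasts within-species polymorphism (Pn nonsynonymous, Ps
synonymous) with fixed between-species divergence (Dn, Ds):

* neutrality index        NI  = (Pn/Ps) / (Dn/Ds)
* adaptive fraction       alpha = 1 - (Pn * Ds) / (Ps * Dn)
* direction of selection  DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps)

NI > 1 indicates purifying selection, NI < 1 (alpha > 0, DoS > 0) positive
selection.  Any zero denominator flags the affected statistic undefined
rather than substituting a pseudocount; an optional +0.5 pseudocount on
every cell is available for exploratory use.  The 2x2 table
[[Pn, Ps], [Dn, Ds]] gets a two-sided exact-test p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["MKResult", "mk_test", "mk_table", "pooled_mk"]


@dataclass
class MKResult:
    gene: str
    pn: int
    ps: int
    dn: int
    ds: int
    ni: float          # NaN when undefined
    alpha: float       # NaN when undefined
    dos: float         # NaN when undefined
    p_value: float
    defined: bool      # True when NI/alpha are defined


def mk_test(pn: int, ps: int, dn: int, ds: int, gene: str = "",
            pseudocount: float = 0.0) -> MKResult:
    """MK statistics for one gene's polymorphism/divergence counts.

    ``pseudocount`` (typically 0.5) is added to every cell before the ratio
    statistics when non-zero; the exact-test p always uses the raw counts.
    """
    for v in (pn, ps, dn, ds):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    a_pn, a_ps, a_dn, a_ds = (v + pseudocount for v in (pn, ps, dn, ds))
    defined = a_ps > 0 and a_dn > 0 and a_ds > 0
    if defined:
        ni = (a_pn / a_ps) / (a_dn / a_ds)
        alpha = 1.0 - (a_pn * a_ds) / (a_ps * a_dn)
    else:
        ni = alpha = math.nan
    dos = math.nan
    if a_dn + a_ds > 0 and a_pn + a_ps > 0:
        dos = a_dn / (a_dn + a_ds) - a_pn / (a_pn + a_ps)
    _, p = stats.fisher_exact([[pn, ps], [dn, ds]], alternative="two-sided")
    return MKResult(gene, int(pn), int(ps), int(dn), int(ds),
                    ni, alpha, dos, float(p), bool(defined))


def mk_table(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Apply :func:`mk_test` to a gene-indexed Pn/Ps/Dn/Ds table."""
    rows = [
        mk_test(r.Pn, r.Ps, r.Dn, r.Ds, gene=str(g), pseudocount=pseudocount)
        for g, r in counts.iterrows()
    ]
    return pd.DataFrame([vars(r) for r in rows]).set_index("gene")


def pooled_mk(counts: pd.DataFrame, pseudocount: float = 0.0) -> MKResult:
    """MK test on counts summed across genes (stabilizes alpha)."""
    if counts.empty:
        raise ValueError("pooled_mk requires a non-empty count table")
    s = counts[["Pn", "Ps", "Dn", "Ds"]].sum()
    return mk_test(int(s.Pn), int(s.Ps), int(s.Dn), int(s.Ds),
                   gene="pooled", pseudocount=pseudocount)
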