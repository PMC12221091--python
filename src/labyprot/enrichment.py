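"""Over/under-representation of annotation terms in protein sets.

Each (term, foreground) cell is tested with the exact hypergeometric tail
probabilities against the detected-protein background (the Fisher's exact
one-sided p): p_over = P(X >= k) and p_under = P(X <= k) for
X ~ Hypergeometric(N, K, n).  Both tails are reported and Benjamini-
Hochberg corrected as two separate families, so a term can be flagged as
over-represented in one foreground and under-represented in another.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import AnnotationMap


@dataclass
class EnrichmentRecord:
    term: str
    namespace: str
    foreground: str
    k: int           # term members in foreground
    K: int           # term members in background
    n: int           # foreground size
    N: int           # background size
    odds_ratio: float
    p_over: float
    p_under: float


def hypergeom_test(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Exact tail probabilities (p_over = P(X >= k), p_under = P(X <= k)).

    X counts term members drawn in a size-n sample without replacement from
    a population of N containing K term members.
    """
    if not (0 <= k <= min(K, n) and N >= max(K, n) >= 0):
        raise ValidationError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if N == 0:
        return 1.0, 1.0
    p_over = float(hypergeom.sf(k - 1, N, K, n))
    p_under = float(hypergeom.cdf(k, N, K, n))
    return min(p_over, 1.0), min(p_under, 1.0)


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - K - (n - k)
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def enrich_sets(annotations: AnnotationMap, foregrounds: dict[str, set[str]],
                background: set[str], fdr: float = 0.05) -> pd.DataFrame:
    """Test every term against every named foreground.

    Returns one row per (term, foreground) with both tail p-values, their
    BH-adjusted values (`p_adj_over`, `p_adj_under`, corrected across the
    whole record family per tail) and flags at the requested FDR.
    """
    for name, fg in foregrounds.items():
        stray = fg - background
        if stray:
            raise ValidationError(
                f"foreground {name!r} contains proteins absent from the background: "
                f"{sorted(stray)[:5]}"
            )
    N = len(background)
    rows = []
    for term, members in annotations.terms.items():
        in_bg = members & background
        K = len(in_bg)
        for name, fg in foregrounds.items():
            k = len(in_bg & fg)
            n = len(fg)
            p_over, p_under = hypergeom_test(k, K, n, N)
            rows.append({
                "term": term, "namespace": annotations.namespace, "foreground": name,
                "k": k, "K": K, "n": n, "N": N,
                "odds_ratio": _odds_ratio(k, K, n, N),
                "p_over": p_over, "p_under": p_under,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        for c in ("p_adj_over", "p_adj_under"):
            out[c] = []
        return out
    out["p_adj_over"] = multipletests(out["p_over"], method="fdr_bh")[1]
    out["p_adj_under"] = multipletests(out["p_under"], method="fdr_bh")[1]
    out["over_flag"] = out["p_adj_over"] < fdr
    out["under_flag"] = out["p_adj_under"] < fdr
    return out
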