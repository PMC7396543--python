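"""Aggregation of conversion calls and GO enrichment.

Percentages are rounded half-away-from-zero to two decimals, matching how the
published wheat tables print ratios.  Enrichment uses the two-sided Fisher
exact test on the 2x2 table (converted vs not) x (in category vs not) — for
fixed margins this is the hypergeometric tail convention summing all tables
with probability at most the observed one.  Raw p-values are the headline
output; a Benjamini–Hochberg column is added as a clearly labelled extension.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

__all__ = [
    "round_half_up",
    "percent",
    "fisher_two_sided",
    "summarize_by_comparison",
    "donor_split_percent",
    "orthogroup_support_percent",
    "go_enrichment",
]

logger = logging.getLogger(__name__)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    With fixed margins this equals the hypergeometric convention summing all
    tables whose probability does not exceed the observed one.
    """
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def donor_split_percent(counts: Tuple[int, int]) -> Tuple[float, float] | None:
    """Two-decimal percent pair for a donor count pair; None when both zero."""
    c1, c2 = counts
    if c1 < 0 or c2 < 0:
        raise ValueError("donor counts must be non-negative")
    total = c1 + c2
    if total == 0:
        return None
    return percent(c1, total), percent(c2, total)


def summarize_by_comparison(calls: Iterable) -> pd.DataFrame:
    """Per-comparison quartet/conversion counts, percents and donor split.

    ``calls`` may be ConversionCall objects or a DataFrame with columns
    ``comparison``, ``status``, ``donor_role``.  Quartets counted are the
    non-filtered ones that entered calling.
    """
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        df = pd.DataFrame(
            {
                "comparison": [c.comparison for c in calls],
                "status": [c.status for c in calls],
                "donor_role": [c.donor_role or "" for c in calls],
            }
        )
    rows = []
    for comparison, grp in df.groupby("comparison", sort=True):
        entered = grp[grp["status"] != "filtered"]
        converted = entered[entered["status"] == "converted"]
        n_q, n_c = len(entered), len(converted)
        donor_x = int((converted["donor_role"] == "hexaploid-X").sum())
        donor_y = int((converted["donor_role"] == "hexaploid-Y").sum())
        split = donor_split_percent((donor_x, donor_y))
        rows.append(
            {
                "comparison": comparison,
                "n_quartets": n_q,
                "n_converted": n_c,
                "percent_converted": percent(n_c, n_q) if n_q else float("nan"),
                "donor_x": donor_x,
                "donor_y": donor_y,
                "donor_percent_x": split[0] if split else float("nan"),
                "donor_percent_y": split[1] if split else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def orthogroup_support_percent(
    pairs: Sequence[Tuple[str, str]],
    clusters: Mapping[str, str],
    decimals: int = 2,
) -> Tuple[int, float]:
    """Colinear pairs supported by shared ortho-group membership.

    A pair is supported when both genes map to the same cluster id; genes
    missing from the cluster table count as unsupported (and are logged).
    """
    supported = 0
    missing = 0
    for g1, g2 in pairs:
        c1, c2 = clusters.get(g1), clusters.get(g2)
        if c1 is None or c2 is None:
            missing += 1
            continue
        if c1 == c2:
            supported += 1
    if missing:
        logger.info("%d pairs had genes missing from the cluster table", missing)
    if not pairs:
        return 0, 0.0
    return supported, percent(supported, len(pairs), decimals)


def go_enrichment(
    converted: Set[str],
    background: Set[str],
    annotations: pd.DataFrame,
    category_column: str = "go_id",
) -> pd.DataFrame:
    """Fisher/hypergeometric enrichment of converted genes per GO category.

    ``annotations`` needs columns ``gene_id`` and ``category_column`` (a gene
    may carry several categories).  Categories with no annotated background
    gene are skipped.  Rows are sorted by p-value; ``direction`` is
    enriched/depleted by the odds-ratio side; ``bh_fdr`` is a
    Benjamini–Hochberg-adjusted extension of the raw p-values.
    """
    if not converted <= background:
        raise ValueError("converted genes must be a subset of the background")
    ann = annotations[annotations["gene_id"].isin(background)]
    n_conv = len(converted)
    n_bg = len(background)
    rows = []
    for category, grp in ann.groupby(category_column, sort=True):
        genes_in = set(grp["gene_id"])
        if not genes_in:
            continue
        a = len(genes_in & converted)  # converted, in category
        b = n_conv - a  # converted, not in category
        c = len(genes_in) - a  # not converted, in category
        d = (n_bg - n_conv) - c
        p = fisher_two_sided(a, b, c, d)
        direction = "enriched" if a * d > b * c else (
            "depleted" if a * d < b * c else "none"
        )
        rows.append(
            {
                "category": category,
                "n_converted_in": a,
                "n_converted": n_conv,
                "n_background_in": len(genes_in),
                "n_background": n_bg,
                "direction": direction,
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["p_value", "category"], kind="stable"
        ).reset_index(drop=True)
        out["bh_fdr"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out
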