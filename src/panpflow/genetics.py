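"""Segregation statistics from reciprocal crosses and fluorescence ratios.

Transmission efficiency (TE) of a mutant allele from a het × wild-type
cross is 100 × n_het / n_wt — 100% under Mendelian 1:1 transmission. The
accompanying chi-square goodness-of-fit tests the 1:1 expectation without
continuity correction against the df=1, α=0.05 critical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .simulate import CrossCounts

__all__ = [
    "OvuleIntensities",
    "transmission_efficiency",
    "chisq_1to1",
    "phenotype_fraction",
    "relative_fluorescence",
    "cross_table",
]

CHI2_CRIT_1DF_05 = 3.85  # conventional critical value, df=1, alpha=0.05


@dataclass
class OvuleIntensities:
    """Per-nucleus fluorescence intensity sums within one ovule."""

    sums: list[float]

    def __post_init__(self) -> None:
        if not self.sums:
            raise ValueError("need at least one nucleus")
        if any(s <= 0 for s in self.sums):
            raise ValueError("intensity sums must be positive")


def _round_half_away(x: float, ndigits: int = 1) -> float:
    factor = 10**ndigits
    return np.floor(abs(x) * factor + 0.5) / factor * np.sign(x)


def transmission_efficiency(counts: CrossCounts) -> float:
    """TE percent = 100 × het / wt, rounded half-away-from-zero to 1 d.p."""
    if counts.n_wt == 0:
        raise ValueError("TE undefined with zero wild-type progeny")
    return float(_round_half_away(100.0 * counts.n_het / counts.n_wt, 1))


def transmission_efficiency_raw(counts: CrossCounts) -> float:
    if counts.n_wt == 0:
        raise ValueError("TE undefined with zero wild-type progeny")
    return 100.0 * counts.n_het / counts.n_wt


def chisq_1to1(counts: CrossCounts) -> tuple[float, float, bool]:
    """(X², expected per class, significant) against a 1:1 segregation.

    X² = Σ(obs − exp)²/exp with exp = total/2; no continuity correction;
    significant when X² exceeds the df=1, α=0.05 critical value 3.85.
    """
    total = counts.n_het + counts.n_wt
    expected = total / 2.0
    x2 = (counts.n_het - expected) ** 2 / expected + (counts.n_wt - expected) ** 2 / expected
    return float(x2), float(expected), bool(x2 > CHI2_CRIT_1DF_05)


def phenotype_fraction(n_abnormal: int, n_total: int) -> tuple[int, tuple[float, float]]:
    """Percent (rounded to integer) with a Wilson 95% CI, both in percent."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_abnormal <= n_total:
        raise ValueError("n_abnormal must lie in [0, n_total]")
    pct = int(_round_half_away(100.0 * n_abnormal / n_total, 0))
    lo, hi = proportion_confint(n_abnormal, n_total, alpha=0.05, method="wilson")
    return pct, (100.0 * lo, 100.0 * hi)


def relative_fluorescence(ovule: OvuleIntensities) -> list[float]:
    """Within-ovule intensities relative to the dimmest nucleus (set to 1)."""
    m = min(ovule.sums)
    return [s / m for s in ovule.sums]


def cross_table(crosses: list[CrossCounts]) -> pd.DataFrame:
    """Summary table: one row per cross with TE and chi-square columns."""
    rows = []
    for c in crosses:
        x2, exp, sig = chisq_1to1(c)
        rows.append(
            {
                "line": c.line,
                "direction": c.direction,
                "n_het": c.n_het,
                "n_wt": c.n_wt,
                "total": c.n_het + c.n_wt,
                "expected_per_class": exp,
                "chi2": float(_round_half_away(x2, 1)),
                "chi2_raw": x2,
                "significant": sig,
                "TE_percent": transmission_efficiency(c),
                "TE_percent_raw": transmission_efficiency_raw(c),
            }
        )
    return pd.DataFrame(rows)
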