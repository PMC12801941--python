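"""Mutation-rate arithmetic from pairwise synonymous divergence.

A symbiont's per-year mutation rate can be approximated by dividing the
pairwise synonymous substitution rate (dS, substitutions per synonymous
site) between two strains by the divergence time of their hosts, under
the assumption of temporal congruence between host and symbiont
divergences.  Two divisor conventions exist and both are implemented and
labelled: *per-lineage* divides by 2T (each lineage accumulates changes
for T years), *per-pair* divides by T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

CONVENTIONS = ("per-lineage", "per-pair")


@dataclass(frozen=True)
class RatePair:
    pair: str                      # e.g. "wWil-wPau"
    ds_symbiont: float             # substitutions / synonymous site
    ds_host: Optional[float] = None
    host_divergence_years: Optional[float] = None
    convention: str = "per-lineage"

    def __post_init__(self):
        if self.ds_symbiont < 0:
            raise ValueError("dS must be >= 0")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")


def ds_ratio(ds_symbiont: float, ds_host: float) -> float:
    """Symbiont/host relative synonymous substitution rate."""
    if ds_host <= 0:
        raise ValueError("host dS must be positive")
    return ds_symbiont / ds_host


def mutation_rate(ds_symbiont: float, host_divergence_years: float,
                  convention: str = "per-lineage") -> float:
    """Substitutions per synonymous site per year.

    ``per-lineage`` divides dS by 2T; ``per-pair`` divides by T.
    """
    if host_divergence_years <= 0:
        raise ValueError("divergence time must be positive")
    if convention == "per-lineage":
        return ds_symbiont / (2.0 * host_divergence_years)
    if convention == "per-pair":
        return ds_symbiont / host_divergence_years
    raise ValueError(f"unknown convention {convention!r}")


def rate_table(pairs: Sequence[RatePair]) -> pd.DataFrame:
    """One row per strain pair: dS ratio, divergence and mutation rate.

    Cells stay blank (NA) where inputs are absent; rows keep input order.
    """
    rows = []
    for p in pairs:
        ratio = (ds_ratio(p.ds_symbiont, p.ds_host)
                 if p.ds_host else None)
        rate = (mutation_rate(p.ds_symbiont, p.host_divergence_years,
                              p.convention)
                if p.host_divergence_years else None)
        rows.append({
            "pair": p.pair,
            "dS_symbiont": p.ds_symbiont,
            "dS_ratio": ratio,
            "host_divergence_years": p.host_divergence_years,
            "mutation_rate": rate,
            "convention": p.convention,
        })
    return pd.DataFrame(rows, columns=["pair", "dS_symbiont", "dS_ratio",
                                       "host_divergence_years",
                                       "mutation_rate", "convention"])


def format_rate(rate: Optional[float]) -> str:
    """Scientific notation with 2 significant figures; '-' when absent."""
    if rate is None:
        return "-"
    return f"{rate:.1e}"
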