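"""Combined PSAII + ToPAS triage rule.

Psoriasis patients are first split by whether they complain of joint pain
(arthralgia).  In the arthralgia group, a PSAII >= 18 OR a ToPAS >= 7 puts
the patient in the PSA high-risk group.  In the non-arthralgia group the
low-risk condition is PSAII < 18 OR ToPAS < 7, so high risk requires
PSAII >= 18 AND ToPAS >= 7.  Note the boundary here is >= by design,
unlike the strict > rule used when an index is screened against its own
cutoff in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import compute_index, get_index

__all__ = ["StrategyRule", "RiskDecision", "assign_risk", "triage_table"]


@dataclass(frozen=True)
class StrategyRule:
    psaii_threshold: float = 18.0
    topas_threshold: float = 7.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.psaii_threshold) and np.isfinite(self.topas_threshold)):
            raise ValueError("thresholds must be finite")
        if self.psaii_threshold <= 0:
            raise ValueError("psaii_threshold must be positive")


@dataclass(frozen=True)
class RiskDecision:
    subject_id: str
    arthralgia: bool
    psaii: float
    topas: int
    risk: str  # "low" | "high"


def assign_risk(arthralgia: bool, psaii: float, topas: int,
                rule: StrategyRule | None = None,
                subject_id: str = "") -> RiskDecision:
    """Assign low/high PSA risk under the combined triage rule."""
    rule = rule or StrategyRule()
    if not np.isfinite(psaii):
        raise ValueError("psaii must be finite")
    if topas < 0:
        raise ValueError("topas must be non-negative")
    psaii_hi = psaii >= rule.psaii_threshold
    topas_hi = topas >= rule.topas_threshold
    if arthralgia:
        high = psaii_hi or topas_hi
    else:
        high = psaii_hi and topas_hi
    return RiskDecision(
        subject_id=subject_id,
        arthralgia=bool(arthralgia),
        psaii=float(psaii),
        topas=int(topas),
        risk="high" if high else "low",
    )


def triage_table(table: pd.DataFrame, rule: StrategyRule | None = None) -> pd.DataFrame:
    """Vectorized triage for a cohort table.

    Requires ``arthralgia`` and ``topas`` columns and either a ``PSAII``
    column or the raw PSAII components to compute one.
    """
    rule = rule or StrategyRule()
    for col in ("arthralgia", "topas"):
        if col not in table.columns:
            raise KeyError(
                f"triage requires a precomputed {col!r} column; "
                "the rule has no fallback when it is unavailable"
            )
    psaii = (table["PSAII"] if "PSAII" in table.columns
             else compute_index(get_index("PSAII"), table))
    arthralgia = table["arthralgia"].astype(bool).to_numpy()
    psaii_hi = psaii.to_numpy() >= rule.psaii_threshold
    topas_hi = table["topas"].to_numpy() >= rule.topas_threshold
    high = np.where(arthralgia, psaii_hi | topas_hi, psaii_hi & topas_hi)
    out = pd.DataFrame({
        "arthralgia": arthralgia.astype(int),
        "psaii": psaii.to_numpy(),
        "topas": table["topas"].to_numpy(),
        "risk": np.where(high, "high", "low"),
    }, index=table.index)
    if "subject_id" in table.columns:
        out.insert(0, "subject_id", table["subject_id"])
    return out
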