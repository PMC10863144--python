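"""Tumor mutational burden and MSI-high calling.

TMB is the count of missense variants at VAF >= 5%, divided by the targeted
(non-overlapping) region length in megabases.  Default lengths are the cancer
gene panel (3,040,053 bp) and the exome capture (38,289,292 bp).  TMB >= 5
mutations/Mb is the actionability threshold (immune-checkpoint trial
eligibility); an inclusive comparison is the default and a strict ``> 5`` mode
is available.  MSI-high is a threshold call (score >= 10) on a precomputed
microsatellite-instability score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .variant_filters import SmallVariant

__all__ = [
    "PANEL_LENGTH_BP",
    "EXOME_LENGTH_BP",
    "TmbResult",
    "compute_tmb",
    "call_msi_high",
]

PANEL_LENGTH_BP = 3_040_053
EXOME_LENGTH_BP = 38_289_292


@dataclass
class TmbResult:
    sample_id: str
    missense_count: int
    target_length_bp: int
    tmb: float  # mutations per megabase
    actionable: bool


def compute_tmb(
    variants: Iterable[SmallVariant],
    target_length_bp: int = PANEL_LENGTH_BP,
    min_vaf: float = 0.05,
    actionable_cutoff: float = 5.0,
    inclusive_cutoff: bool = True,
    sample_id: str = "",
) -> TmbResult:
    """Mutations-per-megabase burden from missense variants at VAF >= ``min_vaf``."""
    if target_length_bp <= 0:
        raise ValueError(f"target_length_bp must be positive, got {target_length_bp}")
    count = sum(
        1 for v in variants if v.consequence == "missense" and v.vaf >= min_vaf
    )
    tmb = count / (target_length_bp / 1e6)
    actionable = tmb >= actionable_cutoff if inclusive_cutoff else tmb > actionable_cutoff
    return TmbResult(
        sample_id=sample_id,
        missense_count=count,
        target_length_bp=target_length_bp,
        tmb=tmb,
        actionable=actionable,
    )


def call_msi_high(msi_score: float, cutoff: float = 10.0) -> bool:
    """MSI-high iff the precomputed MSI score is ``cutoff`` or higher."""
    if not math.isfinite(msi_score) or msi_score < 0:
        raise ValueError(f"MSI score must be finite and non-negative, got {msi_score}")
    return msi_score >= cutoff
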