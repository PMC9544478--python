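"""Relative ONSEN copy number from qPCR by the delta-delta-Ct method.

Genomic DNA is assayed with an ONSEN-specific primer pair and a
single-copy reference gene (ACTIN2, AT3G18780) that normalises DNA input;
Col-0 wild-type DNA is the calibrator sample.  With perfect doubling per
cycle, the fold change of ONSEN content relative to the wild type is

    dCt    = Ct_target − Ct_reference        (per sample)
    ddCt   = dCt_sample − dCt_control
    fold   = 2^(−ddCt)

and the genomic copy estimate is fold x wild-type copy number (8 ONSEN
copies in Col-0, so an 8-fold increase corresponds to ~64 copies).  The
replicate standard deviation is propagated in quadrature through both
differences and to the fold scale by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "FoldChange",
    "fold_change_ddct",
    "copies_from_fold",
    "analyze_plate",
]

#: ONSEN copies in the Col-0 wild-type genome, the calibrator baseline.
DEFAULT_WT_COPIES = 8


@dataclass
class QpcrMeasurement:
    """Technical-replicate Ct values of one sample for target and
    reference gene."""

    sample: str
    target_cts: Sequence[float]
    reference_cts: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.target_cts) < 1 or len(self.reference_cts) < 1:
            raise ValueError(f"sample {self.sample}: need >= 1 technical replicate")
        if any(ct <= 0 for ct in list(self.target_cts) + list(self.reference_cts)):
            raise ValueError(f"sample {self.sample}: Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.target_cts) - np.mean(self.reference_cts))

    @property
    def delta_ct_sd(self) -> float:
        """Replicate SD of dCt, target and reference combined in quadrature."""
        sd_t = float(np.std(self.target_cts, ddof=1)) if len(self.target_cts) > 1 else 0.0
        sd_r = (
            float(np.std(self.reference_cts, ddof=1))
            if len(self.reference_cts) > 1
            else 0.0
        )
        return float(np.hypot(sd_t, sd_r))


@dataclass
class FoldChange:
    sample: str
    fold: float
    sd: float
    ddct: float
    ddct_sd: float


def fold_change_ddct(sample: QpcrMeasurement, control: QpcrMeasurement) -> FoldChange:
    """Fold change of the target relative to the control sample,
    2^(−ddCt), with SD propagated from replicate scatter."""
    ddct = sample.delta_ct - control.delta_ct
    ddct_sd = float(np.hypot(sample.delta_ct_sd, control.delta_ct_sd))
    fold = float(2.0 ** (-ddct))
    # delta method: d(2^-x)/dx = -ln2 * 2^-x
    sd = float(np.log(2.0) * fold * ddct_sd)
    return FoldChange(sample=sample.sample, fold=fold, sd=sd, ddct=ddct, ddct_sd=ddct_sd)


def copies_from_fold(fold: float, wt_copies: int = DEFAULT_WT_COPIES) -> int:
    """Genomic copy estimate: fold change times the wild-type copy number,
    rounded to the nearest whole copy."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    if wt_copies < 1:
        raise ValueError("wt_copies must be >= 1")
    return round(fold * wt_copies)


def analyze_plate(
    plate: pd.DataFrame,
    control_sample: str,
    target_gene: str = "ONSEN",
    reference_gene: str = "ACTIN2",
    wt_copies: int = DEFAULT_WT_COPIES,
) -> pd.DataFrame:
    """Fold changes and copy estimates for every sample on a plate.

    ``plate`` is long-format with columns ``sample, gene, ct, replicate``.
    The control sample must be present; every sample needs Cts for both
    the target and the reference gene.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(plate.columns):
        raise ValueError(f"plate table needs columns {sorted(required)}")

    def measurement(name: str) -> QpcrMeasurement:
        sub = plate[plate["sample"] == name]
        target = sub.loc[sub["gene"] == target_gene, "ct"].to_numpy(dtype=float)
        ref = sub.loc[sub["gene"] == reference_gene, "ct"].to_numpy(dtype=float)
        if target.size == 0 or ref.size == 0:
            raise ValueError(
                f"sample {name!r}: missing {target_gene} or {reference_gene} Ct values"
            )
        return QpcrMeasurement(name, target, ref)

    if control_sample not in set(plate["sample"]):
        raise ValueError(f"control sample {control_sample!r} not on plate")
    control = measurement(control_sample)
    rows = []
    for name in pd.unique(plate["sample"]):
        fc = fold_change_ddct(measurement(str(name)), control)
        rows.append(
            {
                "sample": name,
                "fold": fc.fold,
                "fold_sd": fc.sd,
                "ddct": fc.ddct,
                "copies": copies_from_fold(fc.fold, wt_copies),
            }
        )
    return pd.DataFrame(rows)
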