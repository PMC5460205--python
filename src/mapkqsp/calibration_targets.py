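"""Reference calibration targets for the baseline signaling fit.

These encode the qualitative/quantitative cell-line behavior the baseline
model is required to reproduce, expressed as generic-inhibitor (95% target
suppression) experiments on a BRAF-V600E background:

* pERK dynamics under BRAF inhibition over 48 h: EGFR-high (colorectal)
  cells show transient suppression followed by a rebound to ~40% of
  baseline by 48 h; EGFR-low (melanoma) cells show deep, sustained
  suppression.
* 72-h fold-expansion phenotypes across a mutation × drug matrix: BRAF
  inhibition is ineffective in EGFR-high cells but effective in EGFR-low
  cells; MEK inhibition works in EGFR-high cells but is blunted by MEK
  amplification or mutation; ERK inhibition suppresses growth regardless of
  genetic background; the BRAFi+MEKi doublet is potent except in MEK-mutant
  cells.
"""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationData, GrowthDataset, PerkDataset
from .core_model import Genotype

__all__ = ["reference_calibration_data", "CRC", "MELANOMA",
           "UNTREATED_FOLD_72H"]

CRC = Genotype(mutations=("BRAF_V600E",), tissue="CRC")
MELANOMA = Genotype(mutations=("BRAF_V600E",), tissue="melanoma")

SUPPRESSION = 0.95
#: untreated 72-h fold expansion of a fast-growing V600E line.
UNTREATED_FOLD_72H = 6.0


def _mut(*names) -> Genotype:
    return Genotype(mutations=("BRAF_V600E",) + names, tissue="CRC")


def reference_calibration_data() -> CalibrationData:
    # post-treatment times only: the quasi-steady-state cascade responds to
    # target suppression instantaneously, so the pre-drug t=0 baseline is
    # not part of the treated trajectory (values are baseline-normalized)
    t_h = np.array([2.0, 4.0, 8.0, 24.0, 36.0, 48.0])
    perk = [
        # transient suppression for up to ~24 h, rebound to 40% of
        # baseline by 48 h in EGFR-high cells
        PerkDataset(genotype=CRC, suppression={"BRAF": SUPPRESSION},
                    t_h=t_h,
                    values=np.array([0.20, 0.15, 0.15, 0.25, 0.33, 0.40])),
        # deep, sustained suppression in EGFR-low cells
        PerkDataset(genotype=MELANOMA, suppression={"BRAF": SUPPRESSION},
                    t_h=t_h,
                    values=np.array([0.10, 0.08, 0.06, 0.05, 0.05, 0.05])),
    ]
    s = SUPPRESSION
    F = UNTREATED_FOLD_72H
    growth = [
        GrowthDataset(CRC, {}, fold=F),
        GrowthDataset(MELANOMA, {}, fold=F),
        # BRAFi: bypassed via EGFR/RAS/CRAF in EGFR-high cells only
        GrowthDataset(CRC, {"BRAF": s}, fold=0.9 * F),
        GrowthDataset(MELANOMA, {"BRAF": s}, fold=1.2),
        # MEKi: active in EGFR-high cells, blunted by MEK mutation/amp
        GrowthDataset(CRC, {"MEK": s}, fold=1.5),
        GrowthDataset(_mut("MEK_mut"), {"MEK": s}, fold=0.75 * F),
        GrowthDataset(_mut("MEK_amp"), {"MEK": s}, fold=0.6 * F),
        # ERKi: effective regardless of genetic background
        GrowthDataset(CRC, {"ERK": s}, fold=1.2),
        GrowthDataset(_mut("MEK_mut"), {"ERK": s}, fold=1.3),
        GrowthDataset(_mut("BRAF_amp"), {"ERK": s}, fold=1.3),
        GrowthDataset(_mut("KRAS_amp"), {"ERK": s}, fold=1.3),
        # BRAFi+MEKi doublet: potent except in MEK-mutant cells
        GrowthDataset(CRC, {"BRAF": s, "MEK": s}, fold=1.0),
        GrowthDataset(_mut("MEK_mut"), {"BRAF": s, "MEK": s}, fold=0.7 * F),
    ]
    return CalibrationData(perk=perk, growth=growth)
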