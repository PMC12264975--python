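"""Worked-example effect-measure arithmetic on published per-arm risks.

``PUBLISHED_TRIALS`` holds per-arm 8-year mortality risks (events per 100
persons) and the corresponding published risk differences, risk ratios and
numbers needed to treat from a nationwide prescription-registry screen of
drug initiation after Parkinson-disease diagnosis.  They serve as inputs
to :func:`ttescreen.estimation.effect_measures` in worked examples and
consistency checks: the risk ratio recomputed from the two risks matches
the published value to two decimals, and for most rows the published NNT
equals ``round(100 / rd)`` with ``rd`` the difference of the printed
risks (a few published NNTs were evidently derived from unrounded risk
differences and differ by one).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PUBLISHED_TRIALS", "published_trials_frame"]

# atc: (drug, n_target, n_control, risk_target, risk_control, rd, nnt, rr)
PUBLISHED_TRIALS = {
    "A02BA02": ("ranitidine", 360, 10000, 62.7, 70.5, 7.7, 13, 0.89),
    "A02BC02": ("pantoprazole", 1673, 8538, 65.4, 69.7, 4.3, 23, 0.94),
    "A02BC05": ("esomeprazole", 764, 9130, 65.2, 70.8, 5.6, 18, 0.92),
    "C09CA01": ("losartan", 281, 10000, 51.6, 63.5, 12.0, 8, 0.81),
    "C10AA05": ("atorvastatin", 811, 8268, 54.5, 64.9, 10.4, 10, 0.84),
    "G04BE08": ("tadalafil", 545, 2288, 39.8, 49.1, 9.3, 11, 0.81),
    "H03AA01": ("levothyroxine sodium", 175, 1738, 46.1, 64.3, 18.2, 6, 0.72),
    "J01CE02": ("phenoxymethylpenicillin", 3119, 8385, 57.2, 62.3, 5.1, 20, 0.92),
    "J01FA01": ("erythromycin", 660, 10000, 57.8, 63.9, 6.1, 17, 0.91),
    "J01FA10": ("azithromycin", 273, 10000, 52.0, 64.1, 12.1, 8, 0.81),
    "M01AC01": ("piroxicam", 235, 2072, 41.3, 59.0, 17.7, 6, 0.70),
    "M01AC06": ("meloxicam", 136, 2082, 46.2, 60.7, 14.5, 7, 0.76),
    "M01AE02": ("naproxen", 587, 1992, 48.5, 59.0, 10.6, 9, 0.82),
    "M01AX05": ("glucosamine", 204, 2069, 44.7, 60.0, 15.3, 7, 0.75),
    "N02AJ06": ("codeine and paracetamol", 3227, 10000, 58.7, 66.6, 8.0, 13, 0.88),
    "N02AX02": ("tramadol", 2407, 10000, 60.6, 65.4, 4.8, 21, 0.93),
    "N06AX03": ("mianserin", 663, 10000, 57.9, 64.4, 6.5, 15, 0.90),
    "R01AD09": ("mometasone", 584, 8110, 49.5, 56.4, 6.9, 14, 0.88),
    "R05DA01": ("ethylmorphine", 1706, 6340, 49.9, 58.5, 8.7, 12, 0.85),
    "R05FA02": ("ethylmorphine and expectorant", 404, 9020, 49.5, 56.5, 7.0, 14, 0.88),
    "S01BA01": ("dexamethasone", 531, 7321, 52.9, 62.4, 9.6, 10, 0.85),
}

_COLS = [
    "drug", "n_target", "n_control", "risk_target", "risk_control",
    "published_rd", "published_nnt", "published_rr",
]


def published_trials_frame() -> pd.DataFrame:
    """The published per-arm risks and contrasts as a DataFrame."""
    df = pd.DataFrame.from_dict(PUBLISHED_TRIALS, orient="index", columns=_COLS)
    df.index.name = "atc_code"
    return df
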