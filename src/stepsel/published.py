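"""Published final-model estimates for the reintroduced scimitar-horned oryx
population (Ouadi Rime-Ouadi Achim reserve, Chad).

The original study's final dry- and wet-period models (tier M4) report, per
term, a coefficient on the standardized scale, its relative selection
strength RSS = exp(coefficient), a robust standard error, and whether the
term is significant at p < 0.05.  These printed values are inputs here: the
underlying GPS data are not public, so they anchor the exp(coefficient) = RSS
identity checks and give worked examples their reference numbers.

Note: in the dry period the printed Elevation:group_size row pairs a positive
coefficient (0.007185) with an RSS below one (0.992841 = exp(-0.007185)); the
printed sign of one of the two is a typo in the source table.  The row is
retained as printed and flagged ``consistent=False``.
"""
from __future__ import annotations

import math

import pandas as pd

# term, period, coefficient, rss, se, significant
_ROWS = [
    ("sl", "dry", 0.031216, 1.031709, 0.006206, False),
    ("log_sl", "dry", -0.066014, 0.936118, 0.006020, True),
    ("aNDVI", "dry", 0.220561, 1.246776, 0.025554, True),
    ("dNDVI", "dry", -0.118859, 0.887933, 0.040020, True),
    ("elevation", "dry", 0.033046, 1.033598, 0.007553, True),
    ("TRI", "dry", -0.069324, 0.933025, 0.005778, True),
    ("temperature", "dry", -0.018336, 0.981831, 0.008080, True),
    ("experience", "dry", 0.013913, 1.014010, 0.032343, False),
    ("group_size", "dry", -0.002478, 0.997526, 0.005738, False),
    ("aNDVI^2", "dry", -0.018772, 0.981403, 0.003777, True),
    ("dNDVI^2", "dry", -0.009814, 0.990234, 0.003132, True),
    ("temperature^2", "dry", -0.012278, 0.987797, 0.005011, True),
    ("sl:experience", "dry", 0.002168, 1.002170, 0.005965, False),
    ("log_sl:experience", "dry", -0.035228, 0.965386, 0.005695, True),
    ("aNDVI:experience", "dry", 0.033742, 1.034317, 0.031870, False),
    ("dNDVI:experience", "dry", -0.160548, 0.851677, 0.051272, True),
    ("elevation:experience", "dry", -0.033265, 0.967283, 0.009731, True),
    ("TRI:experience", "dry", 0.052383, 1.053779, 0.006479, True),
    ("temperature:experience", "dry", 0.031204, 1.031696, 0.010877, True),
    ("sl:group_size", "dry", -0.121270, 0.885795, 0.007104, True),
    ("log_sl:group_size", "dry", 0.102707, 1.108167, 0.007067, True),
    ("aNDVI:group_size", "dry", 0.003632, 1.003638, 0.004126, False),
    ("dNDVI:group_size", "dry", 0.004128, 1.004136, 0.004067, True),
    ("elevation:group_size", "dry", 0.007185, 0.992841, 0.006904, False),
    ("TRI:group_size", "dry", 0.026482, 1.026836, 0.005851, True),
    ("temperature:group_size", "dry", 0.000303, 1.000303, 0.005580, True),
    ("sl", "wet", -0.085392, 0.918152, 0.007023, True),
    ("log_sl", "wet", 0.145373, 1.156471, 0.007344, True),
    ("aNDVI", "wet", 0.040974, 1.041825, 0.012642, True),
    ("dNDVI", "wet", 0.034369, 1.034966, 0.015879, True),
    ("elevation", "wet", -0.028966, 0.971450, 0.009258, True),
    ("TRI", "wet", 0.027761, 1.028150, 0.005825, True),
    ("temperature", "wet", 0.008782, 1.008821, 0.007739, True),
    ("experience", "wet", -0.012551, 0.987527, 0.029001, False),
    ("group_size", "wet", -0.007034, 0.992991, 0.005433, True),
    ("aNDVI^2", "wet", -0.010235, 0.989817, 0.003493, True),
    ("dNDVI^2", "wet", -0.009695, 0.990352, 0.004679, True),
    ("sl:experience", "wet", 0.031899, 1.032414, 0.006149, True),
    ("log_sl:experience", "wet", -0.032891, 0.967644, 0.006980, False),
    ("aNDVI:experience", "wet", 0.013910, 1.014007, 0.008011, False),
    ("dNDVI:experience", "wet", -0.009679, 0.990368, 0.013125, False),
    ("elevation:experience", "wet", 0.020697, 1.020912, 0.010874, True),
    ("TRI:experience", "wet", -0.015166, 0.984949, 0.007235, True),
    ("sl:group_size", "wet", -0.057897, 0.943747, 0.007664, True),
    ("log_sl:group_size", "wet", 0.072373, 1.075057, 0.008066, True),
    ("aNDVI:group_size", "wet", 0.007308, 1.007335, 0.006514, True),
    ("dNDVI:group_size", "wet", -0.003953, 0.996055, 0.005836, True),
    ("elevation:group_size", "wet", -0.014649, 0.985458, 0.006387, True),
    ("TRI:group_size", "wet", 0.016766, 1.016908, 0.005480, True),
]


def published_coefficients() -> pd.DataFrame:
    """The published final-model (M4) coefficient table for both seasons.

    Columns: term, period, coefficient, rss, se, significant, consistent —
    the last flags whether exp(coefficient) reproduces the printed RSS to
    printed precision (one printed row carries a sign typo; see module notes).
    """
    df = pd.DataFrame(_ROWS, columns=["term", "period", "coefficient", "rss",
                                      "se", "significant"])
    df["consistent"] = [
        abs(math.exp(c) - r) < 1e-4 for c, r in zip(df["coefficient"], df["rss"])
    ]
    return df
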