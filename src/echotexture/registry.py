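"""Fixed registry of the 250 texture-feature names.

The registry is the single source of feature naming and ordering: every
extractor emits names drawn from it, the feature table writes its columns in
registry order, and rank ties in feature screening are broken by registry
position.  Nine groups, 250 features total:

======================================  =====
group                                   count
======================================  =====
Histogram                                   9
Autoregressive model                        5
Gradient                                    5
Histogram of oriented gradients            28
Gabor                                      24
Wavelet                                    24
Run-length matrix                          28
Co-occurrence matrix                       11
Local binary patterns                     116
======================================  =====
"""

from __future__ import annotations

from collections import OrderedDict

#: Texture directions shared by the Gabor, run-length and co-occurrence
#: machinery: horizontal (H, 0 deg), first diagonal (Z, 45 deg),
#: vertical (V, 90 deg), second diagonal (N, 135 deg).
DIRECTIONS = ("H", "Z", "V", "N")

#: Degrees corresponding to each direction letter.
DIRECTION_DEGREES = {"H": 0, "Z": 45, "V": 90, "N": 135}

#: Gaussian-envelope sizes (pixels) of the Gabor bank.
GABOR_SIZES = (2, 4, 6, 8, 10, 12)

#: Dyadic decomposition levels of the Haar wavelet energies.
WAVELET_LEVELS = tuple(range(1, 9))
WAVELET_CHANNELS = ("LH", "HL", "HH")

GLRLM_STATS = (
    "RLNonUni",
    "GLevNonUn",
    "LngREmph",
    "ShrtREmph",
    "Fraction",
    "NRLNonUni",
    "NGLevNonUni",
)

HISTOGRAM_NAMES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc01",
    "Perc10",
    "Perc50",
    "Perc90",
    "Perc99",
)
AR_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")
GRADIENT_NAMES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
HOG_NAMES = tuple(f"O{b}b{i}" for b in (4, 8, 16) for i in range(b))
GABOR_NAMES = tuple(f"Gab{s}{d}" for s in GABOR_SIZES for d in DIRECTIONS)
WAVELET_NAMES = tuple(
    f"HaarS{k}{c}" for k in WAVELET_LEVELS for c in WAVELET_CHANNELS
)
GLRLM_NAMES = tuple(f"{d}{s}" for d in DIRECTIONS for s in GLRLM_STATS)
GLCM_NAMES = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)
LBP_NAMES = (
    tuple(f"Oc4n{i}" for i in range(16))
    + tuple(f"Tr4n{i}" for i in range(16))
    + tuple(f"Cs4n{i}" for i in range(4))
    + tuple(f"Cs8n{i}" for i in range(16))
    + tuple(f"Cs12n{i}" for i in range(64))
)

#: Group display name -> ordered feature names, in extraction order.
GROUPS: "OrderedDict[str, tuple[str, ...]]" = OrderedDict(
    [
        ("Histogram", HISTOGRAM_NAMES),
        ("Autoregressive model", AR_NAMES),
        ("Gradient", GRADIENT_NAMES),
        ("Histogram of oriented gradients", HOG_NAMES),
        ("Gabor", GABOR_NAMES),
        ("Wavelet", WAVELET_NAMES),
        ("Run-length matrix", GLRLM_NAMES),
        ("Co-occurrence matrix", GLCM_NAMES),
        ("Local binary patterns", LBP_NAMES),
    ]
)

#: All 250 feature names in canonical order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    name for names in GROUPS.values() for name in names
)

#: Feature name -> group display name.
FEATURE_GROUP: dict[str, str] = {
    name: group for group, names in GROUPS.items() for name in names
}

#: Feature name -> position in the canonical order.
FEATURE_INDEX: dict[str, int] = {n: i for i, n in enumerate(FEATURE_NAMES)}

GROUP_SIZES: dict[str, int] = {g: len(names) for g, names in GROUPS.items()}

N_FEATURES = len(FEATURE_NAMES)

assert N_FEATURES == 250, "feature registry must contain exactly 250 names"
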