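"""Published summary statistics of the acupuncture-for-CA prescription corpus.

The analysis this package reimplements was run on a database of 33 acupoint
formulas (one per syndrome-differentiated treatment arm, drawn from 27
controlled trials of acupuncture for cancer-related anorexia, 38 distinct
acupoints overall).  The raw database was never deposited; what survives are
its printed summary tables: the frequent-pattern counts, the top-10
association rules with their four metrics, the FP-growth rule confidences,
and the 21 acupoints entering the cluster analysis.  Those published numbers
are collected here verbatim and serve as the constraint system from which
:mod:`acumine.fixture` reconstructs an observationally equivalent database.
"""

from __future__ import annotations

N_FORMULAS = 33
N_STUDIES = 27
UNIVERSE_SIZE = 38

#: Reported frequent patterns: itemset -> exact support count (out of 33).
REPORTED_PATTERNS: dict[tuple[str, ...], int] = {
    ("DU20",): 9,
    ("DU20", "RN12"): 9,
    ("HT7",): 9,
    ("HT7", "RN12"): 9,
    ("RN4", "SP6"): 11,
    ("RN4", "SP6", "RN12"): 10,
    ("RN4", "RN12"): 12,
    ("PC6", "RN12"): 9,
    ("PC6", "ST36"): 11,
    ("SP6",): 14,
    ("SP6", "RN12"): 11,
    ("RN12",): 22,
    ("RN12", "ST36"): 13,
    ("ST36",): 24,
}

#: Reported top-10 association rules (support >= 24%, confidence >= 75%):
#: (lhs, rhs, support, confidence, lift) at print precision (3 decimals).
REPORTED_RULES: list[tuple[tuple[str, ...], tuple[str, ...], float, float, float]] = [
    (("RN4",), ("RN12",), 0.364, 0.923, 1.385),
    (("PC6",), ("ST36",), 0.333, 0.846, 1.163),
    (("RN4",), ("SP6",), 0.333, 0.846, 1.995),
    (("SP6",), ("RN4",), 0.333, 0.786, 1.995),
    (("SP6",), ("RN12",), 0.333, 0.786, 1.179),
    (("RN4", "SP6"), ("RN12",), 0.303, 0.909, 1.364),
    (("RN4", "RN12"), ("SP6",), 0.303, 0.833, 1.964),
    (("SP6", "RN12"), ("RN4",), 0.303, 0.909, 2.308),
    (("HT7",), ("RN12",), 0.273, 1.000, 1.500),
    (("DU20",), ("RN12",), 0.273, 1.000, 1.500),
]

#: Reported FP-growth rule confidences at 2-decimal precision.
REPORTED_FP_RULES: list[tuple[tuple[str, ...], tuple[str, ...], float]] = [
    (("DU20",), ("RN12",), 1.00),
    (("HT7",), ("RN12",), 1.00),
    (("SP6",), ("RN12",), 0.79),
    (("RN4", "SP6"), ("RN12",), 0.91),
    (("RN4", "RN12"), ("SP6",), 0.83),
    (("SP6", "RN12"), ("RN4",), 0.91),
]

#: The ten most frequently chosen acupoints, in reported order.
TOP10_ITEMS = ["ST36", "RN12", "SP6", "RN4", "PC6", "DU20", "HT7", "RN6", "ST37", "ST25"]

#: The seven acupoints whose counts are pinned (directly or derivably) by the
#: published tables; all frequent patterns live on these.
CORE_ITEMS = ["ST36", "RN12", "SP6", "RN4", "PC6", "HT7", "DU20"]

#: The 21 acupoints entering the published cluster analysis.
CLUSTERED_ITEMS = [
    "ST36", "RN12", "DU20", "HT7", "SP6", "RN4", "PC6",
    "RN6", "LI4", "ST19", "BL21", "BL13", "BL20", "BL23",
    "RN8", "SP9", "LI11", "SJ6", "ST37", "ST39", "ST25",
]

#: Filler acupoints completing the 38-item universe.  Their identities beyond
#: the clustered list are not published; these are plausible stand-ins.
EXTRA_ITEMS = [
    "LR3", "GB34", "BL17", "DU14", "SJ5", "LI10", "SP10", "ST21", "RN13",
    "RN10", "KI3", "GB20", "DU26", "PC5", "SP3", "ST40", "BL18",
]
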