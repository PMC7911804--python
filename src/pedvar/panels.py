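"""Reference STR panel: the 21-marker ISAG canine parentage set.

Allele frequencies and per-locus summary statistics published for the Polish
Greyhound survey population (n = 174 genotyped dogs).  Alleles are fragment
lengths in base pairs; frequencies are as printed, rounded to three decimals
(some sets sum to 0.999-1.008 and are renormalised where a proper
distribution is required).  These frequency sets parameterise the synthetic
genotype generator and serve as fixed inputs for the deterministic
recomputation of He and PIC.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PANEL_FREQUENCIES", "printed_locus_stats", "locus_frequencies", "panel_loci"]

# locus -> {allele size (bp): frequency}
PANEL_FREQUENCIES: dict[str, dict[int, float]] = {
    "AHTk211": {87: 0.057, 89: 0.445, 91: 0.477, 95: 0.020},
    "CXX279": {116: 0.178, 118: 0.431, 120: 0.037, 124: 0.055, 126: 0.193, 130: 0.106},
    "REN169O18": {158: 0.009, 162: 0.233, 164: 0.293, 166: 0.032, 168: 0.040, 170: 0.394},
    "INU055": {200: 0.009, 210: 0.718, 212: 0.017, 214: 0.014, 216: 0.129,
               218: 0.092, 220: 0.020},
    "REN54P11": {226: 0.239, 228: 0.052, 232: 0.250, 234: 0.026, 236: 0.402, 238: 0.032},
    "INRA21": {95: 0.578, 97: 0.017, 101: 0.124, 103: 0.282},
    "AHT137": {131: 0.580, 133: 0.221, 137: 0.035, 143: 0.023, 147: 0.098, 153: 0.043},
    "REN169d01": {202: 0.328, 210: 0.184, 212: 0.014, 216: 0.348, 218: 0.052, 222: 0.075},
    "AHTh260": {240: 0.023, 244: 0.072, 246: 0.175, 248: 0.351, 252: 0.313, 254: 0.066},
    "AHTk253": {286: 0.011, 288: 0.701, 290: 0.121, 292: 0.124, 294: 0.034, 296: 0.009},
    "INU005": {110: 0.161, 122: 0.011, 124: 0.667, 126: 0.029, 132: 0.132},
    "INU030": {144: 0.422, 148: 0.009, 150: 0.534, 152: 0.034},
    "FH2848": {234: 0.043, 236: 0.029, 238: 0.253, 240: 0.279, 244: 0.397},
    "AHT121": {94: 0.167, 96: 0.103, 98: 0.029, 100: 0.267, 104: 0.112, 106: 0.322},
    "FH2054": {152: 0.029, 156: 0.305, 160: 0.210, 164: 0.181, 168: 0.264, 172: 0.011},
    "REN162c04": {196: 0.101, 202: 0.242, 204: 0.256, 206: 0.359, 208: 0.043},
    "AHT171": {217: 0.342, 219: 0.164, 221: 0.109, 223: 0.034, 225: 0.259,
               227: 0.026, 229: 0.011, 233: 0.055},
    "REN247M23": {266: 0.247, 268: 0.632, 270: 0.046, 278: 0.075},
    "REN64e19": {139: 0.170, 141: 0.158, 145: 0.158, 147: 0.221, 149: 0.006,
                 151: 0.014, 155: 0.273},
    "AHTh130": {121: 0.091, 125: 0.032, 127: 0.773, 131: 0.112},
    "REN115lo3": {227: 0.187, 229: 0.092, 233: 0.322, 235: 0.356, 239: 0.017, 241: 0.026},
}

# printed per-locus statistics: (PIC, Ho, He, FIS, HWE p-value)
_PRINTED = {
    "AHTk211": (0.477, 0.580, 0.570, -0.018, 0.030),
    "CXX279": (0.695, 0.764, 0.731, -0.046, 0.053),
    "REN169O18": (0.648, 0.684, 0.702, 0.026, 0.061),
    "INU055": (0.430, 0.483, 0.458, -0.055, 0.010),
    "REN54P11": (0.667, 0.707, 0.715, 0.011, 0.616),
    "INRA21": (0.514, 0.540, 0.577, 0.064, 0.004),
    "AHT137": (0.560, 0.638, 0.602, -0.059, 0.138),
    "REN169d01": (0.684, 0.753, 0.730, -0.031, 0.003),
    "AHTh260": (0.696, 0.759, 0.738, -0.027, 0.178),
    "AHTk253": (0.446, 0.529, 0.477, -0.108, 0.869),
    "INU005": (0.474, 0.477, 0.513, 0.070, 0.121),
    "INU030": (0.432, 0.580, 0.535, -0.086, 0.041),
    "FH2848": (0.651, 0.701, 0.705, 0.006, 0.113),
    "AHT121": (0.739, 0.810, 0.773, -0.048, 0.044),
    "FH2054": (0.719, 0.707, 0.760, 0.070, 0.001),
    "REN162c04": (0.692, 0.787, 0.737, -0.068, 0.004),
    "AHT171": (0.741, 0.816, 0.773, -0.056, 0.028),
    "REN247M23": (0.476, 0.529, 0.532, 0.005, 0.062),
    "REN64e19": (0.767, 0.764, 0.798, 0.042, 0.028),
    "AHTh130": (0.361, 0.374, 0.384, 0.026, 0.013),
    "REN115lo3": (0.678, 0.793, 0.725, -0.094, 0.418),
}


def panel_loci() -> list[str]:
    """Locus names in panel order."""
    return list(PANEL_FREQUENCIES)


def locus_frequencies(locus: str, renormalise: bool = False) -> dict[int, float]:
    """Frequency set of one locus; optionally renormalised to sum exactly 1."""
    freqs = dict(PANEL_FREQUENCIES[locus])
    if renormalise:
        total = sum(freqs.values())
        freqs = {a: p / total for a, p in freqs.items()}
    return freqs


def printed_locus_stats() -> pd.DataFrame:
    """Published per-locus summary table (PIC, Ho, He, FIS, HWE p)."""
    rows = [{"locus": loc, "n_alleles": len(PANEL_FREQUENCIES[loc]),
             "PIC": v[0], "Ho": v[1], "He": v[2], "FIS": v[3], "hwe_p": v[4]}
            for loc, v in _PRINTED.items()]
    return pd.DataFrame(rows).set_index("locus")
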