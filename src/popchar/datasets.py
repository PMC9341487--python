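"""Published reference coordinates for the Purunã composite breed.

Small plain-text constants used for arithmetic cross-checks (segment-length
conventions, breed-fraction recursion) and as example inputs.  Coordinates
are 1-based bp on the bovine autosomes (ARS-UCD1.2).
"""

from __future__ import annotations

import pandas as pd

#: Expected base-breed fractions of the composite under the two-stage
#: crossing design (Charolais x Caracu) x (Angus x Canchim), with Canchim
#: itself 5/8 Charolais + 3/8 Nellore.
EXPECTED_COMPOSITE_FRACTIONS = {
    "CHL": 13 / 32,
    "CAR": 8 / 32,
    "ANG": 8 / 32,
    "NEL": 3 / 32,
}

#: The BTA5 region in homozygosity in 36% of genotyped Purunã animals:
#: (chrom, start_bp, end_bp, n_snps).
ROH_ISLAND_BTA5 = (5, 54_304_681, 62_031_799, 131)

#: HER islands present in at least 10% of genotyped Purunã animals:
#: chrom, incidence_pct, start_bp (BP1), end_bp (BP2), n_snps, length_bp.
_HER_ISLAND_ROWS = [
    (1, 11, 26_505_838, 29_555_484, 22, 3_049_646),
    (2, 17, 42_384_465, 43_575_039, 23, 1_190_574),
    (3, 10, 8_435_805, 9_838_978, 23, 1_403_173),
    (5, 14, 70_752_944, 72_012_890, 23, 1_259_946),
    (5, 14, 75_043_240, 75_983_135, 26, 939_895),
    (6, 11, 27_154_761, 28_275_511, 21, 1_120_750),
    (7, 13, 8_562_310, 10_432_630, 24, 1_870_320),
    (10, 11, 44_820_482, 46_032_038, 25, 1_211_556),
    (11, 14, 67_243_961, 69_096_131, 22, 1_852_170),
    (12, 10, 40_237_435, 41_970_427, 25, 1_732_992),
    (14, 17, 24_167_298, 25_953_073, 24, 1_785_775),
    (14, 16, 50_608_626, 51_640_291, 23, 1_031_665),
    (15, 10, 1_215_097, 1_819_862, 30, 604_765),
    (18, 10, 23_515_690, 24_470_198, 23, 954_508),
    (19, 12, 34_233_799, 35_283_135, 25, 1_049_336),
    (20, 10, 44_099_958, 45_220_153, 21, 1_120_195),
    (22, 10, 48_961_009, 52_638_988, 21, 3_677_979),
    (23, 27, 26_021, 1_697_122, 27, 1_671_101),
    (24, 10, 40_975_659, 41_855_725, 21, 880_066),
]


def her_islands() -> pd.DataFrame:
    """Published Purunã HER-island table as a DataFrame."""
    return pd.DataFrame(
        _HER_ISLAND_ROWS,
        columns=["chrom", "incidence_pct", "start_bp", "end_bp", "n_snps", "length_bp"],
    )
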