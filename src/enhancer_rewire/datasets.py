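"""Published reference tallies used for rate arithmetic.

Per-tissue enhancer counts for the 11 orthologous human/mouse tissues,
with the human enhancers broken down into enhancer gains (EG),
functionally conserved enhancers (FCE) and reprogrammed enhancers (RPE).
Multi-tissue enhancers are counted once per tissue they are active in, so
the category columns sum to the human enhancer column per row.

The cumulative reprogramming rate of a tissue is RPE / human enhancers;
across these tissues it ranges from 25% (placenta) to 30% (cortex).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_tissue_counts", "cumulative_reprogramming_rate"]

_ROWS = [
    # tissue, human, mouse, human_EG, human_FCE, human_RPE
    ("BAT", 35356, 47267, 17309, 6566, 11481),
    ("Cortex", 27682, 57310, 13198, 6070, 8414),
    ("Heart", 36003, 61646, 16789, 8370, 10844),
    ("Intestine", 18581, 48469, 9296, 3359, 5926),
    ("Liver", 37241, 53162, 21061, 6125, 10055),
    ("Lung", 28932, 61685, 14576, 5890, 8466),
    ("Placenta", 31221, 61926, 17925, 5433, 7863),
    ("Spleen", 24152, 38090, 14245, 3102, 6805),
    ("Thymus", 14722, 35854, 7735, 2362, 4625),
    ("Limb", 40101, 62557, 19908, 8501, 11692),
    ("Leukemia", 19907, 36488, 12797, 1303, 5807),
]


def reference_tissue_counts() -> pd.DataFrame:
    """The 11-tissue reference table as a DataFrame indexed by tissue."""
    df = pd.DataFrame(
        _ROWS,
        columns=["tissue", "human_enhancers", "mouse_enhancers",
                 "human_EG", "human_FCE", "human_RPE"],
    ).set_index("tissue")
    return df


def cumulative_reprogramming_rate(tissue: str) -> float:
    """Fraction of a tissue's human enhancers categorised as reprogrammed."""
    df = reference_tissue_counts()
    row = df.loc[tissue]
    return row["human_RPE"] / row["human_enhancers"]
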