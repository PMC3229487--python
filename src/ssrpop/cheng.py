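"""Morphological indica/japonica classification by the Cheng index.

Six diagnostic traits (glume hair, phenol reaction, length of the 1st-2nd
rachis internode, glume color at heading, leaf hair, grain length/width
ratio) are each scored 0-4, with 0 the indica-typical and 4 the
japonica-typical expression.  The index is the sum of the six scores
(0-24) and classifies a variety as typical indica (<=7), indica-clined
(8-13), japonica-clined (14-17) or typical japonica (>=18).

The two measured traits are binned as follows (half-open bins anchored so
every printed interval boundary keeps its printed score; values falling
in the gaps between printed intervals go to the adjacent lower-magnitude
bin):

* rachis internode (cm): <=2.0 -> 0, <=2.5 -> 1, <=3.0 -> 2, <=3.5 -> 3, else 4
* grain length/width:    >3.5 -> 0, >=3.1 -> 1, >=2.6 -> 2, >=2.1 -> 3, else 4
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import NUMERIC_TRAITS, ORDINAL_TRAITS

TYPICAL_INDICA = "typical-indica"
INDICA_CLINED = "indica-clined"
JAPONICA_CLINED = "japonica-clined"
TYPICAL_JAPONICA = "typical-japonica"

CLASSES = (TYPICAL_INDICA, INDICA_CLINED, JAPONICA_CLINED, TYPICAL_JAPONICA)

#: score order used throughout: the six traits of the index
SCORE_COLUMNS = ("glume_hair", "phenol_reaction", "rachis_score",
                 "glume_color", "leaf_hair", "grain_score")

MAX_INDEX = 4 * 6  # every trait at its highest score


@dataclass(frozen=True)
class ChengRecord:
    variety_id: str
    scores: tuple[int, int, int, int, int, int]
    index: int
    cheng_class: str


def score_numeric_trait(trait: str, value: float) -> int:
    """Score rachis-internode length (cm) or grain L/W ratio on 0-4."""
    if value <= 0:
        raise ValueError(f"{trait} must be positive, got {value}")
    if trait == "rachis_cm":
        return int(np.searchsorted([2.0, 2.5, 3.0, 3.5], value, side="left"))
    if trait == "grain_lw":
        if value > 3.5:
            return 0
        if value >= 3.1:
            return 1
        if value >= 2.6:
            return 2
        if value >= 2.1:
            return 3
        return 4
    raise ValueError(f"unknown numeric trait {trait!r}")


def classify_index(index: int) -> str:
    if index <= 7:
        return TYPICAL_INDICA
    if index <= 13:
        return INDICA_CLINED
    if index <= 17:
        return JAPONICA_CLINED
    return TYPICAL_JAPONICA


def cheng_classify(scores, variety_id: str = "") -> ChengRecord:
    """Sum six 0-4 trait scores into the index and its 4-way class."""
    scores = tuple(int(s) for s in scores)
    if len(scores) != 6:
        raise ValueError(f"expected six scores, got {len(scores)}")
    if any(s < 0 or s > 4 for s in scores):
        raise ValueError(f"scores must be in 0..4: {scores}")
    index = sum(scores)
    return ChengRecord(variety_id, scores, index, classify_index(index))


def score_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Turn a trait table into the six 0-4 scores (SCORE_COLUMNS order)."""
    out = pd.DataFrame(index=traits.index)
    out["glume_hair"] = traits["glume_hair"]
    out["phenol_reaction"] = traits["phenol_reaction"]
    out["rachis_score"] = [score_numeric_trait("rachis_cm", v)
                           for v in traits["rachis_cm"]]
    out["glume_color"] = traits["glume_color"]
    out["leaf_hair"] = traits["leaf_hair"]
    out["grain_score"] = [score_numeric_trait("grain_lw", v)
                          for v in traits["grain_lw"]]
    return out.astype(int)


def classify_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Score + classify a whole trait table.

    Returns a frame with the six scores, the summed index and the class.
    """
    scores = score_traits(traits)
    out = scores.copy()
    out["index"] = scores.sum(axis=1)
    out["cheng_class"] = [classify_index(i) for i in out["index"]]
    return out


def germplasm_type(cheng_class: str) -> str:
    """Collapse the 4-way class to the indica/japonica germplasm type."""
    return "indica" if cheng_class in (TYPICAL_INDICA, INDICA_CLINED) else "japonica"
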