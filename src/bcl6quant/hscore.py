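"""HSCORE semi-quantitative immunostaining scoring.

The HSCORE summarises nuclear staining of the glandular epithelium on a
0-4 scale from the percentages of epithelial cells labelled at three
visually judged intensities (weak, moderate, intense):

    HSCORE = sum_i P_i * (i + 1) / 100,   i in {1, 2, 3}

where ``P_i`` is the percentage of epithelial cells labelled at
intensity ``i`` (0-100); cells may remain unlabelled, so the three
percentages need not sum to 100.  The score reaches 4 when every cell
is intensely labelled and 0 when no cell is labelled.

For validation against the pixel-based pipeline, continuous intensities
can be bucketed into the three categories with configurable grey-level
cut points; blinded observers are compared by per-section absolute
difference and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError

#: default grey-level cuts (unlabelled | weak | moderate | intense):
#: equal quartiles of the 8-bit range; observers judge these visually,
#: so the cuts are a convention, not a measurement.
DEFAULT_CUTS = (63, 127, 191)

#: optional positivity cutoff from earlier diagnostic work (score >= 1.4
#: called elevated); provided as a convenience flag only, not validated
#: against any clinical claim here.
EVANS_HOEKER_CUTOFF = 1.4


@dataclass(frozen=True)
class CategoryPercentages:
    """Percentages of epithelial cells labelled weak/moderate/intense."""

    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ContractError(f"{name}={v} outside [0, 100]")
        if self.p1 + self.p2 + self.p3 > 100.0 + 1e-9:
            raise ContractError(
                f"category percentages sum to {self.p1 + self.p2 + self.p3} > 100"
            )

    @property
    def unlabelled(self) -> float:
        return 100.0 - (self.p1 + self.p2 + self.p3)


@dataclass
class HScoreResult:
    """A scalar HSCORE in [0, 4] for one section (and optional observer)."""

    score: float
    section_id: str = ""
    observer_id: str | None = None


@dataclass
class ObserverAgreement:
    """Between-observer agreement over paired per-section HSCOREs."""

    mean_abs_diff: float
    r: float
    consensus: pd.Series  # per-section mean of the two observers


def compute_hscore(
    p: CategoryPercentages | tuple[float, float, float],
    section_id: str = "",
    observer_id: str | None = None,
) -> HScoreResult:
    """Evaluate ``HSCORE = sum_i P_i (i + 1) / 100`` on a 0-4 scale."""
    if not isinstance(p, CategoryPercentages):
        p = CategoryPercentages(*p)
    score = (p.p1 * 2.0 + p.p2 * 3.0 + p.p3 * 4.0) / 100.0
    return HScoreResult(score=score, section_id=section_id, observer_id=observer_id)


def categorize_intensities(
    values: np.ndarray,
    cuts: tuple[float, float, float] = DEFAULT_CUTS,
) -> CategoryPercentages:
    """Bucket continuous intensities into weak/moderate/intense percentages.

    With cuts ``(c1, c2, c3)``: unlabelled <= c1 < weak <= c2 < moderate
    <= c3 < intense.  Bridges the pixel-based measurement to the
    categorical score so the two quantification routes can be compared
    on synthetic data.
    """
    c1, c2, c3 = cuts
    if not (0 <= c1 < c2 < c3 <= 255):
        raise ContractError(f"cuts must satisfy 0 <= c1 < c2 < c3 <= 255, got {cuts}")
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ContractError("cannot categorize an empty set of intensities")
    n = values.size
    p1 = 100.0 * np.count_nonzero((values > c1) & (values <= c2)) / n
    p2 = 100.0 * np.count_nonzero((values > c2) & (values <= c3)) / n
    p3 = 100.0 * np.count_nonzero(values > c3) / n
    return CategoryPercentages(p1, p2, p3)


def hscore_from_distribution(
    counts: np.ndarray, cuts: tuple[float, float, float] = DEFAULT_CUTS
) -> float:
    """HSCORE of a 256-level intensity histogram via categorisation.

    Pixel counts per grey level stand in for cell counts per intensity
    category; equivalent to categorising the underlying pixel values.
    """
    counts = np.asarray(counts, dtype=np.float64)
    levels = np.arange(counts.size)
    total = counts.sum()
    if total <= 0:
        raise ContractError("empty distribution has no HSCORE")
    c1, c2, c3 = cuts
    p1 = 100.0 * counts[(levels > c1) & (levels <= c2)].sum() / total
    p2 = 100.0 * counts[(levels > c2) & (levels <= c3)].sum() / total
    p3 = 100.0 * counts[levels > c3].sum() / total
    return compute_hscore(CategoryPercentages(p1, p2, p3)).score


def observer_agreement(
    scores_a: Mapping[str, float] | pd.Series,
    scores_b: Mapping[str, float] | pd.Series,
) -> ObserverAgreement:
    """Compare two blinded observers' per-section HSCOREs.

    Sections are paired by id; unpaired sections are a contract error
    (named in the message).  Returns the mean absolute per-section
    difference, the Pearson correlation, and the per-section consensus
    (mean of the two observers).
    """
    a = pd.Series(scores_a, dtype=float)
    b = pd.Series(scores_b, dtype=float)
    unpaired = sorted(set(a.index) ^ set(b.index))
    if unpaired:
        raise ContractError(f"unpaired sections: {unpaired}")
    if len(a) < 3:
        raise ContractError("observer agreement requires >= 3 paired sections")
    b = b.reindex(a.index)
    diff = float((a - b).abs().mean())
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        r = 1.0 if diff == 0 or (a - b).std(ddof=0) == 0 else np.nan
    else:
        r = float(sps.pearsonr(a, b).statistic)
    return ObserverAgreement(mean_abs_diff=diff, r=r, consensus=(a + b) / 2.0)


def consensus_scores(metas: Sequence) -> dict[str, float]:
    """Per-section mean of available observer HSCOREs from metadata."""
    out = {}
    for m in metas:
        if m.observer_hscores:
            out[m.section_id] = float(np.mean(m.observer_hscores))
    return out
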