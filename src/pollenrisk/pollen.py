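"""Pollen composition metrics from morphotype grain counts.

A morphotype is retained if it reaches the sporadic threshold (default 3%
relative abundance) on at least one slide in the study; everything else is
pooled into "other".  Richness counts retained morphotypes with a positive
count in a sample — the "other" pool never counts toward richness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import PollenSample

__all__ = ["classify_sporadic", "composition", "PollenComposition", "OTHER"]

OTHER = "other"


def classify_sporadic(
    samples: Sequence[PollenSample], threshold: float = 0.03
) -> set[str]:
    """Morphotypes at >= ``threshold`` relative abundance in at least one
    sample; all others are sporadic and pooled into "other".

    The comparison is >= (boundary counts as retained).  A threshold of 0
    retains every observed morphotype.
    """
    if not samples:
        raise ValueError("classify_sporadic needs at least one sample")
    if not (0 <= threshold <= 1):
        raise ValueError(f"threshold must be a fraction in [0, 1], got {threshold}")
    retained: set[str] = set()
    for s in samples:
        if s.total_counted == 0:
            raise ValueError(f"{s.site_id}: empty pollen counts")
        for m, c in s.counts.items():
            if c > 0 and c / s.total_counted >= threshold:
                retained.add(m)
    return retained


@dataclass(frozen=True)
class PollenComposition:
    """Relative abundances of retained morphotypes for one site, the pooled
    sporadic fraction, the focal-crop fraction, and richness."""

    site_id: str
    rel_abundance: Mapping[str, float]
    other_fraction: float
    focal_fraction: float
    richness: int


def composition(
    sample: PollenSample,
    retained: set[str],
    focal: str = "Malus",
) -> PollenComposition:
    """Normalize one sample's counts over the retained morphotype set.

    Fractions are count/total; sporadic (non-retained) grains are pooled
    into ``other_fraction``; richness counts retained morphotypes with a
    positive count in this sample.  The focal fraction is 0 when the focal
    morphotype is absent (or itself sporadic).
    """
    if sample.total_counted <= 0:
        raise ValueError(f"{sample.site_id}: zero grains counted")
    total = sample.total_counted
    rel = {}
    other = 0.0
    richness = 0
    for m, c in sample.counts.items():
        if m in retained:
            rel[m] = c / total
            if c > 0:
                richness += 1
        else:
            other += c / total
    return PollenComposition(
        site_id=sample.site_id,
        rel_abundance=rel,
        other_fraction=other,
        focal_fraction=rel.get(focal, 0.0),
        richness=richness,
    )
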