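"""Standard curves, quantification and label-claim comparison.

A qPCR standard curve is the ordinary least-squares line
``Ct = slope * log10(concentration) + intercept``; per-cycle
amplification efficiency follows from the slope as
``(10**(-1/slope) - 1) * 100`` (a slope of -1/log10(2) = -3.3219 means
perfect doubling, 100%).  Quantification inverts the line; estimates
outside the calibrated dynamic range (default 8e5 to 8e9 CFU/mL) are
returned but flagged extrapolated.

Label-claim comparison maps a product's labeled taxa against the taxa a
species/subspecies-specific assay detected, with a species-level label
satisfied by any of its subspecies (products are often labeled only to
species level while the assay resolves subspecies).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "DetectionCall",
    "LabelComparison",
    "Taxonomy",
    "fit_standard_curve",
    "efficiency_from_slope",
    "quantify",
    "compare_to_label",
    "CT_CUTOFF",
    "DEFAULT_DYNAMIC_RANGE",
]

logger = logging.getLogger(__name__)

CT_CUTOFF = 35.0  # assay runs 35 cycles
DEFAULT_DYNAMIC_RANGE = (math.log10(8e5), math.log10(8e9))
R2_RELIABLE = 0.98


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope."""
    if slope >= 0:
        raise ValueError("a valid standard curve has a negative slope")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


@dataclass(frozen=True)
class StandardCurve:
    taxon: str
    slope: float  # Ct per log10(CFU/mL)
    intercept: float  # Ct
    r_squared: float
    efficiency_percent: float
    dynamic_range: tuple[float, float] = DEFAULT_DYNAMIC_RANGE

    def predict(self, log10_conc: float) -> float:
        return self.slope * log10_conc + self.intercept

    def invert(self, ct: float) -> float:
        return (ct - self.intercept) / self.slope


def fit_standard_curve(
    points: list[tuple[float, float]],
    taxon: str = "",
    dynamic_range: tuple[float, float] | None = None,
) -> StandardCurve:
    """OLS fit of Ct against log10 concentration.

    Needs >= 3 distinct concentrations.  R^2 is the squared Pearson
    correlation; a warning is logged below the 0.98 reliability
    threshold conventional for quantitative assays.
    """
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(xs)) < 3:
        raise ValueError("fit_standard_curve needs >= 3 distinct concentrations")
    fit = stats.linregress(xs, ys)
    r2 = float(fit.rvalue**2)
    if r2 < R2_RELIABLE:
        logger.warning("standard curve for %s has R^2=%.4f < %.2f", taxon or "?", r2, R2_RELIABLE)
    rng = dynamic_range
    if rng is None:
        rng = (float(xs.min()), float(xs.max())) if len(xs) else DEFAULT_DYNAMIC_RANGE
    return StandardCurve(
        taxon=taxon,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        efficiency_percent=efficiency_from_slope(float(fit.slope)),
        dynamic_range=rng,
    )


@dataclass(frozen=True)
class DetectionCall:
    product_id: str
    taxon: str
    ct: float | None  # None = no amplification
    positive: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", self.ct is not None and self.ct <= CT_CUTOFF)


def quantify(ct: float, curve: StandardCurve) -> tuple[float, bool]:
    """(estimated log10 CFU/mL, extrapolated?) from a Ct and a curve."""
    x = curve.invert(ct)
    lo, hi = curve.dynamic_range
    return x, not lo <= x <= hi


@dataclass
class Taxonomy:
    """Declared taxon vocabulary: species -> list of subspecies labels.

    Species without subspecies map to an empty list.  ``nonspecific``
    holds tokens like "Lactic acid bacteria" that name no taxon the
    assay can verify.
    """

    species: dict[str, list[str]]
    nonspecific: list[str] = field(default_factory=list)

    def vocabulary(self) -> list[str]:
        vocab = list(self.nonspecific)
        for sp, subs in self.species.items():
            vocab.append(sp)
            vocab.extend(subs)
        return sorted(vocab)

    def parent_of(self, taxon: str) -> str | None:
        for sp, subs in self.species.items():
            if taxon in subs:
                return sp
        return None

    def check(self, taxon: str) -> None:
        if taxon not in self.vocabulary():
            raise ValueError(
                f"unknown taxon {taxon!r}; known vocabulary: {self.vocabulary()}"
            )


@dataclass(frozen=True)
class LabelComparison:
    product_id: str
    labeled: tuple[str, ...]
    detected: tuple[str, ...]
    verdict: str  # consistent | consistent_with_refinement | mismatch | unverifiable_label
    detail: str = ""


def compare_to_label(
    product_id: str,
    labeled: list[str],
    detected: list[str],
    taxonomy: Taxonomy,
) -> LabelComparison:
    """Deterministic verdict on a product's label versus assay detections.

    Rules, in order: (1) all labels non-specific -> unverifiable_label;
    (2) a labeled subspecies must be detected exactly, a labeled species
    is satisfied by itself or any of its subspecies; (3) a detection not
    covered by any label (species labels covering their subspecies) is a
    mismatch, as is an unsatisfied label; (4) otherwise consistent, or
    consistent_with_refinement when a species-level label was satisfied
    only at subspecies level.
    """
    for t in list(labeled) + list(detected):
        taxonomy.check(t)
    labeled_set = sorted(set(labeled))
    detected_set = sorted(set(detected))
    specific = [t for t in labeled_set if t not in taxonomy.nonspecific]
    if labeled_set and not specific:
        return LabelComparison(
            product_id, tuple(labeled_set), tuple(detected_set), "unverifiable_label",
            detail=f"detected: {', '.join(detected_set) or 'none'}",
        )

    notes = []
    refined = False
    unsatisfied = []
    for lab in specific:
        subs = taxonomy.species.get(lab, [])
        if lab in detected_set:
            continue
        hit = [d for d in detected_set if d in subs]
        if hit:
            refined = True
            notes.append(f"{lab} refined to {'/'.join(hit)}")
        else:
            unsatisfied.append(lab)

    covered = set()
    for lab in specific:
        covered.add(lab)
        covered.update(taxonomy.species.get(lab, []))
    extras = [d for d in detected_set if d not in covered]

    if unsatisfied or extras:
        bits = []
        if unsatisfied:
            bits.append(f"labeled but not detected: {', '.join(unsatisfied)}")
        if extras:
            bits.append(f"detected but not labeled: {', '.join(extras)}")
        return LabelComparison(
            product_id, tuple(labeled_set), tuple(detected_set), "mismatch", "; ".join(bits)
        )
    verdict = "consistent_with_refinement" if refined else "consistent"
    return LabelComparison(
        product_id, tuple(labeled_set), tuple(detected_set), verdict, "; ".join(notes)
    )
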