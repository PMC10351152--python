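"""Organoid drug-response scoring (RS) and Bliss-independence synergy.

The response score of a treated patient-derived organoid (PDO) culture is the
ratio of the products (organoid count x mean maximal diameter x viability)
at baseline versus after 72 h of treatment:

    RS = (n0 * d0 * v0) / (n72 * d72 * v72)

RS = 1 means no effect; larger values mean stronger response (fewer, smaller
or less viable organoids after treatment).  Synergy of a two-drug dose grid is
summarized as 100x the mean excess of observed inhibition over the Bliss
independence expectation ``y_a + y_b - y_a*y_b``, with the conventional
bands: score < -10 antagonistic, -10..10 additive, > 10 synergistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ValidationError


@dataclass
class OrganoidTimepoint:
    """One timepoint of a PDO culture: count, mean max diameter (um), viability.

    Viability may be entered as a percent (0-100] or a fraction [0-1];
    percent inputs are normalized to fractions on construction.  Use the same
    convention for both timepoints of a comparison.
    """

    n_organoids: int
    mean_max_diameter: float
    viability: float

    def __post_init__(self) -> None:
        if self.n_organoids < 0:
            raise ValidationError("n_organoids must be non-negative")
        if self.viability > 1.0:
            self.viability = self.viability / 100.0
        if not 0.0 <= self.viability <= 1.0:
            raise ValidationError("viability must be a fraction or percent")
        if self.n_organoids > 0 and self.mean_max_diameter <= 0:
            raise ValidationError("diameter must be positive when organoids exist")

    @property
    def product(self) -> float:
        return self.n_organoids * self.mean_max_diameter * self.viability


@dataclass
class ResponseScore:
    rs: float
    components: tuple[float, float]  # (t0 product, t72 product)
    infinite: bool = False
    label: str | None = None


def response_score(
    t0: OrganoidTimepoint, t72: OrganoidTimepoint, use_viability: bool = True
) -> ResponseScore:
    """RS = t0 product / t72 product.

    ``use_viability=False`` drops the viability factor from both products
    (the two-factor variant of the score).  A zero 72 h product (no surviving
    organoids) yields an infinite RS with ``infinite=True`` rather than an
    exception.
    """
    if use_viability:
        p0, p72 = t0.product, t72.product
    else:
        p0 = t0.n_organoids * t0.mean_max_diameter
        p72 = t72.n_organoids * t72.mean_max_diameter
    if p72 == 0:
        return ResponseScore(rs=math.inf, components=(p0, p72), infinite=True)
    return ResponseScore(rs=p0 / p72, components=(p0, p72))


def classify_sensitivity(
    rs_treated: ResponseScore, rs_control: ResponseScore, margin: float = 0.2
) -> str:
    """Label a PDO sensitive when the treated RS exceeds the control RS by
    more than ``margin`` (relative); resistant otherwise.

    The cutoff is a package convention: any treated/control ratio within the
    margin is read as no treatment effect.
    """
    if margin < 0:
        raise ValidationError("margin must be non-negative")
    if rs_treated.infinite:
        return "sensitive"
    if rs_control.infinite:
        return "resistant"
    return "sensitive" if rs_treated.rs > rs_control.rs * (1.0 + margin) else "resistant"


def bliss_expected(y_a: float, y_b: float) -> float:
    """Bliss independence expectation for inhibition fractions."""
    if not (0.0 <= y_a <= 1.0 and 0.0 <= y_b <= 1.0):
        raise ValidationError("inhibition fractions must lie in [0, 1]")
    return y_a + y_b - y_a * y_b


@dataclass
class DoseResponseMatrix:
    """Inhibition fractions on a two-agent dose grid (rows: agent a doses).

    Both dose vectors must start at 0 (single-agent margins); inhibition at
    (0, 0) is 0 by convention.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.doses_a.ndim != 1 or self.doses_b.ndim != 1:
            raise ValidationError("dose vectors must be one-dimensional")
        if self.doses_a[0] != 0.0 or self.doses_b[0] != 0.0:
            raise ValidationError("dose grids must include zero-dose margins")
        if (np.diff(self.doses_a) <= 0).any() or (np.diff(self.doses_b) <= 0).any():
            raise ValidationError("doses must be strictly ascending")
        if self.inhibition.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValidationError("inhibition grid does not match dose vectors")
        if np.isnan(self.inhibition).any():
            raise ValidationError("inhibition grid is incomplete")
        if ((self.inhibition < 0) | (self.inhibition > 1)).any():
            raise ValidationError("inhibition must lie in [0, 1]")
        if self.inhibition[0, 0] != 0.0:
            raise ValidationError("inhibition at (0, 0) must be 0")

    def swapped(self) -> "DoseResponseMatrix":
        return DoseResponseMatrix(self.doses_b, self.doses_a, self.inhibition.T)


@dataclass
class SynergyResult:
    bliss_score: float  # x100 scale
    excess: np.ndarray  # per combination cell (i>0, j>0)
    classification: str


def classify_bliss(score: float) -> str:
    """-10/+10 bands; a score of exactly +/-10 counts as additive."""
    if score < -10.0:
        return "antagonistic"
    if score > 10.0:
        return "synergistic"
    return "additive"


def bliss_synergy_score(m: DoseResponseMatrix, include_margins: bool = False) -> SynergyResult:
    """Mean Bliss excess over the combination cells, on the x100 scale.

    ``excess(i, j) = inhibition(i, j) - bliss_expected(margin_a(i), margin_b(j))``
    for i > 0, j > 0.  ``include_margins=True`` also averages the single-agent
    cells (whose excess is 0 by construction), diluting the score.
    """
    ya = m.inhibition[:, 0]
    yb = m.inhibition[0, :]
    expected = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    full_excess = m.inhibition - expected
    combo = full_excess[1:, 1:]
    if include_margins:
        score = 100.0 * float(full_excess.mean())
    else:
        if combo.size == 0:
            raise ValidationError("no combination cells in the grid")
        score = 100.0 * float(combo.mean())
    return SynergyResult(bliss_score=score, excess=combo, classification=classify_bliss(score))
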