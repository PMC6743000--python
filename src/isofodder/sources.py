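"""Diet–tissue spacing and C3/C4 dietary end-members.

Consumer tissues are systematically offset from diet in delta13C (the
diet–tissue discrimination, or "spacing", factor): large for enamel
bioapatite, smaller for bone collagen and keratin.  Subtracting the spacing
converts a tissue value to a dietary value on a common scale, from which the
two dietary end-members — local C3 steppe vegetation (reconstructed from wild
and free-ranging herbivores) and cultivated broomcorn millet (C4) — are
summarised as normal source distributions for the mixing model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpacingTable",
    "DietSource",
    "tissue_to_diet",
    "build_source_distributions",
    "DEFAULT_SPACING",
]


class UnknownTissueError(KeyError):
    """Raised when a tissue kind has no entry in the spacing table."""


@dataclass(frozen=True)
class SpacingTable:
    """Per-tissue diet-to-tissue delta13C spacing in permil.

    Defaults are standard isotope-ecology values for large herbivores:
    +14.1 permil for enamel bioapatite (whole diet), +5.0 permil for bone
    collagen (dietary protein), +3.2 permil for hair keratin.  All are
    overridable per run, and every analysis output records the table used.
    """

    spacing: dict = field(
        default_factory=lambda: {"enamel": 14.1, "collagen": 5.0, "hair": 3.2}
    )
    sd: dict = field(default_factory=dict)

    def __post_init__(self):
        for kind, value in self.spacing.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite spacing for tissue {kind!r}")

    def __contains__(self, tissue_kind: str) -> bool:
        return tissue_kind in self.spacing

    def get(self, tissue_kind: str) -> float:
        try:
            return float(self.spacing[tissue_kind])
        except KeyError:
            raise UnknownTissueError(
                f"unknown tissue kind {tissue_kind!r}; known: {sorted(self.spacing)}"
            ) from None

    def to_dict(self) -> dict:
        return {"spacing": dict(self.spacing), "sd": dict(self.sd)}


DEFAULT_SPACING = SpacingTable()


@dataclass(frozen=True)
class DietSource:
    """A dietary delta13C end-member summarised as a normal distribution."""

    name: str
    mean: float
    sd: float
    n: int = 0

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"source {self.name!r} requires sd > 0, got {self.sd}")


def tissue_to_diet(value, tissue_kind, table: SpacingTable = DEFAULT_SPACING):
    """Convert tissue delta13C to dietary delta13C by subtracting the spacing.

    Parameters
    ----------
    value : float or array-like
        Tissue delta13C in permil VPDB.
    tissue_kind : str or array-like of str
        Tissue of each value; every kind must appear in `table`.
    table : SpacingTable

    Returns
    -------
    Same shape as `value`: dietary delta13C in permil.
    """
    if isinstance(tissue_kind, str):
        offset = table.get(tissue_kind)
        if np.isscalar(value):
            return float(value) - offset
        return np.asarray(value, dtype=float) - offset
    kinds = pd.Series(tissue_kind).astype(str)
    offsets = kinds.map(lambda k: table.get(k)).to_numpy(dtype=float)
    return np.asarray(value, dtype=float) - offsets


def build_source_distributions(
    reference_diet_values,
    millet_values,
    sd_floor: float = 0.3,
) -> tuple[DietSource, DietSource]:
    """Summarise C3 and C4 dietary end-members from observed dietary values.

    `reference_diet_values` are spacing-corrected dietary delta13C values of
    local wild/free-ranging herbivores (the C3 end-member); `millet_values`
    are measured delta13C of broomcorn millet (the C4 end-member).  Sample
    standard deviations use the n-1 denominator with a floor of `sd_floor`
    permil to avoid degenerate likelihoods from tiny reference sets.

    Raises
    ------
    ValueError
        If either source has fewer than 2 values, or the C3 mean is not
        below the C4 mean ("sources not separable").
    """
    ref = np.asarray(reference_diet_values, dtype=float)
    mil = np.asarray(millet_values, dtype=float)
    if ref.size < 2 or mil.size < 2:
        raise ValueError("need >= 2 values per source")
    if not (np.isfinite(ref).all() and np.isfinite(mil).all()):
        raise ValueError("non-finite source values")
    c3_mean, c4_mean = ref.mean(), mil.mean()
    if c3_mean >= c4_mean:
        raise ValueError(
            f"sources not separable: C3 mean {c3_mean:.2f} >= C4 mean {c4_mean:.2f}"
        )
    c3 = DietSource("C3_steppe", c3_mean, max(ref.std(ddof=1), sd_floor), ref.size)
    c4 = DietSource("C4_millet", c4_mean, max(mil.std(ddof=1), sd_floor), mil.size)
    return c3, c4
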