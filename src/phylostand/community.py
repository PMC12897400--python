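"""Plot-level community descriptors from inventory tree lists.

Each inventory plot is a list of stems (species, DBH in cm) plus abiotic
covariates.  From the stems we derive per-species basal areas, which drive

* the stand-type classification (conifer / broadleaved / mixed by a 75%
  basal-area-share rule),
* species richness, and
* community-weighted mean (CWM) traits, ``CWM_x = sum_i p_i * t_i`` with
  ``p_i`` the species' share of total plot basal area.

All stems provided in a plot's tree list participate in basal-area sums;
what counts as a "tree" is the data provider's choice, recorded upstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "TreeRecord",
    "PlotCommunity",
    "TraitTable",
    "basal_area",
    "classify_stand",
    "species_richness",
    "species_basal_areas",
    "cwm",
    "STAND_TYPES",
]

STAND_TYPES = ("broadleaved", "conifer", "mixed")

#: basal-area share a single group must reach for a pure stand type
STAND_SHARE_THRESHOLD = 0.75


@dataclass(frozen=True)
class TreeRecord:
    """One stem: species label, DBH (cm) and optional height (m, unused by core math)."""

    species: str
    dbh: float
    height: float | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("empty species label in tree record")
        if not (math.isfinite(self.dbh) and self.dbh > 0):
            raise ValidationError(
                f"dbh must be finite and positive, got {self.dbh!r} for {self.species}"
            )
        if self.height is not None and not (
            math.isfinite(self.height) and self.height > 0
        ):
            raise ValidationError(f"height must be positive, got {self.height!r}")


@dataclass
class PlotCommunity:
    """One inventory plot: stems plus abiotic covariates.

    Covariates: elevation (m), mat (mean annual temperature, degC),
    map_mm (mean annual precipitation, mm), stand_age (yr).
    """

    plot_id: str
    trees: list[TreeRecord]
    elevation: float
    mat: float
    map_mm: float
    stand_age: float

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValidationError(f"plot {self.plot_id}: needs at least one tree")
        for name in ("elevation", "mat", "map_mm", "stand_age"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(
                    f"plot {self.plot_id}: covariate {name} is not finite ({v!r})"
                )

    @property
    def species(self) -> set[str]:
        return {t.species for t in self.trees}


@dataclass
class TraitTable:
    """Species-level trait means: SLA (mm^2/mg), maximum height (m), conifer flag."""

    sla: dict[str, float] = field(default_factory=dict)
    mh: dict[str, float] = field(default_factory=dict)
    is_conifer: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("sla", self.sla), ("mh", self.mh)):
            for sp, v in table.items():
                if v is not None and not (math.isfinite(v) and v > 0):
                    raise ValidationError(
                        f"trait {name} for {sp!r} must be positive, got {v!r}"
                    )

    def trait(self, name: str) -> dict[str, float]:
        if name not in ("sla", "mh"):
            raise ValidationError(f"unknown trait {name!r} (expected 'sla' or 'mh')")
        return getattr(self, name)


def basal_area(dbh: float) -> float:
    """Basal area (m^2) of a stem from its DBH (cm): pi * (dbh / 200)^2."""
    if not (math.isfinite(dbh) and dbh > 0):
        raise ValidationError(f"dbh must be finite and positive, got {dbh!r}")
    return math.pi * (dbh / 200.0) ** 2


def species_basal_areas(plot: PlotCommunity) -> dict[str, float]:
    """Per-species summed stem basal areas (m^2) for one plot."""
    ba: dict[str, float] = {}
    for t in plot.trees:
        ba[t.species] = ba.get(t.species, 0.0) + basal_area(t.dbh)
    return ba


def species_richness(plot: PlotCommunity) -> int:
    """Number of distinct species among the plot's stems."""
    return len(plot.species)


def classify_stand(plot: PlotCommunity, traits: TraitTable) -> str:
    """Classify a plot as 'conifer', 'broadleaved' or 'mixed'.

    Conifer if the conifer basal-area share is >= 75% of total basal area,
    broadleaved if the broadleaved share is >= 75%, otherwise mixed.  The
    threshold is inclusive.  Shares are computed from per-stem basal areas
    summed by species, never from stem counts.
    """
    ba = species_basal_areas(plot)
    missing = sorted(sp for sp in ba if sp not in plot_conifer_flags(traits))
    if missing:
        raise ValidationError(
            f"plot {plot.plot_id}: no conifer/broadleaved flag for species: "
            + ", ".join(missing)
        )
    total = sum(ba.values())
    conifer_share = sum(v for sp, v in ba.items() if traits.is_conifer[sp]) / total
    # shares sum to 1, so test order cannot change the outcome
    if conifer_share >= STAND_SHARE_THRESHOLD:
        return "conifer"
    if (1.0 - conifer_share) >= STAND_SHARE_THRESHOLD:
        return "broadleaved"
    return "mixed"


def plot_conifer_flags(traits: TraitTable) -> dict[str, bool]:
    return traits.is_conifer


def cwm(plot: PlotCommunity, traits: TraitTable, trait_name: str) -> float:
    """Community-weighted mean of a trait, weighted by species basal-area shares.

    ``CWM = sum_i p_i * t_i`` where ``p_i`` is species i's summed basal area
    divided by the total usable basal area.  Species with a missing trait
    value are dropped and the weights renormalized over the remainder; a
    warning reports the basal-area coverage so callers can demand 100% on
    curated data.
    """
    table = traits.trait(trait_name)
    ba = species_basal_areas(plot)
    total = sum(ba.values())
    usable = {sp: v for sp, v in ba.items() if table.get(sp) is not None}
    covered = sum(usable.values())
    if covered <= 0:
        raise ValidationError(
            f"plot {plot.plot_id}: no basal area carries trait {trait_name!r}"
        )
    if covered < total:
        warnings.warn(
            f"plot {plot.plot_id}: trait {trait_name!r} covers "
            f"{100 * covered / total:.1f}% of basal area; weights renormalized",
            stacklevel=2,
        )
    return sum((v / covered) * table[sp] for sp, v in usable.items())
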