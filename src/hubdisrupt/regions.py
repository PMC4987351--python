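"""Brain parcellation regions and hemisphere bookkeeping.

A parcellation is an ordered list of :class:`RegionDefinition` objects.  The
default template mirrors a bilateral cortical/cerebellar parcellation with 44
regions per hemisphere plus a single midline structure (the cerebellar
vermis), i.e. 89 regions in total.  Midline regions have no contralateral
homologue and are dropped from intra-hemispheric analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

HEMISPHERES = ("left", "right", "midline")


@dataclass(frozen=True)
class RegionDefinition:
    """One parcel of the brain parcellation.

    Parameters
    ----------
    region_id
        Unique integer label (as found in a label image).
    name
        Human-readable region name.
    hemisphere
        One of ``"left"``, ``"right"`` or ``"midline"``.
    homologue_id
        ``region_id`` of the contralateral counterpart, or ``None`` for
        midline structures.
    """

    region_id: int
    name: str
    hemisphere: str
    homologue_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.hemisphere == "midline" and self.homologue_id is not None:
            raise ValueError(
                f"midline region {self.region_id} cannot have a homologue"
            )


def validate_regions(regions: Sequence[RegionDefinition]) -> None:
    """Check uniqueness of ids and the left/right homologue bijection."""
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("region_ids are not unique")
    by_id = {r.region_id: r for r in regions}
    for r in regions:
        if r.homologue_id is None:
            continue
        mate = by_id.get(r.homologue_id)
        if mate is None:
            raise ValueError(
                f"region {r.region_id} points to unknown homologue {r.homologue_id}"
            )
        if mate.homologue_id != r.region_id:
            raise ValueError(
                f"homologue mapping not symmetric for region {r.region_id}"
            )
        if {r.hemisphere, mate.hemisphere} != {"left", "right"}:
            raise ValueError(
                f"homologues {r.region_id}/{mate.region_id} must span left/right"
            )


def make_bilateral_parcellation(
    n_per_hemisphere: int = 44,
    midline_names: Sequence[str] = ("Vermis",),
) -> list[RegionDefinition]:
    """Build a symmetric bilateral template.

    Left regions get ids ``1..n``, right regions ``n+1..2n`` (homologous to
    the left region with the same ordinal), and midline regions follow.
    """
    regions: list[RegionDefinition] = []
    n = n_per_hemisphere
    for i in range(n):
        regions.append(
            RegionDefinition(i + 1, f"L_{i + 1:02d}", "left", homologue_id=n + i + 1)
        )
    for i in range(n):
        regions.append(
            RegionDefinition(n + i + 1, f"R_{i + 1:02d}", "right", homologue_id=i + 1)
        )
    for j, name in enumerate(midline_names):
        regions.append(RegionDefinition(2 * n + j + 1, name, "midline"))
    validate_regions(regions)
    return regions


def hemisphere_indices(regions: Sequence[RegionDefinition], side: str) -> list[int]:
    """Positional indices of the regions belonging to one hemisphere."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    idx = [i for i, r in enumerate(regions) if r.hemisphere == side]
    if not idx:
        raise ValueError(f"no regions on side {side!r}")
    return idx


def homologue_pairs(regions: Sequence[RegionDefinition]) -> list[tuple[int, int]]:
    """(left_index, right_index) positional pairs of homologous regions.

    Midline regions and regions without a homologue are skipped.
    """
    pos = {r.region_id: i for i, r in enumerate(regions)}
    pairs = []
    for r in regions:
        if r.hemisphere == "left" and r.homologue_id is not None:
            pairs.append((pos[r.region_id], pos[r.homologue_id]))
    return pairs
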