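"""Region atlas: the ordered node set of the network.

The default atlas is the 78-cortical-region subset of the Automated
Anatomical Labeling (AAL) parcellation (39 regions per hemisphere;
subcortical and cerebellar regions excluded).  Region labels are the
conventional AAL abbreviations suffixed with ``-L`` / ``-R``; left and
right homologues share the stem (``PreCG-L`` <-> ``PreCG-R``), which is
what hemispheric pairing relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


#: AAL cortical region stems, in atlas order (39 per hemisphere).
AAL78_STEMS: tuple[str, ...] = (
    "PreCG", "SFGdor", "ORBsupb", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBmed", "REC", "INS", "ACG",
    "MCG", "PCG", "PHG", "CAL", "CUN", "LING", "SOG", "MOG", "IOG", "FFG",
    "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL", "HES", "STG",
    "TPOsup", "MTG", "TPOmid", "ITG",
)


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region labels with hemisphere tags; defines matrix indexing.

    Parameters
    ----------
    labels
        Unique region abbreviations, e.g. ``"PreCG-L"``.  The order fixes
        the row/column indexing of every connectivity matrix.
    hemisphere
        Per-label tag, each ``"L"`` or ``"R"``.
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("atlas labels must be unique")
        if len(self.labels) < 2:
            raise ValueError("atlas needs at least 2 regions")
        if len(self.hemisphere) != len(self.labels):
            raise ValueError("one hemisphere tag per label required")
        bad = [h for h in self.hemisphere if h not in ("L", "R")]
        if bad:
            raise ValueError(f"hemisphere tags must be 'L' or 'R', got {bad[:3]}")
        object.__setattr__(
            self, "index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def stem(self, label: str) -> str:
        """Hemisphere-free stem of a label (``'PreCG-L'`` -> ``'PreCG'``)."""
        return label.rsplit("-", 1)[0]

    def hemisphere_pairs(self) -> list[tuple[int, int]]:
        """(left_index, right_index) pairs matched by shared stem.

        Raises ``ValueError`` listing any label without a partner.
        """
        left = {self.stem(l): i for i, (l, h) in
                enumerate(zip(self.labels, self.hemisphere)) if h == "L"}
        right = {self.stem(l): i for i, (l, h) in
                 enumerate(zip(self.labels, self.hemisphere)) if h == "R"}
        unpaired = sorted(
            [self.labels[i] for s, i in left.items() if s not in right]
            + [self.labels[i] for s, i in right.items() if s not in left]
        )
        if unpaired:
            raise ValueError(f"unpaired hemisphere labels: {unpaired}")
        return [(left[s], right[s]) for s in sorted(left)]


def default_atlas() -> RegionAtlas:
    """The packaged 78-region cortical AAL atlas (39 per hemisphere).

    Ordered left/right interleaved in the conventional AAL listing order.
    """
    labels: list[str] = []
    hemis: list[str] = []
    for stem in AAL78_STEMS:
        labels += [f"{stem}-L", f"{stem}-R"]
        hemis += ["L", "R"]
    return RegionAtlas(tuple(labels), tuple(hemis))


def synthetic_atlas(n_regions: int) -> RegionAtlas:
    """A generic paired atlas with ``n_regions`` nodes (synthetic stand-in).

    Labels are ``R01-L, R01-R, R02-L, ...``; requires an even region count
    so every label has a hemispheric partner.
    """
    if n_regions == 78:
        return default_atlas()
    if n_regions % 2:
        raise ValueError("synthetic atlas requires an even number of regions")
    labels: list[str] = []
    hemis: list[str] = []
    for k in range(n_regions // 2):
        labels += [f"R{k + 1:02d}-L", f"R{k + 1:02d}-R"]
        hemis += ["L", "R"]
    return RegionAtlas(tuple(labels), tuple(hemis))


def read_atlas(path: str | Path) -> RegionAtlas:
    """Read a two-column TSV atlas file: label<TAB>hemisphere."""
    labels: list[str] = []
    hemis: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"atlas line needs 2 tab-separated fields: {line!r}")
        labels.append(parts[0])
        hemis.append(parts[1])
    return RegionAtlas(tuple(labels), tuple(hemis))


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    """Write the two-column TSV atlas format."""
    Path(path).write_text(
        "".join(f"{l}\t{h}\n" for l, h in zip(atlas.labels, atlas.hemisphere))
    )
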