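"""Registry of porcine TCR beta-chain variable-gene (TRBV) primer groups.

Spectratype PCR amplifies the CDR3-spanning region of rearranged TCR beta
transcripts with one forward primer per TRBV group and a common fluorochrome-
labelled C-beta reverse primer.  In-frame rearrangements produce a ladder of
products spaced 3 bp apart, so each group is described by the fragment size of
a reference in-frame product (``anchor_bp``), the closed interval of product
sizes the assay can produce (``range_bp``) and the label dye.

The porcine assay tracks 21 groups: 19 IMGT-named TRBV groups, TRBV24 and the
TRBV12-AS subgroup.  Anchor and range values are assay calibration data that
must be supplied (YAML) for real runs; :func:`default_registry` ships a
**synthetic** calibration used by the bundled simulator and the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "FLUOROCHROMES",
    "TRBVGroup",
    "TRBVRegistry",
    "default_registry",
    "load_registry",
    "save_registry",
]

FLUOROCHROMES = ("FAM", "HEX", "TET")

#: group identities: 19 IMGT-named groups + TRBV24 + subgroup TRBV12-AS = 21
DEFAULT_GROUP_IDS = (
    "TRBV2S", "TRBV3S", "TRBV4S", "TRBV5S", "TRBV6S", "TRBV7S", "TRBV9S",
    "TRBV10S", "TRBV11S", "TRBV12S", "TRBV14S", "TRBV15S", "TRBV16S",
    "TRBV18S", "TRBV19S", "TRBV20S", "TRBV21S", "TRBV26S", "TRBV29S",
    "TRBV24", "TRBV12-AS",
)


@dataclass(frozen=True)
class TRBVGroup:
    """One TRBV primer group with its expected fragment-size calibration.

    Parameters
    ----------
    group_id:
        Group label, e.g. ``"TRBV29S"``.
    anchor_bp:
        Fragment size (bp) of a reference in-frame product; bin index 0.
    range_bp:
        Closed ``(lo, hi)`` interval (bp) of anticipated product sizes.
    fluorochrome:
        Label dye, one of ``FAM``, ``HEX``, ``TET``.
    """

    group_id: str
    anchor_bp: float
    range_bp: tuple[float, float]
    fluorochrome: str

    def __post_init__(self) -> None:
        lo, hi = (float(self.range_bp[0]), float(self.range_bp[1]))
        object.__setattr__(self, "range_bp", (lo, hi))
        object.__setattr__(self, "anchor_bp", float(self.anchor_bp))
        if not self.group_id:
            raise ValueError("group_id must be non-empty")
        if not lo < hi:
            raise ValueError(f"{self.group_id}: range_bp must satisfy lo < hi, got {self.range_bp}")
        if not lo <= self.anchor_bp <= hi:
            raise ValueError(
                f"{self.group_id}: anchor {self.anchor_bp} bp outside expected range {self.range_bp}"
            )
        if self.fluorochrome not in FLUOROCHROMES:
            raise ValueError(
                f"{self.group_id}: fluorochrome {self.fluorochrome!r} not one of {FLUOROCHROMES}"
            )

    def bin_span(self, spacing_bp: float = 3.0) -> tuple[int, int]:
        """Inclusive (k_min, k_max) bin indices whose grid sizes lie in range."""
        lo, hi = self.range_bp
        k_min = math.ceil((lo - self.anchor_bp) / spacing_bp - 1e-9)
        k_max = math.floor((hi - self.anchor_bp) / spacing_bp + 1e-9)
        return k_min, k_max

    def grid(self, spacing_bp: float = 3.0) -> np.ndarray:
        """Expected in-frame fragment sizes: anchor + k*spacing within range."""
        k_min, k_max = self.bin_span(spacing_bp)
        return self.anchor_bp + np.arange(k_min, k_max + 1) * spacing_bp


class TRBVRegistry(Mapping[str, TRBVGroup]):
    """Immutable mapping group_id -> :class:`TRBVGroup`."""

    def __init__(self, groups: Iterator[TRBVGroup] | list[TRBVGroup]):
        d: dict[str, TRBVGroup] = {}
        for g in groups:
            if g.group_id in d:
                raise ValueError(f"duplicate group_id {g.group_id!r} in registry")
            d[g.group_id] = g
        self._groups = d

    def __getitem__(self, group_id: str) -> TRBVGroup:
        try:
            return self._groups[group_id]
        except KeyError:
            raise KeyError(
                f"group {group_id!r} not in registry (have {len(self._groups)} groups)"
            ) from None

    def __iter__(self):
        return iter(self._groups)

    def __len__(self) -> int:
        return len(self._groups)

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(self._groups)


def default_registry() -> TRBVRegistry:
    """Synthetic calibration for the 21 porcine TRBV groups/subgroup.

    Anchors step through 150-250 bp and each range spans +/-13 bp around the
    anchor (9 in-frame 3-bp bins); dyes cycle FAM/HEX/TET as in multiplexed
    capillary runs.  These numbers are invented calibration for simulation and
    testing -- real analyses must load the instrument's own registry.
    """
    groups = []
    for i, gid in enumerate(DEFAULT_GROUP_IDS):
        anchor = 150.0 + 5.0 * i
        groups.append(
            TRBVGroup(
                group_id=gid,
                anchor_bp=anchor,
                range_bp=(anchor - 13.0, anchor + 13.0),
                fluorochrome=FLUOROCHROMES[i % 3],
            )
        )
    return TRBVRegistry(groups)


def load_registry(path: str | Path) -> TRBVRegistry:
    """Read a registry from YAML (see :func:`save_registry` for the layout)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"registry file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ValueError(f"registry {path}: expected a mapping with a 'groups' list")
    groups = [
        TRBVGroup(
            group_id=str(entry["group_id"]),
            anchor_bp=float(entry["anchor_bp"]),
            range_bp=(float(entry["range_bp"][0]), float(entry["range_bp"][1])),
            fluorochrome=str(entry["fluorochrome"]),
        )
        for entry in doc["groups"]
    ]
    return TRBVRegistry(groups)


def save_registry(registry: TRBVRegistry, path: str | Path) -> None:
    doc = {
        "groups": [
            {
                "group_id": g.group_id,
                "anchor_bp": g.anchor_bp,
                "range_bp": [g.range_bp[0], g.range_bp[1]],
                "fluorochrome": g.fluorochrome,
            }
            for g in registry.values()
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
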