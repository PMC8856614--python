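"""Canonical antennal-lobe glomerulus map.

The adult fly antennal lobe is subdivided into ~55 discrete glomeruli, each
the target of one olfactory receptor neuron class. Binary innervation
profiles are vectors over this ordered name list. The shipped canonical list
follows the standard antennal-lobe nomenclature (DA/DC/DL/DM dorsal groups,
VA/VC/VL/VM ventral groups, V, DP1, VP); any custom ordered list of unique
names can be substituted for non-standard atlases.
"""
from __future__ import annotations

from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field

from .errors import SchemaError

#: Canonical 55-glomerulus antennal-lobe map.
CANONICAL_GLOMERULI: tuple[str, ...] = (
    "D", "DA1", "DA2", "DA3", "DA4l", "DA4m",
    "DC1", "DC2", "DC3", "DC4",
    "DL1", "DL2d", "DL2v", "DL3", "DL4", "DL5",
    "DM1", "DM2", "DM3", "DM4", "DM5", "DM6",
    "DP1l", "DP1m",
    "V",
    "VA1d", "VA1v", "VA2", "VA3", "VA4", "VA5", "VA6", "VA7l", "VA7m",
    "VC1", "VC2", "VC3l", "VC3m", "VC4", "VC5",
    "VL1", "VL2a", "VL2p",
    "VM1", "VM2", "VM3", "VM4", "VM5d", "VM5v", "VM6", "VM7d", "VM7v",
    "VP1", "VP2", "VP3",
)


@dataclass(frozen=True)
class GlomerulusMap:
    """Ordered, unique glomerulus name list used to align binary profiles."""

    names: tuple[str, ...] = CANONICAL_GLOMERULI

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise SchemaError("glomerulus names must be unique")
        if not names:
            raise SchemaError("glomerulus map must be non-empty")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        """Position of ``name`` in the map; raises ``SchemaError`` if absent."""
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown glomerulus {name!r}") from None

    def subset_indices(self, names: Sequence[str]) -> list[int]:
        return [self.index(n) for n in names]


def default_map() -> GlomerulusMap:
    """The canonical 55-glomerulus map."""
    return GlomerulusMap()
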