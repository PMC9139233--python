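"""Cell-class ontology and the 10-color CLL MRD panel definition.

The event classifier works over 14 mutually exclusive, exhaustive cell
classes. The panel is the single-tube 10-color CLL MRD combination
(3 light-scatter + 10 fluorescence channels = 13 parameters per event).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

#: Canonical class order. Index in this tuple is the integer class id used
#: throughout training and prediction; argmax ties break toward the lower id.
CLASSES: tuple[str, ...] = (
    "CLL_cells",
    "aggregates",
    "B_cells",
    "basophils_dendritic",
    "blasts",
    "debris",
    "erythroblasts",
    "granulocytes",
    "hematogones",
    "monocytes",
    "NK_cells",
    "plasma_cells",
    "T_cells",
    "unknown",
)

CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

N_CLASSES = len(CLASSES)

#: Classes removed from the white-blood-cell denominator: aggregates are
#: coincident multi-cell events, debris is non-cellular.
WBC_EXCLUDED_CLASSES = frozenset({"aggregates", "debris"})

#: Classes pooled into "Other cell categories" when reporting per-population
#: metrics (individually classified, combined for reporting).
OTHER_CATEGORY_CLASSES = frozenset(
    {
        "basophils_dendritic",
        "blasts",
        "erythroblasts",
        "granulocytes",
        "monocytes",
        "NK_cells",
        "unknown",
    }
)

OTHER_CATEGORY_NAME = "Other cell categories"


@dataclass(frozen=True)
class Channel:
    """One acquisition parameter: a scatter or a marker-fluorochrome channel."""

    name: str
    kind: Literal["scatter", "fluorescence"]


#: Scatter parameters. An area/height pair is required so that cell
#: aggregates (doublets, FSC-A >> FSC-H) are encodable.
SCATTER_CHANNELS: tuple[Channel, ...] = (
    Channel("FSC-A", "scatter"),
    Channel("FSC-H", "scatter"),
    Channel("SSC-A", "scatter"),
)

FLUORO_CHANNELS: tuple[Channel, ...] = (
    Channel("CD5-BV480", "fluorescence"),
    Channel("CD19-PE-Cy7", "fluorescence"),
    Channel("CD20-APC-H7", "fluorescence"),
    Channel("CD22-APC", "fluorescence"),
    Channel("CD38-APC-R700", "fluorescence"),
    Channel("CD43-BV605", "fluorescence"),
    Channel("CD45-PerCP-Cy5.5", "fluorescence"),
    Channel("CD200-BV421", "fluorescence"),
    Channel("Kappa-FITC", "fluorescence"),
    Channel("Lambda-PE", "fluorescence"),
)

PANEL: tuple[Channel, ...] = SCATTER_CHANNELS + FLUORO_CHANNELS

N_CHANNELS = len(PANEL)  # 13

CHANNEL_NAMES: tuple[str, ...] = tuple(c.name for c in PANEL)


def validate_panel(channels: list[Channel] | tuple[Channel, ...]) -> None:
    """Check the 3-scatter + 10-fluorescence panel shape and name uniqueness.

    Channels are matched by name, not position (instrument exports reorder
    parameters).
    """
    names = [c.name for c in channels]
    if len(set(names)) != len(names):
        raise ValueError("channel names must be unique within a panel")
    n_scatter = sum(c.kind == "scatter" for c in channels)
    n_fluoro = sum(c.kind == "fluorescence" for c in channels)
    if n_scatter != 3 or n_fluoro != 10:
        raise ValueError(
            f"panel must have 3 scatter + 10 fluorescence channels, "
            f"got {n_scatter} + {n_fluoro}"
        )


def class_ids(labels) -> "np.ndarray":  # noqa: F821
    """Map an iterable of class-name strings to integer ids; reject unknowns."""
    import numpy as np

    try:
        return np.array([CLASS_INDEX[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"unknown class label {exc.args[0]!r}; allowed classes: {list(CLASSES)}"
        ) from None
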