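"""Parcellation atlases: packaged node lists and custom atlas loading.

Four parcellations are shipped with the package, matching the node counts of
the common FreeSurfer outputs they mirror:

``desikan_killiany``
    68 cortical parcels (34 per hemisphere, ``lh_`` block then ``rh_`` block).
``destrieux``
    148 cortical parcels (74 per hemisphere, same hemisphere blocking).
``subcortical17``
    12 bilateral deep-grey structures (thalamus, caudate, putamen, pallidum,
    hippocampus, amygdala; left/right interleaved per structure) plus five
    bilaterally merged cingulate subdivisions (posterior, mid-posterior,
    central, mid-anterior, anterior) — 17 nodes.
``hipp_amyg_subfields``
    19 hippocampal subfield labels and 9 amygdala nucleus labels per
    hemisphere (left block then right block) — 56 nodes.

A custom atlas is any plain-text file with one unique node label per line.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .exceptions import AtlasNotFoundError, ValidationError

PACKAGED_ATLASES = {
    "desikan_killiany": 68,
    "destrieux": 148,
    "subcortical17": 17,
    "hipp_amyg_subfields": 56,
}


def _infer_hemisphere(label: str) -> str:
    low = label.lower()
    if low.startswith(("lh_", "lh.", "left-", "left_")):
        return "lh"
    if low.startswith(("rh_", "rh.", "right-", "right_")):
        return "rh"
    return "bilateral"


@dataclass(frozen=True)
class AtlasSpec:
    """An ordered, validated list of network nodes (ROIs).

    Parameters
    ----------
    name : str
        Identifier of the parcellation.
    roi_names : tuple of str
        Ordered, unique node labels. Matrix rows/columns follow this order
        everywhere in the package.
    hemisphere : tuple of str
        Per-node tag: ``"lh"``, ``"rh"`` or ``"bilateral"``.
    """

    name: str
    roi_names: tuple[str, ...]
    hemisphere: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.roi_names)) != len(self.roi_names):
            dupes = sorted({r for r in self.roi_names if list(self.roi_names).count(r) > 1})
            raise ValidationError(f"duplicate ROI labels in atlas {self.name!r}: {dupes}")
        if not self.roi_names:
            raise ValidationError(f"atlas {self.name!r} has no ROI labels")
        if not self.hemisphere:
            object.__setattr__(
                self, "hemisphere", tuple(_infer_hemisphere(r) for r in self.roi_names)
            )
        if len(self.hemisphere) != len(self.roi_names):
            raise ValidationError("hemisphere tags must match roi_names in length")

    @property
    def n_nodes(self) -> int:
        return len(self.roi_names)

    def index_of(self, labels: Sequence[str]) -> list[int]:
        """Positions of ``labels`` in atlas order; raises on unknown labels."""
        lookup = {r: i for i, r in enumerate(self.roi_names)}
        missing = [x for x in labels if x not in lookup]
        if missing:
            raise ValidationError(f"labels not in atlas {self.name!r}: {missing}")
        return [lookup[x] for x in labels]


def _read_node_list(name: str, lines: Sequence[str]) -> AtlasSpec:
    labels = [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    return AtlasSpec(name=name, roi_names=tuple(labels))


def load_atlas(name: str | Path) -> AtlasSpec:
    """Load a packaged atlas by identifier, or a custom one from a file path.

    Parameters
    ----------
    name : str or Path
        One of :data:`PACKAGED_ATLASES` or a path to a node-list file
        (one label per line; ``#`` comments ignored).

    Returns
    -------
    AtlasSpec

    Raises
    ------
    AtlasNotFoundError
        Unknown identifier that is not an existing file.
    ValidationError
        Custom file with duplicate or no labels.
    """
    key = str(name)
    if key in PACKAGED_ATLASES:
        ref = importlib.resources.files("covnet.data").joinpath(f"{key}.txt")
        spec = _read_node_list(key, ref.read_text().splitlines())
        assert spec.n_nodes == PACKAGED_ATLASES[key]
        return spec
    path = Path(name)
    if path.is_file():
        return _read_node_list(path.stem, path.read_text().splitlines())
    raise AtlasNotFoundError(
        f"unknown atlas {key!r}: not one of {sorted(PACKAGED_ATLASES)} and not a file"
    )
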