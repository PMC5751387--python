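"""Electrode geometry and neighbor topology.

An :class:`ElectrodeMontage` names the electrodes of a recording (10-20
nomenclature), stores their 3D positions, and carries the explicit
nearest-neighbor (``neighbors_small``) and next-nearest-neighbor
(``neighbors_large``) rings used by the Laplacian-style LAR filters.  For the
WAR filters the neighbor set of a target defaults to every other montage
electrode, but a montage file may pin it explicitly (``neighbors_war``) so
published electrode subsets are reproducible.

Montage files are YAML; two are bundled with the package::

    load_builtin_montage("gait_1020")       # motor-cortex montage, targets Cz/CP1/CP2
    load_builtin_montage("occipital_1020")  # SSVEP montage, targets O1/O2/Oz
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ElectrodeMontage",
    "MontageError",
    "load_montage",
    "load_builtin_montage",
    "derive_neighbors_by_rank",
]

#: neighbor-set modes understood by :meth:`ElectrodeMontage.neighbor_set`
MODES = ("lar_small", "lar_large", "war")


class MontageError(ValueError):
    """Malformed or inconsistent montage description."""


@dataclass
class ElectrodeMontage:
    """Named electrodes with positions and per-target neighbor rings.

    Parameters
    ----------
    electrodes
        Ordered electrode labels.
    positions
        Map label -> 3D coordinate (arbitrary but consistent length units),
        or ``None`` when the montage is purely topological; distance-based
        weights then require the unit-distance flag of the filters.
    neighbors_small, neighbors_large
        Explicit nearest / next-nearest neighbor rings per target.
    neighbors_war
        Optional explicit WAR surround per target; when absent the WAR set
        of a target is every other electrode of the montage.
    targets
        Electrodes this montage designates as filter targets.
    """

    electrodes: list[str]
    positions: dict[str, np.ndarray] | None = None
    neighbors_small: dict[str, list[str]] = field(default_factory=dict)
    neighbors_large: dict[str, list[str]] = field(default_factory=dict)
    neighbors_war: dict[str, list[str]] = field(default_factory=dict)
    targets: list[str] = field(default_factory=list)
    name: str = ""
    reference_note: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        labels = set(self.electrodes)
        if len(labels) != len(self.electrodes):
            raise MontageError("duplicate electrode labels")
        if self.positions is not None:
            missing = labels - set(self.positions)
            if missing:
                raise MontageError(f"positions missing for {sorted(missing)}")
            self.positions = {
                k: np.asarray(v, dtype=float) for k, v in self.positions.items()
            }
            for k, v in self.positions.items():
                if v.shape != (3,) or not np.all(np.isfinite(v)):
                    raise MontageError(f"position of {k!r} is not a finite 3-vector")
        for attr in ("neighbors_small", "neighbors_large", "neighbors_war"):
            mapping = getattr(self, attr)
            for tgt, nbrs in mapping.items():
                if tgt not in labels:
                    raise MontageError(f"{attr}: unknown target {tgt!r}")
                for nb in nbrs:
                    if nb not in labels:
                        raise MontageError(
                            f"{attr}[{tgt!r}]: neighbor {nb!r} is not a montage electrode"
                        )
                    if nb == tgt:
                        raise MontageError(f"{attr}[{tgt!r}]: electrode is its own neighbor")
        for tgt in self.targets:
            if tgt not in labels:
                raise MontageError(f"target {tgt!r} is not a montage electrode")
            if len(self.electrodes) > 1 and not (
                self.neighbors_small.get(tgt)
                or self.neighbors_large.get(tgt)
                or len(self.electrodes) >= 2
            ):  # pragma: no cover - war fallback always provides a set
                raise MontageError(f"target {tgt!r} has no neighbors")

    # -- queries ------------------------------------------------------------
    def index(self, label: str) -> int:
        try:
            return self.electrodes.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def neighbor_set(self, target: str, mode: str) -> list[str]:
        """Neighbor labels of *target* for a filter mode.

        ``lar_small`` / ``lar_large`` return the explicit rings; ``war``
        returns the explicit WAR surround when the montage pins one, else all
        other electrodes.  Adaptive mode names (``ad_war`` ...) are accepted
        and mapped to their base mode.
        """
        if target not in self.electrodes:
            raise KeyError(f"electrode {target!r} not in montage")
        mode = mode.removeprefix("ad_")
        if mode == "war":
            if target in self.neighbors_war:
                return list(self.neighbors_war[target])
            return [e for e in self.electrodes if e != target]
        if mode == "lar_small":
            ring = self.neighbors_small.get(target)
        elif mode == "lar_large":
            ring = self.neighbors_large.get(target)
        else:
            raise ValueError(f"unknown filter mode {mode!r}")
        if not ring:
            raise MontageError(f"montage defines no {mode} neighbors for {target!r}")
        return list(ring)

    def distance(self, i: str, j: str) -> float:
        """Euclidean inter-electrode distance (montage length units)."""
        if self.positions is None:
            raise MontageError(
                "montage has no positions; run distance-based weights with "
                "unit_distances=True"
            )
        if i not in self.electrodes or j not in self.electrodes:
            raise KeyError(f"electrode {i!r} or {j!r} not in montage")
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))


def load_montage(path: str | Path) -> ElectrodeMontage:
    """Load and validate a YAML montage file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise MontageError(f"cannot parse montage file {path}: {exc}") from exc
    if not isinstance(raw, dict) or "electrodes" not in raw:
        raise MontageError(f"montage file {path} lacks an 'electrodes' field")
    elecs = raw["electrodes"]
    if isinstance(elecs, dict):
        labels = list(elecs)
        positions = {k: np.asarray(v, float) for k, v in elecs.items()}
    else:  # plain list of labels, no geometry
        labels, positions = list(elecs), None
    return ElectrodeMontage(
        electrodes=labels,
        positions=positions,
        neighbors_small={k: list(v) for k, v in (raw.get("neighbors_small") or {}).items()},
        neighbors_large={k: list(v) for k, v in (raw.get("neighbors_large") or {}).items()},
        neighbors_war={k: list(v) for k, v in (raw.get("neighbors_war") or {}).items()},
        targets=list(raw.get("targets") or []),
        name=str(raw.get("name", path.stem)),
        reference_note=str(raw.get("reference_note", "")),
    )


def load_builtin_montage(name: str) -> ElectrodeMontage:
    """Load a bundled montage: ``"gait_1020"`` or ``"occipital_1020"``."""
    fname = f"montage_{name.removeprefix('montage_')}.yaml"
    ref = resources.files("adaptref.data").joinpath(fname)
    with resources.as_file(ref) as p:
        if not p.exists():
            raise MontageError(f"no bundled montage named {name!r}")
        return load_montage(p)


def derive_neighbors_by_rank(
    montage: ElectrodeMontage, target: str, n_small: int = 4, n_large: int = 4
) -> tuple[list[str], list[str]]:
    """Derive small/large rings for *target* by distance rank.

    Helper for montages that do not pin rings explicitly: the ``n_small``
    nearest electrodes form the small ring and the next ``n_large`` the large
    ring.
    """
    others = [e for e in montage.electrodes if e != target]
    ranked = sorted(others, key=lambda e: montage.distance(target, e))
    return ranked[:n_small], ranked[n_small : n_small + n_large]
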