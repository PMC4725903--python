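"""Many-protein configurations: positions, orientations, species, box."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .shapes import ProteinShape


@dataclass
class Configuration:
    """Positions + orientations of N proteins in a (possibly periodic) box.

    ``species`` indexes into ``shapes``; the box is an axis-aligned
    rectangle (W, H) with the origin at its lower-left corner.
    """

    positions: np.ndarray            # (N, 2) nm
    orientations: np.ndarray         # (N,) radians
    species: np.ndarray              # (N,) int indices into shapes
    shapes: list[ProteinShape]
    box: tuple[float, float]
    periodic: bool = True
    rng_seed: int | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.orientations = np.asarray(self.orientations, float)
        self.species = np.asarray(self.species, int)
        n = len(self.positions)
        if not (len(self.orientations) == len(self.species) == n):
            raise ValueError("positions, orientations, species length mismatch")
        if self.periodic:
            self.wrap()

    @property
    def n(self) -> int:
        return len(self.positions)

    def wrap(self) -> None:
        W, H = self.box
        self.positions[:, 0] %= W
        self.positions[:, 1] %= H

    def displacement(self, i: int, j: int) -> np.ndarray:
        """Minimum-image displacement r_j - r_i."""
        d = self.positions[j] - self.positions[i]
        if self.periodic:
            W, H = self.box
            d[0] -= W * np.round(d[0] / W)
            d[1] -= H * np.round(d[1] / H)
        return d

    def placements(self):
        """(shape-with-orientation, center) pairs, e.g. for meshing."""
        return [
            (self.shapes[s].with_orientation(w), tuple(p))
            for s, w, p in zip(self.species, self.orientations, self.positions)
        ]

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(), self.orientations.copy(), self.species.copy(),
            list(self.shapes), tuple(self.box), self.periodic, self.rng_seed,
        )

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "positions": self.positions.tolist(),
            "orientations": self.orientations.tolist(),
            "species": self.species.tolist(),
            "shapes": [s.to_dict() for s in self.shapes],
            "box": list(self.box),
            "periodic": self.periodic,
            "rng_seed": self.rng_seed,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "Configuration":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        return cls(
            np.array(doc["positions"]), np.array(doc["orientations"]),
            np.array(doc["species"]), [ProteinShape.from_dict(d) for d in doc["shapes"]],
            tuple(doc["box"]), doc["periodic"], doc.get("rng_seed"),
        )

    def write_xyz_frame(self, fh, comment: str = "") -> None:
        """Append one extended-XYZ-style text frame (label x y omega state)."""
        fh.write(f"{self.n}\n{comment}\n")
        for s, (x, y), w in zip(self.species, self.positions, self.orientations):
            sh = self.shapes[s]
            fh.write(f"{sh.label or 's' + str(s)} {x:.6f} {y:.6f} {w:.6f} {sh.state.value}\n")
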