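"""Run configuration, manifests, fixtures and tabular output writers."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .configuration import Configuration
from .fe_core import BilayerParams
from .monte_carlo import AnnealSchedule
from .shapes import mscl_shape, package_defaults


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (with its seed)."""

    bilayer: dict = field(default_factory=lambda: {})
    mesh_contour_points: int = 100
    table_d_step: float = 0.25
    table_n_omega: int = 12
    table_d_cut: float = 12.0
    schedule: dict = field(default_factory=lambda: asdict(AnnealSchedule()))
    seed: int = 0
    output_dir: str = "."

    def params(self) -> BilayerParams:
        return BilayerParams(**self.bilayer) if self.bilayer else BilayerParams()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text_or_path) -> "RunConfig":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        return cls(**doc)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: RunConfig | None = None, inputs=(), extra=None):
    """Write a reproducibility manifest next to an output file."""
    doc = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config) if config else None,
        "input_hashes": {str(p): sha256_of(p) for p in inputs},
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return doc


def append_energy_csv(path, rows: list[dict]) -> None:
    """Append rows to a long-format CSV results table, creating a header."""
    import pandas as pd

    df = pd.DataFrame(rows)
    header = not Path(path).exists()
    df.to_csv(path, mode="a", header=header, index=False)


def write_trajectory(path, frames: list[Configuration], comments=None) -> None:
    with open(path, "w") as fh:
        for i, frame in enumerate(frames):
            c = comments[i] if comments else f"frame {i}"
            frame.write_xyz_frame(fh, c)


def read_trajectory_positions(path) -> list[np.ndarray]:
    """Positions per frame of an extended-XYZ trajectory (label x y w state)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        block = lines[i + 2: i + 2 + n]
        frames.append(np.array([[float(v) for v in ln.split()[1:3]] for ln in block]))
        i += 2 + n
    return frames


# -- deterministic fixtures ------------------------------------------------


def fixture_generator(kind: str, out_dir, seed: int = 0, **kw) -> dict:
    """Write small deterministic fixtures for tests and demos.

    kinds: 'toy-mesh' (coarse annulus around one cylinder), 'random-gas'
    (non-overlapping protein gas, JSON configuration), 'lattice-seeded'
    (pre-built face-on square lattice).  Same seed -> identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    if kind == "toy-mesh":
        from .meshing import MeshOptions, mesh_patch, write_msh

        cyl = mscl_shape("cylinder", "closed")
        mesh = mesh_patch([(cyl, (0.0, 0.0))],
                          opts=MeshOptions(contour_points=kw.get("contour_points", 40)))
        p = out / "toy_annulus.msh"
        write_msh(mesh, p)
        files["mesh"] = p
    elif kind == "random-gas":
        from .monte_carlo import random_gas

        n = kw.get("n", 20)
        box = kw.get("box", (60.0, 60.0))
        tables = kw["tables"]
        cfg = random_gas([kw.get("shape") or mscl_shape("pentamer", "closed")],
                         [n], box, tables, seed=seed)
        p = out / f"gas_{n}_{seed}.json"
        cfg.to_json(p)
        files["configuration"] = p
    elif kind == "lattice-seeded":
        from .lattices import LatticeSpec, build_lattice

        shape = kw.get("shape") or mscl_shape("tetramer", "closed")
        spec = LatticeSpec("square", spacing=kw.get("d", 5.4),
                           size=kw.get("L", 4), orientation_scheme="face-on")
        cfg = build_lattice(spec, shape)
        p = out / f"square_L{spec.size}.json"
        cfg.to_json(p)
        files["configuration"] = p
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    manifest = out / f"{kind}_manifest.json"
    write_manifest(manifest, None, files.values(), extra={"kind": kind, "seed": seed})
    files["manifest"] = manifest
    return files
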