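"""Molecular geometry model, XYZ I/O and distance-based fragment detection.

A *fragment* is the smallest analysis unit of a LED study (a nucleobase on a
DNA strand, a single water molecule in a cluster, ...). The fragmentation
engine assigns every atom of a supersystem to exactly one fragment by
building a bond graph from interatomic distances and covalent radii and
taking its connected components.

The XYZ dialect: standard XYZ is accepted and written; optionally each atom
line may carry a trailing integer column holding the atom's 1-based fragment
label ("labeled XYZ"). Coordinates are in Ångström.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError, ElementError, XYZFormatError

__all__ = [
    "Atom",
    "Geometry",
    "FragmentationParams",
    "covalent_radius",
    "read_xyz",
    "write_xyz",
    "build_bond_graph",
    "detect_fragments",
]


def _load_radii() -> dict[str, float]:
    with resources.files("ledkit.data").joinpath("covalent_radii.csv").open() as fh:
        rows = csv.DictReader(fh)
        return {r["element"]: float(r["radius_angstrom"]) for r in rows}


_COVALENT_RADII: dict[str, float] = _load_radii()


def covalent_radius(element: str) -> float:
    """Covalent radius in Å from the bundled single-bond table (Cordero 2008)."""
    try:
        return _COVALENT_RADII[element]
    except KeyError:
        raise ElementError(f"element {element!r} has no covalent radius in the bundled table")


@dataclass
class Atom:
    """One atom: chemical symbol, Cartesian position (Å) and ghost flag.

    Ghost atoms carry basis functions but no nucleus/electrons; they appear
    only in counterpoise-corrected calculation inputs, never in supersystem
    geometries read from XYZ.
    """

    element: str
    position: np.ndarray
    ghost: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("coordinates must be finite")
        if self.element not in _COVALENT_RADII:
            raise ElementError(f"unrecognized element symbol {self.element!r}")


@dataclass
class Geometry:
    """An ordered list of atoms plus a map atom-index -> 1-based fragment id."""

    atoms: list[Atom]
    fragment_of: dict[int, int] = field(default_factory=dict)
    comment: str = ""

    def __post_init__(self) -> None:
        if not self.fragment_of:
            self.fragment_of = {i: 1 for i in range(len(self.atoms))}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_fragments(self) -> int:
        return max(self.fragment_of.values(), default=0)

    @property
    def fragment_ids(self) -> list[int]:
        return sorted(set(self.fragment_of.values()))

    def fragment_atoms(self, fragment_id: int) -> list[int]:
        """Atom indices of one fragment, in original order."""
        return [i for i in range(len(self.atoms)) if self.fragment_of[i] == fragment_id]

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]) if self.atoms else np.zeros((0, 3))

    def validate_partition(self) -> None:
        """Check every atom is labeled and fragment ids are contiguous from 1."""
        if set(self.fragment_of) != set(range(len(self.atoms))):
            raise ConfigurationError("every atom must have exactly one fragment id")
        ids = set(self.fragment_of.values())
        if ids and ids != set(range(1, max(ids) + 1)):
            raise ConfigurationError(f"fragment ids must be contiguous 1..F, got {sorted(ids)}")


@dataclass
class FragmentationParams:
    """Tunable knobs of the fragmentation engine.

    cutoff_scale
        Dimensionless multiplier on the sum of the two atoms' covalent radii;
        two atoms are bonded when their distance does not exceed
        ``cutoff_scale * (r_i + r_j)``. Default 1.15, a common heuristic.
    absolute_cutoff
        When set (Å), replaces the radius-based rule with a single maximum
        bonding distance.
    coordination_overrides
        Map element -> maximum coordination number; an atom's excess edges
        are pruned farthest-first (ties broken by the lower neighbour index).
    custom_bonds
        List of ``(i, j, "bond"|"break")`` entries applied last; ``bond``
        forces an edge, ``break`` removes one. Atom indices are 0-based.
    """

    cutoff_scale: float = 1.15
    absolute_cutoff: float | None = None
    coordination_overrides: Mapping[str, int] = field(default_factory=dict)
    custom_bonds: Sequence[tuple[int, int, Literal["bond", "break"]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cutoff_scale <= 0:
            raise ConfigurationError("cutoff_scale must be positive")
        if any(v < 0 for v in self.coordination_overrides.values()):
            raise ConfigurationError("coordination numbers must be >= 0")
        for i, j, kind in self.custom_bonds:
            if kind not in ("bond", "break"):
                raise ConfigurationError(f"custom bond tag must be 'bond' or 'break', got {kind!r}")


def read_xyz(path: str | Path) -> Geometry:
    """Read a (possibly fragment-labeled) XYZ file.

    Line 1 is the atom count, line 2 a free comment, then ``El x y z`` with an
    optional trailing integer fragment label. When labels are absent all atoms
    are provisionally assigned fragment 1 (run :func:`detect_fragments` to
    replace that).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZFormatError(f"{path}: first line must be the atom count")
    comment = lines[1] if len(lines) > 1 else ""
    atoms: list[Atom] = []
    labels: list[int | None] = []
    for ln in lines[2:]:
        if not ln.strip():
            continue
        parts = ln.split()
        if len(parts) not in (4, 5):
            raise XYZFormatError(f"{path}: bad atom line {ln!r}")
        el = parts[0]
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZFormatError(f"{path}: non-numeric coordinate in {ln!r}")
        label: int | None = None
        if len(parts) == 5:
            try:
                label = int(parts[4])
            except ValueError:
                raise XYZFormatError(f"{path}: fragment label must be an integer in {ln!r}")
        atoms.append(Atom(el, np.array(xyz)))
        labels.append(label)
    if len(atoms) != declared:
        raise XYZFormatError(f"{path}: declared {declared} atoms, parsed {len(atoms)}")
    if any(l is not None for l in labels):
        if any(l is None for l in labels):
            raise XYZFormatError(f"{path}: mixed labeled and unlabeled atom lines")
        fragment_of = {i: int(l) for i, l in enumerate(labels)}  # type: ignore[arg-type]
    else:
        fragment_of = {i: 1 for i in range(len(atoms))}
    return Geometry(atoms=atoms, fragment_of=fragment_of, comment=comment)


def write_xyz(geom: Geometry, path: str | Path, labeled: bool = False) -> Path:
    """Write standard XYZ; with ``labeled`` each line gains the fragment id."""
    path = Path(path)
    lines = [str(len(geom.atoms)), geom.comment]
    for i, atom in enumerate(geom.atoms):
        x, y, z = atom.position
        line = f"{atom.element:<3s} {x:14.6f} {y:14.6f} {z:14.6f}"
        if labeled:
            line += f"  {geom.fragment_of[i]}"
        lines.append(line)
    path.write_text("\n".join(lines) + "\n")
    return path


def build_bond_graph(geom: Geometry, params: FragmentationParams | None = None) -> nx.Graph:
    """Bond graph over atom indices.

    Edge rule: (i, j) bonded iff dist <= absolute_cutoff when that override is
    set, else dist <= cutoff_scale * (r_cov_i + r_cov_j). Coordination-number
    overrides then prune each over-coordinated atom's farthest edges; custom
    bond/break entries are applied last and have the final word.
    """
    params = params or FragmentationParams()
    n = len(geom.atoms)
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(range(n))
    if n == 0:
        return g
    coords = geom.coordinates()
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    radii = np.array([covalent_radius(a.element) for a in geom.atoms])
    if params.absolute_cutoff is not None:
        thresh = np.full((n, n), params.absolute_cutoff)
    else:
        thresh = params.cutoff_scale * (radii[:, None] + radii[None, :])
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= thresh[i, j]:
                g.add_edge(i, j, distance=float(dist[i, j]))

    # prune over-coordination farthest-first, ties by lower neighbour index
    for i in range(n):
        max_cn = params.coordination_overrides.get(geom.atoms[i].element)
        if max_cn is None:
            continue
        while g.degree[i] > max_cn:
            worst = max(g[i], key=lambda j: (g[i][j]["distance"], -j))
            g.remove_edge(i, worst)

    for i, j, kind in params.custom_bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise ConfigurationError(f"custom bond ({i},{j}) outside 0..{n - 1}")
        if kind == "bond":
            g.add_edge(i, j, distance=float(dist[i, j]))
        elif g.has_edge(i, j):
            g.remove_edge(i, j)
    return g


def detect_fragments(geom: Geometry, params: FragmentationParams | None = None) -> Geometry:
    """Assign fragments as connected components of the bond graph.

    Components are numbered 1..F by their lowest atom index, so labels are
    reproducible and stable under re-runs. Returns a new Geometry; the input
    is not modified.
    """
    g = build_bond_graph(geom, params)
    components = sorted(nx.connected_components(g), key=min)
    fragment_of: dict[int, int] = {}
    for fid, comp in enumerate(components, start=1):
        for idx in comp:
            fragment_of[idx] = fid
    out = Geometry(atoms=list(geom.atoms), fragment_of=fragment_of, comment=geom.comment)
    out.validate_partition()
    return out
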