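"""Enumeration and rendering of LED calculation inputs.

A full LED study of a multifragment supersystem needs many single-point
calculations: the supersystem itself, each subsystem (with the remaining
atoms as ghosts when counterpoise-corrected), every fragment pair spanning
two different subsystems (two-body analysis), and the monomers those pairs
are referenced against. Per computational setting the counts are

* uncorrected: ``1 + S + P + F``
* corrected:   ``1 + S + 3P``

with ``S`` subsystems, ``F`` fragments and ``P = sum_{i<j} f_i f_j``
spanning pairs — e.g. 18 and 30 for two three-fragment subsystems, growing
to 72 and 120 over the four settings a combined CBS+CPS extrapolation needs.
This module enumerates those calculations as :class:`CalcSpec` objects and
renders each as an engine input file with ghost atoms marked by a colon
after the element symbol and per-atom fragment indices in parentheses.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, ConsistencyError
from .molgeom import Geometry

__all__ = [
    "SubsystemSpec",
    "Setting",
    "CalcSpec",
    "enumerate_nbody",
    "enumerate_twobody",
    "enumerate_campaign",
    "render_input",
    "write_campaign",
]

METHODS = ("DLPNO-CCSD(T)", "DLPNO-CCSD", "HFLD")


@dataclass(frozen=True)
class SubsystemSpec:
    """A named group of fragment ids (e.g. one DNA strand)."""

    name: str
    fragment_ids: frozenset[int]

    def __init__(self, name: str, fragment_ids: Iterable[int]) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "fragment_ids", frozenset(int(f) for f in fragment_ids))
        if not self.fragment_ids:
            raise ConfigurationError(f"subsystem {name!r} has no fragments")


@dataclass(frozen=True)
class Setting:
    """One computational setting: method, basis and optional PNO threshold.

    ``tcutpno_exponent`` is the positive integer X of T_CutPNO = 10^-X; two
    settings with successive exponents feed a CPS extrapolation, two with
    successive basis cardinal numbers feed a CBS extrapolation.
    """

    label: str
    basis: str
    method: str = "DLPNO-CCSD(T)"
    tcutpno_exponent: int | None = None
    extra_keywords: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.tcutpno_exponent is not None and self.tcutpno_exponent <= 0:
            raise ConfigurationError("tcutpno_exponent must be a positive integer")


@dataclass(frozen=True)
class CalcSpec:
    """One renderable calculation: role, real/ghost fragment sets, setting."""

    role: str  # supersystem | subsystem | pair | monomer
    real_fragments: frozenset[int]
    ghost_fragments: frozenset[int]
    setting: Setting
    bsse_corrected: bool
    filename: str
    subsystem_name: str | None = None

    def __post_init__(self) -> None:
        if self.real_fragments & self.ghost_fragments:
            raise ConfigurationError("real and ghost fragment sets must be disjoint")
        if self.role == "monomer" and len(self.real_fragments) != 1:
            raise ConfigurationError("monomer spec must have exactly one real fragment")
        if self.role == "pair" and len(self.real_fragments) != 2:
            raise ConfigurationError("pair spec must have exactly two real fragments")
        if not self.bsse_corrected and self.ghost_fragments:
            raise ConfigurationError("uncorrected specs carry no ghost fragments")

    @property
    def all_fragments(self) -> frozenset[int]:
        return self.real_fragments | self.ghost_fragments

    def local_fragment_map(self) -> dict[int, int]:
        """Map supersystem fragment id -> contiguous 1-based index inside this
        input file (real fragments first, each group in supersystem order)."""
        ordered = sorted(self.real_fragments) + sorted(self.ghost_fragments)
        return {fid: k for k, fid in enumerate(ordered, start=1)}


def _mode_tag(bsse: bool) -> str:
    return "cp" if bsse else "nocp"


def _validate_subsystems(geom: Geometry, subsystems: Sequence[SubsystemSpec]) -> None:
    if not subsystems:
        raise ConfigurationError("at least one subsystem is required")
    all_ids: set[int] = set()
    for sub in subsystems:
        if all_ids & sub.fragment_ids:
            raise ConfigurationError("subsystems must be disjoint")
        all_ids |= sub.fragment_ids
    geom_ids = set(geom.fragment_of.values())
    if all_ids != geom_ids:
        raise ConfigurationError(
            f"subsystems cover fragments {sorted(all_ids)} but geometry has {sorted(geom_ids)}"
        )


def enumerate_nbody(
    geom: Geometry,
    subsystems: Sequence[SubsystemSpec],
    setting: Setting,
    bsse: bool,
) -> list[CalcSpec]:
    """Supersystem + one calculation per subsystem (1 + S specs).

    With counterpoise correction each subsystem keeps all other subsystems'
    fragments as ghosts, so every part is computed in the full supersystem
    basis.
    """
    _validate_subsystems(geom, subsystems)
    all_ids = frozenset(geom.fragment_of.values())
    tag = _mode_tag(bsse)
    specs = [
        CalcSpec(
            role="supersystem",
            real_fragments=all_ids,
            ghost_fragments=frozenset(),
            setting=setting,
            bsse_corrected=bsse,
            filename=f"{setting.label}_{tag}_super.inp",
        )
    ]
    for sub in subsystems:
        ghosts = frozenset(all_ids - sub.fragment_ids) if bsse else frozenset()
        specs.append(
            CalcSpec(
                role="subsystem",
                real_fragments=sub.fragment_ids,
                ghost_fragments=ghosts,
                setting=setting,
                bsse_corrected=bsse,
                filename=f"{setting.label}_{tag}_sub-{sub.name}.inp",
                subsystem_name=sub.name,
            )
        )
    return specs


def spanning_pairs(subsystems: Sequence[SubsystemSpec]) -> list[tuple[int, int]]:
    """All fragment pairs (x, y), x < y, whose members lie in different subsystems."""
    pairs: list[tuple[int, int]] = []
    for sub_a, sub_b in itertools.combinations(subsystems, 2):
        for x in sorted(sub_a.fragment_ids):
            for y in sorted(sub_b.fragment_ids):
                pairs.append((min(x, y), max(x, y)))
    return sorted(pairs)


def enumerate_twobody(
    geom: Geometry,
    subsystems: Sequence[SubsystemSpec],
    setting: Setting,
    bsse: bool,
) -> list[CalcSpec]:
    """Pair + monomer calculations for the two-body analysis.

    One pair calculation per spanning fragment pair. Monomer references:
    uncorrected, one isolated monomer per fragment (F specs); corrected, two
    per pair with the partner's atoms as ghosts — real and ghost exchanged
    between the two (2P specs).
    """
    _validate_subsystems(geom, subsystems)
    if len(subsystems) < 2:
        raise ConfigurationError("two-body analysis needs at least two subsystems")
    tag = _mode_tag(bsse)
    specs: list[CalcSpec] = []
    pairs = spanning_pairs(subsystems)
    for x, y in pairs:
        specs.append(
            CalcSpec(
                role="pair",
                real_fragments=frozenset({x, y}),
                ghost_fragments=frozenset(),
                setting=setting,
                bsse_corrected=bsse,
                filename=f"{setting.label}_{tag}_pair-{x}-{y}.inp",
            )
        )
    if bsse:
        for x, y in pairs:
            for real, ghost in ((x, y), (y, x)):
                specs.append(
                    CalcSpec(
                        role="monomer",
                        real_fragments=frozenset({real}),
                        ghost_fragments=frozenset({ghost}),
                        setting=setting,
                        bsse_corrected=True,
                        filename=f"{setting.label}_{tag}_mono-{real}-g{ghost}.inp",
                    )
                )
    else:
        for fid in sorted(set(geom.fragment_of.values())):
            specs.append(
                CalcSpec(
                    role="monomer",
                    real_fragments=frozenset({fid}),
                    ghost_fragments=frozenset(),
                    setting=setting,
                    bsse_corrected=False,
                    filename=f"{setting.label}_{tag}_mono-{fid}.inp",
                )
            )
    return specs


def enumerate_campaign(
    geom: Geometry,
    subsystems: Sequence[SubsystemSpec],
    settings: Sequence[Setting],
    bsse: bool,
    include_twobody: bool = True,
) -> list[CalcSpec]:
    """Concatenate N-body (and optionally two-body) enumerations over settings."""
    if not settings:
        raise ConfigurationError("at least one setting is required")
    labels = [s.label for s in settings]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate setting labels: {labels}")
    specs: list[CalcSpec] = []
    for setting in settings:
        specs.extend(enumerate_nbody(geom, subsystems, setting, bsse))
        if include_twobody:
            specs.extend(enumerate_twobody(geom, subsystems, setting, bsse))
    names = [s.filename for s in specs]
    if len(set(names)) != len(names):  # pragma: no cover - guarded by label uniqueness
        raise ConfigurationError("filename collision in campaign")
    return specs


def render_input(spec: CalcSpec, geom: Geometry) -> str:
    """Render one CalcSpec as engine input text.

    Layout: a ``!`` keyword line (method, basis, extra keywords), an ``%mdci``
    block with the LED fragment count and optional TCutPNO, then the
    coordinate block. Each atom line is ``El(k)`` with the file-local fragment
    index k; ghost atoms are written ``El:(k)``. Fragment indices run
    contiguously from 1 inside the file, real fragments first, following
    supersystem order.
    """
    missing = spec.all_fragments - set(geom.fragment_of.values())
    if missing:
        raise ConsistencyError(f"spec references unknown fragment ids {sorted(missing)}")
    s = spec.setting
    keywords = f"! {s.method} {s.basis}"
    if s.extra_keywords:
        keywords += f" {s.extra_keywords}"
    local = spec.local_fragment_map()
    lines = [keywords, "%mdci", f"  LED {len(local)}"]
    if s.tcutpno_exponent is not None:
        lines.append(f"  TCutPNO 1e-{s.tcutpno_exponent}")
    lines += ["end", "* xyz 0 1"]
    for fid in sorted(spec.real_fragments) + sorted(spec.ghost_fragments):
        is_ghost = fid in spec.ghost_fragments
        for idx in geom.fragment_atoms(fid):
            atom = geom.atoms[idx]
            sym = f"{atom.element}:" if is_ghost else atom.element
            x, y, z = atom.position
            lines.append(f"{sym}({local[fid]}) {x:14.6f} {y:14.6f} {z:14.6f}")
    lines.append("*")
    return "\n".join(lines) + "\n"


def write_campaign(
    specs: Sequence[CalcSpec],
    geom: Geometry,
    out_dir: str | Path,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write every input file plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        (out_dir / spec.filename).write_text(render_input(spec, geom))
        rows.append(
            {
                "filename": spec.filename,
                "role": spec.role,
                "real_fragments": " ".join(map(str, sorted(spec.real_fragments))),
                "ghost_fragments": " ".join(map(str, sorted(spec.ghost_fragments))),
                "setting": spec.setting.label,
                "bsse_corrected": spec.bsse_corrected,
            }
        )
    manifest = out_dir / manifest_name
    with manifest.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
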