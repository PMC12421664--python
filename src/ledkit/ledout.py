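"""LED output files: grammar, parser, label alignment and record merging.

The package reads a documented plain-text LED output grammar modelled on the
LED blocks a DLPNO-CCSD(T)/HFLD engine prints: a method/setting header, a
fragment table with real/ghost markers and coordinates, the final and
reference single-point energies, per-fragment ``INTRA FRAGMENT`` blocks with
reference and correlation energies, and per-pair
``INTERACTION OF FRAGMENTS X AND Y`` blocks with the component resolution

    eps(X,Y) = eps_elstat + eps_exch + eps_no-disp + eps_disp [+ eps_solv]

All energies are in Hartree at full printed precision. The parser is
whitespace-tolerant and ignores unrecognized trailing content; the writer
(:func:`write_led_output`, used by the mock-data generator) emits exactly
this grammar, so writer/parser round trips are exact. An annotated example
lives in ``docs/led_output_grammar.md``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import AlignmentError, IncompatibilityError, LEDParseError, MethodError

__all__ = [
    "ComponentSet",
    "FragmentInfo",
    "LEDRecord",
    "write_led_output",
    "parse_led_output",
    "relabel",
    "align_labels",
    "merge_alternative",
    "exclude_redundant_hfld",
]

logger = logging.getLogger(__name__)

#: order of the interfragment components in files and records
COMPONENT_FIELDS = ("elstat", "exch", "no_disp", "disp", "solv")

_COMPONENT_LINE = {
    "elstat": "Electrostatics (REF.)",
    "exch": "Exchange (REF.)",
    "no_disp": "Non-dispersion (CORR.)",
    "disp": "Dispersion (CORR.)",
    "solv": "Solvation",
}


@dataclass
class ComponentSet:
    """Interfragment interaction components for one fragment pair, Hartree.

    Any field may be ``None`` when the producing run did not print it (e.g. a
    crashed correlation stage); :func:`merge_alternative` fills such holes
    from an alternative output.
    """

    elstat: float | None = None
    exch: float | None = None
    no_disp: float | None = None
    disp: float | None = None
    solv: float | None = None

    def total(self) -> float:
        """Sum of the components that are present."""
        return sum(v for v in (self.elstat, self.exch, self.no_disp, self.disp, self.solv) if v is not None)

    def is_complete(self) -> bool:
        return None not in (self.elstat, self.exch, self.no_disp, self.disp)


@dataclass
class FragmentInfo:
    """One fragment as declared in an output's fragment table."""

    label: int
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    ghost: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.elements), 3)


@dataclass
class LEDRecord:
    """Everything parsed from one LED output file.

    ``intra`` maps fragment label -> ``{"ref": Eh, "corr": Eh}`` (values may
    be None when missing); ``pairwise`` maps ``frozenset({x, y})`` ->
    :class:`ComponentSet`. Ghost fragments carry neither intra terms nor
    pair components.
    """

    fragments: list[FragmentInfo]
    intra: dict[int, dict[str, float | None]] = field(default_factory=dict)
    pairwise: dict[frozenset, ComponentSet] = field(default_factory=dict)
    total_energy: float | None = None
    reference_energy: float | None = None
    method: str = "DLPNO-CCSD(T)"
    setting_label: str = ""
    excluded: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        return [f.label for f in self.fragments]

    @property
    def real_labels(self) -> list[int]:
        return [f.label for f in self.fragments if not f.ghost]

    def fragment(self, label: int) -> FragmentInfo:
        for f in self.fragments:
            if f.label == label:
                return f
        raise KeyError(f"no fragment labeled {label}")

    def recompute_totals(self) -> None:
        """Recompute total and reference energies from the stored terms."""
        intra_ref = sum(v["ref"] or 0.0 for v in self.intra.values())
        intra_corr = sum(v["corr"] or 0.0 for v in self.intra.values())
        pair_ref = sum((c.elstat or 0.0) + (c.exch or 0.0) + (c.solv or 0.0) for c in self.pairwise.values())
        pair_corr = sum((c.no_disp or 0.0) + (c.disp or 0.0) for c in self.pairwise.values())
        self.reference_energy = intra_ref + pair_ref
        self.total_energy = self.reference_energy + intra_corr + pair_corr


def write_led_output(rec: LEDRecord, path: str | Path) -> Path:
    """Write a record in the documented LED output grammar (mock writer)."""
    path = Path(path)
    lines: list[str] = []
    lines.append("=" * 20 + " LED ANALYSIS " + "=" * 20)
    lines.append(f"Method  : {rec.method}")
    lines.append(f"Setting : {rec.setting_label}")
    lines.append("")
    lines.append("FRAGMENT TABLE")
    for frag in rec.fragments:
        kind = "ghost" if frag.ghost else "real"
        lines.append(f"FRAGMENT {frag.label} ({kind})")
        for el, (x, y, z) in zip(frag.elements, frag.coords):
            lines.append(f"  {el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    lines.append("END OF FRAGMENT TABLE")
    lines.append("")
    if rec.total_energy is not None:
        lines.append(f"FINAL SINGLE POINT ENERGY {rec.total_energy:22.12f}")
    if rec.reference_energy is not None:
        lines.append(f"REFERENCE ENERGY          {rec.reference_energy:22.12f}")
    lines.append("")
    for label in sorted(rec.intra):
        terms = rec.intra[label]
        lines.append(f"INTRA FRAGMENT {label}")
        if terms.get("ref") is not None:
            lines.append(f"  Intra REF. energy        {terms['ref']:22.12f}")
        if terms.get("corr") is not None:
            lines.append(f"  Intra correlation energy {terms['corr']:22.12f}")
        lines.append("")
    for pair in sorted(rec.pairwise, key=lambda p: tuple(sorted(p))):
        x, y = sorted(pair)
        comp = rec.pairwise[pair]
        lines.append(f"INTERACTION OF FRAGMENTS {x} AND {y}")
        for name in COMPONENT_FIELDS:
            value = getattr(comp, name)
            if value is not None:
                lines.append(f"  {_COMPONENT_LINE[name]:<25s} {value:22.12f}")
        lines.append(f"  {'Total interaction':<25s} {comp.total():22.12f}")
        lines.append("")
    path.write_text("\n".join(lines) + "\n")
    return path


_NUM = r"(-?\d+\.\d+(?:[eE][+-]?\d+)?)"
_RE_FINAL = re.compile(r"FINAL SINGLE POINT ENERGY\s+" + _NUM)
_RE_REF = re.compile(r"REFERENCE ENERGY\s+" + _NUM)
_RE_FRAG_HEAD = re.compile(r"FRAGMENT\s+(\d+)\s*\((real|ghost)\)")
_RE_ATOM = re.compile(r"^\s*([A-Z][a-z]?)\s+" + _NUM + r"\s+" + _NUM + r"\s+" + _NUM + r"\s*$")
_RE_INTRA = re.compile(r"INTRA FRAGMENT\s+(\d+)")
_RE_PAIR = re.compile(r"INTERACTION OF FRAGMENTS\s+(\d+)\s+AND\s+(\d+)")
_RE_METHOD = re.compile(r"Method\s*:\s*(\S.*)")
_RE_SETTING = re.compile(r"Setting\s*:\s*(\S.*)")

_PAIR_LINE_KEYS = {
    "Electrostatics (REF.)": "elstat",
    "Exchange (REF.)": "exch",
    "Non-dispersion (CORR.)": "no_disp",
    "Dispersion (CORR.)": "disp",
    "Solvation": "solv",
}


def parse_led_output(path: str | Path) -> LEDRecord:
    """Parse a LED output file into a :class:`LEDRecord`.

    Raises :class:`~ledkit.errors.LEDParseError` naming the missing block when
    the final-energy line is absent, or with the line number for a malformed
    pair block. Unparsed trailing content is ignored; numbers are read at
    full printed precision.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()

    rec = LEDRecord(fragments=[])
    m = _RE_METHOD.search(text)
    if m:
        rec.method = m.group(1).strip()
    m = _RE_SETTING.search(text)
    if m:
        rec.setting_label = m.group(1).strip()

    m = _RE_FINAL.search(text)
    if not m:
        raise LEDParseError(f"{path}: missing FINAL SINGLE POINT ENERGY block")
    rec.total_energy = float(m.group(1))
    m = _RE_REF.search(text)
    if m:
        rec.reference_energy = float(m.group(1))

    # fragment table
    in_table = False
    current: FragmentInfo | None = None
    pending: list[tuple[str, list[float]]] = []

    def _flush() -> None:
        nonlocal current, pending
        if current is not None:
            current.elements = [e for e, _ in pending]
            current.coords = np.array([c for _, c in pending]).reshape(len(pending), 3)
            rec.fragments.append(current)
        current, pending = None, []

    for ln in lines:
        if "FRAGMENT TABLE" in ln and "END OF" not in ln:
            in_table = True
            continue
        if "END OF FRAGMENT TABLE" in ln:
            _flush()
            in_table = False
            continue
        if not in_table:
            continue
        mh = _RE_FRAG_HEAD.search(ln)
        if mh:
            _flush()
            current = FragmentInfo(
                label=int(mh.group(1)), elements=[], coords=np.zeros((0, 3)), ghost=mh.group(2) == "ghost"
            )
            continue
        ma = _RE_ATOM.match(ln)
        if ma and current is not None:
            pending.append((ma.group(1), [float(ma.group(k)) for k in (2, 3, 4)]))

    real = {f.label for f in rec.fragments if not f.ghost}

    # intra blocks
    for i, ln in enumerate(lines):
        mi = _RE_INTRA.search(ln)
        if not mi:
            continue
        label = int(mi.group(1))
        terms: dict[str, float | None] = {"ref": None, "corr": None}
        for follow in lines[i + 1 : i + 4]:
            if "Intra REF. energy" in follow:
                terms["ref"] = _read_trailing_number(follow, path, i)
            elif "Intra correlation energy" in follow:
                terms["corr"] = _read_trailing_number(follow, path, i)
        rec.intra[label] = terms

    # pair blocks
    for i, ln in enumerate(lines):
        mp = _RE_PAIR.search(ln)
        if not mp:
            continue
        x, y = int(mp.group(1)), int(mp.group(2))
        comp = ComponentSet()
        stored_total: float | None = None
        for j in range(i + 1, min(i + 8, len(lines))):
            follow = lines[j]
            if not follow.strip():
                break
            matched = False
            for key, attr in _PAIR_LINE_KEYS.items():
                if key in follow:
                    setattr(comp, attr, _read_trailing_number(follow, path, j))
                    matched = True
                    break
            if not matched:
                if "Total interaction" in follow:
                    stored_total = _read_trailing_number(follow, path, j)
                else:
                    raise LEDParseError(f"{path}:{j + 1}: malformed pair-block line {follow!r}")
        if stored_total is not None and abs(comp.total() - stored_total) > 1e-9:
            raise LEDParseError(
                f"{path}:{i + 1}: pair ({x},{y}) components sum to {comp.total():.12f}, "
                f"stored total is {stored_total:.12f}"
            )
        if real and not ({x, y} <= real):
            raise LEDParseError(f"{path}:{i + 1}: pair ({x},{y}) references a ghost or undeclared fragment")
        rec.pairwise[frozenset({x, y})] = comp

    return rec


def _read_trailing_number(line: str, path: Path, lineno: int) -> float:
    m = re.search(_NUM + r"\s*$", line)
    if not m:
        raise LEDParseError(f"{path}:{lineno + 1}: expected a number at end of {line!r}")
    return float(m.group(1))


def relabel(rec: LEDRecord, mapping: dict[int, int]) -> LEDRecord:
    """Return a copy of ``rec`` with fragment labels mapped through ``mapping``."""
    missing = set(rec.labels) - set(mapping)
    if missing:
        raise AlignmentError(f"relabel mapping lacks labels {sorted(missing)}")
    fragments = [
        FragmentInfo(mapping[f.label], list(f.elements), f.coords.copy(), f.ghost) for f in rec.fragments
    ]
    intra = {mapping[k]: dict(v) for k, v in rec.intra.items()}
    pairwise = {frozenset(mapping[l] for l in pair): replace(comp) for pair, comp in rec.pairwise.items()}
    return LEDRecord(
        fragments=fragments,
        intra=intra,
        pairwise=pairwise,
        total_energy=rec.total_energy,
        reference_energy=rec.reference_energy,
        method=rec.method,
        setting_label=rec.setting_label,
        excluded=set(rec.excluded),
        provenance=dict(rec.provenance),
    )


def align_labels(child: LEDRecord, parent: LEDRecord, tol: float = 1e-4) -> dict[int, int]:
    """Map child fragment labels to parent labels by geometry.

    A child fragment matches a parent fragment when the element sequences are
    identical and every atom lies within ``tol`` Å. Matching is greedy
    nearest-neighbour with conflict detection, so the result is bijective
    onto its image; ghost fragments are mapped like real ones.
    """
    candidates: dict[int, list[tuple[float, int]]] = {}
    for cf in child.fragments:
        options: list[tuple[float, int]] = []
        for pf in parent.fragments:
            if cf.elements != pf.elements:
                continue
            dev = float(np.max(np.linalg.norm(cf.coords - pf.coords, axis=1)))
            if dev <= tol:
                options.append((dev, pf.label))
        if not options:
            raise AlignmentError(
                f"child fragment {cf.label} ({''.join(cf.elements)}) has no geometric match in parent"
            )
        candidates[cf.label] = sorted(options)

    # assign best matches first so conflicts fall to the next-nearest option
    mapping: dict[int, int] = {}
    taken: set[int] = set()
    for clabel in sorted(candidates, key=lambda c: candidates[c][0][0]):
        for _, plabel in candidates[clabel]:
            if plabel not in taken:
                mapping[clabel] = plabel
                taken.add(plabel)
                break
        else:
            raise AlignmentError(f"child fragment {clabel}: all geometric matches already claimed")
    return mapping


def merge_alternative(main: LEDRecord, alt: LEDRecord, tol: float = 1e-4) -> LEDRecord:
    """Fill fields missing in ``main`` from an alternative output of the same system.

    Fields present in main always win; a disagreement on a field both carry is
    logged as a warning but main's value is kept. The merged record's
    ``provenance`` lists every field taken from the alternative. Raises
    :class:`~ledkit.errors.IncompatibilityError` when the two records do not
    describe the same fragment composition.
    """
    try:
        mapping = align_labels(alt, main, tol=tol)
    except AlignmentError as exc:
        raise IncompatibilityError(f"alternative output is geometrically incompatible: {exc}") from exc
    if len(mapping) != len(main.fragments):
        raise IncompatibilityError("alternative output does not cover the main fragment composition")
    alt = relabel(alt, mapping)

    merged = relabel(main, {l: l for l in main.labels})  # deep-ish copy

    def _fill(path: str, main_val: float | None, alt_val: float | None) -> float | None:
        if main_val is None and alt_val is not None:
            merged.provenance[path] = "alternative"
            logger.info("merged %s from alternative output", path)
            return alt_val
        if main_val is not None and alt_val is not None and abs(main_val - alt_val) > 1e-9:
            logger.warning("main and alternative disagree on %s (%g vs %g); keeping main", path, main_val, alt_val)
        return main_val

    merged.total_energy = _fill("total_energy", main.total_energy, alt.total_energy)
    merged.reference_energy = _fill("reference_energy", main.reference_energy, alt.reference_energy)
    for label in merged.intra:
        alt_terms = alt.intra.get(label, {})
        for key in ("ref", "corr"):
            merged.intra[label][key] = _fill(
                f"intra[{label}].{key}", merged.intra[label].get(key), alt_terms.get(key)
            )
    for label, terms in alt.intra.items():
        if label not in merged.intra:
            merged.intra[label] = dict(terms)
            merged.provenance[f"intra[{label}]"] = "alternative"
    for pair in set(merged.pairwise) | set(alt.pairwise):
        if pair not in merged.pairwise:
            merged.pairwise[pair] = replace(alt.pairwise[pair])
            merged.provenance[f"pair[{tuple(sorted(pair))}]"] = "alternative"
            continue
        if pair not in alt.pairwise:
            continue
        mc, ac = merged.pairwise[pair], alt.pairwise[pair]
        for name in COMPONENT_FIELDS:
            setattr(
                mc, name, _fill(f"pair[{tuple(sorted(pair))}].{name}", getattr(mc, name), getattr(ac, name))
            )
    return merged


def exclude_redundant_hfld(rec: LEDRecord) -> LEDRecord:
    """Drop the correlation terms HFLD does not define.

    HFLD keeps reference-level terms plus London dispersion; the
    non-dispersive correlation components and the correlation part of the
    electronic preparation are zeroed and flagged, and the record totals are
    recomputed. Idempotent; refuses non-HFLD records.
    """
    if "hfld_filtered" in rec.excluded:
        return rec
    if "HFLD" not in rec.method.upper():
        raise MethodError(f"HFLD term exclusion applies to HFLD records, not {rec.method!r}")
    out = relabel(rec, {l: l for l in rec.labels})
    for label, terms in out.intra.items():
        if terms.get("corr") not in (None, 0.0):
            out.excluded.add(f"intra[{label}].corr")
        terms["corr"] = 0.0
    for pair, comp in out.pairwise.items():
        if comp.no_disp not in (None, 0.0):
            out.excluded.add(f"pair[{tuple(sorted(pair))}].no_disp")
        comp.no_disp = 0.0
    out.excluded.add("hfld_filtered")
    out.recompute_totals()
    return out
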