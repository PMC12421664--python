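"""Ground-truth generator for desk-scale testing of the LED pipeline.

Real LED studies need a quantum-chemistry engine; this module replaces it
with an analytic fixture layer. It constructs a fragmented supersystem
geometry from rigid water-like units, plants every energy the LED machinery
consumes — isolated-monomer intra energies, electronic-preparation
perturbations, per-pair interaction components, counterpoise (BSSE)
lowerings — and exposes them both as in-memory :class:`~ledkit.ledout.LEDRecord`
objects and as grammar-conforming mock output files.

Energies are planted *additively* (supersystem terms = isolated terms +
perturbations), so the standard-LED differences taken by the assembly code
recover the planted perturbations exactly and every conservation law holds
to machine precision by construction. Magnitudes imitate real data:
monomer energies near -76 Eh (a water molecule), interfragment components
on a -30..+10 kcal/mol scale.

For extrapolation tests the generator can emit two settings whose energies
lie exactly on the CBS model forms E(n) = E_inf + A exp(-a sqrt(n)) /
E(n) = E_inf + B n^-b, or on the CPS form, together with the planted
limit ("limit" setting), so two-point extrapolation must recover the limit
to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .extrap import ExtrapolationParams
from .inputgen import CalcSpec, Setting, SubsystemSpec, enumerate_campaign, spanning_pairs
from .ledout import ComponentSet, FragmentInfo, LEDRecord, relabel, write_led_output
from .molgeom import Atom, Geometry
from .units import HARTREE_TO_KCAL

__all__ = ["GroundTruth", "generate_ground_truth", "write_mock_outputs"]

MODES = ("uncorrected", "corrected")

#: leaf keys carrying reference-level energies vs correlation energies
_REF_KEYS = {"ref", "elstat", "exch", "solv"}
_CORR_KEYS = {"corr", "no_disp", "disp"}

_EPS_RANGES = {
    # Hartree; roughly -30..+10 kcal/mol across components
    "elstat": (-0.035, 0.008),
    "exch": (-0.012, 0.0),
    "no_disp": (-0.004, 0.002),
    "disp": (-0.009, 0.0),
    "solv": (-0.006, 0.003),
}


def _draw_eps(rng: np.random.Generator, solvation: bool) -> dict[str, float]:
    names = ["elstat", "exch", "no_disp", "disp"] + (["solv"] if solvation else [])
    return {n: float(rng.uniform(*_EPS_RANGES[n])) for n in names}


def _water_unit(rng: np.random.Generator, origin: np.ndarray) -> list[Atom]:
    """One rigid O-H-H unit with a small seeded jitter (O-H ~ 0.96 Å)."""
    base = np.array([[0.0, 0.0, 0.0], [0.76, 0.59, 0.0], [-0.76, 0.59, 0.0]])
    jitter = rng.uniform(-0.02, 0.02, size=(3, 3))
    coords = base + jitter + origin
    return [Atom(el, xyz) for el, xyz in zip(("O", "H", "H"), coords)]


def _make_geometry(rng: np.random.Generator, n_fragments: int) -> Geometry:
    """Water units on a 4.2 Å grid: intra-unit bonded, inter-unit well separated."""
    atoms: list[Atom] = []
    fragment_of: dict[int, int] = {}
    for k in range(n_fragments):
        origin = np.array([4.2 * (k % 4), 4.2 * (k // 4), 0.0])
        for atom in _water_unit(rng, origin):
            fragment_of[len(atoms)] = k + 1
            atoms.append(atom)
    return Geometry(atoms=atoms, fragment_of=fragment_of, comment="mock water cluster")


def _plant_tree(
    rng: np.random.Generator,
    fragments: list[int],
    same_sub_pairs: list[tuple[int, int]],
    span_pairs: list[tuple[int, int]],
    solvation: bool,
) -> dict:
    """Plant every scalar one computational setting needs (all in Hartree)."""
    all_pairs = sorted(set(same_sub_pairs) | set(span_pairs))
    tree: dict = {
        "iso": {
            x: {"ref": float(rng.normal(-76.0, 0.5)), "corr": float(rng.normal(-0.30, 0.02))}
            for x in fragments
        },
        "super_pert": {
            x: {"ref": float(rng.normal(0.0, 0.003)), "corr": float(rng.normal(0.0, 0.001))}
            for x in fragments
        },
        "epsN": {p: _draw_eps(rng, solvation) for p in all_pairs},
        "pair_intra_pert": {
            p: {
                x: {"ref": float(rng.normal(0.0, 0.002)), "corr": float(rng.normal(0.0, 0.0007))}
                for x in p
            }
            for p in span_pairs
        },
        "eps2": {p: _draw_eps(rng, solvation) for p in span_pairs},
        "mono_bsse": {
            p: {
                x: {"ref": float(abs(rng.normal(0.0, 0.001))), "corr": float(abs(rng.normal(0.0, 0.0004)))}
                for x in p
            }
            for p in span_pairs
        },
        "sub_pert": {},
        "epsSub": {},
    }
    # subsystem-context values per BSSE mode; the corrected intra energies sit
    # below the uncorrected ones (ghost basis functions lower each part)
    unc = {
        x: {"ref": float(rng.normal(0.0, 0.0015)), "corr": float(rng.normal(0.0, 0.0006))}
        for x in fragments
    }
    cor = {
        x: {
            "ref": unc[x]["ref"] - float(abs(rng.normal(0.0, 0.0012))),
            "corr": unc[x]["corr"] - float(abs(rng.normal(0.0, 0.0005))),
        }
        for x in fragments
    }
    tree["sub_pert"] = {"uncorrected": unc, "corrected": cor}
    tree["epsSub"] = {
        mode: {p: _draw_eps(rng, solvation) for p in same_sub_pairs} for mode in MODES
    }
    return tree


def _transform_tree(tree, transform):
    """Apply ``transform(leaf_class, value) -> value`` to every float leaf."""
    def walk(node, key=None):
        if isinstance(node, dict):
            return {k: walk(v, k) for k, v in node.items()}
        cls = "ref" if key in _REF_KEYS else "corr"
        return transform(cls, node)

    return walk(tree)


@dataclass
class GroundTruth:
    """A planted LED campaign: geometry, subsystems, and all energies.

    ``plants`` maps setting label -> scalar tree (Hartree). For extrapolation
    variants an extra ``"limit"`` tree holds the planted CBS/CPS limit, and
    ``extrapolation`` the parameters that connect the finite settings to it.
    """

    geometry: Geometry
    subsystems: list[SubsystemSpec]
    settings: list[Setting]
    seed: int
    solvation: bool
    plants: dict[str, dict]
    extrapolation: ExtrapolationParams | None = None

    @property
    def fragments(self) -> list[int]:
        return sorted(set(self.geometry.fragment_of.values()))

    @property
    def span_pairs(self) -> list[tuple[int, int]]:
        return spanning_pairs(self.subsystems)

    @property
    def same_sub_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for sub in self.subsystems:
            ids = sorted(sub.fragment_ids)
            pairs.extend((x, y) for i, x in enumerate(ids) for y in ids[i + 1 :])
        return sorted(pairs)

    def setting(self, label: str) -> Setting:
        for s in self.settings:
            if s.label == label:
                return s
        if label == "limit":
            s0 = self.settings[0]
            return Setting("limit", s0.basis, s0.method)
        raise ConfigurationError(f"no setting labeled {label!r}")

    # ---------------- record construction ----------------

    def _fragment_info(self, fid: int, ghost: bool = False) -> FragmentInfo:
        idx = self.geometry.fragment_atoms(fid)
        return FragmentInfo(
            label=fid,
            elements=[self.geometry.atoms[i].element for i in idx],
            coords=np.array([self.geometry.atoms[i].position for i in idx]),
            ghost=ghost,
        )

    def _new_record(self, label: str, real: list[int], ghost: list[int]) -> LEDRecord:
        setting = self.setting(label)
        return LEDRecord(
            fragments=[self._fragment_info(f) for f in real]
            + [self._fragment_info(f, ghost=True) for f in ghost],
            method=setting.method,
            setting_label=setting.label,
        )

    def records(self, setting_label: str, mode: str) -> dict:
        """All LEDRecords of one (setting, BSSE-mode) campaign, in supersystem labels.

        Returns ``{"super": rec, "subsystems": {name: rec}, "pairs":
        {frozenset: rec}, "monomers": {(real, ghost_or_None): rec}}``.
        The supersystem and pair records are shared between modes (the same
        calculation serves both); subsystem and monomer records differ.
        """
        if mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        t = self.plants[setting_label]
        bsse = mode == "corrected"
        frags = self.fragments

        sup = self._new_record(setting_label, frags, [])
        for x in frags:
            sup.intra[x] = {
                "ref": t["iso"][x]["ref"] + t["super_pert"][x]["ref"],
                "corr": t["iso"][x]["corr"] + t["super_pert"][x]["corr"],
            }
        for p, comps in t["epsN"].items():
            sup.pairwise[frozenset(p)] = ComponentSet(**comps)
        sup.recompute_totals()

        subs: dict[str, LEDRecord] = {}
        for sub in self.subsystems:
            real = sorted(sub.fragment_ids)
            ghost = sorted(set(frags) - sub.fragment_ids) if bsse else []
            rec = self._new_record(setting_label, real, ghost)
            for x in real:
                rec.intra[x] = {
                    "ref": t["iso"][x]["ref"] + t["sub_pert"][mode][x]["ref"],
                    "corr": t["iso"][x]["corr"] + t["sub_pert"][mode][x]["corr"],
                }
            for p, comps in t["epsSub"][mode].items():
                if set(p) <= sub.fragment_ids:
                    rec.pairwise[frozenset(p)] = ComponentSet(**comps)
            rec.recompute_totals()
            subs[sub.name] = rec

        pairs: dict[frozenset, LEDRecord] = {}
        for p in self.span_pairs:
            rec = self._new_record(setting_label, list(p), [])
            for x in p:
                rec.intra[x] = {
                    "ref": t["iso"][x]["ref"] + t["pair_intra_pert"][p][x]["ref"],
                    "corr": t["iso"][x]["corr"] + t["pair_intra_pert"][p][x]["corr"],
                }
            rec.pairwise[frozenset(p)] = ComponentSet(**t["eps2"][p])
            rec.recompute_totals()
            pairs[frozenset(p)] = rec

        monomers: dict[tuple[int, int | None], LEDRecord] = {}
        if bsse:
            for p in self.span_pairs:
                for x, y in (p, p[::-1]):
                    rec = self._new_record(setting_label, [x], [y])
                    rec.intra[x] = {
                        "ref": t["iso"][x]["ref"] - t["mono_bsse"][p][x]["ref"],
                        "corr": t["iso"][x]["corr"] - t["mono_bsse"][p][x]["corr"],
                    }
                    rec.recompute_totals()
                    monomers[(x, y)] = rec
        else:
            for x in frags:
                rec = self._new_record(setting_label, [x], [])
                rec.intra[x] = dict(t["iso"][x])
                rec.recompute_totals()
                monomers[(x, None)] = rec

        return {"super": sup, "subsystems": subs, "pairs": pairs, "monomers": monomers}

    # ---------------- analytic expectations ----------------

    def expected_standard_components(self, setting_label: str, mode: str) -> dict[str, np.ndarray]:
        """The planted standard N-body matrices, kcal/mol, labels sorted."""
        t = self.plants[setting_label]
        frags = self.fragments
        f = len(frags)
        idx = {x: i for i, x in enumerate(frags)}
        names = ["elprep", "elstat", "exch", "no_disp", "disp"] + (["solv"] if self.solvation else [])
        out = {n: np.zeros((f, f)) for n in names}
        for x in frags:
            i = idx[x]
            out["elprep"][i, i] = (
                t["super_pert"][x]["ref"]
                - t["sub_pert"][mode][x]["ref"]
                + t["super_pert"][x]["corr"]
                - t["sub_pert"][mode][x]["corr"]
            ) * HARTREE_TO_KCAL
        for p, comps in t["epsN"].items():
            i, j = idx[p[0]], idx[p[1]]
            sub_c = t["epsSub"][mode].get(p)
            for n in comps:
                val = comps[n] - (sub_c[n] if sub_c else 0.0)
                out[n][i, j] = out[n][j, i] = val * HARTREE_TO_KCAL
        out["total"] = sum(out[n] for n in names)
        return out

    def expected_interaction_energy(self, setting_label: str, mode: str) -> float:
        """Planted dE_int in kcal/mol."""
        mats = self.expected_standard_components(setting_label, mode)
        total = mats["total"]
        return float(np.sum(np.triu(total)))

    def expected_twobody_components(
        self, setting_label: str, mode: str, layout: str = "fp"
    ) -> dict[str, np.ndarray]:
        """Planted two-body matrices, kcal/mol; non-spanning cells are NaN."""
        t = self.plants[setting_label]
        frags = self.fragments
        f = len(frags)
        idx = {x: i for i, x in enumerate(frags)}
        names = ["elprep", "elstat", "exch", "no_disp", "disp"] + (["solv"] if self.solvation else [])
        out = {n: np.full((f, f), np.nan) for n in names}
        diag = np.zeros(f)
        for p in self.span_pairs:
            i, j = idx[p[0]], idx[p[1]]
            for n, v in t["eps2"][p].items():
                out[n][i, j] = out[n][j, i] = v * HARTREE_TO_KCAL
            prep = 0.0
            for x in p:
                dx = t["pair_intra_pert"][p][x]["ref"] + t["pair_intra_pert"][p][x]["corr"]
                if mode == "corrected":
                    dx += t["mono_bsse"][p][x]["ref"] + t["mono_bsse"][p][x]["corr"]
                diag[idx[x]] += dx * HARTREE_TO_KCAL
                prep += dx * HARTREE_TO_KCAL
            if layout == "fp":
                out["elprep"][i, j] = out["elprep"][j, i] = prep
        if layout == "standard":
            for i in range(f):
                out["elprep"][i, i] = diag[i]
                for n in names:
                    if n != "elprep" and np.isnan(out[n][i, i]):
                        out[n][i, i] = 0.0
        with np.errstate(invalid="ignore"):
            out["total"] = sum(np.nan_to_num(out[n]) for n in names)
        mask = np.isnan(out["elstat"]) if layout == "fp" else np.isnan(out["elstat"]) & ~np.eye(f, dtype=bool)
        out["total"][mask] = np.nan
        return out


def generate_ground_truth(
    S: int,
    f: Sequence[int],
    settings: Sequence[Setting] | None = None,
    seed: int = 0,
    solvation: bool = False,
    extrapolation: ExtrapolationParams | None = None,
) -> GroundTruth:
    """Build a reproducible planted campaign.

    ``S`` subsystems with ``f[i]`` fragments each; fragments are numbered
    consecutively and subsystems named "A", "B", ... When ``extrapolation``
    is given, exactly two settings are produced whose planted energies lie on
    the corresponding model form, plus a ``"limit"`` plant holding the exact
    extrapolation limit.
    """
    if S < 1 or len(f) != S or any(fi < 1 for fi in f):
        raise ConfigurationError(f"invalid subsystem/fragment counts S={S}, f={list(f)}")
    rng = np.random.default_rng(seed)
    n_frag = int(sum(f))
    geometry = _make_geometry(rng, n_frag)

    subsystems = []
    start = 1
    for k, fi in enumerate(f):
        name = chr(ord("A") + k)
        subsystems.append(SubsystemSpec(name, range(start, start + fi)))
        start += fi

    frags = list(range(1, n_frag + 1))
    same_sub = []
    for sub in subsystems:
        ids = sorted(sub.fragment_ids)
        same_sub.extend((x, y) for i, x in enumerate(ids) for y in ids[i + 1 :])
    span = spanning_pairs(subsystems)

    if extrapolation is None:
        if settings is None:
            settings = [Setting("main", "def2-TZVP")]
        plants = {s.label: _plant_tree(rng, frags, same_sub, span, solvation) for s in settings}
        return GroundTruth(geometry, subsystems, list(settings), seed, solvation, plants)

    params = extrapolation
    limit = _plant_tree(rng, frags, same_sub, span, solvation)
    if params.kind == "CBS":
        settings = [
            Setting(f"card{params.X}", f"basis-{params.X}Z"),
            Setting(f"card{params.Y}", f"basis-{params.Y}Z"),
        ]

        # one coefficient per leaf, shared between the two settings: draw the
        # coefficients once, then evaluate the model at both points
        coeffs = _transform_tree(limit, lambda cls, v: float(rng.normal(0.0, 0.05 if cls == "ref" else 0.02)))

        def eval_at(n: int):
            def walk(lim, coef, key=None):
                if isinstance(lim, dict):
                    return {k: walk(lim[k], coef[k], k) for k in lim}
                cls = "ref" if key in _REF_KEYS else "corr"
                if cls == "ref":
                    return lim + coef * math.exp(-params.alpha * math.sqrt(n))
                return lim + coef * n**-params.beta
            return walk(limit, coeffs)

        plants = {
            settings[0].label: eval_at(params.X),
            settings[1].label: eval_at(params.Y),
            "limit": limit,
        }
    else:  # CPS
        base = settings[0] if settings else Setting("pno", "def2-TZVP")
        settings = [
            Setting(f"pno{params.X}", base.basis, base.method, tcutpno_exponent=params.X),
            Setting(f"pno{params.Y}", base.basis, base.method, tcutpno_exponent=params.Y),
        ]
        deltas = _transform_tree(limit, lambda cls, v: float(rng.normal(0.0, 0.002)))

        def eval_cps(which: str):
            def walk(lim, d, key=None):
                if isinstance(lim, dict):
                    return {k: walk(lim[k], d[k], k) for k in lim}
                cls = "ref" if key in _REF_KEYS else "corr"
                if cls == "ref":
                    return lim  # PNO truncation leaves the reference energy alone
                e_x = lim - params.F * d
                return e_x if which == "X" else e_x + d
            return walk(limit, deltas)

        plants = {
            settings[0].label: eval_cps("X"),
            settings[1].label: eval_cps("Y"),
            "limit": limit,
        }

    return GroundTruth(geometry, subsystems, list(settings), seed, solvation, plants, extrapolation=params)


def write_mock_outputs(
    gt: GroundTruth,
    out_dir: str | Path,
    mode: str = "uncorrected",
    setting_label: str | None = None,
    include_twobody: bool = True,
) -> list[Path]:
    """Write one grammar-conforming output file per campaign calculation.

    Files carry *local* fragment labels (contiguous from 1, real fragments
    first) exactly as a real engine run on the rendered input would, so the
    parse -> align -> assemble pipeline is exercised end to end. Filenames
    follow the campaign manifest with ``.inp`` replaced by ``.out``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = [setting_label] if setting_label else [s.label for s in gt.settings]
    written: list[Path] = []
    for label in labels:
        recs = gt.records(label, mode)
        specs = enumerate_campaign(
            gt.geometry, gt.subsystems, [gt.setting(label)], mode == "corrected", include_twobody
        )
        for spec in specs:
            rec = _record_for_spec(recs, spec)
            local = relabel(rec, spec.local_fragment_map())
            path = out_dir / spec.filename.replace(".inp", ".out")
            write_led_output(local, path)
            written.append(path)
    return written


def _record_for_spec(recs: dict, spec: CalcSpec) -> LEDRecord:
    if spec.role == "supersystem":
        return recs["super"]
    if spec.role == "subsystem":
        for rec in recs["subsystems"].values():
            if set(rec.real_labels) == set(spec.real_fragments):
                return rec
        raise ConfigurationError(f"no subsystem record for {sorted(spec.real_fragments)}")
    if spec.role == "pair":
        return recs["pairs"][frozenset(spec.real_fragments)]
    real = next(iter(spec.real_fragments))
    ghost = next(iter(spec.ghost_fragments)) if spec.ghost_fragments else None
    return recs["monomers"][(real, ghost)]
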