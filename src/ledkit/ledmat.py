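"""Assembly of LED interaction-energy matrices.

The interaction energy of a supersystem, defined as the supersystem energy
minus the sum of the part energies at the supersystem geometry, is decomposed
into intrafragment electronic-preparation terms and interfragment terms:

    dE_int = sum_X dE_el-prep(X) + sum_{X>Y} eps(X,Y)             (standard)
    dE_int = sum_{X>Y} [dE_el-prep(X,Y) + eps(X,Y)]               (fp)

In the *standard* layout the F x F matrix carries the cumulative
dE_el-prep(X) on the diagonal and the eps components off-diagonal; for a
fragment pair within one subsystem the cell is a *differential* term
(supersystem value minus the value in that subsystem's own calculation),
while pairs spanning two subsystems take the supersystem value directly.
The *fragment-pairwise* (fp) layout redistributes the diagonal preparation
energies over fragment pairs so every matrix element is a pair quantity;
any redistribution scheme must conserve the total exactly.

Two-body matrices are assembled from LED runs on each isolated spanning
pair against its monomer references; subtracting them from the N-body
matrix isolates cooperative (many-body) effects.

All matrices are stored in kcal/mol. Components tracked: ``total``,
``elprep`` (with its ``elprep_ref``/``elprep_corr`` split, needed for
extrapolation), ``elstat``, ``exch``, ``no_disp``, ``disp`` and optionally
``solv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AlignmentError, CompletenessError, ConfigurationError, PartitionError
from .inputgen import SubsystemSpec, spanning_pairs
from .ledout import ComponentSet, LEDRecord
from .units import HARTREE_TO_KCAL

__all__ = [
    "LEDMatrixSet",
    "EPS_COMPONENTS",
    "interaction_energy",
    "assemble_standard_nbody",
    "assemble_fp_nbody",
    "assemble_twobody",
    "cooperativity",
    "grand_total",
]

#: interfragment components as stored in matrix sets (solv optional)
EPS_COMPONENTS = ("elstat", "exch", "no_disp", "disp")

PUBLIC_COMPONENTS = ("total", "elprep", "elstat", "exch", "no_disp", "disp", "solv")


@dataclass
class LEDMatrixSet:
    """Component-resolved F x F interaction-energy matrices, kcal/mol.

    ``absent_mask[i, j]`` is True where the element is undefined (e.g. the
    intra-subsystem cells of a two-body analysis); absent cells hold NaN and
    are exported as empty cells, never as zeros. ``fully_coop_mask`` is set
    by :func:`cooperativity` where the two-body term was absent and the
    N-body value is therefore entirely cooperative.
    """

    layout: str  # "standard" | "fp"
    components: dict[str, np.ndarray]
    fragment_labels: list[int]
    subsystem_of: dict[int, str]
    bsse_corrected: bool
    body_order: str = "nbody"  # "nbody" | "twobody" | "cooperativity"
    absent_mask: np.ndarray | None = None
    fully_coop_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = len(self.fragment_labels)
        if self.absent_mask is None:
            self.absent_mask = np.zeros((f, f), dtype=bool)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_labels)

    def index_of(self, label: int) -> int:
        return self.fragment_labels.index(label)

    def component(self, name: str) -> np.ndarray:
        return self.components[name]

    def has_solv(self) -> bool:
        return "solv" in self.components


def _to_kcal(value: float) -> float:
    return value * HARTREE_TO_KCAL


def interaction_energy(super_rec: LEDRecord, parts: Sequence[LEDRecord]) -> float:
    """dE_int = E(super) - sum E(part), in kcal/mol.

    For a counterpoise-corrected analysis the parts must be the ghost-padded
    records (each part computed in the supersystem basis).
    """
    _check_partition(super_rec, parts)
    return _to_kcal(super_rec.total_energy - sum(p.total_energy for p in parts))


def _check_partition(super_rec: LEDRecord, parts: Sequence[LEDRecord]) -> None:
    seen: set[int] = set()
    for p in parts:
        real = set(p.real_labels)
        if real & seen:
            raise PartitionError(f"fragments {sorted(real & seen)} are real in more than one part")
        extra = real - set(super_rec.real_labels)
        if extra:
            raise AlignmentError(f"part fragments {sorted(extra)} unknown to the supersystem record")
        seen |= real
    if seen != set(super_rec.real_labels):
        raise PartitionError(
            f"parts cover fragments {sorted(seen)} but supersystem has {sorted(super_rec.real_labels)}"
        )


def _subsystem_map(subsystems: Sequence[SubsystemSpec]) -> dict[int, str]:
    return {fid: sub.name for sub in subsystems for fid in sub.fragment_ids}


def _component_value(comp: ComponentSet, name: str) -> float:
    v = getattr(comp, name)
    return 0.0 if v is None else v


def _empty_components(f: int, with_solv: bool) -> dict[str, np.ndarray]:
    names = ["total", "elprep", "elprep_ref", "elprep_corr", *EPS_COMPONENTS]
    if with_solv:
        names.append("solv")
    return {n: np.zeros((f, f)) for n in names}


def _recompute_total(ms: LEDMatrixSet) -> None:
    names = ["elprep", *EPS_COMPONENTS] + (["solv"] if ms.has_solv() else [])
    total = np.zeros_like(ms.components["elprep"])
    for n in names:
        total += np.nan_to_num(ms.components[n], nan=0.0)
    total[ms.absent_mask] = np.nan
    ms.components["total"] = total


def _apply_mask(ms: LEDMatrixSet) -> None:
    for mat in ms.components.values():
        mat[ms.absent_mask] = np.nan


def assemble_standard_nbody(
    super_rec: LEDRecord,
    parts: Sequence[LEDRecord],
    subsystems: Sequence[SubsystemSpec],
) -> LEDMatrixSet:
    """Standard-layout N-body LED matrix from a supersystem record and its parts.

    All records must already be expressed in supersystem fragment labels
    (see :func:`ledkit.ledout.align_labels`). Diagonal cells hold
    dE_el-prep(X) = intra_X(super) - intra_X(part); same-subsystem off-diagonal
    cells hold the differential eps components (super minus part); spanning
    cells take the supersystem eps components directly.
    """
    _check_partition(super_rec, parts)
    labels = sorted(super_rec.real_labels)
    sub_of = _subsystem_map(subsystems)
    if set(sub_of) != set(labels):
        raise PartitionError("subsystem definition does not match the supersystem fragments")
    part_of: dict[int, LEDRecord] = {}
    for p in parts:
        for l in p.real_labels:
            part_of[l] = p

    with_solv = all(c.solv is not None for c in super_rec.pairwise.values()) and bool(super_rec.pairwise)
    f = len(labels)
    comps = _empty_components(f, with_solv)

    for i, x in enumerate(labels):
        sup = super_rec.intra[x]
        iso = part_of[x].intra[x]
        dref = (sup["ref"] or 0.0) - (iso["ref"] or 0.0)
        dcorr = (sup["corr"] or 0.0) - (iso["corr"] or 0.0)
        comps["elprep_ref"][i, i] = _to_kcal(dref)
        comps["elprep_corr"][i, i] = _to_kcal(dcorr)
        comps["elprep"][i, i] = _to_kcal(dref + dcorr)

    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if j <= i:
                continue
            pair = frozenset({x, y})
            sup_c = super_rec.pairwise.get(pair)
            if sup_c is None:
                raise CompletenessError(f"supersystem record lacks pair ({x},{y})")
            same_sub = sub_of[x] == sub_of[y]
            names = list(EPS_COMPONENTS) + (["solv"] if with_solv else [])
            for name in names:
                value = _component_value(sup_c, name)
                if same_sub:
                    part_c = part_of[x].pairwise.get(pair)
                    if part_c is None:
                        raise CompletenessError(
                            f"subsystem record for {sub_of[x]} lacks pair ({x},{y})"
                        )
                    value -= _component_value(part_c, name)
                comps[name][i, j] = comps[name][j, i] = _to_kcal(value)

    ms = LEDMatrixSet(
        layout="standard",
        components=comps,
        fragment_labels=labels,
        subsystem_of=sub_of,
        bsse_corrected=any(f.ghost for p in parts for f in p.fragments),
        body_order="nbody",
        meta={"method": super_rec.method, "setting": super_rec.setting_label},
    )
    _recompute_total(ms)
    return ms


def _fp_redistribute(diag: np.ndarray, eps_total: np.ndarray, scheme: str) -> np.ndarray:
    """Spread a diagonal el-prep vector over fragment pairs, conserving the sum.

    ``equal``: fragment X's el-prep splits evenly over its F-1 partners, the
    (X, Y) cell collecting both members' shares. ``prop_eps``: X's shares are
    proportional to |eps_total(X, Y)| over its partners, falling back to the
    equal split when all magnitudes vanish.
    """
    f = len(diag)
    out = np.zeros((f, f))
    if f == 1:
        return out
    for i in range(f):
        partners = [j for j in range(f) if j != i]
        if scheme == "equal":
            weights = np.full(len(partners), 1.0 / (f - 1))
        elif scheme == "prop_eps":
            mags = np.array([abs(eps_total[i, j]) for j in partners])
            weights = mags / mags.sum() if mags.sum() > 0 else np.full(len(partners), 1.0 / (f - 1))
        else:
            raise ConfigurationError(f"unknown fp el-prep scheme {scheme!r}")
        for w, j in zip(weights, partners):
            out[i, j] += diag[i] * w
    return out + out.T - np.diag(np.diag(out + out.T))  # symmetrize shares onto unordered pairs


def assemble_fp_nbody(std: LEDMatrixSet, partitioner: str = "equal") -> LEDMatrixSet:
    """Fragment-pairwise layout: diagonal el-prep redistributed over pairs.

    eps components are copied unchanged; conservation
    sum_{X>Y} dE_el-prep(X,Y) = sum_X dE_el-prep(X) holds exactly for every
    scheme, and each cell's total is dE_int(X,Y) = dE_el-prep(X,Y) + eps(X,Y).
    """
    if std.layout != "standard":
        raise ConfigurationError("fp assembly expects a standard-layout matrix set")
    f = std.n_fragments
    comps = {k: v.copy() for k, v in std.components.items()}
    eps_total = sum(np.nan_to_num(std.components[n]) for n in EPS_COMPONENTS)
    if std.has_solv():
        eps_total = eps_total + np.nan_to_num(std.components["solv"])
    for key in ("elprep_ref", "elprep_corr"):
        diag = np.diag(std.components[key]).copy()
        comps[key] = _fp_redistribute(np.nan_to_num(diag), eps_total, partitioner)
    comps["elprep"] = comps["elprep_ref"] + comps["elprep_corr"]
    ms = LEDMatrixSet(
        layout="fp",
        components=comps,
        fragment_labels=list(std.fragment_labels),
        subsystem_of=dict(std.subsystem_of),
        bsse_corrected=std.bsse_corrected,
        body_order=std.body_order,
        absent_mask=std.absent_mask.copy(),
        meta={**std.meta, "fp_scheme": partitioner},
    )
    _recompute_total(ms)
    _apply_mask(ms)
    return ms


def _monomer_lookup(
    monomer_records: Sequence[LEDRecord], bsse: bool
) -> dict[tuple[int, int | None], LEDRecord]:
    """Key monomers by (real label, ghost label) — ghost None when uncorrected."""
    table: dict[tuple[int, int | None], LEDRecord] = {}
    for rec in monomer_records:
        real = rec.real_labels
        if len(real) != 1:
            raise ConfigurationError("monomer record must have exactly one real fragment")
        ghosts = [f.label for f in rec.fragments if f.ghost]
        key = (real[0], ghosts[0] if (bsse and ghosts) else None)
        table[key] = rec
    return table


def assemble_twobody(
    pair_records: Sequence[LEDRecord],
    monomer_records: Sequence[LEDRecord],
    subsystems: Sequence[SubsystemSpec],
    bsse: bool,
    layout: str = "standard",
) -> LEDMatrixSet:
    """Two-body LED matrix from isolated spanning-pair runs and their monomers.

    Records must be expressed in supersystem labels. In the standard layout
    the diagonal collects each fragment's pair-vs-monomer el-prep over all
    its spanning partners and intra-subsystem off-diagonal cells are absent;
    in the fp layout the el-prep lands directly on its pair cell and every
    non-spanning cell is absent.
    """
    if not pair_records:
        raise CompletenessError("no pair records supplied")
    if layout not in ("standard", "fp"):
        raise ConfigurationError(f"unknown layout {layout!r}")
    sub_of = _subsystem_map(subsystems)
    labels = sorted(sub_of)
    f = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    wanted = {frozenset(p) for p in spanning_pairs(subsystems)}

    by_pair: dict[frozenset, LEDRecord] = {}
    for rec in pair_records:
        key = frozenset(rec.real_labels)
        if len(key) != 2:
            raise ConfigurationError("pair record must have exactly two real fragments")
        by_pair[key] = rec
    missing = wanted - set(by_pair)
    if missing:
        raise CompletenessError(
            "missing pair records: " + ", ".join(str(tuple(sorted(p))) for p in sorted(missing, key=sorted))
        )
    monomers = _monomer_lookup(monomer_records, bsse)

    with_solv = all(
        by_pair[p].pairwise[p].solv is not None for p in wanted if p in by_pair
    ) and bool(wanted)
    comps = _empty_components(f, with_solv)
    absent = np.ones((f, f), dtype=bool)

    for pair in sorted(wanted, key=sorted):
        x, y = sorted(pair)
        rec = by_pair[pair]
        comp = rec.pairwise.get(pair)
        if comp is None:
            raise CompletenessError(f"pair record ({x},{y}) lacks its interaction block")
        i, j = idx[x], idx[y]
        absent[i, j] = absent[j, i] = False
        names = list(EPS_COMPONENTS) + (["solv"] if with_solv else [])
        for name in names:
            comps[name][i, j] = comps[name][j, i] = _to_kcal(_component_value(comp, name))
        # pair-vs-monomer electronic preparation
        dref = dcorr = 0.0
        for real, ghost in ((x, y), (y, x)):
            mono = monomers.get((real, ghost if bsse else None))
            if mono is None:
                raise CompletenessError(f"missing monomer record for fragment {real} (pair {x},{y})")
            dref_k = (rec.intra[real]["ref"] or 0.0) - (mono.intra[real]["ref"] or 0.0)
            dcorr_k = (rec.intra[real]["corr"] or 0.0) - (mono.intra[real]["corr"] or 0.0)
            if layout == "standard":
                k = idx[real]
                comps["elprep_ref"][k, k] += _to_kcal(dref_k)
                comps["elprep_corr"][k, k] += _to_kcal(dcorr_k)
            dref += dref_k
            dcorr += dcorr_k
        if layout == "fp":
            comps["elprep_ref"][i, j] = comps["elprep_ref"][j, i] = _to_kcal(dref)
            comps["elprep_corr"][i, j] = comps["elprep_corr"][j, i] = _to_kcal(dcorr)

    if layout == "standard":
        np.fill_diagonal(absent, False)
    comps["elprep"] = comps["elprep_ref"] + comps["elprep_corr"]

    ms = LEDMatrixSet(
        layout=layout,
        components=comps,
        fragment_labels=labels,
        subsystem_of=sub_of,
        bsse_corrected=bsse,
        body_order="twobody",
        absent_mask=absent,
        meta={"method": pair_records[0].method, "setting": pair_records[0].setting_label},
    )
    _recompute_total(ms)
    _apply_mask(ms)
    return ms


def cooperativity(nbody: LEDMatrixSet, twobody: LEDMatrixSet) -> LEDMatrixSet:
    """Many-body (cooperative) contribution: N-body minus two-body, cellwise.

    Where the two-body matrix has no element (intra-subsystem cells), the
    N-body value passes through unchanged and the cell is flagged fully
    cooperative.
    """
    if nbody.fragment_labels != twobody.fragment_labels:
        raise AlignmentError("fragment labels differ between N-body and two-body sets")
    if nbody.layout != twobody.layout:
        raise AlignmentError("layout mismatch between N-body and two-body sets")
    comps: dict[str, np.ndarray] = {}
    names = set(nbody.components) & set(twobody.components)
    fully = twobody.absent_mask & ~nbody.absent_mask
    np.fill_diagonal(fully, False)  # full cooperativity is a pair-cell notion
    for name in names:
        a = nbody.components[name]
        b = np.where(twobody.absent_mask, 0.0, np.nan_to_num(twobody.components[name]))
        comps[name] = a - b
    ms = LEDMatrixSet(
        layout=nbody.layout,
        components=comps,
        fragment_labels=list(nbody.fragment_labels),
        subsystem_of=dict(nbody.subsystem_of),
        bsse_corrected=nbody.bsse_corrected,
        body_order="cooperativity",
        absent_mask=nbody.absent_mask.copy(),
        fully_coop_mask=fully,
        meta={**nbody.meta, "twobody_setting": twobody.meta.get("setting")},
    )
    _apply_mask(ms)
    return ms


def grand_total(ms: LEDMatrixSet, component: str = "total") -> float:
    """Sum of the diagonal plus the upper triangle, skipping absent cells.

    For a standard N-body set this equals the interaction energy dE_int; for
    an fp set the diagonal is zero and the pair cells alone carry dE_int.
    """
    mat = ms.components[component]
    f = ms.n_fragments
    total = 0.0
    for i in range(f):
        for j in range(i, f):
            if not ms.absent_mask[i, j] and np.isfinite(mat[i, j]):
                total += mat[i, j]
    return total
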