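"""Two-point complete-basis-set (CBS) and complete-PNO-space (CPS) extrapolation.

CBS: reference (mean-field) energies converge as E(n) = E_CBS + A exp(-a sqrt(n))
in the basis cardinal number n, correlation energies as E(n) = E_CBS + B n^-b.
Each form is solved through two successive cardinal numbers. The default
(a, b) pairs for the (aug)-cc-pVnZ family ship as a user-overridable table:
(4.420, 2.460) for cardinals 2/3 and (5.460, 3.050) for 3/4.

CPS: correlation energies at two successive T_CutPNO exponents X and X+1
(thresholds 10^-X, 10^-(X+1)) are extrapolated to the complete PNO space as
E_CPS = E_X + F (E_Y - E_X), default F = 1.5. PNO truncation does not touch
the reference energy, so reference-level terms pass through from the
tighter-threshold calculation.

Both forms are affine in (E_X, E_Y), so extrapolation commutes with any
linear combination of LED terms — individual LED matrix elements are
extrapolated exactly like the parent energies.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import AlignmentError, ConfigurationError, DegenerateParametersError
from .ledmat import EPS_COMPONENTS, LEDMatrixSet, _recompute_total, _apply_mask

__all__ = [
    "ExtrapolationParams",
    "default_cbs_params",
    "cbs_reference",
    "cbs_correlation",
    "cps",
    "extrapolate_matrixset",
]

#: matrix components extrapolated with the reference-energy (exponential) form
REFERENCE_COMPONENTS = ("elstat", "exch", "elprep_ref", "solv")
#: matrix components extrapolated with the correlation (inverse-power / CPS) form
CORRELATION_COMPONENTS = ("no_disp", "disp", "elprep_corr")


@dataclass(frozen=True)
class ExtrapolationParams:
    """Parameters of one two-point extrapolation.

    kind
        "CBS" (X, Y are basis cardinal numbers; alpha/beta exponents) or
        "CPS" (X, Y are T_CutPNO exponents; F multiplier).
    """

    kind: str
    X: int
    Y: int
    alpha: float | None = None
    beta: float | None = None
    F: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("CBS", "CPS"):
            raise ConfigurationError(f"kind must be CBS or CPS, got {self.kind!r}")
        if self.Y <= self.X:
            raise ConfigurationError("Y must exceed X")
        if self.kind == "CBS":
            if self.alpha is None or self.beta is None:
                raise ConfigurationError("CBS extrapolation needs alpha and beta")
            if self.alpha <= 0 or self.beta <= 0:
                raise ConfigurationError("alpha and beta must be positive")
        if self.kind == "CPS" and self.F is None:
            object.__setattr__(self, "F", 1.5)


def _load_cbs_table() -> list[dict]:
    with resources.files("ledkit.data").joinpath("cbs_coefficients.csv").open() as fh:
        return list(csv.DictReader(fh))


def default_cbs_params(X: int, Y: int, basis_family: str = "cc") -> ExtrapolationParams:
    """Look up shipped alpha/beta for a cardinal pair of a basis family."""
    for row in _load_cbs_table():
        if row["basis_family"] == basis_family and int(row["cardinal_low"]) == X and int(row["cardinal_high"]) == Y:
            return ExtrapolationParams("CBS", X, Y, alpha=float(row["alpha"]), beta=float(row["beta"]))
    raise ConfigurationError(f"no shipped CBS coefficients for {basis_family}({X}/{Y})")


def cbs_reference(E_X: float, E_Y: float, params: ExtrapolationParams) -> float:
    """Two-point exponential extrapolation of a reference-level energy."""
    if params.kind != "CBS":
        raise ConfigurationError("cbs_reference requires CBS params")
    ex = math.exp(-params.alpha * math.sqrt(params.X))
    ey = math.exp(-params.alpha * math.sqrt(params.Y))
    if not math.isfinite(ex - ey) or ex == ey:
        raise DegenerateParametersError("exp(-a sqrt(X)) and exp(-a sqrt(Y)) coincide numerically")
    A = (E_X - E_Y) / (ex - ey)
    return E_X - A * ex


def cbs_correlation(E_X: float, E_Y: float, params: ExtrapolationParams) -> float:
    """Two-point inverse-power extrapolation of a correlation energy."""
    if params.kind != "CBS":
        raise ConfigurationError("cbs_correlation requires CBS params")
    if params.X == params.Y:
        raise DegenerateParametersError("cardinal numbers coincide")
    xb = params.X**params.beta
    yb = params.Y**params.beta
    return (xb * E_X - yb * E_Y) / (xb - yb)


def cps(E_X: float, E_Y: float, params: ExtrapolationParams) -> float:
    """Complete-PNO-space estimate from the looser (X) and tighter (Y) thresholds."""
    if params.kind != "CPS":
        raise ConfigurationError("cps requires CPS params")
    return E_X + params.F * (E_Y - E_X)


def extrapolate_matrixset(
    ms_X: LEDMatrixSet, ms_Y: LEDMatrixSet, params: ExtrapolationParams
) -> LEDMatrixSet:
    """Extrapolate every cell of every LED component.

    CBS: reference-derived components (elstat, exch, solv, the reference part
    of the electronic preparation) go through the exponential form,
    correlation-derived ones (no_disp, disp, correlation el-prep) through the
    inverse-power form. CPS: the affine formula is applied to correlation
    components only; reference components pass through from the
    tighter-threshold set. Totals are recomputed; absent cells stay absent.
    """
    if ms_X.fragment_labels != ms_Y.fragment_labels:
        raise AlignmentError("fragment labels differ between the two matrix sets")
    if ms_X.layout != ms_Y.layout:
        raise AlignmentError("layout mismatch between the two matrix sets")
    if not np.array_equal(ms_X.absent_mask, ms_Y.absent_mask):
        raise AlignmentError("absent-cell masks differ between the two matrix sets")

    comps: dict[str, np.ndarray] = {}
    for name in ms_Y.components:
        if name in ("total", "elprep"):
            continue
        a = np.nan_to_num(ms_X.components[name])
        b = np.nan_to_num(ms_Y.components[name])
        if params.kind == "CBS":
            fn = cbs_reference if name in REFERENCE_COMPONENTS else cbs_correlation
            comps[name] = np.vectorize(lambda ex, ey: fn(ex, ey, params))(a, b) if a.size else a.copy()
        else:  # CPS
            if name in CORRELATION_COMPONENTS:
                comps[name] = a + params.F * (b - a)
            else:
                comps[name] = b.copy()
    comps["elprep"] = comps["elprep_ref"] + comps["elprep_corr"]

    ms = LEDMatrixSet(
        layout=ms_Y.layout,
        components=comps,
        fragment_labels=list(ms_Y.fragment_labels),
        subsystem_of=dict(ms_Y.subsystem_of),
        bsse_corrected=ms_Y.bsse_corrected,
        body_order=ms_Y.body_order,
        absent_mask=ms_Y.absent_mask.copy(),
        meta={
            **ms_Y.meta,
            "extrapolation": f"{params.kind}({params.X}/{params.Y})",
            "extrapolated_from": (ms_X.meta.get("setting"), ms_Y.meta.get("setting")),
        },
    )
    _recompute_total(ms)
    _apply_mask(ms)
    return ms
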