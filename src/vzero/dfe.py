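"""Distributions of fitness effects (DFEs) and the weighted-integral engine.

A DFE here is a mixture of a beneficial component (effects ``s > 0``) and a
deleterious component (effects ``s < 0``), with mixture weights set by the
ratio ``eta = Ub/Ud`` of beneficial to deleterious mutation rates:
``w_b = eta/(1+eta)`` and ``w_d = 1/(1+eta)``.  Deleterious scales are stored
as positive numbers (``sd``, ``gamma_d``); the sign is applied inside the
integral kernels.

Every theory quantity in this package is a weighted integral
``∫ ρ(γ) K(γ) dγ`` of the *scaled* DFE (``γ = Tc·s``, with ``Tc`` the
coalescence timescale) against one of a small family of kernels
(:data:`KERNELS`).  Delta and exponential components use closed forms;
gamma-distributed and tabulated components go through adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "DFESpec",
    "ScaledDFE",
    "Kernel",
    "KERNELS",
    "DivergentIntegralError",
    "dfe_integral",
    "scale_dfe",
    "unscale_dfe",
    "with_eta",
    "deleterious_magnitudes",
]

FAMILIES = ("two_effect", "exponential_pair", "gamma_pair", "tabulated")


class DivergentIntegralError(ValueError):
    """The beneficial tail decays more slowly than the kernel grows."""


# ---------------------------------------------------------------------------
# DFE containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DFESpec:
    """A distribution of unscaled fitness effects ρ(s).

    Parameters
    ----------
    family:
        One of ``two_effect`` (delta masses at +sb and −sd),
        ``exponential_pair`` (exponential |s| on each side with means sb, sd),
        ``gamma_pair`` (gamma-distributed |s| with means sb, sd and shapes
        shape_b, shape_d) or ``tabulated`` (discrete atoms).
    sb, sd:
        Beneficial / deleterious effect scales, both positive.  For the
        parametric families these are the means of |s| on each side.
    eta:
        Ratio Ub/Ud of beneficial to deleterious mutation rates; the mixture
        weights are eta/(1+eta) and 1/(1+eta).
    shape_b, shape_d:
        Gamma shapes (gamma_pair only).
    table:
        Sequence of ``(s, weight)`` atoms (tabulated only); weights are
        normalized to sum to one.  Atoms are treated as discrete masses, not
        an interpolated density.
    """

    family: str
    sb: float | None = None
    sd: float | None = None
    eta: float | None = None
    shape_b: float | None = None
    shape_d: float | None = None
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown DFE family {self.family!r}")
        if self.family == "tabulated":
            if not self.table:
                raise ValueError("tabulated DFE requires a non-empty table")
            total = sum(w for _, w in self.table)
            if total <= 0:
                raise ValueError("tabulated weights must have positive sum")
            object.__setattr__(
                self,
                "table",
                tuple((float(s), float(w) / total) for s, w in self.table),
            )
        else:
            if self.sb is None or self.sd is None or self.eta is None:
                raise ValueError(f"{self.family} DFE requires sb, sd and eta")
            if self.sb <= 0 or self.sd <= 0:
                raise ValueError("effect scales sb, sd must be positive")
            if self.eta < 0:
                raise ValueError("eta = Ub/Ud must be non-negative")
            if self.family == "gamma_pair":
                if not self.shape_b or not self.shape_d:
                    raise ValueError("gamma_pair requires shape_b and shape_d")
                if self.shape_b <= 0 or self.shape_d <= 0:
                    raise ValueError("gamma shapes must be positive")

    # mixture weights -------------------------------------------------------
    @property
    def weight_beneficial(self) -> float:
        if self.family == "tabulated":
            return sum(w for s, w in self.table if s > 0)
        if math.isinf(self.eta):
            return 1.0
        return self.eta / (1.0 + self.eta)

    @property
    def weight_deleterious(self) -> float:
        if self.family == "tabulated":
            return sum(w for s, w in self.table if s < 0)
        if math.isinf(self.eta):
            return 0.0
        return 1.0 / (1.0 + self.eta)

    def ratio_eta(self) -> float:
        """Ub/Ud implied by the mixture weights."""
        if self.family == "tabulated":
            wd = self.weight_deleterious
            if wd == 0:
                return math.inf
            return self.weight_beneficial / wd
        return self.eta


@dataclass(frozen=True)
class ScaledDFE:
    """The same mixture over scaled effects γ = Tc·s.

    ``gamma_b`` and ``gamma_d`` are the (positive) scaled effect scales of the
    two components; for ``exponential_pair`` beneficial parts, integrals
    against exponentially growing kernels exist only when ``gamma_b < 1``.
    """

    family: str
    gamma_b: float | None = None
    gamma_d: float | None = None
    eta: float | None = None
    shape_b: float | None = None
    shape_d: float | None = None
    table: tuple[tuple[float, float], ...] | None = None

    __post_init__ = DFESpec.__post_init__

    # mirror the DFESpec accessors, mapping the field names
    @property
    def sb(self):  # noqa: D102 - alias used by the shared integral engine
        return self.gamma_b

    @property
    def sd(self):
        return self.gamma_d

    weight_beneficial = DFESpec.weight_beneficial
    weight_deleterious = DFESpec.weight_deleterious
    ratio_eta = DFESpec.ratio_eta


def scale_dfe(dfe: DFESpec, Tc: float) -> ScaledDFE:
    """Map a DFE of unscaled effects s to scaled effects γ = Tc·s."""
    if Tc <= 0:
        raise ValueError(f"Tc must be positive, got {Tc}")
    if dfe.family == "tabulated":
        return ScaledDFE(
            family="tabulated",
            table=tuple((Tc * s, w) for s, w in dfe.table),
        )
    return ScaledDFE(
        family=dfe.family,
        gamma_b=Tc * dfe.sb,
        gamma_d=Tc * dfe.sd,
        eta=dfe.eta,
        shape_b=dfe.shape_b,
        shape_d=dfe.shape_d,
    )


def unscale_dfe(sdfe: ScaledDFE, Tc: float) -> DFESpec:
    """Inverse of :func:`scale_dfe`; ``unscale(scale(d, Tc), Tc) == d``."""
    if Tc <= 0:
        raise ValueError(f"Tc must be positive, got {Tc}")
    if sdfe.family == "tabulated":
        return DFESpec(
            family="tabulated",
            table=tuple((g / Tc, w) for g, w in sdfe.table),
        )
    return DFESpec(
        family=sdfe.family,
        sb=sdfe.gamma_b / Tc,
        sd=sdfe.gamma_d / Tc,
        eta=sdfe.eta,
        shape_b=sdfe.shape_b,
        shape_d=sdfe.shape_d,
    )


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

# series cutoff below which kernels with removable singularities at 0 switch
# to a Taylor branch to avoid cancellation
_SERIES_CUT = 1e-6


def _expm1_over(g):
    """(e^γ − 1)/γ, continuous at 0."""
    g = np.asarray(g, dtype=float)
    small = np.abs(g) < _SERIES_CUT
    gs = np.where(small, 1.0, g)
    return np.where(small, 1.0 + g / 2.0 + g * g / 6.0, np.expm1(gs) / gs)


def _k_v(g):
    g = np.asarray(g, dtype=float)
    return g * np.exp(g)


def _k_F(g):
    return np.expm1(np.asarray(g, dtype=float))


def _k_alpha(g):
    # e^γ + (1−e^γ)/γ  =  (γe^γ + 1 − e^γ)/γ ; → 0 as γ→0 (series γ/2+γ²/3+…)
    g = np.asarray(g, dtype=float)
    small = np.abs(g) < 1e-4
    gs = np.where(small, 1.0, g)
    exact = np.exp(gs) - np.expm1(gs) / gs
    series = g / 2.0 + g * g / 3.0 + g ** 3 / 8.0 + g ** 4 / 30.0
    return np.where(small, series, exact)


def _k_eq8(g):
    return _expm1_over(g)


def _k_xc(g):
    # γe^γ + 1 − e^γ ;  series γ²/2 + γ³/3 + …
    g = np.asarray(g, dtype=float)
    small = np.abs(g) < 1e-4
    gs = np.where(small, 1.0, g)
    exact = gs * np.exp(gs) - np.expm1(gs)
    series = g * g / 2.0 + g ** 3 / 3.0 + g ** 4 / 8.0
    return np.where(small, series, exact)


def _k_b3(g):
    g = np.asarray(g, dtype=float)
    return g * g * np.exp(g)


def _k_ne(g):
    # (1 − e^{−γ})/γ, continuous at 0
    g = np.asarray(g, dtype=float)
    small = np.abs(g) < _SERIES_CUT
    gs = np.where(small, 1.0, g)
    exact = -np.expm1(-gs) / gs
    series = 1.0 - g / 2.0 + g * g / 6.0
    return np.where(small, series, exact)


@dataclass(frozen=True)
class Kernel:
    """A named integral kernel K(γ) with per-family closed forms.

    ``exp_pos(m)`` / ``exp_neg(m)`` give ∫K dρ for an exponential component of
    mean scaled effect m on the positive / negative side; ``grows_pos`` /
    ``grows_neg`` mark the side on which K grows like e^{|γ|}, so that an
    exponential (or gamma) tail with scale ≥ 1 on that side diverges.
    ``fe`` is K(γ)·e^{−|γ|} on the growing side, a bounded form the quadrature
    path multiplies back into the exponential weight's log to avoid overflow.
    """

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    exp_pos: Callable[[float], float]
    exp_neg: Callable[[float], float]
    grows_pos: bool = True
    grows_neg: bool = False
    fe: Callable[[np.ndarray], np.ndarray] | None = None


def _log1p(x):
    return math.log1p(x)


KERNELS: dict[str, Kernel] = {
    # γ e^γ — the v=0 kernel (Σ ρ γ e^γ has the sign of Tc² v)
    "v": Kernel(
        "v",
        _k_v,
        exp_pos=lambda m: m / (1.0 - m) ** 2,
        exp_neg=lambda m: -m / (1.0 + m) ** 2,
        fe=lambda u: u,
    ),
    # e^γ − 1 — the F=U kernel (sign of F − U)
    "F": Kernel(
        "F",
        _k_F,
        exp_pos=lambda m: m / (1.0 - m),
        exp_neg=lambda m: -m / (1.0 + m),
        fe=lambda u: -np.expm1(-u),
    ),
    # e^γ + (1−e^γ)/γ — the α=0 kernel
    "alpha": Kernel(
        "alpha",
        _k_alpha,
        exp_pos=lambda m: 1.0 / (1.0 - m) + math.log1p(-m) / m,
        exp_neg=lambda m: 1.0 / (1.0 + m) - _log1p(m) / m,
        fe=lambda u: 1.0 - _k_ne(u),
    ),
    # (e^γ − 1)/γ — the dimensionless integral in the Tc relation
    "eq8": Kernel(
        "eq8",
        _k_eq8,
        exp_pos=lambda m: -math.log1p(-m) / m,
        exp_neg=lambda m: _log1p(m) / m,
        fe=_k_ne,
    ),
    # γ e^γ + 1 − e^γ — the fitness-lead (xc) kernel
    "xc": Kernel(
        "xc",
        _k_xc,
        exp_pos=lambda m: m * m / (1.0 - m) ** 2,
        exp_neg=lambda m: m * m / (1.0 + m) ** 2,
        fe=lambda u: u + np.expm1(-u),
    ),
    # γ² e^γ — the Airy fitness-scale (b³) kernel
    "b3": Kernel(
        "b3",
        _k_b3,
        exp_pos=lambda m: 2.0 * m * m / (1.0 - m) ** 3,
        exp_neg=lambda m: 2.0 * m * m / (1.0 + m) ** 3,
        fe=lambda u: u * u,
    ),
    # (1 − e^{−γ})/γ — the background-selection (Ne-heuristic) kernel
    "ne": Kernel(
        "ne",
        _k_ne,
        exp_pos=lambda m: _log1p(m) / m,
        exp_neg=lambda m: -math.log1p(-m) / m,  # = E[(e^u−1)/u], m<1 only
        grows_pos=False,
        grows_neg=True,
        fe=_k_ne,  # (1−e^{−u})/u = K(−u)·e^{−u} on the growing (−) side
    ),
    # γ — mean scaled effect (diagnostics, small-γ limits)
    "gamma": Kernel(
        "gamma",
        lambda g: np.asarray(g, dtype=float),
        exp_pos=lambda m: m,
        exp_neg=lambda m: -m,
        grows_pos=False,
        grows_neg=False,
    ),
}


# ---------------------------------------------------------------------------
# The integral engine
# ---------------------------------------------------------------------------


def _component_integral(
    kernel: Kernel,
    kind: str,
    sign: int,
    mean: float,
    shape: float | None,
    method: str,
) -> float:
    """∫ K(sign·|γ|) dρ for one normalized single-sided component."""
    grows = kernel.grows_pos if sign > 0 else kernel.grows_neg
    scale = mean if kind != "gamma" else mean / shape
    if grows and kind in ("exponential", "gamma") and scale >= 1.0:
        raise DivergentIntegralError(
            f"kernel {kernel.name!r} diverges against {kind} tail with "
            f"scale {scale:.6g} >= 1 on the {'+' if sign > 0 else '-'} side"
        )
    if kind == "delta":
        return float(kernel.f(sign * mean))
    if kind == "exponential" and method == "closed":
        return kernel.exp_pos(mean) if sign > 0 else kernel.exp_neg(mean)
    # quadrature over the magnitude u ∈ (0, ∞) of a gamma(shape, theta) weight
    if kind == "exponential":
        shape = 1.0
    theta = mean / shape
    lognorm = shape * math.log(theta) + math.lgamma(shape)

    if grows and kernel.fe is not None:
        # K(sign·u)·w(u) = [K e^{−u}](u) · exp(logw(u) + u); the bracketed
        # factor is bounded, and the exponent decays since theta < 1 here
        def integrand(u):
            u = np.asarray(u, dtype=float)
            logw = (shape - 1.0) * np.log(u) - u * (1.0 / theta - 1.0) - lognorm
            return kernel.fe(u) * np.exp(logw)

    else:

        def integrand(u):
            u = np.asarray(u, dtype=float)
            logw = (shape - 1.0) * np.log(u) - u / theta - lognorm
            return kernel.f(sign * u) * np.exp(logw)

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=1e-300, epsrel=1e-11, limit=400
    )
    return float(val)


def dfe_integral(
    dfe: "DFESpec | ScaledDFE",
    kernel: "str | Kernel | Callable[[np.ndarray], np.ndarray]",
    Tc: float | None = None,
    method: str = "auto",
) -> float:
    """Weighted integral ∫ ρ̃(γ) K(γ) dγ of a (scaled) DFE against a kernel.

    Parameters
    ----------
    dfe:
        A :class:`ScaledDFE`, or a :class:`DFESpec` together with ``Tc`` (in
        which case it is scaled by γ = Tc·s first).
    kernel:
        A name from :data:`KERNELS`, a :class:`Kernel`, or a bare callable
        K(γ) (custom kernels always integrate by quadrature, assumed
        convergent).
    method:
        ``auto`` (closed forms where available), ``closed`` (closed forms
        only; error otherwise) or ``quad`` (force adaptive quadrature — the
        independent cross-check path).

    Raises
    ------
    DivergentIntegralError
        If a growing kernel meets an exponential/gamma tail with scale ≥ 1.
    """
    if isinstance(dfe, DFESpec):
        if Tc is None:
            raise ValueError("a DFESpec requires Tc to form scaled effects")
        dfe = scale_dfe(dfe, Tc)
    if isinstance(kernel, str):
        kernel = KERNELS[kernel]
    elif not isinstance(kernel, Kernel):
        kernel = Kernel("custom", kernel, exp_pos=None, exp_neg=None)

    if dfe.family == "tabulated":
        gs = np.array([g for g, _ in dfe.table])
        ws = np.array([w for _, w in dfe.table])
        return float(np.sum(ws * kernel.f(gs)))

    kind = {
        "two_effect": "delta",
        "exponential_pair": "exponential",
        "gamma_pair": "gamma",
    }[dfe.family]
    comp_method = method
    if method == "auto":
        comp_method = "closed" if (kind != "gamma" and kernel.exp_pos) else "quad"
    elif method == "closed":
        if kind == "gamma" or kernel.exp_pos is None:
            raise ValueError(
                f"no closed form for {dfe.family} against kernel {kernel.name!r}"
            )
    wb = dfe.weight_beneficial
    wd = dfe.weight_deleterious
    total = 0.0
    if wb > 0:
        total += wb * _component_integral(
            kernel, kind, +1, dfe.gamma_b, dfe.shape_b, comp_method
        )
    if wd > 0:
        total += wd * _component_integral(
            kernel, kind, -1, dfe.gamma_d, dfe.shape_d, comp_method
        )
    return total


def with_eta(dfe, eta: float):
    """Copy of a parametric DFE with the beneficial fraction replaced."""
    if dfe.family == "tabulated":
        raise ValueError("eta is not a free parameter of a tabulated DFE")
    return replace(dfe, eta=eta)


def deleterious_magnitudes(dfe):
    """The deleterious component as a positive-side distribution over |s|.

    Used by the background-selection coalescence estimate, whose integral
    runs over deleterious effect magnitudes.  Returned with the same type
    (DFESpec or ScaledDFE) as the input; ``eta = inf`` puts all weight on the
    positive side.
    """
    if dfe.family == "tabulated":
        atoms = tuple((-s, w) for s, w in dfe.table if s < 0)
        if not atoms:
            raise ValueError("DFE has no deleterious component")
        return type(dfe)(family="tabulated", table=atoms)
    kwargs = dict(
        family=dfe.family,
        eta=math.inf,
        shape_b=dfe.shape_d,
        shape_d=dfe.shape_d,
    )
    if isinstance(dfe, DFESpec):
        return DFESpec(sb=dfe.sd, sd=dfe.sd, **kwargs)
    return ScaledDFE(gamma_b=dfe.gamma_d, gamma_d=dfe.gamma_d, **kwargs)
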