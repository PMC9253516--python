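"""Single-site (1:1) binding isotherm simulation, fitting and thermodynamics.

Implements the standard isothermal titration calorimetry (ITC) forward model
for a perfusion (overfill) cell: serial injections of a titrant X into an
analyte M displace liquid from the active cell volume, and the measured heat
of each injection is the change in total binding enthalpy of the cell
contents, corrected for the displaced volume.  The bound concentration at
each point follows the single-site quadratic, and fitted parameters are the
stoichiometry N, dissociation constant K_D, molar enthalpy dH and a constant
heat-of-dilution offset.

Units convention: volumes in microlitres, concentrations in micromolar at the
interface; internally moles/litres.  Heats are kcal per mole of injectant.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TitrationScheme",
    "BindingParameters",
    "Isotherm",
    "FitResult",
    "simulate_isotherm",
    "fit_isotherm",
    "thermo_decompose",
    "c_value",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "read_scheme_yaml",
    "write_scheme_yaml",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3


def _default_injections() -> list[float]:
    # Small priming injection followed by 15 full injections, the scheme
    # used throughout the MicroCal Auto-iTC200 runs this package models.
    return [0.5] + [2.5] * 15


@dataclass
class TitrationScheme:
    """One ITC run: cell/syringe concentrations and the injection series."""

    cell_volume_ul: float = 200.0
    syringe_conc_uM: float = 50.0
    cell_conc_uM: float = 5.0
    injection_volumes_ul: list[float] = field(default_factory=_default_injections)
    spacing_s: float = 180.0
    temperature_C: float = 20.0
    exclude_first: bool = True

    def validate(self) -> None:
        if self.cell_volume_ul <= 0:
            raise ValueError("cell_volume_ul must be positive")
        if self.syringe_conc_uM <= 0 or self.cell_conc_uM <= 0:
            raise ValueError("concentrations must be positive")
        vols = np.asarray(self.injection_volumes_ul, dtype=float)
        if vols.size == 0 or np.any(vols <= 0):
            raise ValueError("injection volumes must be positive and nonempty")
        if vols.sum() >= self.cell_volume_ul:
            raise ValueError(
                f"cumulative injected volume {vols.sum():g} ul must stay below "
                f"the cell volume {self.cell_volume_ul:g} ul"
            )

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15


@dataclass
class BindingParameters:
    """Thermodynamic parameters of the 1:1 binding model."""

    N: float = 1.0
    KD_M: float = 1e-7
    dH_kcal_mol: float = -6.0
    dilution_offset_kcal_mol: float = 0.0

    def validate(self) -> None:
        if self.KD_M <= 0:
            raise ValueError("KD_M must be positive")
        if self.N <= 0:
            raise ValueError("stoichiometry N must be positive")


@dataclass
class Isotherm:
    """Per-injection normalized heats against the cell molar ratio."""

    molar_ratio: np.ndarray
    q_per_mol: np.ndarray
    included: np.ndarray

    def __post_init__(self) -> None:
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.q_per_mol = np.asarray(self.q_per_mol, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        if not (len(self.molar_ratio) == len(self.q_per_mol) == len(self.included)):
            raise ValueError("isotherm columns must have equal length")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")

    def __len__(self) -> int:
        return len(self.molar_ratio)


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and the free-energy split."""

    params: BindingParameters
    se: dict
    dG_kcal_mol: float
    minus_TdS_kcal_mol: float
    rss: float
    converged: bool
    warnings: list = field(default_factory=list)

    @property
    def KD_nM(self) -> float:
        return self.params.KD_M * 1e9


def _injection_heats(
    scheme: TitrationScheme, params: BindingParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward model: per-injection heats for a perfusion-cell titration.

    Returns (molar_ratio, dq_kcal, moles_injected) per injection.  After
    injection i with cumulative volume V_i into active volume V0 the total
    concentrations are the displacement-corrected

        M_i = M0 (1 - V_i/2V0) / (1 + V_i/2V0)
        X_i = X_syr (V_i/V0) / (1 + V_i/2V0)

    the bound concentration is the single-site quadratic root, the cell heat
    content is Q_i = [MX]_i dH V0, and the measured injection heat corrects
    for the complex carried out in the displaced plug:

        dQ_i = Q_i - Q_{i-1} + (v_i/V0) (Q_i + Q_{i-1}) / 2
    """
    scheme.validate()
    params.validate()
    v = np.asarray(scheme.injection_volumes_ul, dtype=float) * 1e-6  # L
    V0 = scheme.cell_volume_ul * 1e-6
    M0 = scheme.cell_conc_uM * 1e-6
    Xs = scheme.syringe_conc_uM * 1e-6
    Vcum = np.cumsum(v)

    M = M0 * (1.0 - Vcum / (2.0 * V0)) / (1.0 + Vcum / (2.0 * V0))
    X = Xs * (Vcum / V0) / (1.0 + Vcum / (2.0 * V0))

    b = params.N * M + X + params.KD_M
    disc = b * b - 4.0 * params.N * M * X
    mx = 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))

    Q = mx * params.dH_kcal_mol * V0  # kcal
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dq = Q - Qprev + (v / V0) * (Q + Qprev) / 2.0

    moles = Xs * v
    return X / M, dq, moles


def simulate_isotherm(
    scheme: TitrationScheme,
    params: BindingParameters,
    noise_sd_kcal_mol: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    """Simulate a normalized 1:1 binding isotherm for a titration scheme.

    Heats are kcal per mole of injectant; the dilution offset is added to
    every injection and Gaussian noise of the given SD on top.  With
    ``scheme.exclude_first`` the first (priming) injection is marked excluded
    but still simulated.
    """
    ratio, dq, moles = _injection_heats(scheme, params)
    q = dq / moles + params.dilution_offset_kcal_mol
    if noise_sd_kcal_mol:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd_kcal_mol, size=q.shape)
    included = np.ones(len(q), dtype=bool)
    if scheme.exclude_first:
        included[0] = False
    return Isotherm(molar_ratio=ratio, q_per_mol=q, included=included)


def c_value(scheme: TitrationScheme, KD_M: float, N: float = 1.0) -> float:
    """Wiseman c parameter, N*[cell]/K_D; governs sigmoid sharpness."""
    if KD_M <= 0 or scheme.cell_conc_uM <= 0:
        raise ValueError("inputs must be positive")
    return N * scheme.cell_conc_uM * 1e-6 / KD_M


def thermo_decompose(
    KD_M: float, dH_kcal_mol: float, temperature_C: float
) -> tuple[float, float]:
    """Split binding free energy: dG = RT ln K_D, -TdS = dG - dH (kcal/mol)."""
    if KD_M <= 0:
        raise ValueError("KD_M must be positive")
    T = temperature_C + 273.15
    dG = R_KCAL * T * math.log(KD_M)
    return dG, dG - dH_kcal_mol


def _residuals(p: lmfit.Parameters, scheme: TitrationScheme, iso: Isotherm) -> np.ndarray:
    params = BindingParameters(
        N=p["n"].value,
        KD_M=10.0 ** p["log10_kd"].value,
        dH_kcal_mol=p["dh"].value,
        dilution_offset_kcal_mol=p["offset"].value,
    )
    _, dq, moles = _injection_heats(scheme, params)
    model = dq / moles + params.dilution_offset_kcal_mol
    return (model - iso.q_per_mol)[iso.included]


def fit_isotherm(
    iso: Isotherm,
    scheme: TitrationScheme,
    init: BindingParameters | None = None,
) -> FitResult:
    """Least-squares fit of the 1:1 model to a normalized isotherm.

    Minimizes over (N, log10 K_D, dH, dilution offset) with
    Levenberg-Marquardt, multi-started from a coarse log-spaced K_D grid
    (1e-11 to 1e-4 M) to avoid local minima; deterministic and seed-free.
    The first injection is excluded via the isotherm's ``included`` mask.
    Reports asymptotic standard errors; ``converged`` is False for
    featureless (flat) data, and a c-value outside [1, 1000] is recorded
    as a warning rather than an error.
    """
    if int(iso.included.sum()) < 5:
        raise ValueError("need at least 5 included injections to fit")

    q = iso.q_per_mol[iso.included]
    span = float(np.max(q) - np.min(q))
    warnings: list[str] = []
    if span <= 1e-12 or not np.isfinite(span):
        params = BindingParameters(
            N=1.0, KD_M=1e-7, dH_kcal_mol=0.0,
            dilution_offset_kcal_mol=float(np.mean(q)) if np.isfinite(q).all() else 0.0,
        )
        dG, mTdS = thermo_decompose(params.KD_M, params.dH_kcal_mol, scheme.temperature_C)
        return FitResult(
            params=params, se={}, dG_kcal_mol=dG, minus_TdS_kcal_mol=mTdS,
            rss=float(np.sum((q - np.mean(q)) ** 2)), converged=False,
            warnings=["flat isotherm: no detectable binding transition"],
        )

    # Initial guesses from the curve shape: the early plateau approximates
    # dH + offset, the late plateau the offset alone.
    dh0 = float(q[0] - q[-1]) if init is None else init.dH_kcal_mol
    off0 = float(q[-1]) if init is None else init.dilution_offset_kcal_mol
    n0 = 1.0 if init is None else init.N

    kd_starts = (
        [init.KD_M]
        if init is not None
        else list(np.logspace(-11, -4, 8))
    )

    best = None
    for kd0 in kd_starts:
        p = lmfit.Parameters()
        p.add("n", value=n0, min=1e-3, max=1e3)
        p.add("log10_kd", value=math.log10(kd0), min=-13.0, max=-1.0)
        p.add("dh", value=dh0 if abs(dh0) > 1e-9 else -1.0)
        p.add("offset", value=off0)
        try:
            res = lmfit.minimize(
                _residuals, p, args=(scheme, iso), method="leastsq",
                nan_policy="raise",
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    bp = best.params
    kd = 10.0 ** bp["log10_kd"].value
    params = BindingParameters(
        N=float(bp["n"].value),
        KD_M=float(kd),
        dH_kcal_mol=float(bp["dh"].value),
        dilution_offset_kcal_mol=float(bp["offset"].value),
    )
    se: dict[str, float] = {}
    if bp["log10_kd"].stderr is not None:
        se["KD_M"] = float(kd * math.log(10.0) * bp["log10_kd"].stderr)
    for name, key in [("n", "N"), ("dh", "dH_kcal_mol"), ("offset", "dilution_offset_kcal_mol")]:
        if bp[name].stderr is not None:
            se[key] = float(bp[name].stderr)

    cv = c_value(scheme, params.KD_M, params.N)
    if not (1.0 <= cv <= 1000.0):
        warnings.append(
            f"c-value {cv:.3g} outside [1, 1000]: K_D poorly constrained by this scheme"
        )

    converged = bool(best.success)
    # A fitted transition much smaller than the residual scatter means the
    # optimizer settled on noise, not a binding signature.
    resid_rms = math.sqrt(best.chisqr / max(best.ndata, 1))
    if abs(params.dH_kcal_mol) < 3.0 * resid_rms:
        converged = False
        warnings.append("fitted enthalpy indistinguishable from residual noise")

    dG, mTdS = thermo_decompose(params.KD_M, params.dH_kcal_mol, scheme.temperature_C)
    return FitResult(
        params=params,
        se=se,
        dG_kcal_mol=dG,
        minus_TdS_kcal_mol=mTdS,
        rss=float(best.chisqr),
        converged=converged,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# File formats


def write_isotherm_csv(iso: Isotherm, scheme: TitrationScheme, path) -> None:
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, len(iso) + 1),
            "volume_ul": np.asarray(scheme.injection_volumes_ul, dtype=float),
            "molar_ratio": iso.molar_ratio,
            "q_per_mol_kcal": iso.q_per_mol,
            "included": iso.included.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_isotherm_csv(path) -> Isotherm:
    df = pd.read_csv(path)
    return Isotherm(
        molar_ratio=df["molar_ratio"].to_numpy(),
        q_per_mol=df["q_per_mol_kcal"].to_numpy(),
        included=df["included"].to_numpy().astype(bool),
    )


def write_scheme_yaml(scheme: TitrationScheme, path) -> None:
    data = {
        "cell_volume_ul": scheme.cell_volume_ul,
        "syringe_conc_uM": scheme.syringe_conc_uM,
        "cell_conc_uM": scheme.cell_conc_uM,
        "injection_volumes_ul": list(map(float, scheme.injection_volumes_ul)),
        "spacing_s": scheme.spacing_s,
        "temperature_C": scheme.temperature_C,
        "exclude_first": scheme.exclude_first,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_scheme_yaml(path) -> TitrationScheme:
    if isinstance(path, io.IOBase):
        data = yaml.safe_load(path)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    scheme = TitrationScheme(**data)
    scheme.validate()
    return scheme
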