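"""Single-site binding isotherms (ITC) and thermal-melt fitting (TSA).

ITC model
---------
A titration injects ligand X (syringe) into macromolecule M (cell,
constant volume ``V0``; each injection displaces an equal volume of
mixed cell content).  With site concentration ``n*[M]`` and
dissociation constant ``K_D``, the bound-complex concentration after
each injection is the root of the single-site mass-action quadratic

    [MX] = ((S + X + K_D) - sqrt((S + X + K_D)^2 - 4 S X)) / 2,

with S = n*[M].  The heat of injection i is

    q_i = V0 * dH * ([MX]_i - [MX]_{i-1} * (1 - dV_i/V0)) + baseline

in microcalories (dH in cal/mol), the ``(1 - dV/V0)`` factor being the
complex displaced out of the cell by the injection.  Identifiability is
governed by the Wiseman c-value ``c = n*[M]/K_D``; fits at c outside
[0.1, 1000] are flagged low-confidence.

TSA model
---------
Melt curves are fitted with a Boltzmann sigmoid
``S(T) = low + (high - low) / (1 + exp((Tm - T)/k))``; a
derivative-maximum Tm estimator is provided as a model-free
cross-check, and ``delta_tm`` reports the shift against a reference
(apo) fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

R_CAL = 1.9872042586  # gas constant, cal/(mol K)


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument protocol: volumes in litres, concentrations in mol/L."""

    cell_volume: float = 1400e-6
    cell_conc: float = 0.05e-3
    syringe_conc: float = 1e-3
    injection_volume: float = 5e-6
    syringe_volume: float = 300e-6

    def __post_init__(self) -> None:
        for name in ("cell_volume", "cell_conc", "syringe_conc",
                     "injection_volume", "syringe_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def max_injections(self) -> int:
        return int(self.syringe_volume / self.injection_volume + 1e-9)

    def injection_volumes(self, n_injections: int | None = None) -> np.ndarray:
        n = self.max_injections if n_injections is None else n_injections
        if n < 1 or n > self.max_injections:
            raise ValueError(f"n_injections must be in [1, {self.max_injections}]")
        return np.full(n, self.injection_volume)


#: the two protocols used for the UBR-box peptide titrations
STANDARD_PROTOCOL = TitrationProtocol()
HIGH_CONC_PROTOCOL = TitrationProtocol(cell_conc=0.225e-3, syringe_conc=4.5e-3)


@dataclass
class TitrationSeries:
    cell_volume: float           # L
    cell_conc: float             # mol/L (macromolecule)
    syringe_conc: float          # mol/L (ligand)
    injection_volumes: np.ndarray  # L
    heats: np.ndarray            # microcal per injection

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, float)
        self.heats = np.asarray(self.heats, float)
        if min(self.cell_volume, self.cell_conc, self.syringe_conc) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")
        if len(self.injection_volumes) != len(self.heats):
            raise ValueError("injection_volumes and heats differ in length")
        if not np.all(np.isfinite(self.heats)):
            raise ValueError("heats must be finite")

    @property
    def n_injections(self) -> int:
        return len(self.heats)


def _complex_conc(sites: np.ndarray, ligand: np.ndarray, kd: float) -> np.ndarray:
    b = sites + ligand + kd
    disc = np.maximum(b * b - 4.0 * sites * ligand, 0.0)
    return 0.5 * (b - np.sqrt(disc))


def titration_concentrations(protocol_or_series, injection_volumes=None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-injection total macromolecule and ligand concentrations in the
    cell under the constant-volume displacement model."""
    p = protocol_or_series
    dv = np.asarray(p.injection_volumes if injection_volumes is None
                    else injection_volumes, float)
    v0 = p.cell_volume
    m = np.empty(len(dv))
    x = np.empty(len(dv))
    mc, xc = p.cell_conc, 0.0
    for i, d in enumerate(dv):
        f = d / v0
        mc *= (1.0 - f)
        xc = xc * (1.0 - f) + p.syringe_conc * f
        m[i], x[i] = mc, xc
    return m, x


def itc_heats(n: float, kd: float, dh: float, baseline: float,
              series: TitrationSeries) -> np.ndarray:
    """Model heats (microcal per injection) for the series' protocol."""
    if kd <= 0 or n <= 0:
        raise ValueError("K_D and stoichiometry n must be positive")
    m, x = titration_concentrations(series)
    bound = _complex_conc(n * m, x, kd)
    f = series.injection_volumes / series.cell_volume
    prev = np.concatenate([[0.0], bound[:-1]])
    dq = bound - prev * (1.0 - f)
    return series.cell_volume * dh * dq * 1e6 + baseline


@dataclass
class ITCFit:
    n: float
    kd: float                    # mol/L
    dh: float                    # cal/mol
    baseline: float              # microcal
    stderr: dict[str, float | None] = field(default_factory=dict)
    converged: bool = True
    identifiable: bool = True
    low_confidence: bool = False
    c_value: float = math.nan
    rss: float = math.nan

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6

    def delta_g(self, temperature_c: float = 25.0) -> float:
        """Binding free energy RT*ln(K_D), cal/mol (negative = favourable)."""
        return R_CAL * (temperature_c + 273.15) * math.log(self.kd)


def fit_itc(series: TitrationSeries, init: dict | None = None,
            fix_n: float | None = None, exclude_first: bool = True) -> ITCFit:
    """Nonlinear least-squares fit of the single-site model.

    Levenberg–Marquardt over (n, log10 K_D, dH, baseline), multi-started
    across K_D decades 1e-7..1e-2 M with the lowest residual sum kept.
    The first injection is excluded by default (partial-fill artefact in
    practice).  Requires at least 8 injections.  Degenerate (flat)
    series return a fit flagged ``identifiable=False`` rather than an
    exception; non-convergence is flagged, never silent.
    """
    if series.n_injections < 8:
        raise ValueError("need at least 8 injections to fit the isotherm")
    heats = series.heats
    mask = np.ones(len(heats), dtype=bool)
    if exclude_first:
        mask[0] = False

    scale = float(np.max(np.abs(heats[mask] - np.median(heats[mask]))))
    if scale < 1e-9:
        return ITCFit(n=fix_n or 1.0, kd=math.nan, dh=0.0,
                      baseline=float(np.mean(heats[mask])),
                      converged=True, identifiable=False)

    init = init or {}

    def residual(params: lmfit.Parameters) -> np.ndarray:
        model = itc_heats(params["n"].value, 10.0 ** params["log10_kd"].value,
                          params["dh"].value, params["baseline"].value, series)
        return model[mask] - heats[mask]

    dh0 = init.get("dh", float(np.sum(heats[mask])) /
                   (series.cell_volume * series.cell_conc * 1e6))
    best = None
    starts = [init["kd"]] if "kd" in init else [10.0 ** e for e in range(-7, -1)]
    for kd0 in starts:
        params = lmfit.Parameters()
        if fix_n is not None:
            params.add("n", value=fix_n, vary=False)
        else:
            params.add("n", value=init.get("n", 1.0), min=0.05, max=10.0)
        params.add("log10_kd", value=math.log10(kd0), min=-9.0, max=0.0)
        params.add("dh", value=dh0 if dh0 != 0 else -1000.0)
        params.add("baseline", value=init.get("baseline", 0.0))
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return ITCFit(n=fix_n or 1.0, kd=math.nan, dh=0.0, baseline=0.0,
                      converged=False, identifiable=False)

    p = best.params
    kd = 10.0 ** p["log10_kd"].value
    ln10 = math.log(10.0)
    kd_err = (p["log10_kd"].stderr * ln10 * kd
              if p["log10_kd"].stderr is not None else None)
    c = p["n"].value * series.cell_conc / kd
    identifiable = kd_err is not None and kd_err < kd
    return ITCFit(
        n=float(p["n"].value), kd=float(kd), dh=float(p["dh"].value),
        baseline=float(p["baseline"].value),
        stderr={"n": p["n"].stderr, "kd": kd_err, "dh": p["dh"].stderr,
                "baseline": p["baseline"].stderr},
        converged=bool(best.success), identifiable=identifiable,
        low_confidence=not (0.1 <= c <= 1000.0), c_value=float(c),
        rss=float(best.chisqr))


# ---------------------------------------------------------------------------
# thermal shift


@dataclass
class MeltCurve:
    temperatures: np.ndarray  # degrees C, strictly increasing
    signal: np.ndarray        # arbitrary fluorescence units

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.signal = np.asarray(self.signal, float)
        if len(self.temperatures) != len(self.signal):
            raise ValueError("temperature and signal lengths differ")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    tm: float        # degrees C
    lower: float
    upper: float
    slope: float     # degrees C
    stderr: dict[str, float | None] = field(default_factory=dict)
    rss: float = math.nan


def boltzmann(t: np.ndarray, tm: float, lower: float, upper: float,
              slope: float) -> np.ndarray:
    return lower + (upper - lower) / (1.0 + np.exp((tm - t) / slope))


def tm_derivative(curve: MeltCurve, window: int = 5) -> float:
    """Model-free Tm: temperature of the maximum first derivative of the
    (lightly smoothed) signal."""
    sig = curve.signal
    edge = 0
    if window > 1 and len(sig) > 3 * window:
        kernel = np.ones(window) / window
        sig = np.convolve(sig, kernel, mode="same")
        edge = window  # moving-average ramp at the ends is not a transition
    grad = np.gradient(sig, curve.temperatures)
    interior = slice(edge, len(grad) - edge if edge else None)
    idx = int(np.argmax(grad[interior])) + edge
    return float(curve.temperatures[idx])


def fit_melt(curve: MeltCurve) -> MeltFit:
    """Boltzmann sigmoid fit; raises ``ValueError`` if the data show no
    transition inside the scanned range."""
    t, s = curve.temperatures, curve.signal
    if len(t) < 8:
        raise ValueError("need at least 8 points to fit a melt curve")
    amplitude = float(np.max(s) - np.min(s))
    if amplitude < 1e-12 or amplitude < 3.0 * float(np.std(np.diff(s))):
        raise ValueError("no melt transition detected in the scanned range")

    params = lmfit.Parameters()
    params.add("tm", value=tm_derivative(curve), min=t[0], max=t[-1])
    params.add("lower", value=float(np.min(s)))
    params.add("upper", value=float(np.max(s)))
    params.add("slope", value=max((t[-1] - t[0]) / 50.0, 0.1), min=1e-3)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return boltzmann(t, p["tm"].value, p["lower"].value,
                         p["upper"].value, p["slope"].value) - s

    res = lmfit.minimize(residual, params, method="leastsq")
    p = res.params
    tm = float(p["tm"].value)
    if not t[0] <= tm <= t[-1]:
        raise ValueError("fitted Tm outside the scanned temperature range")
    return MeltFit(tm=tm, lower=float(p["lower"].value),
                   upper=float(p["upper"].value), slope=float(p["slope"].value),
                   stderr={k: p[k].stderr for k in ("tm", "lower", "upper", "slope")},
                   rss=float(res.chisqr))


def delta_tm(fit: MeltFit, reference: MeltFit) -> float:
    """Melting-temperature shift of ``fit`` relative to ``reference`` (deg C)."""
    return fit.tm - reference.tm
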