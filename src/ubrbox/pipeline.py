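"""End-to-end structure profiling and thermogram fitting.

``profile_structure`` chains parse -> (optional) symmetry expansion ->
ring detection -> pi-pi / cation-pi contacts -> metal sites -> hydrogen
bonds -> pocket waters into a single JSON-serializable report that
records every threshold used, so a profile is reproducible from the
report alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import find_hbonds, find_metal_sites, waters_near
from .geometry import (PiCationCriteria, PiPiThresholds, find_pi_cation_contacts,
                       find_pi_pi_contacts, structure_rings)
from .model import StructureModel
from .structure_io import parse_structure, expand_symmetry
from .thermo import (MeltCurve, TitrationProtocol, TitrationSeries, delta_tm,
                     fit_itc, fit_melt, tm_derivative)


@dataclass(frozen=True)
class ProfileConfig:
    """Every tunable threshold of the profiling pipeline."""

    expand: bool = False
    symmetry_radius: float = 5.0
    pi_pi: PiPiThresholds = PiPiThresholds()
    pi_cation: PiCationCriteria = PiCationCriteria()
    metal_cutoff: float = 3.0
    hbond_cutoff: float = 3.5
    water_cutoff: float = 4.0
    water_anchor_chain: str | None = None
    water_anchor_residue: int | None = None

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


@dataclass
class ProfileReport:
    structure_id: str
    rings: list[dict] = field(default_factory=list)
    pi_pi: list[dict] = field(default_factory=list)
    pi_cation: list[dict] = field(default_factory=list)
    metal_sites: list[dict] = field(default_factory=list)
    hbonds: list[dict] = field(default_factory=list)
    pocket_waters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    def contacts_tsv(self) -> str:
        """pi-pi contact table as TSV (one row per contact)."""
        if not self.pi_pi:
            return "ring_a\tring_b\tr_cen\tgamma\tconformation\tintermolecular\tsymmetry_op\n"
        return pd.DataFrame(self.pi_pi).to_csv(sep="\t", index=False)


def profile_structure(source: str | Path | StructureModel,
                      config: ProfileConfig = ProfileConfig()) -> ProfileReport:
    """Run the full structural profile; stage failures are collected in
    ``report.errors`` (parse failures raise)."""
    if isinstance(source, StructureModel):
        model = source
    else:
        model = parse_structure(source)
    report = ProfileReport(structure_id=model.id, provenance=config.provenance())

    work = model
    if config.expand:
        try:
            work = expand_symmetry(model, config.symmetry_radius)
        except ValueError as exc:
            report.errors.append(f"symmetry expansion: {exc}")

    try:
        rings = structure_rings(work)
        report.rings = [{
            "residue": r.tag, "ring": r.ring_label,
            "planarity_rms": round(r.planarity_rms, 4)} for r in rings]
        report.pi_pi = [c.row() for c in find_pi_pi_contacts(work, thresholds=config.pi_pi)]
        report.pi_cation = [c.row() for c in
                            find_pi_cation_contacts(work, criteria=config.pi_cation)]
    except Exception as exc:  # pragma: no cover - defensive
        report.errors.append(f"pi-interaction analysis: {exc}")

    try:
        sites = find_metal_sites(work, cutoff=config.metal_cutoff)
        report.metal_sites = [{
            "metal": f"{s.metal.chain_id}/{s.metal.residue_name}{s.metal.residue_number}",
            "element": s.metal.element,
            "pattern": s.pattern,
            "n_donors": len(s.donors),
            "donors": [f"{a.chain_id}/{a.residue_name}{a.residue_number}/{a.name}"
                       f"@{d:.2f}" for a, d in s.donors],
        } for s in sites]
    except Exception as exc:  # pragma: no cover
        report.errors.append(f"metal sites: {exc}")

    try:
        protein = lambda a: not a.het and not a.is_water  # noqa: E731
        hetero = lambda a: a.het and not a.is_water and a.element.upper() not in {"ZN"}  # noqa: E731
        report.hbonds = [h.row() for h in
                         find_hbonds(work, protein, hetero, config.hbond_cutoff)]
    except Exception as exc:  # pragma: no cover
        report.errors.append(f"hydrogen bonds: {exc}")

    try:
        if config.water_anchor_residue is not None:
            anchor = lambda a: (a.residue_number == config.water_anchor_residue  # noqa: E731
                                and (config.water_anchor_chain is None
                                     or a.chain_id == config.water_anchor_chain)
                                and not a.is_water)
        else:
            anchor = lambda a: not a.het and not a.is_water  # noqa: E731
        count, hits = waters_near(work, anchor, config.water_cutoff)
        report.pocket_waters = {
            "count": count,
            "waters": [f"{w.chain_id}/HOH{w.residue_number}" for w in hits],
        }
    except Exception as exc:  # pragma: no cover
        report.errors.append(f"water census: {exc}")

    return report


# ---------------------------------------------------------------------------
# thermogram CSV ingestion + fitting


def read_itc_csv(path: str | Path, protocol: TitrationProtocol) -> TitrationSeries:
    """Read an (injection, heat) CSV; requires a ``heat_ucal`` column."""
    df = pd.read_csv(path)
    if "heat_ucal" not in df.columns:
        raise ValueError(f"{path}: expected a 'heat_ucal' column, "
                         f"found {list(df.columns)}")
    heats = df["heat_ucal"].to_numpy(float)
    return TitrationSeries(
        cell_volume=protocol.cell_volume, cell_conc=protocol.cell_conc,
        syringe_conc=protocol.syringe_conc,
        injection_volumes=protocol.injection_volumes(len(heats)),
        heats=heats)


def write_itc_csv(series: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame({"injection": np.arange(1, series.n_injections + 1),
                  "heat_ucal": series.heats}).to_csv(path, index=False)


def read_melt_csv(path: str | Path) -> MeltCurve:
    """Read a (temperature_c, signal) CSV."""
    df = pd.read_csv(path)
    for col in ("temperature_c", "signal"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected a {col!r} column, "
                             f"found {list(df.columns)}")
    return MeltCurve(df["temperature_c"].to_numpy(float),
                     df["signal"].to_numpy(float))


def write_melt_csv(curve: MeltCurve, path: str | Path) -> None:
    pd.DataFrame({"temperature_c": curve.temperatures,
                  "signal": curve.signal}).to_csv(path, index=False)


def fit_thermo(path: str | Path, mode: str,
               protocol: TitrationProtocol | None = None,
               reference: str | Path | None = None) -> dict:
    """Fit one thermogram CSV; returns a JSON-ready report dict.

    ``mode`` is ``"itc"`` (requires ``protocol``) or ``"tsa"``
    (``reference`` optionally names a second melt CSV for delta-Tm).
    """
    if mode == "itc":
        if protocol is None:
            protocol = TitrationProtocol()
        series = read_itc_csv(path, protocol)
        fit = fit_itc(series)
        return {
            "mode": "itc", "source": str(path),
            "n": fit.n, "kd_M": fit.kd, "kd_uM": fit.kd_uM,
            "dh_cal_per_mol": fit.dh, "baseline_ucal": fit.baseline,
            "stderr": fit.stderr, "c_value": fit.c_value,
            "converged": fit.converged, "identifiable": fit.identifiable,
            "low_confidence": fit.low_confidence, "rss": fit.rss,
            "protocol": dataclasses.asdict(protocol),
        }
    if mode == "tsa":
        curve = read_melt_csv(path)
        fit = fit_melt(curve)
        out = {
            "mode": "tsa", "source": str(path),
            "tm_c": fit.tm, "lower": fit.lower, "upper": fit.upper,
            "slope_c": fit.slope, "stderr": fit.stderr, "rss": fit.rss,
            "tm_derivative_c": tm_derivative(curve),
        }
        if reference is not None:
            ref_fit = fit_melt(read_melt_csv(reference))
            out["reference_tm_c"] = ref_fit.tm
            out["delta_tm_c"] = delta_tm(fit, ref_fit)
        return out
    raise ValueError(f"unknown mode {mode!r}: expected 'itc' or 'tsa'")
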