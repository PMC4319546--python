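"""Scan orchestration: site selection, per-residue mutation, rescoring,
ΔΔG ranking, hotspot calls and report files.

The per-residue statistic is ΔΔG = E_mut − E_wt on the intermolecular
interaction score, so a residue whose contacts stabilize the complex
(negative contribution to E_wt) yields a positive ΔΔG when truncated;
residues at or above the hotspot threshold (default 0.5) are nominated as
loss-of-function mutation candidates.
"""

from __future__ import annotations

import json
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .model import LigandModel, LigandSelector, Structure, format_rid
from .mutate import MutationSkipped, minimize_local, model_quality, mutate_to_alanine
from .pdbio import write_pdb
from .prep import prepare_ligand, prepare_receptor
from .scoring import EnergyBreakdown, interaction_energy
from .site import DEFAULT_CUTOFF, BindingSite, resolve_ligand, select_binding_site
from .params import DEFAULT_SCORING, ScoringParams

__all__ = ["ScanConfig", "ScanRecord", "ScanResult", "alanine_scan",
           "classify_hotspots", "site_summary", "write_reports",
           "DEFAULT_HOTSPOT_THRESHOLD"]

DEFAULT_HOTSPOT_THRESHOLD = 0.5  # kcal/mol


@dataclass(frozen=True)
class ScanConfig:
    cutoff: float = DEFAULT_CUTOFF
    threshold: float = DEFAULT_HOTSPOT_THRESHOLD
    minimize: bool = False
    seed: int = 0
    scoring: ScoringParams = DEFAULT_SCORING


@dataclass
class ScanRecord:
    rid: tuple[str, int, str]
    res_name: str
    min_distance: float
    skipped: bool = False
    skip_reason: str = ""
    E_wt: Optional[float] = None
    E_mut: Optional[float] = None
    ddG: Optional[float] = None
    component_deltas: Optional[EnergyBreakdown] = None
    hotspot: bool = False
    quality: Optional[dict] = None

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.rid[1]}{self.rid[2]}:{self.rid[0]}"


@dataclass
class ScanResult:
    records: list[ScanRecord]
    site: BindingSite
    ligand: Optional[LigandSelector]
    E_wt_total: float
    wt_breakdown: EnergyBreakdown
    cutoff: float
    threshold: float
    provenance: dict = field(default_factory=dict)

    def scored(self) -> list[ScanRecord]:
        return [r for r in self.records if not r.skipped]

    def hotspots(self) -> list[ScanRecord]:
        return [r for r in self.scored() if r.hotspot]

    def sort(self) -> None:
        """Ranked order: ΔΔG descending, skipped records last, ties by residue id."""
        self.records.sort(key=lambda r: (r.skipped, -(r.ddG if r.ddG is not None else 0.0), r.rid))


def _log(verbose: bool, msg: str) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def alanine_scan(complex_structure: Structure,
                 ligand: Union[LigandSelector, LigandModel, str],
                 config: ScanConfig = ScanConfig(),
                 verbose: bool = False) -> ScanResult:
    """Run the full scan on a protein-ligand complex.

    ``ligand`` may be a selector (``RESNAME:CHAIN:RESSEQ`` string or
    :class:`LigandSelector`) naming a hetero group to be typed and charged
    natively, or a pre-prepared :class:`LigandModel` (parsed from a ligand
    PDBQT — the escape hatch for bridge waters, metals or unusual types).
    """
    t0 = time.perf_counter()
    if isinstance(ligand, str):
        ligand = LigandSelector.parse(ligand)

    if isinstance(ligand, LigandModel):
        ligand_model = ligand
    else:
        lig_res = resolve_ligand(complex_structure, ligand)
        try:
            ligand_model = prepare_ligand([lig_res], selector=ligand)
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"ligand {ligand} could not be typed/charged natively ({exc}); "
                f"supply a prepared ligand PDBQT instead") from exc
    ligand_model.validate()

    site = select_binding_site(complex_structure, ligand, cutoff=config.cutoff)
    _log(verbose, f"[site] {len(site)} residues within {config.cutoff:.2f} A "
                  f"({time.perf_counter() - t0:.2f}s)")

    raw_receptor = complex_structure.receptor_only()
    t1 = time.perf_counter()
    wt_prepared = prepare_receptor(raw_receptor)
    wt_energy = interaction_energy(wt_prepared, ligand_model, config.scoring)
    _log(verbose, f"[wild-type] E = {wt_energy.total:.3f} kcal/mol "
                  f"({time.perf_counter() - t1:.2f}s)")

    records: list[ScanRecord] = []
    mutants: dict[str, Structure] = {}
    for sres in site.residues:
        rec = ScanRecord(rid=sres.rid, res_name=sres.res_name,
                         min_distance=sres.min_distance)
        t2 = time.perf_counter()
        try:
            mutant = mutate_to_alanine(raw_receptor, sres.rid,
                                       ligand_atoms=ligand_model.atoms)
        except MutationSkipped as skip:
            rec.skipped = True
            rec.skip_reason = skip.reason
            records.append(rec)
            _log(verbose, f"[skip] {rec.label}: {skip.reason}")
            continue
        if config.minimize:
            mutant = minimize_local(mutant, ligand_atoms=ligand_model.atoms,
                                    seed=config.seed)
        mut_prepared = prepare_receptor(mutant.structure)
        mut_energy = interaction_energy(mut_prepared, ligand_model, config.scoring)
        rec.E_wt = wt_energy.total
        rec.E_mut = mut_energy.total
        rec.ddG = mut_energy.total - wt_energy.total
        rec.component_deltas = mut_energy - wt_energy
        rec.quality = model_quality(mutant)
        records.append(rec)
        mutants[rec.label] = mutant.structure
        _log(verbose, f"[mutant] {rec.label}: ddG = {rec.ddG:+.3f} kcal/mol "
                      f"({time.perf_counter() - t2:.2f}s)")

    result = ScanResult(
        records=records, site=site, ligand=ligand_model.selector,
        E_wt_total=wt_energy.total, wt_breakdown=wt_energy,
        cutoff=config.cutoff, threshold=config.threshold,
        provenance={
            "abscan_version": __version__,
            "cutoff": config.cutoff,
            "threshold": config.threshold,
            "minimize": config.minimize,
            "seed": config.seed,
            "ligand": str(ligand_model.selector) if ligand_model.selector else None,
            "ligand_includes_bridge_waters": ligand_model.includes_bridge_waters,
            "n_ligand_atoms": len(ligand_model.atoms),
        })
    result._mutant_structures = mutants  # carried for report writing
    classify_hotspots(result, config.threshold)
    result.sort()
    _log(verbose, f"[scan] done in {time.perf_counter() - t0:.2f}s")
    return result


def classify_hotspots(result: ScanResult,
                      threshold: float = DEFAULT_HOTSPOT_THRESHOLD) -> ScanResult:
    """Flag records with ΔΔG ≥ threshold (boundary inclusive)."""
    result.threshold = threshold
    for rec in result.records:
        rec.hotspot = (not rec.skipped and rec.ddG is not None
                       and rec.ddG >= threshold)
    return result


def site_summary(result: ScanResult) -> dict:
    """Mean ΔΔG over scored residues, hotspot count and fraction."""
    scored = result.scored()
    if not scored:
        return {}
    ddgs = [r.ddG for r in scored]
    n_hot = sum(1 for r in scored if r.hotspot)
    return {
        "n_site_residues": len(result.records),
        "n_scored": len(scored),
        "mean_ddG": sum(ddgs) / len(ddgs),
        "max_ddG": max(ddgs),
        "n_hotspots": n_hot,
        "hotspot_fraction": n_hot / len(scored),
    }


def _records_frame(result: ScanResult) -> pd.DataFrame:
    rows = []
    for rec in result.records:
        cd = rec.component_deltas
        rows.append({
            "chain": rec.rid[0], "res_seq": rec.rid[1], "i_code": rec.rid[2],
            "res_name": rec.res_name, "min_distance": rec.min_distance,
            "E_wt": rec.E_wt, "E_mut": rec.E_mut, "ddG": rec.ddG,
            "d_vdw": cd.vdw if cd else None, "d_hbond": cd.hbond if cd else None,
            "d_elec": cd.elec if cd else None, "d_desolv": cd.desolv if cd else None,
            "hotspot": rec.hotspot, "skipped": rec.skipped,
            "skip_reason": rec.skip_reason,
            "n_clashes": rec.quality["n_clashes"] if rec.quality else None,
        })
    return pd.DataFrame(rows)


def _gradient_color(value: float, vmin: float, vmax: float) -> str:
    """Red (max ΔΔG, critical) to blue (min) hex color."""
    if vmax <= vmin:
        t = 1.0
    else:
        t = (value - vmin) / (vmax - vmin)
    r = int(round(255 * t))
    b = int(round(255 * (1.0 - t)))
    return f"0x{r:02X}00{b:02X}"


def _coloring_script(result: ScanResult) -> str:
    """PyMOL-syntax commands mapping ΔΔG onto a red-blue residue gradient."""
    scored = result.scored()
    lines = ["# color binding-site residues by ddG (red = largest contribution)",
             "hide everything", "show cartoon", "color grey80"]
    if scored:
        vmin = min(r.ddG for r in scored)
        vmax = max(r.ddG for r in scored)
        for rec in scored:
            col = _gradient_color(rec.ddG, vmin, vmax)
            sel = f"chain {rec.rid[0]} and resi {rec.rid[1]}{rec.rid[2]}"
            lines.append(f"color {col}, {sel}  # {rec.label} ddG={rec.ddG:.4f}")
            lines.append(f"show sticks, {sel}")
    return "\n".join(lines) + "\n"


def write_reports(result: ScanResult, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write scan.csv, scan.json, mutants/*.pdb and color_ddg.pml.

    The CSV is written with fixed 6-decimal formatting, so identical scans
    produce bitwise-identical files and ΔΔG survives a round-trip well
    beyond 4 decimals.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "mutants").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    paths: dict[str, Path] = {}
    frame = _records_frame(result)
    paths["csv"] = out / "scan.csv"
    frame.to_csv(paths["csv"], index=False, float_format="%.6f")

    paths["json"] = out / "scan.json"
    payload = {
        "provenance": result.provenance,
        "E_wt": result.E_wt_total,
        "wt_components": result.wt_breakdown.as_dict(),
        "summary": site_summary(result),
        "records": frame.where(pd.notna(frame), None).to_dict(orient="records"),
    }
    paths["json"].write_text(json.dumps(payload, indent=2, default=str) + "\n")

    paths["coloring"] = out / "color_ddg.pml"
    paths["coloring"].write_text(_coloring_script(result))

    mutants = getattr(result, "_mutant_structures", {})
    for label, structure in mutants.items():
        p = out / "mutants" / f"{label.replace(':', '_')}.pdb"
        p.write_text(write_pdb(structure))
    if mutants:
        paths["mutants_dir"] = out / "mutants"
    return paths
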