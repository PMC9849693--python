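"""File formats and stage orchestration.

Plain-text dialects only: CSV/TSV for tables, multi-model PDB for
coordinate ensembles, JSON for configurations, graphs and summary
reports.  Concentrations are molar in files, energies kcal/mol,
temperatures K, coordinates Å.

``run_stage`` is the programmatic driver: it takes a
:class:`RunConfig`, reads the declared inputs, executes one analysis
stage and returns (and optionally writes) a machine-readable summary
carrying the config, a config hash and the seed, so every run is
reproducible from its own log.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Atom import Atom
from Bio.PDB.Chain import Chain
from Bio.PDB.Model import Model
from Bio.PDB.Residue import Residue
from Bio.PDB.Structure import Structure

from camryr import equilibria, kinetics, psn as psn_mod, reference
from camryr.calorimetry import ITCProtocol, Thermogram, fit_itc, subtract_dilution
from camryr.ensemble import Ensemble, ParticleLabel
from camryr.equilibria import TitrationSeries, fit_fluorescence_titration
from camryr.kinetics import Sensorgram, fit_langmuir_series
from camryr.psn import InteractionRecord, build_psn, ef_hand_cr, persistence_from_records


class SchemaError(ValueError):
    """A table is missing required columns."""


class ParseError(ValueError):
    """A row failed to parse; the message names the offending line."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found "
                          f"{list(df.columns)}")


def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, skip_blank_lines=True, **kw)
    except pd.errors.ParserError as exc:  # pandas names the bad line
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- titrations

def read_titrations(path) -> list[TitrationSeries]:
    """Titration CSV: columns titrant_M, signal, replicate."""
    df = _read_csv(path)
    _require_columns(df, ["titrant_M", "signal", "replicate"], path)
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("titrant_M")
        out.append(TitrationSeries(
            titrant_total=grp["titrant_M"].to_numpy(float),
            signal=grp["signal"].to_numpy(float),
            ligand_total=float(grp["ligand_M"].iloc[0]) if "ligand_M" in grp else 1e-6,
            replicate_id=str(rep)))
    return out


def write_titrations(series: list[TitrationSeries], path) -> None:
    rows = []
    for s in series:
        for x, y in zip(s.titrant_total, s.signal):
            rows.append({"titrant_M": x, "signal": y,
                         "replicate": s.replicate_id,
                         "ligand_M": s.ligand_total})
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------------------- ITC

def read_itc(csv_path, protocol_json) -> tuple[Thermogram, ITCProtocol]:
    """Injection CSV (inj_vol_uL, heat) + protocol JSON.

    ``heat`` is kcal per mole of injectant; an optional ``blank``
    column carries the dilution run.
    """
    df = _read_csv(csv_path)
    _require_columns(df, ["inj_vol_uL", "heat"], csv_path)
    with open(protocol_json) as fh:
        proto = json.load(fh)
    protocol = ITCProtocol(
        cell_volume=proto["cell_volume_L"],
        cell_conc=proto["cell_conc_M"],
        syringe_conc=proto["syringe_conc_M"],
        injection_volumes=df["inj_vol_uL"].to_numpy(float) * 1e-6,
        temperature=proto.get("temperature_K", equilibria.STANDARD_TEMPERATURE))
    blank = df["blank"].to_numpy(float) if "blank" in df.columns else None
    return Thermogram(heats=df["heat"].to_numpy(float), blank_heats=blank), protocol


def write_itc(thermogram: Thermogram, protocol: ITCProtocol,
              csv_path, protocol_json) -> None:
    df = pd.DataFrame({"inj_vol_uL": protocol.injection_volumes * 1e6,
                       "heat": thermogram.heats})
    if thermogram.blank_heats is not None:
        df["blank"] = thermogram.blank_heats
    df.to_csv(csv_path, index=False)
    with open(protocol_json, "w") as fh:
        json.dump({"cell_volume_L": protocol.cell_volume,
                   "cell_conc_M": protocol.cell_conc,
                   "syringe_conc_M": protocol.syringe_conc,
                   "temperature_K": protocol.temperature}, fh, indent=1)


# ----------------------------------------------------------------------- SPR

def read_sensorgrams(path) -> list[Sensorgram]:
    """Sensorgram CSV: time_s, RU, conc_M, phase, curve (curve optional)."""
    df = _read_csv(path)
    _require_columns(df, ["time_s", "RU", "conc_M", "phase"], path)
    if "curve" not in df.columns:
        df = df.assign(curve=df["conc_M"].astype(str))
    out = []
    for _, grp in df.groupby("curve", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "association"]["time_s"]
        dissoc = grp[grp["phase"] == "dissociation"]["time_s"]
        if assoc.empty or dissoc.empty:
            raise SchemaError(f"{path}: each curve needs both phases")
        out.append(Sensorgram(
            time=grp["time_s"].to_numpy(float),
            response=grp["RU"].to_numpy(float),
            analyte_conc=float(grp["conc_M"].iloc[0]),
            assoc_window=(float(assoc.min()), float(assoc.max())),
            dissoc_window=(float(assoc.max()), float(dissoc.max()))))
    return out


def write_sensorgrams(curves: list[Sensorgram], path) -> None:
    rows = []
    for k, c in enumerate(curves):
        phase = np.where(c.time <= c.assoc_window[1], "association", "dissociation")
        rows.append(pd.DataFrame({"time_s": c.time, "RU": c.response,
                                  "conc_M": c.analyte_conc, "phase": phase,
                                  "curve": f"c{k:03d}"}))
    pd.concat(rows).to_csv(path, index=False)


# ----------------------------------------------------------- PSN record IO

def read_interaction_records(path) -> tuple[list[InteractionRecord], int]:
    """Interaction CSV: frame, residue_i, residue_j, interaction_class.

    Returns the records and the frame count (max frame index + 1,
    overridable by an ``n_frames`` column).
    """
    df = _read_csv(path)
    _require_columns(df, ["frame", "residue_i", "residue_j",
                          "interaction_class"], path)
    records = []
    for idx, row in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            records.append(InteractionRecord(
                frame=int(row.frame), residue_i=str(row.residue_i),
                residue_j=str(row.residue_j),
                interaction_class=str(row.interaction_class)))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {idx}: {exc}") from exc
    if "n_frames" in df.columns:
        n_frames = int(df["n_frames"].iloc[0])
    else:
        n_frames = max((r.frame for r in records), default=0) + 1
    return records, n_frames


def write_interaction_records(records: list[InteractionRecord], path,
                              n_frames: int | None = None) -> None:
    df = pd.DataFrame([{"frame": r.frame, "residue_i": r.residue_i,
                        "residue_j": r.residue_j,
                        "interaction_class": r.interaction_class}
                       for r in records])
    if n_frames is not None:
        df["n_frames"] = n_frames
    df.to_csv(path, index=False)


def write_edge_list(graph: psn_mod.PSNGraph, path) -> None:
    """Edge-list TSV: node_i, node_j, persistence."""
    rows = [{"node_i": i, "node_j": j, "persistence": d.get("persistence", 1.0)}
            for i, j, d in sorted(graph.graph.edges(data=True))]
    pd.DataFrame(rows, columns=["node_i", "node_j", "persistence"]).to_csv(
        path, sep="\t", index=False)


# -------------------------------------------------------------- PDB ensembles

def write_ensemble_pdb(ensemble: Ensemble, path) -> None:
    """Multi-model PDB: one MODEL per frame, CA atoms per labelled particle."""
    structure = Structure("ens")
    for f in range(ensemble.n_frames):
        model = Model(f)
        chains: dict[str, Chain] = {}
        for p, label in enumerate(ensemble.particle_labels):
            chain = chains.setdefault(label.chain, Chain(label.chain))
            res = Residue((" ", label.resnum, " "), "ALA", "")
            atom = Atom(label.atom, ensemble.frames[f, p], 0.0, 1.0, " ",
                        label.atom, p + 1, element="C")
            res.add(atom)
            chain.add(res)
        for chain in chains.values():
            model.add(chain)
        structure.add(model)
    pdb_io = PDBIO()
    pdb_io.set_structure(structure)
    pdb_io.save(str(path))


def read_ensemble_pdb(path) -> Ensemble:
    """Read a multi-model PDB into an Ensemble (occupancy/B optional)."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    models = list(structure)
    if len(models) < 2:
        raise ParseError(f"{path}: an ensemble PDB needs at least 2 MODELs")
    labels, frames = None, []
    for model in models:
        frame_labels, coords = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    frame_labels.append(ParticleLabel(
                        chain=chain.id, resnum=res.id[1], atom=atom.get_name()))
                    coords.append(atom.get_coord())
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise ParseError(f"{path}: particle set differs between models")
        frames.append(np.asarray(coords, dtype=float))
    return Ensemble(particle_labels=tuple(labels), frames=np.stack(frames))


def read_xyz_csv(path) -> Ensemble:
    """Per-frame XYZ table: frame, chain, resnum, atom, x, y, z."""
    df = _read_csv(path)
    _require_columns(df, ["frame", "chain", "resnum", "atom", "x", "y", "z"], path)
    labels, frames = None, []
    for _, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values(["chain", "resnum", "atom"])
        frame_labels = [ParticleLabel(str(r.chain), int(r.resnum), str(r.atom))
                        for r in grp.itertuples()]
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise ParseError(f"{path}: particle set differs between frames")
        frames.append(grp[["x", "y", "z"]].to_numpy(float))
    return Ensemble(particle_labels=tuple(labels), frames=np.stack(frames))


# --------------------------------------------------------------- run driver

_KNOWN_STAGES = ("thermo", "fit_fluor", "fit_itc", "fit_spr", "psn")


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: stage, inputs, model options, seed, output dir."""

    stage: str
    inputs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in _KNOWN_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; "
                             f"choose from {_KNOWN_STAGES}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        allowed = {"stage", "inputs", "options", "seed", "output_dir"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_stage(config: RunConfig) -> dict:
    """Execute one analysis stage and return its summary bundle."""
    summary: dict = {
        "stage": config.stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }

    if config.stage == "thermo":
        table = reference.itc_comparison_table()
        summary["table"] = table.to_dict(orient="records")
        summary["max_abs_dev_kcal"] = float(max(
            (table["dg_calc"] - table["dg_ref"]).abs().max(),
            (table["minus_tds_calc"] - table["minus_tds_ref"]).abs().max(),
            (table["ddg_calc"] - table["ddg_ref"]).abs().max(),
        ))

    elif config.stage == "fit_fluor":
        series = read_titrations(config.inputs["titrations"])
        model_tag = config.options.get("model_tag", "hyperbolic")
        fits = [fit_fluorescence_titration(
            s, model_tag, config.options.get("fix_endpoints", False))
            for s in series]
        agg = equilibria.aggregate_replicates(fits)
        summary["fits"] = [{"replicate": f.replicate_id, "kd_M": f.kd,
                            "residual_norm": f.residual_norm} for f in fits]
        summary["kd_mean_M"] = agg.kd_mean
        summary["kd_sd_M"] = agg.kd_sd

    elif config.stage == "fit_itc":
        thermogram, protocol = read_itc(config.inputs["heats"],
                                        config.inputs["protocol"])
        if thermogram.blank_heats is not None:
            thermogram = subtract_dilution(
                thermogram, Thermogram(heats=thermogram.blank_heats))
        record = fit_itc(thermogram, protocol)
        summary["thermo_record"] = {
            "kd_M": record.kd, "dh_kcal": record.dh, "dg_kcal": record.dg,
            "minus_tds_kcal": record.minus_tds, "n_sites": record.n_sites}

    elif config.stage == "fit_spr":
        curves = read_sensorgrams(config.inputs["sensorgrams"])
        fit = fit_langmuir_series(
            curves, koff_mode=config.options.get("koff_mode", "per_curve"))
        summary["kinetic_fit"] = {
            "kon_M-1s-1": fit.kon, "kon_sem": fit.kon_sem,
            "koff_s-1": fit.koff, "koff_sem": fit.koff_sem,
            "kd_kinetic_M": fit.kd_kinetic, "n_curves": fit.n_curves}

    elif config.stage == "psn":
        records, n_frames = read_interaction_records(config.inputs["records"])
        persistence = persistence_from_records(records, n_frames)
        pt = config.options.get("pt")
        if pt is None:
            pt = psn_mod.select_pt(persistence.only("hydrophobic"))
        graph = build_psn(persistence, pt,
                          merge=config.options.get("merge", "max"))
        summary["pt"] = pt
        summary["n_nodes"] = graph.graph.number_of_nodes()
        summary["n_edges"] = graph.graph.number_of_edges()
        ef_map = config.options.get("ef_map")
        if ef_map is not None or all(
                n in graph.graph for n in psn_mod.DEFAULT_EF_MAP.values()):
            cr = ef_hand_cr(graph, ef_map,
                            form=config.options.get("cr_form", "n_pt_over_l"))
            summary["cr"] = {f"{a}-{b}": cr.pair(a, b)
                             for i, a in enumerate(cr.values.index)
                             for b in cr.values.columns[i + 1:]}
            summary["robust"] = {k: v >= cr.robust_threshold
                                 for k, v in summary["cr"].items()}
        if config.output_dir:
            write_edge_list(graph, Path(config.output_dir) / "edges.tsv")

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{config.stage}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if obj is None or (isinstance(obj, float) and math.isnan(obj)):
        return None
    return str(obj)
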