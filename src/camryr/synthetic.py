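"""Seeded generators emulating every input stage of the analysis.

Each generator is a pure function of its arguments: the same seed gives
bit-identical output, and the ground-truth parameters are returned next
to the data so recovery tests are self-describing.  The defaults are
the study conditions of the wet-lab protocols being emulated: 1 µM
peptide titrated with 0–4 µM CaM (fluorescence), thirty 1-µL
injections of 125 µM peptide into 10 µM CaM in a 200 µL cell (ITC),
60 s association / 300 s dissociation sensorgrams at sub-µM to µM
analyte (SPR), harmonic fluctuation ensembles with planted principal
modes (MD stand-in), and Bernoulli per-frame interaction records with
planted hubs and communication routes (network stand-in).

Default noise levels: 2 % of signal span (fluorescence), 2 % of the
largest |heat| (ITC), 1 RU (SPR), 0.3 Å isotropic jitter (ensembles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from camryr.calorimetry import ITCProtocol, Thermogram, itc_forward
from camryr.ensemble import Ensemble, ParticleLabel
from camryr.equilibria import TitrationSeries, one_site_model
from camryr.kinetics import Sensorgram
from camryr.psn import InteractionRecord


@dataclass(frozen=True)
class GeneratorSpec:
    """Record of a generator call: seed, noise model, truth parameters."""

    seed: int
    noise_model: str
    parameters: dict = field(default_factory=dict)


# concentration grid emulating a 0-4 µM CaM titration of 1 µM peptide
TITRATION_GRID_M = np.array(
    [0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0]) * 1e-6


def gen_titration(seed: int, kd: float = 110e-9, ligand_total: float = 1e-6,
                  y0: float = 350.0, ymax: float = 332.0,
                  noise_frac: float = 0.02, n_replicates: int = 1,
                  titrant_grid=None) -> tuple[list[TitrationSeries], dict]:
    """Fluorescence titration replicas with Gaussian signal noise.

    The noise-free signal follows the exact quadratic-depletion
    isotherm (the 1 µM fixed peptide is comparable to K_D, so depletion
    is material); ``noise_frac`` scales the Gaussian σ by the signal
    span |ymax − y0|.  The Trp emission peak blue-shifts on binding,
    hence ymax < y0 by default.
    """
    rng = np.random.default_rng(seed)
    x = TITRATION_GRID_M if titrant_grid is None else np.asarray(titrant_grid, float)
    fb = one_site_model(x, kd, ligand_total, "quadratic_depletion")
    clean = y0 + (ymax - y0) * fb
    sigma = noise_frac * abs(ymax - y0)
    series = []
    for r in range(n_replicates):
        noisy = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean.copy()
        series.append(TitrationSeries(titrant_total=x, signal=noisy,
                                      ligand_total=ligand_total,
                                      replicate_id=f"rep{r + 1}"))
    truth = {"kd": kd, "ligand_total": ligand_total, "y0": y0, "ymax": ymax,
             "noise_sd": sigma, "seed": seed, "model": "quadratic_depletion"}
    return series, truth


def gen_itc(seed: int, kd: float = 12.31e-9, dh: float = -9.94,
            n_sites: float = 1.0, cell_volume: float = 200e-6,
            cell_conc: float = 10e-6, syringe_conc: float = 125e-6,
            n_injections: int = 30, injection_volume: float = 1e-6,
            noise_frac: float = 0.02, dilution_offset: float = 0.0
            ) -> tuple[Thermogram, ITCProtocol, dict]:
    """One-set-of-sites thermogram with Gaussian heat noise.

    Defaults emulate thirty 1-µL injections of 125 µM peptide into
    10 µM CaM in a 200 µL cell at 25 °C; noise σ is ``noise_frac``
    times the largest |heat|.  ``dilution_offset`` adds a constant
    per-injection heat of dilution (kcal/mol of injectant) that a blank
    run would remove.
    """
    rng = np.random.default_rng(seed)
    protocol = ITCProtocol(cell_volume=cell_volume, cell_conc=cell_conc,
                           syringe_conc=syringe_conc,
                           injection_volumes=np.full(n_injections, injection_volume))
    clean = itc_forward(protocol, n_sites, kd, dh).heats
    sigma = noise_frac * np.max(np.abs(clean))
    heats = clean + dilution_offset
    if sigma > 0:
        heats = heats + rng.normal(0.0, sigma, size=heats.shape)
    truth = {"kd": kd, "dh": dh, "n_sites": n_sites, "noise_sd": sigma,
             "dilution_offset": dilution_offset, "seed": seed}
    return Thermogram(heats=heats), protocol, truth


def gen_sensorgrams(seed: int, kon: float = 1e5, koff: float = 0.01,
                    rmax: float = 120.0,
                    concentrations=(0.25e-6, 0.5e-6, 1e-6, 2e-6),
                    n_replicates: int = 3, assoc_s: float = 60.0,
                    dissoc_s: float = 300.0, dt: float = 0.5,
                    noise_ru: float = 1.0) -> tuple[list[Sensorgram], dict]:
    """1:1 Langmuir sensorgrams over a concentration series.

    Association follows ``Req·(1 − exp(−kobs t))`` with
    ``kobs = kon·C + koff`` and ``Req = Rmax·C/(C + K_D)``; the
    dissociation phase decays single-exponentially from the response
    reached at the end of injection.  Gaussian RU noise is added
    pointwise.
    """
    rng = np.random.default_rng(seed)
    kd = koff / kon
    curves = []
    for conc in concentrations:
        for _ in range(n_replicates):
            t_assoc = np.arange(0.0, assoc_s + dt / 2, dt)
            t_dissoc = np.arange(dt, dissoc_s + dt / 2, dt)
            kobs = kon * conc + koff
            req = rmax * conc / (conc + kd)
            r_assoc = req * (1.0 - np.exp(-kobs * t_assoc))
            r_end = r_assoc[-1]
            r_dissoc = r_end * np.exp(-koff * t_dissoc)
            t = np.concatenate([t_assoc, assoc_s + t_dissoc])
            r = np.concatenate([r_assoc, r_dissoc])
            if noise_ru > 0:
                r = r + rng.normal(0.0, noise_ru, size=r.shape)
            curves.append(Sensorgram(
                time=t, response=r, analyte_conc=conc,
                assoc_window=(0.0, assoc_s),
                dissoc_window=(assoc_s, assoc_s + dissoc_s)))
    truth = {"kon": kon, "koff": koff, "kd_kinetic": kd, "rmax": rmax,
             "concentrations": tuple(concentrations), "noise_ru": noise_ru,
             "seed": seed}
    return curves, truth


def _helix_backbone(n_particles: int) -> np.ndarray:
    """Idealized α-helical Cα trace used as the resting geometry (Å)."""
    idx = np.arange(n_particles)
    theta = idx * np.deg2rad(100.0)
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx])


def gen_ensemble(seed: int, n_particles: int = 20, n_frames: int = 500,
                 mode_vectors: np.ndarray | None = None,
                 mode_variances=(4.0, 1.0), jitter_sd: float = 0.3,
                 rigid_nuisance: bool = False) -> tuple[Ensemble, dict]:
    """Harmonic-fluctuation ensemble with planted principal modes.

    Frames are the helical base geometry displaced along planted
    orthonormal 3P-dimensional mode vectors with Gaussian amplitudes of
    the given variances (Å²), plus isotropic per-coordinate jitter.
    ``rigid_nuisance`` additionally applies a random rotation and
    translation to every frame, which superposition must remove.
    """
    rng = np.random.default_rng(seed)
    base = _helix_backbone(n_particles)
    dim = 3 * n_particles
    variances = np.asarray(mode_variances, dtype=float)
    if mode_vectors is None:
        raw = rng.normal(size=(dim, variances.size))
        mode_vectors, _ = np.linalg.qr(raw)
    modes = np.asarray(mode_vectors, dtype=float)

    amplitudes = rng.normal(0.0, np.sqrt(variances), size=(n_frames, variances.size))
    displacements = amplitudes @ modes.T
    frames = base[None, :, :] + displacements.reshape(n_frames, n_particles, 3)
    if jitter_sd > 0:
        frames = frames + rng.normal(0.0, jitter_sd, size=frames.shape)

    if rigid_nuisance:
        for f in range(n_frames):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ])
            frames[f] = frames[f] @ rot.T + rng.normal(0.0, 5.0, size=3)

    labels = tuple(ParticleLabel(chain="A", resnum=i + 1, atom="CA")
                   for i in range(n_particles))
    truth = {"mode_vectors": modes, "mode_variances": variances,
             "jitter_sd": jitter_sd, "rigid_nuisance": rigid_nuisance,
             "seed": seed}
    # without nuisance motion the frames share one reference frame already
    return Ensemble(particle_labels=labels, frames=frames,
                    superposed=not rigid_nuisance), truth


def gen_interaction_records(seed: int, planted: dict, n_frames: int = 100
                            ) -> tuple[list[InteractionRecord], dict]:
    """Bernoulli per-frame interaction records with planted persistences.

    ``planted`` maps ``(residue_i, residue_j, interaction_class)`` to a
    target persistence in [0, 1]; each pair is present in each frame
    independently with that probability.
    """
    rng = np.random.default_rng(seed)
    records: list[InteractionRecord] = []
    for (ri, rj, cls), p in sorted(planted.items()):
        present = rng.random(n_frames) < p
        records.extend(InteractionRecord(frame=f, residue_i=ri, residue_j=rj,
                                         interaction_class=cls)
                       for f in np.nonzero(present)[0])
    truth = {"planted": dict(planted), "n_frames": n_frames, "seed": seed}
    return records, truth


def gen_ef_network_records(seed: int, n_frames: int = 100,
                           break_ef1_ef3: bool = False,
                           route_persistence: float = 0.8,
                           distractor_persistence: float = 0.05,
                           n_distractors: int = 10
                           ) -> tuple[list[InteractionRecord], dict]:
    """Interaction records with planted EF-hand communication routes.

    Emulates the network structure of a CaM-peptide complex: the four
    EF-hand glutamates (E31, E67, E104, E140) are wired through
    intermediate residues.  The EF3-EF4 route is always robust (two
    parallel two-hop paths at high persistence).  The EF1-EF3 route is
    robust by default ("WT-RyR2-like"); with ``break_ef1_ef3`` the
    bridging contacts are removed so EF1 can reach EF3 only through a
    long detour ("mutant-like").  Distractor pairs at low persistence
    sit below any sensible threshold.
    """
    planted: dict[tuple[str, str, str], float] = {}

    def plant(a, b, cls="hydrophobic", p=route_persistence):
        planted[(a, b, cls)] = p

    # EF3-EF4: two parallel 2-hop routes, always robust
    plant("E104", "F141", p=route_persistence)
    plant("F141", "E140", p=route_persistence)
    plant("E104", "M144", p=route_persistence)
    plant("M144", "E140", p=route_persistence)
    # EF1-EF2 and EF2-EF4 background wiring
    plant("E31", "F19", "hbond")
    plant("F19", "E67", "hbond")
    plant("E67", "M76", "electrostatic")
    plant("M76", "E140", "electrostatic")
    if not break_ef1_ef3:
        # EF1-EF3: two parallel 2-hop routes through the central linker
        plant("E31", "M72", p=route_persistence)
        plant("M72", "E104", p=route_persistence)
        plant("E31", "F89", p=route_persistence)
        plant("F89", "E104", p=route_persistence)

    rng = np.random.default_rng(seed)
    distractor_pool = [f"X{i}" for i in range(1, n_distractors + 2)]
    for k in range(n_distractors):
        a, b = sorted(rng.choice(len(distractor_pool), size=2, replace=False))
        planted[(distractor_pool[a], distractor_pool[b], "hydrophobic")] = \
            distractor_persistence

    records, truth = gen_interaction_records(seed + 1, planted, n_frames)
    truth.update({"break_ef1_ef3": break_ef1_ef3,
                  "route_persistence": route_persistence})
    return records, truth
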