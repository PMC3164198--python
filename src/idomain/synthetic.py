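"""Synthetic alpha-I-domain templates, trajectories and unbinding traces.

Every analysis stage in this package can be exercised without downloading
crystal structures or running molecular dynamics: this module generates
*geometric scaffolds* -- poly-alanine-like chains carrying named landmark
residues with proper Cbeta and side-chain-oxygen pseudo-atoms -- whose
geometry is controlled exactly, together with truth records sufficient to
recompute the expected downstream output.

The scaffolds are emphatically NOT homology models.  They reproduce the
*statistical and geometric structure the analysis assumes*:

* an LA (low-affinity) template whose MIDAS oxygens realise the
  crystallographic sphere pattern (Ser139/Ser141/Asp239 within the 3.5 A
  primary sphere, Asp137/Thr206 beyond it);
* an HA template whose alpha7 segment is rigidly displaced axially by a
  configured amount (default 9 A, within the 8-11 A per-residue range
  such transitions show), with the zipper Cbeta pairs closing from ~10 A
  to ~5 A as a consequence, and the MIDAS ion shifted inward;
* equilibration trajectories realising the four run categories
  (stay-LA / drift-to-midpoint / sigmoidal LA->HA transition with inward
  ion motion / 30-45 degree swing-out), with isotropic Gaussian
  coordinate noise, independent across frames (no kinetics is claimed);
* constant-force separation traces with a known threshold-crossing time,
  optional transient rebinding excursions, and optional censoring.

All randomness flows from one seeded generator per call; the seed is
recorded in every :class:`TruthRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .observables import SeparationTrace
from .structure_io import (
    BACKBONE_ATOMS,
    SelectionSpec,
    Structure,
    Trajectory,
    find_midas_ion,
)

__all__ = [
    "TemplateSpec",
    "TruthRecord",
    "make_template",
    "make_equilibration",
    "make_smd_trace",
    "core_spec",
    "alpha7_spec",
]

# Landmark residue identities, LFA-1-like author numbering.
_LANDMARKS = {
    137: "ASP", 139: "SER", 141: "SER", 144: "SER",
    150: "ILE", 153: "PHE", 157: "VAL", 161: "LEU",
    206: "THR", 239: "ASP", 241: "GLU",
    292: "PHE", 293: "GLU", 299: "PHE", 305: "LYS",
}

# Min side-chain-oxygen -> ion target distances (A) per affinity state.
# LA realises the crystal pattern (S139/S141/D239 primary, D137/T206
# secondary); the activated pattern swaps S141 out and D137/T206 in.
_MIDAS_DISTANCES = {
    "LA": {137: 4.5, 139: 2.2, 141: 2.3, 144: 4.0, 206: 4.2, 239: 2.1, 241: 4.8},
    "ACTIVE": {137: 2.4, 139: 2.2, 141: 4.3, 144: 4.0, 206: 2.3, 239: 2.1, 241: 4.8},
}

# Unit directions from the ion to each MIDAS residue's nearest oxygen.
_MIDAS_DIRECTIONS = {
    137: (0.0, -1.0, 0.0),
    139: (1.0, 0.0, 0.0),
    141: (0.0, 1.0, 0.0),
    144: (0.0, 0.6, -0.8),
    206: (0.6, 0.0, 0.8),
    239: (-1.0, 0.0, 0.0),
    241: (-0.6, 0.0, -0.8),
}

_SIDE_OXYGENS = {"SER": ("OG",), "THR": ("OG1",), "ASP": ("OD1", "OD2"),
                 "GLU": ("OE1", "OE2")}

# Zipper geometry: the alpha7-side Cbeta sits above its alpha1 partner by
# DZ and laterally by DX, chosen so the pair distance is exactly 10 A in
# the LA template and exactly 5 A after the 9 A axial displacement.
_ZIP_DZ = 26.0 / 3.0
_ZIP_DX = float(np.sqrt(100.0 - _ZIP_DZ ** 2))

_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
               "OG": "O", "OG1": "O", "OD1": "O", "OD2": "O",
               "OE1": "O", "OE2": "O"}


@dataclass(frozen=True)
class TemplateSpec:
    """Geometry of the synthetic I-domain scaffold.

    ``state`` selects the alpha7 placement and MIDAS oxygen pattern:
    ``"LA"`` (reference), ``"IA"`` (axial displacement scaled by
    ``ia_fraction``) or ``"HA"`` (full displacement).  The mobile unit is
    residues ``mobile_start``..``alpha7[1]`` -- the helix plus the
    zipper phenylalanine immediately preceding it -- translated rigidly,
    so the configured axial displacement *is* the core-aligned segment
    RMSD between the HA and LA templates.
    """

    state: str = "LA"
    n_residues: int = 190
    first_res_id: int = 130
    chain: str = "A"
    alpha7: tuple[int, int] = (293, 305)
    mobile_start: int = 292
    axial_displacement: float = 9.0
    ia_fraction: float = 0.5
    ion_inward_shift: float = 2.5
    core_ranges: tuple[tuple[int, int], ...] = ((170, 200), (250, 280))
    include_ligand: bool = False
    ligand: tuple[str, int, str] = ("B", 34, "GLU")

    def state_fraction(self) -> float:
        try:
            return {"LA": 0.0, "IA": self.ia_fraction, "HA": 1.0}[self.state]
        except KeyError:
            raise ValueError(f"unknown state {self.state!r}; use LA, IA or HA") from None


@dataclass
class TruthRecord:
    """Ground truth of one generated artefact, enough to predict the analysis."""

    run_id: str
    kind: str  # "template" | "equilibration" | "smd"
    seed: int
    category: int | None = None
    swing_angle_deg: float | None = None
    ion_shift_A: float | None = None
    crossing_time_ns: float | None = None
    censored: bool = False
    noise_sigma: float = 0.0
    n_frames: int = 0
    time_per_frame: float = 0.0


def core_spec(spec: TemplateSpec = TemplateSpec()) -> SelectionSpec:
    """Backbone selection of the configured stable-core residue ranges."""
    return SelectionSpec(
        chain=spec.chain, resid_ranges=spec.core_ranges, atom_names=BACKBONE_ATOMS
    )


def alpha7_spec(spec: TemplateSpec = TemplateSpec()) -> SelectionSpec:
    """Backbone selection of the alpha7 helix segment."""
    return SelectionSpec(
        chain=spec.chain, resid_ranges=(spec.alpha7,), atom_names=BACKBONE_ATOMS
    )


def _perp(u: np.ndarray) -> np.ndarray:
    axis = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, axis)
    return v / np.linalg.norm(v)


def _backbone(ca: np.ndarray) -> list[tuple[str, np.ndarray]]:
    return [
        ("N", ca + np.array([-1.2, 0.6, 0.0])),
        ("CA", ca),
        ("C", ca + np.array([1.2, 0.6, 0.0])),
        ("O", ca + np.array([1.8, 1.6, 0.3])),
    ]


def make_template(spec: TemplateSpec = TemplateSpec(), seed: int = 0) -> Structure:
    """Build one scaffold conformation; deterministic for a given (spec, seed).

    The LA template places the MIDAS side-chain oxygens so that the
    S139/S141/D239 analogues lie within 3.5 A of the ion and the
    D137/T206 analogues beyond it; IA/HA variants shift the mobile alpha7
    unit axially, move the ion inward and switch to the activated oxygen
    pattern.
    """
    fraction = spec.state_fraction()
    t_vec = np.array([0.0, 0.0, -spec.axial_displacement]) * fraction
    ion_pos = np.array([-spec.ion_inward_shift, 0.0, 0.0]) * fraction
    distances = _MIDAS_DISTANCES["LA" if spec.state == "LA" else "ACTIVE"]

    a7_lo, a7_hi = spec.alpha7
    mobile = range(spec.mobile_start, a7_hi + 1)

    names: list[str] = []
    elements: list[str] = []
    res_names: list[str] = []
    res_ids: list[int] = []
    chains: list[str] = []
    coords: list[np.ndarray] = []
    hetero: list[bool] = []

    def add(name: str, res_name: str, res_id: int, chain: str, xyz: np.ndarray,
            het: bool = False, element: str | None = None):
        names.append(name)
        elements.append(element or _ELEMENT_OF[name])
        res_names.append(res_name)
        res_ids.append(res_id)
        chains.append(chain)
        coords.append(np.asarray(xyz, dtype=np.float64))
        hetero.append(het)

    zipper_cb = {
        153: np.array([15.5, 3.0, 4.0]),
        161: np.array([15.5, 3.0, -5.6]),
    }
    zipper_cb[292] = zipper_cb[153] + np.array([_ZIP_DX, 0.0, _ZIP_DZ])
    zipper_cb[299] = zipper_cb[161] + np.array([_ZIP_DX, 0.0, _ZIP_DZ])

    for k in range(spec.n_residues):
        res_id = spec.first_res_id + k
        res_name = _LANDMARKS.get(res_id, "ALA")
        extra: list[tuple[str, np.ndarray]] = []
        cb: np.ndarray | None = None

        if res_id in _MIDAS_DIRECTIONS:
            u = np.asarray(_MIDAS_DIRECTIONS[res_id], dtype=np.float64)
            u /= np.linalg.norm(u)
            d = distances[res_id]
            ca = ion_pos + (d + 2.5) * u
            cb = ion_pos + (d + 1.3) * u
            oxygens = _SIDE_OXYGENS[res_name]
            extra.append((oxygens[0], ion_pos + d * u))
            if len(oxygens) > 1:
                u2 = u + 0.3 * _perp(u)
                u2 /= np.linalg.norm(u2)
                extra.append((oxygens[1], ion_pos + (d + 0.6) * u2))
        elif 148 <= res_id <= 165:
            ca = np.array([14.0, 3.0, 10.0 - 1.2 * (res_id - 148)])
        elif res_id in mobile:
            ca = np.array([22.0, 3.0, 12.0 - 1.5 * (res_id - spec.mobile_start)])
        else:
            theta = np.radians(40.0 * k)
            ca = np.array([10.0 * np.cos(theta), 10.0 * np.sin(theta), -25.0 + 0.45 * k])

        if res_id in zipper_cb:
            cb = zipper_cb[res_id].copy()

        atoms = _backbone(ca)
        if res_name != "GLY":
            atoms.append(("CB", cb if cb is not None else ca + np.array([0.0, -1.5, 0.4])))
        atoms.extend(extra)
        shift = t_vec if res_id in mobile else 0.0
        for name, xyz in atoms:
            add(name, res_name, res_id, spec.chain, xyz + shift)

    # MIDAS metal ion: a HETATM calcium, distinguishable from Calpha by
    # its record type and element.
    add("CA", "CA", 401, spec.chain, ion_pos, het=True, element="CA")

    if spec.include_ligand:
        lig_chain, lig_res, lig_name = spec.ligand
        u = np.array([0.0, -1.0, -1.0]) / np.sqrt(2.0)
        ox = _SIDE_OXYGENS[lig_name]
        for name, xyz in _backbone(ion_pos + 5.5 * u):
            add(name, lig_name, lig_res, lig_chain, xyz)
        add("CB", lig_name, lig_res, lig_chain, ion_pos + 3.8 * u)
        add(ox[0], lig_name, lig_res, lig_chain, ion_pos + 2.2 * u)
        u2 = u + 0.3 * _perp(u)
        u2 /= np.linalg.norm(u2)
        add(ox[1], lig_name, lig_res, lig_chain, ion_pos + 2.9 * u2)

    return Structure(
        name=names,
        element=elements,
        res_name=res_names,
        res_id=res_ids,
        chain=chains,
        coords=np.stack(coords),
        hetero=hetero,
        metadata={"name": spec.state, "state": spec.state, "seed": seed,
                  "synthetic": True},
    )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 3.0 * u ** 2 - 2.0 * u ** 3


def make_equilibration(
    category: int,
    n_frames: int = 100,
    time_per_frame: float = 0.1,
    noise_sigma: float = 0.5,
    seed: int = 0,
    spec: TemplateSpec = TemplateSpec(),
) -> tuple[Trajectory, TruthRecord]:
    """Generate one equilibration run of a given conformational category.

    The run starts at the LA scaffold; the category drives the mobile
    alpha7 unit over the first 60% of the frames (smoothstep schedule),
    then holds:

    1. no systematic motion (stay-LA);
    2. rigid drift to the midpoint between the LA and HA placements;
    3. full sigmoidal LA -> HA displacement, with the MIDAS ion
       translated inward by a drawn 2.1-2.8 A;
    4. rotation of the helix about an axis through its N-terminal Calpha
       by a drawn 30-45 degree swing-out angle.

    Isotropic Gaussian noise of ``noise_sigma`` A is added to every atom
    in every frame, independently across frames.
    """
    if category not in (1, 2, 3, 4):
        raise ValueError(f"category must be 1-4, got {category}")
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    rng = np.random.default_rng(seed)
    base = make_template(replace(spec, state="LA"), seed=seed)
    coords0 = base.coords
    a7_lo, a7_hi = spec.alpha7
    mobile = np.flatnonzero(
        (base.chain == spec.chain)
        & (base.res_id >= spec.mobile_start)
        & (base.res_id <= a7_hi)
        & ~base.hetero
    )
    ion_index = find_midas_ion(base)
    pivot = coords0[base.atom_index(spec.chain, a7_lo, "CA")]
    t_full = np.array([0.0, 0.0, -spec.axial_displacement])

    swing = float(rng.uniform(30.0, 45.0)) if category == 4 else None
    ion_shift = float(rng.uniform(2.1, 2.8)) if category == 3 else None

    ramp_end = max(1, int(round(0.6 * (n_frames - 1))))
    schedule = _smoothstep(np.arange(n_frames) / ramp_end)

    frames = np.empty((n_frames, base.n_atoms, 3))
    for f in range(n_frames):
        s = schedule[f]
        frame = coords0.copy()
        if category == 2:
            frame[mobile] += 0.5 * s * t_full
        elif category == 3:
            frame[mobile] += s * t_full
            frame[ion_index] += s * ion_shift * np.array([-1.0, 0.0, 0.0])
        elif category == 4:
            rot = Rotation.from_rotvec(np.radians(s * swing) * np.array([1.0, 0.0, 0.0]))
            frame[mobile] = rot.apply(frame[mobile] - pivot) + pivot
        if noise_sigma > 0:
            frame += rng.normal(0.0, noise_sigma, frame.shape)
        frames[f] = frame

    trajectory = Trajectory(base, frames, time_per_frame)
    truth = TruthRecord(
        run_id=f"cat{category}-seed{seed}",
        kind="equilibration",
        seed=seed,
        category=category,
        swing_angle_deg=swing,
        ion_shift_A=ion_shift,
        noise_sigma=noise_sigma,
        n_frames=n_frames,
        time_per_frame=time_per_frame,
    )
    return trajectory, truth


def make_smd_trace(
    crossing_time: float | None = 6.15,
    baseline: float = 2.2,
    post_slope: float = 20.0,
    noise_sigma: float = 0.0,
    n_frames: int = 800,
    time_per_frame: float = 0.01,
    seed: int = 0,
    threshold: float = 10.0,
    rebinding: tuple[float, int] | None = None,
    censored: bool = False,
    force_pn: float = 800.0,
) -> tuple[SeparationTrace, TruthRecord]:
    """Generate one constant-force separation trace with known crossing time.

    The distance sits at ``baseline`` (a bound ion-oxygen contact, ~2.2 A)
    until ``crossing_time`` ns, then jumps to ``threshold`` and ramps
    away at ``post_slope`` A/ns -- so with zero noise the extracted
    lifetime equals the first frame time at or after ``crossing_time``.
    ``rebinding=(start_time, n_excursion_frames)`` inserts a transient
    above-threshold excursion before the crossing to exercise the dwell
    rule; ``censored=True`` produces a trace that never crosses.
    """
    rng = np.random.default_rng(seed)
    times = time_per_frame * np.arange(n_frames)
    if censored:
        distances = np.full(n_frames, baseline)
        true_crossing = None
    else:
        if crossing_time is None:
            raise ValueError("crossing_time required unless censored=True")
        if crossing_time >= times[-1]:
            raise ValueError(
                f"crossing_time {crossing_time} ns is beyond the run end {times[-1]:.4g} ns"
            )
        distances = np.where(
            times < crossing_time,
            baseline,
            threshold + post_slope * (times - crossing_time),
        )
        first = int(np.searchsorted(times, crossing_time, side="left"))
        true_crossing = float(times[first])
    if rebinding is not None:
        start_time, n_excursion = rebinding
        start = int(np.searchsorted(times, start_time, side="left"))
        stop = start + int(n_excursion)
        if true_crossing is not None and times[min(stop, n_frames - 1)] >= true_crossing:
            raise ValueError("rebinding excursion overlaps the final crossing")
        distances = distances.copy()
        distances[start:stop] = threshold + 1.0
    if noise_sigma > 0:
        distances = distances + rng.normal(0.0, noise_sigma, n_frames)
    distances = np.clip(distances, 0.05, None)

    trace = SeparationTrace(
        times=times,
        distances=distances,
        force_pn=force_pn,
        label="synthetic",
    )
    truth = TruthRecord(
        run_id=f"smd-seed{seed}",
        kind="smd",
        seed=seed,
        crossing_time_ns=true_crossing,
        censored=censored,
        noise_sigma=noise_sigma,
        n_frames=n_frames,
        time_per_frame=time_per_frame,
    )
    return trace, truth
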