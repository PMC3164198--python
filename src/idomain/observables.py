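"""Named geometric observables of the integrin alpha-I domain.

* MIDAS coordination spheres -- every candidate residue is *primary* if
  the minimal distance from any of its side-chain oxygens to the metal
  ion is <= 3.5 A (inclusive), *secondary* otherwise.
* Zipper-junction Cbeta-Cbeta distances between alpha1- and alpha7-helix
  residues (e.g. F153-F292 and L161-F299 in LFA-1), per frame.
* Swing-out angle of the alpha7 helix: the angle between the helix axis
  vector (Calpha of the C-terminal residue to Calpha of the N-terminal
  residue, K305 -> E293 in LFA-1) of the frame and of the crystal
  reference, measured after superposing the stable core onto the
  reference so the angle is invariant under global rigid motion.
* Ion-ligand separation: per-frame minimum distance between the MIDAS
  ion and the carboxylate side-chain oxygens of the acidic ligand residue
  (E34 of ICAM-1 D1 or D229 of D3), the quantity that defines the
  forced-unbinding lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import (
    Selection,
    SelectionError,
    SelectionSpec,
    Structure,
    Trajectory,
    find_midas_ion,
)
from .superpose import kabsch, paired_indices

__all__ = [
    "SIDE_CHAIN_OXYGENS",
    "CARBOXYLATE_OXYGENS",
    "CoordinationAssignment",
    "JunctionDistances",
    "SwingAngleSeries",
    "SeparationTrace",
    "coordination_spheres",
    "junction_distances",
    "swing_angle",
    "separation_trace",
]

#: Side-chain oxygen atom names considered for metal coordination.  The
#: backbone carbonyl O is deliberately excluded: the sphere definition is
#: about side-chain oxygens only.
SIDE_CHAIN_OXYGENS = ("OG", "OG1", "OD1", "OD2", "OE1", "OE2", "OH")

CARBOXYLATE_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class CoordinationAssignment:
    """Primary/secondary sphere label per candidate MIDAS residue."""

    ion_index: int
    cutoff: float
    labels: dict[tuple[str, int], str]
    min_distances: dict[tuple[str, int], float]
    residue_names: dict[tuple[str, int], str]

    def primary(self) -> list[tuple[str, int]]:
        return [k for k, v in self.labels.items() if v == "primary"]

    def secondary(self) -> list[tuple[str, int]]:
        return [k for k, v in self.labels.items() if v == "secondary"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": chain,
                "res_id": res_id,
                "res_name": self.residue_names[(chain, res_id)],
                "sphere": label,
                "min_oxygen_distance_A": self.min_distances[(chain, res_id)],
            }
            for (chain, res_id), label in self.labels.items()
        ]
        return pd.DataFrame(rows)


def coordination_spheres(
    frame: Structure,
    candidates: Sequence,
    ion=None,
    cutoff: float = 3.5,
    chain: str = "A",
) -> CoordinationAssignment:
    """Assign candidate residues to the primary or secondary coordination sphere.

    Parameters
    ----------
    frame
        One conformation containing the MIDAS ion as a HETATM.
    candidates
        Residues to classify, as author residue numbers (``chain`` applies)
        or ``(chain, res_id)`` pairs.  Each must carry at least one
        side-chain oxygen; a residue without one (e.g. Ala) is an error
        naming the residue, not a silent skip.
    ion
        Atom index of the ion, or None to auto-detect the single divalent
        metal HETATM.
    cutoff
        Sphere boundary in A, inclusive: min side-chain-oxygen distance
        <= cutoff means primary.
    """
    if ion is None:
        ion_index = find_midas_ion(frame)
    elif isinstance(ion, Selection):
        if len(ion) != 1:
            raise SelectionError(f"ion selection must resolve to 1 atom, got {len(ion)}")
        ion_index = int(ion.indices[0])
    else:
        ion_index = int(ion)
    ion_pos = frame.coords[ion_index]

    labels: dict[tuple[str, int], str] = {}
    dists: dict[tuple[str, int], float] = {}
    names: dict[tuple[str, int], str] = {}
    for cand in candidates:
        if isinstance(cand, (tuple, list)):
            cand_chain, res_id = str(cand[0]), int(cand[1])
        else:
            cand_chain, res_id = chain, int(cand)
        mask = (
            (frame.chain == cand_chain)
            & (frame.res_id == res_id)
            & np.isin(frame.name, SIDE_CHAIN_OXYGENS)
            & ~frame.hetero
        )
        oxy = np.flatnonzero(mask)
        if oxy.size == 0:
            res_mask = (frame.chain == cand_chain) & (frame.res_id == res_id)
            res_name = frame.res_name[res_mask][0] if res_mask.any() else "?"
            raise SelectionError(
                f"residue {res_name} {cand_chain}:{res_id} has no side-chain oxygen"
            )
        dmin = float(np.min(np.linalg.norm(frame.coords[oxy] - ion_pos, axis=1)))
        key = (cand_chain, res_id)
        labels[key] = "primary" if dmin <= cutoff else "secondary"
        dists[key] = dmin
        names[key] = str(frame.res_name[oxy[0]])
    return CoordinationAssignment(
        ion_index=ion_index,
        cutoff=cutoff,
        labels=labels,
        min_distances=dists,
        residue_names=names,
    )


@dataclass
class JunctionDistances:
    """Per-frame Cbeta-Cbeta distances for configured zipper residue pairs."""

    labels: list[str]
    times: np.ndarray
    distances: np.ndarray  # shape (n_pairs, n_frames)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, row in zip(self.labels, self.distances):
            frames.append(
                pd.DataFrame({"time_ns": self.times, "pair": label, "distance_A": row})
            )
        return pd.concat(frames, ignore_index=True)


def _pair_label(structure: Structure, chain: str, res_id: int) -> str:
    idx = structure.atom_index(chain, res_id, "CB")
    one = _THREE_TO_ONE.get(str(structure.res_name[idx]), "X")
    return f"{one}{res_id}Cb"


def junction_distances(
    trajectory: Trajectory,
    pairs: Sequence[tuple[int, int]],
    chain: str = "A",
) -> JunctionDistances:
    """Euclidean Cbeta-Cbeta distance per frame for each residue pair.

    Both residues of a pair must have a CB atom; Gly (or a truncated
    residue) is an error.  The observable is symmetric in pair order.
    """
    topology = trajectory.topology
    labels: list[str] = []
    rows = []
    for res_a, res_b in pairs:
        try:
            idx_a = topology.atom_index(chain, int(res_a), "CB")
            idx_b = topology.atom_index(chain, int(res_b), "CB")
        except SelectionError as err:
            raise SelectionError(
                f"zipper pair ({res_a}, {res_b}): {err} "
                f"(Gly has no CB and cannot anchor a junction distance)"
            ) from None
        labels.append(
            f"{_pair_label(topology, chain, int(res_a))}-"
            f"{_pair_label(topology, chain, int(res_b))}"
        )
        diff = trajectory.frames[:, idx_a, :] - trajectory.frames[:, idx_b, :]
        rows.append(np.linalg.norm(diff, axis=1))
    return JunctionDistances(
        labels=labels, times=trajectory.times, distances=np.asarray(rows)
    )


@dataclass
class SwingAngleSeries:
    """Per-frame alpha7 swing-out angle in degrees, 0..180."""

    times: np.ndarray
    angles_deg: np.ndarray
    helix_pair: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "swing_angle_deg": self.angles_deg})


def swing_angle(
    trajectory: Trajectory,
    helix_pair: tuple[int, int],
    reference: Structure,
    core,
    chain: str = "A",
) -> SwingAngleSeries:
    """Angle between the frame helix vector and the reference helix vector.

    ``helix_pair`` is ``(res_from, res_to)`` at Calpha (K305 -> E293 for
    LFA-1).  Each frame's stable core is superposed onto the reference
    core first; only the rotation part matters for the angle, which makes
    the observable invariant under any rigid motion of the frame.
    """
    core = SelectionSpec.coerce(core)
    topology = trajectory.topology
    res_from, res_to = helix_pair
    idx_from = topology.atom_index(chain, int(res_from), "CA")
    idx_to = topology.atom_index(chain, int(res_to), "CA")
    ref_from = reference.coords[reference.atom_index(chain, int(res_from), "CA")]
    ref_to = reference.coords[reference.atom_index(chain, int(res_to), "CA")]
    v_ref = ref_to - ref_from
    norm_ref = np.linalg.norm(v_ref)
    if norm_ref < 1e-9:
        raise ValueError("reference helix vector has zero length")
    core_t, core_r = paired_indices(core, topology, reference)
    ref_core = reference.coords[core_r]

    angles = np.empty(trajectory.n_frames)
    for i, frame in enumerate(trajectory.frames):
        fit = kabsch(frame[core_t], ref_core)
        v = fit.rotation @ (frame[idx_to] - frame[idx_from])
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError(f"frame {i}: helix vector has zero length")
        cosine = np.clip(np.dot(v, v_ref) / (norm * norm_ref), -1.0, 1.0)
        angles[i] = np.degrees(np.arccos(cosine))
    return SwingAngleSeries(
        times=trajectory.times, angles_deg=angles, helix_pair=(int(res_from), int(res_to))
    )


@dataclass
class SeparationTrace:
    """Ion-to-ligand-carboxylate distance vs. time, with pulling metadata."""

    times: np.ndarray
    distances: np.ndarray
    force_pn: float | None = None
    pulled_atom: str | None = None
    fixed_atom: str | None = None
    label: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if len(self.times) != len(self.distances):
            raise ValueError("times and distances differ in length")
        if len(self.times) == 0:
            raise ValueError("empty separation trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.distances[np.isfinite(self.distances)] <= 0):
            raise ValueError("distances must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "distance_A": self.distances})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, **metadata) -> "SeparationTrace":
        frame = pd.read_csv(path)
        missing = {"time_ns", "distance_A"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        return cls(
            times=frame["time_ns"].to_numpy(),
            distances=frame["distance_A"].to_numpy(),
            **metadata,
        )


def separation_trace(
    trajectory: Trajectory,
    ligand_residue: tuple[str, int],
    ion=None,
    force_pn: float | None = None,
    pulled_atom: str | None = None,
    fixed_atom: str | None = None,
) -> SeparationTrace:
    """Per-frame minimum ion-to-carboxylate-oxygen distance.

    The ligand residue must be Asp or Glu; the distance is the minimum
    over whichever of its carboxylate oxygens (OD1/OD2 or OE1/OE2) are
    present, so relabelling the two chemically equivalent oxygens cannot
    change the trace.
    """
    topology = trajectory.topology
    if ion is None:
        ion_index = find_midas_ion(topology)
    elif isinstance(ion, Selection):
        if len(ion) != 1:
            raise SelectionError(f"ion selection must resolve to 1 atom, got {len(ion)}")
        ion_index = int(ion.indices[0])
    else:
        ion_index = int(ion)
    chain, res_id = str(ligand_residue[0]), int(ligand_residue[1])
    res_mask = (topology.chain == chain) & (topology.res_id == res_id)
    if not res_mask.any():
        raise SelectionError(f"no ligand residue {chain}:{res_id}")
    res_name = str(topology.res_name[res_mask][0])
    oxygen_names = CARBOXYLATE_OXYGENS.get(res_name)
    if oxygen_names is None:
        raise SelectionError(
            f"ligand residue {res_name} {chain}:{res_id} is not Asp/Glu "
            f"(no carboxylate side chain)"
        )
    oxy = np.flatnonzero(res_mask & np.isin(topology.name, oxygen_names))
    if oxy.size == 0:
        raise SelectionError(
            f"ligand residue {res_name} {chain}:{res_id} lacks carboxylate oxygens"
        )
    diffs = trajectory.frames[:, oxy, :] - trajectory.frames[:, [ion_index], :]
    distances = np.min(np.linalg.norm(diffs, axis=2), axis=1)
    return SeparationTrace(
        times=trajectory.times,
        distances=distances,
        force_pn=force_pn,
        pulled_atom=pulled_atom,
        fixed_atom=fixed_atom,
        label=f"{res_name}{res_id}",
    )
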