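"""Rigid-body superposition and the three RMSD observables.

Three observables are built on one least-squares fit primitive:

* **global RMSD** -- fit a backbone selection onto the reference and report
  the RMSD of that same selection (fit = measure); quantifies whole-domain
  stability against the run's own crystal reference.
* **per-residue RMSD** -- one global backbone fit per frame, then each
  residue's backbone RMSD measured in that common frame and averaged over
  time; flags the unstable residues.
* **segment RMSD vs. multiple references** -- fit a configured *stable
  core* onto each named crystal reference (low/intermediate/high-affinity
  state) and measure a segment (the alpha7 helix) *without refitting*; the
  segment's displacement relative to the core is the signal that tells the
  affinity states apart, so refitting the segment would destroy it.

RMSD is plain coordinate RMSD over the selected heavy atoms, unweighted:
the backbone atoms have near-equal masses and mass weighting would change
nothing qualitative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import (
    BACKBONE_ATOMS,
    SelectionError,
    SelectionSpec,
    Structure,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "SuperpositionResult",
    "RMSDSeries",
    "PerResidueRMSD",
    "kabsch",
    "coordinate_rmsd",
    "paired_indices",
    "global_rmsd",
    "per_residue_rmsd",
    "segment_rmsd_vs_references",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """An optimal rigid transform: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def coordinate_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Unweighted coordinate RMSD between two equally-sized point sets."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1; reflections are never
    returned) and translation minimising the RMSD, plus that minimal
    RMSD.  Requires >= 3 points in general position: collinear point sets
    leave the rotation under-determined and are rejected.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point-count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 points of shape (n, 3)")
    centroid_mobile = mobile.mean(axis=0)
    centroid_reference = reference.mean(axis=0)
    mob = mobile - centroid_mobile
    ref = reference - centroid_reference
    if (np.linalg.matrix_rank(mob, tol=1e-8) < 2
            or np.linalg.matrix_rank(ref, tol=1e-8) < 2):
        raise ValueError("degenerate geometry: points are collinear")
    # scipy's align_vectors is the Kabsch solution with proper rotation
    # enforced.  The RMSD is recomputed from the transformed coordinates:
    # the solver's rssd loses precision to cancellation near zero.
    rotation, _ = Rotation.align_vectors(ref, mob)
    matrix = rotation.as_matrix()
    translation = centroid_reference - matrix @ centroid_mobile
    return SuperpositionResult(
        rotation=matrix,
        translation=translation,
        rmsd=coordinate_rmsd(mobile @ matrix.T + translation, reference),
    )


def paired_indices(spec, topology: Structure, reference: Structure,
                   max_drop_fraction: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Corresponding atom indices for one selection in two structures.

    Atoms are matched by ``(chain, res_id, atom name)``.  Atoms present on
    one side only are dropped from both with a warning; losing more than
    ``max_drop_fraction`` of either side is an error, because the RMSD
    would then no longer measure what the selection names.
    """
    sel_topo = resolve_selection(topology, spec)
    sel_ref = resolve_selection(reference, spec)
    ref_map = {
        (reference.chain[i], int(reference.res_id[i]), reference.name[i]): i
        for i in sel_ref.indices
    }
    idx_topo, idx_ref = [], []
    for i in sel_topo.indices:
        key = (topology.chain[i], int(topology.res_id[i]), topology.name[i])
        j = ref_map.get(key)
        if j is not None:
            idx_topo.append(i)
            idx_ref.append(j)
    n_pairs = len(idx_topo)
    dropped = max(len(sel_topo), len(sel_ref)) - n_pairs
    if dropped:
        warnings.warn(
            f"{dropped} unmatched atom(s) dropped from selection correspondence",
            stacklevel=2,
        )
        if dropped > max_drop_fraction * max(len(sel_topo), len(sel_ref)):
            raise SelectionError(
                f"correspondence mismatch: {dropped} of "
                f"{max(len(sel_topo), len(sel_ref))} atoms unmatched"
            )
    if n_pairs == 0:
        raise SelectionError("no corresponding atoms between topology and reference")
    return np.asarray(idx_topo), np.asarray(idx_ref)


@dataclass
class RMSDSeries:
    """Per-frame RMSD of one selection against one named reference."""

    reference_name: str
    times: np.ndarray
    values: np.ndarray
    fit_spec: SelectionSpec | None = None
    measure_spec: SelectionSpec | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "rmsd_A": self.values,
                "reference_name": self.reference_name,
            }
        )


@dataclass
class PerResidueRMSD:
    """Time-averaged backbone RMSD per residue (common global fit per frame)."""

    chains: np.ndarray
    res_ids: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chain": self.chains, "res_id": self.res_ids, "mean_rmsd_A": self.values}
        )


def segment_rmsd_vs_references(
    trajectory: Trajectory,
    references: Mapping[str, Structure],
    core,
    segment,
) -> list[RMSDSeries]:
    """Core-aligned segment RMSD against each named reference.

    For every frame and every reference: superpose the *core* selection of
    the frame onto the reference core, then report the RMSD of the
    *segment* selection in that core frame -- no refit on the segment.
    A trajectory of a structure whose segment sits at the low-affinity
    position therefore reads ~0 against the low-affinity reference and
    reads the full segment displacement against the high-affinity one.
    """
    core = SelectionSpec.coerce(core)
    segment = SelectionSpec.coerce(segment)
    topology = trajectory.topology
    out: list[RMSDSeries] = []
    times = trajectory.times
    for name, reference in references.items():
        core_t, core_r = paired_indices(core, topology, reference)
        seg_t, seg_r = paired_indices(segment, topology, reference)
        ref_core = reference.coords[core_r]
        ref_seg = reference.coords[seg_r]
        values = np.empty(trajectory.n_frames)
        for i, frame in enumerate(trajectory.frames):
            fit = kabsch(frame[core_t], ref_core)
            values[i] = coordinate_rmsd(fit.apply(frame[seg_t]), ref_seg)
        out.append(
            RMSDSeries(
                reference_name=name,
                times=times.copy(),
                values=values,
                fit_spec=core,
                measure_spec=segment,
            )
        )
    return out


def global_rmsd(trajectory: Trajectory, reference: Structure, selection,
                reference_name: str | None = None) -> RMSDSeries:
    """Whole-selection RMSD per frame, fit and measure on the same selection.

    Implemented as the fit = measure special case of
    :func:`segment_rmsd_vs_references`, so the two observables are
    arithmetically identical whenever segment and core coincide.
    """
    if reference_name is None:
        reference_name = reference.metadata.get("name", "reference")
    [series] = segment_rmsd_vs_references(
        trajectory, {reference_name: reference}, core=selection, segment=selection
    )
    return series


def per_residue_rmsd(
    trajectory: Trajectory,
    reference: Structure,
    fit_selection,
    measure_selection=None,
) -> PerResidueRMSD:
    """Average backbone RMSD of each residue over time.

    One fit per frame on ``fit_selection`` (typically the full backbone),
    then each residue of ``measure_selection`` is measured in that common
    frame; per-residue values are averaged over frames.  Default measure
    selection: backbone atoms of every residue in the fit chain.
    """
    fit_selection = SelectionSpec.coerce(fit_selection)
    if measure_selection is None:
        measure_selection = SelectionSpec(
            chain=fit_selection.chain, atom_names=BACKBONE_ATOMS
        )
    else:
        measure_selection = SelectionSpec.coerce(measure_selection)
    topology = trajectory.topology
    fit_t, fit_r = paired_indices(fit_selection, topology, reference)
    meas_t, meas_r = paired_indices(measure_selection, topology, reference)
    ref_fit = reference.coords[fit_r]
    ref_meas = reference.coords[meas_r]

    keys = [(topology.chain[i], int(topology.res_id[i])) for i in meas_t]
    order: dict[tuple[str, int], list[int]] = {}
    for pos, key in enumerate(keys):
        order.setdefault(key, []).append(pos)
    residues = list(order)
    groups = [np.asarray(order[key]) for key in residues]

    acc = np.zeros(len(residues))
    for frame in trajectory.frames:
        fit = kabsch(frame[fit_t], ref_fit)
        moved = fit.apply(frame[meas_t])
        sq = np.sum((moved - ref_meas) ** 2, axis=1)
        for j, group in enumerate(groups):
            acc[j] += np.sqrt(np.mean(sq[group]))
    acc /= trajectory.n_frames
    return PerResidueRMSD(
        chains=np.asarray([c for c, _ in residues]),
        res_ids=np.asarray([r for _, r in residues]),
        values=acc,
    )
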