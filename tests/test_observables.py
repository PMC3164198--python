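import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import idomain as idm
from idomain.observables import (
    SeparationTrace,
    coordination_spheres,
    junction_distances,
    separation_trace,
    swing_angle,
)
from idomain.structure_io import SelectionError, Structure, Trajectory
from idomain.synthetic import TemplateSpec, core_spec, make_template


def build_midas_geometry(residue_specs, ion_pos=(0.0, 0.0, 0.0)):
    """A minimal structure: ion + residues with oxygens at given distances.

    residue_specs: list of (res_id, res_name, oxygen_name -> distance dict).
    Oxygens are placed along distinct directions from the ion.
    """
    names, elements, res_names, res_ids, chains, coords, hetero = (
        [], [], [], [], [], [], []
    )
    directions = Rotation.from_euler(
        "zyz",
        [[37.0 * k, 63.0 * k % 180, 11.0 * k] for k in range(40)],
        degrees=True,
    ).apply(np.array([1.0, 0.0, 0.0]))
    ion = np.asarray(ion_pos)
    k = 0
    for res_id, res_name, oxygens in residue_specs:
        # backbone stub so the residue exists
        for name, offset in (("CA", 8.0), ("CB", 7.0)):
            names.append(name)
            elements.append("C")
            res_names.append(res_name)
            res_ids.append(res_id)
            chains.append("A")
            coords.append(ion + directions[k % 40] * offset + res_id * 0.01)
            hetero.append(False)
        for oxygen_name, distance in oxygens.items():
            names.append(oxygen_name)
            elements.append("O")
            res_names.append(res_name)
            res_ids.append(res_id)
            chains.append("A")
            coords.append(ion + directions[k % 40] * distance)
            hetero.append(False)
            k += 1
    names.append("CA")
    elements.append("CA")
    res_names.append("CA")
    res_ids.append(900)
    chains.append("A")
    coords.append(ion)
    hetero.append(True)
    return Structure(
        name=names, element=elements, res_name=res_names, res_id=res_ids,
        chain=chains, coords=np.asarray(coords), hetero=hetero,
    )


class TestCoordinationSpheres:
    def test_cutoff_boundary_and_min_rule(self):
        frame = build_midas_geometry(
            [
                (1, "SER", {"OG": 3.40}),
                (2, "ASP", {"OD1": 3.60, "OD2": 4.50}),
                (3, "ASP", {"OD1": 3.49, "OD2": 3.51}),
            ]
        )
        assign = coordination_spheres(frame, [1, 2, 3])
        assert assign.labels[("A", 1)] == "primary"
        assert assign.labels[("A", 2)] == "secondary"
        # min over the two oxygens decides: 3.49 <= 3.5
        assert assign.labels[("A", 3)] == "primary"
        assert abs(assign.min_distances[("A", 3)] - 3.49) < 1e-9

    def test_la_crystal_pattern_on_template(self, la_template):
        assign = coordination_spheres(la_template, [137, 139, 141, 206, 239])
        assert sorted(r for _, r in assign.primary()) == [139, 141, 239]
        assert sorted(r for _, r in assign.secondary()) == [137, 206]

    def test_candidate_without_sidechain_oxygen_is_named_in_error(self, la_template):
        with pytest.raises(SelectionError, match="ALA A:170"):
            coordination_spheres(la_template, [170])

    def test_partition_every_candidate_labelled_once(self, la_template):
        candidates = [137, 139, 141, 144, 206, 239, 241]
        assign = coordination_spheres(la_template, candidates)
        assert len(assign.primary()) + len(assign.secondary()) == len(candidates)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        distance=st.floats(2.0, 5.0),
        low_cutoff=st.floats(2.5, 4.5),
        delta=st.floats(0.0, 1.0),
    )
    def test_raising_cutoff_never_demotes_primary(self, distance, low_cutoff, delta):
        frame = build_midas_geometry([(1, "SER", {"OG": distance})])
        low = coordination_spheres(frame, [1], cutoff=low_cutoff)
        high = coordination_spheres(frame, [1], cutoff=low_cutoff + delta)
        if low.labels[("A", 1)] == "primary":
            assert high.labels[("A", 1)] == "primary"


class TestJunctionDistances:
    def test_exact_distance_and_symmetry(self, la_template, ha_template):
        traj = Trajectory(la_template, la_template.coords[None], 0.1)
        forward = junction_distances(traj, [(153, 292)])
        backward = junction_distances(traj, [(292, 153)])
        assert abs(forward.distances[0, 0] - 10.0) < 1e-9
        np.testing.assert_allclose(forward.distances, backward.distances)
        ha = junction_distances(
            Trajectory(ha_template, ha_template.coords[None], 0.1), [(153, 292)]
        )
        assert abs(ha.distances[0, 0] - 5.0) < 1e-9

    def test_linear_ramp_then_plateau(self, la_template, ha_template):
        ramp = np.linspace(0, 1, 11)
        frames = [
            (1 - f) * la_template.coords + f * ha_template.coords for f in ramp
        ] + [ha_template.coords] * 4
        traj = Trajectory(la_template, np.asarray(frames), 0.1)
        junction = junction_distances(traj, [(161, 299)])
        values = junction.distances[0]
        assert abs(values[0] - 10.0) < 1e-9
        assert abs(values[-1] - 5.0) < 1e-9
        np.testing.assert_allclose(values[11:], values[11], atol=1e-9)

    def test_glycine_pair_rejected(self, la_template):
        # build a copy where residue 153 pretends to be Gly without CB
        keep = ~(
            (la_template.res_id == 153) & (la_template.name == "CB")
        )
        stripped = Structure(
            name=la_template.name[keep], element=la_template.element[keep],
            res_name=la_template.res_name[keep], res_id=la_template.res_id[keep],
            chain=la_template.chain[keep], coords=la_template.coords[keep],
            hetero=la_template.hetero[keep],
        )
        traj = Trajectory(stripped, stripped.coords[None], 0.1)
        with pytest.raises(SelectionError, match="no CB"):
            junction_distances(traj, [(153, 292)])


class TestSwingAngle:
    def test_reference_frame_reads_zero(self, la_template, core):
        traj = Trajectory(la_template, la_template.coords[None], 0.1)
        series = swing_angle(traj, (305, 293), la_template, core)
        assert abs(series.angles_deg[0]) < 1e-6

    @pytest.mark.parametrize("angle", [10.0, 37.0, 90.0])
    def test_constructed_rotation_recovered_exactly(self, la_template, core, angle):
        mobile = (la_template.res_id >= 292) & (la_template.res_id <= 305) \
            & ~la_template.hetero
        pivot = la_template.coords[la_template.atom_index("A", 293, "CA")]
        rotation = Rotation.from_rotvec(np.radians(angle) * np.array([1.0, 0.0, 0.0]))
        frame = la_template.coords.copy()
        frame[mobile] = rotation.apply(frame[mobile] - pivot) + pivot
        traj = Trajectory(la_template, frame[None], 0.1)
        series = swing_angle(traj, (305, 293), la_template, core)
        assert abs(series.angles_deg[0] - angle) < 1e-6

    def test_invariant_under_global_rigid_motion(self, la_template, core, rng):
        mobile = (la_template.res_id >= 292) & (la_template.res_id <= 305) \
            & ~la_template.hetero
        pivot = la_template.coords[la_template.atom_index("A", 293, "CA")]
        rotation = Rotation.from_rotvec(np.radians(25.0) * np.array([1.0, 0.0, 0.0]))
        frame = la_template.coords.copy()
        frame[mobile] = rotation.apply(frame[mobile] - pivot) + pivot
        global_rot = Rotation.random(rng=rng).as_matrix()
        moved = frame @ global_rot.T + np.array([30.0, -12.0, 7.0])
        series = swing_angle(
            Trajectory(la_template, moved[None], 0.1), (305, 293), la_template, core
        )
        assert abs(series.angles_deg[0] - 25.0) < 1e-6


class TestSeparationTrace:
    def test_min_over_carboxylate_oxygens(self):
        ligated = make_template(TemplateSpec(state="LA", include_ligand=True))
        traj = Trajectory(ligated, ligated.coords[None], 0.01)
        trace = separation_trace(traj, ("B", 34))
        ion = ligated.coords[idm.find_midas_ion(ligated)]
        oe1 = ligated.coords[ligated.atom_index("B", 34, "OE1")]
        oe2 = ligated.coords[ligated.atom_index("B", 34, "OE2")]
        expected = min(np.linalg.norm(oe1 - ion), np.linalg.norm(oe2 - ion))
        assert abs(trace.distances[0] - expected) < 1e-9
        assert abs(trace.distances[0] - 2.2) < 1e-9

    def test_swapping_oxygen_labels_leaves_trace_unchanged(self):
        ligated = make_template(TemplateSpec(state="LA", include_ligand=True))
        swapped_names = ligated.name.copy()
        i1 = ligated.atom_index("B", 34, "OE1")
        i2 = ligated.atom_index("B", 34, "OE2")
        swapped_names[i1], swapped_names[i2] = "OE2", "OE1"
        swapped = Structure(
            name=swapped_names, element=ligated.element, res_name=ligated.res_name,
            res_id=ligated.res_id, chain=ligated.chain, coords=ligated.coords,
            hetero=ligated.hetero,
        )
        a = separation_trace(Trajectory(ligated, ligated.coords[None], 0.01), ("B", 34))
        b = separation_trace(Trajectory(swapped, swapped.coords[None], 0.01), ("B", 34))
        np.testing.assert_allclose(a.distances, b.distances)

    def test_non_acidic_ligand_rejected(self, la_template):
        traj = Trajectory(la_template, la_template.coords[None], 0.01)
        with pytest.raises(SelectionError, match="not Asp/Glu"):
            separation_trace(traj, ("A", 170))

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            SeparationTrace(times=[0.0, 0.0, 0.1], distances=[2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            SeparationTrace(times=[0.0, 0.1], distances=[2.0, -1.0])
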