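"""Contact detection: grid vs brute force, accumulation, frequency maps."""

import numpy as np
import pandas as pd
import pytest

from conftest import hand_system
from lipidsites import (
    brute_force_pairs,
    cutoff_sensitivity,
    find_contacts,
    frequency_map,
    periodic_pairs,
    scan_contacts,
)
from lipidsites.contacts import ContactTable
from lipidsites.system import Trajectory


def test_strict_inequality_at_the_cutoff():
    a = np.array([[0.0, 0.0, 0.0]])
    box = np.array([10.0, 10.0, 10.0])
    b = np.array([[0.4, 0.0, 0.0], [0.5, 0.0, 0.0], [0.6, 0.0, 0.0]])
    pairs = periodic_pairs(a, b, box, 0.5)
    assert pairs.tolist() == [[0, 0]]          # exactly 0.5 nm is excluded


def test_minimum_image_wraps_across_the_box():
    box = np.array([10.0, 8.0, 6.0])
    a = np.array([[0.1, 0.1, 0.1]])
    b = np.array([[9.8, 7.9, 5.9]])            # 0.3/0.2/0.2 away through faces
    pairs = periodic_pairs(a, b, box, 0.5)
    assert len(pairs) == 1


def test_cutoff_validation():
    box = np.array([1.0, 1.0, 1.0])
    pts = np.zeros((1, 3))
    with pytest.raises(ValueError, match="half the smallest box"):
        periodic_pairs(pts, pts, box, 0.6)
    with pytest.raises(ValueError, match="positive"):
        periodic_pairs(pts, pts, box, -0.1)


@pytest.mark.parametrize("seed,na,nb,cutoff,box", [
    (0, 200, 300, 0.5, (10, 10, 10)),
    (1, 500, 500, 1.0, (8, 12, 6)),
    (2, 50, 400, 0.9, (2.0, 2.0, 2.0)),     # few cells: dedupe path
    (3, 100, 100, 0.3, (3.0, 9.0, 1.2)),
])
def test_grid_equals_bruteforce(seed, na, nb, cutoff, box):
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    a = rng.uniform(-5, 15, (na, 3))           # includes out-of-box coords
    b = rng.uniform(-5, 15, (nb, 3))
    got = periodic_pairs(a, b, box, cutoff)
    want = brute_force_pairs(a, b, box, cutoff)
    assert np.array_equal(got, want)


def test_empty_inputs_give_empty_pairs():
    box = np.array([5.0, 5.0, 5.0])
    assert len(periodic_pairs(np.empty((0, 3)), np.zeros((3, 3)), box, 0.5)) == 0


def _schedule_system_traj():
    """Two single-bead lipids and one protein bead with a scripted schedule:
    lipid 0 contacts in frames 0 and 2, lipid 1 only in frame 1."""
    system = hand_system(n_lipids=2)
    box = np.array([10.0, 10.0, 10.0])
    far = np.array([5.0, 5.0, 5.0])
    near = np.array([0.3, 0.0, 0.0])
    coords = np.zeros((3, system.n_beads, 3))
    coords[:, 1] = far
    coords[:, 2] = far + 2.0
    coords[0, 1] = near
    coords[2, 1] = near
    coords[1, 2] = near
    return system, Trajectory(coordinates=coords, box=np.tile(box, (3, 1)))


def test_scripted_contact_schedule_recovered():
    system, traj = _schedule_system_traj()
    table = scan_contacts(traj, system, 0.5)
    assert table.residue_totals().tolist() == [3]
    assert table.events.tolist() == [[True, False], [False, True],
                                     [True, False]]


def test_repeating_a_frame_scales_counts_linearly():
    system, traj = _schedule_system_traj()
    rep = Trajectory(coordinates=np.tile(traj.coordinates, (10, 1, 1)),
                     box=np.tile(traj.box, (10, 1)))
    t1 = scan_contacts(traj, system, 0.5)
    t10 = scan_contacts(rep, system, 0.5)
    for sp in t1.counts:
        assert np.array_equal(t10.counts[sp], 10 * t1.counts[sp])


def test_scan_matches_per_frame_search(small_run):
    """The trajectory scanner (fast path) is contractually identical to the
    frame-by-frame grid search."""
    system, traj, truth = small_run
    sub = Trajectory(coordinates=traj.coordinates[:15], box=traj.box[:15])
    table = scan_contacts(sub, system, 0.5)
    pid, lid = system.protein_indices, system.lipid_indices
    total = 0
    events = np.zeros((15, system.n_lipids), dtype=bool)
    for f in range(15):
        pairs = find_contacts(sub.coordinates[f], sub.box[f], pid, lid, 0.5)
        total += len(pairs)
        for lip in np.unique(system.lipid_ids[pairs[:, 1]]):
            events[f, lip] = True
    assert int(table.residue_totals().sum()) == total
    assert np.array_equal(table.events, events)


def test_scan_generic_path_matches_static_path(small_run):
    """Jittering the protein between frames disables the static fast path;
    the generic minimum-image route gives identical results when the
    jitter is zero-sized in a copied trajectory."""
    system, traj, truth = small_run
    sub_coords = np.array(traj.coordinates[:10], dtype=np.float64)
    jitter = sub_coords.copy()
    # move the protein rigidly in frame 0 only, then move it back: the
    # chunk is no longer static but frame contents are unchanged for f>0
    sub = Trajectory(coordinates=sub_coords, box=traj.box[:10])
    t_static = scan_contacts(sub, system, 0.5)
    jitter[0, system.protein_indices] += 1e-9
    t_generic = scan_contacts(
        Trajectory(coordinates=jitter, box=traj.box[:10]), system, 0.5)
    assert np.array_equal(t_static.events[1:], t_generic.events[1:])
    assert abs(int(t_static.residue_totals().sum())
               - int(t_generic.residue_totals().sum())) <= 0


def test_frequency_map_normalisation():
    system, traj = _schedule_system_traj()
    table = scan_contacts(traj, system, 0.5)
    fm = frequency_map(table)
    assert fm["frequency_pct"].max() == 100.0
    # single contacting residue -> that residue is 100%
    assert fm.loc[fm["count"].idxmax(), "frequency_pct"] == 100.0


def test_all_zero_table_warns_and_maps_to_zero(caplog):
    import logging
    system = hand_system(n_lipids=1)
    coords = np.zeros((2, system.n_beads, 3))
    coords[:, 1] = [5.0, 5.0, 5.0]
    traj = Trajectory(coordinates=coords, box=np.tile([10.0, 10, 10], (2, 1)))
    table = scan_contacts(traj, system, 0.5)
    with caplog.at_level(logging.WARNING):
        fm = frequency_map(table)
    assert (fm["frequency_pct"] == 0).all()
    assert "all-zero" in caplog.text


def test_per_class_aggregation_sums_to_residue_total(biased_run):
    system, traj, truth = biased_run
    sub = Trajectory(coordinates=traj.coordinates[:50], box=traj.box[:50])
    table = scan_contacts(sub, system, 0.5)
    per_class = table.per_class_counts("POPC")
    assert per_class.sum() == table.residue_totals().sum()
    assert set(per_class.index) <= {"head", "phosphate", "glycerol",
                                    "tailA", "tailB"}


def test_counts_monotone_in_cutoff(biased_run, helices):
    system, traj, truth = biased_run
    sub = Trajectory(coordinates=traj.coordinates[:60], box=traj.box[:60])
    maps, agreement = cutoff_sensitivity(sub, system, (0.5, 0.6, 0.7),
                                         helices=helices)
    c5 = maps[0.5]["count"].to_numpy()
    c6 = maps[0.6]["count"].to_numpy()
    c7 = maps[0.7]["count"].to_numpy()
    assert np.all(c6 >= c5) and np.all(c7 >= c6)
    assert ((maps[0.5]["frequency_pct"] >= 0)
            & (maps[0.5]["frequency_pct"] <= 100)).all()
    assert not agreement["spearman_rho"].isna().any()


def test_unsorted_cutoffs_rejected(small_run):
    system, traj, truth = small_run
    with pytest.raises(ValueError, match="ascending"):
        cutoff_sensitivity(traj, system, (0.7, 0.5))


def test_merge_pools_replicates(small_run):
    system, traj, truth = small_run
    half1 = Trajectory(coordinates=traj.coordinates[:20], box=traj.box[:20])
    half2 = Trajectory(coordinates=traj.coordinates[20:], box=traj.box[20:])
    t1 = scan_contacts(half1, system, 0.5)
    t2 = scan_contacts(half2, system, 0.5)
    whole = scan_contacts(traj, system, 0.5)
    merged = ContactTable.merge([t1, t2])
    for sp in whole.counts:
        assert np.array_equal(merged.counts[sp], whole.counts[sp])
    assert np.array_equal(merged.events, whole.events)
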