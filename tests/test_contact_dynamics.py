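import numpy as np
import pytest

from clampkit.contact_dynamics import (Contact, ContactCriteria,
                                       ContactTimeline, PullingRun,
                                       NEVER_FORMED, UNBROKEN, breakup_map,
                                       breakup_time, build_timelines,
                                       classify_contacts, classify_pathway,
                                       contact_present, reformation_screen)


@pytest.fixture(scope="module")
def classified(toy_interface):
    s, _, spec, gt = toy_interface
    pairs = {(a, b): -2.0 for a, b, _, _ in gt}
    contacts = classify_contacts(s, pairs, ContactCriteria(), interface=spec)
    by_class = {}
    for c in contacts:
        by_class.setdefault(c.contact_class, []).append(c)
    return s, spec, gt, contacts, by_class


class TestClassifyContacts:
    def test_every_planted_class_recovered(self, classified):
        _, _, gt, contacts, _ = classified
        found = {(c.residue_a, c.residue_b): c.contact_class for c in contacts}
        for res_a, res_b, cls, _ in gt:
            assert found[(res_a, res_b)] == cls

    def test_salt_bridge_beats_hbond_precedence(self, classified):
        # Glu carboxylate O vs Lys side-chain N within H-bond range must
        # classify as salt bridge even though it also satisfies donor/acceptor
        _, _, _, _, by_class = classified
        sb = by_class["salt_bridge"][0]
        names = {sb.residue_a[0], sb.residue_b[0]}
        assert names == {"A", "B"}

    def test_axis_fractions_near_plan(self, classified):
        _, _, gt, contacts, _ = classified
        targets = {(a, b): t for a, b, _, t in gt}
        for c in contacts:
            assert abs(c.axis_fraction - targets[(c.residue_a, c.residue_b)]) <= 0.05

    def test_same_chain_pair_rejected(self, classified):
        s = classified[0]
        with pytest.raises(ValueError, match="within one subunit"):
            classify_contacts(s, {(("A", 1), ("A", 2)): -2.0})


class TestContactPresent:
    def make_hbond(self, d, tilt_deg):
        """Donor N at origin with one H (bond 1.0 A, tilted ``tilt_deg``
        off the N->O axis), acceptor O at distance d along +x.  Returns the
        system, the contact, and the D-H...A deviation from linearity
        computed directly from the geometry (the in-test oracle)."""
        from test_energetics import make_atoms

        theta = np.radians(tilt_deg)
        h = np.array([np.cos(theta), np.sin(theta), 0.0])
        o = np.array([d, 0.0, 0.0])
        s = make_atoms([
            ("N", "N", "A", (0, 0, 0), -0.4, 1.55, 1.824, 0.17),
            ("H", "H", "A", tuple(h), 0.3, 1.2, 0.6, 0.0157),
            ("O", "O", "B", tuple(o), -0.5, 1.5, 1.6612, 0.21),
        ])
        contact = Contact(residue_a=("A", 1), residue_b=("B", 1),
                          contact_class="sidechain_hbond",
                          atoms_a=(0,), atoms_b=(2,), hydrogens={0: (1,)})
        hd, ha = -h, o - h
        cosang = hd @ ha / (np.linalg.norm(hd) * np.linalg.norm(ha))
        deviation = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        return s, contact, deviation

    @pytest.mark.parametrize("d,tilt", [
        (3.2, 0.0), (3.2, 30.0), (3.2, 40.0), (3.0, 55.0), (3.0, 75.0),
    ])
    def test_presence_matches_geometry_oracle(self, d, tilt):
        s, c, deviation = self.make_hbond(d, tilt)
        expected = d <= 3.3 and deviation <= 50.0
        assert contact_present(s, s.positions, c) == expected

    def test_within_distance_and_moderate_deviation_present(self):
        s, c, deviation = self.make_hbond(3.2, 30.0)
        assert 20.0 < deviation <= 50.0  # bent but acceptable
        assert contact_present(s, s.positions, c)

    def test_distance_cutoff_is_strict(self):
        s, c, deviation = self.make_hbond(3.4, 0.0)
        assert deviation < 1e-9
        assert not contact_present(s, s.positions, c)

    def test_hydrogen_free_contact_uses_distance_only(self):
        s, c, deviation = self.make_hbond(3.2, 75.0)
        assert deviation > 50.0
        import dataclasses
        no_h = dataclasses.replace(c, hydrogens={})
        assert contact_present(s, s.positions, no_h)
        assert not contact_present(s, s.positions, c)

    def test_hydrophobic_pair_breaks_when_separated(self, classified):
        s, _, _, _, by_class = classified
        c = by_class["hydrophobic"][0]
        assert contact_present(s, s.positions, c)
        moved = s.positions.copy()
        moved[list(c.atoms_b)] += np.array([10.0, 0, 0])
        assert not contact_present(s, moved, c)

    def test_rigid_transform_invariance(self, classified):
        from scipy.spatial.transform import Rotation

        s, _, _, contacts, _ = classified
        R = Rotation.from_rotvec([0.3, 0.9, -0.5]).as_matrix()
        moved = s.positions @ R.T + np.array([3.0, -8.0, 1.0])
        for c in contacts:
            assert contact_present(s, moved, c) == contact_present(
                s, s.positions, c)


class TestBreakupTime:
    def make_timeline(self, presence, dt=10.0):
        c = Contact(residue_a=("A", 1), residue_b=("B", 1),
                    contact_class="polar_proximal", atoms_a=(0,), atoms_b=(1,))
        times = dt * np.arange(1, len(presence) + 1)
        return ContactTimeline(contact=c, times=times,
                               present=np.array(presence, dtype=bool))

    def test_last_occurrence_after_reforming(self):
        tl = self.make_timeline([1, 1, 0, 1, 0, 0])
        assert breakup_time(tl) == 40.0

    def test_never_formed_flag(self):
        assert breakup_time(self.make_timeline([0, 0, 0])) == NEVER_FORMED

    def test_unbroken_flag_at_trajectory_end(self):
        tl = self.make_timeline([1] * 1200, dt=10.0)
        assert breakup_time(tl) == (12000.0, UNBROKEN)


def scripted_run(schedule, n_frames=120, dt=10.0):
    """PullingRun from (axis_fraction, last_present_frame, reform) specs."""
    timelines = []
    for k, item in enumerate(schedule):
        frac, last = item[:2]
        present = np.zeros(n_frames, dtype=bool)
        present[:last + 1] = True
        for a, b in (item[2] if len(item) > 2 else []):
            present[a:b] = False
        c = Contact(residue_a=("A", k + 1), residue_b=("B", n_frames - k),
                    contact_class="polar_proximal", atoms_a=(0,), atoms_b=(1,),
                    axis_fraction=frac)
        timelines.append(ContactTimeline(
            contact=c, times=dt * np.arange(1, n_frames + 1), present=present))
    return PullingRun(timelines=timelines)


class TestReformationScreen:
    def test_monotone_rupture_retained(self):
        run = scripted_run([(0.2, 30), (0.5, 40), (0.8, 50)])
        assert reformation_screen(run) == "retained"

    def test_substantial_reformation_excluded(self):
        # all contacts gone by frame 51, then 2 of 5 (40%) re-form for
        # frames 60..110 (510 ps >= the 500 ps window)
        sched = [(0.1, 40), (0.3, 45), (0.5, 50),
                 (0.7, 110, [(51, 60)]), (0.9, 110, [(51, 60)])]
        run = scripted_run(sched)
        assert reformation_screen(run) == "excluded_reforming"

    def test_boundary_thirty_percent_for_window_is_excluded(self):
        # exactly 30% of contacts re-form for exactly the 500 ps window;
        # the >= comparisons on both fraction and window must exclude it
        sched = [(0.1, 50), (0.2, 55), (0.3, 60), (0.4, 65),
                 (0.5, 70), (0.6, 74), (0.7, 78),
                 (0.95, 149, [(80, 100)]),
                 (0.55, 149, [(80, 100)]), (0.45, 149, [(80, 100)])]
        run = scripted_run(sched, n_frames=200)
        # 3/10 contacts present frames 100..149 = 500 ps
        assert reformation_screen(run, reform_fraction=0.30,
                                  window=500.0) == "excluded_reforming"
        # one frame shorter than the window -> retained
        sched2 = sched[:-3] + [(f, 148, [(80, 100)]) for f in (0.95, 0.55, 0.45)]
        run2 = scripted_run(sched2, n_frames=200)
        assert reformation_screen(run2, reform_fraction=0.30,
                                  window=500.0) == "retained"

    def test_empty_run_errors(self):
        with pytest.raises(ValueError):
            reformation_screen(PullingRun(timelines=[]))


class TestClassifyPathway:
    def test_early_top_break_is_top_down(self):
        run = scripted_run([(0.9, 10), (0.8, 20), (0.2, 70), (0.1, 80)])
        assert classify_pathway(run) == "top_down"

    def test_mirrored_schedule_is_bottom_up(self):
        run = scripted_run([(0.1, 10), (0.2, 20), (0.8, 70), (0.9, 80)])
        assert classify_pathway(run) == "bottom_up"

    def test_margin_is_strict_at_exact_separation(self):
        # half-means exactly 500 ps apart: no direction declared
        run = scripted_run([(0.9, 14), (0.2, 64)])  # 150 ps vs 650 ps
        assert classify_pathway(run) == "concerted"

    def test_tight_schedule_is_concerted(self):
        # all break within 0.3 ns: below the 0.5 ns margin
        run = scripted_run([(0.9, 40), (0.8, 42), (0.2, 41), (0.1, 43)])
        assert classify_pathway(run) == "concerted"

    def test_never_formed_excluded_unbroken_counts_at_end(self):
        run = scripted_run([(0.9, 10), (0.8, -1), (0.2, 119), (0.1, 119)])
        # (0.8, -1) never forms; bottom contacts unbroken -> count at 1200 ps
        assert classify_pathway(run) == "top_down"

    def test_empty_half_errors(self):
        run = scripted_run([(0.9, 10), (0.8, 20)])
        with pytest.raises(ValueError, match="each half"):
            classify_pathway(run)


class TestBreakupMap:
    def test_single_run_identity_and_mean(self):
        r1 = scripted_run([(0.9, 19), (0.2, 39)])  # breaks at 200, 400 ps
        r2 = scripted_run([(0.9, 39), (0.2, 39)])
        r1.pathway_label = r2.pathway_label = "top_down"
        name = r1.timelines[0].contact.name
        single = breakup_map([r1], "top_down")
        assert single[name][0] == pytest.approx(200.0)
        both = breakup_map([r1, r2], "top_down")
        assert both[name][0] == pytest.approx(300.0)

    def test_color_clamps_at_scale_end(self):
        run = scripted_run([(0.9, 1059), (0.2, 100)], n_frames=1200)
        run.pathway_label = "top_down"
        name = run.timelines[0].contact.name
        out = breakup_map([run], "top_down")
        # 10.6 ns exceeds the 8 ns color scale -> clamped to 1.0
        assert out[name][0] == pytest.approx(10600.0)
        assert out[name][1] == 1.0

    def test_empty_class_errors(self):
        run = scripted_run([(0.9, 10)])
        run.pathway_label = "concerted"
        with pytest.raises(ValueError):
            breakup_map([run], "top_down")


class TestScriptedRoundTrip:
    def test_breakup_recovery_through_geometry(self, toy_interface):
        """Scripted trajectories must reproduce every scheduled
        last-occurrence time exactly, including break-and-reform."""
        from clampkit.synthetic_data import (RuptureScript, ScriptedContact,
                                             make_scripted_rupture)

        s, _, spec, gt = toy_interface
        pairs = {(a, b): -2.0 for a, b, _, _ in gt}
        contacts = classify_contacts(s, pairs, ContactCriteria(), interface=spec)
        entries = []
        expected = {}
        for k, c in enumerate(contacts):
            last = 100.0 + 60.0 * k
            gaps = ((40.0, 70.0),) if k % 2 else ()
            entries.append(ScriptedContact(contact=c, last_time=last, gaps=gaps))
            expected[c.name] = last
        script = RuptureScript(entries=tuple(entries), frame_spacing=10.0,
                               duration=600.0)
        frames, times = make_scripted_rupture(s, script, seed=3)
        tls = build_timelines(s, frames, times, contacts, ContactCriteria())
        for tl in tls:
            assert breakup_time(tl) == expected[tl.contact.name]
        # reform gap visible: absent then present again before final break
        gapped = [tl for tl in tls
                  if tl.contact.name == contacts[1].name][0]
        idx = np.flatnonzero(~gapped.present)
        assert gapped.present[np.flatnonzero(gapped.present)[-1]]
        assert idx[0] * 10 + 10 <= 70.0
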