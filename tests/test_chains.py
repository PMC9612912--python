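from collections import Counter

import numpy as np
import pytest

from ligpath.chains import (
    BindingChain,
    Pathway,
    association_census,
    chains_from_profiles,
    classify_mechanism,
    detect_chains,
    is_docked,
    split_chain,
)
from ligpath.core import pairwise_distances

from conftest import trajectory_from_ligand_distances


class TestChainsFromProfiles:
    def test_example_profile(self):
        # frame-by-frame oracle: association triggers at 5 A (frame 2),
        # chain survives 7 A (frame 3), dies past 10 A (frame 4)
        d = np.array([12, 8, 5, 7, 11], dtype=float)
        assert chains_from_profiles(d, d) == [(2, 3, True)]

    def test_never_associates(self):
        d = np.full(6, 10.5)
        assert chains_from_profiles(d, d) == []

    def test_unterminated_chain(self):
        d = np.array([5.0, 5.0, 5.0])
        assert chains_from_profiles(d, d) == [(0, 2, False)]

    def test_parameter_error(self):
        with pytest.raises(ValueError):
            chains_from_profiles(np.ones(3), np.ones(3), assoc_cutoff=10, dissoc_cutoff=6)

    def test_hysteresis_band(self):
        # oscillation inside (6, 10] never starts a chain...
        osc = np.array([12.0, 7.0, 9.5, 6.5, 8.0, 12.0])
        assert chains_from_profiles(osc, osc) == []
        # ...but never ends one either
        series = np.array([12.0, 5.0, 9.5, 6.5, 9.9, 11.0])
        assert chains_from_profiles(series, series) == [(1, 4, True)]

    def test_back_to_back_restart(self):
        # chain dies at frame 2 and a new one starts the same frame it
        # re-enters the association zone
        d = np.array([5.0, 5.0, 11.0, 5.5, 12.0])
        assert chains_from_profiles(d, d) == [(0, 1, True), (3, 3, True)]


class TestIsDocked:
    def test_condition1(self):
        nh1, nh2 = [0, 0, 0], [0, 2.2, 0]
        ot1 = [3.5, 0, 0]  # NH1-OT1 = 3.5
        ot2 = [3.8, 2.2, 0]  # NH2-OT2 = 3.8
        assert is_docked(nh1, nh2, ot1, ot2)

    def test_condition2_swapped(self):
        nh1, nh2 = [0, 0, 0], [0, 10, 0]
        ot2 = [3.9, 0, 0]  # NH1-OT2 = 3.9
        ot1 = [3.0, 10, 0]  # NH2-OT1 = 3.0
        assert is_docked(nh1, nh2, ot1, ot2)

    def test_one_pair_only_fails(self):
        nh1, nh2 = [0, 0, 0], [0, 10, 0]
        ot1 = [3.5, 0, 0]  # NH1-OT1 = 3.5 but NH2-OT2 = 4.5
        ot2 = [4.5, 10, 0]
        assert not is_docked(nh1, nh2, ot1, ot2)

    def test_cutoff_configurable(self):
        nh1, nh2 = [0, 0, 0], [0, 2.2, 0]
        ot1, ot2 = [4.5, 0, 0], [4.5, 2.2, 0]
        assert not is_docked(nh1, nh2, ot1, ot2, dock_cutoff=4.0)
        assert is_docked(nh1, nh2, ot1, ot2, dock_cutoff=5.0)


def _chain(start, end, docked, terminated=True, copy=0):
    n = end - start + 1
    return BindingChain(
        ligand_copy=copy,
        start_frame=start,
        end_frame=end,
        per_frame_contacts=[frozenset()] * n,
        docked_frames=frozenset(docked),
        terminated=terminated,
    )


class TestSplitChain:
    def _traj(self, n_frames):
        return trajectory_from_ligand_distances(np.linspace(1, 2, n_frames))

    def test_binding_and_unbinding(self):
        traj = self._traj(120)
        chain = _chain(10, 100, range(50, 81))
        paths = split_chain(chain, traj)
        assert [p.direction for p in paths] == ["binding", "unbinding-reversed"]
        assert paths[0].frames == list(range(10, 51))
        assert paths[1].frames == list(range(100, 79, -1))
        # stored trace is the time-reversed segment
        ref = traj.coordinates[:, 1, :]
        np.testing.assert_allclose(paths[1].trace, ref[paths[1].frames])

    def test_never_docked_discarded(self):
        assert split_chain(_chain(0, 10, []), self._traj(20)) == []

    def test_docked_at_final_frame(self):
        paths = split_chain(_chain(5, 30, [30]), self._traj(40))
        assert [p.direction for p in paths] == ["binding"]
        assert paths[0].frames[-1] == 30

    def test_unterminated_chain_no_unbinding(self):
        paths = split_chain(_chain(5, 30, [10, 11], terminated=False), self._traj(40))
        assert [p.direction for p in paths] == ["binding"]

    def test_overlap_only_at_docked_frames(self):
        chain = _chain(0, 50, [20, 21, 40])
        paths = split_chain(chain, self._traj(60))
        b, u = (set(p.frames) for p in paths)
        assert b & u <= set(chain.docked_frames)
        assert b <= set(chain.frames) and u <= set(chain.frames)


class TestClassifyMechanism:
    def _path(self, residues):
        return Pathway(
            chain_id=0, ligand_copy=0, direction="binding",
            trace=np.zeros((1, 3)), frames=[0],
            contact_residues=Counter({r: 1 for r in residues}),
        )

    def test_zero_contacts_is_free(self):
        assert classify_mechanism(self._path([500]), docking_site_residues=frozenset({500})) == "free"

    def test_many_contacts_is_guided(self):
        assert classify_mechanism(self._path(range(8))) == "guided"

    def test_threshold_one_always_guided(self):
        assert classify_mechanism(self._path([42]), min_distinct_residues=1) == "guided"


class TestDetectionOracle:
    """detect_chains must equal a literal brute-force re-implementation."""

    @staticmethod
    def brute_force(traj, copy, assoc=6.0, dissoc=10.0, dock=4.0):
        top = traj.topology
        lig = top.ligand_copies[copy]
        prot = sorted(top.protein_atom_ids)
        lp = [top.atom_index(i) for i in sorted(lig)
              if top.atom(i).is_polar and top.atom(i).is_heavy]
        lh = [top.atom_index(i) for i in sorted(lig) if top.atom(i).is_heavy]
        pp = [top.atom_index(i) for i in prot
              if top.atom(i).is_polar and top.atom(i).is_heavy]
        ph = [top.atom_index(i) for i in prot if top.atom(i).is_heavy]
        dk = top.docking_atoms[copy]
        di = [top.atom_index(i) for i in dk.as_tuple()]
        spans, start = [], None
        docked_all = set()
        for f in range(traj.n_frames):
            x = traj.coordinates[f]
            amin = min(np.linalg.norm(x[i] - x[j]) for i in lp for j in pp)
            dmin = min(np.linalg.norm(x[i] - x[j]) for i in lh for j in ph)
            if start is None and amin <= assoc:
                start = f
            elif start is not None and dmin > dissoc:
                spans.append((start, f - 1, True))
                start = f if amin <= assoc else None
            if start is not None:
                d = lambda a, b: np.linalg.norm(x[a] - x[b])
                if (d(di[0], di[2]) <= dock and d(di[1], di[3]) <= dock) or (
                    d(di[0], di[3]) <= dock and d(di[1], di[2]) <= dock
                ):
                    docked_all.add(f)
        if start is not None:
            spans.append((start, traj.n_frames - 1, False))
        return spans, docked_all

    def test_exact_frame_agreement(self, guided_sim, guided_chains):
        traj, _ = guided_sim
        for copy, chains in guided_chains.items():
            spans, docked = self.brute_force(traj, copy)
            assert [(c.start_frame, c.end_frame, c.terminated) for c in chains] == spans
            assert set().union(*[c.docked_frames for c in chains], set()) == docked

    def test_ground_truth_agreement(self, guided_sim, guided_chains):
        _, log = guided_sim
        for copy, chains in guided_chains.items():
            assert [
                (c.start_frame, c.end_frame, c.terminated) for c in chains
            ] == log.association_intervals(copy)

    def test_contact_sets_match_cutoff(self, guided_sim, guided_chains):
        traj, _ = guided_sim
        top = traj.topology
        copy, chains = next(iter(guided_chains.items()))
        lig_polar = [top.atom_index(i) for i in sorted(top.ligand_copies[copy])
                     if top.atom(i).is_polar]
        for ch in chains[:2]:
            for f in list(ch.frames)[:5]:
                x = traj.coordinates[f]
                expected = set()
                for a in top.atoms:
                    if a.atom_id in top.ligand_atom_ids or not a.is_polar:
                        continue
                    dmin = pairwise_distances(
                        x[lig_polar], x[[top.atom_index(a.atom_id)]]
                    ).min()
                    if dmin <= 6.0:
                        expected.add(a.residue_id)
                assert ch.per_frame_contacts[f - ch.start_frame] == expected


class TestCensus:
    def test_success_fraction(self):
        traj = trajectory_from_ligand_distances(np.full(1000, 50.0))
        chains = [_chain(0, 5, []), _chain(10, 15, [12]), _chain(20, 25, [])]
        c = association_census(traj, chains)
        assert c.n_associations == 3 and c.n_docked == 1
        assert c.success_fraction == pytest.approx(1 / 3)
        # conservation: associations = docked + non-docked
        assert c.n_associations == c.n_docked + sum(
            1 for ch in chains if not ch.docked
        )

    def test_residue_success_percentage(self):
        traj = trajectory_from_ligand_distances(np.full(1000, 50.0))
        chains = []
        for i in range(300):
            docked = [1] if i < 5 else []
            ch = BindingChain(
                ligand_copy=0, start_frame=0, end_frame=1,
                per_frame_contacts=[frozenset({777}), frozenset({777})],
                docked_frames=frozenset(docked), terminated=True, chain_id=i,
            )
            chains.append(ch)
        c = association_census(traj, chains)
        n, s = c.per_residue[777]
        assert (n, s) == (300, 5)
        pct = 100 * c.residue_success_probability()[777]
        assert pct == pytest.approx(1.6667, abs=1e-3)
        assert pct > 1.0  # passes the pathway-residue screen

    def test_uncontacted_residue_absent(self):
        traj = trajectory_from_ligand_distances(np.full(10, 50.0))
        c = association_census(traj, [_chain(0, 1, [])])
        assert 12345 not in c.residue_success_probability()

    def test_rates_per_microsecond(self, guided_sim, guided_chains):
        traj, _ = guided_sim
        chains = guided_chains[0]
        c = association_census(traj, chains)
        assert c.associations_per_us == pytest.approx(
            len(chains) / (traj.duration_ns / 1000.0)
        )

    def test_zero_duration_error(self):
        traj = trajectory_from_ligand_distances([50.0])
        with pytest.raises(ValueError):
            association_census(traj, [])


def test_detect_rejects_bad_cutoffs(guided_sim):
    traj, _ = guided_sim
    with pytest.raises(ValueError):
        detect_chains(traj, 0, assoc_cutoff=10.0, dissoc_cutoff=6.0)
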