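import math

import numpy as np
import pytest

from aquabridge.structure_io import (
    ACCEPTOR,
    DONOR,
    DONOR_ACCEPTOR,
    HYDROPHOBIC,
    ProteinStructure,
)
from aquabridge.water_scoring import (
    VDW_RADII,
    VINA_WEIGHTS,
    WATER_O_RADIUS,
    ScoringParams,
    assign_interaction_types,
    local_refine,
    score_water_at,
)


def make_structure(coords, elements, types=None, names=None, resnames=None):
    n = len(coords)
    return ProteinStructure(
        serial=np.arange(1, n + 1),
        name=names or ["X"] * n,
        residue_name=resnames or ["PSA"] * n,
        residue_id=np.arange(1, n + 1),
        chain=["A"] * n,
        element=list(elements),
        coords=np.asarray(coords, float).reshape(-1, 3),
        occupancy=np.ones(n),
        interaction_types=list(types) if types else [],
    )


@pytest.fixture()
def single_acceptor():
    st = make_structure([[0.0, 0.0, 0.0]], ["O"], types=[ACCEPTOR])
    return st


class TestTyping:
    def test_alanine_rules(self):
        st = make_structure(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
            ["N", "C", "O", "C"],
            names=["N", "CA", "O", "CB"],
            resnames=["ALA"] * 4,
        )
        assign_interaction_types(st)
        assert st.interaction_types == [DONOR, HYDROPHOBIC, ACCEPTOR, HYDROPHOBIC]

    def test_serine_og_is_donor_acceptor(self):
        st = make_structure([[0, 0, 0]], ["O"], names=["OG"], resnames=["SER"])
        assign_interaction_types(st)
        assert st.interaction_types == [DONOR_ACCEPTOR]

    def test_declared_types_pass_through(self):
        st = make_structure([[0, 0, 0]], ["O"], types=[DONOR])
        assign_interaction_types(st)
        assert st.interaction_types == [DONOR]

    def test_unknown_element_typed_other(self):
        from aquabridge.structure_io import OTHER

        st = make_structure([[0, 0, 0]], ["Zz"])
        assign_interaction_types(st)
        assert st.interaction_types == [OTHER]


class TestScoreWaterAt:
    def test_zero_beyond_cutoff(self, single_acceptor):
        assert score_water_at(single_acceptor, [10.0, 0, 0]) == 0.0

    def test_positive_on_clash(self, single_acceptor):
        e = score_water_at(single_acceptor, [0.0, 0.0, 0.0])
        assert e > 0

    def test_single_pair_matches_term_by_term_oracle(self, single_acceptor):
        """Hand-evaluated terms for one acceptor at surface distance d."""
        for d in (-0.7, -0.3, 0.0, 0.5, 1.5):
            r = d + WATER_O_RADIUS + VDW_RADII["O"]
            pos = [r, 0.0, 0.0]
            g1 = math.exp(-((d / 0.5) ** 2))
            g2 = math.exp(-(((d - 3.0) / 2.0) ** 2))
            rep = d * d if d < 0 else 0.0
            hb = 1.0 if d <= -0.7 else (-d / 0.7 if d < 0 else 0.0)
            expected = (VINA_WEIGHTS["gauss1"] * g1
                        + VINA_WEIGHTS["gauss2"] * g2
                        + VINA_WEIGHTS["repulsion"] * rep
                        + VINA_WEIGHTS["hbond"] * hb)
            assert score_water_at(single_acceptor, pos) == pytest.approx(
                expected, abs=1e-12), d

    def test_hbond_inactive_for_hydrophobic_partner(self):
        st = make_structure([[0, 0, 0]], ["C"], types=[HYDROPHOBIC])
        d = -0.7
        r = d + WATER_O_RADIUS + VDW_RADII["C"]
        e = score_water_at(st, [r, 0, 0])
        expected = (VINA_WEIGHTS["gauss1"] * math.exp(-((d / 0.5) ** 2))
                    + VINA_WEIGHTS["gauss2"] * math.exp(-(((d - 3.0) / 2.0) ** 2))
                    + VINA_WEIGHTS["repulsion"] * d * d)
        assert e == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self, pocket_bundle, rng):
        from scipy.spatial.transform import Rotation

        pocket, _, planted = pocket_bundle
        pos = planted[0]
        e0 = score_water_at(pocket, pos)
        rot = Rotation.from_euler("xyz", rng.uniform(0, 360, 3), degrees=True)
        t = rng.uniform(-20, 20, 3)
        moved = make_structure(pocket.coords @ rot.as_matrix().T + t,
                               pocket.element,
                               types=list(pocket.interaction_types))
        e1 = score_water_at(moved, rot.as_matrix() @ pos + t)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_additive_over_atom_subsets(self, pocket_bundle):
        pocket, _, planted = pocket_bundle
        pos = planted[0] + np.array([0.3, 0.1, -0.2])
        half = pocket.n_atoms // 2
        parts = []
        for sl in (slice(None, half), slice(half, None)):
            sub = make_structure(pocket.coords[sl], pocket.element[sl],
                                 types=list(pocket.interaction_types[sl]))
            parts.append(score_water_at(sub, pos))
        assert sum(parts) == pytest.approx(score_water_at(pocket, pos), abs=1e-12)

    def test_empty_neighbourhood_scores_zero(self):
        st = make_structure(np.zeros((0, 3)), [])
        assert score_water_at(st, [0, 0, 0]) == 0.0


class TestLocalRefine:
    def test_uniform_field_returns_seed(self):
        st = make_structure([[50.0, 0, 0]], ["O"], types=[ACCEPTOR])
        seed = np.array([0.0, 0.0, 0.0])
        res = local_refine(st, seed)
        np.testing.assert_array_equal(res.best_coords, seed)
        assert res.energy == 0.0

    def test_refined_energy_never_above_seed_energy(self, pocket_bundle):
        pocket, ligand, _ = pocket_bundle
        from aquabridge.functional_groups import detect_motifs
        from aquabridge.hydration_model import build_all_shells

        for s in build_all_shells(ligand, detect_motifs(ligand)):
            res = local_refine(pocket, s.coords)
            assert res.energy <= score_water_at(pocket, s.coords) + 1e-12

    def test_stays_inside_box(self, pocket_bundle):
        pocket, _, planted = pocket_bundle
        params = ScoringParams()
        seed = planted[0] + 0.1
        res = local_refine(pocket, seed, params)
        assert np.linalg.norm(res.best_coords - seed) <= \
            params.box_half_width * math.sqrt(3) + 1e-9

    def test_finds_planted_minimum_against_dense_oracle(self, single_acceptor):
        """Seed offset from the optimum; grid search lands within one step
        of the dense 0.01 A brute-force minimum."""
        # optimum surface distance for a single acceptor pair
        seed = np.array([WATER_O_RADIUS + VDW_RADII["O"] - 0.3, 0.0, 0.0])
        params = ScoringParams()
        res = local_refine(single_acceptor, seed, params)

        # dense 0.01 A brute force, evaluated with independent arithmetic
        step = 0.01
        off = np.arange(-0.25, 0.25 + 1e-9, step)
        gx, gy, gz = np.meshgrid(off, off, off, indexing="ij")
        pts = seed + np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        d = np.linalg.norm(pts, axis=1) - WATER_O_RADIUS - VDW_RADII["O"]
        e = (VINA_WEIGHTS["gauss1"] * np.exp(-((d / 0.5) ** 2))
             + VINA_WEIGHTS["gauss2"] * np.exp(-(((d - 3.0) / 2.0) ** 2))
             + VINA_WEIGHTS["repulsion"] * np.where(d < 0, d * d, 0.0)
             + VINA_WEIGHTS["hbond"] * np.clip(-d / 0.7, 0.0, 1.0))
        k = int(np.argmin(e))
        # the single-pair minimum is a spherical shell about the acceptor,
        # so compare the optimal radius and energy, not the point itself
        assert np.linalg.norm(res.best_coords) == pytest.approx(
            np.linalg.norm(pts[k]), abs=params.grid_step * math.sqrt(3))
        assert res.energy == pytest.approx(float(e[k]), abs=5e-3)

    def test_monotone_in_box_half_width(self, pocket_bundle):
        pocket, _, planted = pocket_bundle
        seed = planted[0] + np.array([0.05, -0.05, 0.1])
        energies = [
            local_refine(pocket, seed,
                         ScoringParams(box_half_width=h, grid_step=0.05)).energy
            for h in (0.05, 0.15, 0.25, 0.35)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))


class TestExternalBackend:
    def test_missing_executable_is_fatal(self, pocket_bundle):
        from aquabridge.hydration_model import HydrationSite
        from aquabridge.water_scoring import score_backend_external

        pocket, _, planted = pocket_bundle
        site = HydrationSite(coords=planted[0], motif_id=0, polar_atom=0)
        with pytest.raises(RuntimeError, match="not found"):
            score_backend_external(pocket, [site],
                                   vina_executable="definitely-not-a-binary")

    def test_empty_site_list(self, pocket_bundle):
        from aquabridge.water_scoring import score_backend_external

        pocket, _, _ = pocket_bundle
        assert score_backend_external(pocket, []) == []

    def test_stub_executable_roundtrip(self, tmp_path, pocket_bundle, monkeypatch):
        """A stub 'vina' emitting well-formed output exercises the parser;
        a malformed stub triggers the diagnostic naming the site."""
        import stat

        from aquabridge.hydration_model import HydrationSite
        from aquabridge.water_scoring import score_backend_external

        pocket, _, planted = pocket_bundle
        good = tmp_path / "vina"
        good.write_text(
            "#!/bin/sh\n"
            'out=""\n'
            'while [ $# -gt 0 ]; do\n'
            '  if [ "$1" = "--out" ]; then out="$2"; fi\n'
            "  shift\n"
            "done\n"
            'printf "REMARK VINA RESULT:    -1.23      0.000      0.000\\n" > "$out"\n'
            'printf "ATOM      1  O   HOH W   1       1.000   2.000   3.000  1.00  0.00\\n" >> "$out"\n'
        )
        good.chmod(good.stat().st_mode | stat.S_IEXEC)
        monkeypatch.setenv("PATH", f"{tmp_path}:/usr/bin:/bin")
        site = HydrationSite(coords=planted[0], motif_id=0, polar_atom=0)
        (res,) = score_backend_external(pocket, [site], vina_executable="vina")
        assert res.energy == pytest.approx(-1.23)
        np.testing.assert_allclose(res.best_coords, [1.0, 2.0, 3.0])

        good.write_text("#!/bin/sh\nexit 0\n")  # produces no output file
        with pytest.raises(RuntimeError, match="site 0"):
            score_backend_external(pocket, [site], vina_executable="vina")
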